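"""Closed-form calculators for lentiviral-vector characterization assays.

Covers the arithmetic that accompanies a vector screen: droplet digital PCR
(ddPCR) Poisson quantification and vector copy number (VCN), functional
titer, restimulation-induced cell death (RICD) percent loss, NK-cell
cytotoxicity normalization, fluorescence-intensity fold changes, and the
ordinary-least-squares regression of titer against proviral size.

All operations are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class DdpcrWell:
    """One ddPCR well: droplet partition counts plus reaction geometry.

    ``droplet_volume`` is in µL (Bio-Rad droplet readers assume 0.85 nL);
    ``dilution_factor`` scales the estimated concentration back to the
    undiluted sample.
    """

    total_droplets: int
    positive_droplets: int
    droplet_volume: float = 0.00085
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.total_droplets < 0 or self.positive_droplets < 0:
            raise ValueError("droplet counts must be non-negative")
        if self.positive_droplets > self.total_droplets:
            raise ValueError("positive droplets exceed total droplets")
        if self.droplet_volume <= 0:
            raise ValueError("droplet volume must be positive")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")


@dataclass(frozen=True)
class TitrationRecord:
    """Inputs of the transducing-unit titer formula.

    vcn: vector copies per cell measured at the titration endpoint;
    cells_at_transduction: cells plated when virus was added;
    dilution: fold dilution of the supernatant applied (10 for 1:10).
    """

    vcn: float
    cells_at_transduction: float
    dilution: float

    def __post_init__(self) -> None:
        if self.vcn < 0:
            raise ValueError("vcn must be non-negative")
        if self.cells_at_transduction <= 0 or self.dilution <= 0:
            raise ValueError("cell count and dilution must be positive")


@dataclass(frozen=True)
class CytotoxRecord:
    """Live target-cell events from one effector:target co-culture well."""

    live_target_count_treated: float
    live_target_count_target_only: float
    effector_to_target_ratio: str = ""

    def __post_init__(self) -> None:
        if self.live_target_count_treated < 0:
            raise ValueError("treated count must be non-negative")
        if self.live_target_count_target_only <= 0:
            raise ValueError("target-only control count must be positive")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float


class UnquantifiableWell(ValueError):
    """Raised when a ddPCR well is saturated or empty and λ cannot be inferred."""


def ddpcr_concentration(well: DdpcrWell) -> float:
    """Target concentration (copies/µL, dilution-corrected) from droplet counts.

    Droplets are independent Poisson partitions, so the per-droplet mean
    occupancy is recovered from the positive fraction p as λ = −ln(1 − p),
    and concentration = λ / droplet_volume × dilution_factor.
    """
    if well.total_droplets == 0:
        raise UnquantifiableWell("no droplets in well")
    if well.positive_droplets == well.total_droplets:
        raise UnquantifiableWell("saturated well: every droplet positive")
    p = well.positive_droplets / well.total_droplets
    lam = -np.log1p(-p)
    return float(lam / well.droplet_volume * well.dilution_factor)


def vcn_from_ddpcr(
    psi_well: DdpcrWell,
    reference_well: DdpcrWell,
    reference_copies_per_genome: int = 2,
) -> float:
    """Vector copies per cell from a vector-target well and an autosomal
    reference-gene well.

    The reference gene is present at ``reference_copies_per_genome`` copies
    per cell (2 for a diploid autosomal locus), so
    VCN = reference_copies_per_genome × conc(vector) / conc(reference).
    """
    psi = ddpcr_concentration(psi_well)
    ref = ddpcr_concentration(reference_well)
    if ref <= 0:
        raise ValueError("reference concentration is zero: invalid reference well")
    return float(reference_copies_per_genome * psi / ref)


def titer(record: TitrationRecord, volume_ml: float = 1.0) -> float:
    """Functional titer in TU/mL: TU = VCN × cells at transduction × dilution.

    Assumes the transduction volume ``volume_ml`` (1 mL in the standard
    protocol); TU/mL divides total transducing units by that volume.
    """
    if volume_ml <= 0:
        raise ValueError("transduction volume must be positive")
    return record.vcn * record.cells_at_transduction * record.dilution / volume_ml


def ricd_cell_loss(live_restimulated: float, live_untreated: float) -> float:
    """Percent cell loss after TCR restimulation.

    percent loss = [1 − (live restimulated / live untreated)] × 100, using
    live (PI-negative) event counts. A negative value (outgrowth under
    restimulation) is returned as-is.
    """
    if live_untreated <= 0:
        raise ValueError("untreated control count must be positive")
    if live_restimulated < 0:
        raise ValueError("restimulated count must be non-negative")
    return (1.0 - live_restimulated / live_untreated) * 100.0


def nk_percent_killing(record: CytotoxRecord, floor: float | None = None) -> float:
    """Percent killing from live target counts, normalized to target-only wells.

    percent killing = (1 − treated / target_only) × 100. Negative values
    (more targets than control, within counting noise) are reported as-is
    unless a ``floor`` is given, in which case they are clipped up to it.
    """
    pct = (1.0 - record.live_target_count_treated / record.live_target_count_target_only) * 100.0
    if floor is not None:
        pct = max(pct, floor)
    return pct


def mfi_fold_change(mfi_condition: float, mfi_reference: float) -> float:
    """Fold change of mean fluorescence intensity over a reference condition."""
    if mfi_reference <= 0:
        raise ValueError("reference MFI must be positive")
    return mfi_condition / mfi_reference


def titer_size_regression(
    points: list[tuple[float, float]],
    log_transform_titer: bool = False,
) -> RegressionResult:
    """OLS of titer on proviral length; optionally on log10(titer).

    Larger proviruses package less efficiently, so titer declines with
    insert size; R² summarizes how much of the titer variation size
    explains. Requires ≥3 points with non-constant lengths.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for a regression")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate design: proviral lengths are constant")
    if log_transform_titer:
        if np.any(y <= 0):
            raise ValueError("log transform requires positive titers")
        y = np.log10(y)
    if np.allclose(y, y[0]):
        # flat response: the zero-slope line fits with nothing to explain
        return RegressionResult(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
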