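"""RNA/gDNA barcode-ratio activity scoring for pooled enhancer screens.

The screen's estimator: within a lineage, each barcode's RNA read frequency
(transcription) is divided by its gDNA read frequency (integration
abundance), cancelling differences in transduction efficiency and pool
representation. Duplicate barcodes of a construct are reconciled by
geometric mean — the natural average for a multiplicative ratio — and every
element's activity is expressed as fold over the promoter-only construct in
the same lineage, whose fold is therefore exactly 1. Folds are binned into
the screen's activity classes:

    none ≤ 1 < minimal ≤ 1.25 < low ≤ 1.5 < medium ≤ 2 < high

(intervals left-open/right-closed; "high" is strictly greater than 2-fold).

A small pseudocount stabilizes ratios for shallowly covered barcodes, and
barcodes below a minimum gDNA count are excluded from reconciliation rather
than contributing unstable ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode_quant import ScreenCounts
from .synthetic_data import LibraryDesign

CLASS_ORDER = ("none", "minimal", "low", "medium", "high")


@dataclass(frozen=True)
class ClassThresholds:
    """Lower bounds (fold units) of the activity classes; strictly increasing.

    A fold at or below ``minimal_lo`` is "none"; each class covers the
    left-open/right-closed interval up to the next bound; above ``high_lo``
    is "high".
    """

    minimal_lo: float = 1.0
    low_lo: float = 1.25
    medium_lo: float = 1.5
    high_lo: float = 2.0

    def __post_init__(self) -> None:
        bounds = (self.minimal_lo, self.low_lo, self.medium_lo, self.high_lo)
        if not all(a < b for a, b in zip(bounds, bounds[1:])):
            raise ValueError("class boundaries must be strictly increasing")


def classify_activity(fold: float, thresholds: ClassThresholds | None = None) -> str:
    """Map a fold-over-promoter value to its activity class."""
    if not fold > 0 or not math.isfinite(fold):
        raise ValueError(f"fold must be a positive finite number, got {fold}")
    t = thresholds or ClassThresholds()
    if fold <= t.minimal_lo:
        return "none"
    if fold <= t.low_lo:
        return "minimal"
    if fold <= t.medium_lo:
        return "low"
    if fold <= t.high_lo:
        return "medium"
    return "high"


def barcode_ratios(
    counts: ScreenCounts,
    library: LibraryDesign,
    pseudocount: float = 0.5,
    min_dna_count: int = 10,
) -> pd.DataFrame:
    """Per-(barcode, lineage) RNA/gDNA frequency ratios.

    For barcode b in lineage l:
    ratio = ((RNA_b + pc) / Σ(RNA + pc)) / ((DNA_b + pc) / Σ(DNA + pc)).
    Barcodes with raw gDNA count below ``min_dna_count`` get filtered=True
    and are excluded from duplicate reconciliation. A lineage with zero
    assigned gDNA reads is unquantifiable and aborts with a diagnostic.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts.check_conservation()
    b2e = library.barcode_to_element
    barcode_ids = library.barcode_ids
    lineages = sorted({lin for lin, _ in counts.counts})
    rows = []
    for lin in lineages:
        dna = counts.counts.get((lin, "gDNA"))
        rna = counts.counts.get((lin, "RNA"))
        if dna is None or rna is None:
            raise ValueError(f"lineage {lin!r} lacks a gDNA or RNA fraction")
        dna_vec = np.array([dna.get(b, 0) for b in barcode_ids], dtype=float)
        rna_vec = np.array([rna.get(b, 0) for b in barcode_ids], dtype=float)
        if dna_vec.sum() == 0:
            raise ValueError(
                f"lineage {lin!r} has zero assigned gDNA reads; cannot normalize"
            )
        dna_freq = (dna_vec + pseudocount) / (dna_vec + pseudocount).sum()
        rna_freq = (rna_vec + pseudocount) / (rna_vec + pseudocount).sum()
        ratio = rna_freq / dna_freq
        for i, b in enumerate(barcode_ids):
            rows.append(
                {
                    "lineage": lin,
                    "barcode_id": b,
                    "element_id": b2e[b],
                    "rna_count": int(rna_vec[i]),
                    "dna_count": int(dna_vec[i]),
                    "rna_freq": rna_freq[i],
                    "dna_freq": dna_freq[i],
                    "ratio": ratio[i],
                    "filtered": bool(dna_vec[i] < min_dna_count),
                }
            )
    return pd.DataFrame(rows)


def reconcile_duplicates(
    ratios: pd.DataFrame,
    library: LibraryDesign,
    method: str = "geometric_mean",
) -> pd.DataFrame:
    """Collapse a construct's duplicate barcodes to one activity per lineage.

    activity = geometric mean of the unfiltered barcode ratios;
    duplicate_cv = sample coefficient of variation of those ratios (NaN for
    a single surviving barcode). Constructs whose barcodes are all filtered
    appear with activity NaN (missing, not zero).
    """
    if method != "geometric_mean":
        raise ValueError(f"unknown reconciliation method {method!r}")
    rows = []
    for (lin, eid), grp in ratios.groupby(["lineage", "element_id"], sort=False):
        kept = grp.loc[~grp["filtered"], "ratio"].to_numpy(dtype=float)
        if kept.size == 0:
            activity = float("nan")
            cv = float("nan")
        else:
            activity = float(np.exp(np.mean(np.log(kept))))
            cv = (
                float(np.std(kept, ddof=1) / np.mean(kept))
                if kept.size > 1
                else float("nan")
            )
        rows.append(
            {
                "lineage": lin,
                "element_id": eid,
                "activity": activity,
                "duplicate_cv": cv,
                "n_barcodes": int(kept.size),
            }
        )
    return pd.DataFrame(rows)


def fold_over_promoter(
    activities: pd.DataFrame,
    library: LibraryDesign,
) -> pd.DataFrame:
    """Normalize each element's activity to the promoter-only construct.

    fold(e, l) = activity(e, l) / activity(promoter_only, l); the
    promoter-only construct's fold is exactly 1 in every lineage. A lineage
    whose promoter-only activity is missing or non-positive aborts.
    """
    promoter_id = next(
        c.element_id for c in library.constructs if c.category == "promoter_only"
    )
    out = activities.copy()
    out["fold"] = np.nan
    for lin, grp in activities.groupby("lineage", sort=False):
        base_rows = grp.loc[grp["element_id"] == promoter_id, "activity"]
        if base_rows.empty or not np.isfinite(base_rows.iloc[0]) or base_rows.iloc[0] <= 0:
            raise ValueError(
                f"promoter-only activity missing or non-positive in lineage {lin!r}"
            )
        base = float(base_rows.iloc[0])
        mask = out["lineage"] == lin
        out.loc[mask, "fold"] = out.loc[mask, "activity"] / base
        out.loc[mask & (out["element_id"] == promoter_id), "fold"] = 1.0
    return out


def specificity_summary(
    folds: pd.DataFrame,
    on_target: tuple[str, ...],
    off_target: tuple[str, ...],
    on_cutoff: float = 1.25,
    off_cutoff: float = 1.25,
) -> pd.DataFrame:
    """Per-element lineage-specificity call.

    An element is "specific" when its weakest on-target fold exceeds
    ``on_cutoff`` and its strongest off-target fold stays at or below
    ``off_cutoff`` — activity where it belongs, silence where it does not.
    """
    on, off = set(on_target), set(off_target)
    if on & off:
        raise ValueError("on_target and off_target lineage sets must be disjoint")
    present = set(folds["lineage"])
    missing = (on | off) - present
    if missing:
        raise ValueError(f"lineages {sorted(missing)} absent from fold table")
    rows = []
    for eid, grp in folds.groupby("element_id", sort=False):
        on_folds = grp.loc[grp["lineage"].isin(on), "fold"]
        off_folds = grp.loc[grp["lineage"].isin(off), "fold"]
        min_on = float(on_folds.min()) if not on_folds.empty else float("nan")
        max_off = float(off_folds.max()) if not off_folds.empty else float("nan")
        specific = bool(
            np.isfinite(min_on)
            and min_on > on_cutoff
            and (off_folds.empty or (np.isfinite(max_off) and max_off <= off_cutoff))
        )
        rows.append(
            {
                "element_id": eid,
                "min_on_target_fold": min_on,
                "max_off_target_fold": max_off,
                "specific": specific,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ActivityTable:
    """Scored screen: barcode-level ratios and element-level activities.

    ``element_level`` carries activity, duplicate_cv, fold (over
    promoter-only) and activity_class per (element, lineage);
    ``barcode_level`` keeps the underlying per-barcode ratios for QC.
    """

    barcode_level: pd.DataFrame
    element_level: pd.DataFrame
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)

    def fold_matrix(self) -> pd.DataFrame:
        return self.element_level.pivot(
            index="element_id", columns="lineage", values="fold"
        )

    def class_matrix(self) -> pd.DataFrame:
        return self.element_level.pivot(
            index="element_id", columns="lineage", values="activity_class"
        )


def score_screen(
    counts: ScreenCounts,
    library: LibraryDesign,
    pseudocount: float = 0.5,
    min_dna_count: int = 10,
    thresholds: ClassThresholds | None = None,
) -> ActivityTable:
    """Full scoring pass: ratios → duplicate reconciliation → fold → class."""
    t = thresholds or ClassThresholds()
    ratios = barcode_ratios(counts, library, pseudocount, min_dna_count)
    activities = reconcile_duplicates(ratios, library)
    folds = fold_over_promoter(activities, library)
    folds["activity_class"] = [
        classify_activity(f, t) if np.isfinite(f) and f > 0 else "missing"
        for f in folds["fold"]
    ]
    return ActivityTable(barcode_level=ratios, element_level=folds, thresholds=t)
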