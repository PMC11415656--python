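"""Synthetic barcoded enhancer screens with known ground truth.

Emulates the data a pooled lentiviral reporter screen produces. A library of
candidate enhancer constructs — each carrying duplicate 20-nt barcodes, plus
a promoter-only construct (baseline) and a ubiquitous-promoter control — is
"transduced" into several cell lineages at low vector copy number. Vector
integration per barcode is multinomial over an equally represented pool;
genomic-DNA read abundance is proportional to integration, and RNA read
abundance to integration × the element's true activity multiplier in that
lineage. Reads carry the amplicon structure anchor·barcode·anchor padded to
the read length, with independent per-base substitution errors.

Every stochastic quantity is drawn from a seeded generator and recorded in a
truth sidecar, so downstream estimates can be compared with the exact
expectations that produced the data. Assay-level fixtures (ddPCR droplet
counts, titration series, restimulation-induced-death and NK-cytotoxicity
plates) are generated the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_calcs import DdpcrWell
from .barcode_design import BarcodeSet, CompositionRules, generate_barcodes

FRACTIONS = ("gDNA", "RNA")
DEFAULT_LINEAGES = ("T", "NK", "NKT", "B_LCL")
DEFAULT_ON_TARGET = ("T", "NK", "NKT")
DEFAULT_OFF_TARGET = ("B_LCL",)
PROMOTER_ID = "Pro"
EFS_ID = "EFS"

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class Construct:
    """One vector in the pool: an element (or control) and its barcodes."""

    element_id: str
    category: str  # enhancer | promoter_only | efs_control
    barcode_ids: list[str]
    provirus_length: int

    def __post_init__(self) -> None:
        if self.category not in {"enhancer", "promoter_only", "efs_control"}:
            raise ValueError(f"unknown construct category {self.category!r}")
        if not self.barcode_ids:
            raise ValueError(f"construct {self.element_id} carries no barcode")


@dataclass
class LibraryDesign:
    """The pooled library: constructs, their barcodes, and amplicon anchors.

    ``anchor5``/``anchor3`` are the constant sequences flanking the barcode
    in the sequencing amplicon; extraction locates the barcode between them.
    """

    constructs: list[Construct]
    anchor5: str
    anchor3: str
    barcode_set: BarcodeSet

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        known = set(self.barcode_set.labels)
        n_promoter = 0
        for c in self.constructs:
            if c.category == "promoter_only":
                n_promoter += 1
            for b in c.barcode_ids:
                if b not in known:
                    raise ValueError(f"{c.element_id} references unknown barcode {b}")
                if b in seen:
                    raise ValueError(f"barcode {b} shared by {seen[b]} and {c.element_id}")
                seen[b] = c.element_id
        if n_promoter != 1:
            raise ValueError("library must contain exactly one promoter_only construct")

    @property
    def barcode_ids(self) -> list[str]:
        """All assigned barcode labels, in construct order."""
        return [b for c in self.constructs for b in c.barcode_ids]

    @property
    def barcode_to_element(self) -> dict[str, str]:
        return {b: c.element_id for c in self.constructs for b in c.barcode_ids}

    def construct(self, element_id: str) -> Construct:
        for c in self.constructs:
            if c.element_id == element_id:
                return c
        raise KeyError(element_id)

    def assigned_barcode_set(self) -> BarcodeSet:
        """The subset of the barcode set actually assigned to constructs."""
        labels = self.barcode_ids
        seqs = [self.barcode_set.sequence_of(b) for b in labels]
        return BarcodeSet(
            barcodes=seqs,
            length=self.barcode_set.length,
            min_distance=self.barcode_set.min_distance,
            seed=self.barcode_set.seed,
            constraints=self.barcode_set.constraints,
            labels=labels,
        )


@dataclass
class ScreenTruth:
    """Latent parameters of a simulated screen.

    activity maps (element_id, lineage) to the expression multiplier per
    integrated copy, with the promoter-only construct defining 1. mean_vcn
    is vector copies per cell (the screen transduces at 0.1–0.2); depth is
    reads per fraction per lineage; error_rate the per-base substitution
    probability.
    """

    activity: dict[tuple[str, str], float]
    mean_vcn: float = 0.15
    depth: int = 100_000
    error_rate: float = 0.01
    n_cells: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.activity.values()):
            raise ValueError("activity multipliers must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.mean_vcn <= 0 or self.n_cells <= 0 or self.depth <= 0:
            raise ValueError("mean_vcn, n_cells and depth must be positive")

    @property
    def lineages(self) -> list[str]:
        out: list[str] = []
        for _, lin in self.activity:
            if lin not in out:
                out.append(lin)
        return out


@dataclass
class SimulatedScreen:
    """Paths and ground truth of one emitted synthetic screen."""

    fastq_paths: dict[tuple[str, str], Path]
    truth_table: pd.DataFrame
    truth_path: Path | None = None


def simulate_library(
    n_elements: int = 34,
    barcodes_per_construct: int = 2,
    barcode_params: dict | None = None,
    provirus_length_range: tuple[int, int] = (4500, 7500),
    seed: int = 0,
    anchor_length: int = 15,
) -> LibraryDesign:
    """Build a screen library: ``n_elements`` enhancer constructs plus one
    promoter-only and one ubiquitous-promoter (EFS) control, each carrying
    ``barcodes_per_construct`` distinct barcodes.

    Amplicon anchors are drawn at random and re-drawn if they collide with
    any barcode (substring in either direction). Provirus lengths are
    uniform over ``provirus_length_range``.
    """
    if n_elements < 0:
        raise ValueError("n_elements must be >= 0")
    if barcodes_per_construct < 1:
        raise ValueError("barcodes_per_construct must be >= 1")
    params = {"length": 20, "min_distance": 10}
    if barcode_params:
        params.update(barcode_params)
    n_constructs = n_elements + 2
    bset = generate_barcodes(
        n=n_constructs * barcodes_per_construct, seed=seed, **params
    )

    rng = np.random.default_rng([seed, 211])
    lo, hi = provirus_length_range
    if lo > hi:
        raise ValueError("provirus_length_range must be (low, high)")
    element_ids = [f"E{i + 1:02d}" for i in range(n_elements)] + [PROMOTER_ID, EFS_ID]
    categories = ["enhancer"] * n_elements + ["promoter_only", "efs_control"]
    lengths = rng.integers(lo, hi + 1, size=n_constructs)
    constructs = []
    for i, (eid, cat) in enumerate(zip(element_ids, categories)):
        start = i * barcodes_per_construct
        constructs.append(
            Construct(
                element_id=eid,
                category=cat,
                barcode_ids=bset.labels[start : start + barcodes_per_construct],
                provirus_length=int(lengths[i]),
            )
        )

    anchor5, anchor3 = _draw_anchors(bset, anchor_length, rng)
    return LibraryDesign(
        constructs=constructs, anchor5=anchor5, anchor3=anchor3, barcode_set=bset
    )


def _draw_anchors(
    bset: BarcodeSet, anchor_length: int, rng: np.random.Generator, max_tries: int = 100
) -> tuple[str, str]:
    anchors: list[str] = []
    for _ in range(max_tries):
        cand = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=anchor_length))
        if any(cand in bc or bc in cand for bc in bset.barcodes):
            continue
        if cand in anchors:
            continue
        anchors.append(cand)
        if len(anchors) == 2:
            return anchors[0], anchors[1]
    raise RuntimeError("could not draw collision-free amplicon anchors")


def make_default_truth(
    library: LibraryDesign,
    lineages: tuple[str, ...] = DEFAULT_LINEAGES,
    on_target: tuple[str, ...] = DEFAULT_ON_TARGET,
    seed: int = 0,
    headline_element: str | None = None,
    headline_activity: float = 4.0,
    mean_vcn: float = 0.15,
    depth: int = 100_000,
    error_rate: float = 0.01,
    n_cells: int = 100_000,
) -> ScreenTruth:
    """Default true-activity landscape for a simulated screen.

    On-target lineages get element multipliers log-uniform in [0.8, 4.0]
    (the screen's observed range tops out near 4-fold over promoter);
    off-target lineages log-uniform in [0.8, 1.3] (mostly inactive). One
    designated headline element is pinned to exactly ``headline_activity``
    (default 4.0) in the first on-target lineage. The promoter-only
    construct defines activity 1 everywhere; the ubiquitous EFS control is
    set to 2.0 in every lineage.
    """
    rng = np.random.default_rng([seed, 101])
    enhancers = [c.element_id for c in library.constructs if c.category == "enhancer"]
    activity: dict[tuple[str, str], float] = {}
    for lin in lineages:
        lo, hi = (0.8, 4.0) if lin in on_target else (0.8, 1.3)
        draws = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(enhancers)))
        for eid, a in zip(enhancers, draws):
            activity[(eid, lin)] = float(a)
        activity[(PROMOTER_ID, lin)] = 1.0
        if any(c.category == "efs_control" for c in library.constructs):
            activity[(EFS_ID, lin)] = 2.0
    if enhancers and on_target:
        pin = headline_element or enhancers[min(2, len(enhancers) - 1)]
        activity[(pin, on_target[0])] = float(headline_activity)
    return ScreenTruth(
        activity=activity,
        mean_vcn=mean_vcn,
        depth=depth,
        error_rate=error_rate,
        n_cells=n_cells,
        seed=seed,
    )


def _sample_lineage_counts(
    library: LibraryDesign, truth: ScreenTruth, lineage: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integration, gDNA-read and RNA-read counts per barcode for one lineage.

    Both fractions condition on the same integration realization — they come
    from the same cells — so integration noise cancels in RNA/DNA ratios.
    """
    barcode_ids = library.barcode_ids
    b2e = library.barcode_to_element
    nbar = len(barcode_ids)
    n_int = max(1, round(truth.n_cells * truth.mean_vcn))
    integrations = rng.multinomial(n_int, np.full(nbar, 1.0 / nbar))
    gdna = rng.multinomial(truth.depth, integrations / integrations.sum())
    act = np.array(
        [truth.activity[(b2e[b], lineage)] for b in barcode_ids], dtype=float
    )
    w = integrations * act
    rna = rng.multinomial(truth.depth, w / w.sum())
    return integrations, gdna, rna


def _truth_rows(
    library: LibraryDesign,
    truth: ScreenTruth,
    lineage: str,
    integrations: np.ndarray,
    gdna: np.ndarray,
    rna: np.ndarray,
) -> list[dict]:
    b2e = library.barcode_to_element
    cat = {c.element_id: c.category for c in library.constructs}
    act = np.array(
        [truth.activity[(b2e[b], lineage)] for b in library.barcode_ids], dtype=float
    )
    w = integrations * act
    rows = []
    for i, b in enumerate(library.barcode_ids):
        rows.append(
            {
                "lineage": lineage,
                "barcode_id": b,
                "element_id": b2e[b],
                "category": cat[b2e[b]],
                "activity": act[i],
                "integrations": int(integrations[i]),
                "expected_gdna_freq": integrations[i] / integrations.sum(),
                "expected_rna_freq": w[i] / w.sum(),
                "gdna_count": int(gdna[i]),
                "rna_count": int(rna[i]),
            }
        )
    return rows


def simulate_screen_counts(
    library: LibraryDesign,
    truth: ScreenTruth,
    lineages: tuple[str, ...] | None = None,
):
    """Sample per-barcode read counts without emitting reads.

    Returns a :class:`~smartscreen.barcode_quant.ScreenCounts` (every read
    assigned; no extraction/decoding noise) and the truth sidecar. Uses the
    same per-lineage random streams as :func:`simulate_screen_reads`, so the
    sampled counts match the read counts that function would emit.
    """
    from .barcode_quant import ScreenCounts

    lins = tuple(lineages) if lineages is not None else tuple(truth.lineages)
    counts: dict[tuple[str, str], dict[str, int]] = {}
    rows: list[dict] = []
    for li, lineage in enumerate(lins):
        rng = np.random.default_rng([truth.seed, li])
        integ, gdna, rna = _sample_lineage_counts(library, truth, lineage, rng)
        rows.extend(_truth_rows(library, truth, lineage, integ, gdna, rna))
        counts[(lineage, "gDNA")] = dict(zip(library.barcode_ids, gdna.tolist()))
        counts[(lineage, "RNA")] = dict(zip(library.barcode_ids, rna.tolist()))
    sc = ScreenCounts(
        counts=counts,
        unassigned={k: 0 for k in counts},
        ambiguous={k: 0 for k in counts},
        total_reads={k: sum(v.values()) for k, v in counts.items()},
    )
    return sc, pd.DataFrame(rows)


def simulate_screen_reads(
    library: LibraryDesign,
    truth: ScreenTruth,
    lineages: tuple[str, ...],
    outdir: str | Path,
    read_length: int = 150,
    quality: int = 30,
) -> SimulatedScreen:
    """Emit one gDNA and one RNA FASTQ per lineage, plus the truth sidecar.

    Each read is anchor5·barcode·anchor3 padded to ``read_length`` with a
    fixed downstream context (standing in for constant vector backbone),
    then perturbed by independent per-base substitutions at
    ``truth.error_rate``. Exactly ``truth.depth`` reads are written per
    fraction. Identical library/truth/seed give byte-identical files.
    """
    a5, a3, L = library.anchor5, library.anchor3, library.barcode_set.length
    amplicon = len(a5) + L + len(a3)
    if read_length < amplicon:
        raise ValueError(
            f"read_length {read_length} shorter than amplicon {amplicon}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pad_rng = np.random.default_rng([truth.seed, 10_007])
    pad = pad_rng.integers(0, 4, size=read_length)  # constant backbone context
    templates = np.empty((len(library.barcode_ids), read_length), dtype=np.uint8)
    a5_idx = _seq_to_idx(a5)
    a3_idx = _seq_to_idx(a3)
    for i, b in enumerate(library.barcode_ids):
        bc_idx = _seq_to_idx(library.barcode_set.sequence_of(b))
        row = np.concatenate([a5_idx, bc_idx, a3_idx, pad])[:read_length]
        templates[i] = row

    qual_line = chr(33 + quality) * read_length
    paths: dict[tuple[str, str], Path] = {}
    rows: list[dict] = []
    for li, lineage in enumerate(lineages):
        count_rng = np.random.default_rng([truth.seed, li])
        integ, gdna, rna = _sample_lineage_counts(library, truth, lineage, count_rng)
        rows.extend(_truth_rows(library, truth, lineage, integ, gdna, rna))
        read_rng = np.random.default_rng([truth.seed, li, 1])
        for fraction, cvec in (("gDNA", gdna), ("RNA", rna)):
            path = outdir / f"{lineage}_{fraction}.fastq"
            _emit_fastq(
                path, templates, cvec, truth.error_rate, read_rng,
                qual_line, f"{lineage}:{fraction}",
            )
            paths[(lineage, fraction)] = path

    truth_table = pd.DataFrame(rows)
    truth_path = outdir / "truth.tsv"
    truth_table.to_csv(truth_path, sep="\t", index=False)
    return SimulatedScreen(fastq_paths=paths, truth_table=truth_table, truth_path=truth_path)


def _seq_to_idx(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (idx == 255).any():
        raise ValueError(f"non-ACGT base in sequence {seq!r}")
    return idx


def _emit_fastq(
    path: Path,
    templates: np.ndarray,
    counts: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
    qual_line: str,
    id_prefix: str,
) -> None:
    order = np.repeat(np.arange(len(counts)), counts)
    rng.shuffle(order)
    reads = templates[order]
    if error_rate > 0 and reads.size:
        mask = rng.random(reads.shape) < error_rate
        k = int(mask.sum())
        if k:
            reads[mask] = (reads[mask] + rng.integers(1, 4, size=k).astype(np.uint8)) % 4
    byte_mat = _BASE_LUT[reads]
    n, L = byte_mat.shape if byte_mat.size else (0, templates.shape[1])
    blob = byte_mat.tobytes().decode("ascii")
    with open(path, "w") as fh:
        chunk: list[str] = []
        for i in range(n):
            chunk.append(
                f"@{id_prefix}:{i}\n{blob[i * L:(i + 1) * L]}\n+\n{qual_line}\n"
            )
            if len(chunk) == 50_000:
                fh.write("".join(chunk))
                chunk = []
        fh.write("".join(chunk))


# ---------------------------------------------------------------------------
# assay-level fixtures


def simulate_ddpcr(
    true_copies_per_ul: float,
    droplets: int = 20_000,
    droplet_volume: float = 0.00085,
    seed: int = 0,
    dilution_factor: float = 1.0,
) -> DdpcrWell:
    """Simulate droplet partitioning of a target at known concentration.

    Each droplet is positive independently with probability
    1 − exp(−c·v) where c is the loaded concentration (true concentration
    over the dilution factor) and v the droplet volume in µL.
    """
    if true_copies_per_ul < 0:
        raise ValueError("concentration must be non-negative")
    if droplets <= 0 or droplet_volume <= 0 or dilution_factor <= 0:
        raise ValueError("droplets, droplet_volume and dilution_factor must be positive")
    rng = np.random.default_rng(seed)
    p = -np.expm1(-(true_copies_per_ul / dilution_factor) * droplet_volume)
    positive = int(rng.binomial(droplets, p))
    return DdpcrWell(
        total_droplets=droplets,
        positive_droplets=positive,
        droplet_volume=droplet_volume,
        dilution_factor=dilution_factor,
    )


def simulate_assay_counts(
    kind: str, params: dict, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event-count fixtures for the plate-level assay calculators.

    kind="ricd": live (PI−) counts for restimulated vs untreated wells at
    each stimulation condition, Poisson around means set by the true percent
    loss. kind="nk_killing": live target counts for treated vs target-only
    wells per effector:target ratio. kind="titration": replicate VCN
    measurements from Poisson integration at the VCN implied by the true
    titer. Returns (records, truth) tables.
    """
    rng = np.random.default_rng([seed, 13])
    if kind == "ricd":
        loss = params["true_loss_pct"]
        mean_untreated = float(params.get("untreated_mean", 50_000))
        reps = int(params.get("replicates", 3))
        rec, tru = [], []
        for cond, pct in loss.items():
            tru.append({"condition": cond, "true_loss_pct": float(pct)})
            for r in range(reps):
                rec.append(
                    {
                        "condition": cond,
                        "replicate": r + 1,
                        "live_untreated": int(rng.poisson(mean_untreated)),
                        "live_restimulated": int(
                            rng.poisson(mean_untreated * (1 - pct / 100.0))
                        ),
                    }
                )
        return pd.DataFrame(rec), pd.DataFrame(tru)
    if kind == "nk_killing":
        killing = params["true_killing_pct"]
        mean_targets = float(params.get("target_only_mean", 10_000))
        reps = int(params.get("replicates", 3))
        rec, tru = [], []
        for ratio, pct in killing.items():
            tru.append({"et_ratio": ratio, "true_killing_pct": float(pct)})
            for r in range(reps):
                rec.append(
                    {
                        "et_ratio": ratio,
                        "replicate": r + 1,
                        "live_target_treated": int(
                            rng.poisson(mean_targets * (1 - pct / 100.0))
                        ),
                        "live_target_only": int(rng.poisson(mean_targets)),
                    }
                )
        return pd.DataFrame(rec), pd.DataFrame(tru)
    if kind == "titration":
        true_titer = float(params["true_titer"])
        cells = float(params.get("cells", 1e5))
        dilution = float(params.get("dilution", 10))
        reps = int(params.get("replicates", 3))
        true_vcn = true_titer / (cells * dilution)
        rec = [
            {
                "replicate": r + 1,
                "vcn": rng.poisson(cells * true_vcn) / cells,
                "cells_at_transduction": cells,
                "dilution": dilution,
            }
            for r in range(reps)
        ]
        tru = [{"true_titer": true_titer, "true_vcn": true_vcn}]
        return pd.DataFrame(rec), pd.DataFrame(tru)
    raise ValueError(f"unknown assay kind {kind!r}")


# ---------------------------------------------------------------------------
# library serialization


def write_library_tsv(library: LibraryDesign, path: str | Path) -> None:
    """Long-format library table; anchors and code parameters ride in
    '#'-prefixed header lines so one file round-trips the whole design."""
    rows = []
    for c in library.constructs:
        for b in c.barcode_ids:
            rows.append(
                {
                    "element_id": c.element_id,
                    "category": c.category,
                    "barcode_id": b,
                    "barcode_seq": library.barcode_set.sequence_of(b),
                    "provirus_length": c.provirus_length,
                }
            )
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# anchor5={library.anchor5}\n")
        fh.write(f"# anchor3={library.anchor3}\n")
        fh.write(f"# barcode_length={library.barcode_set.length}\n")
        fh.write(f"# min_distance={library.barcode_set.min_distance}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_library_tsv(path: str | Path) -> LibraryDesign:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    for key in ("anchor5", "anchor3", "barcode_length", "min_distance"):
        if key not in meta:
            raise ValueError(f"library TSV missing '# {key}=' header line")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"element_id": str})
    labels, seqs = [], []
    for _, row in df.drop_duplicates("barcode_id").iterrows():
        labels.append(str(row["barcode_id"]))
        seqs.append(str(row["barcode_seq"]).upper())
    bset = BarcodeSet(
        barcodes=seqs,
        length=int(meta["barcode_length"]),
        min_distance=int(meta["min_distance"]),
        seed=None,
        constraints=CompositionRules(),
        labels=labels,
    )
    constructs = []
    for eid, grp in df.groupby("element_id", sort=False):
        constructs.append(
            Construct(
                element_id=str(eid),
                category=str(grp["category"].iloc[0]),
                barcode_ids=[str(b) for b in grp["barcode_id"]],
                provirus_length=int(grp["provirus_length"].iloc[0]),
            )
        )
    return LibraryDesign(
        constructs=constructs,
        anchor5=meta["anchor5"],
        anchor3=meta["anchor3"],
        barcode_set=bset,
    )
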