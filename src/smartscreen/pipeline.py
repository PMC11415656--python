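"""Pipeline orchestration: simulate → count → score → report.

One configuration file drives a full reproducible run. In simulation mode
(the default) the pipeline builds the library, emits per-lineage gDNA/RNA
FASTQ files with a truth sidecar, demultiplexes them, scores activities and
writes the fold/class matrices plus a specificity summary. With
``library``/``reads_manifest`` paths set, the simulation stage is skipped
and existing FASTQs are counted instead. Every artifact written is listed
in a JSON manifest; identical config + seed reproduce byte-identical
tabular outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import activity_scoring, barcode_design, barcode_quant, synthetic_data
from .activity_scoring import ActivityTable, ClassThresholds, score_screen
from .barcode_quant import DecodeParams, count_barcodes
from .synthetic_data import (
    DEFAULT_LINEAGES,
    DEFAULT_OFF_TARGET,
    DEFAULT_ON_TARGET,
    LibraryDesign,
    make_default_truth,
    read_library_tsv,
    simulate_library,
    simulate_screen_reads,
    write_library_tsv,
)

logger = logging.getLogger("smartscreen.pipeline")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; unknown config keys are rejected.

    Simulation fields (n_elements … read_length) apply when no ``library``
    path is given; decode/scoring fields apply always.
    """

    seed: int = 0
    # simulation
    n_elements: int = 34
    barcodes_per_construct: int = 2
    barcode_length: int = 20
    min_distance: int = 10
    lineages: list[str] = field(default_factory=lambda: list(DEFAULT_LINEAGES))
    depth: int = 100_000
    error_rate: float = 0.01
    mean_vcn: float = 0.15
    n_cells: int = 100_000
    read_length: int = 150
    # existing-data mode
    library: str | None = None
    reads_manifest: str | None = None
    # decoding
    max_errors: int | None = 4
    anchor_mismatch_budget: int = 1
    revcomp_rescue: bool = False
    # scoring
    pseudocount: float = 0.5
    min_dna_count: int = 10
    thresholds: list[float] = field(default_factory=lambda: [1.0, 1.25, 1.5, 2.0])
    on_target: list[str] = field(default_factory=lambda: list(DEFAULT_ON_TARGET))
    off_target: list[str] = field(default_factory=lambda: list(DEFAULT_OFF_TARGET))

    def __post_init__(self) -> None:
        if len(self.thresholds) != 4 or not all(
            a < b for a, b in zip(self.thresholds, self.thresholds[1:])
        ):
            raise ConfigError("thresholds must be 4 strictly increasing fold bounds")
        if set(self.on_target) & set(self.off_target):
            raise ConfigError("on_target and off_target lineage sets must be disjoint")
        if (self.library is None) != (self.reads_manifest is None):
            raise ConfigError("library and reads_manifest must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def class_thresholds(self) -> ClassThresholds:
        return ClassThresholds(*self.thresholds)

    def decode_params(self) -> DecodeParams:
        return DecodeParams(
            max_errors=self.max_errors,
            anchor_mismatch_budget=self.anchor_mismatch_budget,
            revcomp_rescue=self.revcomp_rescue,
        )


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log")
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    handler.setFormatter(fmt)
    root = logging.getLogger("smartscreen")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def read_manifest_tsv(path: str | Path) -> dict[tuple[str, str], Path]:
    df = pd.read_csv(path, sep="\t")
    needed = {"lineage", "fraction", "path"}
    if not needed <= set(df.columns):
        raise ConfigError(f"reads manifest needs columns {sorted(needed)}")
    base = Path(path).parent
    out: dict[tuple[str, str], Path] = {}
    for _, row in df.iterrows():
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = base / p
        out[(str(row["lineage"]), str(row["fraction"]))] = p
    return out


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages and return the artifact manifest (also written as
    manifest.json). Any stage failure propagates with a stage-tagged log
    line; nothing after the failing stage is written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    manifest: dict[str, object] = {"outdir": str(outdir), "artifacts": []}
    arts: list[str] = manifest["artifacts"]  # type: ignore[assignment]

    def record(path: Path) -> Path:
        arts.append(str(path.relative_to(outdir)))
        return path

    try:
        # validate referenced inputs before writing anything, so a bad
        # config leaves no partial outputs behind
        if config.library is not None:
            if not Path(config.library).exists():
                raise ConfigError(f"library path does not exist: {config.library}")
            if not Path(config.reads_manifest).exists():
                raise ConfigError(
                    f"reads manifest does not exist: {config.reads_manifest}"
                )
            fastq_paths = read_manifest_tsv(config.reads_manifest)
            for key, p in fastq_paths.items():
                if not p.exists():
                    raise ConfigError(f"manifest path for {key} does not exist: {p}")

        config.to_yaml(record(outdir / "config.used.yaml"))

        # stage 1: library
        logger.info("stage=library start")
        if config.library is not None:
            library = read_library_tsv(config.library)
        else:
            library = simulate_library(
                n_elements=config.n_elements,
                barcodes_per_construct=config.barcodes_per_construct,
                barcode_params={
                    "length": config.barcode_length,
                    "min_distance": config.min_distance,
                },
                seed=config.seed,
            )
            write_library_tsv(library, record(outdir / "library.tsv"))
            barcode_design.write_fasta(
                library.assigned_barcode_set(), record(outdir / "barcodes.fasta")
            )
            # stage 2: reads
            logger.info("stage=simulate start")
            truth = make_default_truth(
                library,
                lineages=tuple(config.lineages),
                on_target=tuple(config.on_target),
                seed=config.seed,
                mean_vcn=config.mean_vcn,
                depth=config.depth,
                error_rate=config.error_rate,
                n_cells=config.n_cells,
            )
            sim = simulate_screen_reads(
                library,
                truth,
                tuple(config.lineages),
                outdir / "reads",
                read_length=config.read_length,
            )
            fastq_paths = sim.fastq_paths
            record(sim.truth_path)
            for p in sim.fastq_paths.values():
                record(p)
            mrows = [
                {"lineage": lin, "fraction": frac, "path": str(p.relative_to(outdir))}
                for (lin, frac), p in sim.fastq_paths.items()
            ]
            pd.DataFrame(mrows).to_csv(
                record(outdir / "reads_manifest.tsv"), sep="\t", index=False
            )

        # stage 3: count
        logger.info("stage=count start")
        counts = count_barcodes(fastq_paths, library, config.decode_params())
        counts.write_tsv(
            record(outdir / "counts.tsv"), record(outdir / "qc.tsv")
        )

        # stage 4: score
        logger.info("stage=score start")
        table = score_screen(
            counts,
            library,
            pseudocount=config.pseudocount,
            min_dna_count=config.min_dna_count,
            thresholds=config.class_thresholds(),
        )
        table.barcode_level.to_csv(
            record(outdir / "activity_barcode_level.tsv"), sep="\t", index=False
        )
        table.element_level.to_csv(
            record(outdir / "activity_long.tsv"), sep="\t", index=False
        )
        table.fold_matrix().to_csv(record(outdir / "fold_matrix.tsv"), sep="\t")
        table.class_matrix().to_csv(record(outdir / "class_matrix.tsv"), sep="\t")
        (outdir / "class_matrix.txt").write_text(
            render_class_matrix(table, config.lineages, on_target=config.on_target)
        )
        record(outdir / "class_matrix.txt")

        # stage 5: specificity
        logger.info("stage=specificity start")
        on = [l for l in config.on_target if l in set(table.element_level["lineage"])]
        off = [l for l in config.off_target if l in set(table.element_level["lineage"])]
        if on:
            summary = activity_scoring.specificity_summary(
                table.element_level, tuple(on), tuple(off)
            )
            summary.to_csv(record(outdir / "specificity.tsv"), sep="\t", index=False)

        arts.append("manifest.json")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: %d artifacts", len(arts))
        return manifest
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logging.getLogger("smartscreen").removeHandler(handler)
        handler.close()


def render_class_matrix(
    table: ActivityTable,
    lineage_order: list[str] | None = None,
    on_target: list[str] | None = None,
) -> str:
    """Plain-text element × lineage matrix of activity classes with folds.

    Each cell shows ``class(fold)``; elements are sorted by their maximum
    on-target fold (all lineages if no on-target set is given), most active
    first, so the screen's hits read from the top.
    """
    el = table.element_level
    if el.empty:
        raise ValueError("cannot render an empty activity table")
    lineages = [
        l for l in (lineage_order or sorted(el["lineage"].unique()))
        if l in set(el["lineage"])
    ]
    rank_lineages = [l for l in (on_target or lineages) if l in lineages] or lineages
    folds = el.pivot(index="element_id", columns="lineage", values="fold")
    classes = el.pivot(index="element_id", columns="lineage", values="activity_class")
    order = folds[rank_lineages].max(axis=1).sort_values(ascending=False).index
    width = max(16, max(len(l) for l in lineages) + 2)
    name_w = max(len(str(e)) for e in order) + 2
    lines = ["".join([" " * name_w] + [l.rjust(width) for l in lineages])]
    for eid in order:
        cells = []
        for lin in lineages:
            f = folds.loc[eid, lin]
            c = classes.loc[eid, lin]
            cell = f"{c}({f:.2f})" if pd.notna(f) else "missing"
            cells.append(cell.rjust(width))
        lines.append("".join([str(eid).ljust(name_w)] + cells))
    return "\n".join(lines) + "\n"
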