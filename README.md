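# smartscreen

Quantification toolkit for pooled, barcoded lentiviral enhancer screens —
the kind used to find regulatory elements that drive lineage-specific
expression (e.g., candidate *SH2D1A* enhancers active in T/NK/NKT cells but
silent in B cells), plus the closed-form assay math that accompanies vector
characterization.

## What it computes

**Barcode code design.** Each vector in the pool is tagged with a 20-nt DNA
barcode. The barcodes form an error-correcting code with minimum pairwise
Hamming distance *d* = 10, so a read with up to ⌊(d−1)/2⌋ = 4 sequencing
substitutions is still strictly closer to its barcode of origin than to any
other barcode. `barcode_design` builds such codes by seeded greedy search
under GC-content and homopolymer constraints and verifies them exhaustively.

**Demultiplexing.** `barcode_quant` extracts barcodes from amplicon FASTQ
reads between two constant anchors (mismatch-tolerant) and assigns them by
bounded-distance decoding. Every read is routed to exactly one of
{barcode, unassigned, ambiguous}; assigned + unassigned + ambiguous = total
is asserted on every run.

**Activity scoring.** For barcode *b* in lineage *l*, the activity estimator
is the ratio of read frequencies

&nbsp;&nbsp;&nbsp;&nbsp;ratio(b, l) = f_RNA(b, l) / f_gDNA(b, l),

which cancels transduction-efficiency and pool-representation differences.
Duplicate barcodes of a construct are reconciled by geometric mean, and each
element is expressed as fold over the promoter-only construct (whose fold is
exactly 1). Folds map to activity classes: none (≤1), minimal (1–1.25],
low (1.25–1.5], medium (1.5–2], high (>2).

**Assay calculators.** ddPCR Poisson concentration λ = −ln(1 − p) per
droplet; VCN = 2 × conc(vector)/conc(diploid reference); titer
TU/mL = VCN × cells × dilution; RICD percent cell loss
= [1 − restim/untreated] × 100; NK percent killing normalized to target-only
wells; MFI fold changes; OLS of titer versus proviral size.

**Synthetic screens.** `synthetic_data` generates complete screens with
known truth: multinomial vector integration at low copy number (VCN ≈ 0.15),
gDNA reads ∝ integration, RNA reads ∝ integration × activity, per-base
substitution errors, all from one seed, with a truth sidecar that lets every
estimate be compared to its exact expectation.

## Worked example

```python
from smartscreen import (simulate_library, make_default_truth, simulate_screen_reads,
                         count_barcodes, score_screen, validate_barcode_set)

library = simulate_library(seed=1)            # 34 elements x 2 barcodes + controls
report = validate_barcode_set(library.assigned_barcode_set())
print("observed min Hamming distance:", report.observed_min_distance)

truth = make_default_truth(library, seed=1)   # pins element E03 to 4.0-fold in T cells
sim = simulate_screen_reads(library, truth, ("T", "NK", "NKT", "B_LCL"), "scratch/demo")
counts = count_barcodes(sim.fastq_paths, library)
print("assignment rate (T, RNA): %.3f" % counts.assignment_rate("T", "RNA"))

table = score_screen(counts, library)
el = table.element_level
row = el[(el.element_id == "E03") & (el.lineage == "T")].iloc[0]
print("E03 in T: fold=%.2f class=%s" % (row["fold"], row["activity_class"]))
print("promoter-only folds:", el[el.element_id == "Pro"]["fold"].tolist())
```

prints

```
observed min Hamming distance: 10
assignment rate (T, RNA): 0.980
E03 in T: fold=4.15 class=high
promoter-only folds: [1.0, 1.0, 1.0, 1.0]
```

The 72 assigned barcodes keep the designed distance-10 guarantee; with 1%
per-base error, 98% of the 10⁵ reads per fraction decode (the rest fail the
anchor check — none cross-assign); the element simulated at a true 4.0-fold
multiplier is estimated at 4.15-fold ("high" class) and the promoter-only
baseline is exactly 1 in every lineage.

The same pipeline runs from the shell:

```bash
smartscreen design-barcodes --n 70 --length 20 --min-dist 10 --seed 1 --out barcodes.fasta
smartscreen run --config run.yaml --outdir results/run1
smartscreen ricd --in ricd.csv --out ricd.tsv
```

## Layout

- `src/smartscreen/barcode_design.py` — distance-guaranteed code generation and validation
- `src/smartscreen/synthetic_data.py` — seeded screen, ddPCR and plate-assay simulators
- `src/smartscreen/barcode_quant.py` — anchor extraction + bounded-distance decoding
- `src/smartscreen/activity_scoring.py` — RNA/gDNA ratios, folds, classes, specificity
- `src/smartscreen/assay_calcs.py` — ddPCR/VCN/titer/RICD/NK/MFI/regression formulas
- `src/smartscreen/pipeline.py`, `cli.py` — orchestration, config, reporting, CLI
- `docs/methods.md` — model, assumptions, parameter choices, limitations
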