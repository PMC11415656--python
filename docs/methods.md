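# Methods

## The measurement model

A pooled screen transduces a library of reporter vectors — each carrying a
candidate enhancer upstream of a minimal promoter, plus a promoter-only
baseline construct and a ubiquitous-promoter (EFS) comparator — into several
cell lineages at low vector copy number. Each construct is identified by
duplicate 20-nt barcodes placed inside the transcript, so the same tag is
readable from genomic DNA (how many copies integrated) and from mRNA (how
much they transcribe).

For barcode *b* in lineage *l*, with read frequencies
f = count / Σ counts within a fraction, the activity estimator is

    ratio(b, l) = f_RNA(b, l) / f_gDNA(b, l).

Because both fractions come from the same cells, the integration realization
is common to numerator and denominator and cancels, as do pool-composition
and transduction-efficiency differences. This is what makes the score robust
to the (unknown) pre-transduction pool proportions. Duplicate barcodes are
combined by geometric mean — the natural mean for a multiplicative quantity —
after which each element is normalized to the promoter-only construct in the
same lineage. The promoter-only fold is therefore exactly 1 by construction,
and folds map to classes with left-open/right-closed intervals:
none (≤1), minimal (1, 1.25], low (1.25, 1.5], medium (1.5, 2], high (>2).
The right-closed convention is forced by the shared endpoints of the class
definitions together with "high" meaning strictly greater than 2-fold; a
fold of exactly 1.5 is "low" and exactly 2 is "medium". Sub-promoter
activity (fold ≤ 1, possible silencing) is reported numerically but kept in
class "none" rather than given classes of its own.

Duplicates are reconciled *before* normalization to the promoter; since the
promoter activity is a per-lineage constant, normalizing each barcode first
and then averaging would give the identical result — the ordering matters
only for how the duplicate CV is reported.

## Barcode code design and decoding

The code is built by seeded random-candidate greedy accumulation: uniform
random candidates are filtered by composition rules and accepted when at
Hamming distance ≥ d from every accepted codeword. At screen scale (70–72
codewords, length 20, d = 10) random pairs differ at ~15 positions on
average, so rejections are rare and generation takes milliseconds; the
procedure is exactly reproducible from its seed. This is deliberately not a
maximal-code construction — the screen needs tens of codewords, not
thousands.

Composition defaults are standard amplicon hygiene: GC fraction in
[0.25, 0.75] and homopolymer runs of at most 3, both configurable. Codewords
are uppercase A/C/G/T only.

A minimum distance d guarantees unique nearest-neighbor decoding within
radius ⌊(d−1)/2⌋ = 4 substitutions: a perturbed codeword is at distance ≤ 4
from its origin and, by the triangle inequality, at distance ≥ 6 from every
other codeword. The decoder is bounded-distance: a candidate with no
codeword within the radius is unassigned; two or more codewords tied at the
minimum qualifying distance is ambiguous (possible only when the radius is
raised beyond the guarantee) and such reads are excluded from counts.
Qualities are ignored — the code distance already absorbs errors — and N
bases count as mismatches to every codeword. Reads are assumed
sense-oriented; a reverse-complement rescue pass is available by flag.

Anchor search is leftmost-first: the barcode is read at the first offset
where both flanking anchors match within the mismatch budget (default 1
mismatch per 15-nt anchor). With 15-nt anchors, spurious double-anchor
contexts in random sequence are vanishingly rare (~10⁻⁷ per offset).

## The synthetic screen

The generator's defaults are the screen's stated conditions: 34 candidate
elements, each cloned with 2 distinct barcodes, plus promoter-only and EFS
control constructs (also duplicated, for uniform concordance checks);
lineages T, NK, NKT (on-target) and B-LCL (off-target); mean VCN 0.15 per
lineage (inside the protocol's 0.1–0.2 window) over 10⁵ cells; 10⁵ reads
per fraction per lineage; 1% per-base substitution error; 150-nt reads
(single-end, as from a 2×150 amplicon run).

Sampling: integrations are multinomial over barcodes with equal pool
representation; gDNA reads are multinomial with probabilities proportional
to integrations; RNA reads with probabilities proportional to
integrations × activity. True activity multipliers default to log-uniform
[0.8, 4.0] in on-target lineages — the screen's observed dynamic range tops
out near 4-fold over promoter — and log-uniform [0.8, 1.3] (essentially
inactive) off-target, with the EFS control at 2.0 everywhere and one
designated element pinned to exactly 4.0-fold in the first on-target lineage
so headline-magnitude recovery is directly checkable. The error model is
substitution-only, uniform over positions and bases (a Hamming-distance code
is the matching design assumption); no indels, no PCR jackpotting, no UMI
structure, no paired-end reads. Quality strings are constant Q30 —
syntactically valid FASTQ that the decoder ignores.

What passing tests on these simulations do **not** show about real data:
robustness to indels and primer slippage, PCR duplicate structure,
position-dependent error profiles, or unequal pool representation beyond
what the gDNA normalization removes. Pool proportions and per-vector
transduction efficiencies are exposed as configuration rather than fixed,
since the estimator's whole point is insensitivity to them.

`simulate_screen_counts` draws per-barcode counts from the same per-lineage
random streams as the FASTQ emitter without writing reads; statistical
property tests use it to reach large depths cheaply, while end-to-end tests
keep the full FASTQ → extraction → decoding path.

## Assay formulas

- ddPCR: droplets are independent Poisson partitions; λ = −ln(1 − p) from
  positive fraction p, concentration λ/v × dilution, with v = 0.85 nL by
  droplet-reader convention (configurable; saturated and empty wells are
  rejected as unquantifiable).
- VCN = reference_copies_per_genome × conc(vector target)/conc(reference),
  with a diploid autosomal reference (default 2 copies per genome).
- Titer TU/mL = VCN × cells at transduction × dilution, assuming the
  protocol's 1 mL transduction volume (a volume parameter generalizes it).
- RICD percent cell loss = [1 − (live restimulated / live untreated)] × 100;
  negative values (outgrowth) are returned as-is.
- NK percent killing = (1 − treated/target-only) × 100; negatives reported
  unless a floor is requested.
- Titer-versus-proviral-size: ordinary least squares on the raw titer scale
  by default (matching how such figures plot infectious particles against
  proviral length), log10 scale by flag; a flat response returns slope 0 and
  R² = 0.

## Numerical and design choices

- Pseudocount 0.5 added to every barcode count in both fractions;
  minimum gDNA count 10 for a barcode to enter reconciliation. Constructs
  with all barcodes filtered are reported missing (NaN), never zero.
- Fold scale-invariance under uniform count rescaling is exact at
  pseudocount 0; with a pseudocount it holds to ~pc/(2·count) relative —
  about 10⁻⁴ at the default depths — not to machine precision.
- Depth scaling follows the multinomial square-root law: quadrupling the
  read depth halves the CV of estimated activities (the property suite
  checks the ratio at two depths across 20 seeds).
- Duplicate CV is the sample SD over mean of a construct's barcode ratios;
  undefined (NaN) for a single surviving barcode.
- Determinism: every stochastic step derives its generator from the run
  seed plus a fixed stream index, so identical configuration gives
  byte-identical FASTQ and tabular outputs; emitting reads and drawing
  counts-only share the count streams.
- Specificity: an element is called specific when its minimum on-target
  fold exceeds 1.25 and its maximum off-target fold stays at or below 1.25
  (both cutoffs configurable).
- Config files are flat YAML validated against the known key set; unknown
  keys fail fast before any output is written.

## Problem sizes used in the test suite

End-to-end recovery runs use the full default screen (34 × 2 library, four
lineages, 10⁵ reads per fraction, 1% error) over 20 seeds through the
complete FASTQ path; statistical property tests use the counts-only sampler
at depths 10³–10⁵; ddPCR bias checks use 20,000 droplets × 100 seeds per
occupancy in 0.05–2. The headline-element check asserts the mean estimate
across seeds within ±10% of truth (a single seed's multinomial CV at these
depths is ~4%, so the per-seed estimate is itself usually within ±10%).

## Known limitations

- Edit-distance (indel-tolerant) decoding is out of scope; one indel inside
  the barcode usually costs the read (anchor or distance failure) but does
  not cross-assign it.
- The greedy code generator makes no optimality claim; for requests near
  the combinatorial limit it reports how many codewords it could place.
- No negative-binomial/MPRA-style dispersion model: uncertainty is conveyed
  by duplicate CV, not per-element standard errors.
- Significance testing of wet-lab panels (ANOVA/Tukey of MFI data) is
  deliberately not reimplemented; standard statistics packages cover it.
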