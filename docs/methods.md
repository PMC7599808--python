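# Methods

This note documents the models, rules and numerical choices behind
`evsmallrna`, what the synthetic benchmark does and does not emulate, and
the design decisions taken where the underlying analysis convention was
genuinely open.

## Read simulation (`refsim`)

The simulator generates libraries whose statistical structure matches
small-RNA sequencing of stem cells and their EVs:

- **miRNA reads**: a mature miRNA sequence (20–24 nt, mode 22), with
  probability `tail_prob` (default 0.25) extended by a 1–3 nt untemplated
  3′ tail drawn from {A, T} (length probabilities 0.5/0.3/0.2). Tails model
  the enzymatic 3′ adenylation/uridylation of isomiRs.
- **tRNA halves**: a cut position is drawn uniformly inside the annotated
  7-nt anticodon loop; the 5′ or 3′ piece (equal probability) is kept and
  clipped into the 30–40 nt window. 3′ halves always retain the mature 3′
  CCA end, as true acceptor-end cleavage products do.
- **tRNA fragments**: 17–26 nt windows at uniform positions.
- **Background** (rRNA/mRNA/other small RNA/genome): 20–35 nt windows of
  longer reference sequences.
- **Adapter read-through**: inserts are followed by the TruSeq small-RNA 3′
  adapter (`TGGAATTCTCGGGTGCCAAGG`) and truncated to a 50 nt read. The
  adapter itself is a configuration default, not a biological claim.
- **Errors**: per-base substitutions at `error_rate` (valid range
  [0, 0.05)); a substituted base's quality drops from the Q36 baseline to
  Q12. This is deliberately the simplest noise model that exercises the
  quality filter and the mismatch budgets.

Reference sequences are uniform-random ACGT (GC ≈ 0.5) and are screened so
that **no 17-mer occurs twice** anywhere in the reference set. Because an
ungapped alignment of length ≥ 18 with at most one mismatch must contain an
exact 17-mer from each side, no simulated read of any class can match a
wrong reference within the cascade's mismatch budgets, and 17 nt fragments
are safe because the tRNA stage is tried first and an exact hit always
beats a 1-mismatch impostor. This is what makes 100% truth recovery a
meaningful expectation rather than a statistical accident.

Per-condition defaults (class compositions per compartment and day;
isoacceptor usage with EV pools dominated by Gly-GCC, Val-AAC/Val-CAC or
Glu-CTC/Gly-CCC depending on lineage and compartment) emulate the observed
compartment differences: miRNA-dominated cells (~56–63%), tsRNA-rich EVs at
D0 (~47–52% tRNA) and the BMSC-EV tRNA collapse at D7 (→ ~14%). Within a
condition the day effect rescales a whole class; it does not single out
individual features (see the differential-expression section for the
consequence).

What the simulator does **not** emulate: sequence-dependent ligation and
PCR bias, tRNA modification-induced misincorporations or hard stops, 5′
isomiR raggedness beyond the 1 nt half-anchor tolerance, donor-level
biological covariance beyond optional composition jitter, UMIs, and real
genomic repeat structure (the genome stage is a decoy sequence set
standing in for the cascade's final catch-all). Passing recovery tests
therefore demonstrates the pipeline's correctness under its stated rules,
not robustness to every artefact of real libraries.

## Preprocessing (`preprocess`)

Per read: (1) mean Phred ≥ 20 and N-fraction ≤ 0.1 (thresholds are
conventional defaults, overridable); (2) 3′ adapter search — leftmost
occurrence with the fewest mismatches, allowing a suffix overlap of ≥ 10 nt
and a mismatch budget of ⌊0.1 × overlap⌋; (3) insert length window
[15, 45] nt, bracketing fragments (17–26), miRNAs (~22) and halves
(30–40) with margin. Reads with no detectable adapter are **retained** when
already inside the window — discarding untrimmed reads would lose fully
read-through long tsRNAs. Every input read lands in exactly one tally
(clean / low quality / too short / too long), which the `TrimStats`
invariant enforces.

## Annotation cascade (`annotate`)

Stages in fixed order: tRNA (≤1 mismatch) → miRNA (0 mismatches, 3′ A/T
tail of ≤3 nt allowed) → rRNA → mRNA → other small RNA → genome (each ≤1
mismatch) → unmapped. A read is assigned at the first stage with any hit.
Alignment is ungapped, end-to-end and sense-strand only, appropriate for
reads derived from mature transcripts. Within a stage, ties break by fewest
mismatches, then smallest reference start, then lexicographic reference
name; each read is counted exactly once (no fractional multi-mapping).

Tail calling is *minimal*: the smallest t ∈ [0, 3] such that the read minus
its last t bases (all A/T) matches a mature miRNA exactly. A terminal base
that is templated in the reference is therefore never called a tail.

The engine indexes each reference class by 7-mers and verifies candidates
found via two disjoint seeds (the read's first and last 7-mer); by
pigeonhole this enumerates every ≤1-mismatch placement for reads ≥ 14 nt,
so it is semantically identical to a full scan — an equivalence the test
suite checks against an independent brute-force oracle. The genome stage
raises if asked for a >1 mismatch budget, where two seeds would no longer
be complete.

## tsRNA typing (`tsrna`)

A tRNA-mapped read of length ≥ 30 anchored at the 5′ end (start ≤ 1) is a
5′ half; anchored at the 3′ end (end ≥ L−1) a 3′ half; length 17–29 a
fragment. The 1 nt anchor tolerance absorbs ragged termini; strict 0-only
anchoring proved too brittle a convention. Lengths 27–29 fall between the
canonical fragment (17–26) and half (30–40) windows and are classified as
fragments ("shorter than 30 nt"); reads ≥ 30 nt anchored at neither end,
and reads < 17 nt, are counted as fragments but flagged `nonstandard`.
Isoacceptor tables report percentages of all tRNA-mapped reads (majority
type per isoacceptor, ties resolved toward halves); coverage profiles
accumulate interval depth per mature tRNA and aggregate it into 100
percentile bins, where anticodon-loop halves show the characteristic
5′/3′-half pile-up. Coverage is raw depth; a normalized variant is a
display choice left to the caller.

## Differential expression (`diffexpr`)

Counts are aggregated per mature miRNA or per tRNA isoacceptor (halves and
fragments collapse onto the isoacceptor label; the dominant type is carried
as metadata). Features with raw counts < 50 in **all** samples are removed
before testing (boundary inclusive: a single sample at 50 keeps the
feature). Size factors are median-of-ratios over features with all-positive
counts, rescaled to geometric mean 1 — the median is taken in linear space,
which matters when the number of reference features is even.

The Wald test is per feature: normalized group means, pooled
method-of-moments dispersion α = max(1e-8, (s²−μ)/μ²) (variance with one
delta degree of freedom, pooled across both groups), log2FC with a 0.5
pseudocount guarding empty groups, delta-method SE from the NB variance
function, two-sided normal p, BH within each contrast and feature level.
Contrasts run independently within each (cell type, compartment) stratum,
unpaired across day — donor pairing is not modeled. All-zero features are
reported with NaN p-values and excluded from BH.

Known behaviour, verified by simulation (and deliberately accepted):

- Under 3 vs 3 nulls across means 50–1000 and dispersions 0.05–0.2 the
  test rejects at roughly 0.01–0.04 at p < 0.05 — slightly conservative,
  because the pooled dispersion absorbs between-group noise.
- Mean log2FC is recovered within ±0.2 for 4-fold effects at mean 1000
  when DE features are embedded in a null majority that anchors the size
  factors.
- A day effect that rescales an entire feature class uniformly (as the
  class-composition defaults do) is absorbed by within-level
  normalization and yields *no* feature-level calls: compositional shifts
  between classes and per-feature differential expression are distinct
  phenomena, and the demo pipeline shows this honestly.

Significance conventions: miRNAs use |log2FC| ≥ 1 and raw p < 0.05; tsRNAs
use |log2FC| ≥ 1 and BH-adjusted p < 0.05. The asymmetry (raw p for one
level, FDR for the other) reproduces the reporting convention of the
reference tables as printed rather than harmonizing it.

## Reporting (`report`)

Overlap between two DE sets decomposes the shared features into
concordant-up, concordant-down and discordant by log2FC sign; exact zeros
carry no direction and are flagged neutral rather than forced into a
class. Abundance slicing uses a strict baseMean inequality. PCA runs on
log2(normalized+1) values of the 500 most variable features, centered per
feature, via SVD with the sign of each component fixed by the first
non-vanishing loading (the transform choice is this package's documented
stand-in; rlog/vst-style variance stabilization is out of scope).
Hierarchical clustering is average-linkage Euclidean on the same
transform, with scipy's deterministic tie handling.

The packaged `data/de_tables.tsv` is a transcription of the reference
differential-expression tables (parental-cell miRNA blocks, the BMSC-EV
and ASC-EV miRNA tables, and the two tsRNA blocks with their
fragment/halve annotations); it is the desk-scale ground truth for the
overlap, slicing and tally arithmetic and round-trips unchanged through
the TSV reader.

## Problem sizes and determinism

The recovery benchmark uses 12 libraries × 10,000 reads against 30 miRNAs,
20 isoacceptors and 8 background records; calibration simulations use 500
null features (3 vs 3) and 30 embedded 4-fold features among 300 null.
These sizes give binomial/KS noise comfortably inside the asserted bands
while keeping any single check in seconds. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
configurations produce byte-identical FASTQ, truth tables and pipeline
summaries.

## Limitations

Ungapped sense-strand matching cannot place reads spanning splice or
processing junctions; the genome stage is a decoy contract, not hg38;
dispersion is unshrunken, so per-feature p-values differ from
shrinkage-based engines (strong effects agree, weak ones are called more
conservatively); and the simulator's independence assumptions make
recovery rates upper bounds on real-library performance.
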