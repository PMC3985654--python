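# Methods

## The marking model

`rgbarcode` models clonal tracking with *color-signature barcodes*:
integrating (lentiviral) vectors that each carry one fluorescent
protein — red, green or blue — plus a short DNA barcode cassette.  The
cassette alternates RANDOM and FIXED segments.  The random ("wobble")
bases individualise every vector copy; the fixed bases are identical
for all barcodes of one vector and act as a **signature** that decodes
to the vector of origin.  A cell transduced with several vectors
therefore acquires (i) a combinatorial fluorescent hue, additive over
the copies it carries, and (ii) a multiset of barcodes that can be read
back by PCR and sequencing.  Two cells belong to the same clone exactly
when their barcode sets are identical.

### Default cassette layout

`(RANDOM 2 + FIXED 3) x 7 + RANDOM 2 + FIXED 1` — eight random pairs
separated by fixed triplets, with one terminal fixed base: 16 random
and 22 fixed positions, 38 nt.  The published totals (eight random
pairs; 22 non-random positions) do not decompose into internal triplets
alone (7 x 3 = 21), so the default adds a single terminal fixed base;
the layout is a plain data structure and any alternative decomposition
is one configuration change.  The theoretical barcode space is
4^16 = 4 294 967 296 per vector.

### Signature design

Signatures are drawn by rejection sampling (bounded at 10^5 attempts,
deterministic per seed) under three constraints:

* **No restriction sites.** The cassette is cloned through XbaI
  (`TCTAGA`) and XhoI (`CTCGAG`); the scan is worst-case — every
  motif-length window of the rendered template is checked against *all*
  fills of the random positions it overlaps, so a passing template can
  never produce a site whatever bases it draws.
* **No long homopolymers.** Enforced as ≤ 3 nt on the concatenated
  22-nt fixed sequence.  Within single fixed segments (≤ 3 nt) the
  constraint would be vacuous; the concatenated reading is strictly
  stronger and keeps signatures sequence-diverse.
* **Pairwise Hamming distance ≥ 8** (default) between signatures, so
  vector assignment survives several sequencing errors per read and
  never becomes ambiguous.

## Synthetic data generator

The generator reproduces the statistical structure of a barcoded
transduction experiment; its defaults are the study conditions of the
two reference scenarios.

* **Transduction.** Integrations per cell and vector ~ Poisson(MOI),
  each drawing a fresh uniform barcode.  Reference MOIs: 1.4 per vector
  for RGB marking of a cell line (total 4.2 → 98.5% of cells marked,
  mean 4.26 copies among marked cells), MOI 4 for the single-vector
  oncogene graft.  Collisions between independently drawn barcodes are
  ignored — `expected_collisions` puts them at ~0.03 duplicates per
  half-million draws from a 4^16 space.
* **Clonal expansion.** Multinomial resampling of cells by clone at
  prescribed proportions; the remainder is spread uniformly over
  unlisted clones; genotypes are copied verbatim.
* **Reads.** Each read is `left flank + cassette + right flank` with
  constant Phred+33 'I' qualities.  Per-barcode read counts are
  multinomial with weights (copy count) x (lognormal PCR factor,
  σ = 0.5 on the log scale — a skew typical of amplicon libraries).
  Errors are i.i.d. per-base substitutions (default 10^-3); indels are
  not modelled because calling is position-anchored and
  length-preserving errors are the relevant failure mode — indel
  support is an extension point, not a silent assumption.  A flag emits
  a configurable fraction of reverse-complement reads.
* **Subclone picks.** A single cell's mixed PCR product is subcloned;
  each picked colony carries one barcode sampled uniformly over the
  copy multiset (a 2-copy barcode is twice as likely per pick).  Ten
  picks recover all three barcodes of a 3-copy cell with probability
  ~0.95; the workflow reports what the picks contained, it does not
  guarantee saturation.
* **ddPCR.** Perfect Poisson partitioning, independent channels, no
  rain.  Control occupancy λc is a parameter (default 0.5, a typical
  loading); vector occupancy is (copy number / 2) · λc because the
  control locus is autosomal with 2 copies per diploid genome.

What the generator does *not* emulate: integration-site choice and
insertional effects, quality-score structure, chimeric/index-hopped
reads, droplet rain, sample cross-contamination.  Passing tests
therefore demonstrate correctness of the calling and inference
machinery under the stated noise model, not robustness to every
artefact of real sequencers.

## Calling pipeline

1. **Extraction.** Exact left-anchor match; the following 38 bases are
   the barcode.  Reads without the anchor, truncated windows, or
   windows containing non-ACGT bases are counted as unassigned
   (assigned + unassigned = input reads; nothing is silently dropped).
   Anchor mismatch tolerance is deliberately absent by default,
   mirroring the strict fixed-position philosophy; reverse-complement
   handling is a flag.  Internal coordinates are 0-based half-open.
2. **Quality filter.** Keep entries that match some signature perfectly
   at all 22 fixed positions AND have count ≥ 10.  Both thresholds are
   parameters; the filter is idempotent and reports per-stage read
   accounting rather than one opaque pass rate.
3. **Error correction.** Directional merging, descending count order
   (ties broken lexicographically): B is absorbed into A when both
   share the exact fixed-position string, Hamming distance over the 16
   random positions ≤ 1, and count(A) ≥ 2·count(B) + 1.  The ratio
   guard separates error satellites from genuinely co-abundant
   barcodes and prevents chaining.  The absorber's count grows as it
   merges and the guard is evaluated against the running count; totals
   are conserved.  Correction runs *after* the frequency filter by
   default (the stated pipeline filters only); the order is
   configurable because correcting first can rescue low-count true
   barcodes.
4. **Decoding.** Strict mode demands a perfect signature match; with a
   min-distance-8 design a library barcode can never decode to the
   wrong color.  Tolerant mode takes the nearest signature if its
   distance is ≤ 2 and strictly smaller than all others; ties are
   `UNASSIGNED`, never guessed.

## Analysis

* **Abundance.** Per-sample normalized frequencies, ranked count-desc /
  sequence-asc; top-k (default 10) with the remainder aggregated.
* **Dominance.** Barcodes above a read-share threshold, default 10%.
  "Strongly dominant" has no canonical number; the threshold is a
  reported parameter.  Note its sensitivity: with PCR-bias σ = 0.5 a
  true founder barcode at an expected share of ~0.23 falls below 10% in
  roughly 1 run in 15; analyses that must not miss copies should set
  the threshold near the geometric midpoint of the expected per-copy
  share and the background share (the scenario test suite uses 0.03
  for its k = 1..4 sweep on exactly this reasoning).
* **ddPCR copy number.** λ = −ln(1 − positives/n) per channel; copies
  per diploid genome = 2 λv / λc (autosomal two-copy control assumed —
  sex-chromosome dosage is not modelled).  The 95% interval propagates
  Wilson binomial intervals through the same transform by taking ratio
  extremes.  Saturated vector channels and empty control channels are
  explicit failures, not numbers.
* **Clone structure.** k dominant barcodes and c copies per cell imply
  k/c clones when k is divisible by c (the ddPCR estimate is rounded
  half-up to an integer).  Multi-clone groupings additionally require
  co-occurrence support: Pearson r > 0.9 between per-sample frequency
  profiles, connected components of that graph, every component of
  size c.  Any mismatch sets `consistent = False` with a message;
  nothing is silently resolved.
* **Color prediction.** Additive model: per-channel copy counts
  normalized by the maximum channel; the hue name is the nearest entry
  of an 11-entry table (primaries, secondaries, white, and the
  tertiaries orange / pink / chartreuse / azure).  "Pink" is the
  red-dominant red+blue mix (1, 0, 0.5).  Scale- and
  permutation-invariant by construction.

## Reference scenarios and problem sizes

* *Pink clone*: a fixed genotype of 2 red + 1 blue copies, two picked
  cells, 10 subclone picks each, decoded strictly; predicted hue
  "pink"; clonal identity from the two barcode sets.
* *Leukemia*: 400 pool cells at MOI 4, a founder with k = 3 copies
  expanded to 75% of 2 000 cells (the measured leukemic share in the
  reference organs falls between 0.66 and 0.89), 30 000 reads at error
  10^-3 with PCR bias σ = 0.5, QC at min count 10, correction, 10%
  dominance threshold, 20 000 droplets at λc = 0.5.  The test suite
  scales the k-sweep variant down to 800 cells / 12 000 reads, which
  keeps every per-copy expected depth far above the QC threshold while
  the 20-seed × 4-k sweep runs in seconds.

All randomness flows from explicit integer seeds through
`numpy.random.Generator`; child seeds are derived via `SeedSequence`.
Identical configs produce byte-identical outputs, and the pipeline
manifest records parameter and output checksums so any drift between
runs is detectable.

## Known limitations

* Substitution-only error model; no indels, no quality-aware consensus.
* Single-sample calling; demultiplexing is out of scope.
* The co-occurrence grouping assumes clones are either clearly
  correlated (> 0.9) or not; intermediate correlation structures are
  flagged inconsistent rather than resolved.
* The ddPCR interval treats the two channels as independent binomials;
  droplet-volume variation is not propagated.
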