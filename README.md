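# rgbarcode

Design, simulation and calling of **color-signature DNA barcodes** for
clonal cell tracking.

Integrating lentiviral vectors can mark cells two ways at once: a
fluorescent protein (red, green or blue — combinatorial transduction
paints each clone a distinctive additive hue) and a DNA barcode read
back by PCR and sequencing.  `rgbarcode` implements the combined
scheme end to end for people who design such experiments or analyse
their sequencing output: barcode cassettes whose *fixed* positions
carry a vector-specific signature while the *random* positions
individualise every vector copy, so any barcode retrieved later
identifies both its clone and its vector of origin.

## The model in brief

* Cassette: `(N₂ + F₃) × 7 + N₂ + F₁` — 16 random and 22 fixed
  positions, 38 nt; barcode space 4¹⁶ ≈ 4.29 × 10⁹ per vector.
  Signatures are designed with pairwise Hamming distance ≥ 8, no
  XbaI/XhoI sites (worst-case over all random fills) and no long
  homopolymers.
* Transduction: integrations per cell ~ Poisson(MOI); the fraction of
  marked cells is 1 − e^(−λ) and marked cells carry λ/(1 − e^(−λ))
  copies on average (≈ 3 at total MOI 2.8).
* Calling: exact anchor match → perfect 22-position signature match +
  frequency ≥ 10 → directional Hamming-distance error correction
  (absorb B into A if distance ≤ 1 on the random part, same signature,
  count(A) ≥ 2·count(B) + 1).
* Analysis: normalized abundance and dominance detection; ddPCR copy
  number 2·λ_v/λ_c with λ = −ln(1 − positives/droplets); clone count =
  dominant barcodes / copy number; additive RGB hue prediction;
  clonal identity = identical barcode sets.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Track a monoclonal leukemia: a founder clone carrying three vector
copies expands to 75% of the sample; amplicon reads are simulated with
PCR bias and sequencing error, called, filtered and corrected; droplet
digital PCR pins the copy number.

```console
$ rgbarcode demo-leukemia --seed 0
QC pass fraction: 0.830
dominant barcodes (3):
  AGACCGATCTTCGATGCGAGCCCTCCTCATTGACCAAA	0.318
  GTACCTTTCTAAGATGTGAGGTCTCATCATAAACCGTA	0.312
  CCACCGGTCTACGATCCGAGTCCTCTGCATTGACCGCA	0.223
ddPCR copy number: 2.90 [2.78, 3.03]
clone structure: monoclonal (consistent=True, clones=1)
founder barcodes recovered: True
```

Reading the output: 83% of simulated reads survive the quality
criteria; exactly three barcodes exceed the 10% dominance threshold
(read shares 0.32/0.31/0.22); the droplet assay estimates 2.90 copies
per genome (95% CI 2.78–3.03), which rounds to 3 — three dominant
barcodes at three copies per cell means **one** clone, and the three
recovered barcodes are indeed the founder's.

The companion demo deciphers a pink colony by single-cell subcloning:

```console
$ rgbarcode demo-pink-clone --seed 0
cell 1: 3 distinct barcodes
  ACACCGTTCTCAGATCGGAGGCCTCCTCATGCACCGAA	red
  ATACCGTTCTAAGATCGGAGTCCTCTCCATCAACCTTA	red
  ATGAGTCTATAGGGTAGGTCACCGCGGATATTTACGTG	blue
...
predicted hue: pink mix=(1.0, 0.0, 0.5)
clonal identity: True
```

Two red copies plus one blue mix to (1, 0, 0.5) — pink — and both
picked cells carry the identical barcode set, proving they are one
clone.

Library interface (same machinery, no CLI):

```python
from rgbarcode import design, simulate, calling, analysis
from rgbarcode.scenarios import default_templates

templates = default_templates(seed=1)
lib = design.generate_library(templates["red"], 100_000, seed=7)
design.theoretical_complexity(templates["red"])   # 4294967296
design.distance_profile(lib, 20_000, seed=0).mean # ~12.0 of 16
```

Other subcommands: `design`, `simulate`, `call`, `analyze` and `run`
(full pipeline from a YAML config, writing a checksum manifest).

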