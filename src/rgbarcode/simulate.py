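"""Synthetic populations, amplicon reads, subclone picks and ddPCR droplets.

The generators mirror the statistical structure of a barcoded-vector
clonal-tracking experiment: vector integrations per cell are Poisson at
the multiplicity of infection (MOI), every integration carries a fresh
barcode, clones expand to prescribed abundances, amplicon sequencing
adds lognormal PCR bias and i.i.d. substitution errors, and droplet
digital PCR partitions template molecules Poisson-wise into droplets.
Everything is reproducible from (parameters, seed).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .design import BarcodeTemplate, _random_fills

_NT_BYTES = np.frombuffer(b"ACGT", dtype="S1")

#: Default amplicon flanks: constant primer-site sequence on either side
#: of the barcode cassette in the simulated amplicon.
DEFAULT_LEFT_ANCHOR = "ACTGGCCGTCGTTTTACAAC"
DEFAULT_RIGHT_ANCHOR = "GTCGTGACTGGGAAAACCCT"

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class CellGenotype:
    """A cell's multiset of (vector color, barcode) integrations.

    The integration multiset is the unit of clonal identity: two cells
    belong to the same clone exactly when their multisets are identical.
    """

    cell_id: int
    integrations: tuple[tuple[str, str], ...]

    @property
    def clone_key(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(self.integrations))

    @property
    def barcode_set(self) -> frozenset[str]:
        return frozenset(bc for _, bc in self.integrations)

    def color_counts(self) -> Counter:
        return Counter(color for color, _ in self.integrations)


@dataclass
class Population:
    """Cells plus per-cell clone ids (constant on identical genotypes)."""

    cells: list[CellGenotype]
    clone_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.clone_ids:
            self.clone_ids = self._assign_clone_ids()
        if len(self.clone_ids) != len(self.cells):
            raise ValueError("clone_ids must align with cells")

    def _assign_clone_ids(self) -> list[int]:
        seen: dict[tuple, int] = {}
        out = []
        for cell in self.cells:
            key = cell.clone_key
            if key not in seen:
                seen[key] = len(seen)
            out.append(seen[key])
        return out

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def n_clones(self) -> int:
        return len(set(self.clone_ids))

    def clone_members(self) -> dict[int, list[int]]:
        members: dict[int, list[int]] = {}
        for idx, cid in enumerate(self.clone_ids):
            members.setdefault(cid, []).append(idx)
        return members


@dataclass
class ReadSet:
    """Simulated amplicon reads plus the ground-truth read→barcode map."""

    records: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    truth: dict[str, str]  # read_id -> source barcode (error-free)

    def __post_init__(self) -> None:
        for rid, seq, qual in self.records:
            if len(seq) != len(qual):
                raise ValueError(f"sequence/quality length mismatch for {rid}")
        missing = {rid for rid, _, _ in self.records} - set(self.truth)
        if missing:
            raise ValueError("truth map does not cover all records")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class DropletAssay:
    """Two-channel droplet counts from a duplex vector/control ddPCR."""

    n_droplets: int
    positive_vector: int
    positive_control: int

    def __post_init__(self) -> None:
        if not 0 <= self.positive_vector <= self.n_droplets:
            raise ValueError("vector positives outside [0, n_droplets]")
        if not 0 <= self.positive_control <= self.n_droplets:
            raise ValueError("control positives outside [0, n_droplets]")


def transduced_fraction_expected(total_moi: float) -> float:
    """Expected fraction of cells with >= 1 integration: 1 - exp(-MOI)."""
    if total_moi < 0:
        raise ValueError("MOI must be >= 0")
    return -math.expm1(-total_moi)


def conditional_mean_copies(total_moi: float) -> float:
    """Mean vector copies among transduced cells: lambda / (1 - exp(-lambda)).

    Poisson integration counts conditioned on being >= 1; tends to 1 as
    MOI -> 0 and to the MOI itself for large MOI.  Efficient combinatorial
    color marking needs this around 3, i.e. total MOI ~ 2.8.
    """
    if total_moi <= 0:
        raise ValueError("MOI must be > 0 for a conditional mean")
    return total_moi / -math.expm1(-total_moi)


def simulate_transduction(
    n_cells: int,
    moi_per_vector: dict[str, float],
    templates: dict[str, BarcodeTemplate],
    seed: int = 0,
) -> Population:
    """Transduce ``n_cells`` with one barcoded vector library per color.

    Per cell and vector the integration count is Poisson(MOI); each
    integration draws a fresh barcode uniformly from that vector's
    template space (the plasmid library is assumed complex enough that
    re-draws of the same barcode are negligible at these scales, cf.
    :func:`rgbarcode.design.expected_collisions`).
    """
    for color, moi in moi_per_vector.items():
        if moi < 0:
            raise ValueError(f"negative MOI for {color!r}")
        if color not in templates:
            raise ValueError(f"no template for vector color {color!r}")
    rng = np.random.default_rng(seed)
    per_cell: list[list[tuple[str, str]]] = [[] for _ in range(n_cells)]
    for color in sorted(moi_per_vector):
        counts = rng.poisson(moi_per_vector[color], n_cells)
        total = int(counts.sum())
        barcodes = _random_fills(templates[color], total, rng)
        pos = 0
        for cell_idx in np.nonzero(counts)[0]:
            k = counts[cell_idx]
            for bc in barcodes[pos : pos + k]:
                per_cell[cell_idx].append((color, bc))
            pos += k
    cells = [
        CellGenotype(cell_id=i, integrations=tuple(ints))
        for i, ints in enumerate(per_cell)
    ]
    return Population(cells=cells)


def expand_clones(
    population: Population,
    abundance_spec: dict[int, float],
    n_final: int,
    seed: int = 0,
) -> Population:
    """Resample cells by clone at prescribed proportions.

    ``abundance_spec`` maps clone ids to target proportions (summing to
    <= 1); the remainder is spread uniformly over all unlisted clones.
    Output cells keep their genotypes (clonal expansion copies the
    integration pattern), and get fresh cell ids.
    """
    total_spec = sum(abundance_spec.values())
    if any(p < 0 for p in abundance_spec.values()) or total_spec > 1 + 1e-12:
        raise ValueError("clone proportions must be >= 0 and sum to <= 1")
    members = population.clone_members()
    unknown = set(abundance_spec) - set(members)
    if unknown:
        raise ValueError(f"unknown clone ids in abundance_spec: {sorted(unknown)}")
    unlisted = sorted(set(members) - set(abundance_spec))
    remainder = 1.0 - total_spec
    if remainder > 1e-9 and not unlisted:
        raise ValueError("proportions sum to < 1 but no unlisted clones remain")

    clone_order = sorted(members)
    probs = np.zeros(len(clone_order))
    for idx, cid in enumerate(clone_order):
        if cid in abundance_spec:
            probs[idx] = abundance_spec[cid]
        elif unlisted:
            probs[idx] = remainder / len(unlisted)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_final, probs)
    out_cells: list[CellGenotype] = []
    out_clone_ids: list[int] = []
    for cid, k in zip(clone_order, counts):
        if k == 0:
            continue
        source = rng.choice(members[cid], size=k)
        for src in source:
            out_cells.append(
                CellGenotype(
                    cell_id=len(out_cells),
                    integrations=population.cells[src].integrations,
                )
            )
            out_clone_ids.append(cid)
    return Population(cells=out_cells, clone_ids=out_clone_ids)


def _apply_substitutions(
    mat: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. per-base substitution errors on a byte matrix of reads."""
    if error_rate == 0:
        return mat
    mask = rng.random(mat.shape) < error_rate
    n_err = int(mask.sum())
    if n_err == 0:
        return mat
    # substitute with one of the three *other* nucleotides
    orig = mat[mask]
    offsets = rng.integers(1, 4, n_err)
    idx = np.searchsorted(_NT_BYTES, orig)
    mat[mask] = _NT_BYTES[(idx + offsets) % 4]
    return mat


def simulate_reads(
    population: Population,
    depth: int,
    error_rate: float = 0.0,
    pcr_bias_sd: float = 0.5,
    amplicon_flanks: tuple[str, str] = (DEFAULT_LEFT_ANCHOR, DEFAULT_RIGHT_ANCHOR),
    seed: int = 0,
    rc_fraction: float = 0.0,
) -> ReadSet:
    """Simulate barcode amplicon reads from a cell population.

    Each read is ``left_flank + barcode + right_flank``.  Per-barcode
    read counts are multinomial with weights (copies in the population)
    x (lognormal PCR factor, sigma = ``pcr_bias_sd`` on the log scale),
    then i.i.d. substitution errors are applied at ``error_rate`` per
    base across the whole read.  Quality strings are constant Phred+33
    'I'; ``rc_fraction`` flips that share of reads to the reverse
    strand.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if not 0 <= rc_fraction <= 1:
        raise ValueError("rc_fraction must be in [0, 1]")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    if depth == 0 or len(population) == 0:
        return ReadSet(records=[], truth={})

    copies: Counter = Counter()
    for cell in population.cells:
        for _, bc in cell.integrations:
            copies[bc] += 1
    if not copies:
        return ReadSet(records=[], truth={})
    barcodes = sorted(copies)
    weights = np.array([copies[bc] for bc in barcodes], dtype=float)
    if pcr_bias_sd > 0:
        weights = weights * rng.lognormal(0.0, pcr_bias_sd, len(weights))
    counts = rng.multinomial(depth, weights / weights.sum())

    left, right = amplicon_flanks
    read_len = len(left) + len(barcodes[0]) + len(right)
    source_idx = np.repeat(np.arange(len(barcodes)), counts)
    mat = np.empty((depth, read_len), dtype="S1")
    for b_idx, bc in enumerate(barcodes):
        rows = source_idx == b_idx
        if rows.any():
            mat[rows] = np.frombuffer((left + bc + right).encode(), dtype="S1")
    mat = _apply_substitutions(mat, error_rate, rng)
    seqs = [s.decode() for s in mat.view(f"S{read_len}").ravel()]
    if rc_fraction > 0:
        flip = rng.random(depth) < rc_fraction
        seqs = [
            reverse_complement(s) if f else s for s, f in zip(seqs, flip)
        ]
    qual = "I" * read_len
    records = []
    truth = {}
    for i, (seq, b_idx) in enumerate(zip(seqs, source_idx)):
        rid = f"read_{i:07d}"
        records.append((rid, seq, qual))
        truth[rid] = barcodes[b_idx]
    return ReadSet(records=records, truth=truth)


def simulate_subclone_picks(
    cell: CellGenotype, n_picks: int, seed: int = 0
) -> list[str]:
    """Pick bacterial subclones of a single-cell PCR product.

    The mixed amplicon from one cell is subcloned; each picked colony
    carries exactly one of the cell's barcodes, sampled uniformly over
    the copy multiset (a 2-copy barcode is twice as likely per pick).
    """
    if not cell.integrations:
        raise ValueError("cell has no integrations; nothing to amplify")
    rng = np.random.default_rng(seed)
    barcodes = [bc for _, bc in cell.integrations]
    idx = rng.integers(0, len(barcodes), n_picks)
    return [barcodes[i] for i in idx]


def simulate_ddpcr(
    copy_number: float,
    control_occupancy: float,
    n_droplets: int,
    seed: int = 0,
) -> DropletAssay:
    """Simulate a duplex vector/control droplet digital PCR.

    Template molecules partition Poisson-wise, so a channel with mean
    occupancy lambda has positive-droplet probability 1 - exp(-lambda).
    The control locus is autosomal (2 copies per diploid genome), hence
    vector occupancy lambda_v = (copy_number / 2) * lambda_c.  Channels
    are independent; no droplet "rain" is modelled.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    if copy_number < 0:
        raise ValueError("copy_number must be >= 0")
    if control_occupancy < 0:
        raise ValueError("control_occupancy must be >= 0")
    rng = np.random.default_rng(seed)
    lam_c = control_occupancy
    lam_v = (copy_number / 2.0) * lam_c
    pos_c = int(rng.binomial(n_droplets, -math.expm1(-lam_c)))
    pos_v = int(rng.binomial(n_droplets, -math.expm1(-lam_v)))
    return DropletAssay(
        n_droplets=n_droplets, positive_vector=pos_v, positive_control=pos_c
    )
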