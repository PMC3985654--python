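"""Barcode layout, color-signature design and library statistics.

A barcode is a short cassette of alternating RANDOM and FIXED segments.
The random positions ("wobble" bases) individualise each vector copy,
while the fixed positions carry a vector-specific *signature* shared by
every barcode of one vector: reading the fixed positions of any called
barcode identifies the vector (and hence the fluorescent color) it came
from.  The default layout is eight random pairs separated by fixed
triplets plus one terminal fixed base — 16 random and 22 fixed
positions, 38 nt in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable, Sequence

import numpy as np

NUCLEOTIDES = "ACGT"
_NT_BYTES = np.frombuffer(b"ACGT", dtype="S1")

#: Restriction sites that must never appear in a rendered cassette: the
#: cassette is cloned through these enzymes, so an internal site would be
#: re-cut during library construction.
XBAI_SITE = "TCTAGA"
XHOI_SITE = "CTCGAG"
FORBIDDEN_MOTIFS = (XBAI_SITE, XHOI_SITE)

#: Longest homopolymer tolerated inside the fixed (signature) part.
MAX_FIXED_HOMOPOLYMER = 3


class SegmentKind(str, Enum):
    FIXED = "FIXED"
    RANDOM = "RANDOM"


@dataclass(frozen=True)
class BarcodeLayout:
    """Ordered alternation of FIXED and RANDOM segments.

    Parameters
    ----------
    segments
        Tuple of ``(kind, length)`` pairs.  Kinds must strictly
        alternate and every length must be positive.
    """

    segments: tuple[tuple[SegmentKind, int], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("layout needs at least one segment")
        prev = None
        for kind, length in self.segments:
            kind = SegmentKind(kind)
            if length <= 0:
                raise ValueError("zero/negative-length segment in layout")
            if prev is not None and kind == prev:
                raise ValueError("layout segments must alternate FIXED/RANDOM")
            prev = kind

    @classmethod
    def default(cls) -> "BarcodeLayout":
        """Eight random pairs interleaved with fixed triplets.

        ``(RANDOM 2 + FIXED 3) x 7 + RANDOM 2 + FIXED 1`` — 16 random and
        22 fixed positions (38 nt).  Seven internal triplets plus a
        terminal fixed base reconcile the published totals; alternative
        decompositions are a config change away.
        """
        segs: list[tuple[SegmentKind, int]] = []
        for _ in range(7):
            segs += [(SegmentKind.RANDOM, 2), (SegmentKind.FIXED, 3)]
        segs += [(SegmentKind.RANDOM, 2), (SegmentKind.FIXED, 1)]
        return cls(tuple(segs))

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.segments)

    @property
    def fixed_total(self) -> int:
        return sum(l for k, l in self.segments if SegmentKind(k) == SegmentKind.FIXED)

    @property
    def random_total(self) -> int:
        return sum(l for k, l in self.segments if SegmentKind(k) == SegmentKind.RANDOM)

    def positions(self, kind: SegmentKind) -> np.ndarray:
        """0-based template positions belonging to segments of ``kind``."""
        kind = SegmentKind(kind)
        out: list[int] = []
        pos = 0
        for k, length in self.segments:
            if SegmentKind(k) == kind:
                out.extend(range(pos, pos + length))
            pos += length
        return np.asarray(out, dtype=np.intp)

    @property
    def fixed_positions(self) -> np.ndarray:
        return self.positions(SegmentKind.FIXED)

    @property
    def random_positions(self) -> np.ndarray:
        return self.positions(SegmentKind.RANDOM)


def _homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = None
    for c in seq:
        run = run + 1 if c == prev else 1
        best = max(best, run)
        prev = c
    return best


def render_template(fixed_seq: str, layout: BarcodeLayout) -> str:
    """Interleave a signature into a layout, ``N`` at random positions."""
    if len(fixed_seq) != layout.fixed_total:
        raise ValueError(
            f"signature length {len(fixed_seq)} != layout fixed total "
            f"{layout.fixed_total}"
        )
    out: list[str] = []
    i = 0
    for kind, length in layout.segments:
        if SegmentKind(kind) == SegmentKind.FIXED:
            out.append(fixed_seq[i : i + length])
            i += length
        else:
            out.append("N" * length)
    return "".join(out)


def template_can_contain_motif(rendered: str, motif: str) -> bool:
    """True if some fill of the ``N`` positions creates ``motif``.

    Every window of ``len(motif)`` is checked against all fills of the
    N positions it overlaps (worst-case enumeration), so a template that
    passes can never produce the motif whatever random bases it draws.
    """
    m = len(motif)
    for start in range(len(rendered) - m + 1):
        window = rendered[start : start + m]
        n_idx = [i for i, c in enumerate(window) if c == "N"]
        if not n_idx:
            if window == motif:
                return True
            continue
        ok = all(window[i] == motif[i] for i in range(m) if i not in n_idx)
        if ok:  # the N positions can always be filled to complete it
            return True
    return False


@dataclass(frozen=True)
class Signature:
    """The fixed nucleotides identifying one vector's barcodes.

    ``fixed_seq`` is the concatenation of all FIXED segments in layout
    order; it is shared by every barcode of the vector and decodes to
    ``color_label``.
    """

    color_label: str
    vector_name: str
    fixed_seq: str

    def __post_init__(self) -> None:
        if not self.fixed_seq or set(self.fixed_seq) - set(NUCLEOTIDES):
            raise ValueError("fixed_seq must be a non-empty A/C/G/T string")

    def validate(self, layout: BarcodeLayout) -> None:
        """Raise if the signature violates design constraints under ``layout``."""
        rendered = render_template(self.fixed_seq, layout)
        for motif in FORBIDDEN_MOTIFS:
            if template_can_contain_motif(rendered, motif):
                raise ValueError(f"signature can render restriction site {motif}")
        if _homopolymer_run(self.fixed_seq) > MAX_FIXED_HOMOPOLYMER:
            raise ValueError("homopolymer run >= 4 in fixed sequence")


@dataclass(frozen=True)
class BarcodeTemplate:
    """A signature rendered into a layout: IUPAC string with N wobbles."""

    layout: BarcodeLayout
    signature: Signature
    rendered: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "rendered", render_template(self.signature.fixed_seq, self.layout)
        )

    def __len__(self) -> int:
        return len(self.rendered)

    def fixed_part(self, barcode: str) -> str:
        """Extract the signature-position bases of a realized barcode."""
        if len(barcode) != len(self.rendered):
            raise ValueError("barcode length does not match template")
        return "".join(barcode[i] for i in self.layout.fixed_positions)

    def random_part(self, barcode: str) -> str:
        if len(barcode) != len(self.rendered):
            raise ValueError("barcode length does not match template")
        return "".join(barcode[i] for i in self.layout.random_positions)


@dataclass
class BarcodeLibrary:
    """Realized barcodes drawn from one template."""

    template: BarcodeTemplate
    barcodes: list[str]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.barcodes)


def make_template(signature: Signature, layout: BarcodeLayout | None = None) -> BarcodeTemplate:
    """Render ``signature`` into ``layout`` (default layout if omitted)."""
    layout = layout or BarcodeLayout.default()
    return BarcodeTemplate(layout=layout, signature=signature)


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def design_signatures(
    n_colors: int,
    layout: BarcodeLayout | None = None,
    min_distance: int = 8,
    seed: int = 0,
    color_labels: Sequence[str] | None = None,
    max_attempts: int = 100_000,
) -> list[Signature]:
    """Design mutually distant color signatures by rejection sampling.

    Each candidate fixed sequence is drawn uniformly, rejected if it can
    render a forbidden restriction site, contains a long homopolymer, or
    sits closer than ``min_distance`` (Hamming) to an accepted
    signature.  Deterministic for a given seed.

    Parameters
    ----------
    n_colors
        Number of signatures (vectors) to design.
    min_distance
        Minimum pairwise Hamming distance between fixed sequences; a
        large margin keeps vector assignment unambiguous even for reads
        carrying several sequencing errors.
    """
    layout = layout or BarcodeLayout.default()
    if n_colors < 1:
        raise ValueError("n_colors must be >= 1")
    if min_distance > layout.fixed_total:
        raise ValueError("min_distance exceeds number of fixed positions")
    if color_labels is None:
        defaults = ["red", "green", "blue", "yellow", "cyan", "magenta"]
        color_labels = [
            defaults[i] if i < len(defaults) else f"color{i}" for i in range(n_colors)
        ]
    if len(color_labels) != n_colors:
        raise ValueError("color_labels length must equal n_colors")

    rng = np.random.default_rng(seed)
    accepted: list[Signature] = []
    for _ in range(max_attempts):
        cand = "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, layout.fixed_total))
        sig = Signature(
            color_label=color_labels[len(accepted)],
            vector_name=f"vector-{color_labels[len(accepted)]}",
            fixed_seq=cand,
        )
        try:
            sig.validate(layout)
        except ValueError:
            continue
        if any(hamming_distance(cand, s.fixed_seq) < min_distance for s in accepted):
            continue
        accepted.append(sig)
        if len(accepted) == n_colors:
            return accepted
    raise RuntimeError(
        f"could not design {n_colors} signatures at min_distance={min_distance} "
        f"within {max_attempts} attempts"
    )


def generate_library(
    template: BarcodeTemplate, n: int, seed: int = 0
) -> BarcodeLibrary:
    """Draw ``n`` barcodes with i.i.d. uniform bases at random positions."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    seqs = _random_fills(template, n, rng)
    return BarcodeLibrary(template=template, barcodes=seqs, seed=seed)


def _random_fills(
    template: BarcodeTemplate, n: int, rng: np.random.Generator
) -> list[str]:
    """Vectorised draw of n realized barcodes from a template."""
    if n == 0:
        return []
    length = len(template.rendered)
    base = np.frombuffer(template.rendered.encode(), dtype="S1")
    mat = np.tile(base, (n, 1))
    rand_pos = template.layout.random_positions
    mat[:, rand_pos] = _NT_BYTES[rng.integers(0, 4, size=(n, rand_pos.size))]
    flat = mat.view(f"S{length}").ravel()
    return [s.decode() for s in flat]


def theoretical_complexity(template: BarcodeTemplate) -> int:
    """Size of the barcode space: 4 ** (number of random positions)."""
    return 4 ** int(template.layout.random_total)


@dataclass(frozen=True)
class DistanceProfile:
    """Summary of sampled pairwise Hamming distances at random positions."""

    min: int
    mean: float
    histogram: np.ndarray  # index d -> number of sampled pairs at distance d
    n_pairs: int


def distance_profile(
    library: BarcodeLibrary, sample_pairs: int = 10_000, seed: int = 0
) -> DistanceProfile:
    """Estimate the pairwise-distance distribution over random positions.

    Distances are computed at the wobble positions only (the signature is
    constant within a library).  For uniform random barcodes the expected
    distance is 3/4 of the number of random positions.
    """
    if len(library) < 2:
        raise ValueError("library must contain at least 2 barcodes")
    rng = np.random.default_rng(seed)
    rand_pos = library.template.layout.random_positions
    arr = np.frombuffer(
        "".join(library.barcodes).encode(), dtype="S1"
    ).reshape(len(library), -1)[:, rand_pos]
    i = rng.integers(0, len(library), sample_pairs)
    j = rng.integers(0, len(library) - 1, sample_pairs)
    j = np.where(j >= i, j + 1, j)  # j != i, uniform over the rest
    dists = (arr[i] != arr[j]).sum(axis=1)
    hist = np.bincount(dists, minlength=rand_pos.size + 1)
    return DistanceProfile(
        min=int(dists.min()),
        mean=float(dists.mean()),
        histogram=hist,
        n_pairs=sample_pairs,
    )


def expected_collisions(n_draws: int, space_size: int) -> float:
    """Expected number of duplicated draws when sampling with replacement.

    E[n - #distinct] = n - K * (1 - (1 - 1/K)**n) for n uniform draws
    from a space of size K; used to judge how far an observed
    unique-barcode count can sit below the number of clones sampled.
    """
    if space_size < 1:
        raise ValueError("space_size must be >= 1")
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    if n_draws == 0:
        return 0.0
    if space_size == 1:
        return float(n_draws - 1)
    k = float(space_size)
    # K*(1-(1-1/K)^n) via expm1/log1p to survive K ~ 4^16
    expected_distinct = -k * math.expm1(n_draws * math.log1p(-1.0 / k))
    return n_draws - expected_distinct


def estimate_complexity_from_colonies(
    colony_count: int, plated_fraction: float
) -> float:
    """Scale a plated-aliquot colony count up to full library complexity."""
    if not 0 < plated_fraction <= 1:
        raise ValueError("plated_fraction must be in (0, 1]")
    if colony_count < 0:
        raise ValueError("colony_count must be >= 0")
    return colony_count / plated_fraction
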