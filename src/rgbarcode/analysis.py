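"""Clonal abundance, copy-number inference and additive color prediction.

This layer turns filtered barcode counts into biology: which barcodes
dominate a sample, how many vector copies each cell carries (from
droplet digital PCR), whether the dominant barcodes are one clone or
several, what hue a cell with a given vector combination should
display under the additive color model, and whether two cells share
clonal identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import CountTable
from .simulate import DropletAssay

OTHER_LABEL = "(other)"

#: Additive-mix naming table.  Mixes are normalized so the strongest
#: channel is 1; a hue gets the name of the nearest table entry
#: (Euclidean distance, ties broken by table order).  "pink" denotes the
#: red-dominant red+blue mix, distinct from balanced magenta.
HUE_TABLE: tuple[tuple[str, tuple[float, float, float]], ...] = (
    ("red", (1.0, 0.0, 0.0)),
    ("green", (0.0, 1.0, 0.0)),
    ("blue", (0.0, 0.0, 1.0)),
    ("yellow", (1.0, 1.0, 0.0)),
    ("cyan", (0.0, 1.0, 1.0)),
    ("magenta", (1.0, 0.0, 1.0)),
    ("white", (1.0, 1.0, 1.0)),
    ("orange", (1.0, 0.5, 0.0)),
    ("pink", (1.0, 0.0, 0.5)),
    ("chartreuse", (0.5, 1.0, 0.0)),
    ("azure", (0.0, 0.5, 1.0)),
)

_CHANNEL = {"red": 0, "green": 1, "blue": 2}


@dataclass
class AbundanceProfile:
    """Per-sample barcode frequencies with deterministic ranking."""

    df: pd.DataFrame  # columns: sample, barcode, count, frequency, rank
    top_k: int = 10

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def ranked(self, sample: str) -> pd.DataFrame:
        sub = self.df[self.df["sample"] == sample]
        return sub.sort_values("rank").reset_index(drop=True)

    def top_table(self, sample: str) -> pd.DataFrame:
        """Top-k rows plus one aggregated remainder row."""
        sub = self.ranked(sample)
        head = sub.head(self.top_k)
        rest = sub.iloc[self.top_k :]
        if len(rest):
            other = pd.DataFrame(
                [
                    {
                        "sample": sample,
                        "barcode": OTHER_LABEL,
                        "count": int(rest["count"].sum()),
                        "frequency": float(rest["frequency"].sum()),
                        "rank": self.top_k + 1,
                    }
                ]
            )
            return pd.concat([head, other], ignore_index=True)
        return head.reset_index(drop=True)


def abundance_profile(table: CountTable, top_k: int = 10) -> AbundanceProfile:
    """Normalize per-sample counts to frequencies and rank them.

    Ranking is deterministic: count descending, then sequence
    ascending.  Frequencies within a sample sum to 1 exactly (up to
    float rounding).  An empty table yields an explicit empty profile.
    """
    if not len(table.df):
        df = pd.DataFrame(columns=["sample", "barcode", "count", "frequency", "rank"])
        return AbundanceProfile(df=df, top_k=top_k)
    frames = []
    for sample in table.samples:
        sub = table.df[table.df["sample"] == sample].copy()
        total = sub["count"].sum()
        sub = sub.sort_values(["count", "barcode"], ascending=[False, True])
        sub["frequency"] = sub["count"] / total
        sub["rank"] = np.arange(1, len(sub) + 1)
        frames.append(sub)
    return AbundanceProfile(df=pd.concat(frames, ignore_index=True), top_k=top_k)


def detect_dominant(
    profile: AbundanceProfile, threshold: float = 0.10, sample: str | None = None
) -> list[str]:
    """Barcodes whose read share exceeds ``threshold``, in rank order.

    A clone that has expanded (e.g. a leukemic founder) shows up as one
    dominant barcode per vector copy it carries.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if sample is None:
        samples = profile.samples
        if not samples:
            return []
        if len(samples) > 1:
            raise ValueError("sample must be given for a multi-sample profile")
        sample = samples[0]
    sub = profile.ranked(sample)
    return list(sub.loc[sub["frequency"] > threshold, "barcode"])


@dataclass(frozen=True)
class CopyNumberEstimate:
    """ddPCR vector copies per diploid genome with a confidence interval."""

    estimate: float
    low: float
    high: float
    lambda_vector: float
    lambda_control: float


def ddpcr_copy_number(
    assay: DropletAssay, confidence: float = 0.95
) -> CopyNumberEstimate:
    """Poisson-correct droplet counts into vector copies per genome.

    Each channel's mean occupancy is recovered as
    ``lambda = -ln(1 - positives / n)``; with an autosomal two-copy
    control locus the copy number is ``2 * lambda_v / lambda_c``.  The
    interval propagates Wilson binomial intervals on each channel's
    positive fraction through the same transform (extremes of the
    ratio).
    """
    n = assay.n_droplets
    if assay.positive_control < 1:
        raise ValueError("control channel has no positive droplets")
    if assay.positive_vector >= n:
        raise ValueError("vector channel saturated (all droplets positive)")

    def lam(positives: float) -> float:
        return -math.log1p(-positives / n)

    lam_v = lam(assay.positive_vector)
    lam_c = lam(assay.positive_control)
    estimate = 2.0 * lam_v / lam_c

    alpha = 1.0 - confidence
    v_lo, v_hi = _wilson(assay.positive_vector, n, alpha)
    c_lo, c_hi = _wilson(assay.positive_control, n, alpha)
    low = 2.0 * lam(n * v_lo) / lam(n * c_hi)
    high = 2.0 * lam(n * min(v_hi, 1 - 1e-12)) / lam(n * c_lo)
    return CopyNumberEstimate(
        estimate=estimate, low=low, high=high, lambda_vector=lam_v, lambda_control=lam_c
    )


def _wilson(k: int, n: int, alpha: float) -> tuple[float, float]:
    z = sps.norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


@dataclass(frozen=True)
class CloneCall:
    """One inferred clone: its barcode set and abundance."""

    barcodes: frozenset[str]
    copy_number: int
    abundance: float | None = None


@dataclass
class CloneStructure:
    """Result of matching dominant barcodes against a copy number."""

    clones: list[CloneCall] = field(default_factory=list)
    consistent: bool = True
    message: str = ""

    @property
    def n_clones(self) -> int:
        return len(self.clones)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def infer_clone_structure(
    dominant: list[str],
    copy_number: float,
    co_occurrence: dict[str, list[float]] | None = None,
    correlation_cutoff: float = 0.9,
) -> CloneStructure:
    """Partition dominant barcodes into clones of ``copy_number`` each.

    With k dominant barcodes and c vector copies per cell the sample
    holds k / c clones — provided k is divisible by c, and (when
    multi-sample frequencies are available) barcodes grouped into one
    clone rise and fall together across samples (Pearson r above
    ``correlation_cutoff``).  Any mismatch is flagged as inconsistent,
    never silently resolved.
    """
    c = round_half_up(copy_number)
    if c < 1:
        raise ValueError("copy_number must round to >= 1")
    k = len(dominant)
    if k == 0:
        return CloneStructure(clones=[], consistent=True, message="no dominant barcodes")
    if k % c != 0:
        return CloneStructure(
            clones=[],
            consistent=False,
            message=f"{k} dominant barcodes not divisible by copy number {c}",
        )
    n_clones = k // c
    if n_clones == 1:
        return CloneStructure(
            clones=[CloneCall(barcodes=frozenset(dominant), copy_number=c)],
            consistent=True,
            message="monoclonal",
        )
    if co_occurrence is None:
        return CloneStructure(
            clones=[],
            consistent=False,
            message=(
                f"{n_clones} clones implied but no co-occurrence profiles "
                "given to group barcodes"
            ),
        )
    missing = [bc for bc in dominant if bc not in co_occurrence]
    if missing:
        raise ValueError(f"co_occurrence missing barcodes: {missing}")
    groups = _correlation_components(dominant, co_occurrence, correlation_cutoff)
    if sorted(len(g) for g in groups) != [c] * n_clones:
        return CloneStructure(
            clones=[],
            consistent=False,
            message=(
                f"co-occurrence groups of sizes {sorted(len(g) for g in groups)} "
                f"do not form {n_clones} clones of {c} barcodes"
            ),
        )
    clones = [
        CloneCall(barcodes=frozenset(g), copy_number=c)
        for g in sorted(groups, key=lambda g: sorted(g)[0])
    ]
    return CloneStructure(clones=clones, consistent=True, message=f"{n_clones} clones")


def _correlation_components(
    barcodes: list[str],
    profiles: dict[str, list[float]],
    cutoff: float,
) -> list[set[str]]:
    """Connected components of the pairwise-Pearson > cutoff graph."""
    n = len(barcodes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a = np.asarray(profiles[barcodes[i]], dtype=float)
            b = np.asarray(profiles[barcodes[j]], dtype=float)
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if r > cutoff:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i, bc in enumerate(barcodes):
        comps.setdefault(find(i), set()).add(bc)
    return list(comps.values())


@dataclass(frozen=True)
class HueResult:
    """Normalized additive RGB mix and its nearest hue name."""

    mix: tuple[float, float, float]
    hue_name: str


def predict_color(integrations) -> HueResult:
    """Predict the display hue of a cell from its vector copies.

    Under the additive color model each vector copy contributes its
    primary; per-channel copy counts are normalized by the maximum, so
    a cell with two red and one blue copy mixes to (1, 0, 0.5) — pink.
    Accepts a mapping color -> copies or an iterable of color labels.

    Scale-invariant (doubling all copies changes nothing) and
    permutation-invariant in the input order.
    """
    if hasattr(integrations, "items"):
        counts = dict(integrations)
    else:
        counts = {}
        for label in integrations:
            counts[label] = counts.get(label, 0) + 1
    if not counts or sum(counts.values()) == 0:
        raise ValueError("integration multiset must be non-empty")
    mix = [0.0, 0.0, 0.0]
    for label, k in counts.items():
        if label not in _CHANNEL:
            raise ValueError(f"unknown color label {label!r} (expected red/green/blue)")
        if k < 0:
            raise ValueError("copy counts must be >= 0")
        mix[_CHANNEL[label]] += k
    peak = max(mix)
    if peak == 0:
        raise ValueError("integration multiset must be non-empty")
    mix = [m / peak for m in mix]
    best_name = min(
        HUE_TABLE,
        key=lambda entry: sum((a - b) ** 2 for a, b in zip(mix, entry[1])),
    )[0]
    return HueResult(mix=tuple(mix), hue_name=best_name)


@dataclass(frozen=True)
class IdentityResult:
    """Outcome of a clonal-identity comparison between two cells."""

    identical: bool | None  # None = indeterminate (an empty set)
    shared: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]


def clonal_identity(cell_a, cell_b) -> IdentityResult:
    """Two cells are the same clone iff their barcode sets are identical.

    Empty input sets give an indeterminate result (no evidence either
    way), never ``False``.
    """
    a, b = frozenset(cell_a), frozenset(cell_b)
    shared = a & b
    if not a or not b:
        return IdentityResult(identical=None, shared=shared, only_a=a - b, only_b=b - a)
    return IdentityResult(
        identical=(a == b), shared=shared, only_a=a - b, only_b=b - a
    )


def marked_cell_dose(n_cells: int, positive_fraction: float) -> float:
    """Transgene-positive cells in a graft: total cells x marked fraction."""
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must be in [0, 1]")
    return n_cells * positive_fraction


def plot_abundance_stacked(profile: AbundanceProfile, samples=None, ax=None):
    """Stacked per-sample abundance bars: top-k barcodes plus remainder."""
    import matplotlib.pyplot as plt

    samples = samples or profile.samples
    if ax is None:
        _fig, ax = plt.subplots(figsize=(1.2 * len(samples) + 2, 4))
    # union of top-k barcodes across samples, consistent colors
    top_union: list[str] = []
    for s in samples:
        for bc in profile.top_table(s)["barcode"]:
            if bc != OTHER_LABEL and bc not in top_union:
                top_union.append(bc)
    cmap = plt.get_cmap("tab20")
    colors = {bc: cmap(i % 20) for i, bc in enumerate(top_union)}
    colors[OTHER_LABEL] = (0.6, 0.6, 0.6, 1.0)
    for x, s in enumerate(samples):
        sub = profile.ranked(s)
        bottom = 0.0
        for _, row in sub.iterrows():
            bc = row["barcode"] if row["barcode"] in colors else OTHER_LABEL
            ax.bar(x, row["frequency"], bottom=bottom, color=colors[bc], width=0.7)
            bottom += row["frequency"]
    ax.set_xticks(range(len(samples)))
    ax.set_xticklabels(samples)
    ax.set_ylabel("barcode read share")
    ax.set_ylim(0, 1)
    return ax
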