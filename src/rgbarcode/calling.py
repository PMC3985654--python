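"""Barcode extraction, quality filtering, decoding and error correction.

The calling pipeline is deliberately strict, matching the design of
position-anchored barcodes: the amplicon anchor must match exactly, a
called barcode must match some vector signature perfectly at every
fixed position, and only barcodes seen at least ``min_count`` times are
kept.  Residual sequencing errors at the random positions are removed
by directional Hamming-distance merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import BarcodeTemplate, hamming_distance
from .simulate import ReadSet, reverse_complement

UNASSIGNED = "UNASSIGNED"

_VALID_BASES = frozenset("ACGT")


@dataclass
class CountTable:
    """Read counts per (sample, barcode).

    Thin wrapper over a tidy DataFrame with columns ``sample``,
    ``barcode`` and ``count``; ``barcode_length`` is the template length
    all entries must share.
    """

    df: pd.DataFrame
    barcode_length: int | None = None

    def __post_init__(self) -> None:
        required = {"sample", "barcode", "count"}
        if not required <= set(self.df.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        if (self.df["count"] < 1).any():
            raise ValueError("counts must be >= 1")
        if self.barcode_length is not None and len(self.df):
            lengths = self.df["barcode"].str.len()
            if (lengths != self.barcode_length).any():
                raise ValueError("barcode length differs from template length")
        self.df = (
            self.df.sort_values(["sample", "count", "barcode"], ascending=[True, False, True])
            .reset_index(drop=True)
        )

    @classmethod
    def from_counts(
        cls, counts: dict[str, int], sample: str = "sample", barcode_length: int | None = None
    ) -> "CountTable":
        df = pd.DataFrame(
            {"sample": sample, "barcode": list(counts), "count": list(counts.values())}
        )
        return cls(df=df, barcode_length=barcode_length)

    def sample_counts(self, sample: str) -> dict[str, int]:
        sub = self.df[self.df["sample"] == sample]
        return dict(zip(sub["barcode"], sub["count"]))

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def total_reads(self, sample: str | None = None) -> int:
        if sample is None:
            return int(self.df["count"].sum())
        return int(self.df.loc[self.df["sample"] == sample, "count"].sum())

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class BarcodeCall:
    """One decoded barcode: sequence, vector color and wobble bases."""

    barcode: str
    color_label: str
    random_part: str
    count: int


@dataclass
class ExtractionStats:
    reads_in: int = 0
    anchored: int = 0
    unassigned: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_in": self.reads_in,
            "anchored": self.anchored,
            "unassigned": self.unassigned,
        }


@dataclass
class QCReport:
    """Per-stage accounting for the quality filter."""

    entries_in: int
    entries_signature_pass: int
    entries_retained: int
    reads_in: int
    reads_retained: int

    @property
    def pass_fraction(self) -> float:
        return self.reads_retained / self.reads_in if self.reads_in else 0.0

    def as_dict(self) -> dict[str, float | int]:
        return {
            "entries_in": self.entries_in,
            "entries_signature_pass": self.entries_signature_pass,
            "entries_retained": self.entries_retained,
            "reads_in": self.reads_in,
            "reads_retained": self.reads_retained,
            "pass_fraction": self.pass_fraction,
        }


def extract_barcodes(
    reads: ReadSet,
    templates: list[BarcodeTemplate],
    anchors: tuple[str, str],
    sample: str = "sample",
    handle_rc: bool = False,
) -> tuple[CountTable, ExtractionStats]:
    """Locate the barcode window in each read by exact anchor match.

    The left anchor is searched exactly (first occurrence); the
    following ``template_length`` bases are taken as the barcode.  Reads
    without the anchor, with a truncated window, or with non-ACGT bases
    in the window are tallied as unassigned, so
    ``anchored + unassigned == reads_in`` always holds.  With
    ``handle_rc`` the reverse complement of the read is tried when the
    forward search fails.
    """
    if not templates:
        raise ValueError("template list must not be empty")
    left, _right = anchors
    if not left:
        raise ValueError("left anchor must be non-empty")
    length = len(templates[0])
    if any(len(t) != length for t in templates):
        raise ValueError("all templates must share one length")

    stats = ExtractionStats(reads_in=len(reads.records))
    counts: dict[str, int] = {}
    for _rid, seq, _qual in reads.records:
        window = _find_window(seq, left, length)
        if window is None and handle_rc:
            window = _find_window(reverse_complement(seq), left, length)
        if window is None or set(window) - _VALID_BASES:
            stats.unassigned += 1
            continue
        stats.anchored += 1
        counts[window] = counts.get(window, 0) + 1
    if counts:
        table = CountTable.from_counts(counts, sample=sample, barcode_length=length)
    else:
        table = CountTable(
            df=pd.DataFrame(columns=["sample", "barcode", "count"]),
            barcode_length=length,
        )
    return table, stats


def _find_window(seq: str, left_anchor: str, length: int) -> str | None:
    pos = seq.find(left_anchor)
    if pos < 0:
        return None
    start = pos + len(left_anchor)
    window = seq[start : start + length]
    if len(window) < length:
        return None
    return window


def _signature_set(templates: list[BarcodeTemplate]) -> dict[str, str]:
    """Map exact fixed-position string -> color label."""
    out: dict[str, str] = {}
    for t in templates:
        out[t.signature.fixed_seq] = t.signature.color_label
    return out


def qc_filter(
    raw: CountTable,
    templates: list[BarcodeTemplate],
    min_count: int = 10,
) -> tuple[CountTable, QCReport]:
    """Apply the two quality criteria to a raw count table.

    An entry is retained iff (a) its fixed positions match some vector
    signature *perfectly at every position* and (b) its read count is at
    least ``min_count`` (default 10).  Both criteria together suppress
    false-positive barcodes created by PCR and sequencing errors.
    Idempotent: filtering a filtered table changes nothing.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not templates:
        raise ValueError("template list must not be empty")
    signatures = _signature_set(templates)
    fixed_pos = templates[0].layout.fixed_positions

    reads_in = raw.total_reads()
    if not len(raw.df):
        empty = CountTable(df=raw.df.copy(), barcode_length=raw.barcode_length)
        return empty, QCReport(0, 0, 0, reads_in, 0)

    barcodes = raw.df["barcode"].to_numpy()
    arr = np.frombuffer("".join(barcodes).encode(), dtype="S1").reshape(
        len(barcodes), -1
    )
    fixed_strings = [b"".join(row).decode() for row in arr[:, fixed_pos]]
    sig_ok = np.array([fs in signatures for fs in fixed_strings])
    count_ok = raw.df["count"].to_numpy() >= min_count
    keep = sig_ok & count_ok

    filtered = CountTable(
        df=raw.df.loc[keep].reset_index(drop=True),
        barcode_length=raw.barcode_length,
    )
    report = QCReport(
        entries_in=len(raw.df),
        entries_signature_pass=int(sig_ok.sum()),
        entries_retained=int(keep.sum()),
        reads_in=reads_in,
        reads_retained=filtered.total_reads(),
    )
    return filtered, report


def decode_signature(
    barcode: str,
    templates: list[BarcodeTemplate],
    strict: bool = True,
    tolerance: int = 2,
) -> str:
    """Decode the vector color of a barcode from its fixed positions.

    Strict mode requires a perfect match to exactly one signature.  In
    tolerant mode the nearest signature wins provided its Hamming
    distance is <= ``tolerance`` and strictly smaller than every other
    signature's; ties and everything else return ``UNASSIGNED``.
    """
    if not templates:
        raise ValueError("template list must not be empty")
    length = len(templates[0])
    if len(barcode) != length:
        raise ValueError(f"barcode length {len(barcode)} != template length {length}")
    fixed_pos = templates[0].layout.fixed_positions
    fixed = "".join(barcode[i] for i in fixed_pos)
    if strict:
        for t in templates:
            if fixed == t.signature.fixed_seq:
                return t.signature.color_label
        return UNASSIGNED
    dists = sorted(
        (hamming_distance(fixed, t.signature.fixed_seq), t.signature.color_label)
        for t in templates
    )
    if dists[0][0] > tolerance:
        return UNASSIGNED
    if len(dists) > 1 and dists[1][0] == dists[0][0]:
        return UNASSIGNED
    return dists[0][1]


def error_correct(
    table: CountTable,
    templates: list[BarcodeTemplate],
    max_distance: int = 1,
    ratio: float = 2.0,
) -> CountTable:
    """Directional merging of sequencing-error satellites.

    Entries are processed per sample in descending count order (ties
    broken lexicographically by sequence).  An entry B is absorbed into
    a retained entry A when the two share the same fixed-position
    string, their Hamming distance over the *random* positions is at
    most ``max_distance``, and ``count(A) >= ratio * count(B) + 1`` —
    the count asymmetry distinguishes an error satellite from two
    genuinely co-abundant barcodes, and the directional rule prevents
    chains of abundant true barcodes from collapsing.  Counts of
    absorbed entries are added to the absorber, so total reads are
    conserved.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    if not templates:
        raise ValueError("template list must not be empty")
    layout = templates[0].layout
    rand_pos = layout.random_positions
    fixed_pos = layout.fixed_positions

    out_frames = []
    for sample in table.samples:
        counts = table.sample_counts(sample)
        order = sorted(counts, key=lambda bc: (-counts[bc], bc))
        retained: list[str] = []
        merged: dict[str, int] = {}
        parts = {
            bc: (
                "".join(bc[i] for i in fixed_pos),
                "".join(bc[i] for i in rand_pos),
            )
            for bc in order
        }
        for bc in order:
            fixed_b, rand_b = parts[bc]
            absorbed = False
            if max_distance > 0:
                for a in retained:
                    fixed_a, rand_a = parts[a]
                    if fixed_a != fixed_b:
                        continue
                    if merged[a] < ratio * counts[bc] + 1:
                        continue
                    if hamming_distance(rand_a, rand_b) <= max_distance:
                        merged[a] += counts[bc]
                        absorbed = True
                        break
            if not absorbed:
                retained.append(bc)
                merged[bc] = counts[bc]
        out_frames.append(
            pd.DataFrame(
                {"sample": sample, "barcode": retained, "count": [merged[b] for b in retained]}
            )
        )
    if out_frames:
        df = pd.concat(out_frames, ignore_index=True)
    else:
        df = table.df.copy()
    return CountTable(df=df, barcode_length=table.barcode_length)


def call_table(
    table: CountTable,
    templates: list[BarcodeTemplate],
    strict: bool = True,
    tolerance: int = 2,
) -> pd.DataFrame:
    """Annotate a count table with decoded color and wobble bases.

    Returns a tidy DataFrame with columns ``sample, barcode,
    random_part, color, count`` — the package's canonical call output.
    """
    layout = templates[0].layout
    rows = []
    for _, rec in table.df.iterrows():
        bc = rec["barcode"]
        rows.append(
            {
                "sample": rec["sample"],
                "barcode": bc,
                "random_part": "".join(bc[i] for i in layout.random_positions),
                "color": decode_signature(bc, templates, strict=strict, tolerance=tolerance),
                "count": rec["count"],
            }
        )
    return pd.DataFrame(rows, columns=["sample", "barcode", "random_part", "color", "count"])


def unique_barcode_count(
    table: CountTable, templates: list[BarcodeTemplate]
) -> pd.DataFrame:
    """Distinct retained barcodes per sample, stratified by decoded color."""
    if not len(table.df):
        return pd.DataFrame(columns=["sample", "color", "unique_barcodes"])
    calls = call_table(table, templates)
    out = (
        calls.groupby(["sample", "color"])["barcode"]
        .nunique()
        .reset_index(name="unique_barcodes")
        .sort_values(["sample", "color"])
        .reset_index(drop=True)
    )
    return out
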