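"""File formats: FASTA libraries, FASTQ reads, TSV tables, YAML configs.

All writers round-trip: ``read(write(x))`` reproduces the sequences and
counts bit-for-bit.  TSV is tab-separated with a header row, UTF-8,
'.' decimal separator.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import CountTable
from .design import (
    BarcodeLayout,
    BarcodeLibrary,
    BarcodeTemplate,
    SegmentKind,
    Signature,
    make_template,
)
from .simulate import ReadSet

CONFIG_SCHEMA_VERSION = 1


# ---------------------------------------------------------------- FASTA


def write_library_fasta(library: BarcodeLibrary, path: str | Path) -> None:
    """One record per barcode; header carries color label and serial."""
    color = library.template.signature.color_label
    records = (
        SeqRecord(Seq(bc), id=f"{color}|{i:06d}", description="")
        for i, bc in enumerate(library.barcodes)
    )
    SeqIO.write(records, str(path), "fasta")


def read_library_fasta(
    path: str | Path, template: BarcodeTemplate | None = None
) -> BarcodeLibrary:
    barcodes = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return BarcodeLibrary(template=template, barcodes=barcodes, seed=None)


# ---------------------------------------------------------------- FASTQ


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    """Phred+33 FASTQ, one record per simulated read."""
    with open(path, "w", encoding="utf-8") as fh:
        for rid, seq, qual in reads.records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse Phred+33 FASTQ into (read_id, sequence, quality) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append((rec.id, str(rec.seq), qual))
    return out


def read_fastq_as_readset(path: str | Path) -> ReadSet:
    """Load external reads; the truth map is trivially self-referential."""
    records = read_fastq(path)
    return ReadSet(records=records, truth={rid: "" for rid, _, _ in records})


# ------------------------------------------------------------------ TSV


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path, barcode_length: int | None = None) -> CountTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "barcode": str, "count": int})
    return CountTable(df=df, barcode_length=barcode_length)


def write_truth_table(reads: ReadSet, path: str | Path) -> None:
    df = pd.DataFrame(
        {"read_id": list(reads.truth), "source_barcode": list(reads.truth.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- JSON


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# -------------------------------------------------- template config (YAML)


def layout_to_dict(layout: BarcodeLayout) -> list[dict]:
    return [
        {"kind": SegmentKind(kind).value, "length": int(length)}
        for kind, length in layout.segments
    ]


def layout_from_dict(data: list[dict]) -> BarcodeLayout:
    return BarcodeLayout(
        tuple((SegmentKind(seg["kind"]), int(seg["length"])) for seg in data)
    )


def write_template_config(
    templates: list[BarcodeTemplate], path: str | Path
) -> None:
    """Versioned key-value document defining layout and signatures."""
    if not templates:
        raise ValueError("no templates to write")
    doc = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "layout": layout_to_dict(templates[0].layout),
        "signatures": [
            {
                "color_label": t.signature.color_label,
                "vector_name": t.signature.vector_name,
                "fixed_seq": t.signature.fixed_seq,
            }
            for t in templates
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_template_config(path: str | Path) -> list[BarcodeTemplate]:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    version = doc.get("schema_version")
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported template config schema_version {version!r}")
    layout = layout_from_dict(doc["layout"])
    return [
        make_template(
            Signature(
                color_label=s["color_label"],
                vector_name=s["vector_name"],
                fixed_seq=s["fixed_seq"],
            ),
            layout,
        )
        for s in doc["signatures"]
    ]
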