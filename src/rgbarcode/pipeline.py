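"""End-to-end pipeline runner with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

from . import __version__, analysis, calling, design, io, simulate
from .config import RunConfig

logger = logging.getLogger("rgbarcode")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    """Execute design -> simulate -> call -> analyze and write all artifacts.

    Outputs: template config (YAML), optional library FASTA per color,
    reads FASTQ + truth TSV, raw/filtered/corrected count TSVs, QC JSON,
    calls and abundance TSVs, dominant-barcode JSON, and a manifest
    recording version, parameters and output checksums — identical
    configs yield byte-identical tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, writer, *args) -> Path:
        path = outdir / name
        writer(*args, path)
        outputs[name] = sha256_of(path)
        return path

    # ---- design
    logger.info("designing %d signatures", len(config.design.colors))
    layout = design.BarcodeLayout.default()
    signatures = design.design_signatures(
        len(config.design.colors),
        layout,
        min_distance=config.design.min_distance,
        seed=config.design.seed,
        color_labels=config.design.colors,
    )
    templates = {s.color_label: design.make_template(s, layout) for s in signatures}
    template_list = list(templates.values())
    emit("templates.yaml", io.write_template_config, template_list)
    if config.design.library_size:
        for color, template in templates.items():
            lib = design.generate_library(
                template, config.design.library_size, seed=config.design.seed
            )
            emit(f"library_{color}.fasta", io.write_library_fasta, lib)

    # ---- simulate
    sim = config.simulate
    logger.info("simulating %d cells, depth %d", sim.n_cells, sim.depth)
    population = simulate.simulate_transduction(
        sim.n_cells, sim.moi_per_vector, templates, seed=sim.seed
    )
    reads = simulate.simulate_reads(
        population,
        depth=sim.depth,
        error_rate=sim.error_rate,
        pcr_bias_sd=sim.pcr_bias_sd,
        rc_fraction=sim.rc_fraction,
        seed=sim.seed,
    )
    emit("reads.fastq", io.write_fastq, reads)
    emit("truth.tsv", io.write_truth_table, reads)

    # ---- call
    raw, extraction = calling.extract_barcodes(
        reads,
        template_list,
        anchors=(simulate.DEFAULT_LEFT_ANCHOR, simulate.DEFAULT_RIGHT_ANCHOR),
        sample=config.sample_name,
        handle_rc=config.call.handle_rc,
    )
    filtered, qc_report = calling.qc_filter(
        raw, template_list, min_count=config.call.min_count
    )
    corrected = calling.error_correct(
        filtered,
        template_list,
        max_distance=config.call.max_distance,
        ratio=config.call.ratio,
    )
    calls = calling.call_table(
        corrected, template_list, strict=config.call.strict_signature
    )
    emit("counts_raw.tsv", io.write_count_table, raw)
    emit("counts_filtered.tsv", io.write_count_table, filtered)
    emit("counts_corrected.tsv", io.write_count_table, corrected)
    emit("calls.tsv", io.write_tsv, calls)
    emit(
        "qc.json",
        io.write_json,
        {"extraction": extraction.as_dict(), "filter": qc_report.as_dict()},
    )

    # ---- analyze
    profile = analysis.abundance_profile(corrected, top_k=config.analyze.top_k)
    dominant = (
        analysis.detect_dominant(
            profile, threshold=config.analyze.dominance_threshold,
            sample=config.sample_name,
        )
        if len(profile.df)
        else []
    )
    emit("abundance.tsv", io.write_tsv, profile.df)
    emit(
        "dominant.json",
        io.write_json,
        {
            "threshold": config.analyze.dominance_threshold,
            "dominant_barcodes": dominant,
        },
    )

    manifest = {
        "rgbarcode_version": __version__,
        "config": config.model_dump(),
        "outputs": outputs,
    }
    io.write_json(manifest, outdir / "manifest.json")
    return PipelineResult(outdir=outdir, manifest=manifest)
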