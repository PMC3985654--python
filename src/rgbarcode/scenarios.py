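"""Worked end-to-end scenarios used by the demos and the test suite.

Two reference experiments are wired up here:

* the *pink clone*: an RGB-marked cell line clone carrying two copies of
  the red vector and one of the blue vector; two single cells are
  picked, their mixed single-cell PCR product is subcloned, ten colonies
  per cell are Sanger-sequenced, and the decoded signatures must agree
  with the additive color model and prove clonal identity;
* the *leukemia*: a transduced hematopoietic graft in which one founder
  clone (carrying k vector copies, hence k barcodes) expands to
  dominance; amplicon sequencing, QC, error correction and ddPCR must
  recover exactly k dominant barcodes and a monoclonal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import analysis, calling, design, simulate

#: Conditions of the reference experiments: per-vector MOI for RGB
#: marking of the cell line, vector MOI for the oncogene graft, and the
#: graft size / marking rate of the transplant.
RGB_MOI_PER_VECTOR = 1.4
LEUKEMIA_MOI = 4.0
GRAFT_CELLS = 300_000
GRAFT_MARKED_FRACTION = 0.017


def _split_seed(seed: int, n: int) -> list[int]:
    """Derive n child seeds < 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def default_templates(
    seed: int = 0, colors: tuple[str, ...] = ("red", "green", "blue"), min_distance: int = 8
) -> dict[str, design.BarcodeTemplate]:
    """Design one signature per color and render the templates."""
    layout = design.BarcodeLayout.default()
    sigs = design.design_signatures(
        len(colors), layout, min_distance=min_distance, seed=seed, color_labels=list(colors)
    )
    return {s.color_label: design.make_template(s, layout) for s in sigs}


@dataclass
class PinkCloneResult:
    """Everything the pink-clone workflow produces."""

    genotype: simulate.CellGenotype
    picks_per_cell: list[list[str]]  # raw pick sequences, one list per cell
    decoded_per_cell: list[dict[str, str]]  # barcode -> color, per cell
    barcode_sets: list[frozenset[str]]
    hue: analysis.HueResult
    identity: analysis.IdentityResult

    @property
    def distinct_barcodes_per_cell(self) -> list[int]:
        return [len(s) for s in self.barcode_sets]


def pink_clone_scenario(
    seed: int = 0, n_cells_picked: int = 2, n_picks: int = 10
) -> PinkCloneResult:
    """Two red + one blue vector copies, deciphered by subclone picking.

    The clone's genotype is fixed by construction (2 red integrations,
    1 blue); both picked cells share it, as all cells of one clone do.
    Each cell's PCR product is subcloned and ``n_picks`` colonies are
    sequenced; the decoded signature set must read 2 red + 1 blue, the
    predicted hue "pink", and the two cells must test clonally
    identical.
    """
    seeds = _split_seed(seed, 2 + n_cells_picked)
    templates = default_templates(seed=seeds[0])
    rng = np.random.default_rng(seeds[1])
    red = design._random_fills(templates["red"], 2, rng)
    blue = design._random_fills(templates["blue"], 1, rng)
    genotype = simulate.CellGenotype(
        cell_id=0,
        integrations=(("red", red[0]), ("red", red[1]), ("blue", blue[0])),
    )
    template_list = list(templates.values())
    picks_per_cell = []
    decoded_per_cell = []
    barcode_sets = []
    for i in range(n_cells_picked):
        picks = simulate.simulate_subclone_picks(genotype, n_picks, seed=seeds[2 + i])
        decoded = {
            bc: calling.decode_signature(bc, template_list, strict=True)
            for bc in sorted(set(picks))
        }
        picks_per_cell.append(picks)
        decoded_per_cell.append(decoded)
        barcode_sets.append(frozenset(decoded))
    hue = analysis.predict_color(genotype.color_counts())
    identity = analysis.clonal_identity(barcode_sets[0], barcode_sets[1])
    return PinkCloneResult(
        genotype=genotype,
        picks_per_cell=picks_per_cell,
        decoded_per_cell=decoded_per_cell,
        barcode_sets=barcode_sets,
        hue=hue,
        identity=identity,
    )


@dataclass
class LeukemiaResult:
    """Everything the leukemia-tracking workflow produces."""

    founder_barcodes: frozenset[str]
    population: simulate.Population
    reads: simulate.ReadSet
    raw_table: calling.CountTable
    extraction: calling.ExtractionStats
    qc_report: calling.QCReport
    corrected: calling.CountTable
    profile: analysis.AbundanceProfile
    dominant: list[str]
    ddpcr: simulate.DropletAssay
    copy_number: analysis.CopyNumberEstimate
    structure: analysis.CloneStructure


def leukemia_scenario(
    seed: int = 0,
    k_integrations: int = 3,
    n_background_cells: int = 400,
    dominant_share: float = 0.75,
    n_final_cells: int = 2000,
    depth: int = 30_000,
    error_rate: float = 0.001,
    pcr_bias_sd: float = 0.5,
    min_count: int = 10,
    dominance_threshold: float = 0.10,
    n_droplets: int = 20_000,
    control_occupancy: float = 0.5,
) -> LeukemiaResult:
    """A monoclonal malignancy tracked through the whole pipeline.

    A pool of cells is transduced with one barcoded (oncogene) vector
    library at MOI ``LEUKEMIA_MOI``; a founder cell carrying exactly
    ``k_integrations`` copies expands to ``dominant_share`` of the final
    population while the remaining clones stay at background level.
    Reads are simulated with PCR bias and substitution error, called,
    QC-filtered, error-corrected and quantified; ddPCR droplets are
    simulated at the founder's true copy number and Poisson-corrected
    back into a copy-number estimate that is combined with the dominant
    barcodes into a clone structure.
    """
    seeds = _split_seed(seed, 6)
    templates = default_templates(seed=seeds[0], colors=("green",))
    pool = simulate.simulate_transduction(
        n_background_cells,
        {"green": LEUKEMIA_MOI},
        templates,
        seed=seeds[1],
    )
    founder_idx = next(
        (i for i, c in enumerate(pool.cells) if len(c.integrations) == k_integrations),
        None,
    )
    if founder_idx is None:
        raise RuntimeError(
            f"no cell with exactly {k_integrations} integrations in the pool; "
            "increase n_background_cells"
        )
    founder_clone = pool.clone_ids[founder_idx]
    founder_barcodes = pool.cells[founder_idx].barcode_set

    expanded = simulate.expand_clones(
        pool, {founder_clone: dominant_share}, n_final_cells, seed=seeds[2]
    )
    reads = simulate.simulate_reads(
        expanded,
        depth=depth,
        error_rate=error_rate,
        pcr_bias_sd=pcr_bias_sd,
        seed=seeds[3],
    )
    template_list = list(templates.values())
    raw, extraction = calling.extract_barcodes(
        reads,
        template_list,
        anchors=(simulate.DEFAULT_LEFT_ANCHOR, simulate.DEFAULT_RIGHT_ANCHOR),
        sample="leukemia",
    )
    filtered, qc_report = calling.qc_filter(raw, template_list, min_count=min_count)
    corrected = calling.error_correct(filtered, template_list)
    profile = analysis.abundance_profile(corrected)
    dominant = analysis.detect_dominant(profile, threshold=dominance_threshold)

    ddpcr = simulate.simulate_ddpcr(
        copy_number=k_integrations,
        control_occupancy=control_occupancy,
        n_droplets=n_droplets,
        seed=seeds[4],
    )
    copy_number = analysis.ddpcr_copy_number(ddpcr)
    structure = analysis.infer_clone_structure(dominant, copy_number.estimate)
    return LeukemiaResult(
        founder_barcodes=founder_barcodes,
        population=expanded,
        reads=reads,
        raw_table=raw,
        extraction=extraction,
        qc_report=qc_report,
        corrected=corrected,
        profile=profile,
        dominant=dominant,
        ddpcr=ddpcr,
        copy_number=copy_number,
        structure=structure,
    )
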