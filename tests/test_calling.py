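"""Extraction, quality filtering, decoding and error correction."""

import math

import pytest

from rgbarcode import calling, simulate
from rgbarcode.calling import (
    UNASSIGNED,
    CountTable,
    decode_signature,
    error_correct,
    extract_barcodes,
    qc_filter,
    unique_barcode_count,
)
from rgbarcode.design import _random_fills, generate_library
from rgbarcode.simulate import (
    DEFAULT_LEFT_ANCHOR,
    DEFAULT_RIGHT_ANCHOR,
    CellGenotype,
    Population,
    ReadSet,
    reverse_complement,
    simulate_reads,
)

ANCHORS = (DEFAULT_LEFT_ANCHOR, DEFAULT_RIGHT_ANCHOR)


def _population_with_depths(templates, per_barcode: dict[str, int]):
    """One cell per planted barcode; read depths set via copy counts."""
    cells = []
    for i, (bc, copies) in enumerate(sorted(per_barcode.items())):
        cells.append(CellGenotype(i, tuple(("red", bc) for _ in range(copies))))
    return Population(cells=cells)


def _planted_reads(templates, per_barcode: dict[str, int]) -> ReadSet:
    """Error-free reads with exactly the requested per-barcode depths."""
    records, truth = [], {}
    i = 0
    for bc, depth in sorted(per_barcode.items()):
        for _ in range(depth):
            rid = f"r{i:06d}"
            seq = DEFAULT_LEFT_ANCHOR + bc + DEFAULT_RIGHT_ANCHOR
            records.append((rid, seq, "I" * len(seq)))
            truth[rid] = bc
            i += 1
    return ReadSet(records=records, truth=truth)


class TestExtraction:
    def test_error_free_counts_are_exact(self, templates, template_list):
        lib = generate_library(templates["red"], 5, seed=1)
        planted = {bc: 10 + 3 * i for i, bc in enumerate(lib.barcodes)}
        reads = _planted_reads(templates, planted)
        table, stats = extract_barcodes(reads, template_list, ANCHORS)
        assert stats.anchored == stats.reads_in == len(reads)
        assert stats.unassigned == 0
        assert table.sample_counts("sample") == planted

    def test_anchorless_read_is_unassigned_and_totals_conserved(self, template_list):
        seq = "T" * 60
        reads = ReadSet(records=[("r0", seq, "I" * 60)], truth={"r0": ""})
        table, stats = extract_barcodes(reads, template_list, ANCHORS)
        assert stats.unassigned == 1 and stats.anchored == 0
        assert stats.anchored + stats.unassigned == stats.reads_in
        assert len(table) == 0

    def test_n_in_window_is_unassigned(self, templates, template_list):
        bc = generate_library(templates["red"], 1, seed=1).barcodes[0]
        bad = bc[:5] + "N" + bc[6:]
        seq = DEFAULT_LEFT_ANCHOR + bad + DEFAULT_RIGHT_ANCHOR
        reads = ReadSet(records=[("r0", seq, "I" * len(seq))], truth={"r0": bad})
        _, stats = extract_barcodes(reads, template_list, ANCHORS)
        assert stats.unassigned == 1

    def test_reverse_complement_read_maps_to_forward_twin(self, templates, template_list):
        bc = generate_library(templates["red"], 1, seed=2).barcodes[0]
        fwd = DEFAULT_LEFT_ANCHOR + bc + DEFAULT_RIGHT_ANCHOR
        reads = ReadSet(
            records=[
                ("f", fwd, "I" * len(fwd)),
                ("r", reverse_complement(fwd), "I" * len(fwd)),
            ],
            truth={"f": bc, "r": bc},
        )
        table, stats = extract_barcodes(reads, template_list, ANCHORS, handle_rc=True)
        assert stats.anchored == 2
        assert table.sample_counts("sample") == {bc: 2}
        # without RC handling the reverse read is unassigned
        _, stats_fwd = extract_barcodes(reads, template_list, ANCHORS)
        assert stats_fwd.unassigned == 1

    def test_empty_template_list_rejected(self, templates):
        reads = _planted_reads(templates, {})
        with pytest.raises(ValueError):
            extract_barcodes(reads, [], ANCHORS)


class TestQcFilter:
    def test_frequency_threshold_boundary(self, templates, template_list):
        lib = generate_library(templates["red"], 2, seed=3)
        a, b = lib.barcodes
        table = CountTable.from_counts({a: 10, b: 9}, barcode_length=38)
        filtered, report = qc_filter(table, template_list, min_count=10)
        assert filtered.sample_counts("sample") == {a: 10}
        assert report.entries_signature_pass == 2
        assert report.entries_retained == 1
        assert report.reads_in == 19 and report.reads_retained == 10

    def test_single_fixed_position_mismatch_removed(self, templates, template_list):
        bc = generate_library(templates["red"], 1, seed=4).barcodes[0]
        fixed_idx = int(templates["red"].layout.fixed_positions[0])
        wrong = "".join(
            ("A" if bc[i] != "A" else "C") if i == fixed_idx else c
            for i, c in enumerate(bc)
        )
        table = CountTable.from_counts({bc: 100, wrong: 100}, barcode_length=38)
        filtered, _ = qc_filter(table, template_list)
        assert filtered.sample_counts("sample") == {bc: 100}

    def test_idempotent(self, templates, template_list):
        lib = generate_library(templates["red"], 20, seed=5)
        table = CountTable.from_counts(
            {bc: 5 + i for i, bc in enumerate(lib.barcodes)}, barcode_length=38
        )
        once, _ = qc_filter(table, template_list)
        twice, report = qc_filter(once, template_list)
        assert once.df.equals(twice.df)
        assert report.pass_fraction == 1.0


class TestDecode:
    def test_library_barcodes_decode_to_their_color(self, templates, template_list):
        for color in templates:
            for bc in generate_library(templates[color], 20, seed=6).barcodes:
                assert decode_signature(bc, template_list, strict=True) == color

    def test_tolerant_mode_survives_one_signature_error(self, templates, template_list):
        bc = generate_library(templates["red"], 1, seed=7).barcodes[0]
        idx = int(templates["red"].layout.fixed_positions[3])
        mutated = bc[:idx] + ("A" if bc[idx] != "A" else "C") + bc[idx + 1 :]
        assert decode_signature(mutated, template_list, strict=True) == UNASSIGNED
        assert decode_signature(mutated, template_list, strict=False) == "red"

    def test_equidistant_is_unassigned(self, layout, template_list):
        """A fixed part equally far from two signatures stays ambiguous."""
        red = template_list[0].signature.fixed_seq
        green = template_list[1].signature.fixed_seq
        diff = [i for i in range(22) if red[i] != green[i]]
        half = diff[: len(diff) // 2]
        hybrid = "".join(green[i] if i in half else red[i] for i in range(22))
        if len(diff) % 2 == 1:  # make it exactly equidistant
            hybrid = list(hybrid)
            i = diff[-1]
            hybrid[i] = next(c for c in "ACGT" if c not in (red[i], green[i]))
            hybrid = "".join(hybrid)
        # rebuild a full-length barcode around the hybrid fixed part
        fixed_pos = list(template_list[0].layout.fixed_positions)
        bc = ["A"] * 38
        for k, i in enumerate(fixed_pos):
            bc[i] = hybrid[k]
        result = decode_signature("".join(bc), template_list, strict=False, tolerance=22)
        assert result == UNASSIGNED

    def test_length_mismatch_rejected(self, template_list):
        with pytest.raises(ValueError):
            decode_signature("ACGT", template_list)


class TestErrorCorrect:
    def _pair(self, templates, counts):
        bc = generate_library(templates["red"], 1, seed=8).barcodes[0]
        rand_idx = int(templates["red"].layout.random_positions[0])
        sat = bc[:rand_idx] + ("A" if bc[rand_idx] != "A" else "C") + bc[rand_idx + 1 :]
        table = CountTable.from_counts(
            {bc: counts[0], sat: counts[1]}, barcode_length=38
        )
        return bc, sat, table

    def test_satellite_absorbed(self, templates, template_list):
        bc, _sat, table = self._pair(templates, (100, 3))
        out = error_correct(table, template_list)
        assert out.sample_counts("sample") == {bc: 103}

    def test_ratio_guard_keeps_coabundant_barcodes(self, templates, template_list):
        bc, sat, table = self._pair(templates, (100, 80))
        out = error_correct(table, template_list)
        assert out.sample_counts("sample") == {bc: 100, sat: 80}

    def test_singleton_unchanged(self, templates, template_list):
        bc = generate_library(templates["red"], 1, seed=9).barcodes[0]
        table = CountTable.from_counts({bc: 42}, barcode_length=38)
        out = error_correct(table, template_list)
        assert out.sample_counts("sample") == {bc: 42}

    def test_total_reads_conserved(self, templates, template_list):
        lib = generate_library(templates["red"], 30, seed=10)
        table = CountTable.from_counts(
            {bc: 1 + 7 * i for i, bc in enumerate(lib.barcodes)}, barcode_length=38
        )
        out = error_correct(table, template_list)
        assert out.total_reads() == table.total_reads()

    def test_different_signatures_never_merge(self, templates, template_list):
        red = generate_library(templates["red"], 1, seed=11).barcodes[0]
        # same random part under the blue signature
        rand = templates["red"].random_part(red)
        blue_t = templates["blue"]
        bc_blue = list(blue_t.rendered)
        for i, c in zip(blue_t.layout.random_positions, rand):
            bc_blue[i] = c
        table = CountTable.from_counts(
            {red: 1000, "".join(bc_blue): 2}, barcode_length=38
        )
        out = error_correct(table, template_list)
        assert len(out) == 2


class TestEndToEnd:
    def test_exact_recovery_zero_error(self, templates, template_list):
        """Zero error + depth >= min_count => exact planted counts out."""
        pop = _population_with_depths(templates, {})
        lib = generate_library(templates["red"], 40, seed=12)
        pop = Population(
            cells=[CellGenotype(i, (("red", bc),)) for i, bc in enumerate(lib.barcodes)]
        )
        depth = 40 * 25
        reads = simulate_reads(pop, depth=depth, error_rate=0.0, pcr_bias_sd=0.0, seed=13)
        raw, stats = extract_barcodes(reads, template_list, ANCHORS)
        assert stats.unassigned == 0
        filtered, _ = qc_filter(raw, template_list, min_count=10)
        corrected = error_correct(filtered, template_list)
        planted = {}
        for bc in reads.truth.values():
            planted[bc] = planted.get(bc, 0) + 1
        kept = {bc: c for bc, c in planted.items() if c >= 10}
        assert corrected.sample_counts("sample") == kept

    def test_robust_recovery_with_errors(self, templates, template_list):
        """Planted set recovered exactly after QC + correction at e=0.003."""
        lib = generate_library(templates["red"], 60, seed=14)
        pop = Population(
            cells=[CellGenotype(i, (("red", bc),)) for i, bc in enumerate(lib.barcodes)]
        )
        reads = simulate_reads(
            pop, depth=60 * 150, error_rate=0.003, pcr_bias_sd=0.0, seed=15
        )
        raw, _ = extract_barcodes(reads, template_list, ANCHORS)
        filtered, _ = qc_filter(raw, template_list, min_count=10)
        corrected = error_correct(filtered, template_list)
        assert set(corrected.sample_counts("sample")) == set(lib.barcodes)

    def test_unique_barcode_count_strata(self, templates, template_list):
        red = generate_library(templates["red"], 3, seed=16).barcodes
        blue = generate_library(templates["blue"], 2, seed=17).barcodes
        counts = {bc: 20 for bc in red + blue}
        table = CountTable.from_counts(counts, barcode_length=38)
        out = unique_barcode_count(table, template_list)
        by_color = dict(zip(out["color"], out["unique_barcodes"]))
        assert by_color == {"red": 3, "blue": 2}

    def test_unique_barcode_count_empty(self, template_list):
        import pandas as pd

        table = CountTable(df=pd.DataFrame(columns=["sample", "barcode", "count"]))
        assert len(unique_barcode_count(table, template_list)) == 0
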