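"""Demultiplexing, barcode matching, and count-table construction."""

import numpy as np
import pandas as pd
import pytest

from barseqfit import (
    BarcodeCatalog,
    ReadLayout,
    SimulationConfig,
    combine_tags,
    count_barcodes,
    demultiplex_read,
    match_barcode,
    validate_sample_sheet,
    write_reads,
)

LAYOUT = ReadLayout(spacer="GTCGA", barcode_length=8, read_length=42)


@pytest.fixture()
def tiny_catalog():
    return BarcodeCatalog(
        pd.DataFrame(
            {
                "uptag_seq": ["AAAAAAAA", "CCCCCCCC", "GGGGGGGG"],
                "dntag_seq": ["AAAATTTT", "CCCCTTTT", "GGGGTTTT"],
            },
            index=pd.Index(["m1", "m2", "m3"], name="mutant_id"),
        )
    )


@pytest.fixture()
def tiny_sheet():
    return validate_sample_sheet(
        pd.DataFrame(
            {
                "sample_id": ["s_up", "s_dn"],
                "index_seq": ["CGAT", "TATA"],
                "tag_class": ["up", "dn"],
                "condition": ["control", "control"],
                "batch": ["1", "1"],
                "fastq": ["run.fastq", "run.fastq"],
            }
        )
    )


def fastq_text(seqs):
    return "".join(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n" for i, s in enumerate(seqs))


def pad(seq):
    return seq + "A" * (42 - len(seq))


class TestDemultiplex:
    def test_exact_prefix_assigns(self):
        assert demultiplex_read("CGATTTAC" + "A" * 34, {"CGAT": "S1"}) == "S1"

    def test_unknown_prefix_unassigned(self):
        assert demultiplex_read("NNNN" + "A" * 38, {"CGAT": "S1"}) is None

    def test_one_mismatch_is_unassigned(self):
        # zero-tolerance rule: 3-4 nt indices cannot absorb mismatches
        assert demultiplex_read("CGAA" + "A" * 38, {"CGAT": "S1"}) is None

    def test_case_insensitive(self):
        assert demultiplex_read("cgatTT" + "A" * 36, {"CGAT": "S1"}) == "S1"

    def test_mixed_index_lengths(self):
        table = {"CTA": "S1", "CGAT": "S2"}
        assert demultiplex_read("CTA" + "G" * 39, table) == "S1"
        assert demultiplex_read("CGAT" + "G" * 38, table) == "S2"

    def test_duplicate_index_rejected_at_load(self, tiny_sheet):
        bad = tiny_sheet.copy()
        bad.loc[1, "index_seq"] = "CGAT"
        with pytest.raises(ValueError, match="share an index"):
            validate_sample_sheet(bad)

    def test_prefix_collision_rejected_at_load(self, tiny_sheet):
        bad = tiny_sheet.copy()
        bad.loc[1, "index_seq"] = "CGA"
        with pytest.raises(ValueError, match="prefix"):
            validate_sample_sheet(bad)


class TestMatchBarcode:
    def test_exact_match(self, tiny_catalog):
        assert match_barcode("AAAAAAAA", tiny_catalog, "up") == ("m1", "assigned")

    def test_one_mismatch_unique(self, tiny_catalog):
        assert match_barcode("AAAAAAAT", tiny_catalog, "up", max_mismatch=1) == ("m1", "assigned")
        assert match_barcode("AAAAAAAT", tiny_catalog, "up", max_mismatch=0) == (None, "unassigned")

    def test_equidistant_tie_is_ambiguous(self):
        catalog = BarcodeCatalog(
            pd.DataFrame(
                {"uptag_seq": ["AAAA", "AAAT"], "dntag_seq": ["CCCC", "GGGG"]},
                index=pd.Index(["m1", "m2"], name="mutant_id"),
            )
        )
        # AAAG is at distance 1 from both catalog entries
        assert match_barcode("AAAG", catalog, "up", max_mismatch=1) == (None, "ambiguous")

    def test_length_mismatch_unassigned_not_raised(self, tiny_catalog):
        assert match_barcode("AAAA", tiny_catalog, "up") == (None, "unassigned")

    def test_far_sequence_unassigned(self, tiny_catalog):
        assert match_barcode("TTTTTTTT", tiny_catalog, "up") == (None, "unassigned")


class TestCountBarcodes:
    def write_run(self, tmp_path, seqs):
        path = tmp_path / "run.fastq"
        path.write_text(fastq_text(seqs))
        return path

    def test_hand_built_reads_match_oracle(
        self, tmp_path, tiny_catalog, tiny_sheet, brute_force_counter
    ):
        seqs = [
            pad("CGAT" + "GTCGA" + "AAAAAAAA"),  # exact uptag m1
            pad("CGAT" + "GTCGA" + "AAAAAAAT"),  # 1-mismatch uptag m1
            pad("CGAT" + "GTCGA" + "TTTTTTTT"),  # unassigned barcode
            pad("TATA" + "GTCGA" + "CCCCTTTT"),  # exact dntag m2
            pad("GGGG" + "GTCGA" + "AAAAAAAA"),  # unknown index
            pad("TATA" + "GTCGA" + "AAAATTTA"),  # 1-mismatch dntag m1
        ]
        path = self.write_run(tmp_path, seqs)
        res = count_barcodes([path], tiny_catalog, tiny_sheet, LAYOUT, 1, "keep-separate")
        oracle = brute_force_counter(seqs, tiny_catalog, tiny_sheet, LAYOUT, 1)
        pd.testing.assert_frame_equal(res.unit_counts, oracle, check_dtype=False)
        qc = res.file_qc.loc["run.fastq"]
        assert qc["total_reads"] == 6
        assert qc["assigned"] == 4
        assert qc["unassigned_index"] == 1
        assert qc["unassigned_barcode"] == 1

    def test_empty_fastq(self, tmp_path, tiny_catalog, tiny_sheet):
        path = self.write_run(tmp_path, [])
        res = count_barcodes([path], tiny_catalog, tiny_sheet, LAYOUT)
        assert (res.counts == 0).all().all()
        assert res.file_qc["total_reads"].sum() == 0

    def test_short_read_counted_unassigned_barcode(self, tmp_path, tiny_catalog, tiny_sheet):
        path = self.write_run(tmp_path, ["CGATGTCGAAAA"])  # shorter than index+spacer+barcode
        res = count_barcodes([path], tiny_catalog, tiny_sheet, LAYOUT)
        assert res.file_qc.loc["run.fastq", "unassigned_barcode"] == 1

    def test_truncated_fastq_names_file(self, tmp_path, tiny_catalog, tiny_sheet):
        (tmp_path / "run.fastq").write_text("@r0\nACGT\n+\n")  # missing quality line
        with pytest.raises(ValueError, match="run.fastq"):
            count_barcodes([tmp_path / "run.fastq"], tiny_catalog, tiny_sheet, LAYOUT)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            BarcodeCatalog(pd.DataFrame(columns=["uptag_seq", "dntag_seq"]))

    def test_qc_conservation_and_mismatch_monotonicity(
        self, tmp_path, small_design, small_sheet, small_counts
    ):
        """On an error-laden synthetic run: QC categories partition all reads,
        and allowing one mismatch never decreases the assigned count."""
        config = SimulationConfig(n_mutants=30, reads_per_sample=20_000, seed=5, error_rate=0.01)
        write_reads(small_counts, small_design, small_sheet, config, tmp_path)
        fastqs = sorted(tmp_path.glob("*.fastq"))
        catalog = small_design.catalog()
        assigned = {}
        for mm in (0, 1):
            res = count_barcodes(fastqs, catalog, small_sheet, small_design.layout, mm)
            qc = res.file_qc
            assert (
                qc[["assigned", "unassigned_index", "unassigned_barcode", "ambiguous"]].sum(axis=1)
                == qc["total_reads"]
            ).all()
            assigned[mm] = qc["assigned"].sum()
        assert assigned[1] >= assigned[0]

    def test_read_order_invariance(self, tmp_path, tiny_catalog, tiny_sheet):
        rng = np.random.default_rng(0)
        seqs = [
            pad("CGAT" + "GTCGA" + bc)
            for bc in ("AAAAAAAA", "CCCCCCCC", "GGGGGGGG", "AAAAAAAT", "TTTTTTTT")
            for _ in range(4)
        ]
        a = self.write_run(tmp_path, seqs)
        res_a = count_barcodes([a], tiny_catalog, tiny_sheet, LAYOUT)
        shuffled = list(seqs)
        rng.shuffle(shuffled)
        (tmp_path / "run.fastq").write_text(fastq_text(shuffled))
        res_b = count_barcodes([a], tiny_catalog, tiny_sheet, LAYOUT)
        pd.testing.assert_frame_equal(res_a.counts, res_b.counts)

    def test_simulated_roundtrip_exact(self, tmp_path, small_design, small_sheet, small_counts):
        config = SimulationConfig(n_mutants=30, reads_per_sample=20_000, seed=42)
        write_reads(small_counts, small_design, small_sheet, config, tmp_path)
        res = count_barcodes(
            sorted(tmp_path.glob("*.fastq")),
            small_design.catalog(),
            small_sheet,
            small_design.layout,
            1,
            "keep-separate",
        )
        pd.testing.assert_frame_equal(res.unit_counts, small_counts.astype(np.int64))

    def test_error_rate_roundtrip_within_tolerance(self, tmp_path):
        """At error 0.005 the assigned fraction matches the substitution model
        and surviving per-mutant shares are nearly unbiased."""
        from barseqfit import FitnessModel, generate_library, make_sample_sheet, simulate_experiment

        n = 50
        design = generate_library(n, seed=21)
        fm = FitnessModel.neutral(n)
        config = SimulationConfig(n_mutants=n, reads_per_sample=100_000, seed=3, error_rate=0.005)
        sheet = make_sample_sheet(["control"], n_batches=1)
        counts = simulate_experiment(design, {"x": fm}, config, sheet)
        write_reads(counts, design, sheet, config, tmp_path)
        res = count_barcodes(
            sorted(tmp_path.glob("*.fastq")), design.catalog(), sheet, design.layout, 1, "keep-separate"
        )
        e = 0.005
        # index must be error-free (exact demux); barcode survives <= 1 substitution
        p_index_ok = (1 - e) ** 4
        p_barcode_ok = (1 - e) ** 20 + 20 * e * (1 - e) ** 19
        expected_assigned = p_index_ok * p_barcode_ok
        qc = res.file_qc.iloc[0]
        assert qc["assigned"] / qc["total_reads"] == pytest.approx(expected_assigned, abs=0.005)
        # loss is uniform across mutants: recovered shares track input shares within 2%
        share_in = counts / counts.sum(axis=0)
        share_out = res.unit_counts / res.unit_counts.sum(axis=0)
        rel = (share_out - share_in).abs() / share_in
        assert rel.to_numpy().max() < 0.02 * 4  # 2% systematic + sampling slack on ~2000-read bins


class TestCombineTags:
    def test_modes(self, tiny_sheet):
        unit = pd.DataFrame(
            {"s_up": [1, 2, 3], "s_dn": [10, 20, 30]}, index=["m1", "m2", "m3"]
        )
        summed = combine_tags(unit, tiny_sheet, "sum")
        assert list(summed.columns) == ["control.1"]
        assert summed["control.1"].tolist() == [11, 22, 33]
        up = combine_tags(unit, tiny_sheet, "uptag-only")
        assert up["control.1"].tolist() == [1, 2, 3]
        dn = combine_tags(unit, tiny_sheet, "dntag-only")
        assert dn["control.1"].tolist() == [10, 20, 30]
        sep = combine_tags(unit, tiny_sheet, "keep-separate")
        assert list(sep.columns) == ["s_up", "s_dn"]
        with pytest.raises(ValueError):
            combine_tags(unit, tiny_sheet, "median")
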