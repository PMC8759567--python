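"""Loading, harmonisation, scaling and annotation of omics layers."""

import numpy as np
import pandas as pd
import pytest

from tadomics import (
    OmicsTable,
    annotate_genes,
    assign_tads,
    build_aggregated_table,
    harmonize_samples,
    load_omics_table,
    load_segments,
    reverse_methylation,
    scale_counts,
    scale_freq,
)
from tadomics.aggregate import gene_models

from conftest import make_agg, naive_assign, run_bundle, toy_gtf


def write_table(path, rows, samples=("A", "B")):
    header = "event_id\tchrom\tstart\tend\t" + "\t".join(samples)
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestLoading:
    def test_identity_readback(self, tmp_path):
        path = write_table(tmp_path / "m.tsv", [
            "cg1\tchr1\t100\t102\t0\t50",
            "cg2\tchr2\t200\t202\t50\t100",
            "cg3\tchr3\t300\t302\t100\t0",
        ])
        t = load_omics_table(path, "freq")
        assert t.kind == "freq" and len(t.events) == 3
        assert t.sample_ids == ["A", "B"]
        assert t.values.loc["cg1", "A"] == 0 and t.values.loc["cg3", "A"] == 100

    def test_chromosome_filter_drops_chrX(self, tmp_path):
        path = write_table(tmp_path / "m.tsv", [
            "cg1\tchr1\t100\t102\t0\t50",
            "cgX\tchrX\t100\t102\t10\t20",
        ])
        t = load_omics_table(path, "freq")
        assert list(t.events["event_id"]) == ["cg1"]

    def test_write_reload_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        events = pd.DataFrame({
            "event_id": [f"e{i}" for i in range(5)],
            "chrom": "chr2", "start": np.arange(5) * 10,
            "end": np.arange(5) * 10 + 2})
        values = pd.DataFrame(rng.integers(0, 100, (5, 3)),
                              index=events["event_id"], columns=list("PQR"))
        t = OmicsTable("orig.tsv", "freq", events, values.astype(float))
        t.write(tmp_path / "rt.tsv")
        back = load_omics_table(tmp_path / "rt.tsv", "freq")
        pd.testing.assert_frame_equal(
            back.events.reset_index(drop=True), events)
        np.testing.assert_allclose(back.values.to_numpy(), values.to_numpy())

    @pytest.mark.parametrize("bad_row, message", [
        ("cg9\tchr1\toops\t102\t1\t2", "unparseable"),
        ("cg1\tchr1\t100\t102\t1\t2", "duplicate"),
    ])
    def test_hard_errors(self, tmp_path, bad_row, message):
        path = write_table(tmp_path / "m.tsv", [
            "cg1\tchr1\t100\t102\t0\t50", bad_row])
        with pytest.raises(ValueError, match=message):
            load_omics_table(path, "freq")


class TestHarmonize:
    def _tables(self):
        ev = pd.DataFrame({"event_id": ["e1"], "chrom": ["chr1"],
                           "start": [0], "end": [2]})
        t1 = OmicsTable("a", "freq", ev, pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["e1"], columns=["A", "B", "C"]))
        ev2 = ev.assign(event_id=["e2"])
        t2 = OmicsTable("b", "freq", ev2, pd.DataFrame(
            [[4.0, 5.0, 6.0]], index=["e2"], columns=["B", "C", "D"]))
        return [t1, t2]

    def test_intersect(self):
        out = harmonize_samples(self._tables(), "intersect")
        assert all(t.sample_ids == ["B", "C"] for t in out)

    def test_union_marks_missing(self):
        out = harmonize_samples(self._tables(), "union")
        assert all(t.sample_ids == ["A", "B", "C", "D"] for t in out)
        assert np.isnan(out[1].values.loc["e2", "A"])
        assert np.isnan(out[0].values.loc["e1", "D"])

    def test_single_table_identity(self):
        t = self._tables()[0]
        for mode in ("intersect", "union"):
            out = harmonize_samples([t], mode)
            pd.testing.assert_frame_equal(out[0].values, t.values)

    def test_empty_intersection_errors(self):
        t1, t2 = self._tables()
        t2.values.columns = ["X", "Y", "Z"]
        with pytest.raises(ValueError, match="no samples"):
            harmonize_samples([t1, t2], "intersect")


class TestScaling:
    def test_counts_closed_form(self):
        col = np.array([[np.e - 1], [np.e**2 - 1], [np.e**4 - 1]])
        np.testing.assert_allclose(scale_counts(col).ravel(), [25, 50, 100])

    def test_zero_column_stays_zero(self):
        out = scale_counts(np.zeros((4, 2)))
        assert (out == 0).all()

    def test_nonzero_column_max_is_exactly_100(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            m = rng.integers(0, 500, size=(30, 4)).astype(float)
            out = scale_counts(m)
            for j in range(4):
                if (m[:, j] > 0).any():
                    assert out[:, j].max() == 100.0
            assert (out >= 0).all() and (out <= 100).all()

    def test_matches_direct_formula_and_row_order_invariance(self):
        rng = np.random.default_rng(2)
        m = rng.integers(0, 1000, size=(40, 3)).astype(float)
        expected = np.log1p(m) / np.log1p(m).max(axis=0) * 100
        np.testing.assert_allclose(scale_counts(m), expected)
        perm = rng.permutation(40)
        np.testing.assert_allclose(scale_counts(m[perm]), scale_counts(m)[perm])

    def test_counts_reject_negative_and_nonfinite(self):
        with pytest.raises(ValueError):
            scale_counts(np.array([[-1.0]]))
        with pytest.raises(ValueError):
            scale_counts(np.array([[np.inf]]))

    def test_freq_identity_and_beta_autodetect(self):
        np.testing.assert_allclose(
            scale_freq(np.array([[0.0], [50.0], [100.0]])).ravel(),
            [0, 50, 100])
        np.testing.assert_allclose(
            scale_freq(np.array([[0.0], [0.5], [1.0]])).ravel(),
            [0, 50, 100])

    def test_freq_clamps(self):
        np.testing.assert_allclose(
            scale_freq(np.array([[-3.0], [104.0]])).ravel(), [0, 100])


class TestAnnotateGenes:
    def _genes(self, tmp_path):
        return toy_gtf(tmp_path / "toy.gtf", [
            ("gene1", "chr1", 1000, 5000, "+",
             [("exon", 1000, 2000), ("exon", 4000, 5000), ("CDS", 1200, 1800)]),
            ("gene2", "chr1", 4500, 9000, "-", [("exon", 8000, 9000)]),
            ("gene3", "chr2", 100, 900, "+", [("exon", 100, 900)]),
        ])

    def test_exon_containment(self, tmp_path):
        ev = pd.DataFrame({"event_id": ["e"], "chrom": ["chr1"],
                           "start": [1900], "end": [1902]})
        out = annotate_genes(ev, self._genes(tmp_path))
        assert out.loc[0, "gene_feature"] == "exon"
        assert out.loc[0, "gene_id"] == "gene1"

    def test_cds_beats_exon(self, tmp_path):
        ev = pd.DataFrame({"event_id": ["e"], "chrom": ["chr1"],
                           "start": [1500], "end": [1502]})
        out = annotate_genes(ev, self._genes(tmp_path))
        assert out.loc[0, "gene_feature"] == "cds"

    def test_intergenic(self, tmp_path):
        ev = pd.DataFrame({"event_id": ["e"], "chrom": ["chr1"],
                           "start": [50_000], "end": [50_002]})
        out = annotate_genes(ev, self._genes(tmp_path))
        assert out.loc[0, "gene_feature"] == "intergenic"
        assert out.loc[0, "gene_id"] == ""

    def test_two_genes_joined(self, tmp_path):
        # overlaps gene1's exon [4000,5000) and gene2's intronic span
        ev = pd.DataFrame({"event_id": ["e"], "chrom": ["chr1"],
                           "start": [4600], "end": [4610]})
        out = annotate_genes(ev, self._genes(tmp_path))
        assert out.loc[0, "gene_id"] == "gene1;gene2"
        assert out.loc[0, "gene_feature"] == "exon"

    def test_unknown_chromosome_left_intergenic(self, tmp_path):
        ev = pd.DataFrame({"event_id": ["e"], "chrom": ["chr9"],
                           "start": [100], "end": [102]})
        out = annotate_genes(ev, self._genes(tmp_path))
        assert out.loc[0, "gene_feature"] == "intergenic"

    def test_gene_models_tss_by_strand(self, tmp_path):
        gm = gene_models(self._genes(tmp_path)).set_index("gene_id")
        assert gm.loc["gene1", "tss"] == 1000      # + strand: span start
        assert gm.loc["gene2", "tss"] == 9000 - 1  # - strand: last base


class TestAssignTads:
    def test_containment_and_no_candidate(self):
        segs = pd.DataFrame({"tad_id": ["T1"], "chrom": ["chr1"],
                             "start": [100], "end": [200]})
        ev = pd.DataFrame({"event_id": ["a", "b"],
                           "chrom": ["chr1", "chr7"],
                           "start": [150, 150], "end": [160, 160]})
        out = assign_tads(ev, segs)
        assert list(out["tad_id"]) == ["T1", ""]

    def test_boundary_tie_lexicographic(self):
        segs = pd.DataFrame({"tad_id": ["TB", "TA"], "chrom": ["chr1"] * 2,
                             "start": [0, 100], "end": [100, 200]})
        ev = pd.DataFrame({"event_id": ["e"], "chrom": ["chr1"],
                           "start": [95], "end": [105]})
        out = assign_tads(ev, segs)
        assert out.loc[0, "tad_id"] == "TA"  # 5 vs 5 bases, TA < TB

    def test_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(3)
        segs = pd.DataFrame({
            "tad_id": [f"T{i:03d}" for i in range(60)],
            "chrom": rng.choice(["chr1", "chr2"], 60),
            "start": rng.integers(0, 10_000, 60)})
        segs["end"] = segs["start"] + rng.integers(50, 600, 60)
        ev = pd.DataFrame({
            "event_id": [f"e{i}" for i in range(300)],
            "chrom": rng.choice(["chr1", "chr2", "chr3"], 300),
            "start": rng.integers(0, 10_500, 300)})
        ev["end"] = ev["start"] + rng.integers(1, 80, 300)
        out = assign_tads(ev, segs)
        assert list(out["tad_id"]) == naive_assign(ev, segs)


class TestReverseMethylation:
    def _agg(self):
        values = pd.DataFrame(
            {"S1": [0.0, 25.0, 60.0], "S2": [100.0, 75.0, 40.0]},
            index=["cg1", "cg2", "t1"])
        agg = make_agg(values, sources=["meth.tsv", "meth.tsv", "expr.tsv"])
        agg.annotations.loc[["cg1", "cg2"], "gene_feature"] = "promoter"
        return agg

    def test_complement_on_selected_rows_only(self):
        rev = reverse_methylation(self._agg(), ["meth.tsv"], ("promoter",))
        assert rev.values.loc["cg1", "S1"] == 100.0
        assert rev.values.loc["cg1", "S2"] == 0.0
        assert rev.values.loc["cg2", "S1"] == 75.0
        assert rev.values.loc["t1", "S1"] == 60.0  # expression untouched

    def test_involution(self):
        agg = self._agg()
        twice = reverse_methylation(
            reverse_methylation(agg, ["meth.tsv"], ("promoter",)),
            ["meth.tsv"], ("promoter",))
        pd.testing.assert_frame_equal(twice.values, agg.values)

    def test_unknown_source_errors(self):
        with pytest.raises(ValueError, match="unknown source"):
            reverse_methylation(self._agg(), ["nope.tsv"], ("promoter",))


class TestBuildAggregated:
    def test_bundle_bookkeeping(self, small_planted_run, tmp_path):
        bundle, agg, meta = small_planted_run
        # 50 TADs x 20 events, nothing outside chr1-22, so nothing dropped
        assert agg.n_events == 1000
        assert len(agg.sample_ids) == 40
        vals = agg.values.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 100
        assert set(agg.source_map.values()) == {"freq", "count"}
        agg.save(tmp_path)
        summary = (tmp_path / "summary.txt").read_text()
        assert "methylation.tsv\tfreq" in summary
        assert "expression.tsv\tcount" in summary

    def test_row_count_is_sum_of_layers(self, tmp_path):
        rows_a = ["cg1\tchr1\t100\t102\t0\t50", "cg2\tchr1\t200\t202\t50\t100"]
        rows_b = ["t1\tchr1\t100\t400\t3\t9"]
        (tmp_path / "freq").mkdir(); (tmp_path / "counts").mkdir()
        write_table(tmp_path / "freq" / "m.tsv", rows_a)
        write_table(tmp_path / "counts" / "e.tsv", rows_b)
        toy_gtf(tmp_path / "g.gtf",
                [("gene1", "chr1", 100, 400, "+", [("exon", 100, 400)])])
        (tmp_path / "tads.bed").write_text("chr1\t0\t1000\tT1\n")
        from tadomics import load_omics_dir
        tables = load_omics_dir(tmp_path / "freq", tmp_path / "counts")
        agg = build_aggregated_table(
            tables, load_segments(tmp_path / "tads.bed"), tmp_path / "g.gtf")
        assert agg.n_events == 3
        assert set(agg.annotations["tad_id"]) == {"T1"}
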