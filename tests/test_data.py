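import numpy as np
import pandas as pd
import pytest

import methylclass as mc
from methylclass.data import (read_beta_matrix, write_beta_matrix,
                              read_manifest, write_manifest,
                              read_sample_sheet, write_sample_sheet)


def manifest_from(records):
    df = pd.DataFrame(records, columns=["probe_id", "chromosome", "position",
                                        "snp_flag", "cross_reactive_flag"])
    return mc.ProbeManifest(df.set_index("probe_id"))


class TestBetaMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="beta out of range"):
            mc.BetaMatrix([[1.2]], ["cg1"], ["s1"], ["450k"])
        with pytest.raises(ValueError, match="finite"):
            mc.BetaMatrix([[np.nan]], ["cg1"], ["s1"], ["450k"])
        with pytest.raises(ValueError, match="duplicate probe"):
            mc.BetaMatrix([[0.1], [0.2]], ["cg1", "cg1"], ["s1"], ["450k"])
        with pytest.raises(ValueError, match="platform"):
            mc.BetaMatrix([[0.1]], ["cg1"], ["s1"], ["27k"])

    def test_shape_and_views(self, toy_bm):
        assert toy_bm.values.shape == (3, 2)
        assert toy_bm.X.shape == (2, 3)
        sub = toy_bm.subset_probes(["cg3", "cg1"])
        assert list(sub.probe_ids) == ["cg3", "cg1"]
        assert np.allclose(sub.values[0], [0.2, 0.8])


class TestIO:
    def test_load_toy_file(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("probe_id\ts1\ts2\ncg1\t0.1\t0.9\ncg2\t0.5\t0.5\ncg3\t0.2\t0.8\n")
        bm = read_beta_matrix(path)
        assert bm.values.shape == (3, 2)
        assert list(bm.sample_ids) == ["s1", "s2"]

    def test_out_of_range_value_errors(self, tmp_path):
        path = tmp_path / "beta.tsv"
        path.write_text("probe_id\ts1\ncg1\t1.2\n")
        with pytest.raises(ValueError, match="beta out of range"):
            read_beta_matrix(path)

    def test_roundtrip_simulated_cohort(self, tmp_path, small_cohort):
        """Write -> read preserves ids exactly and values to 1e-12."""
        bm, sheet, man, _ = small_cohort
        write_beta_matrix(bm, tmp_path / "b.tsv")
        write_manifest(man, tmp_path / "m.tsv")
        write_sample_sheet(sheet, tmp_path / "s.csv")
        bm2, man2, sheet2 = mc.load_beta_matrix(tmp_path / "b.tsv",
                                                tmp_path / "m.tsv",
                                                tmp_path / "s.csv")
        assert list(bm2.probe_ids) == list(bm.probe_ids)
        assert list(bm2.sample_ids) == list(bm.sample_ids)
        assert np.abs(bm2.values - bm.values).max() < 1e-12
        assert man2.table.equals(man.table)
        assert list(bm2.platform) == list(bm.platform)  # via sheet column

    def test_sheet_sample_missing_from_matrix(self, tmp_path, small_cohort):
        bm, sheet, man, _ = small_cohort
        write_beta_matrix(bm.subset_samples(bm.sample_ids[:-1]), tmp_path / "b.tsv")
        write_manifest(man, tmp_path / "m.tsv")
        write_sample_sheet(sheet, tmp_path / "s.csv")
        with pytest.raises(ValueError, match="missing from matrix"):
            mc.load_beta_matrix(tmp_path / "b.tsv", tmp_path / "m.tsv",
                                tmp_path / "s.csv")

    def test_transposed_orientation(self, tmp_path, toy_bm):
        df = toy_bm.to_frame().T
        path = tmp_path / "t.csv"
        df.to_csv(path, index_label="sample_id")
        bm = read_beta_matrix(path, orientation="samples_as_rows")
        assert np.allclose(bm.values, toy_bm.values)
        assert list(bm.probe_ids) == list(toy_bm.probe_ids)


class TestFilterProbes:
    def test_flagged_probes_removed(self):
        bm = mc.BetaMatrix(np.full((5, 2), 0.5),
                           [f"cg{i}" for i in range(5)], ["s1", "s2"],
                           ["450k"] * 2)
        man = manifest_from([
            ("cg0", "chrX", 100, 0, 0),
            ("cg1", "chr1", 200, 1, 0),
            ("cg2", "chr2", 300, 0, 1),
            ("cg3", "chr3", 400, 0, 0),
            ("cg4", "chr4", 500, 0, 0),
        ])
        out = mc.filter_probes(bm, man)
        assert list(out.probe_ids) == ["cg3", "cg4"]

    def test_clean_manifest_is_noop_and_idempotent(self, small_cohort):
        bm, _, man, _ = small_cohort
        once = mc.filter_probes(bm, man)
        twice = mc.filter_probes(once, man)
        assert list(once.probe_ids) == list(twice.probe_ids)
        assert np.array_equal(once.values, twice.values)

    def test_probe_missing_from_manifest(self, toy_bm):
        man = manifest_from([("cg1", "chr1", 1, 0, 0)])
        with pytest.raises(ValueError, match="missing from manifest"):
            mc.filter_probes(toy_bm, man)

    def test_all_flagged_warns_and_empties(self):
        bm = mc.BetaMatrix([[0.5], [0.5]], ["cg0", "cg1"], ["s1"], ["450k"])
        man = manifest_from([("cg0", "chrY", 1, 0, 0), ("cg1", "chr1", 2, 1, 0)])
        with pytest.warns(UserWarning, match="all probes removed"):
            out = mc.filter_probes(bm, man)
        assert out.n_probes == 0


class TestQCFilter:
    def test_failing_sample_removed(self):
        bm = mc.BetaMatrix(np.full((20, 2), 0.5),
                           [f"cg{i}" for i in range(20)], ["good", "bad"],
                           ["450k"] * 2)
        p = np.zeros((20, 2))
        p[:2, 1] = 0.9  # 10% failing probes in sample "bad"
        out = mc.qc_filter_samples(bm, p, mc.QCConfig())
        assert list(out.sample_ids) == ["good"]

    def test_clean_data_untouched(self, toy_bm):
        out = mc.qc_filter_samples(toy_bm, np.zeros((3, 2)))
        assert list(out.sample_ids) == list(toy_bm.sample_ids)

    def test_boundary_is_strict(self):
        """A sample failing exactly 5% of probes is retained."""
        bm = mc.BetaMatrix(np.full((20, 1), 0.5),
                           [f"cg{i}" for i in range(20)], ["edge"], ["450k"])
        p = np.zeros((20, 1))
        p[0, 0] = 0.9  # exactly 1/20 = 5%
        out = mc.qc_filter_samples(bm, p)
        assert list(out.sample_ids) == ["edge"]

    def test_shape_mismatch(self, toy_bm):
        with pytest.raises(ValueError, match="shape"):
            mc.qc_filter_samples(toy_bm, np.zeros((2, 2)))


class TestMergePlatforms:
    def _bm(self, probes, samples, fill, platform="450k"):
        rng = np.random.default_rng(abs(hash(tuple(samples))) % 2**31)
        vals = rng.uniform(0.2, 0.8, size=(len(probes), len(samples)))
        return mc.BetaMatrix(vals, probes, samples, [platform] * len(samples))

    def test_intersection_and_concatenation(self):
        a = self._bm(["A", "B", "C"], ["s1", "s2"], 0.3, "450k")
        b = self._bm(["B", "C", "D"], ["s3"], 0.6, "EPIC")
        out = mc.merge_platforms(a, b)
        assert list(out.probe_ids) == ["B", "C"]
        assert list(out.sample_ids) == ["s1", "s2", "s3"]
        assert list(out.platform) == ["450k", "450k", "EPIC"]

    def test_identical_probe_sets_preserve_values(self):
        a = self._bm(["A", "B"], ["s1"], 0.3)
        b = self._bm(["A", "B"], ["s2"], 0.6, "EPIC")
        out = mc.merge_platforms(a, b)
        assert np.array_equal(out.values[:, 0], a.values[:, 0])
        assert np.array_equal(out.values[:, 1], b.values[:, 0])

    def test_disjoint_probes_error(self):
        a = self._bm(["A"], ["s1"], 0.3)
        b = self._bm(["B"], ["s2"], 0.6)
        with pytest.raises(ValueError, match="empty probe intersection"):
            mc.merge_platforms(a, b)

    def test_duplicate_samples_error(self):
        a = self._bm(["A"], ["s1"], 0.3)
        b = self._bm(["A"], ["s1"], 0.6)
        with pytest.raises(ValueError, match="duplicate sample"):
            mc.merge_platforms(a, b)

    def test_commutativity_same_triples(self, small_cohort):
        bm = small_cohort[0]
        a, b = mc.platform_views(bm, drop_fraction=0.05, seed=3)
        ab = mc.merge_platforms(a, b)
        ba = mc.merge_platforms(b, a)
        t_ab = set(map(tuple, ab.to_frame().stack().reset_index().to_numpy()))
        t_ba = set(map(tuple, ba.to_frame().stack().reset_index().to_numpy()))
        assert t_ab == t_ba

    def test_idempotent_on_own_output(self):
        a = self._bm(["A", "B", "C"], ["s1", "s2"], 0.3)
        b = self._bm(["B", "C", "D"], ["s3"], 0.6, "EPIC")
        merged = mc.merge_platforms(a, b)
        again = mc.merge_platforms(
            merged.subset_samples(["s1", "s2"]), merged.subset_samples(["s3"]))
        assert list(again.probe_ids) == list(merged.probe_ids)
        assert np.array_equal(again.values, merged.values)
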