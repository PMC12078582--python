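"""Alteration matrix construction, burden correction, and the measure screen."""

import numpy as np
import pandas as pd
import pytest

from tblsuite import association
from tblsuite.association import AssociationConfig

from conftest import seg_frame


def make_matrix(flags: pd.DataFrame, kind="SNV", burdens=None):
    feats = pd.DataFrame({"feature": flags.columns,
                          "unit": [c.split("|")[0] for c in flags.columns],
                          "kind": kind})
    return association.AlterationMatrix(flags=flags, burdens=burdens or {},
                                        features=feats)


class TestMinimalSignificantP:
    def test_genome_wide_screen_floor(self):
        assert association.minimal_significant_p(0.05, 20000) == pytest.approx(2.5e-06)

    def test_single_test_is_alpha(self):
        assert association.minimal_significant_p(0.05, 1) == 0.05

    def test_direct_division(self):
        assert association.minimal_significant_p(0.01, 100) == pytest.approx(1e-04)


class TestAlterationMatrix:
    GENES = pd.DataFrame({"gene": ["GA", "GB"], "chromosome": ["1", "2"],
                          "start": [1000, 1000], "end": [2000, 2000]})

    def test_arm_gain_loss_neither(self):
        arms = pd.DataFrame({"arm": ["1p"], "chromosome": ["1"],
                             "start": [1], "end": [10_000]})
        seg = seg_frame([("S1", "1", 1, 10_000, 100, 0.3),
                         ("S2", "1", 1, 10_000, 100, -0.3),
                         ("S3", "1", 1, 10_000, 100, 0.1)])
        m = association.build_alteration_matrix(segments=seg, arms=arms)
        assert bool(m.flags.loc["S1", "1p|gain"]) and not m.flags.loc["S1", "1p|loss"]
        assert bool(m.flags.loc["S2", "1p|loss"]) and not m.flags.loc["S2", "1p|gain"]
        assert not m.flags.loc["S3", ["1p|gain", "1p|loss"]].any()

    def test_arm_call_is_length_weighted(self):
        arms = pd.DataFrame({"arm": ["1p"], "chromosome": ["1"],
                             "start": [1], "end": [10_000]})
        # 90% of the arm at 0.3, 10% at -1.0 -> weighted mean 0.17 -> no call
        seg = seg_frame([("S1", "1", 1, 9_000, 90, 0.3),
                         ("S1", "1", 9_001, 10_000, 10, -1.0)])
        m = association.build_alteration_matrix(segments=seg, arms=arms)
        assert not m.flags.loc["S1", ["1p|gain", "1p|loss"]].any()

    def test_sv_breakpoint_containment_sets_flag(self):
        sv = pd.DataFrame({
            "sample_id": ["S1", "S2"], "chrom1": ["1", "1"],
            "start1": [1500, 5000], "end1": [1501, 5001],
            "chrom2": ["1", "1"], "start2": [9000, 9000],
            "end2": [9001, 9001], "sv_type": ["DEL", "DEL"]})
        m = association.build_alteration_matrix(sv=sv, genes=self.GENES)
        assert bool(m.flags.loc["S1", "GA|SV"])       # breakpoint inside GA
        assert not m.flags.loc["S2", "GA|SV"]          # both ends outside
        assert m.burdens["SV"].loc["S1", "GA"] == 1

    def test_snv_flag_once_burden_counts_all(self):
        muts = pd.DataFrame({
            "sample_id": ["S1"] * 3 + ["S2"],
            "gene": ["GA"] * 3 + ["GB"], "chromosome": ["1"] * 3 + ["2"],
            "position": [1100, 1200, 1300, 1500],
            "variant_classification": ["Missense_Mutation"] * 4})
        m = association.build_alteration_matrix(mutations=muts)
        assert bool(m.flags.loc["S1", "GA|SNV"]) and m.burdens["SNV"].loc["S1", "GA"] == 3
        assert not m.flags.loc["S2", "GA|SNV"]

    def test_silent_excluded_from_flags(self):
        muts = pd.DataFrame({
            "sample_id": ["S1"], "gene": ["GA"], "chromosome": ["1"],
            "position": [1100], "variant_classification": ["Silent"]})
        m = association.build_alteration_matrix(mutations=muts)
        assert "GA|SNV" not in m.flags.columns or not m.flags["GA|SNV"].any()


class TestCorrectedMeasure:
    def test_stated_subtraction(self):
        v = pd.Series({"S1": 10.0})
        b = pd.Series({"S1": 2.0})
        assert association.corrected_measure(v, b).loc["S1"] == 8.0

    def test_floors_at_zero(self):
        v = pd.Series({"S1": 5.0})
        b = pd.Series({"S1": 5.0, "S2": 9.0})
        out = association.corrected_measure(v, b)
        assert out.loc["S1"] == 0.0

    def test_zero_burden_equals_raw_and_same_test(self, rng):
        samples = [f"S{i}" for i in range(40)]
        flags = pd.DataFrame({"GA|SV": [True] * 20 + [False] * 20},
                             index=pd.Index(samples, name="sample_id"))
        tbl = rng.poisson(30, size=40).astype(float)
        measures = pd.DataFrame({"sample_id": samples, "tbl": tbl})
        zero_b = pd.DataFrame(0, index=flags.index, columns=["GA"])
        with_corr = association.differential_measure_test(
            make_matrix(flags, "SV", {"SV": zero_b}), measures, "tbl")
        without = association.differential_measure_test(
            make_matrix(flags, "SV"), measures, "tbl")
        pd.testing.assert_frame_equal(with_corr, without)

    def test_fga_never_corrected(self, rng):
        samples = [f"S{i}" for i in range(40)]
        flags = pd.DataFrame({"GA|SV": [True] * 20 + [False] * 20},
                             index=pd.Index(samples, name="sample_id"))
        fga = rng.uniform(0, 1, size=40)
        measures = pd.DataFrame({"sample_id": samples, "fga": fga})
        burden = pd.DataFrame(5, index=flags.index, columns=["GA"])
        res = association.differential_measure_test(
            make_matrix(flags, "SV", {"SV": burden}), measures, "fga")
        bare = association.differential_measure_test(
            make_matrix(flags, "SV"), measures, "fga")
        pd.testing.assert_frame_equal(res, bare)


class TestDifferentialMeasureTest:
    def test_planted_driver_recovered(self, rng):
        samples = [f"S{i}" for i in range(100)]
        altered = np.array([True] * 50 + [False] * 50)
        tbl = np.where(altered, rng.poisson(60, 100), rng.poisson(30, 100)).astype(float)
        flags = pd.DataFrame({"DRV|SNV": altered},
                             index=pd.Index(samples, name="sample_id"))
        measures = pd.DataFrame({"sample_id": samples, "tbl": tbl})
        res = association.differential_measure_test(make_matrix(flags), measures, "tbl")
        row = res.iloc[0]
        assert row["p_adj"] < 0.05
        assert 0.7 <= row["log2_fc"] <= 1.3

    def test_min_group_filter_drops_small_features(self, rng):
        samples = [f"S{i}" for i in range(40)]
        flags = pd.DataFrame({
            "OK|SNV": [True] * 15 + [False] * 25,
            "RARE|SNV": [True] * 9 + [False] * 31,
        }, index=pd.Index(samples, name="sample_id"))
        measures = pd.DataFrame({"sample_id": samples,
                                 "tbl": rng.poisson(30, 40).astype(float)})
        res = association.differential_measure_test(make_matrix(flags), measures, "tbl")
        assert list(res["feature"]) == ["OK|SNV"]

    def test_msi_samples_excluded(self, rng):
        samples = [f"S{i}" for i in range(60)]
        flags = pd.DataFrame({"GA|SNV": [True, False] * 30},
                             index=pd.Index(samples, name="sample_id"))
        measures = pd.DataFrame({
            "sample_id": samples, "tbl": rng.poisson(30, 60).astype(float),
            "msi_status": ["MSI"] * 25 + ["MSS"] * 35})
        res = association.differential_measure_test(make_matrix(flags), measures, "tbl")
        assert res.iloc[0]["n_altered"] + res.iloc[0]["n_wt"] == 35
        keep = association.differential_measure_test(
            make_matrix(flags), measures, "tbl",
            AssociationConfig(msi_excluded=False))
        assert keep.iloc[0]["n_altered"] + keep.iloc[0]["n_wt"] == 60

    def test_null_features_fdr_controlled(self):
        rng = np.random.default_rng(31)
        samples = [f"S{i}" for i in range(100)]
        flags = pd.DataFrame(rng.random((100, 1000)) < 0.5,
                             index=pd.Index(samples, name="sample_id"),
                             columns=[f"g{j}|SNV" for j in range(1000)])
        measures = pd.DataFrame({"sample_id": samples,
                                 "tbl": rng.poisson(30, 100).astype(float)})
        res = association.differential_measure_test(make_matrix(flags), measures, "tbl")
        assert (res["p"] < 0.05).mean() < 0.07          # raw level ~ alpha
        assert (res["p_adj"] < 0.05).sum() <= 5          # BH keeps the screen clean

    def test_sample_order_invariance(self, rng):
        samples = [f"S{i}" for i in range(40)]
        flags = pd.DataFrame({"GA|SNV": rng.random(40) < 0.5},
                             index=pd.Index(samples, name="sample_id"))
        measures = pd.DataFrame({"sample_id": samples,
                                 "tbl": rng.poisson(30, 40).astype(float)})
        a = association.differential_measure_test(make_matrix(flags), measures, "tbl")
        perm = rng.permutation(40)
        b = association.differential_measure_test(
            make_matrix(flags.iloc[perm]), measures.iloc[perm], "tbl")
        pd.testing.assert_frame_equal(a, b)

    def test_bonferroni_option(self, rng):
        samples = [f"S{i}" for i in range(40)]
        flags = pd.DataFrame({"GA|SNV": [True] * 20 + [False] * 20},
                             index=pd.Index(samples, name="sample_id"))
        measures = pd.DataFrame({"sample_id": samples,
                                 "tbl": rng.poisson(30, 40).astype(float)})
        res = association.differential_measure_test(
            make_matrix(flags), measures, "tbl",
            AssociationConfig(multiple_testing="bonferroni", m=20000))
        assert res.iloc[0]["p_adj"] == pytest.approx(min(res.iloc[0]["p"] * 20000, 1.0))
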