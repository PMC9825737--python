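import numpy as np
import pytest

from dabench.core import (CountTable, SampleMetadata, ValidationError,
                          validate_experiment)
from dabench.methods import (MethodRegistry, MethodSpec, da_negbin_wald,
                             da_ttest_clr, da_wilcoxon, run_method, run_methods)
from dabench.normalization import norm_none, norm_tss


def _exp(counts, groups):
    counts = np.atleast_2d(np.asarray(counts, dtype=int))
    t = CountTable([f"f{i}" for i in range(counts.shape[0])],
                   [f"s{j}" for j in range(counts.shape[1])], counts)
    meta = SampleMetadata.from_groups(t.sample_ids, groups)
    return validate_experiment(t, meta, "group")


def _swap(exp):
    groups = exp.metadata.table["group"].map({"A": "B", "B": "A"})
    meta = SampleMetadata.from_groups(exp.table.sample_ids, groups)
    return validate_experiment(exp.table, meta, "group")


class TestRegistry:
    def test_insertion_order(self):
        reg = MethodRegistry()
        reg.register(MethodSpec("m1")).register(MethodSpec("m2"))
        assert reg.ids() == ["m1", "m2"]

    def test_duplicate_rejected(self):
        reg = MethodRegistry().register(MethodSpec("m1"))
        with pytest.raises(ValidationError, match="m1"):
            reg.register(MethodSpec("m1"))

    def test_config_round_trip(self):
        reg = MethodRegistry()
        reg.register(MethodSpec("m1", "wilcoxon", "TSS", {"x": 1}, seed=3))
        reg.register(MethodSpec("m2", "ttest_clr", "none", {}, seed=None))
        again = MethodRegistry.from_config(reg.to_config())
        assert again.to_config() == reg.to_config()

    def test_fingerprint_deterministic(self):
        s1 = MethodSpec("a", params={"x": 1})
        s2 = MethodSpec("b", params={"x": 1})
        assert s1.fingerprint() == s2.fingerprint()
        assert s1.fingerprint() != MethodSpec("c", params={"x": 2}).fingerprint()


class TestWilcoxon:
    def test_exact_enumeration_p(self):
        # (1,2,3) vs (10,11,12): most extreme of C(6,3)=20 rank splits,
        # two-sided tail mass 2/20 = 0.1
        exp = _exp([[1, 2, 3, 10, 11, 12]], list("AAABBB"))
        res = da_wilcoxon(exp, norm_none(exp.table))
        assert res.p_raw[0] == pytest.approx(0.1)
        assert res.direction[0] == 1

    def test_identical_groups(self):
        exp = _exp([[1, 2, 3, 1, 2, 3]], list("AAABBB"))
        res = da_wilcoxon(exp, norm_none(exp.table))
        assert res.p_raw[0] == pytest.approx(1.0)
        assert res.direction[0] == 0

    def test_constant_feature_missing(self):
        exp = _exp([[5, 5, 5, 5, 5, 5]], list("AAABBB"))
        res = da_wilcoxon(exp, norm_none(exp.table))
        assert np.isnan(res.p_raw[0]) and np.isnan(res.p_adj[0])

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        exp = _exp(rng.poisson(15, size=(10, 8)), list("AAAABBBB"))
        a = da_wilcoxon(exp, norm_tss(exp.table))
        b = da_wilcoxon(_swap(exp), norm_tss(exp.table))
        np.testing.assert_allclose(a.p_raw, b.p_raw, atol=1e-12)
        np.testing.assert_array_equal(a.direction, -b.direction)

    def test_within_group_permutation_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(15, size=(6, 8))
        exp = _exp(counts, list("AAAABBBB"))
        perm = [2, 0, 3, 1, 6, 7, 4, 5]  # permutes within each group
        exp2 = _exp(counts[:, perm], list("AAAABBBB"))
        a = da_wilcoxon(exp, norm_tss(exp.table))
        b = da_wilcoxon(exp2, norm_tss(exp2.table))
        np.testing.assert_allclose(a.p_raw, b.p_raw, atol=1e-12)


class TestTTestCLR:
    def test_identical_clr_profiles(self):
        # samples proportional to each other: identical CLR profiles
        base = np.array([1, 2, 4])
        counts = np.column_stack([base, base, base, base])
        exp = _exp(counts, list("AABB"))
        res = da_ttest_clr(exp, pseudocount=1e-9, mc_samples=0)
        np.testing.assert_allclose(res.p_raw, 1.0)
        np.testing.assert_array_equal(res.direction, 0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        exp = _exp(rng.poisson(30, size=(8, 8)), list("AAAABBBB"))
        a = da_ttest_clr(exp, mc_samples=0)
        b = da_ttest_clr(_swap(exp), mc_samples=0)
        np.testing.assert_allclose(a.p_raw, b.p_raw, atol=1e-12)
        np.testing.assert_array_equal(a.direction, -b.direction)

    def test_negative_mc_rejected(self):
        exp = _exp([[1, 2, 3, 4]], list("AABB"))
        with pytest.raises(ValidationError):
            da_ttest_clr(exp, mc_samples=-1)

    def test_mc_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        exp = _exp(rng.poisson(30, size=(6, 8)), list("AAAABBBB"))
        a = da_ttest_clr(exp, mc_samples=8, seed=11)
        b = da_ttest_clr(exp, mc_samples=8, seed=11)
        np.testing.assert_array_equal(a.p_raw, b.p_raw)

    def test_mc_null_calibration(self):
        # mean FPR over mocks of a null table stays near nominal
        from dabench.synthetic import sim_null
        t = sim_null(50, 20, model="NB", dispersion=0.3, seed=5)
        rng = np.random.default_rng(99)
        fprs = []
        for i in range(30):
            labels = np.zeros(20, int)
            labels[rng.permutation(20)[:10]] = 1
            meta = SampleMetadata.from_groups(t.sample_ids,
                                              np.where(labels == 0, "A", "B"))
            exp = validate_experiment(t, meta, "group")
            r = da_ttest_clr(exp, mc_samples=16, seed=i)
            fprs.append(np.mean(r.p_raw < 0.05))
        assert abs(np.mean(fprs) - 0.05) <= 0.03


class TestNegbinWald:
    def test_exact_doubling_recovers_log2(self):
        rng = np.random.default_rng(4)
        y1 = rng.poisson(30, size=(5, 20))
        counts = np.hstack([y1, 2 * y1])
        exp = _exp(counts, ["A"] * 20 + ["B"] * 20)
        res = da_negbin_wald(exp, norm_none(exp.table))
        # group-2 counts exactly double: fitted coefficient = log 2
        betas = res.statistic  # z = beta/se; recompute via direction+p instead
        assert np.all(res.direction == 1)
        # check the coefficient directly through simulation-free identity:
        # mean(y2)/mean(y1) == 2 exactly, so each fitted log-ratio ~ log 2
        from dabench.methods import _nb_irls
        g = np.array([False] * 20 + [True] * 20)
        for i in range(5):
            beta, *_ = _nb_irls(counts[i].astype(float), np.zeros(40), g, 0.01,
                                np.array([np.log(30.0), 0.0]))
            assert abs(beta[1] - np.log(2)) < 0.05

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(25, size=(60, 20))
        exp = _exp(counts, ["A"] * 10 + ["B"] * 10)
        res = da_negbin_wald(exp, norm_tss(exp.table))
        ok = ~np.isnan(res.p_raw)
        assert ok.mean() > 0.9
        assert 0.2 < np.mean(res.p_raw[ok]) < 0.8
        assert np.mean(res.p_raw[ok] < 0.05) < 0.2

    def test_all_zero_feature_missing(self):
        exp = _exp([[0, 0, 0, 0], [1, 2, 3, 4]], list("AABB"))
        res = da_negbin_wald(exp, norm_none(exp.table))
        assert np.isnan(res.p_raw[0])
        assert not np.isnan(res.p_raw[1])

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(6)
        exp = _exp(rng.poisson(20, size=(6, 8)), list("AAAABBBB"))
        a = da_negbin_wald(exp, norm_tss(exp.table))
        b = da_negbin_wald(_swap(exp), norm_tss(exp.table))
        np.testing.assert_allclose(a.p_raw, b.p_raw, atol=1e-6)
        np.testing.assert_array_equal(a.direction, -b.direction)


class TestRunMethods:
    def _registry(self):
        reg = MethodRegistry()
        reg.register(MethodSpec("w", "wilcoxon", "TSS"))
        reg.register(MethodSpec("t", "ttest_clr", "none", {"mc_samples": 0}))
        reg.register(MethodSpec("n", "negbin_wald", "TSS"))
        return reg

    def test_three_results_in_order(self, two_group_exp):
        results = run_methods(two_group_exp, self._registry(), ["w", "t", "n"])
        assert [r.method_id for r in results] == ["w", "t", "n"]

    def test_unknown_id_fails_before_running(self, two_group_exp):
        with pytest.raises(ValidationError, match="nope"):
            run_methods(two_group_exp, self._registry(), ["w", "nope"])

    def test_rerun_bitwise_identical(self, two_group_exp):
        reg = MethodRegistry().register(
            MethodSpec("t", "ttest_clr", "none", {"mc_samples": 8}, seed=5))
        a = run_methods(two_group_exp, reg, ["t"])[0]
        b = run_methods(two_group_exp, reg, ["t"])[0]
        np.testing.assert_array_equal(a.p_raw, b.p_raw)

    def test_plugin_dispatch(self, two_group_exp):
        reg = MethodRegistry().register(
            MethodSpec("pl", "plugin:_plugins.constant_result", "none"))
        res = run_method(reg.get("pl"), two_group_exp)
        assert res.method_id == "pl"
        np.testing.assert_allclose(res.p_raw, 0.5)

    def test_all_p_in_unit_interval(self, two_group_exp):
        for res in run_methods(two_group_exp, self._registry(), ["w", "t", "n"]):
            ok = ~np.isnan(res.p_raw)
            assert np.all((res.p_raw[ok] >= 0) & (res.p_raw[ok] <= 1))
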