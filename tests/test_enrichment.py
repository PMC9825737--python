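import numpy as np
import pytest
from scipy.special import comb

from dabench.core import DAResult, ValidationError
from dabench.enrichment import (ContingencyTable, EnrichmentPrior, TruthSet,
                                build_contingency, classify_features,
                                enrichment_tests, fisher_test, mutual_findings,
                                tp_fp_ranking)
from dabench.synthetic import sim_annotation


def _result(p_adj, direction, fids=None, p_raw=None, stat=None):
    p_adj = np.asarray(p_adj, dtype=float)
    m = p_adj.size
    fids = fids or [f"f{i}" for i in range(m)]
    p_raw = p_adj if p_raw is None else np.asarray(p_raw, dtype=float)
    stat = np.zeros(m) if stat is None else np.asarray(stat, dtype=float)
    return DAResult("m", fids, p_raw, p_adj, stat,
                    np.asarray(direction, dtype=np.int8))


def fisher_oracle(a, b, c, d, alternative):
    """Exhaustive hypergeometric enumeration over all tables with the
    observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1, exact=True)
    masses = {k: comb(r1, k, exact=True) * comb(r2, c1 - k, exact=True) / denom
              for k in range(lo, hi + 1)}
    if alternative == "greater":
        return sum(v for k, v in masses.items() if k >= a)
    obs = masses[a]
    return sum(v for v in masses.values() if v <= obs * (1 + 1e-12))


class TestClassify:
    def test_up(self):
        res = _result([0.01], [1])
        assert classify_features(res, 0.05) == {"f0": "UP"}

    def test_missing_is_nonda(self):
        res = _result([np.nan], [1], p_raw=[np.nan])
        assert classify_features(res, 0.05) == {"f0": "NONDA"}

    def test_zero_direction_is_nonda(self):
        res = _result([0.001], [0])
        assert classify_features(res, 0.05) == {"f0": "NONDA"}

    def test_bad_threshold(self):
        with pytest.raises(ValidationError):
            classify_features(_result([0.5], [1]), 0.0)


class TestContingency:
    def _prior(self):
        ann = {f"f{i}": "lvl" for i in range(4)}
        return EnrichmentPrior(ann, {"lvl": "UP"})

    def test_perfect_separation(self):
        classes = {f"f{i}": ("UP" if i < 4 else "NONDA") for i in range(8)}
        ann = {f"f{i}": ("lvl" if i < 4 else "other") for i in range(8)}
        prior = EnrichmentPrior(ann, {"lvl": "UP"})
        ct = build_contingency(classes, prior, "lvl", "UP")
        assert (ct.a, ct.b, ct.c, ct.d) == (4, 0, 0, 4)

    def test_nothing_called(self):
        classes = {f"f{i}": "NONDA" for i in range(8)}
        ann = {f"f{i}": ("lvl" if i < 4 else "other") for i in range(8)}
        prior = EnrichmentPrior(ann, {"lvl": "UP"})
        ct = build_contingency(classes, prior, "lvl", "UP")
        assert (ct.a, ct.c) == (0, 0)

    def test_mixed_toy(self):
        # 8 features, level size 4; 3 in-level + 1 out-of-level called UP
        classes = {"f0": "UP", "f1": "UP", "f2": "UP", "f3": "NONDA",
                   "f4": "UP", "f5": "NONDA", "f6": "NONDA", "f7": "NONDA"}
        ann = {f"f{i}": ("lvl" if i < 4 else "other") for i in range(8)}
        prior = EnrichmentPrior(ann, {"lvl": "UP"})
        ct = build_contingency(classes, prior, "lvl", "UP")
        assert (ct.a, ct.b, ct.c, ct.d) == (3, 1, 1, 3)

    def test_unannotated_excluded(self):
        classes = {"f0": "UP", "f1": "UP", "fx": "UP"}
        prior = EnrichmentPrior({"f0": "lvl", "f1": "other"}, {"lvl": "UP"})
        ct = build_contingency(classes, prior, "lvl", "UP")
        assert ct.a + ct.b + ct.c + ct.d == 2

    def test_empty_level(self):
        with pytest.raises(ValidationError):
            build_contingency({"f0": "UP"}, self._prior(), "nope", "UP")


class TestFisher:
    def test_two_sided_hand_example(self):
        p, odds = fisher_test(ContingencyTable(3, 1, 1, 3), "two_sided")
        assert p == pytest.approx(34 / 70, abs=1e-12)
        assert odds == 9.0

    def test_greater_hand_example(self):
        p, odds = fisher_test(ContingencyTable(4, 0, 0, 4), "greater")
        assert p == pytest.approx(1 / 70, abs=1e-12)
        assert np.isinf(odds)

    def test_all_zero_table(self):
        p, odds = fisher_test(ContingencyTable(0, 0, 0, 0))
        assert p == 1.0 and np.isnan(odds)

    @pytest.mark.parametrize("alternative", ["two_sided", "greater"])
    def test_matches_oracle_small_tables(self, alternative):
        rng = np.random.default_rng(1)
        for _ in range(150):
            a, b, c, d = rng.integers(0, 7, size=4)
            p, _ = fisher_test(ContingencyTable(int(a), int(b), int(c), int(d)),
                               alternative)
            assert p == pytest.approx(
                fisher_oracle(int(a), int(b), int(c), int(d), alternative),
                abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            fisher_test(ContingencyTable(-1, 0, 0, 0))


class TestMutualFindings:
    def test_disjoint_sets(self):
        r1 = _result([0.01, 1, 1, 1], [1, 0, 0, 0])
        r2 = _result([1, 0.01, 1, 1], [0, 1, 0, 0])
        counts, highlighted = mutual_findings([r1, r2], 0.05)
        assert highlighted == []
        assert counts.tolist() == [1, 1, 0, 0]

    def test_identical_sets(self):
        p = [0.01] * 5 + [1.0] * 3
        d = [1] * 5 + [0] * 3
        counts, highlighted = mutual_findings([_result(p, d), _result(p, d)], 0.05)
        assert len(highlighted) == 5
        assert (counts >= 2).sum() == 5

    def test_single_method_rejected(self):
        with pytest.raises(ValidationError):
            mutual_findings([_result([0.5], [1])], 0.05)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        rs = [_result(rng.random(10), rng.choice([-1, 1], 10)) for _ in range(3)]
        c1, _ = mutual_findings(rs, 0.5)
        c2, _ = mutual_findings(rs[::-1], 0.5)
        assert c1.tolist() == c2.tolist()


class TestTPFPRanking:
    def test_perfect_method(self):
        m, n_da = 12, 10
        truth = TruthSet([f"f{i}" for i in range(m)],
                         [True] * n_da + [False] * 2,
                         [1] * n_da + [0] * 2,
                         [3.0] * n_da + [1.0] * 2)
        p = np.concatenate([np.linspace(1e-6, 1e-3, n_da), [0.9, 0.95]])
        res = _result(p, [1] * n_da + [0, 0])
        curve = tp_fp_ranking(res, truth, thresholds=list(range(1, n_da + 1)))
        np.testing.assert_array_equal(curve.tp_minus_fp, np.arange(1, n_da + 1))

    def test_inverted_directions(self):
        m = 6
        truth = TruthSet([f"f{i}" for i in range(m)], [True] * m, [1] * m,
                         [2.0] * m)
        p = np.linspace(1e-6, 1e-3, m)
        res = _result(p, [-1] * m)
        curve = tp_fp_ranking(res, truth, thresholds=list(range(1, m + 1)))
        np.testing.assert_array_equal(curve.tp_minus_fp, -np.arange(1, m + 1))

    def test_neutral_toy(self):
        # truth UP for f1..f3; f4, f5 unannotated; ranking f1,f4,f2,f5,f3,f6
        prior = EnrichmentPrior(
            {"f1": "up", "f2": "up", "f3": "up"}, {"up": "UP"})
        fids = ["f1", "f4", "f2", "f5", "f3", "f6"]
        res = _result(np.linspace(0.01, 0.06, 6), [1] * 6, fids=fids)
        curve = tp_fp_ranking(res, prior, thresholds=list(range(1, 7)))
        np.testing.assert_array_equal(curve.tp_minus_fp, [1, 1, 2, 2, 3, 3])

    def test_full_depth_order_free(self):
        rng = np.random.default_rng(3)
        m = 20
        is_da = rng.random(m) < 0.5
        direction = np.where(is_da, rng.choice([-1, 1], m), 0)
        truth = TruthSet([f"f{i}" for i in range(m)], is_da, direction,
                         np.where(is_da, 2.0, 1.0))
        calls = rng.choice([-1, 0, 1], m)
        expected_tp = int(np.sum(is_da & (calls == direction) & (calls != 0)))
        expected_fp = int(np.sum((is_da & (calls == -direction) & (calls != 0))
                                 | (~is_da)))
        for seed in range(3):
            p = np.random.default_rng(seed).random(m)
            res = _result(p, calls)
            curve = tp_fp_ranking(res, truth, thresholds=[m])
            assert curve.tp[-1] == expected_tp
            assert curve.fp[-1] == expected_fp

    def test_bad_thresholds(self):
        truth = TruthSet(["f0"], [True], [1], [2.0])
        with pytest.raises(ValidationError):
            tp_fp_ranking(_result([0.5], [1]), truth, thresholds=[2, 1])


class TestEnrichmentTests:
    def test_noise_free_annotation_minimal_p(self):
        m = 20
        is_da = np.arange(m) < 8
        direction = np.where(np.arange(m) < 4, 1, np.where(is_da, -1, 0))
        truth = TruthSet([f"f{i}" for i in range(m)], is_da, direction,
                         np.where(is_da, 3.0, 1.0))
        prior = sim_annotation(truth, noise=0.0)
        # a perfect method: DA features significant UP, rest null
        p_adj = np.where(is_da, 0.001, 0.9)
        res = _result(p_adj, direction)
        df = enrichment_tests(res, prior, threshold=0.05)
        expected = df[df["expected"]]
        controls = df[~df["expected"]]
        assert (expected["p_value"] < controls["p_value"].min()).all()


class TestSimAnnotation:
    def test_noise_zero_aligned(self):
        truth = TruthSet(["a", "b", "c"], [True, True, False], [1, -1, 0],
                         [2.0, 2.0, 1.0])
        prior = sim_annotation(truth, 0.0)
        assert prior.annotation == {"a": "expectedUP", "b": "expectedDOWN"}
        assert prior.expected_direction == {"expectedUP": "UP",
                                            "expectedDOWN": "DOWN"}

    def test_noise_flips_exact_count(self):
        m = 40
        truth = TruthSet([f"f{i}" for i in range(m)], [True] * m,
                         [1] * 20 + [-1] * 20, [2.0] * m)
        base = sim_annotation(truth, 0.0)
        noisy = sim_annotation(truth, 0.2, seed=5)
        flipped = sum(base.annotation[f] != noisy.annotation[f]
                      for f in base.annotation)
        assert flipped == round(0.2 * m)

    def test_noise_bound(self):
        truth = TruthSet(["a"], [True], [1], [2.0])
        with pytest.raises(ValidationError):
            sim_annotation(truth, 0.5)
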