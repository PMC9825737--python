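"""Type-I-error-control engine: mock labelings with no true DA.

All samples of the input table are relabeled into two balanced random
groups N times; every requested method is run on every mock and the raw /
adjusted p-value distributions are summarized (FPR, FDR readings, KS
departure from uniformity).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import (CountTable, DAResult, SampleMetadata, ValidationError,
                   validate_experiment)
from .methods import MethodRegistry, run_method

logger = logging.getLogger("dabench.tiec")

DEFAULT_ALPHAS = (0.01, 0.05, 0.1)
DEFAULT_GAMMAS = (0.01, 0.05, 0.1)


@dataclass
class MockSet:
    sample_ids: list[str]
    labelings: np.ndarray  # N x n_samples of {0, 1}, balanced
    seed: int

    @property
    def n_mocks(self) -> int:
        return self.labelings.shape[0]


@dataclass
class MockResults:
    """Per-mock per-method DAResult collection."""
    results: dict = field(default_factory=dict)  # (mock_idx, method_id) -> DAResult
    n_mocks: int = 0
    method_ids: list[str] = field(default_factory=list)


@dataclass
class Type1Summary:
    summary: pd.DataFrame   # one row per method: fpr_*, fdr_*, any_disc_*, mean_ks
    detail: pd.DataFrame    # long: mock_id, method_id, alpha, fpr, ks
    alphas: tuple
    gammas: tuple


def create_mocks(sample_ids: list[str], n_mocks: int, seed: int) -> MockSet:
    """N balanced random two-group labelings of all samples, deterministic
    given the master seed (mock i uses the derived stream (seed, i))."""
    n = len(sample_ids)
    if n < 4:
        raise ValidationError("need >= 4 samples for a two-group split of >= 2 each")
    if n_mocks < 1:
        raise ValidationError("n_mocks must be >= 1")
    half = n // 2
    labelings = np.zeros((n_mocks, n), dtype=np.int8)
    for i in range(n_mocks):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        perm = rng.permutation(n)
        labelings[i, perm[:half]] = 0
        labelings[i, perm[half:]] = 1
    return MockSet(list(sample_ids), labelings, seed)


def run_mocks(table: CountTable, mocks: MockSet, registry: MethodRegistry,
              method_ids: list[str]) -> MockResults:
    """Run every method on every mock labeling; per-run failures are
    recorded as all-missing results rather than raised."""
    specs = {mid: registry.get(mid) for mid in method_ids}
    out = MockResults(n_mocks=mocks.n_mocks, method_ids=list(method_ids))
    failures = {mid: 0 for mid in method_ids}
    nan = np.full(table.n_features, np.nan)
    for i in range(mocks.n_mocks):
        groups = np.where(mocks.labelings[i] == 0, "grp0", "grp1")
        meta = SampleMetadata.from_groups(mocks.sample_ids, groups)
        exp = validate_experiment(table, meta, "group")
        for mid in method_ids:
            try:
                res = run_method(specs[mid], exp)
            except Exception as exc:  # method failure is data, not fatal
                logger.warning("mock %d method %s failed: %s", i, mid, exc)
                failures[mid] += 1
                res = DAResult(mid, list(table.feature_ids), nan.copy(), nan.copy(),
                               np.zeros(table.n_features),
                               np.zeros(table.n_features, dtype=np.int8))
            out.results[(i, mid)] = res
    for mid, nf in failures.items():
        if nf > mocks.n_mocks / 2:
            warnings.warn(f"method {mid!r} failed on {nf}/{mocks.n_mocks} mocks")
    return out


def ks_uniform(p: np.ndarray) -> float:
    """Two-sided KS distance of non-missing p-values from Uniform(0,1)."""
    p = p[~np.isnan(p)]
    if p.size == 0:
        return np.nan
    return float(stats.kstest(p, "uniform").statistic)


def eval_type1(mock_results: MockResults,
               alphas: tuple = DEFAULT_ALPHAS,
               gammas: tuple = DEFAULT_GAMMAS,
               pool_pvalues: bool = False) -> Type1Summary:
    """Summarize FPR at the given raw-p levels, two FDR readings at the
    adjusted-p levels, and the (mock-averaged or pooled) KS departure."""
    rows = []
    detail = []
    for mid in mock_results.method_ids:
        per_mock = [mock_results.results[(i, mid)]
                    for i in range(mock_results.n_mocks)]
        praw = np.stack([r.p_raw for r in per_mock])   # mocks x features
        padj = np.stack([r.p_adj for r in per_mock])
        if np.isnan(praw).all():
            warnings.warn(f"method {mid!r} produced no p-values; excluded")
            continue
        row = {"method_id": mid,
               "mean_missing": float(np.isnan(praw).sum(axis=1).mean())}
        n_ok = (~np.isnan(praw)).sum(axis=1).astype(float)  # per mock
        valid = n_ok > 0
        for a in alphas:
            with np.errstate(invalid="ignore"):
                fpr_mock = np.nansum(praw < a, axis=1) / np.where(n_ok > 0, n_ok, np.nan)
            row[f"fpr_{a}"] = float(np.nanmean(fpr_mock))
            for i in np.flatnonzero(valid):
                detail.append({"mock_id": i, "method_id": mid, "alpha": a,
                               "fpr": float(fpr_mock[i])})
        for gmm in gammas:
            with np.errstate(invalid="ignore"):
                disc = np.nansum(padj < gmm, axis=1)
                fdr_mock = disc / np.where(n_ok > 0, n_ok, np.nan)
            row[f"fdr_{gmm}"] = float(np.nanmean(fdr_mock))
            row[f"any_discovery_{gmm}"] = float(np.mean(disc[valid] > 0))
        if pool_pvalues:
            row["mean_ks"] = ks_uniform(praw.ravel())
        else:
            ks_vals = np.array([ks_uniform(praw[i]) for i in range(praw.shape[0])])
            row["mean_ks"] = float(np.nanmean(ks_vals))
            for i, k in enumerate(ks_vals):
                if not np.isnan(k):
                    detail.append({"mock_id": i, "method_id": mid,
                                   "alpha": np.nan, "fpr": np.nan, "ks": float(k)})
        rows.append(row)
    if not rows:
        raise ValidationError("no method produced any p-values")
    return Type1Summary(pd.DataFrame(rows), pd.DataFrame(detail),
                        tuple(alphas), tuple(gammas))
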