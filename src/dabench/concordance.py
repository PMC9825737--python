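"""Concordance engine: stratified half-splits, concordance-at-top curves,
within-method (WMC) and between-method (BMC) summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (CountTable, DAResult, SampleMetadata, ValidationError,
                   validate_experiment)
from .methods import MethodRegistry, run_method

logger = logging.getLogger("dabench.concordance")


@dataclass
class SplitSet:
    pairs: list[tuple[list[str], list[str]]]  # (subset1 ids, subset2 ids)
    seed: int

    @property
    def n_splits(self) -> int:
        return len(self.pairs)


@dataclass
class CATCurve:
    values: np.ndarray  # concordance fraction at k = 1..K

    @property
    def k_max(self) -> int:
        return self.values.size


@dataclass
class ConcordanceSummary:
    wmc: pd.Series               # per-method mean rescaled area over splits
    bmc: pd.DataFrame            # method x method symmetric matrix
    detail: pd.DataFrame         # long: split, subset, method_a, method_b, area
    cat_curves: pd.DataFrame = field(default_factory=pd.DataFrame)


def create_splits(metadata: SampleMetadata, group_column: str,
                  n_splits: int, seed: int) -> SplitSet:
    """N stratified half-splits of the samples: within each group level the
    samples are halved at random, so both subsets keep every level."""
    groups = metadata.table[group_column]
    sizes = groups.value_counts()
    small = sizes[sizes < 4]
    if len(small):
        raise ValidationError(
            f"groups too small for half-splitting (need >= 4 samples each): "
            f"{dict(small)}")
    pairs = []
    for i in range(n_splits):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        s1: list[str] = []
        s2: list[str] = []
        for level in sorted(groups.unique()):
            ids = [s for s in metadata.sample_ids if groups[s] == level]
            perm = rng.permutation(len(ids))
            half = len(ids) // 2
            s1.extend(ids[j] for j in perm[:half])
            s2.extend(ids[j] for j in perm[half:])
        pairs.append((sorted(s1), sorted(s2)))
    return SplitSet(pairs, seed)


def rank_features(result: DAResult) -> list[str]:
    """Feature ranking: ascending raw p, ties by descending |statistic|,
    then lexicographic id; missing p ranked last."""
    df = pd.DataFrame({
        "fid": result.feature_ids,
        "p": np.where(np.isnan(result.p_raw), np.inf, result.p_raw),
        "negabs": -np.abs(result.statistic),
    })
    return df.sort_values(["p", "negabs", "fid"], kind="stable")["fid"].tolist()


def cat_curve(rank_a: list[str], rank_b: list[str], k_max: int) -> CATCurve:
    """CAT(k) = |top_k(A) ∩ top_k(B)| / k for k = 1..k_max."""
    if set(rank_a) != set(rank_b):
        raise ValidationError("rankings cover different feature universes")
    if k_max > len(rank_a) or k_max < 1:
        raise ValidationError("k_max must lie in [1, m]")
    in_a: set = set()
    in_b: set = set()
    values = np.empty(k_max)
    overlap = 0
    for k in range(1, k_max + 1):
        fa, fb = rank_a[k - 1], rank_b[k - 1]
        if fa == fb:
            overlap += 1
        else:
            if fa in in_b:
                overlap += 1
            if fb in in_a:
                overlap += 1
        in_a.add(fa)
        in_b.add(fb)
        values[k - 1] = overlap / k
    return CATCurve(values)


def rescaled_area(curve: CATCurve, m: int) -> float:
    """Mean CAT value, centred at the random-overlap expectation and scaled
    so identical rankings score 1 and independent ones ~0."""
    k = np.arange(1, curve.k_max + 1)
    if m == 1:
        return 1.0
    ra_raw = float(curve.values.mean())
    r_random = float(np.mean(k / m))
    if r_random >= 1.0:
        return 1.0
    return (ra_raw - r_random) / (1.0 - r_random)


def run_splits(table: CountTable, metadata: SampleMetadata, group_column: str,
               splits: SplitSet, registry: MethodRegistry,
               method_ids: list[str]) -> dict:
    """Run each method on each subset of each split.

    Returns {(split_idx, subset_idx in {0,1}, method_id): DAResult}; failed
    runs are absent (logged)."""
    specs = {mid: registry.get(mid) for mid in method_ids}
    results: dict = {}
    for si, pair in enumerate(splits.pairs):
        for sub, ids in enumerate(pair):
            sub_table = table.subset_samples(ids)
            sub_meta = SampleMetadata(metadata.table.loc[ids])
            exp = validate_experiment(sub_table, sub_meta, group_column)
            for mid in method_ids:
                try:
                    results[(si, sub, mid)] = run_method(specs[mid], exp)
                except Exception as exc:
                    logger.warning("split %d subset %d method %s failed: %s",
                                   si, sub, mid, exc)
    return results


def eval_concordance(split_results: dict, n_splits: int, method_ids: list[str],
                     m: int, k_max: int | None = None) -> ConcordanceSummary:
    """WMC: a method against itself across the two subsets of each split.
    BMC: two methods on the same subset, averaged over subsets and splits."""
    if k_max is None:
        k_max = min(m, 100)
    ranks = {key: rank_features(res) for key, res in split_results.items()}
    detail = []
    wmc_acc: dict[str, list[float]] = {mid: [] for mid in method_ids}
    bmc_acc: dict[tuple[str, str], list[float]] = {}
    for si in range(n_splits):
        for mid in method_ids:
            a = ranks.get((si, 0, mid))
            b = ranks.get((si, 1, mid))
            if a is None or b is None:
                logger.warning("split %d missing subset result for %s", si, mid)
                continue
            area = rescaled_area(cat_curve(a, b, k_max), m)
            wmc_acc[mid].append(area)
            detail.append({"split": si, "subset": -1, "method_a": mid,
                           "method_b": mid, "kind": "WMC", "area": area})
        for sub in (0, 1):
            for ia, mid_a in enumerate(method_ids):
                for mid_b in method_ids[ia + 1:]:
                    a = ranks.get((si, sub, mid_a))
                    b = ranks.get((si, sub, mid_b))
                    if a is None or b is None:
                        continue
                    area = rescaled_area(cat_curve(a, b, k_max), m)
                    bmc_acc.setdefault((mid_a, mid_b), []).append(area)
                    detail.append({"split": si, "subset": sub, "method_a": mid_a,
                                   "method_b": mid_b, "kind": "BMC", "area": area})
    wmc = pd.Series({mid: float(np.mean(v)) if v else np.nan
                     for mid, v in wmc_acc.items()}, name="WMC")
    bmc = pd.DataFrame(np.eye(len(method_ids)), index=method_ids, columns=method_ids)
    for (a, b), v in bmc_acc.items():
        val = float(np.mean(v))
        bmc.loc[a, b] = val
        bmc.loc[b, a] = val
    return ConcordanceSummary(wmc, bmc, pd.DataFrame(detail))
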