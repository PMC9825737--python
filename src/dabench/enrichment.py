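"""Enrichment engine: direction-aware contingency tables against prior
knowledge, Fisher exact tests, mutual findings, TP-FP ranking curves and
simulation-based power analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DAResult, ValidationError, validate_experiment
from .methods import MethodRegistry, run_methods

UP, DOWN, NONDA = "UP", "DOWN", "NONDA"


@dataclass
class EnrichmentPrior:
    """Per-feature categorical annotation plus the direction in which each
    annotation level is expected to be over-abundant."""
    annotation: dict[str, str]            # feature_id -> level (absent = missing)
    expected_direction: dict[str, str]    # level -> UP | DOWN

    def __post_init__(self) -> None:
        levels = set(self.annotation.values())
        extra = set(self.expected_direction) - levels
        if extra:
            raise ValidationError(
                f"expected_direction has levels absent from annotation: {sorted(extra)}")
        bad = set(self.expected_direction.values()) - {UP, DOWN}
        if bad:
            raise ValidationError(f"expected directions must be UP/DOWN, got {bad}")


@dataclass
class ContingencyTable:
    a: int  # in level, called in expected direction
    b: int  # in level, not so called
    c: int  # outside level, so called
    d: int  # outside level, not so called

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class TPFPCurve:
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray

    @property
    def tp_minus_fp(self) -> np.ndarray:
        return self.tp - self.fp


@dataclass
class TruthSet:
    feature_ids: list[str]
    is_da: np.ndarray          # bool
    direction: np.ndarray      # +1 / -1 where is_da, 0 otherwise
    fold_change: np.ndarray    # 1.0 for non-DA features

    def __post_init__(self) -> None:
        self.is_da = np.asarray(self.is_da, dtype=bool)
        self.direction = np.asarray(self.direction, dtype=np.int8)
        self.fold_change = np.asarray(self.fold_change, dtype=float)
        if np.any(self.direction[~self.is_da] != 0):
            raise ValidationError("direction must be 0 for non-DA features")
        if np.any(self.direction[self.is_da] == 0):
            raise ValidationError("DA features need a direction")

    @property
    def n_da(self) -> int:
        return int(self.is_da.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.feature_ids,
                             "is_da": self.is_da.astype(int),
                             "direction": self.direction.astype(int),
                             "fold_change": self.fold_change})


@dataclass
class PowerSummary:
    detail: pd.DataFrame   # per scenario-replicate per method
    summary: pd.DataFrame  # grouped means with MC standard errors


def classify_features(result: DAResult, threshold: float) -> dict[str, str]:
    """UP/DOWN/NONDA per feature at an adjusted-p cutoff; missing p-values
    and zero directions are NONDA."""
    if not (0 < threshold <= 1):
        raise ValidationError("threshold must lie in (0, 1]")
    out = {}
    for fid, padj, d in zip(result.feature_ids, result.p_adj, result.direction):
        if np.isnan(padj) or padj >= threshold or d == 0:
            out[fid] = NONDA
        else:
            out[fid] = UP if d > 0 else DOWN
    return out


def build_contingency(classes: dict[str, str], prior: EnrichmentPrior,
                      level: str, direction: str) -> ContingencyTable:
    """2x2 table: membership of the annotation level vs being called DA in
    the given direction. Unannotated features are excluded."""
    if level not in set(prior.annotation.values()):
        raise ValidationError(f"annotation level {level!r} is empty")
    a = b = c = d = 0
    for fid, cls in classes.items():
        lev = prior.annotation.get(fid)
        if lev is None:
            continue
        called = cls == direction
        if lev == level:
            a, b = (a + 1, b) if called else (a, b + 1)
        else:
            c, d = (c + 1, d) if called else (c, d + 1)
    return ContingencyTable(a, b, c, d)


def fisher_test(table: ContingencyTable,
                alternative: str = "greater") -> tuple[float, float]:
    """Fisher exact test; returns (p, sample odds ratio ad/bc).

    The odds ratio is inf when bc = 0 and ad > 0, NaN when the table is
    degenerate (a zero margin)."""
    if alternative not in ("two_sided", "greater"):
        raise ValidationError("alternative must be 'two_sided' or 'greater'")
    arr = table.as_array()
    if (arr < 0).any():
        raise ValidationError("contingency counts must be non-negative")
    if arr.sum() == 0:
        return 1.0, float("nan")
    alt = "two-sided" if alternative == "two_sided" else "greater"
    res = stats.fisher_exact(arr, alternative=alt)
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    return float(res.pvalue), odds


def enrichment_tests(result: DAResult, prior: EnrichmentPrior, threshold: float = 0.1,
                     alternative: str = "greater") -> pd.DataFrame:
    """One Fisher test per (annotation level x direction); the direction
    opposite to the expected one serves as a negative control."""
    classes = classify_features(result, threshold)
    rows = []
    for level in sorted(set(prior.annotation.values())):
        expected = prior.expected_direction.get(level)
        for direction in (UP, DOWN):
            ct = build_contingency(classes, prior, level, direction)
            p, odds = fisher_test(ct, alternative)
            rows.append({"method_id": result.method_id, "level": level,
                         "direction": direction,
                         "expected": expected == direction,
                         "a": ct.a, "b": ct.b, "c": ct.c, "d": ct.d,
                         "p_value": p, "odds_ratio": odds})
    return pd.DataFrame(rows)


def mutual_findings(results: list[DAResult], threshold: float = 0.1
                    ) -> tuple[pd.Series, list[str]]:
    """Per-feature count of methods calling it DA, and the features called
    by at least two methods."""
    if len(results) < 2:
        raise ValidationError("mutual findings need >= 2 method results")
    fids = results[0].feature_ids
    counts = pd.Series(0, index=fids, dtype=int)
    for res in results:
        classes = classify_features(res, threshold)
        for fid, cls in classes.items():
            if cls != NONDA:
                counts[fid] += 1
    highlighted = [fid for fid in fids if counts[fid] >= 2]
    return counts, highlighted


def _expected_directions(reference: EnrichmentPrior | TruthSet,
                         feature_ids: list[str]) -> dict[str, int | None]:
    """Per feature: +1/-1 expected direction, 0 for known-null (truth only),
    None for no information (unannotated)."""
    out: dict[str, int | None] = {}
    if isinstance(reference, TruthSet):
        lookup = {fid: (int(d) if da else 0)
                  for fid, da, d in zip(reference.feature_ids, reference.is_da,
                                        reference.direction)}
        for fid in feature_ids:
            out[fid] = lookup.get(fid)
    else:
        for fid in feature_ids:
            lev = reference.annotation.get(fid)
            exp_dir = reference.expected_direction.get(lev) if lev is not None else None
            out[fid] = None if exp_dir is None else (1 if exp_dir == UP else -1)
    return out


def tp_fp_ranking(result: DAResult, reference: EnrichmentPrior | TruthSet,
                  thresholds: list[int] | None = None,
                  statistic: str = "p_raw") -> TPFPCurve:
    """TP-FP curve over rank depths.

    At depth k, among the top-k features of the ranking: TP counts features
    whose call direction matches the expected/true direction; FP counts
    contradictions (opposite direction, or any call on a known-null truth
    feature). Features with no prior information are neutral.
    """
    m = len(result.feature_ids)
    if thresholds is None:
        thresholds = list(range(1, m + 1))
    thresholds = list(thresholds)
    if any(t1 >= t2 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValidationError("thresholds must be strictly ascending")
    if statistic == "p_raw":
        key = np.where(np.isnan(result.p_raw), np.inf, result.p_raw)
    elif statistic == "p_adj":
        key = np.where(np.isnan(result.p_adj), np.inf, result.p_adj)
    elif statistic == "statistic":
        key = -np.abs(result.statistic)
    else:
        raise ValidationError("statistic must be p_raw, p_adj or statistic")
    order = pd.DataFrame({"key": key, "fid": result.feature_ids}).sort_values(
        ["key", "fid"], kind="stable").index.to_numpy()
    expected = _expected_directions(reference, result.feature_ids)
    contrib_tp = np.zeros(m)
    contrib_fp = np.zeros(m)
    for pos, idx in enumerate(order):
        fid = result.feature_ids[idx]
        exp_dir = expected[fid]
        call = int(result.direction[idx])
        if exp_dir is None:
            continue
        if exp_dir == 0:
            contrib_fp[pos] = 1  # known-null feature ranked as a finding
        elif call == exp_dir:
            contrib_tp[pos] = 1
        elif call == -exp_dir:
            contrib_fp[pos] = 1
    tp_cum = np.cumsum(contrib_tp)
    fp_cum = np.cumsum(contrib_fp)
    ks = np.asarray(thresholds, dtype=int)
    return TPFPCurve(ks, tp_cum[ks - 1].astype(int), fp_cum[ks - 1].astype(int))


def power_analysis(scenarios: list, registry: MethodRegistry,
                   method_ids: list[str], threshold: float = 0.05) -> PowerSummary:
    """Run methods on simulated experiments with known truth; report power
    (TP / n true DA) and observed FDR at the adjusted-p threshold.

    ``scenarios`` is a list of (CountTable, SampleMetadata, TruthSet,
    descriptor-dict) tuples, e.g. from :func:`dabench.synthetic.sim_counts`.
    """
    rows = []
    for rep, item in enumerate(scenarios):
        table, metadata, truth, desc = item
        if truth is None:
            raise ValidationError("power analysis needs scenarios with truth")
        exp = validate_experiment(table, metadata, desc.get("group_column", "group"))
        results = run_methods(exp, registry, method_ids)
        truth_dir = {fid: int(d) for fid, d in zip(truth.feature_ids, truth.direction)}
        truth_da = {fid: bool(t) for fid, t in zip(truth.feature_ids, truth.is_da)}
        for res in results:
            classes = classify_features(res, threshold)
            tp = fp = 0
            for fid, cls in classes.items():
                if cls == NONDA:
                    continue
                call = 1 if cls == UP else -1
                if truth_da[fid] and call == truth_dir[fid]:
                    tp += 1
                else:
                    fp += 1
            disc = tp + fp
            n_da = truth.n_da
            rows.append({**desc, "replicate": rep, "method_id": res.method_id,
                         "tp": tp, "fp": fp, "discoveries": disc,
                         "power": tp / n_da if n_da else np.nan,
                         "fdr": fp / disc if disc else 0.0})
    detail = pd.DataFrame(rows)
    group_keys = [c for c in ("method_id", "fold_change", "model", "m",
                              "n_per_group", "frac_da") if c in detail.columns]
    agg = detail.groupby(group_keys, dropna=False).agg(
        power_mean=("power", "mean"),
        power_se=("power", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
        fdr_mean=("fdr", "mean"),
        fdr_se=("fdr", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan),
        n_reps=("power", "size")).reset_index()
    return PowerSummary(detail, agg)
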