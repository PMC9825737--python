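"""Pluggable DA-method contract and three native representative methods.

A method takes a :class:`ValidatedExperiment` (exactly two groups) plus a
normalization and returns a :class:`DAResult` with per-feature raw/adjusted
p-values, a statistic and a direction sign.  The sign convention: direction
+1 means higher abundance in the second (sorted) group level.
"""

from __future__ import annotations

import importlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import DAResult, ValidatedExperiment, ValidationError, params_fingerprint
from .normalization import NormFactors, normalize

logger = logging.getLogger("dabench.methods")


@dataclass
class MethodSpec:
    method_id: str
    test: str = "wilcoxon"  # wilcoxon | ttest_clr | negbin_wald | plugin:<module:func>
    normalization: str = "TSS"
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def fingerprint(self) -> str:
        return params_fingerprint({"test": self.test, "normalization": self.normalization,
                                   "params": self.params, "seed": self.seed})


class MethodRegistry:
    """Insertion-ordered collection of uniquely named method specs."""

    def __init__(self) -> None:
        self._specs: dict[str, MethodSpec] = {}

    def register(self, spec: MethodSpec) -> "MethodRegistry":
        if spec.method_id in self._specs:
            raise ValidationError(f"method id {spec.method_id!r} already registered")
        self._specs[spec.method_id] = spec
        return self

    def get(self, method_id: str) -> MethodSpec:
        if method_id not in self._specs:
            raise ValidationError(f"unknown method id {method_id!r}")
        return self._specs[method_id]

    def ids(self) -> list[str]:
        return list(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def to_config(self) -> list[dict]:
        return [{"method_id": s.method_id, "test": s.test,
                 "normalization": s.normalization, "params": dict(s.params),
                 "seed": s.seed} for s in self._specs.values()]

    @classmethod
    def from_config(cls, blocks: list[dict]) -> "MethodRegistry":
        reg = cls()
        for b in blocks:
            reg.register(MethodSpec(method_id=b["method_id"],
                                    test=b.get("test", "wilcoxon"),
                                    normalization=b.get("normalization", "TSS"),
                                    params=dict(b.get("params") or {}),
                                    seed=b.get("seed")))
        return reg


def _two_group_views(exp: ValidatedExperiment, values: np.ndarray):
    levels = exp.groups
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 group levels, found {levels}")
    m1 = exp.group_mask(levels[0])
    m2 = exp.group_mask(levels[1])
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValidationError("each group needs >= 2 samples")
    return values[:, m1], values[:, m2]


def da_wilcoxon(exp: ValidatedExperiment, norm: NormFactors) -> DAResult:
    """Two-sided Wilcoxon rank-sum per feature on normalized abundances.

    Exact p-values where scipy's auto rule allows, otherwise normal
    approximation with tie correction. Features constant across all samples
    get a missing p-value.
    """
    vals = norm.apply(exp.table)
    g1, g2 = _two_group_views(exp, vals)
    m = exp.table.n_features
    p = np.full(m, np.nan)
    stat = np.zeros(m)
    direction = np.zeros(m, dtype=np.int8)
    n2 = g2.shape[1]
    for i in range(m):
        x2, x1 = g2[i], g1[i]
        if np.ptp(np.concatenate([x1, x2])) == 0:
            continue
        # no continuity correction: better uniformity of the null p-values
        res = stats.mannwhitneyu(x2, x1, alternative="two-sided", method="auto",
                                 use_continuity=False)
        p[i] = min(res.pvalue, 1.0)
        stat[i] = res.statistic + n2 * (n2 + 1) / 2.0  # rank-sum of group 2
        diff = np.median(x2) - np.median(x1)
        direction[i] = int(np.sign(diff))
    return DAResult.from_raw("wilcoxon", exp.table.feature_ids, p, stat, direction)


def da_ttest_clr(exp: ValidatedExperiment, pseudocount: float = 0.5,
                 mc_samples: int = 0, seed: int | None = None) -> DAResult:
    """Welch t-test per feature on CLR-transformed counts.

    With ``mc_samples`` = W > 0, W Dirichlet instances per sample are drawn
    with concentration counts + 0.5, each instance is CLR-transformed and
    tested, and the per-feature mean p over instances is reported.
    """
    if mc_samples < 0:
        raise ValidationError("mc_samples must be >= 0")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    counts = exp.table.counts.astype(float)
    levels = exp.groups
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 group levels, found {levels}")
    m1 = exp.group_mask(levels[0])
    m2 = exp.group_mask(levels[1])

    def welch(clr: np.ndarray):
        a, b = clr[:, m2], clr[:, m1]
        import warnings as _warnings

        with np.errstate(invalid="ignore", divide="ignore"), \
                _warnings.catch_warnings():
            # near-constant features trigger scipy's precision-loss warning;
            # the flat-p fixup below handles them explicitly
            _warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pv = np.asarray(res.pvalue, dtype=float)
        tv = np.asarray(res.statistic, dtype=float)
        diff = a.mean(axis=1) - b.mean(axis=1)
        flat = ~np.isfinite(pv)
        pv[flat & (np.abs(diff) < 1e-12)] = 1.0
        pv[flat & (np.abs(diff) >= 1e-12)] = 0.0
        tv[~np.isfinite(tv)] = 0.0
        return pv, tv, diff

    if mc_samples == 0:
        logs = np.log(counts + pseudocount)
        clr = logs - logs.mean(axis=0, keepdims=True)
        p, t, diff = welch(clr)
    else:
        rng = np.random.default_rng(seed)
        p_acc = np.zeros(exp.table.n_features)
        t_acc = np.zeros(exp.table.n_features)
        d_acc = np.zeros(exp.table.n_features)
        for _ in range(mc_samples):
            g = rng.standard_gamma(counts + 0.5)
            logs = np.log(g)  # CLR is scale-invariant: skip normalization
            clr = logs - logs.mean(axis=0, keepdims=True)
            pw, tw, dw = welch(clr)
            p_acc += pw
            t_acc += tw
            d_acc += dw
        p, t, diff = p_acc / mc_samples, t_acc / mc_samples, d_acc / mc_samples
    direction = np.sign(np.where(np.abs(diff) < 1e-12, 0.0, diff)).astype(np.int8)
    return DAResult.from_raw("ttest_clr", exp.table.feature_ids,
                             np.clip(p, 0, 1), t, direction)


# ---------------------------------------------------------------------------
# NB regression with Wald test
# ---------------------------------------------------------------------------


def _nb_irls(y: np.ndarray, off: np.ndarray, g: np.ndarray, phi: float,
             beta0: np.ndarray, max_iter: int = 50) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Fisher scoring for NB GLM with log link, design [1, g], offset off.

    Returns (beta, cov, loglik, ok)."""
    x = np.column_stack([np.ones_like(y), g.astype(float)])
    beta = beta0.copy()
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = x @ beta + off
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        score = x.T @ ((y - mu) / (1.0 + phi * mu))
        info = (x * w[:, None]).T @ x
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return beta, np.full((2, 2), np.nan), -np.inf, False
        beta = beta + step
        ll = _nb_glm_loglik(y, x @ beta + off, phi)
        if abs(ll - ll_old) < 1e-10 * (abs(ll_old) + 1):
            break
        ll_old = ll
    eta = np.clip(x @ beta + off, -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + phi * mu)
    info = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return beta, np.full((2, 2), np.nan), -np.inf, False
    return beta, cov, _nb_glm_loglik(y, x @ beta + off, phi), True


def _nb_glm_loglik(y: np.ndarray, eta: np.ndarray, phi: float) -> float:
    from scipy.special import gammaln

    mu = np.exp(np.clip(eta, -30, 30))
    if phi < 1e-8:
        return float(np.sum(y * np.log(mu + 1e-300) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu) + 1e-300)))


def da_negbin_wald(exp: ValidatedExperiment, norm: NormFactors) -> DAResult:
    """Per-feature NB regression (log link, offset = log normalization
    factor) with a Wald test on the group coefficient."""
    if norm.factors is None:
        raise ValidationError("negbin_wald requires a factor-based normalization")
    levels = exp.groups
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 group levels, found {levels}")
    g = exp.group_mask(levels[1])
    off = np.log(norm.factors)
    off = off - off.mean()  # centre offsets: affects intercept only
    counts = exp.table.counts.astype(float)
    m = exp.table.n_features
    p = np.full(m, np.nan)
    stat = np.zeros(m)
    direction = np.zeros(m, dtype=np.int8)
    for i in range(m):
        y = counts[i]
        if y.sum() == 0 or y[g].sum() == 0 or y[~g].sum() == 0:
            continue  # separation or empty feature: no finite MLE
        mu1 = max(np.mean(y[~g] / np.exp(off[~g])), 1e-8)
        mu2 = max(np.mean(y[g] / np.exp(off[g])), 1e-8)
        beta0 = np.array([np.log(mu1), np.log(mu2 / mu1)])

        def profile_neg(logphi: float) -> float:
            _, _, ll, ok = _nb_irls(y, off, g, float(np.exp(logphi)), beta0)
            return -ll if ok else np.inf

        from scipy.optimize import minimize_scalar

        res = minimize_scalar(profile_neg, bounds=(np.log(1e-8), np.log(1e2)),
                              method="bounded", options={"xatol": 1e-6})
        phi = float(np.exp(res.x))
        beta, cov, _, ok = _nb_irls(y, off, g, phi, beta0)
        if not ok or not np.isfinite(cov[1, 1]) or cov[1, 1] <= 0:
            continue
        se = float(np.sqrt(cov[1, 1]))
        z = beta[1] / se
        p[i] = float(2 * stats.norm.sf(abs(z)))
        stat[i] = z
        direction[i] = int(np.sign(beta[1])) if abs(beta[1]) > 1e-12 else 0
    return DAResult.from_raw("negbin_wald", exp.table.feature_ids, p, stat, direction)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_BUILTIN_TESTS = {"wilcoxon", "ttest_clr", "negbin_wald"}


def run_method(spec: MethodSpec, exp: ValidatedExperiment) -> DAResult:
    """Run one registered method spec on an experiment."""
    norm_kwargs = {}
    if spec.normalization == "CLR" and "pseudocount" in spec.params:
        norm_kwargs["pseudocount"] = spec.params["pseudocount"]
    norm = normalize(exp.table, spec.normalization, **norm_kwargs)
    if spec.test == "wilcoxon":
        res = da_wilcoxon(exp, norm)
    elif spec.test == "ttest_clr":
        res = da_ttest_clr(exp,
                           pseudocount=spec.params.get("pseudocount", 0.5),
                           mc_samples=spec.params.get("mc_samples", 0),
                           seed=spec.seed)
    elif spec.test == "negbin_wald":
        res = da_negbin_wald(exp, norm)
    elif spec.test.startswith("plugin:"):
        target = spec.test.split(":", 1)[1]
        mod_name, func_name = target.rsplit(".", 1)
        func = getattr(importlib.import_module(mod_name), func_name)
        res = func(exp, norm, **spec.params)
    else:
        raise ValidationError(f"unknown test {spec.test!r}; builtins: "
                              f"{sorted(_BUILTIN_TESTS)} or plugin:<module.func>")
    res.method_id = spec.method_id
    res.params_fingerprint = spec.fingerprint()
    return res


def run_methods(exp: ValidatedExperiment, registry: MethodRegistry,
                method_ids: list[str]) -> list[DAResult]:
    """Run a list of registered methods in request order; per-method wall
    time and missing-p counts are logged."""
    specs = [registry.get(mid) for mid in method_ids]  # fail before any run
    results = []
    for spec in specs:
        t0 = time.perf_counter()
        res = run_method(spec, exp)
        logger.info("method=%s elapsed=%.3fs missing=%d",
                    spec.method_id, time.perf_counter() - t0, res.n_missing)
        results.append(res)
    return results
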