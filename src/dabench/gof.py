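"""Goodness-of-fit engine: five marginal count models per feature.

For each model we report, per feature, the estimated mean count ``EY`` and
the estimated probability of observing a zero ``P0``, and compare both to
their observed counterparts.  Models: NB, zero-inflated NB, zero-inflated
Gaussian on log2(count+1), hurdle (exact zero mass + Gaussian on positive
log counts) and Dirichlet-multinomial (fit jointly across features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import digamma, expit, gammaln
from scipy.stats import norm as normal_dist

from .core import CountTable, ValidationError

MODELS = ("NB", "ZINB", "ZIG", "HURDLE", "DM")

MAX_ITER = 500
REL_TOL = 1e-8
PHI_FLOOR = 1e-10
_PHI_LO, _PHI_HI = 1e-8, 1e4
# back-transformed counts below 1 are "zero" for the continuous models
ZIG_ZERO_BOUNDARY = np.log2(1.5)


@dataclass
class FitStats:
    model: str
    feature_ids: list[str]
    ey: np.ndarray
    p0: np.ndarray
    converged: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ey = np.asarray(self.ey, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        self.converged = np.asarray(self.converged, dtype=bool)


@dataclass
class GofMetrics:
    model: str
    md: np.ndarray
    zpd: np.ndarray
    rmse_md: float
    rmse_zpd: float
    frac_converged: float


# ---------------------------------------------------------------------------
# negative binomial
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: float, phi: float) -> float:
    """Log-likelihood under NB with variance mu + phi*mu^2."""
    if phi < _PHI_LO:
        # Poisson limit
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1))) if mu > 0 else (
            0.0 if not np.any(y) else -np.inf)
    r = 1.0 / phi
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


def _nb_p0(mu: float, phi: float) -> float:
    if phi < 1e-8:
        return float(np.exp(-mu))
    return float((1.0 + phi * mu) ** (-1.0 / phi))


def _fit_nb_feature(y: np.ndarray) -> tuple[float, float, bool]:
    """Intercept-only NB ML: mu is the sample mean, phi by profile likelihood."""
    mu = float(y.mean())
    if mu == 0:
        return 0.0, PHI_FLOOR, True
    if y.var() <= mu:  # under/equi-dispersed: boundary solution
        return mu, PHI_FLOOR, True

    def neg(logphi: float) -> float:
        return -_nb_loglik(y, mu, float(np.exp(logphi)))

    res = minimize_scalar(neg, bounds=(np.log(_PHI_LO), np.log(_PHI_HI)),
                          method="bounded",
                          options={"xatol": 1e-10, "maxiter": MAX_ITER})
    phi = float(np.exp(res.x))
    if -res.fun < _nb_loglik(y, mu, PHI_FLOOR):
        phi = PHI_FLOOR
    return mu, phi, bool(res.success)


def fit_nb(table: CountTable) -> FitStats:
    """Per-feature intercept-only negative binomial maximum likelihood."""
    m = table.n_features
    mu = np.zeros(m)
    phi = np.zeros(m)
    conv = np.ones(m, dtype=bool)
    for i in range(m):
        mu[i], phi[i], conv[i] = _fit_nb_feature(table.counts[i].astype(float))
    p0 = np.array([_nb_p0(m_, f_) if m_ > 0 else 1.0 for m_, f_ in zip(mu, phi)])
    return FitStats("NB", list(table.feature_ids), mu, p0, conv,
                    params={"mu": mu, "dispersion": phi})


# ---------------------------------------------------------------------------
# zero-inflated negative binomial (EM)
# ---------------------------------------------------------------------------


def _zinb_loglik(y: np.ndarray, mu: float, phi: float, pi0: float) -> float:
    zero = y == 0
    nb0 = _nb_p0(mu, phi) if mu > 0 else 1.0
    ll = 0.0
    if zero.any():
        ll += zero.sum() * np.log(pi0 + (1 - pi0) * nb0 + 1e-300)
    if (~zero).any():
        yp = y[~zero]
        if mu <= 0:
            return -np.inf
        r = 1.0 / max(phi, _PHI_LO)
        ll += float(np.sum(np.log1p(-pi0 + 1e-300)
                           + gammaln(yp + r) - gammaln(r) - gammaln(yp + 1)
                           + r * np.log(r / (r + mu)) + yp * np.log(mu / (r + mu))))
    return ll


def _weighted_nb_fit(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Maximize the weighted NB log-likelihood; mu is the weighted mean."""
    wsum = w.sum()
    mu = float(np.sum(w * y) / wsum) if wsum > 0 else 0.0
    if mu <= 0:
        return 0.0, PHI_FLOOR

    def neg(logphi: float) -> float:
        phi = float(np.exp(logphi))
        r = 1.0 / phi
        ll = np.sum(w * (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                         + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))
        return -float(ll)

    res = minimize_scalar(neg, bounds=(np.log(_PHI_LO), np.log(_PHI_HI)),
                          method="bounded", options={"xatol": 1e-10})
    phi = float(np.exp(res.x))
    # compare against the Poisson-limit boundary
    ll_pois = float(np.sum(w * (y * np.log(mu) - mu - gammaln(y + 1))))
    if ll_pois > -res.fun:
        phi = PHI_FLOOR
    return mu, phi


def _fit_zinb_feature(y: np.ndarray, max_iter: int = MAX_ITER,
                      tol: float = REL_TOL, trace: bool = False):
    """EM for the mixture pi0*delta0 + (1-pi0)*NB(mu, phi).

    Returns (mu, phi, pi0, converged[, loglik_trace]).
    """
    zero = y == 0
    n = y.size
    if zero.all():
        out = (0.0, PHI_FLOOR, 1.0, True)
        return out + ([],) if trace else out
    if not zero.any():
        mu, phi, conv = _fit_nb_feature(y)
        out = (mu, phi, 0.0, conv)
        return out + ([],) if trace else out

    pi0 = 0.5 * zero.mean()
    mu = float(y.mean() / (1 - pi0))
    phi = max(float((y.var() - mu) / mu ** 2), 0.01)
    ll_old = _zinb_loglik(y, mu, phi, pi0)
    lls = [ll_old]
    converged = False
    for _ in range(max_iter):
        # E-step: responsibility of the structural-zero component
        nb0 = _nb_p0(mu, phi)
        denom = pi0 + (1 - pi0) * nb0
        r_zero = pi0 / denom if denom > 0 else 1.0
        resp = np.where(zero, r_zero, 0.0)
        # M-step
        pi0 = float(resp.mean())
        pi0 = min(max(pi0, 0.0), 1 - 1e-12)
        mu, phi = _weighted_nb_fit(y.astype(float), 1.0 - resp)
        ll = _zinb_loglik(y, mu, phi, pi0)
        lls.append(ll)
        if abs(ll - ll_old) <= tol * (abs(ll_old) + 1e-12):
            converged = True
            break
        ll_old = ll
    out = (mu, phi, pi0, converged)
    return out + (lls,) if trace else out


def fit_zinb(table: CountTable, max_iter: int = MAX_ITER,
             tol: float = REL_TOL) -> FitStats:
    """Per-feature zero-inflated NB via expectation-maximization."""
    m = table.n_features
    mu = np.zeros(m)
    phi = np.zeros(m)
    pi0 = np.zeros(m)
    conv = np.ones(m, dtype=bool)
    for i in range(m):
        mu[i], phi[i], pi0[i], conv[i] = _fit_zinb_feature(
            table.counts[i].astype(float), max_iter, tol)
    ey = (1 - pi0) * mu
    p0 = pi0 + (1 - pi0) * np.array(
        [_nb_p0(m_, f_) if m_ > 0 else 1.0 for m_, f_ in zip(mu, phi)])
    return FitStats("ZINB", list(table.feature_ids), ey, p0, conv,
                    params={"mu": mu, "dispersion": phi, "pi0": pi0})


# ---------------------------------------------------------------------------
# zero-inflated Gaussian on z = log2(count + 1)
# ---------------------------------------------------------------------------


def _lognormal2_mean(mu_log: float, sigma_log: float) -> float:
    """E[2^Z - 1] for Z ~ N(mu_log, sigma_log^2), floored at 0."""
    return max(2.0 ** (mu_log + sigma_log ** 2 * np.log(2) / 2.0) - 1.0, 0.0)


def _fit_zig_feature(z: np.ndarray) -> tuple[float, float, float, bool]:
    """Returns (pi0, mu_log, sigma_log, converged)."""
    t = ZIG_ZERO_BOUNDARY
    zero = z == 0
    pos = z[~zero]
    if pos.size == 0:
        return 1.0, 0.0, 0.0, True
    if np.ptp(pos) == 0:  # constant positive part: Normal collapses to point mass
        return float(zero.mean()), float(pos[0]), 0.0, True
    if not zero.any():
        return 0.0, float(pos.mean()), float(pos.std()), True

    nz = int(zero.sum())

    def neg(params: np.ndarray) -> float:
        pi0 = expit(params[0])
        mu, sigma = params[1], float(np.exp(params[2]))
        ll = nz * np.log(pi0 + (1 - pi0) * normal_dist.cdf((t - mu) / sigma) + 1e-300)
        ll += np.sum(np.log1p(-pi0) + normal_dist.logpdf(pos, mu, sigma))
        return -float(ll)

    x0 = np.array([np.log(zero.mean() / (1 - zero.mean() + 1e-12) + 1e-12),
                   pos.mean(), np.log(pos.std() + 1e-6)])
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
    pi0 = float(expit(res.x[0]))
    return pi0, float(res.x[1]), float(np.exp(res.x[2])), bool(res.success)


def fit_zig(table: CountTable) -> FitStats:
    """Zero-inflated Gaussian on log2(count+1); zeros may also arise from the
    Gaussian component falling below the zero boundary log2(1.5)."""
    m = table.n_features
    z = np.log2(table.counts + 1.0)
    pi0 = np.zeros(m)
    mu = np.zeros(m)
    sigma = np.zeros(m)
    conv = np.ones(m, dtype=bool)
    for i in range(m):
        pi0[i], mu[i], sigma[i], conv[i] = _fit_zig_feature(z[i])
    with np.errstate(divide="ignore"):
        tail = np.where(sigma > 0,
                        normal_dist.cdf((ZIG_ZERO_BOUNDARY - mu)
                                        / np.where(sigma > 0, sigma, 1.0)),
                        (mu < ZIG_ZERO_BOUNDARY).astype(float))
    p0 = pi0 + (1 - pi0) * tail
    ey = (1 - pi0) * np.array([_lognormal2_mean(m_, s_) for m_, s_ in zip(mu, sigma)])
    all_zero = (table.counts == 0).all(axis=1)
    ey[all_zero] = 0.0
    p0[all_zero] = 1.0
    return FitStats("ZIG", list(table.feature_ids), ey, p0, conv,
                    params={"mu_log": mu, "sigma_log": sigma, "pi0": pi0})


# ---------------------------------------------------------------------------
# hurdle (exact zero mass + Gaussian on positive log counts)
# ---------------------------------------------------------------------------


def fit_hurdle(table: CountTable) -> FitStats:
    """Hurdle model: P0 is the observed zero fraction by construction; the
    positive part is Gaussian ML on log2(count+1) restricted to positives."""
    m = table.n_features
    z = np.log2(table.counts + 1.0)
    zero_frac = (table.counts == 0).mean(axis=1)
    mu = np.zeros(m)
    sigma = np.zeros(m)
    for i in range(m):
        pos = z[i][table.counts[i] > 0]
        if pos.size == 0:
            continue
        mu[i] = pos.mean()
        sigma[i] = pos.std() if pos.size >= 2 else 0.0
    ey = (1 - zero_frac) * np.array(
        [_lognormal2_mean(m_, s_) for m_, s_ in zip(mu, sigma)])
    ey[zero_frac == 1.0] = 0.0
    return FitStats("HURDLE", list(table.feature_ids), ey, zero_frac.copy(),
                    np.ones(m, dtype=bool),
                    params={"mu_pos": mu, "sigma_pos": sigma, "pi0": zero_frac})


# ---------------------------------------------------------------------------
# Dirichlet-multinomial (joint across features)
# ---------------------------------------------------------------------------


def _dm_loglik(x: np.ndarray, alpha: np.ndarray) -> float:
    n_j = x.sum(axis=0)
    a0 = alpha.sum()
    ll = np.sum(gammaln(a0) - gammaln(n_j + a0))
    ll += np.sum(gammaln(x + alpha[:, None]) - gammaln(alpha)[:, None])
    return float(ll)


def _dm_profile(x: np.ndarray, a0: float, p: np.ndarray, max_iter: int,
                tol: float) -> tuple[float, np.ndarray, bool]:
    """Maximize the DM likelihood over the composition for fixed alpha0 via
    the digamma fixed point; returns (loglik, composition, converged)."""
    converged = False
    for _ in range(max_iter):
        alpha = np.maximum(a0 * p, 1e-12)
        num = np.sum(digamma(x + alpha[:, None]) - digamma(alpha)[:, None], axis=1)
        raw = np.maximum(alpha * num, 1e-300)
        p_new = raw / raw.sum()
        if np.max(np.abs(p_new - p)) < tol:
            p = p_new
            converged = True
            break
        p = p_new
    return _dm_loglik(x, np.maximum(a0 * p, 1e-12)), p, converged


def fit_dm(table: CountTable, max_iter: int = 200, tol: float = REL_TOL) -> FitStats:
    """Joint Dirichlet-multinomial ML: fixed-point iteration on the digamma
    score equations for the composition, nested in a bounded 1-D search over
    the total concentration (which is near-flat for multinomial-like data)."""
    if table.n_samples < 2:
        raise ValidationError("Dirichlet-multinomial needs >= 2 samples")
    if table.n_features < 2:
        raise ValidationError("Dirichlet-multinomial needs >= 2 features")
    x = table.counts.astype(float)
    n_j = x.sum(axis=0)
    if np.any(n_j == 0):
        raise ValidationError("sample with zero library size")
    props = x / n_j
    pbar = props.mean(axis=1)
    pbar = np.maximum(pbar, 1e-10)
    pbar /= pbar.sum()

    state = {"p": pbar.copy(), "converged": True}

    def neg(log_a0: float) -> float:
        ll, p, ok = _dm_profile(x, float(np.exp(log_a0)), state["p"],
                                max_iter, max(tol, 1e-10))
        state["p"] = p
        state["converged"] = state["converged"] and ok
        return -ll

    res = minimize_scalar(neg, bounds=(np.log(1e-2), np.log(1e7)),
                          method="bounded", options={"xatol": 1e-6})
    a0_hat = float(np.exp(res.x))
    _, p_hat, ok = _dm_profile(x, a0_hat, state["p"], max_iter, max(tol, 1e-10))
    alpha = np.maximum(a0_hat * p_hat, 1e-12)
    converged = bool(res.success and ok)
    if not converged:
        warnings.warn("Dirichlet-multinomial fit did not converge")
    a0 = alpha.sum()
    ey = np.mean(n_j[None, :] * (alpha[:, None] / a0), axis=1)
    # beta-binomial zero mass, averaged over sample depths
    lg = (gammaln(a0 - alpha[:, None] + n_j[None, :]) + gammaln(a0)
          - gammaln(a0 + n_j[None, :]) - gammaln(a0 - alpha)[:, None])
    p0 = np.exp(lg).mean(axis=1)
    conv = np.full(table.n_features, converged)
    return FitStats("DM", list(table.feature_ids), ey, np.clip(p0, 0, 1), conv,
                    params={"alpha": alpha, "alpha0": a0})


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

_FITTERS = {"NB": fit_nb, "ZINB": fit_zinb, "ZIG": fit_zig,
            "HURDLE": fit_hurdle, "DM": fit_dm}


def fit_model(table: CountTable, model: str) -> FitStats:
    key = model.upper()
    if key not in _FITTERS:
        raise ValidationError(f"unknown model {model!r}; choose from {sorted(_FITTERS)}")
    return _FITTERS[key](table)


def evaluate_fit(fit: FitStats, table: CountTable) -> GofMetrics:
    """Mean-difference (log scale, pseudocount 1) and zero-probability
    difference per feature, with RMSEs over converged features."""
    if len(fit.feature_ids) != table.n_features:
        raise ValidationError("fit and table have different numbers of features")
    obs_mean = table.counts.mean(axis=1)
    obs_zero = (table.counts == 0).mean(axis=1)
    md = np.log(fit.ey + 1.0) - np.log(obs_mean + 1.0)
    zpd = fit.p0 - obs_zero
    ok = fit.converged
    rmse_md = float(np.sqrt(np.mean(md[ok] ** 2))) if ok.any() else np.nan
    rmse_zpd = float(np.sqrt(np.mean(zpd[ok] ** 2))) if ok.any() else np.nan
    return GofMetrics(fit.model, md, zpd, rmse_md, rmse_zpd, float(ok.mean()))


def compare_fits(fits: list[FitStats], table: CountTable) -> pd.DataFrame:
    """One row per model, sorted by RMSE_ZPD then RMSE_MD (best first)."""
    if not fits:
        raise ValidationError("need at least one fit")
    rows = []
    for fit in fits:
        met = evaluate_fit(fit, table)
        rows.append({"model": fit.model, "RMSE_MD": met.rmse_md,
                     "RMSE_ZPD": met.rmse_zpd, "frac_converged": met.frac_converged})
    return (pd.DataFrame(rows)
            .sort_values(["RMSE_ZPD", "RMSE_MD"], kind="stable")
            .reset_index(drop=True))
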