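"""Per-sample scaling factors and the CLR matrix transform.

Each normalizer returns a :class:`NormFactors`; DA methods call
:meth:`NormFactors.apply` to obtain the abundance matrix they test on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .core import CountTable, ValidationError

METHODS = ("TSS", "CLR", "TMM", "RLE", "CSS", "none")


@dataclass
class NormFactors:
    method: str
    factors: np.ndarray | None = None  # per-sample, strictly positive
    matrix: np.ndarray | None = None   # CLR: features x samples transformed values

    def __post_init__(self) -> None:
        if self.factors is not None:
            self.factors = np.asarray(self.factors, dtype=float)
            if np.any(~np.isfinite(self.factors)) or np.any(self.factors <= 0):
                raise ValidationError("normalization factors must be positive and finite")

    def apply(self, table: CountTable) -> np.ndarray:
        """Normalized abundance matrix (features x samples)."""
        if self.method == "CLR":
            assert self.matrix is not None
            return self.matrix
        if self.method == "none":
            return table.counts.astype(float)
        return table.counts / self.factors[np.newaxis, :]

    def to_tsv(self, path, sample_ids) -> None:
        import pandas as pd

        pd.DataFrame({"sample_id": sample_ids, "factor": self.factors}).to_csv(
            path, sep="\t", index=False)


def norm_none(table: CountTable) -> NormFactors:
    return NormFactors("none", np.ones(table.n_samples))


def norm_tss(table: CountTable) -> NormFactors:
    """Total-sum scaling: the factor is the library size."""
    libs = table.library_sizes().astype(float)
    if np.any(libs == 0):
        j = int(np.argmax(libs == 0))
        raise ValidationError(f"sample {table.sample_ids[j]!r} has zero library size")
    return NormFactors("TSS", libs)


def norm_clr(table: CountTable, pseudocount: float = 1.0) -> NormFactors:
    """Centred log-ratio transform of counts + pseudocount, per sample."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    logs = np.log(table.counts + pseudocount)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return NormFactors("CLR", matrix=clr)


def _upper_quartiles(counts: np.ndarray, libs: np.ndarray) -> np.ndarray:
    return np.quantile(counts, 0.75, axis=0) / libs


def norm_tmm(table: CountTable, ref_sample: str | None = None,
             logratio_trim: float = 0.30, abundance_trim: float = 0.05) -> NormFactors:
    """Trimmed mean of M-values with precision weights.

    The reference defaults to the sample whose upper-quartile relative count
    is closest to the mean upper quartile. Factors are rescaled to geometric
    mean 1.
    """
    if not (0 <= logratio_trim < 0.5 and 0 <= abundance_trim < 0.5):
        raise ValidationError("trims must lie in [0, 0.5)")
    counts = table.counts.astype(float)
    libs = counts.sum(axis=0)
    if np.any(libs == 0):
        raise ValidationError("zero library size")
    if ref_sample is None:
        uq = _upper_quartiles(counts, libs)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = table.sample_ids.index(ref_sample)
    ref = counts[:, ref_idx]
    factors = np.empty(table.n_samples)
    for j in range(table.n_samples):
        factors[j] = _tmm_pair(counts[:, j], ref, libs[j], libs[ref_idx],
                               logratio_trim, abundance_trim)
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors("TMM", factors)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              lr_trim: float, a_trim: float) -> float:
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        warnings.warn("TMM: no co-expressed features; factor set to 1")
        return 1.0
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    m_vals = np.log2(o / r)
    a_vals = 0.5 * np.log2(o * r)
    # delta-method precision weights
    w = 1.0 / ((lib_obs - obs[pos]) / (lib_obs * obs[pos])
               + (lib_ref - ref[pos]) / (lib_ref * ref[pos]))
    n = m_vals.size
    lo_l = math.floor(n * lr_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * a_trim) + 1
    hi_s = n + 1 - lo_s
    rm = rankdata(m_vals)
    ra = rankdata(a_vals)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep.any() or w[keep].sum() == 0:
        warnings.warn("TMM: all features trimmed; factor set to 1")
        return 1.0
    f = float(np.sum(w[keep] * m_vals[keep]) / np.sum(w[keep]))
    if abs(f) < 1e-10:
        f = 0.0
    return 2.0 ** f


def norm_rle(table: CountTable) -> NormFactors:
    """Median-of-ratios factors against a geometric-mean reference."""
    counts = table.counts.astype(float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "RLE needs at least one feature positive in every sample; "
            "consider a pseudocount")
    sub = counts[all_pos]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / ref[:, np.newaxis], axis=0)
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors("RLE", factors)


def norm_css(table: CountTable, quantile: float = 0.5) -> NormFactors:
    """Cumulative-sum scaling: per sample, sum counts up to the given
    quantile of its positive counts; factors rescaled by their median."""
    if not (0 < quantile < 1):
        raise ValidationError("quantile must lie in (0, 1)")
    counts = table.counts
    factors = np.empty(table.n_samples)
    for j in range(table.n_samples):
        col = counts[:, j]
        pos = col[col > 0]
        if pos.size == 0:
            raise ValidationError(
                f"sample {table.sample_ids[j]!r} has no positive counts")
        q = np.quantile(pos, quantile)
        factors[j] = col[col <= q].sum()
    factors = factors / np.median(factors)
    return NormFactors("CSS", factors)


_NORMALIZERS = {
    "TSS": norm_tss,
    "CLR": norm_clr,
    "TMM": norm_tmm,
    "RLE": norm_rle,
    "CSS": norm_css,
    "none": norm_none,
}


def normalize(table: CountTable, method: str, **kwargs) -> NormFactors:
    """Dispatch on normalization name (TSS/CLR/TMM/RLE/CSS/none)."""
    if method not in _NORMALIZERS:
        raise ValidationError(f"unknown normalization {method!r}; "
                              f"choose from {sorted(_NORMALIZERS)}")
    return _NORMALIZERS[method](table, **kwargs)
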