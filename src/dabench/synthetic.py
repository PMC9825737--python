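"""Seeded count-table generators with known distributional structure and
known DA truth; the fixture layer for every benchmarking engine."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core import CountTable, SampleMetadata, ValidationError
from .enrichment import EnrichmentPrior, TruthSet

MODELS = ("NB", "ZINB", "DM")


@dataclass
class SimScenario:
    m: int = 100
    n_per_group: int = 10
    model: str = "NB"
    mean_log_range: tuple[float, float] = (np.log(5), np.log(500))
    dispersion: float = 0.5
    pi0: float = 0.0                 # ZINB only
    alpha0: float = 50.0             # DM concentration
    frac_da: float = 0.0
    fold_change: float = 1.0
    direction_balance: float = 0.5   # fraction of DA features that go UP
    library_size_range: tuple[float, float] = (1.0, 1.0)  # multiplicative
    compositional: bool = False      # renormalize group-2 means to same total
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.m < 1:
            bad.append("m")
        if self.n_per_group < 2:
            bad.append("n_per_group")
        if self.model not in MODELS:
            bad.append("model")
        if not (0 <= self.frac_da <= 1):
            bad.append("frac_da")
        if self.fold_change <= 0:
            bad.append("fold_change")
        if not (0 <= self.pi0 < 1):
            bad.append("pi0")
        if self.dispersion <= 0:
            bad.append("dispersion")
        if not (0 <= self.direction_balance <= 1):
            bad.append("direction_balance")
        if (self.mean_log_range[0] > self.mean_log_range[1]
                or self.library_size_range[0] > self.library_size_range[1]
                or self.library_size_range[0] <= 0):
            bad.append("mean_log_range/library_size_range")
        if bad:
            raise ValidationError(f"invalid scenario fields: {bad}")

    def describe(self) -> dict:
        d = asdict(self)
        d["mean_log_range"] = tuple(d["mean_log_range"])
        d["library_size_range"] = tuple(d["library_size_range"])
        return d


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, model: str,
                 dispersion: float, pi0: float, alpha0: float) -> np.ndarray:
    """Draw an m x n count matrix with per-cell means mu."""
    m, n = mu.shape
    if model == "DM":
        # interpret per-cell means as expected composition per sample
        depth = mu.sum(axis=0)
        alpha = mu / depth * alpha0
        out = np.empty((m, n), dtype=np.int64)
        for j in range(n):
            p = rng.dirichlet(alpha[:, j])
            out[:, j] = rng.multinomial(int(round(depth[j])), p)
        return out
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    counts = rng.poisson(lam)
    if model == "ZINB" and pi0 > 0:
        counts = counts * (rng.random(mu.shape) >= pi0)
    return counts.astype(np.int64)


def sim_counts(scenario: SimScenario):
    """Simulate a two-group experiment with spiked-in DA features.

    Returns (CountTable, SampleMetadata, TruthSet). The number of DA
    features is round-half-to-even(frac_da * m); UP features have their
    group-2 mean multiplied by the fold change, DOWN features divided.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    m, npg = scenario.m, scenario.n_per_group
    base_mu = np.exp(rng.uniform(*scenario.mean_log_range, size=m))

    n_da = int(round(scenario.frac_da * m))
    da_idx = rng.choice(m, size=n_da, replace=False) if n_da else np.array([], dtype=int)
    n_up = int(round(scenario.direction_balance * n_da))
    shuffled = rng.permutation(da_idx)
    direction = np.zeros(m, dtype=np.int8)
    direction[shuffled[:n_up]] = 1
    direction[shuffled[n_up:]] = -1
    is_da = np.zeros(m, dtype=bool)
    is_da[da_idx] = True
    fc = np.ones(m)
    fc[is_da] = scenario.fold_change

    mu2 = base_mu * np.where(direction > 0, scenario.fold_change,
                             np.where(direction < 0, 1.0 / scenario.fold_change, 1.0))
    if scenario.compositional:
        mu2 = mu2 * base_mu.sum() / mu2.sum()

    n = 2 * npg
    mu = np.empty((m, n))
    mu[:, :npg] = base_mu[:, None]
    mu[:, npg:] = mu2[:, None]
    lib = rng.uniform(*scenario.library_size_range, size=n)
    mu = mu * lib[None, :]
    counts = _draw_counts(rng, mu, scenario.model, scenario.dispersion,
                          scenario.pi0, scenario.alpha0)

    feature_ids = [f"F{i:04d}" for i in range(m)]
    sample_ids = [f"S{j:03d}" for j in range(n)]
    groups = ["grpA"] * npg + ["grpB"] * npg
    table = CountTable(feature_ids, sample_ids, counts)
    metadata = SampleMetadata.from_groups(sample_ids, groups)
    truth = TruthSet(feature_ids, is_da, direction, fc)
    return table, metadata, truth


def sim_null(m: int, n_samples: int, model: str = "NB",
             mean_log_range: tuple[float, float] = (np.log(5), np.log(500)),
             dispersion: float = 0.5, pi0: float = 0.0, alpha0: float = 50.0,
             library_size_range: tuple[float, float] = (1.0, 1.0),
             seed: int = 0) -> CountTable:
    """Exchangeable-sample null table: every sample i.i.d. from the same
    per-feature distribution, so any balanced relabeling is a true null."""
    rng = np.random.default_rng(seed)
    base_mu = np.exp(rng.uniform(*mean_log_range, size=m))
    lib = rng.uniform(*library_size_range, size=n_samples)
    mu = base_mu[:, None] * lib[None, :]
    counts = _draw_counts(rng, mu, model, dispersion, pi0, alpha0)
    return CountTable([f"F{i:04d}" for i in range(m)],
                      [f"S{j:03d}" for j in range(n_samples)], counts)


def sim_annotation(truth: TruthSet, noise: float = 0.0,
                   seed: int = 0) -> EnrichmentPrior:
    """Annotation aligned with simulated truth: DA features get level
    'expectedUP' or 'expectedDOWN'; a fraction ``noise`` of the annotated
    labels is flipped at random."""
    if not (0 <= noise < 0.5):
        raise ValidationError("noise must lie in [0, 0.5)")
    annotation = {}
    for fid, da, d in zip(truth.feature_ids, truth.is_da, truth.direction):
        if da:
            annotation[fid] = "expectedUP" if d > 0 else "expectedDOWN"
    annotated = sorted(annotation)
    n_flip = int(round(noise * len(annotated)))
    if n_flip:
        rng = np.random.default_rng(seed)
        for fid in rng.choice(annotated, size=n_flip, replace=False):
            annotation[fid] = ("expectedDOWN" if annotation[fid] == "expectedUP"
                               else "expectedUP")
    expected = {}
    if "expectedUP" in annotation.values():
        expected["expectedUP"] = "UP"
    if "expectedDOWN" in annotation.values():
        expected["expectedDOWN"] = "DOWN"
    return EnrichmentPrior(annotation, expected)
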