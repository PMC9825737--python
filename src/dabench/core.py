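"""Core data containers, validation, tabular I/O and shared statistics.

Everything downstream (normalization, DA methods, benchmarking engines)
consumes the types defined here: :class:`CountTable`, :class:`SampleMetadata`,
:class:`ValidatedExperiment` and :class:`DAResult`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed into a valid table."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Feature-by-sample matrix of non-negative integer counts.

    Parameters
    ----------
    feature_ids : sequence of str
        Unique row identifiers.
    sample_ids : sequence of str
        Unique column identifiers.
    counts : ndarray of shape (n_features, n_samples)
        Non-negative integers.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            frac = counts != np.floor(counts)
            if np.any(~np.isfinite(counts)) or frac.any():
                i, j = np.argwhere(~np.isfinite(counts) | frac)[0]
                raise ValidationError(
                    f"non-integer count at feature {self.feature_ids[i]!r}, "
                    f"sample {self.sample_ids[j]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            i, j = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(self.sample_ids) < 2:
            raise ValidationError("need at least 2 samples")
        if len(self.feature_ids) < 1:
            raise ValidationError("need at least 1 feature")
        self.counts = np.asarray(counts, dtype=np.int64)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return CountTable(list(self.feature_ids), list(sample_ids), self.counts[:, idx])


@dataclass
class SampleMetadata:
    """Per-sample annotation table indexed by sample id."""

    table: pd.DataFrame  # index: sample_id

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @classmethod
    def from_groups(cls, sample_ids: Sequence[str], groups: Sequence,
                    group_column: str = "group") -> "SampleMetadata":
        return cls(pd.DataFrame({group_column: list(groups)},
                                index=[str(s) for s in sample_ids]))


@dataclass
class ValidatedExperiment:
    """A CountTable aligned with its metadata and a chosen group column."""

    table: CountTable
    metadata: SampleMetadata
    group_column: str
    group_sizes: dict = field(default_factory=dict)

    @property
    def groups(self) -> list:
        """Group levels in sorted order; the second level is the 'treatment'."""
        return sorted(self.metadata.table[self.group_column].unique())

    def group_mask(self, level) -> np.ndarray:
        return (self.metadata.table[self.group_column] == level).to_numpy()


@dataclass
class DAResult:
    """Per-feature output of one DA method run.

    Missing p-values (method failure on a feature) are NaN; they stay NaN
    after adjustment and are excluded from downstream rates.
    """

    method_id: str
    feature_ids: list[str]
    p_raw: np.ndarray
    p_adj: np.ndarray
    statistic: np.ndarray
    direction: np.ndarray
    params_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.p_raw = np.asarray(self.p_raw, dtype=float)
        self.p_adj = np.asarray(self.p_adj, dtype=float)
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.direction = np.asarray(self.direction, dtype=np.int8)
        ok = ~np.isnan(self.p_raw)
        if np.any((self.p_raw[ok] < 0) | (self.p_raw[ok] > 1)):
            raise ValidationError("p_raw outside [0, 1]")
        if np.any(np.isnan(self.p_raw) & ~np.isnan(self.p_adj)):
            raise ValidationError("p_adj present where p_raw is missing")

    @classmethod
    def from_raw(cls, method_id: str, feature_ids: Sequence[str],
                 p_raw: np.ndarray, statistic: np.ndarray, direction: np.ndarray,
                 params_fingerprint: str = "") -> "DAResult":
        p_raw = np.asarray(p_raw, dtype=float)
        return cls(method_id, list(feature_ids), p_raw, bh_adjust(p_raw),
                   statistic, direction, params_fingerprint)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.p_raw).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature_id": self.feature_ids,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "statistic": self.statistic,
            "direction": self.direction.astype(int),
        })


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_counts(path: str | Path, format: str | None = None) -> CountTable:
    """Read a count matrix from TSV/CSV (feature_id column + sample columns)
    or a MatrixMarket triplet with ``<stem>.rows.txt`` / ``<stem>.cols.txt``
    id sidecars."""
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"tsv": "tsv", "txt": "tsv", "csv": "csv", "mtx": "mtx"}.get(suffix)
        if format is None:
            raise ParseError(f"cannot infer format from suffix of {path.name}")
    if format == "mtx":
        return _load_mtx(path)
    sep = "\t" if format == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, header=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: header line must contain feature_id column "
                         "plus at least one sample column")
    feature_ids = df.iloc[:, 0].astype(str).tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    values = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.iloc[:, 1:].apply(pd.to_numeric, errors="coerce")
        if bad.isna().to_numpy().any():
            i, j = np.argwhere(bad.isna().to_numpy())[0]
            raise ParseError(
                f"{path}: non-numeric count on line {i + 2} "
                f"(feature {feature_ids[i]!r}, sample {sample_ids[j]!r})")
        values = bad.to_numpy()
    return CountTable(feature_ids, sample_ids, values)


def _load_mtx(path: Path) -> CountTable:
    from scipy.io import mmread

    stem = path.with_suffix("")
    rows_path = stem.with_suffix(".rows.txt")
    cols_path = stem.with_suffix(".cols.txt")
    for p in (rows_path, cols_path):
        if not p.exists():
            raise ParseError(f"missing sidecar file {p}")
    try:
        mat = mmread(str(path))
    except Exception as exc:
        raise ParseError(f"failed to parse {path}: {exc}") from exc
    feature_ids = rows_path.read_text().split()
    sample_ids = cols_path.read_text().split()
    arr = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if arr.shape != (len(feature_ids), len(sample_ids)):
        raise ParseError(
            f"{path}: matrix is {arr.shape} but sidecars declare "
            f"{len(feature_ids)} rows x {len(sample_ids)} cols")
    return CountTable(feature_ids, sample_ids, arr)


def write_counts(table: CountTable, path: str | Path, sep: str = "\t") -> None:
    df = table.to_dataframe()
    df.index.name = "feature_id"
    df.to_csv(path, sep=sep)


def load_metadata(path: str | Path, sep: str = "\t") -> SampleMetadata:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: metadata must contain a 'sample_id' column")
    return SampleMetadata(df.set_index("sample_id"))


# ---------------------------------------------------------------------------
# validation and shared statistics
# ---------------------------------------------------------------------------


def validate_experiment(table: CountTable, metadata: SampleMetadata,
                        group_column: str) -> ValidatedExperiment:
    """Align a count table with metadata and check the grouping is usable.

    Columns of the table are reordered to metadata order. Errors list the
    offending sample ids or group levels.
    """
    tset, mset = set(table.sample_ids), set(metadata.sample_ids)
    if tset != mset:
        missing = sorted(tset - mset)
        extra = sorted(mset - tset)
        raise ValidationError(
            "sample id mismatch between counts and metadata; "
            f"only in counts: {missing}; only in metadata: {extra}")
    if group_column not in metadata.table.columns:
        raise ValidationError(f"metadata has no column {group_column!r}")
    levels = metadata.table[group_column].unique()
    if len(levels) < 2:
        raise ValidationError(
            f"group column {group_column!r} needs >= 2 groups, "
            f"found only {sorted(map(str, levels))}")
    ordered = table.subset_samples(metadata.sample_ids)
    sizes = metadata.table[group_column].value_counts().to_dict()
    return ValidatedExperiment(ordered, metadata, group_column, group_sizes=sizes)


def bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, NaN-aware.

    NaN entries are excluded from the procedure and stay NaN.
    """
    p = np.asarray(p_raw, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def params_fingerprint(params: Mapping) -> str:
    """Deterministic short hash of a parameter mapping."""
    blob = json.dumps(params, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
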