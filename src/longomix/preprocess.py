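"""Feature-table container, retention filters and scaling transforms.

The :class:`FeatureTable` is the currency passed between all analysis
stages: a features x samples abundance matrix (``NaN`` marks a value
below the detection limit) together with per-sample design metadata
(condition, culture day, biological replicate) and optional per-feature
metadata such as chromatographic retention time.

Filtering keeps features eluting inside a retention-time window whose
maximum abundance exceeds a floor; scaling offers mean centering and
pareto scaling (divide centered values by the square root of the
standard deviation), the two transforms used upstream of OPLS-DA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "filter_features",
    "pareto_scale",
    "mean_center",
    "impute_missing",
    "Scaler",
    "DEFAULT_RT_WINDOW",
    "DEFAULT_ABUNDANCE_FLOOR",
]

DEFAULT_RT_WINDOW: tuple[float, float] = (0.8, 9.0)
DEFAULT_ABUNDANCE_FLOOR: float = 5000.0

REQUIRED_SAMPLE_COLUMNS = ("condition", "day", "replicate")


@dataclass
class FeatureTable:
    """Features x samples abundance matrix plus design metadata.

    Parameters
    ----------
    abundances:
        DataFrame indexed by feature id with one column per sample id.
        Values are non-negative abundances; ``NaN`` means "not detected".
    sample_meta:
        DataFrame indexed by sample id with columns ``condition``,
        ``day`` and ``replicate``; one row per abundance column.
    feature_meta:
        Optional DataFrame indexed by feature id; an ``rt`` column (minutes)
        enables retention-time filtering.
    """

    abundances: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.abundances.index.has_duplicates:
            raise ValueError("duplicate feature ids in abundance table")
        if self.abundances.columns.has_duplicates:
            raise ValueError("duplicate sample ids in abundance table")
        missing_cols = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in self.sample_meta.columns]
        if missing_cols:
            raise ValueError(f"sample_meta lacks required columns: {missing_cols}")
        if set(self.abundances.columns) != set(self.sample_meta.index):
            raise ValueError("sample ids in abundances and sample_meta differ")
        # keep metadata row order aligned with the matrix columns
        self.sample_meta = self.sample_meta.loc[self.abundances.columns]
        if self.feature_meta is not None:
            if not set(self.abundances.index).issubset(self.feature_meta.index):
                raise ValueError("feature_meta does not cover all feature ids")
            self.feature_meta = self.feature_meta.loc[self.abundances.index]
        vals = self.abundances.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative abundances are not allowed")

    # -- convenience ---------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.abundances.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundances.columns

    @property
    def n_features(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[1]

    def conditions(self) -> list[str]:
        return sorted(self.sample_meta["condition"].unique())

    def days(self) -> np.ndarray:
        return np.sort(self.sample_meta["day"].unique())

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        ids = [f for f in self.feature_ids if f in set(feature_ids)]
        fm = self.feature_meta.loc[ids] if self.feature_meta is not None else None
        return FeatureTable(self.abundances.loc[ids], self.sample_meta.copy(), fm)

    def subset_days(self, days: Sequence[float]) -> "FeatureTable":
        keep = self.sample_meta.index[self.sample_meta["day"].isin(days)]
        fm = self.feature_meta.copy() if self.feature_meta is not None else None
        return FeatureTable(self.abundances[keep], self.sample_meta.loc[keep], fm)

    # -- I/O -----------------------------------------------------------
    def write(self, out_dir: str | Path, prefix: str = "") -> dict[str, Path]:
        """Write abundances/sample metadata (and feature metadata) as TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = out / f"{prefix}abundances.tsv"
        self.abundances.rename_axis("feature_id").to_csv(p, sep="\t")
        paths["abundances"] = p
        p = out / f"{prefix}samples.tsv"
        self.sample_meta.rename_axis("sample_id").to_csv(p, sep="\t")
        paths["samples"] = p
        if self.feature_meta is not None:
            p = out / f"{prefix}features.tsv"
            self.feature_meta.rename_axis("feature_id").to_csv(p, sep="\t")
            paths["features"] = p
        return paths

    @classmethod
    def read(
        cls,
        abundances: str | Path,
        samples: str | Path,
        features: str | Path | None = None,
    ) -> "FeatureTable":
        ab = pd.read_csv(abundances, sep="\t", index_col=0)
        sm = pd.read_csv(samples, sep="\t", index_col=0)
        fm = pd.read_csv(features, sep="\t", index_col=0) if features else None
        return cls(ab, sm, fm)


def filter_features(
    table: FeatureTable,
    rt_window: tuple[float, float] | None = DEFAULT_RT_WINDOW,
    abundance_floor: float = DEFAULT_ABUNDANCE_FLOOR,
) -> FeatureTable:
    """Apply the feature-retention rules.

    A feature is kept when its retention time lies inside ``rt_window``
    (bounds inclusive; pass ``None`` to skip the RT rule) *and* its
    maximum abundance across samples is strictly greater than
    ``abundance_floor``. Feature order is preserved and the operation is
    idempotent.
    """
    mask = pd.Series(True, index=table.feature_ids)
    if rt_window is not None:
        if table.feature_meta is None or "rt" not in table.feature_meta.columns:
            raise ValueError(
                "retention-time filtering requested but feature_meta has no 'rt' column"
            )
        rt = table.feature_meta["rt"]
        mask &= (rt >= rt_window[0]) & (rt <= rt_window[1])
    max_ab = table.abundances.max(axis=1, skipna=True)
    mask &= max_ab > abundance_floor
    kept = table.feature_ids[mask.to_numpy()]
    fm = table.feature_meta.loc[kept] if table.feature_meta is not None else None
    return FeatureTable(table.abundances.loc[kept], table.sample_meta.copy(), fm)


def _as_variable_major(matrix: np.ndarray, by: str) -> np.ndarray:
    """Return a view with variables along axis 1 (observations in rows)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if by == "columns":
        return m
    if by == "rows":
        return m.T
    raise ValueError("'by' must be 'columns' or 'rows'")


def mean_center(matrix: np.ndarray, by: Literal["columns", "rows"] = "columns") -> np.ndarray:
    """Subtract the per-variable mean; variable means are exactly zero after."""
    m = _as_variable_major(matrix, by)
    if m.size == 0:
        raise ValueError("empty matrix")
    centered = m - m.mean(axis=0, keepdims=True)
    return centered if by == "columns" else centered.T


def pareto_scale(matrix: np.ndarray, by: Literal["columns", "rows"] = "columns") -> np.ndarray:
    """Pareto scaling: ``(x - mean) / sqrt(sd)`` per variable.

    ``sd`` is the sample standard deviation (``ddof=1``). Zero-variance
    variables are centered only, yielding all-zero columns.
    """
    m = _as_variable_major(matrix, by)
    if m.shape[0] < 2:
        raise ValueError("pareto scaling needs at least 2 observations per variable")
    centered = m - m.mean(axis=0, keepdims=True)
    sd = m.std(axis=0, ddof=1, keepdims=True)
    denom = np.sqrt(sd)
    scaled = np.divide(centered, denom, out=centered.copy(), where=denom > 0)
    return scaled if by == "columns" else scaled.T


def impute_missing(table: FeatureTable, fill: float) -> FeatureTable:
    """Replace missing (below detection) abundances by ``fill``."""
    if fill < 0:
        raise ValueError("fill value must be non-negative")
    ab = table.abundances.fillna(fill)
    fm = table.feature_meta.copy() if table.feature_meta is not None else None
    return FeatureTable(ab, table.sample_meta.copy(), fm)


@dataclass
class Scaler:
    """Fit/transform wrapper so cross-validation can refit scaling per fold.

    ``mode``: ``"pareto"`` (center + divide by sqrt(sd)), ``"center"``
    (mean centering only) or ``None`` (identity). Statistics are learned
    on the training block and re-applied to held-out observations.
    """

    mode: Literal["pareto", "center"] | None = "pareto"
    mean_: np.ndarray | None = field(default=None, repr=False)
    denom_: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X: np.ndarray) -> "Scaler":
        X = np.asarray(X, dtype=float)
        if self.mode is None:
            return self
        if X.shape[0] < 2 and self.mode == "pareto":
            raise ValueError("pareto scaling needs at least 2 observations")
        self.mean_ = X.mean(axis=0)
        if self.mode == "pareto":
            sd = X.std(axis=0, ddof=1)
            denom = np.sqrt(sd)
            denom[denom == 0] = 1.0
            self.denom_ = denom
        else:
            self.denom_ = np.ones(X.shape[1])
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.mode is None:
            return X.copy()
        if self.mean_ is None:
            raise RuntimeError("Scaler not fitted")
        return (X - self.mean_) / self.denom_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def fresh(self) -> "Scaler":
        return Scaler(mode=self.mode)
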