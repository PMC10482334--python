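"""Time-course integrals, fold changes and regulation calls.

Each feature's abundance trajectory is summarized per condition by the
trapezoidal integral over the culture days (AUC). The signed fold change
between conditions uses the convention that down-regulation ``r < 1`` is
reported as ``-1/r``, so thresholds read symmetrically as "+/- k-fold".
AUCs at or below a detection floor produce infinity sentinels ("infinite
increase/decrease") or, when both conditions are below the floor, an
undefined (NaN) sentinel that can never be called regulated.

A feature counts as differentially regulated only when it passes the
fold-change threshold (metabolites 1.5, proteins 1.1; boundary
inclusive) *and* carries a significant OPLS-DA predictive loading.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import FeatureTable

__all__ = [
    "TimeCourseSummary",
    "DifferentialCall",
    "compute_auc",
    "fold_change",
    "max_fold_change",
    "call_regulation",
    "differential_analysis",
    "METABOLITE_THRESHOLD",
    "PROTEIN_THRESHOLD",
]

METABOLITE_THRESHOLD = 1.5
PROTEIN_THRESHOLD = 1.1


@dataclass
class TimeCourseSummary:
    """Per-feature, per-condition trajectory and its integral."""

    feature_id: str
    condition: str
    days: np.ndarray
    mean_abundance_per_day: np.ndarray
    auc: float


@dataclass
class DifferentialCall:
    feature_id: str
    auc_test: float
    auc_control: float
    signed_fc: float  # may be +/-inf or NaN (undefined)
    max_fc: float | None = None
    max_fc_day: float | None = None
    passes_threshold: bool = False
    opls_significant: bool = False
    regulated: bool = False
    direction: str = "none"  # up | down | none


def compute_auc(
    days: Sequence[float],
    abundances: np.ndarray,
    feature_id: str = "",
    condition: str = "",
) -> TimeCourseSummary:
    """Trapezoidal integral of per-day replicate means over the day grid.

    ``abundances`` is either a ``(n_replicates, n_days)`` matrix or a
    per-day vector; NaN replicate values are skipped in the per-day mean.
    A day at which every replicate is missing raises, naming the day.
    """
    d = np.asarray(days, dtype=float)
    if d.size < 2 or np.unique(d).size != d.size:
        raise ValueError("need at least 2 distinct days")
    if not np.all(np.diff(d) > 0):
        raise ValueError("days must be strictly increasing")
    a = np.asarray(abundances, dtype=float)
    if a.ndim == 1:
        a = a[np.newaxis, :]
    if a.shape[1] != d.size:
        raise ValueError("abundance columns must align with days")
    if np.nanmin(a, initial=0.0) < 0:
        raise ValueError("abundances must be non-negative")
    all_missing = np.all(np.isnan(a), axis=0)
    if all_missing.any():
        bad = d[all_missing][0]
        raise ValueError(f"all replicate values missing at day {bad:g}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(a, axis=0)
    auc = float(np.trapezoid(means, d))
    return TimeCourseSummary(
        feature_id=feature_id, condition=condition, days=d,
        mean_abundance_per_day=means, auc=auc,
    )


def fold_change(auc_test: float, auc_control: float, floor: float = 0.0) -> float:
    """Signed fold change between condition AUCs.

    ``r = test/control``; returned as ``r`` when ``r >= 1`` and ``-1/r``
    otherwise, so the value lives in ``(-inf, -1] U [+1, +inf)``. When
    only one condition exceeds ``floor`` the result is the matching
    infinity sentinel; both at or below the floor yields NaN (undefined).
    """
    if auc_test < 0 or auc_control < 0:
        raise ValueError("AUCs must be non-negative")
    test_above = auc_test > floor
    control_above = auc_control > floor
    if not test_above and not control_above:
        return math.nan
    if test_above and not control_above:
        return math.inf
    if control_above and not test_above:
        return -math.inf
    # down case computed as -(control/test) so antisymmetry is bit-exact
    if auc_test >= auc_control:
        return auc_test / auc_control
    return -(auc_control / auc_test)


def max_fold_change(
    days: Sequence[float],
    means_test: Sequence[float],
    means_control: Sequence[float],
    floor: float = 0.0,
) -> tuple[float, float | None]:
    """Largest-magnitude per-day signed fold change and the day it occurs.

    Per-day ratios follow the :func:`fold_change` conventions (including
    infinity sentinels when one condition is below the floor). Returns
    ``(NaN, None)`` when no day yields a defined ratio.
    """
    d = np.asarray(days, dtype=float)
    mt = np.asarray(means_test, dtype=float)
    mc = np.asarray(means_control, dtype=float)
    if not (d.size == mt.size == mc.size):
        raise ValueError("day grids of the two conditions must be aligned")
    best_fc, best_day = math.nan, None
    for day, t, c in zip(d, mt, mc):
        if np.isnan(t) or np.isnan(c):
            continue
        fc = fold_change(float(t), float(c), floor=floor)
        if math.isnan(fc):
            continue
        if best_day is None or abs(fc) > abs(best_fc):
            best_fc, best_day = fc, float(day)
    return best_fc, best_day


def call_regulation(
    calls: Iterable[DifferentialCall],
    threshold: float,
    significant_ids: set,
    use_max_fc: bool = False,
) -> list[DifferentialCall]:
    """Finalize regulation flags on draft differential calls.

    ``passes_threshold`` is ``|fc| >= threshold`` (infinity passes, NaN
    never does); ``regulated`` additionally requires membership in
    ``significant_ids``; ``direction`` follows the fold-change sign for
    regulated features.
    """
    if threshold < 1:
        raise ValueError("fold-change threshold must be >= 1")
    out = []
    for call in calls:
        fc = call.max_fc if use_max_fc else call.signed_fc
        if fc is None or math.isnan(fc):
            passes = False
        else:
            passes = abs(fc) >= threshold
        call.passes_threshold = passes
        call.opls_significant = call.feature_id in significant_ids
        call.regulated = passes and call.opls_significant
        if call.regulated:
            call.direction = "up" if fc > 0 else "down"
        else:
            call.direction = "none"
        out.append(call)
    return out


def _per_day_means(table: FeatureTable, condition: str, days: np.ndarray) -> pd.DataFrame:
    """Features x days matrix of replicate means for one condition."""
    meta = table.sample_meta
    cols = {}
    for day in days:
        samples = meta.index[(meta["condition"] == condition) & (meta["day"] == day)]
        if len(samples) == 0:
            raise ValueError(f"condition {condition!r} has no samples on day {day:g}")
        cols[day] = table.abundances[samples].mean(axis=1, skipna=True)
    return pd.DataFrame(cols)


def differential_analysis(
    table: FeatureTable,
    significant_ids: set,
    threshold: float = METABOLITE_THRESHOLD,
    floor: float = 0.0,
    test_condition: str = "test",
    control_condition: str = "control",
    statistic: str = "auc",
) -> list[DifferentialCall]:
    """AUC (or max per-day) fold-change calls for every feature of a table.

    The day grid is the intersection of the two conditions' grids (a
    warning is emitted when they differ). The floor for infinity calls
    on AUCs is ``floor`` times the integration span, so an abundance
    floor keeps its meaning after integration over days.
    """
    meta = table.sample_meta
    days_t = set(meta.loc[meta["condition"] == test_condition, "day"])
    days_c = set(meta.loc[meta["condition"] == control_condition, "day"])
    if not days_t or not days_c:
        raise ValueError("both conditions must be present in sample_meta")
    if days_t != days_c:
        warnings.warn("day grids differ between conditions; using their intersection")
    days = np.sort(np.array(sorted(days_t & days_c), dtype=float))
    if days.size < 2:
        raise ValueError("fewer than 2 shared days between conditions")

    means_t = _per_day_means(table, test_condition, days)
    means_c = _per_day_means(table, control_condition, days)
    span = float(days[-1] - days[0])
    auc_floor = floor * span

    use_max = statistic == "max"
    calls = []
    for fid in table.feature_ids:
        mt = means_t.loc[fid].to_numpy()
        mc = means_c.loc[fid].to_numpy()
        auc_t = float(np.trapezoid(np.nan_to_num(mt), days))
        auc_c = float(np.trapezoid(np.nan_to_num(mc), days))
        fc = fold_change(auc_t, auc_c, floor=auc_floor)
        mfc, mday = max_fold_change(days, mt, mc, floor=floor)
        calls.append(DifferentialCall(
            feature_id=fid, auc_test=auc_t, auc_control=auc_c,
            signed_fc=fc, max_fc=mfc, max_fc_day=mday,
        ))
    return call_regulation(calls, threshold, significant_ids, use_max_fc=use_max)


def calls_to_frame(calls: Sequence[DifferentialCall]) -> pd.DataFrame:
    """Tabular view of differential calls (one row per feature)."""
    return pd.DataFrame([
        {
            "feature_id": c.feature_id,
            "auc_test": c.auc_test,
            "auc_control": c.auc_control,
            "signed_fc": c.signed_fc,
            "max_fc": c.max_fc,
            "max_fc_day": c.max_fc_day,
            "passes_threshold": c.passes_threshold,
            "opls_significant": c.opls_significant,
            "regulated": c.regulated,
            "direction": c.direction,
        }
        for c in calls
    ]).set_index("feature_id")
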