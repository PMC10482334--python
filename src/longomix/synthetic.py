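"""Synthetic longitudinal two-condition omics data with known ground truth.

The generator emits a feature x sample abundance table shaped like a
fed-batch culture study: two conditions (test vs control) sampled on a
shared day grid with a few biological replicates, log-normal abundances,
a dominant smooth time trajectory shared by both conditions, a small
planted condition effect on a chosen subset of features, and optional
features detectable in only one condition.

The time signal is a single random cubic day-profile, modulated per
feature by a random amplitude (so it forms one strong orthogonal-to-class
direction), and its overall strength is calibrated numerically so that
the share of variance the trajectory explains in the pareto-scaled data
hits a requested target. The planted effect, membership sets and the
realized variance share are returned as :class:`GroundTruth` so
parameter-recovery tests can score the downstream pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotation import (
    SOURCES,
    TIERS,
    AnnotationEvidence,
    ReferenceStandard,
)
from .preprocess import FeatureTable, pareto_scale

__all__ = [
    "StudyDesign",
    "GroundTruth",
    "generate_dataset",
    "generate_annotation_evidence",
    "realized_time_share",
    "DETECTION_FLOOR",
]

DETECTION_FLOOR = 5000.0  # aligned with the preprocess retention rule


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of a simulated two-condition longitudinal study."""

    n_features: int = 2000
    n_discriminative: int = 50
    effect_log2fc: float = 1.0
    days: tuple[float, ...] = (0.0, 3.0, 5.0, 7.0, 10.0, 12.0, 14.0, 17.0)
    replicates_per_condition: int = 3
    conditions: tuple[str, str] = ("test", "control")
    time_variance_fraction: float = 0.6
    noise_cv: float = 0.2
    n_exclusive: int = 0
    baseline_log_mean: float = math.log(5e4)
    baseline_log_sd: float = 1.0
    detection_floor: float = DETECTION_FLOOR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if not (0 <= self.n_discriminative <= self.n_features):
            raise ValueError("n_discriminative out of range")
        if self.n_exclusive < 0 or self.n_discriminative + self.n_exclusive > self.n_features:
            raise ValueError("n_discriminative + n_exclusive must not exceed n_features")
        days = np.asarray(self.days, dtype=float)
        if days.size < 3 or np.any(days < 0) or not np.all(np.diff(days) > 0):
            raise ValueError("days must be >= 3 strictly increasing non-negative values")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be positive")
        if len(set(self.conditions)) != 2:
            raise ValueError("need two distinct condition labels")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")
        if not (0 < self.time_variance_fraction < 1):
            raise ValueError("time_variance_fraction must lie in (0, 1)")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")

    @property
    def n_samples(self) -> int:
        return 2 * self.replicates_per_condition * len(self.days)


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    discriminative_ids: set[str]
    exclusive_ids: set[str]
    planted_log2fc: dict[str, float]
    time_profile: dict[float, float]  # day -> trajectory value (unit-sd shape)
    time_amplitude: float  # calibrated log-space scale of the trajectory
    realized_time_share: float

    def __post_init__(self) -> None:
        if self.discriminative_ids & self.exclusive_ids:
            raise ValueError("a feature cannot be both discriminative and exclusive")


def _trajectory(rng: np.random.Generator, days: np.ndarray) -> np.ndarray:
    """Random cubic day profile, centered and scaled to unit SD over days."""
    u = 2 * (days - days.min()) / (days.max() - days.min()) - 1
    coefs = rng.normal(size=3)
    g = coefs[0] * u + coefs[1] * u**2 + coefs[2] * u**3
    g = g - g.mean()
    sd = g.std()
    if sd < 1e-9:  # vanishing cubic; fall back to a linear ramp
        g = u - u.mean()
        sd = g.std()
    return g / sd


def realized_time_share(
    table: FeatureTable,
    time_profile: Mapping[float, float],
    impute: float | None = None,
) -> float:
    """Variance share a known day-trajectory explains in the scaled data.

    The table is imputed (default: detection floor / 2), pareto-scaled
    per feature and regressed sample-wise on the centered trajectory;
    the returned value is the explained fraction of the total sum of
    squares. This is an oracle computation (it knows the trajectory),
    independent of the unsupervised component an OPLS-DA fit extracts.
    """
    if impute is None:
        impute = DETECTION_FLOOR / 2
    X = table.abundances.fillna(impute).to_numpy(dtype=float).T  # samples x features
    Xs = pareto_scale(X, by="columns")
    g = np.array([time_profile[float(d)] for d in table.sample_meta["day"]])
    g = g - g.mean()
    gg = float(g @ g)
    if gg == 0:
        return 0.0
    proj = np.outer(g, (g @ Xs) / gg)
    total = float(np.sum(Xs * Xs))
    return float(np.sum(proj * proj) / total)


def generate_dataset(design: StudyDesign) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table with planted structure; bit-reproducible by seed.

    Per feature, log-abundance = baseline + amplitude x shared cubic time
    trajectory + condition offset (``effect_log2fc * ln 2`` in the test
    condition for discriminative features) + i.i.d. log-normal replicate
    noise. Exclusive features are recorded as missing (below the
    detection floor) in the control condition. The trajectory scale is
    calibrated by root finding so the realized time-variance share of
    the scaled data matches ``design.time_variance_fraction``.
    """
    rng = np.random.default_rng(design.seed)
    days = np.asarray(design.days, dtype=float)
    n_feat, n_rep = design.n_features, design.replicates_per_condition
    test_label, control_label = design.conditions

    feature_ids = [f"F{i:05d}" for i in range(n_feat)]
    sample_rows = []
    for cond in (test_label, control_label):
        for rep in range(1, n_rep + 1):
            for day in days:
                sample_rows.append((f"{cond}_r{rep}_d{day:g}", cond, float(day), rep))
    sample_meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "condition", "day", "replicate"]
    ).set_index("sample_id")
    n_samples = len(sample_meta)
    is_test = (sample_meta["condition"] == test_label).to_numpy()
    day_of_sample = sample_meta["day"].to_numpy()

    g = _trajectory(rng, days)
    g_sample = np.interp(day_of_sample, days, g)  # exact on-grid lookup

    picked = rng.choice(n_feat, size=design.n_discriminative + design.n_exclusive,
                        replace=False)
    disc_idx = picked[: design.n_discriminative]
    excl_idx = picked[design.n_discriminative:]

    baseline = rng.normal(design.baseline_log_mean, design.baseline_log_sd, size=n_feat)
    # planted and exclusive features must survive the abundance filter
    lifted = np.concatenate([disc_idx, excl_idx]).astype(int)
    if lifted.size:
        baseline[lifted] = np.maximum(baseline[lifted], math.log(4 * design.detection_floor))
    # positive amplitudes: one shared trajectory direction across features,
    # so the time structure stays close to rank one in the scaled data
    amplitude = rng.uniform(0.6, 1.4, size=n_feat)
    sigma = math.sqrt(math.log(1 + design.noise_cv**2))
    noise = rng.normal(0.0, sigma, size=(n_feat, n_samples))

    delta = np.zeros(n_feat)
    delta[disc_idx] = design.effect_log2fc * math.log(2)
    excl_mask_feat = np.zeros(n_feat, dtype=bool)
    excl_mask_feat[excl_idx] = True
    missing = np.outer(excl_mask_feat, ~is_test)  # exclusive: absent in control

    rt = rng.uniform(0.9, 8.9, size=n_feat)

    def build(kappa: float) -> FeatureTable:
        log_ab = (
            baseline[:, None]
            + kappa * np.outer(amplitude, g_sample)
            + np.outer(delta, is_test.astype(float))
            + noise
        )
        ab = np.exp(log_ab)
        ab = pd.DataFrame(ab, index=feature_ids, columns=sample_meta.index)
        ab = ab.mask(pd.DataFrame(missing, index=ab.index, columns=ab.columns))
        fm = pd.DataFrame({"rt": rt}, index=feature_ids)
        return FeatureTable(ab, sample_meta.copy(), fm)

    profile = {float(d): float(v) for d, v in zip(days, g)}

    def share_gap(kappa: float) -> float:
        return realized_time_share(build(kappa), profile,
                                   impute=design.detection_floor / 2) \
            - design.time_variance_fraction

    lo, hi = 1e-6, 0.5
    while share_gap(hi) < 0 and hi < 64:
        hi *= 2
    kappa = float(brentq(share_gap, lo, hi, xtol=1e-6))
    table = build(kappa)
    share = realized_time_share(table, profile, impute=design.detection_floor / 2)

    truth = GroundTruth(
        discriminative_ids={feature_ids[i] for i in disc_idx},
        exclusive_ids={feature_ids[i] for i in excl_idx},
        planted_log2fc={feature_ids[i]: design.effect_log2fc for i in disc_idx},
        time_profile=profile,
        time_amplitude=kappa,
        realized_time_share=share,
    )
    return table, truth


# -- annotation evidence ----------------------------------------------

_DEFAULT_TIER_PROBS = {"1": 0.10, "1*": 0.05, "2": 0.15, "3": 0.10, "4": 0.25, "5": 0.35}

_TIER_SOURCE = {
    "1": "in_house_standard",
    "1*": "in_house_standard",
    "2": "spectral_library",
    "3": "tentative_structure",
    "4": "sum_formula",
}


def generate_annotation_evidence(
    table: FeatureTable,
    library_size: int,
    seed: int = 0,
    tier_probs: Mapping[str, float] | None = None,
) -> tuple[list[AnnotationEvidence], list[ReferenceStandard], dict[str, str]]:
    """Evidence records and a reference library realizing every tier.

    Each feature is assigned an intended tier and its evidence is
    constructed so the tier rules reproduce that tier exactly: reference
    masses sit on a widely spaced grid (far beyond the ppm tolerance),
    tier-matched features get a mass within tolerance of a reference of
    the required source, tier-5 features a mass between grid points.
    Returns ``(evidence, references, intended_tier_by_feature)``.
    """
    if table.n_features == 0:
        raise ValueError("feature table is empty")
    probs = dict(_DEFAULT_TIER_PROBS if tier_probs is None else tier_probs)
    if set(probs) - set(TIERS):
        raise ValueError(f"unknown tiers in tier_probs: {set(probs) - set(TIERS)}")
    rng = np.random.default_rng(seed)

    needs_library = any(probs.get(t, 0) > 0 for t in _TIER_SOURCE)
    if library_size <= 0 and needs_library:
        raise ValueError("library_size must be positive when matched tiers are requested")

    # reference grid: 1.5 Da spacing >> 3 ppm tolerance at any mass here
    references: list[ReferenceStandard] = []
    by_source: dict[str, list[ReferenceStandard]] = {s: [] for s in SOURCES}
    for k in range(library_size):
        source = SOURCES[k % len(SOURCES)]
        mass = 120.0 + 1.5 * k
        rt = float(rng.uniform(1.0, 8.5)) if source == "in_house_standard" else None
        sid = f"SPEC{k:04d}" if source != "sum_formula" else None
        ref = ReferenceStandard(
            name=f"{source.upper()[:4]}_{k:04d}", monoisotopic_mass=mass,
            source=source, retention_time=rt, msms_spectrum_id=sid,
        )
        references.append(ref)
        by_source[source].append(ref)

    realizable = ["5"] + [t for t, s in _TIER_SOURCE.items() if by_source[s]]
    tiers = [t for t in TIERS if t in realizable and probs.get(t, 0) > 0]
    if not tiers:
        tiers = ["5"]
    weights = np.array([probs[t] for t in tiers], dtype=float)
    weights = weights / weights.sum()

    evidence: list[AnnotationEvidence] = []
    intended: dict[str, str] = {}
    for fid in table.feature_ids:
        tier = str(rng.choice(tiers, p=weights))
        intended[fid] = tier
        if tier == "5":
            k = int(rng.integers(0, max(library_size, 1)))
            mass = 120.0 + 1.5 * k + 0.75  # between grid points: no ppm match
            rt = float(rng.uniform(0.8, 9.0))
            ev = AnnotationEvidence(fid, mass, rt)
        else:
            pool = by_source[_TIER_SOURCE[tier]]
            ref = pool[int(rng.integers(0, len(pool)))]
            ppm_off = float(rng.uniform(-2.5, 2.5))
            mass = ref.monoisotopic_mass * (1 + ppm_off * 1e-6)
            if tier in ("1", "1*"):
                rt = ref.retention_time + float(rng.uniform(-0.25, 0.25))
            else:
                rt = float(rng.uniform(0.8, 9.0))
            ev = AnnotationEvidence(
                fid, mass, rt,
                has_msms=tier in ("1", "2", "3"),
                msms_match_standard=tier == "1",
                msms_match_library=tier == "2",
                msms_manual_structure=tier == "3",
                msigma=float(rng.uniform(10, 90)) if tier == "4" else None,
                formula_match=tier == "4",
            )
        evidence.append(ev)
    return evidence, references, intended


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Persist ground truth as a flat TSV (one row per planted feature)."""
    rows = [
        {"feature_id": fid, "role": "discriminative",
         "planted_log2fc": truth.planted_log2fc.get(fid, 0.0)}
        for fid in sorted(truth.discriminative_ids)
    ] + [
        {"feature_id": fid, "role": "exclusive", "planted_log2fc": math.inf}
        for fid in sorted(truth.exclusive_ids)
    ]
    pd.DataFrame(rows, columns=["feature_id", "role", "planted_log2fc"]).to_csv(
        path, sep="\t", index=False
    )
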