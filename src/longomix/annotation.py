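"""Identification-confidence tiers for small-molecule features.

A feature's evidence (precursor mass, retention time, MS/MS match flags,
isotope-fit score) is compared against a reference library and the first
matching rule assigns the tier:

* ``1``  — in-house standard: retention time within +/-0.3 min, mass
  within +/-3.0 ppm and a matching MS/MS fragmentation pattern.
* ``1*`` — same standard match but the feature lacks MS/MS data.
* ``2``  — mass within +/-3.0 ppm of a spectral-library record plus a
  library MS/MS match.
* ``3``  — mass match to a tentative structure with manually annotated
  MS/MS fragmentation.
* ``4``  — mass match to a sum formula with isotope-pattern agreement
  (mSigma strictly below 100).
* ``5``  — none of the above: a unique mass and retention time only.

Mass and retention-time tolerances are inclusive; the mSigma cutoff is
strict. Among several qualifying references the one with the smallest
|ppm error| wins (ties: smallest |RT error|, then name).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceStandard",
    "AnnotationEvidence",
    "AnnotationRecord",
    "Tolerances",
    "ppm_error",
    "assign_tier",
    "summarize_tiers",
    "read_references",
    "read_evidence",
    "records_to_frame",
    "TIERS",
    "SOURCES",
]

TIERS = ("1", "1*", "2", "3", "4", "5")
SOURCES = ("in_house_standard", "spectral_library", "tentative_structure", "sum_formula")

DEFAULT_BINS = (5_000.0, 10_000.0, 50_000.0, 100_000.0, math.inf)


@dataclass(frozen=True)
class Tolerances:
    rt: float = 0.3  # minutes, inclusive
    ppm: float = 3.0  # inclusive
    msigma: float = 100.0  # strict upper bound

    def __post_init__(self) -> None:
        if self.rt <= 0 or self.ppm <= 0 or self.msigma <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class ReferenceStandard:
    name: str
    monoisotopic_mass: float
    source: str
    retention_time: float | None = None
    msms_spectrum_id: str | None = None

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError("reference mass must be positive")
        if self.source not in SOURCES:
            raise ValueError(f"unknown reference source {self.source!r}")
        if self.source == "in_house_standard" and self.retention_time is None:
            raise ValueError("in-house standards must carry a retention time")


@dataclass
class AnnotationEvidence:
    feature_id: str
    precursor_mass: float
    retention_time: float
    has_msms: bool = False
    msms_match_standard: bool = False
    msms_match_library: bool = False
    msms_manual_structure: bool = False
    msigma: float | None = None
    formula_match: bool = False

    def __post_init__(self) -> None:
        if (self.msms_match_standard or self.msms_match_library
                or self.msms_manual_structure) and not self.has_msms:
            raise ValueError("MS/MS match flags require has_msms")
        if self.msigma is not None and self.msigma < 0:
            raise ValueError("msigma must be non-negative")


@dataclass
class AnnotationRecord:
    feature_id: str
    tier: str
    matched_reference: str | None = None
    ppm_error: float = math.nan
    rt_error: float = math.nan


def ppm_error(observed_mass: float, reference_mass: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if reference_mass <= 0:
        raise ValueError("reference mass must be positive")
    return 1e6 * (observed_mass - reference_mass) / reference_mass


def _best_match(
    evidence: AnnotationEvidence,
    references: Sequence[ReferenceStandard],
    source: str,
    tol: Tolerances,
    require_rt: bool,
) -> tuple[ReferenceStandard, float, float] | None:
    """Closest qualifying reference of a given source, or None."""
    best = None
    for ref in references:
        if ref.source != source:
            continue
        ppm = ppm_error(evidence.precursor_mass, ref.monoisotopic_mass)
        if abs(ppm) > tol.ppm:
            continue
        if require_rt:
            if ref.retention_time is None:
                continue
            drt = evidence.retention_time - ref.retention_time
            if abs(drt) > tol.rt:
                continue
        else:
            drt = (evidence.retention_time - ref.retention_time
                   if ref.retention_time is not None else math.nan)
        key = (abs(ppm), abs(drt) if not math.isnan(drt) else math.inf, ref.name)
        if best is None or key < best[0]:
            best = (key, ref, ppm, drt)
    if best is None:
        return None
    return best[1], best[2], best[3]


def assign_tier(
    evidence: AnnotationEvidence,
    references: Sequence[ReferenceStandard],
    tolerances: Tolerances = Tolerances(),
) -> AnnotationRecord:
    """Assign the identification-confidence tier; first rule that fires wins.

    A missing mSigma score skips the tier-4 rule rather than raising.
    Every evidence record receives exactly one tier.
    """
    tol = tolerances

    std = _best_match(evidence, references, "in_house_standard", tol, require_rt=True)
    if std is not None:
        ref, ppm, drt = std
        if evidence.msms_match_standard:
            return AnnotationRecord(evidence.feature_id, "1", ref.name, ppm, drt)
        if not evidence.has_msms:
            return AnnotationRecord(evidence.feature_id, "1*", ref.name, ppm, drt)

    if evidence.msms_match_library:
        lib = _best_match(evidence, references, "spectral_library", tol, require_rt=False)
        if lib is not None:
            ref, ppm, drt = lib
            return AnnotationRecord(evidence.feature_id, "2", ref.name, ppm, drt)

    if evidence.msms_manual_structure:
        ts = _best_match(evidence, references, "tentative_structure", tol, require_rt=False)
        if ts is not None:
            ref, ppm, drt = ts
            return AnnotationRecord(evidence.feature_id, "3", ref.name, ppm, drt)

    if (evidence.formula_match and evidence.msigma is not None
            and evidence.msigma < tol.msigma):
        sf = _best_match(evidence, references, "sum_formula", tol, require_rt=False)
        if sf is not None:
            ref, ppm, drt = sf
            return AnnotationRecord(evidence.feature_id, "4", ref.name, ppm, drt)

    return AnnotationRecord(evidence.feature_id, "5")


def summarize_tiers(
    records: Sequence[AnnotationRecord],
    abundances: Mapping[str, float],
    bins: Sequence[float] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Cross-tabulate tier by abundance bin (rows = tiers, columns = bins).

    ``bins`` are strictly increasing edges defining left-inclusive
    intervals. Records whose abundance is missing or outside the edges
    are counted in an ``unbinned`` column (with a warning).
    """
    edges = np.asarray(bins, dtype=float)
    if edges.size < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("bins must be strictly increasing with >= 2 edges")
    labels = [
        f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])
    ]
    columns = labels + ["unbinned"]
    counts = pd.DataFrame(0, index=list(TIERS), columns=columns, dtype=int)
    n_unbinned = 0
    for rec in records:
        ab = abundances.get(rec.feature_id)
        col = "unbinned"
        if ab is not None and not (isinstance(ab, float) and math.isnan(ab)):
            idx = np.searchsorted(edges, ab, side="right") - 1
            if 0 <= idx < len(labels):
                col = labels[idx]
        if col == "unbinned":
            n_unbinned += 1
        counts.loc[rec.tier, col] += 1
    if n_unbinned:
        warnings.warn(f"{n_unbinned} record(s) lacked a usable abundance; "
                      "counted as 'unbinned'")
    return counts


# -- TSV interchange ---------------------------------------------------

def read_references(path: str | Path) -> list[ReferenceStandard]:
    df = pd.read_csv(path, sep="\t")
    refs = []
    for row in df.itertuples(index=False):
        rt = getattr(row, "retention_time", None)
        rt = None if rt is None or (isinstance(rt, float) and math.isnan(rt)) else float(rt)
        sid = getattr(row, "msms_spectrum_id", None)
        sid = None if sid is None or (isinstance(sid, float) and math.isnan(sid)) else str(sid)
        refs.append(ReferenceStandard(
            name=str(row.name), monoisotopic_mass=float(row.monoisotopic_mass),
            source=str(row.source), retention_time=rt, msms_spectrum_id=sid,
        ))
    return refs


def read_evidence(path: str | Path) -> list[AnnotationEvidence]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        ms = getattr(row, "msigma", None)
        ms = None if ms is None or (isinstance(ms, float) and math.isnan(ms)) else float(ms)
        out.append(AnnotationEvidence(
            feature_id=str(row.feature_id),
            precursor_mass=float(row.precursor_mass),
            retention_time=float(row.retention_time),
            has_msms=bool(row.has_msms),
            msms_match_standard=bool(row.msms_match_standard),
            msms_match_library=bool(row.msms_match_library),
            msms_manual_structure=bool(row.msms_manual_structure),
            msigma=ms,
            formula_match=bool(row.formula_match),
        ))
    return out


def references_to_frame(references: Sequence[ReferenceStandard]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "name": r.name, "monoisotopic_mass": r.monoisotopic_mass,
            "source": r.source, "retention_time": r.retention_time,
            "msms_spectrum_id": r.msms_spectrum_id,
        } for r in references
    ])


def evidence_to_frame(evidence: Sequence[AnnotationEvidence]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "feature_id": e.feature_id, "precursor_mass": e.precursor_mass,
            "retention_time": e.retention_time, "has_msms": e.has_msms,
            "msms_match_standard": e.msms_match_standard,
            "msms_match_library": e.msms_match_library,
            "msms_manual_structure": e.msms_manual_structure,
            "msigma": e.msigma, "formula_match": e.formula_match,
        } for e in evidence
    ])


def records_to_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "feature_id": r.feature_id, "tier": r.tier,
            "matched_reference": r.matched_reference,
            "ppm_error": r.ppm_error, "rt_error": r.rt_error,
        } for r in records
    ]).set_index("feature_id")
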