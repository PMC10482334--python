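"""End-to-end orchestration: simulate/load -> filter -> scale -> OPLS-DA
-> differential calls -> annotation, with a reproducible run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import platform
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import assign_tier, read_evidence, read_references, records_to_frame
from .differential import (
    METABOLITE_THRESHOLD,
    PROTEIN_THRESHOLD,
    calls_to_frame,
    differential_analysis,
)
from .opls import fit_opls_da, permutation_test, significant_loadings
from .preprocess import (
    DEFAULT_ABUNDANCE_FLOOR,
    DEFAULT_RT_WINDOW,
    FeatureTable,
    Scaler,
    filter_features,
    impute_missing,
)
from .synthetic import StudyDesign, generate_annotation_evidence, generate_dataset, \
    write_ground_truth

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("longomix")

_MODE_THRESHOLDS = {"metabolite": METABOLITE_THRESHOLD, "protein": PROTEIN_THRESHOLD}


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    # inputs: either file paths or a simulation design
    table_path: str | None = None
    samples_path: str | None = None
    features_path: str | None = None
    evidence_path: str | None = None
    library_path: str | None = None
    simulate: StudyDesign | None = None
    simulate_evidence_library: int = 0  # >0: also simulate annotation evidence

    mode: str = "metabolite"  # selects the fold-change threshold
    threshold: float | None = None  # override; default per mode
    scaling: str = "pareto"  # pareto | center
    rt_window: tuple[float, float] | None = DEFAULT_RT_WINDOW
    abundance_floor: float = DEFAULT_ABUNDANCE_FLOOR
    days_used: tuple[float, ...] | None = None  # subset of days for the model
    fc_statistic: str = "auc"  # auc | max

    n_ortho: int | str = "auto"
    folds: int = 7
    n_perm: int = 200  # 0 disables the permutation test
    seed: int = 0
    out_dir: str = "longomix_out"

    def __post_init__(self) -> None:
        errors = []
        if self.simulate is None and (self.table_path is None or self.samples_path is None):
            errors.append("table_path/samples_path: required unless 'simulate' is given")
        if self.mode not in _MODE_THRESHOLDS:
            errors.append(f"mode: must be one of {sorted(_MODE_THRESHOLDS)}")
        if self.scaling not in ("pareto", "center"):
            errors.append("scaling: must be 'pareto' or 'center'")
        if self.fc_statistic not in ("auc", "max"):
            errors.append("fc_statistic: must be 'auc' or 'max'")
        if self.threshold is not None and self.threshold < 1:
            errors.append("threshold: must be >= 1")
        if self.abundance_floor < 0:
            errors.append("abundance_floor: must be non-negative")
        if self.folds < 2:
            errors.append("folds: must be >= 2")
        if self.n_perm < 0:
            errors.append("n_perm: must be >= 0")
        if not (self.n_ortho == "auto"
                or (isinstance(self.n_ortho, int) and self.n_ortho >= 0)):
            errors.append("n_ortho: must be 'auto' or a non-negative integer")
        if errors:
            raise ValueError("invalid pipeline config: " + "; ".join(errors))

    @property
    def effective_threshold(self) -> float:
        return self.threshold if self.threshold is not None else _MODE_THRESHOLDS[self.mode]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if sim is not None:
            sim = StudyDesign(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in sim.items()})
        for key in ("rt_window", "days_used"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)

    def to_manifest(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"] = dataclasses.asdict(self.simulate)
        return d


@dataclass
class RunReport:
    out_dir: Path
    n_features_input: int
    n_features_retained: int
    diagnostics: dict[str, Any]
    n_significant: int
    n_regulated: int
    outputs: dict[str, str]


def _load_inputs(config: PipelineConfig):
    if config.simulate is not None:
        log.info("simulating dataset: %d features, %d samples",
                 config.simulate.n_features, config.simulate.n_samples)
        table, truth = generate_dataset(config.simulate)
        evidence = references = intended = None
        if config.simulate_evidence_library > 0:
            evidence, references, intended = generate_annotation_evidence(
                table, config.simulate_evidence_library, seed=config.simulate.seed,
            )
        return table, truth, evidence, references, intended
    table = FeatureTable.read(config.table_path, config.samples_path,
                              config.features_path)
    evidence = read_evidence(config.evidence_path) if config.evidence_path else None
    references = read_references(config.library_path) if config.library_path else None
    return table, None, evidence, references, None


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run all stages and write TSV/JSON outputs under ``config.out_dir``.

    Identical config + seed produce byte-identical outputs. On failure,
    files already written for this run are removed before re-raising.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, out, written)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _write(df: pd.DataFrame, path: Path, written: list[Path], **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)
    written.append(path)


def _run(config: PipelineConfig, out: Path, written: list[Path]) -> RunReport:
    table, truth, evidence, references, intended = _load_inputs(config)
    n_input = table.n_features

    if truth is not None:
        gt_path = out / "ground_truth.tsv"
        write_ground_truth(truth, gt_path)
        written.append(gt_path)
        for name, part in table.write(out).items():
            written.append(part)

    rt_window = config.rt_window
    if rt_window is not None and (
            table.feature_meta is None or "rt" not in table.feature_meta.columns):
        raise ValueError("rt filtering requested but no feature 'rt' metadata; "
                         "set rt_window to null to skip")
    table = filter_features(table, rt_window, config.abundance_floor)
    log.info("feature filter: %d -> %d features", n_input, table.n_features)

    model_table = table.subset_days(config.days_used) if config.days_used else table
    imputed = impute_missing(model_table, config.abundance_floor / 2)
    X_raw = imputed.abundances.to_numpy(dtype=float).T  # observations x features
    scaler = Scaler(mode=config.scaling)
    X = scaler.fit_transform(X_raw)
    y_labels = imputed.sample_meta["condition"].to_numpy()

    model, diags = fit_opls_da(
        X, y_labels, n_ortho=config.n_ortho, cv_folds=config.folds,
        scaling_spec=config.scaling, feature_ids=list(table.feature_ids),
    )
    if config.n_perm > 0:
        diags.permutation = permutation_test(
            X, y_labels, model.n_ortho, n_perm=config.n_perm,
            seed=config.seed, folds=config.folds,
        )
    sig_ids = significant_loadings(model)
    log.info("OPLS-DA: %d orthogonal component(s), R2Y=%.3f, Q2=%.3f, "
             "%d significant loadings", model.n_ortho, diags.r2y,
             diags.q2 if diags.q2 is not None else float("nan"), len(sig_ids))

    scores = pd.DataFrame(
        {"t_pred": model.t_pred,
         **{f"t_ortho_{k + 1}": model.T_ortho[:, k] for k in range(model.n_ortho)},
         "condition": imputed.sample_meta["condition"].to_numpy(),
         "day": imputed.sample_meta["day"].to_numpy()},
        index=imputed.sample_ids,
    ).rename_axis("sample_id")
    loadings = pd.DataFrame(
        {"p_pred": model.p_pred, "w": model.w,
         **{f"p_ortho_{k + 1}": model.P_ortho[:, k] for k in range(model.n_ortho)},
         "significant": [fid in sig_ids for fid in table.feature_ids]},
        index=table.feature_ids,
    ).rename_axis("feature_id")
    _write(scores, out / "scores.tsv", written)
    _write(loadings, out / "loadings.tsv", written)
    _write(loadings[loadings["significant"]].drop(columns="significant"),
           out / "significant_features.tsv", written)

    diag_dict: dict[str, Any] = {
        "n_ortho": model.n_ortho,
        "r2x_pred": diags.r2x_pred,
        "r2x_ortho": list(diags.r2x_ortho),
        "r2x_residual": diags.r2x_residual,
        "r2y": diags.r2y,
        "q2": diags.q2,
        "cv_folds": diags.cv_folds,
    }
    if diags.permutation is not None:
        diag_dict["permutation"] = {
            "n_perm": diags.permutation.n_perm,
            "observed_r2y": diags.permutation.observed_r2y,
            "observed_q2": diags.permutation.observed_q2,
            "p_value": diags.permutation.p_value,
        }

    test_label, control_label = (
        config.simulate.conditions if config.simulate is not None
        else _infer_conditions(table)
    )
    calls = differential_analysis(
        table, sig_ids, threshold=config.effective_threshold,
        floor=config.abundance_floor, test_condition=test_label,
        control_condition=control_label, statistic=config.fc_statistic,
    )
    calls_df = calls_to_frame(calls)

    if evidence is not None and references is not None:
        records = [assign_tier(ev, references) for ev in evidence]
        ann_df = records_to_frame(records)
        calls_df = calls_df.join(ann_df[["tier", "matched_reference"]], how="left")
        _write(ann_df, out / "annotations.tsv", written)
    _write(calls_df, out / "differential_calls.tsv", written)

    n_reg = int(calls_df["regulated"].sum())
    manifest = {
        "longomix_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_manifest(),
        "n_features_input": n_input,
        "n_features_retained": table.n_features,
        "n_significant": len(sig_ids),
        "n_regulated": n_reg,
        "diagnostics": diag_dict,
    }
    mp = out / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    written.append(mp)

    return RunReport(
        out_dir=out, n_features_input=n_input, n_features_retained=table.n_features,
        diagnostics=diag_dict, n_significant=len(sig_ids), n_regulated=n_reg,
        outputs={p.name: str(p) for p in written},
    )


def _infer_conditions(table: FeatureTable) -> tuple[str, str]:
    conds = table.conditions()
    if len(conds) != 2:
        raise ValueError(f"expected two conditions, found {conds}")
    if "test" in conds:
        other = conds[0] if conds[1] == "test" else conds[1]
        return "test", other
    return conds[1], conds[0]  # lexicographically later label treated as test
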