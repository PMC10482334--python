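"""Two-class OPLS-DA with cross-validated Q2 and permutation validation.

The fit splits the predictor matrix into a single predictive latent
component (correlated with class membership) and a sequence of
orthogonal components (systematic variation uncorrelated with class),
using the classic deflation recursion:

    w  = X'y / ||X'y||            predictive weight (unit norm)
    t  = X w;  p = X't / (t't)
    wo = p - (w'p) w, normalized  orthogonal weight
    to = X wo; po = X'to / (to'to)
    X <- X - to po'               remove orthogonal variation, repeat

The final predictive component is fitted on the orthogonal-filtered
matrix. With ``n_ortho=0`` the model is exactly a one-component PLS1
discriminant model.

Class encoding: the positive class maps to +1 and the other to -1
(labels ``test``/``control`` map to +1/-1 by convention). Q2 is
``1 - PRESS / SS(y)`` with class-stratified folds and, when a scaler is
supplied, scaling refit inside each training fold. The permutation test
refits the model under randomly permuted labels and reports
``p = (1 + #{permuted Q2 >= observed Q2}) / (n_perm + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .preprocess import Scaler

__all__ = [
    "OplsModel",
    "ModelDiagnostics",
    "PermutationResult",
    "fit_opls_da",
    "cross_validate_q2",
    "permutation_test",
    "significant_loadings",
]


def _encode_labels(
    y_labels: Sequence, positive_label: str | None = None
) -> tuple[np.ndarray, dict]:
    labels = np.asarray(y_labels)
    uniq = sorted(np.unique(labels).tolist())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two classes, got {uniq}")
    if positive_label is None:
        positive_label = "test" if "test" in uniq else uniq[-1]
    if positive_label not in uniq:
        raise ValueError(f"positive label {positive_label!r} not among {uniq}")
    negative_label = uniq[0] if uniq[1] == positive_label else uniq[1]
    class_map = {positive_label: 1.0, negative_label: -1.0}
    y = np.where(labels == positive_label, 1.0, -1.0)
    counts = [int((y == v).sum()) for v in (1.0, -1.0)]
    if min(counts) < 2:
        raise ValueError("each class needs at least 2 observations")
    return y, class_map


@dataclass
class OplsModel:
    """Fitted OPLS-DA weights, loadings and scores."""

    w: np.ndarray  # predictive weight, unit norm (n_vars,)
    p_pred: np.ndarray  # predictive loading (n_vars,)
    t_pred: np.ndarray  # predictive score (n_obs,)
    W_ortho: np.ndarray  # orthogonal weights, unit-norm columns (n_vars, k)
    P_ortho: np.ndarray  # orthogonal loadings (n_vars, k)
    T_ortho: np.ndarray  # orthogonal scores (n_obs, k)
    b: float  # inner-relation coefficient for centered y
    y_mean: float
    class_map: dict
    scaling_spec: str | None = None
    feature_ids: list | None = None

    @property
    def n_ortho(self) -> int:
        return self.W_ortho.shape[1]

    def correct(self, X: np.ndarray) -> np.ndarray:
        """Remove the fitted orthogonal components from new observations."""
        Xc = np.asarray(X, dtype=float).copy()
        for k in range(self.n_ortho):
            t_o = Xc @ self.W_ortho[:, k]
            Xc -= np.outer(t_o, self.P_ortho[:, k])
        return Xc

    def predict_response(self, X: np.ndarray) -> np.ndarray:
        """Continuous class response for (already scaled) new observations."""
        t = self.correct(X) @ self.w
        return self.b * t + self.y_mean

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        inv = {v: k for k, v in self.class_map.items()}
        resp = self.predict_response(X)
        return np.where(resp >= 0, inv[1.0], inv[-1.0])


@dataclass
class PermutationResult:
    n_perm: int
    observed_r2y: float
    observed_q2: float
    permuted_r2y: list[float]
    permuted_q2: list[float]
    p_value: float


@dataclass
class ModelDiagnostics:
    """Variance decomposition and predictive quality of a fitted model."""

    r2x_pred: float
    r2x_ortho: tuple[float, ...]
    r2x_residual: float
    r2y: float
    q2: float | None = None
    cv_folds: int | None = None
    permutation: PermutationResult | None = None

    @property
    def r2x_ortho_total(self) -> float:
        return float(sum(self.r2x_ortho))


def _fit_core(X0: np.ndarray, yc: np.ndarray, n_ortho: int):
    """Run the deflation recursion; X0 is consumed as a copy."""
    X = np.array(X0, dtype=float, copy=True)
    w = X.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no class-correlated variation (X'y = 0)")
    w = w / nw
    W_o, P_o, T_o = [], [], []
    for _ in range(n_ortho):
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm_o = np.linalg.norm(w_o)
        if norm_o < 1e-12:  # no orthogonal variation left to extract
            break
        w_o = w_o / norm_o
        t_o = X @ w_o
        denom = t_o @ t_o
        if denom < 1e-300:
            break
        p_o = X.T @ t_o / denom
        X -= np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    t = X @ w
    tt = t @ t
    if tt == 0:
        raise ValueError("degenerate predictive score (all zero)")
    p = X.T @ t / tt
    b = (t @ yc) / tt
    n_vars = X0.shape[1]
    n_obs = X0.shape[0]
    stack = lambda vs, n: (np.column_stack(vs) if vs else np.empty((n, 0)))
    return w, p, t, b, stack(W_o, n_vars), stack(P_o, n_vars), stack(T_o, n_obs), X


def fit_opls_da(
    X: np.ndarray,
    y_labels: Sequence,
    n_ortho: int | Literal["auto"] = "auto",
    positive_label: str | None = None,
    cv_folds: int = 7,
    max_ortho: int = 5,
    q2_improvement: float = 0.01,
    scaling_spec: str | None = None,
    feature_ids: Sequence | None = None,
) -> tuple[OplsModel, ModelDiagnostics]:
    """Fit OPLS-DA on an already-scaled matrix ``X`` (observations x variables).

    ``n_ortho="auto"`` adds orthogonal components while the
    cross-validated Q2 improves by more than ``q2_improvement``
    (capped at ``max_ortho``). Variance fractions (R2X split) are
    computed against the total sum of squares of the input matrix and
    sum to one with the residual.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (observations x variables)")
    y, class_map = _encode_labels(y_labels, positive_label)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows and labels length differ")
    ss_x = float(np.sum(X * X))
    if ss_x == 0:
        raise ValueError("X has zero total variance")
    # Q2 inside the fit: clamp fold count to the smallest class so tiny
    # designs stay fittable; cross_validate_q2 itself remains strict.
    n_min = int(min((y == 1).sum(), (y == -1).sum()))
    cv_folds = min(cv_folds, n_min)

    if n_ortho == "auto":
        q2_prev = cross_validate_q2(X, y_labels, 0, folds=cv_folds,
                                    positive_label=positive_label)
        chosen = 0
        for k in range(1, max_ortho + 1):
            q2_k = cross_validate_q2(X, y_labels, k, folds=cv_folds,
                                     positive_label=positive_label)
            if q2_k > q2_prev + q2_improvement:
                chosen, q2_prev = k, q2_k
            else:
                break
        n_ortho = chosen
    elif not (isinstance(n_ortho, (int, np.integer)) and n_ortho >= 0):
        raise ValueError("n_ortho must be a non-negative integer or 'auto'")

    y_mean = float(y.mean())
    yc = y - y_mean
    w, p, t, b, W_o, P_o, T_o, X_filt = _fit_core(X, yc, int(n_ortho))

    model = OplsModel(
        w=w, p_pred=p, t_pred=t, W_ortho=W_o, P_ortho=P_o, T_ortho=T_o,
        b=b, y_mean=y_mean, class_map=class_map, scaling_spec=scaling_spec,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
    )

    r2x_pred = float((t @ t) * (p @ p) / ss_x)
    r2x_ortho = tuple(
        float((T_o[:, k] @ T_o[:, k]) * (P_o[:, k] @ P_o[:, k]) / ss_x)
        for k in range(T_o.shape[1])
    )
    resid = X_filt - np.outer(t, p)
    r2x_residual = float(np.sum(resid * resid) / ss_x)
    y_hat = b * t
    ss_y = float(yc @ yc)
    r2y = float(1.0 - np.sum((yc - y_hat) ** 2) / ss_y)
    q2 = cross_validate_q2(X, y_labels, int(n_ortho), folds=cv_folds,
                           positive_label=positive_label)
    diags = ModelDiagnostics(
        r2x_pred=r2x_pred, r2x_ortho=r2x_ortho, r2x_residual=r2x_residual,
        r2y=r2y, q2=q2, cv_folds=cv_folds,
    )
    return model, diags


def cross_validate_q2(
    X: np.ndarray,
    y_labels: Sequence,
    n_ortho: int,
    folds: int = 7,
    scaler: Scaler | str | None = None,
    positive_label: str | None = None,
) -> float:
    """Cross-validated Q2 = 1 - PRESS/SS(y) with class-stratified folds.

    When ``scaler`` is given (a :class:`~longomix.preprocess.Scaler` or
    one of ``"pareto"``/``"center"``), scaling statistics are re-learned
    on each training fold and applied to the held-out block, avoiding
    leakage; pass ``None`` when ``X`` is already scaled.
    """
    X = np.asarray(X, dtype=float)
    y, _ = _encode_labels(y_labels, positive_label)
    n_min = int(min((y == 1).sum(), (y == -1).sum()))
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if folds > len(y):
        raise ValueError("more folds than observations")
    if folds > n_min:
        raise ValueError(
            f"{folds} folds would leave a training fold without one class "
            f"(smallest class has {n_min} observations)"
        )
    if isinstance(scaler, str):
        scaler = Scaler(mode=scaler)

    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    press = 0.0
    for train, test in skf.split(X, y):
        Xtr, Xte = X[train], X[test]
        if scaler is not None:
            s = scaler.fresh().fit(Xtr)
            Xtr, Xte = s.transform(Xtr), s.transform(Xte)
        ytr = y[train]
        ymean = ytr.mean()
        w, _, _, b, W_o, P_o, _, _ = _fit_core(Xtr, ytr - ymean, n_ortho)
        Xc = Xte.copy()
        for k in range(W_o.shape[1]):
            Xc -= np.outer(Xc @ W_o[:, k], P_o[:, k])
        y_hat = b * (Xc @ w) + ymean
        press += float(np.sum((y[test] - y_hat) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss


def permutation_test(
    X: np.ndarray,
    y_labels: Sequence,
    n_ortho: int,
    n_perm: int = 200,
    seed: int | None = 0,
    folds: int = 7,
    scaler: Scaler | str | None = None,
    positive_label: str | None = None,
) -> PermutationResult:
    """Label-permutation validity test; Q2 anchors the p-value.

    R2Y and Q2 are recomputed for each of ``n_perm`` random label
    permutations; ``p = (1 + #{Q2_perm >= Q2_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(y_labels)
    rng = np.random.default_rng(seed)

    def _r2y(lbls: np.ndarray) -> float:
        y, _ = _encode_labels(lbls, positive_label)
        Xs = X if scaler is None else (
            Scaler(mode=scaler).fit_transform(X) if isinstance(scaler, str)
            else scaler.fresh().fit_transform(X)
        )
        yc = y - y.mean()
        _, _, t, b, *_ = _fit_core(Xs, yc, n_ortho)
        return float(1.0 - np.sum((yc - b * t) ** 2) / (yc @ yc))

    obs_r2y = _r2y(labels)
    obs_q2 = cross_validate_q2(X, labels, n_ortho, folds=folds, scaler=scaler,
                               positive_label=positive_label)
    perm_r2y, perm_q2 = [], []
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        perm_r2y.append(_r2y(perm))
        perm_q2.append(
            cross_validate_q2(X, perm, n_ortho, folds=folds, scaler=scaler,
                              positive_label=positive_label)
        )
    n_ge = int(sum(q >= obs_q2 for q in perm_q2))
    p = (1 + n_ge) / (n_perm + 1)
    return PermutationResult(
        n_perm=n_perm, observed_r2y=obs_r2y, observed_q2=obs_q2,
        permuted_r2y=perm_r2y, permuted_q2=perm_q2, p_value=p,
    )


def significant_loadings(model: OplsModel, feature_ids: Sequence | None = None) -> set:
    """Features whose |predictive loading| exceeds the loading-vector SD.

    The cutoff is the sample standard deviation of the full predictive
    loading vector; comparison is strictly greater-than, so with all
    loadings equal and nonzero (SD = 0) every feature is flagged, and an
    all-zero vector yields the empty set.
    """
    p = np.asarray(model.p_pred, dtype=float)
    sd = float(p.std(ddof=1)) if p.size > 1 else 0.0
    idx = np.nonzero(np.abs(p) > sd)[0]
    ids = feature_ids if feature_ids is not None else model.feature_ids
    if ids is None:
        return set(idx.tolist())
    ids = list(ids)
    if len(ids) != p.size:
        raise ValueError("feature_ids length does not match loading vector")
    return {ids[i] for i in idx}
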