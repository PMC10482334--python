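"""Independent oracles used by unit and acceptance tests.

These are deliberately coded against different primitives than the
package (sklearn PLS, adaptive quadrature, brute-force group-bys) so
they can cross-check the main implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import interp1d
from sklearn.cross_decomposition import PLSRegression


def osc_pls_scores_loadings(X: np.ndarray, y: np.ndarray, n_ortho: int):
    """Orthogonal-signal-correction pass + sklearn 1-component PLS.

    Returns (predictive scores, predictive loadings) of the corrected
    matrix; the final latent step is delegated entirely to sklearn.
    """
    X = np.array(X, dtype=float, copy=True)
    y = np.asarray(y, dtype=float)
    w = X.T @ y
    w = w / np.linalg.norm(w)
    for _ in range(n_ortho):
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        w_o = w_o / np.linalg.norm(w_o)
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
    pls = PLSRegression(n_components=1, scale=False).fit(X, y)
    return pls.x_scores_[:, 0], pls.x_loadings_[:, 0]


def quadrature_auc(days: np.ndarray, means: np.ndarray) -> float:
    """Adaptive-quadrature integral of the piecewise-linear trajectory."""
    f = interp1d(days, means, kind="linear")
    total = 0.0
    for lo, hi in zip(days[:-1], days[1:]):
        val, _ = quad(f, lo, hi, limit=200)
        total += val
    return total


def planted_two_direction_instance(rng: np.random.Generator, n_obs: int, n_vars: int,
                                   noise: float = 0.05):
    """Centered matrix with one class-aligned and one class-orthogonal direction."""
    y = np.concatenate([np.ones(n_obs // 2), -np.ones(n_obs - n_obs // 2)])
    rng.shuffle(y)
    v = rng.normal(size=n_vars)
    v /= np.linalg.norm(v)
    u = rng.normal(size=n_vars)
    u -= (u @ v) * v
    u /= np.linalg.norm(u)
    s = rng.normal(size=n_obs)
    X = np.outer(y, v) + 2.0 * np.outer(s, u) + noise * rng.normal(size=(n_obs, n_vars))
    X -= X.mean(axis=0)
    return X, y


def reference_tier(ppm_ok: bool, rt_ok: bool, has_msms: bool,
                   msms_match_standard: bool, msms_match_library: bool,
                   msms_manual_structure: bool, formula_match: bool,
                   msigma: float | None) -> str:
    """Straight transcription of the tier rules as an if/elif chain."""
    if ppm_ok and rt_ok and msms_match_standard:
        return "1"
    if ppm_ok and rt_ok and not has_msms:
        return "1*"
    if ppm_ok and msms_match_library:
        return "2"
    if ppm_ok and msms_manual_structure:
        return "3"
    if ppm_ok and formula_match and msigma is not None and msigma < 100.0:
        return "4"
    return "5"
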