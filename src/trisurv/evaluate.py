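"""Selection metrics, surrogate-region mapping and the integrated Brier score.

True/false positive rates score a selected set of triangles against the set
truly carrying imaging signal.  When the fitted mesh differs from the
generating mesh, a surrogate truth set on the fitted mesh is defined by
centroid membership in the true signal region.  Predictive accuracy for
interval-censored data is summarized by the integrated Brier score with the
unknown at-risk indicator imputed from the fitted survival curve.
"""

from __future__ import annotations

import warnings

import numpy as np

from .survival import ModelParams, ISplineBasis, SurvivalData, survival_prob
from .triangulation import Triangulation, barycentric_coords


def tp_fp(selected, truth, M: int) -> tuple[float, float]:
    """Per-replicate true/false positive rates.

    TP = |selected & truth| / |truth|; FP = |selected - truth| / (M - |truth|).
    """
    truth = set(truth)
    selected = set(selected)
    if not truth:
        raise ValueError("truth set must be nonempty")
    if not selected <= set(range(M)):
        raise ValueError("selected indices out of range")
    tp = len(selected & truth) / len(truth)
    denom = M - len(truth)
    fp = len(selected - truth) / denom if denom else 0.0
    return tp, fp


def surrogate_truth(true_mesh: Triangulation, true_set, adopted_mesh: Triangulation,
                    tol: float = 1e-9) -> list:
    """Triangles of ``adopted_mesh`` whose centroid falls inside the union of
    the true signal triangles (boundary counts as inside)."""
    out = []
    tv = [true_mesh.triangle_vertices(l) for l in true_set]
    for l, c in enumerate(adopted_mesh.centroids):
        for V in tv:
            if np.all(barycentric_coords(V, c) >= -tol):
                out.append(l)
                break
    return out


def imputed_indicator(L: float, R: float, t: float, S_t: float, S_L: float,
                      S_R: float) -> float:
    """Estimate of I(T > t) for L < t <= R given the fitted survival curve:
    (S(t) - S(R)) / (S(L) - S(R)), with S(inf) = 0 for right-censored
    records.  Outside (L, R] the indicator is known (1 for t <= L, 0 for
    t > R)."""
    if t <= L:
        return 1.0
    if np.isfinite(R) and t > R:
        return 0.0
    denom = S_L - S_R
    if denom <= 1e-12:
        warnings.warn("degenerate survival difference; imputing 0.5")
        return 0.5
    return float(np.clip((S_t - S_R) / denom, 0.0, 1.0))


def ibs(data: SurvivalData, params: ModelParams, basis: ISplineBasis,
        tmax: float | None = None, n_grid: int = 400,
        survival_fn=None) -> float:
    """Integrated Brier score (1/n) sum_i (1/tmax) int_0^tmax
    (I(T_i > t) - S_i(t))^2 dt with the indicator imputed on (L_i, R_i].

    The time integral uses a fine trapezoid rule; values lie in [0, 1].
    ``survival_fn(i, ts)`` overrides the model curve for subject i (used to
    score externally fitted survival functions).
    """
    tmax = basis.tmax if tmax is None else float(tmax)
    ts = np.linspace(0.0, tmax, n_grid + 1)
    total = 0.0
    n = len(data)
    for i in range(n):
        xi_i = None if data.xi is None else data.xi[i]
        if survival_fn is not None:
            curve = lambda t: np.asarray(survival_fn(i, np.atleast_1d(t)))
        else:
            curve = lambda t: np.atleast_1d(survival_prob(
                params, basis, np.minimum(np.atleast_1d(t), tmax),
                data.Z[i], xi_i))
        S = curve(ts)
        L, R = data.L[i], data.R[i]
        S_L = float(curve(min(L, tmax))[0]) if L > 0 else 1.0
        S_R = float(curve(min(R, tmax))[0]) if np.isfinite(R) else 0.0
        ind = np.empty_like(ts)
        for k, t in enumerate(ts):
            if t <= L:
                ind[k] = 1.0
            elif np.isfinite(R) and t > R:
                ind[k] = 0.0
            else:
                ind[k] = imputed_indicator(L, R, t, float(S[k]), S_L, S_R)
        total += np.trapezoid((ind - S) ** 2, ts) / tmax
    return float(total / n)


def cv_folds(data: SurvivalData, n_folds: int = 10, seed: int = 0) -> list:
    """Seeded fold assignment, stratified by censoring class."""
    rng = np.random.default_rng(seed)
    fold = np.zeros(len(data), dtype=int)
    for mask in (data.is_left, data.is_interval, data.is_right):
        idx = np.nonzero(mask)[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return [np.nonzero(fold == f)[0] for f in range(n_folds)]
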