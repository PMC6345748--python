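"""PLS1 region discovery: percentile predictor selection, NIPALS, Q², VIP.

The workflow mirrors exploratory dose-response mapping on cortical field
data: vertices carrying the strongest fields across the cohort are selected
by a percentile rule, the per-subject field values at those vertices form
the predictor matrix X (standardized columns), and a single-response PLS
regression relates X to the mean normalized MEP.  Model quality is measured
by in-sample R² per component and by Q² from Monte-Carlo repeated k-fold
cross-validation; a component is predictively significant when
Q² > 1 − 0.95² = 0.0975 (strict inequality).  Variable importance for the
projection (VIP) ranks vertices; the maximum-VIP vertex is the observation
point r0 for the downstream mixed-effects analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: Predictive-significance threshold for Q²: components must beat a model
#: explaining 1 − 0.95² of the predictive variance.
Q2_SIGNIFICANCE_THRESHOLD = 1.0 - 0.95**2


@dataclass
class PredictorBlock:
    """Standardized predictor matrix over the selected vertices."""

    x: np.ndarray  # (subjects, selected vertices), standardized
    vertex_ids: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    field_type: str  # "e_abs" | "e_n"
    raw: np.ndarray | None = None  # unstandardized values, for CV refits

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]


@dataclass
class PLSModel:
    """Fitted PLS1 decomposition with per-component diagnostics."""

    n_components: int
    weights: np.ndarray  # (p, A), each column unit norm
    scores: np.ndarray  # (n, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    r2: np.ndarray  # cumulative R² per component
    y: np.ndarray
    q2: np.ndarray | None = None
    q2_significant: np.ndarray | None = None
    vip: np.ndarray | None = None


def select_vertices(
    cohort_matrix: np.ndarray,
    field_type: str,
    r_e_percent: float,
    vertex_ids: np.ndarray | None = None,
) -> PredictorBlock:
    """Select the top ``r_e_percent`` % of vertices by cohort-mean field.

    The selection statistic is the vertex-wise cohort mean of ``E_abs`` or of
    ``|E_n|``; vertices at or above the (100 − r_E)th linear-interpolation
    percentile are retained.  X holds the per-subject values at the retained
    vertices (signed E_n, not its absolute value), standardized column-wise
    (sample SD, ddof=1).  Zero-variance columns are dropped with a warning.
    """
    if not (0 < r_e_percent <= 100):
        raise ValueError("r_E must be in (0, 100]")
    X = np.asarray(cohort_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("cohort matrix must be subjects x vertices")
    if field_type not in ("e_abs", "e_n"):
        raise ValueError("field_type must be 'e_abs' or 'e_n'")
    stat = np.abs(X).mean(axis=0) if field_type == "e_n" else X.mean(axis=0)
    if field_type == "e_abs" and np.any(X < 0):
        raise ValueError("E_abs cohort matrix must be non-negative")
    threshold = np.percentile(stat, 100.0 - r_e_percent)
    keep = np.nonzero(stat >= threshold)[0]
    if keep.size == 0:
        raise ValueError("vertex selection is empty")
    ids = (np.asarray(vertex_ids) if vertex_ids is not None else np.arange(X.shape[1]))[keep]

    raw = X[:, keep]
    sds = raw.std(axis=0, ddof=1)
    nonzero = sds > 0
    if not nonzero.all():
        log.warning("dropping %d zero-variance columns", int((~nonzero).sum()))
        raw, ids, sds = raw[:, nonzero], ids[nonzero], sds[nonzero]
        if raw.shape[1] == 0:
            raise ValueError("vertex selection is empty after dropping constants")
    means = raw.mean(axis=0)
    return PredictorBlock(
        x=(raw - means) / sds,
        vertex_ids=ids,
        column_means=means,
        column_sds=sds,
        field_type=field_type,
        raw=raw,
    )


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """Core NIPALS for a single response; X, y must be centred."""
    n, p = X.shape
    W = np.empty((p, n_components))
    T = np.empty((n, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    Xd, yd = X.copy(), y.astype(float).copy()
    tss = float(y @ y)
    r2 = np.empty(n_components)
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * max(1.0, np.linalg.norm(yd)) or nw == 0.0:
            raise ValueError("degenerate weight: response orthogonal to predictors")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt == 0.0:
            raise ValueError("degenerate component: zero scores")
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd -= np.outer(t, p_a)
        yd -= q_a * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
        r2[a] = 1.0 - float(yd @ yd) / tss
    return W, T, P, q, r2


def fit_pls1(block: PredictorBlock, y: np.ndarray, n_components: int = 1) -> PLSModel:
    """Fit PLS1 by NIPALS with X and y deflation.

    ``y`` is centred internally.  With a single predictor column and one
    component the fit coincides with simple least squares on that column.
    """
    X = block.x
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response length mismatch")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")
    yc = np.asarray(y, dtype=float) - float(np.mean(y))
    W, T, P, q, r2 = _nipals_pls1(X, yc, n_components)
    return PLSModel(
        n_components=n_components,
        weights=W,
        scores=T,
        x_loadings=P,
        y_loadings=q,
        r2=r2,
        y=np.asarray(y, dtype=float),
    )


def _pls1_predict(W, P, q, Xnew, a):
    """Prediction (centred scale) using the first ``a`` components."""
    Wa, Pa, qa = W[:, : a + 1], P[:, : a + 1], q[: a + 1]
    B = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
    return Xnew @ B


def cross_validate_q2(
    block: PredictorBlock,
    y: np.ndarray,
    n_components: int,
    folds: int = 10,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo repeated k-fold cross-validated Q² per component.

    Each repetition draws random disjoint folds (sizes differing by at most
    one); centring and scaling of X and centring of y are refit on the
    training folds only.  Per-component PRESS is accumulated over held-out
    subjects and converted to the incremental convention
    ``Q²_a = 1 − PRESS_a / RSS_{a−1}`` (RSS on the full in-sample fit,
    RSS_0 = TSS), then averaged over repetitions.  A component is flagged
    predictively significant when the averaged Q² strictly exceeds 0.0975.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    raw = block.raw if block.raw is not None else block.x
    y = np.asarray(y, dtype=float)
    n = raw.shape[0]
    if n - int(np.ceil(n / folds)) < 2:
        raise ValueError("a fold would leave fewer than 2 training rows")
    rng = np.random.default_rng(seed)

    # reference in-sample residual sums for the incremental denominator
    yc_full = y - y.mean()
    tss = float(yc_full @ yc_full)
    full = fit_pls1(block, y, n_components)
    rss_prev = np.concatenate([[tss], (1.0 - full.r2[:-1]) * tss]) if n_components > 1 else np.array([tss])

    q2_sum = np.zeros(n_components)
    for _ in range(reps):
        perm = rng.permutation(n)
        press = np.zeros(n_components)
        bounds = np.linspace(0, n, folds + 1).astype(int)
        for f in range(folds):
            test = perm[bounds[f] : bounds[f + 1]]
            if test.size == 0:
                continue
            train = np.setdiff1d(perm, test, assume_unique=True)
            Xtr_raw, ytr = raw[train], y[train]
            mu, sd = Xtr_raw.mean(axis=0), Xtr_raw.std(axis=0, ddof=1)
            ok = sd > 0
            sd_safe = np.where(ok, sd, 1.0)
            Xtr = np.where(ok, (Xtr_raw - mu) / sd_safe, 0.0)
            Xte = np.where(ok, (raw[test] - mu) / sd_safe, 0.0)
            ym = ytr.mean()
            W, T, P, q, _ = _nipals_pls1(Xtr, ytr - ym, n_components)
            for a in range(n_components):
                pred = _pls1_predict(W, P, q, Xte, a) + ym
                press[a] += float(np.sum((y[test] - pred) ** 2))
        q2_sum += 1.0 - press / rss_prev
    q2 = q2_sum / reps
    return q2, q2 > Q2_SIGNIFICANCE_THRESHOLD


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance for the projection.

    ``VIP_j = sqrt(p * sum_a SSY_a w_ja² / sum_a SSY_a)`` with
    ``SSY_a = q_a² t_a't_a``; the mean of VIP² over columns is exactly one.
    For one component this reduces to ``sqrt(p) |w_j|``.
    """
    W, T, q = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    ssy = q**2 * np.einsum("ia,ia->a", T, T)
    vip = np.sqrt(p * (W**2 @ ssy) / ssy.sum())
    model.vip = vip
    return vip


def observation_point(
    vip: np.ndarray,
    vertex_ids: np.ndarray | None = None,
) -> int:
    """Vertex id of the maximal VIP; ties broken by the lowest id (logged)."""
    vip = np.asarray(vip)
    ids = np.asarray(vertex_ids) if vertex_ids is not None else np.arange(len(vip))
    best = np.nonzero(vip == vip.max())[0]
    if best.size > 1:
        log.info("VIP tie among vertices %s; returning the lowest id", ids[best].tolist())
        return int(ids[best].min())
    return int(ids[best[0]])


def observation_point_stability(
    cohort_matrix: np.ndarray,
    y: np.ndarray,
    field_type: str,
    r_e_values=(1.0, 2.0, 3.0, 5.0),
    n_components: int = 1,
) -> dict:
    """r0 per selection ratio, and whether one vertex is the global maximum
    across all ratios (the stability check for the observation point)."""
    r0 = {}
    for r_e in r_e_values:
        block = select_vertices(cohort_matrix, field_type, r_e)
        model = fit_pls1(block, y, n_components)
        r0[r_e] = observation_point(vip_scores(model), block.vertex_ids)
    values = set(r0.values())
    return {"r0_by_ratio": r0, "stable": len(values) == 1}
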