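"""MEP dose-response statistics: normalization, outliers, mixed models, power.

Implements the statistical battery of a sham-controlled crossover tDCS
experiment read out by motor evoked potentials (MEPs):

* Baseline normalization -- the mean over post-stimulation time points of
  ``MEP(t) / MEP_base`` per subject and session.
* Iterative two-sided Grubbs outlier screening.
* Gaussian linear mixed-effects models with a per-subject random intercept,
  fitted by maximum likelihood (profiled over the variance ratio), with
  likelihood-ratio tests between nested fixed-effect sets and Wald F-tests
  for contrasts.
* Paired t / Wilcoxon signed-rank comparisons and Pearson / Spearman /
  partial correlations.
* The simple linear regression of mean normalized MEP on the relative field
  strength (E_n − m)/m, and the Fisher-z sample-size rule for a correlation
  test.

The random-intercept model is authored here (profiled ML has a cheap closed
form per variance ratio for this structure); classical two-sample and
correlation tests are delegated to scipy.stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

POST_TIMES = ("t0", "t10", "t20", "t30")
SESSIONS = ("sham", "real")


@dataclass
class MEPDataset:
    """Long-format MEP amplitudes plus per-subject covariates.

    ``data`` columns: subject, session ('sham'|'real'), time
    ('base'|'t0'|'t10'|'t20'|'t30'), amplitude_mv (> 0).
    ``covariates`` is indexed by subject with columns such as ``e_n``,
    ``e_abs`` (V/m at the observation point) and ``rmt``.
    """

    data: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "session", "time", "amplitude_mv"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"data lacks columns: {sorted(missing)}")
        if (self.data["amplitude_mv"] <= 0).any():
            raise ValueError("MEP amplitudes must be positive")
        has_base = self.data[self.data["time"] == "base"].groupby(
            ["subject", "session"]
        ).size()
        pairs = self.data.groupby(["subject", "session"]).size()
        if len(has_base) != len(pairs):
            raise ValueError("every (subject, session) needs a baseline row")

    def save_csv(self, path: str) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_frames(cls, data: pd.DataFrame, covariates: pd.DataFrame) -> "MEPDataset":
        return cls(data=data.copy(), covariates=covariates.copy())


def mean_normalized_mep(dataset: MEPDataset) -> pd.DataFrame:
    """Mean over post-stimulation time points of MEP(t)/MEP_base.

    Returns one row per (subject, session) with columns ``mep_base_mv`` and
    ``mean_norm_mep``.  A missing post time point is an error -- nothing is
    imputed.
    """
    rows = []
    for (subj, sess), g in dataset.data.groupby(["subject", "session"]):
        by_time = g.set_index("time")["amplitude_mv"]
        missing = [t for t in POST_TIMES if t not in by_time.index]
        if missing:
            raise ValueError(f"subject {subj} session {sess}: missing time points {missing}")
        base = float(by_time["base"])
        post = by_time.loc[list(POST_TIMES)].to_numpy(dtype=float)
        rows.append(
            {
                "subject": subj,
                "session": sess,
                "mep_base_mv": base,
                "mean_norm_mep": float(np.mean(post / base)),
            }
        )
    return pd.DataFrame(rows)


def normalized_long(dataset: MEPDataset) -> pd.DataFrame:
    """Per post-time normalized MEP rows, with baseline as a covariate."""
    wide = dataset.data.pivot_table(
        index=["subject", "session"], columns="time", values="amplitude_mv"
    )
    missing = [t for t in ("base",) + POST_TIMES if t not in wide.columns]
    if missing:
        raise ValueError(f"missing time points {missing}")
    recs = []
    for (subj, sess), row in wide.iterrows():
        for t in POST_TIMES:
            recs.append(
                {
                    "subject": subj,
                    "session": sess,
                    "time": t,
                    "norm_mep": row[t] / row["base"],
                    "mep_base_mv": row["base"],
                }
            )
    return pd.DataFrame(recs)


# --------------------------------------------------------------------------
# Grubbs' test
# --------------------------------------------------------------------------


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical value of the maximum studentized deviation."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_outliers(x: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Indices flagged by the iterative two-sided Grubbs test.

    The most extreme point is tested against the t-based critical value;
    if rejected it is removed and the test repeats until no point is flagged
    or fewer than three remain.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs' test needs at least 3 values")
    idx = np.arange(x.size)
    flagged: list[int] = []
    while idx.size >= 3:
        sub = x[idx]
        sd = sub.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance")
        dev = np.abs(sub - sub.mean())
        j = int(np.argmax(dev))
        g = dev[j] / sd
        if g > grubbs_critical_value(idx.size, alpha):
            flagged.append(int(idx[j]))
            idx = np.delete(idx, j)
        else:
            break
    return np.array(sorted(flagged), dtype=int)


# --------------------------------------------------------------------------
# random-intercept linear mixed model by maximum likelihood
# --------------------------------------------------------------------------


@dataclass
class LMEFit:
    """ML fit of ``y = X beta + Z u + e`` with per-group random intercepts."""

    beta: np.ndarray
    term_names: list[str]
    sigma2_intercept: float
    sigma2_residual: float
    loglik: float
    cov_beta: np.ndarray
    n_obs: int
    n_groups: int
    X: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    groups: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.beta) + 2  # fixed effects + two variances

    def fitted(self) -> np.ndarray:
        return self.X @ self.beta

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_beta))
        return pd.DataFrame(
            {"estimate": self.beta, "se": se}, index=self.term_names
        )


class _ProfileStats:
    """Sufficient statistics for the profiled random-intercept likelihood."""

    def __init__(self, y, X, group_idx):
        self.n = len(y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.SX = np.stack([X[rows].sum(axis=0) for rows in group_idx])
        self.Sy = np.array([y[rows].sum() for rows in group_idx])
        self.sizes = np.array([len(rows) for rows in group_idx], dtype=float)


def _profiled_ml(stats_: _ProfileStats, lam):
    """beta-hat, sigma2-hat and log-likelihood at variance ratio ``lam``."""
    c = lam / (1.0 + lam * stats_.sizes)
    XtVX = stats_.XtX - (stats_.SX * c[:, None]).T @ stats_.SX
    XtVy = stats_.Xty - stats_.SX.T @ (c * stats_.Sy)
    yVy = stats_.yty - float(c @ stats_.Sy**2)
    logdet = float(np.log1p(lam * stats_.sizes).sum())
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular fixed-effect design") from err
    q = yVy - 2 * beta @ XtVy + beta @ XtVX @ beta
    sigma2 = max(q / stats_.n, 1e-300)
    loglik = -0.5 * (stats_.n * np.log(2 * np.pi * sigma2) + logdet + stats_.n)
    return beta, sigma2, loglik, XtVX


def fit_lme(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    term_names: list[str] | None = None,
) -> LMEFit:
    """Fit the random-intercept Gaussian model by maximum likelihood.

    The likelihood is profiled over the ratio ``lambda = sigma_b^2 /
    sigma_e^2``: for fixed lambda, GLS gives beta and the residual variance
    in closed form via the per-group Woodbury identity; the scalar profile
    is maximized by a log-grid scan refined with bounded search, including
    the boundary lambda = 0 (which reproduces OLS exactly).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if X.ndim != 2 or len(y) != X.shape[0] or len(groups) != len(y):
        raise ValueError("shape mismatch between y, X and groups")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design (rank-deficient X)")
    labels, inv = np.unique(groups, return_inverse=True)
    group_idx = [np.nonzero(inv == g)[0] for g in range(len(labels))]
    stats_ = _ProfileStats(y, X, group_idx)

    def negloglik(log_lam):
        return -_profiled_ml(stats_, 10.0**log_lam)[2]

    grid = np.linspace(-8, 3, 45)
    vals = [negloglik(t) for t in grid]
    t0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        negloglik, bounds=(t0 - 0.5, t0 + 0.5), method="bounded",
        options={"xatol": 1e-8},
    )
    lam_best = 10.0**res.x
    beta0, s20, ll0, XtVX0 = _profiled_ml(stats_, 0.0)
    beta1, s21, ll1, XtVX1 = _profiled_ml(stats_, lam_best)
    if ll0 >= ll1:  # boundary solution: no between-subject variance
        beta, s2, ll, XtVX, lam = beta0, s20, ll0, XtVX0, 0.0
    else:
        beta, s2, ll, XtVX, lam = beta1, s21, ll1, XtVX1, lam_best
    names = term_names or [f"x{j}" for j in range(X.shape[1])]
    return LMEFit(
        beta=beta,
        term_names=list(names),
        sigma2_intercept=lam * s2,
        sigma2_residual=s2,
        loglik=float(ll),
        cov_beta=s2 * np.linalg.inv(XtVX),
        n_obs=len(y),
        n_groups=len(labels),
        X=X,
        y=y,
        groups=groups,
    )


def likelihood_ratio_test(fit_null: LMEFit, fit_full: LMEFit) -> tuple[float, int, float]:
    """Chi-square LRT between nested ML fits on the same observations."""
    if fit_null.n_obs != fit_full.n_obs:
        raise ValueError("fits use different data")
    if not set(fit_null.term_names) <= set(fit_full.term_names):
        raise ValueError("models are not nested (term names do not nest)")
    df = len(fit_full.beta) - len(fit_null.beta)
    if df < 0:
        raise ValueError("null model has more parameters than the full model")
    chi2 = max(2.0 * (fit_full.loglik - fit_null.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def contrast_ftest(fit: LMEFit, L: np.ndarray) -> tuple[float, int, int, float]:
    """Wald F-test of ``L beta = 0`` with residual-method denominator df."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if L.shape[1] != len(fit.beta):
        raise ValueError("contrast not conformable with fixed effects")
    q = np.linalg.matrix_rank(L)
    if q < L.shape[0]:
        raise ValueError("rank-deficient contrast matrix")
    Lb = L @ fit.beta
    M = L @ fit.cov_beta @ L.T
    F = float(Lb @ np.linalg.solve(M, Lb)) / q
    df2 = fit.n_obs - len(fit.beta)
    return F, q, df2, float(stats.f.sf(F, q, df2))


# --------------------------------------------------------------------------
# design construction for the crossover MEP models
# --------------------------------------------------------------------------


def build_design(
    frame: pd.DataFrame,
    covariate: str | None = None,
    include_baseline: bool = True,
    center: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design for normalized-MEP rows.

    Base terms: intercept, Time (t0 reference), Session (sham = 0), their
    interaction, and optionally the MEP_base block (main effect and
    interactions with Time, Session, Time x Session).  If ``covariate`` names
    a column (for example the field strength at the observation point or the
    RMT), its full 8-term block -- main effect and interactions with Time,
    Session and Time x Session -- is appended.  Continuous covariates are
    mean-centred by default so the intercept stays interpretable.
    """
    t_dummies = {t: (frame["time"] == t).to_numpy(float) for t in POST_TIMES[1:]}
    sess = (frame["session"] == "real").to_numpy(float)
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    for t, d in t_dummies.items():
        cols.append(d)
        names.append(f"time_{t}")
    cols.append(sess)
    names.append("session")
    for t, d in t_dummies.items():
        cols.append(d * sess)
        names.append(f"time_{t}:session")

    def add_block(values, label):
        v = values.to_numpy(float)
        if center:
            v = v - v.mean()
        cols.append(v)
        names.append(label)
        for t, d in t_dummies.items():
            cols.append(v * d)
            names.append(f"{label}:time_{t}")
        cols.append(v * sess)
        names.append(f"{label}:session")
        for t, d in t_dummies.items():
            cols.append(v * d * sess)
            names.append(f"{label}:time_{t}:session")

    if include_baseline:
        add_block(frame["mep_base_mv"], "base")
    if covariate is not None:
        add_block(frame[covariate], covariate)
    return np.column_stack(cols), names


def fit_mep_models(
    dataset: MEPDataset,
    covariate: str = "e_n",
) -> dict:
    """The crossover analysis pair: base model vs base + covariate block.

    Returns both fits and the likelihood-ratio test for whether the
    covariate block (8 terms) improves the model.
    """
    frame = normalized_long(dataset)
    cov = dataset.covariates[covariate]
    frame = frame.merge(cov.rename(covariate), left_on="subject", right_index=True)
    X0, names0 = build_design(frame)
    X1, names1 = build_design(frame, covariate=covariate)
    y = frame["norm_mep"].to_numpy(float)
    g = frame["subject"].to_numpy()
    fit0 = fit_lme(y, X0, g, names0)
    fit1 = fit_lme(y, X1, g, names1)
    chi2, df, p = likelihood_ratio_test(fit0, fit1)
    return {
        "fit_base": fit0,
        "fit_with_covariate": fit1,
        "lrt": {"chi2": chi2, "df": df, "p": p},
        "frame": frame,
    }


# --------------------------------------------------------------------------
# classical tests and correlations
# --------------------------------------------------------------------------


def association(
    x: np.ndarray,
    y: np.ndarray,
    controls: np.ndarray | None = None,
    method: str = "pearson",
) -> tuple[float, float]:
    """Correlation between x and y: Pearson, Spearman, or partial Pearson.

    The partial correlation regresses both variables on the controls (with
    intercept) and correlates the residuals; the p-value uses n - 2 - k
    degrees of freedom for k controls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    if method == "partial":
        if controls is None:
            raise ValueError("partial correlation needs controls")
        Z = np.column_stack([np.ones(len(x)), np.atleast_2d(np.asarray(controls, float).T).T])
        k = Z.shape[1] - 1
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        # a variable fully explained by the controls has no partial association
        if float(rx @ rx) < 1e-24 * float(x @ x) or float(ry @ ry) < 1e-24 * float(y @ y):
            return 0.0, 1.0
        denom = np.sqrt(float(rx @ rx) * float(ry @ ry))
        r = float(rx @ ry) / denom
        df = len(x) - 2 - k
        t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
        return r, float(2 * stats.t.sf(abs(t), df))
    raise ValueError(f"unknown method {method!r}")


def paired_compare(a: np.ndarray, b: np.ndarray) -> dict:
    """Paired t-test and Wilcoxon signed-rank test of two matched samples.

    The Wilcoxon test drops zero differences, uses mid-ranks for ties, exact
    enumeration for n <= 25 without ties, and otherwise the tie-corrected
    normal approximation without continuity correction (Z reported).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.all(a == b):  # identical samples: t degenerates to 0, Wilcoxon undefined
        return {
            "t": 0.0,
            "df": a.size - 1,
            "t_p": 1.0,
            "wilcoxon_error": "all differences are zero",
        }
    t_stat, t_p = stats.ttest_rel(a, b)
    out = {"t": float(t_stat), "df": a.size - 1, "t_p": float(t_p)}

    d = a - b
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("Wilcoxon undefined: all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not has_ties:
        res = stats.wilcoxon(d, mode="exact")
        out.update({"wilcoxon_w": float(res.statistic), "wilcoxon_p": float(res.pvalue), "wilcoxon_method": "exact"})
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        out.update(
            {
                "wilcoxon_w": w_plus,
                "wilcoxon_z": float(z),
                "wilcoxon_p": float(2 * stats.norm.sf(abs(z))),
                "wilcoxon_method": "normal",
            }
        )
    return out


@dataclass
class RegressionSummary:
    """OLS summary of the field -> response law with t-based 95% CIs."""

    intercept: float
    slope: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    pearson_r: float
    p_value: float
    residuals: np.ndarray
    e_n_mean: float  # the scaling constant m (V/m)

    def predict(self, e_n: np.ndarray) -> np.ndarray:
        x = (np.asarray(e_n, float) - self.e_n_mean) / self.e_n_mean
        return self.intercept + self.slope * x


def simple_regression(e_n: np.ndarray, y: np.ndarray) -> RegressionSummary:
    """OLS of the response on the relative field strength (E_n − m)/m.

    ``m`` is the sample mean of ``e_n``; the slope is therefore the response
    change per 100% relative change in field strength.
    """
    e_n = np.asarray(e_n, dtype=float)
    y = np.asarray(y, dtype=float)
    if e_n.size != y.size or e_n.size < 3:
        raise ValueError("need matched samples of size >= 3")
    m = float(e_n.mean())
    if m == 0:
        raise ValueError("mean field strength is zero")
    x = (e_n - m) / m
    sx = x.std(ddof=1)
    if sx == 0:
        raise ValueError("zero variance in the field values")
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - 2
    s2 = float(resid @ resid) / df
    cov = s2 * np.linalg.inv(X.T @ X)
    tcrit = stats.t.ppf(0.975, df)
    se = np.sqrt(np.diag(cov))
    r, p = stats.pearsonr(x, y)
    return RegressionSummary(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        intercept_ci=(float(beta[0] - tcrit * se[0]), float(beta[0] + tcrit * se[0])),
        slope_ci=(float(beta[1] - tcrit * se[1]), float(beta[1] + tcrit * se[1])),
        pearson_r=float(r),
        p_value=float(p),
        residuals=resid,
        e_n_mean=m,
    )


def required_sample_size(r_squared: float, power: float = 0.80, alpha: float = 0.05) -> int:
    """Minimal n for a two-sided correlation test by the Fisher-z rule.

    ``n = ceil(((z_{1-alpha/2} + z_power) / atanh(sqrt(r_squared)))^2 + 3)``.
    """
    if not (0 < r_squared < 1):
        raise ValueError("r_squared must be in (0, 1)")
    if not (0 < power < 1) or not (0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    c = np.arctanh(np.sqrt(r_squared))
    return int(np.ceil(((z_a + z_b) / c) ** 2 + 3))
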