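"""Three-level random-effects meta-analysis of debt ratios.

Debt ratios are clustered: several outcome measures come from the same
primary study. The model for effect i in study j is

    y_ij = x_ij' beta + u_j + w_ij + e_ij

with u_j ~ N(0, tau2_study) shared within a study (between-study
heterogeneity), w_ij ~ N(0, tau2_effect) per effect (within-study
heterogeneity), and e_ij ~ N(0, v_ij) the known sampling error. The two
variance components are estimated by restricted maximum likelihood (REML)
under non-negativity constraints; beta by generalized least squares at the
estimates, with Wald 95% confidence intervals.

Most primary studies do not report sampling variances; missing v_ij are
imputed as the arithmetic mean of the observed variances within the same
recovery metric. Heterogeneity on the variance-reporting subset is
summarized with the Q-based I^2 index. Categorical moderators are tested
with the omnibus Q_M Wald chi-square, and per-category means come from a
no-intercept (cell-means) fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .debt import mann_whitney_p

_Z975 = stats.norm.ppf(0.975)


def impute_variances(
    rows: pd.DataFrame,
    group_col: str = "metric",
    variance_col: str = "variance",
) -> pd.DataFrame:
    """Fill missing sampling variances with the group mean of observed ones.

    Returns a copy of ``rows`` with ``variance`` completed and an ``imputed``
    boolean column; observed values are untouched. A group with no observed
    variance at all cannot be imputed and raises a ValueError naming it.
    """
    out = rows.copy()
    v = pd.to_numeric(out[variance_col], errors="coerce")
    imputed = v.isna()
    for g, idx in out.groupby(group_col, observed=True).groups.items():
        obs = v.loc[idx].dropna()
        if obs.empty:
            raise ValueError(f"impute_variances: group {g!r} has no observed variances")
        v.loc[idx] = v.loc[idx].fillna(obs.mean())
    out[variance_col] = v
    out["imputed"] = imputed
    return out


def i_squared(effects: Sequence[float], variances: Sequence[float]) -> float:
    """Higgins' I^2 (percent) from Cochran's Q on observed-variance effects.

    Q = sum w_i (y_i - ybar_w)^2 with w_i = 1/v_i; I^2 = max(0, (Q-(k-1))/Q)*100.
    The share of total variation across effects attributable to heterogeneity
    rather than sampling error.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.size < 2:
        raise ValueError("i_squared: need at least 2 effects")
    if np.any(v <= 0):
        raise ValueError("i_squared: variances must be > 0")
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - ybar) ** 2))
    if q == 0.0:
        return 0.0
    k = y.size
    return max(0.0, (q - (k - 1)) / q) * 100.0


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


class _REMLData:
    """Rows sorted by study, with block boundaries, for fast REML evaluation."""

    def __init__(self, y: np.ndarray, v: np.ndarray, X: np.ndarray, study: np.ndarray):
        order = np.argsort(study, kind="stable")
        self.y = y[order]
        self.v = v[order]
        self.X = X[order]
        s = study[order]
        self.starts = np.concatenate([[0], np.flatnonzero(s[1:] != s[:-1]) + 1])
        self.group = np.repeat(
            np.arange(self.starts.size), np.diff(np.concatenate([self.starts, [s.size]]))
        )
        self.n, self.p = self.X.shape
        self.n_studies = self.starts.size
        # constant term matching the usual REML log-likelihood convention
        self.logdet_xtx = float(np.linalg.slogdet(self.X.T @ self.X)[1])


def _reml_core(dat: _REMLData, tau2_study: float, tau2_effect: float):
    """Restricted log-likelihood and the GLS solve at (tau2_study, tau2_effect).

    The marginal covariance is block diagonal by study:
    V_j = diag(v + tau2_effect) + tau2_study * 1 1'. Each block is inverted
    with the rank-one Woodbury identity, so evaluation is O(n).
    """
    d = 1.0 / (dat.v + tau2_effect)  # diagonal of the block-free inverse
    S = np.add.reduceat(d, dat.starts)  # per-study sum of d
    denom = 1.0 + tau2_study * S

    A = np.concatenate([dat.X, dat.y[:, None]], axis=1)  # solve for X and y at once
    DA = d[:, None] * A
    G = np.add.reduceat(DA, dat.starts, axis=0)
    ViA = DA - (tau2_study * d / denom[dat.group])[:, None] * G[dat.group]
    ViX, Viy = ViA[:, :-1], ViA[:, -1]

    XtViX = dat.X.T @ ViX
    XtViy = dat.X.T @ Viy
    ytViy = float(dat.y @ Viy)
    try:
        cF = np.linalg.cholesky(XtViX)
    except np.linalg.LinAlgError:
        return None
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - float(XtViy @ beta)
    logdetV = float(np.sum(np.log(dat.v + tau2_effect)) + np.sum(np.log(denom)))
    logdetF = 2.0 * float(np.sum(np.log(np.diag(cF))))
    ll = (
        -0.5 * (logdetV + logdetF + quad)
        - 0.5 * (dat.n - dat.p) * np.log(2 * np.pi)
        + 0.5 * dat.logdet_xtx
    )
    return ll, beta, XtViX


def reml_loglik(
    y: np.ndarray,
    v: np.ndarray,
    X: np.ndarray,
    study: np.ndarray,
    tau2_study: float,
    tau2_effect: float,
) -> float:
    """Restricted log-likelihood of the three-level model at given components."""
    res = _reml_core(_REMLData(np.asarray(y, float), np.asarray(v, float),
                               np.atleast_2d(np.asarray(X, float)), np.asarray(study)),
                     tau2_study, tau2_effect)
    if res is None:
        return -np.inf
    return res[0]


def _optimize_reml(dat: _REMLData, fix_study: Optional[float], fix_effect: Optional[float]):
    """Maximize the restricted likelihood over the free variance components.

    Natural-scale parameterization with L-BFGS-B box constraints [0, ub] and
    five deterministic starting points spread around a moment estimate of the
    total heterogeneity, so boundary solutions (components exactly 0) are
    reachable and spurious local optima on flat ridges are avoided.
    """
    free = [fix_study is None, fix_effect is None]

    def unpack(theta):
        it = iter(theta)
        ts = next(it) if free[0] else fix_study
        te = next(it) if free[1] else fix_effect
        return ts, te

    def nll(theta):
        if np.any(np.asarray(theta) < 0.0):
            return np.inf
        res = _reml_core(dat, *unpack(theta))
        if res is None or not np.isfinite(res[0]):
            return np.inf
        return -res[0]

    if not any(free):
        return fix_study, fix_effect, -nll([])

    t0 = max(float(np.var(dat.y)) - float(np.mean(dat.v)), 1e-2)
    ub = max(1e3, 100.0 * float(np.var(dat.y)) + 10.0 * float(np.mean(dat.v)))
    starts2 = [(0.5 * t0, 0.5 * t0), (t0, 0.01 * t0), (0.01 * t0, t0), (1e-4, 1e-4), (2 * t0, 2 * t0)]
    starts = [[c for c, f in zip(s, free) if f] for s in starts2]
    # dedupe (when only one component is free, projections coincide)
    uniq = []
    for s in starts:
        if s not in uniq:
            uniq.append(s)

    best = None
    for x0 in uniq:
        res = optimize.minimize(
            nll,
            np.asarray(x0, float),
            method="L-BFGS-B",
            bounds=[(0.0, ub)] * len(x0),
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML optimization failed to produce a finite objective")
    # derivative-free polish: the finite-difference quasi-Newton step size
    # limits accuracy near the optimum
    polish = optimize.minimize(
        nll,
        best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 2000},
    )
    if polish.fun <= best.fun:
        best = polish
    theta = np.clip(np.asarray(best.x), 0.0, ub)
    theta = np.where(theta < 1e-10, 0.0, theta)
    ts, te = unpack(theta)
    return float(ts), float(te), -float(nll(theta))


@dataclass
class MetaFit:
    """Result of a (possibly moderated) three-level random-effects fit."""

    mu: float
    se: float
    ci_low: float
    ci_high: float
    tau2_study: float
    tau2_effect: float
    k: int
    n_studies: int
    loglik_reml: float
    moderator: Optional[str] = None
    intercept: bool = True
    beta: Optional[np.ndarray] = None
    cov_beta: Optional[np.ndarray] = None
    coef_names: Optional[list[str]] = None
    q_m: Optional[float] = None
    q_m_df: Optional[int] = None
    q_m_p: Optional[float] = None
    category_estimates: Optional[pd.DataFrame] = None


class ThreeLevelMetaAnalysis:
    """scikit-learn-style estimator for the three-level random-effects model.

    Parameters
    ----------
    moderator : str, optional
        Column of the effect table holding a categorical moderator. None
        fits the intercept-only (pooled mean) model.
    intercept : bool
        With a moderator: True gives a reference-coded fit (used for the
        Q_M omnibus test), False a cell-means fit (per-category estimates).
    fix_tau2_study, fix_tau2_effect : float, optional
        Pin a variance component instead of estimating it (e.g. 0 to reduce
        the model to a conventional two-level random-effects meta-analysis).

    Attributes (after ``fit``)
    --------------------------
    mu_, se_, ci_low_, ci_high_ : pooled mean and Wald 95% CI (intercept fits)
    tau2_study_, tau2_effect_ : estimated variance components
    loglik_reml_ : restricted log-likelihood at the estimates
    q_m_, q_m_df_, q_m_p_ : omnibus moderator test (moderator fits)
    category_estimates_ : per-category table (cell-means fits)
    """

    def __init__(
        self,
        moderator: Optional[str] = None,
        intercept: bool = True,
        fix_tau2_study: Optional[float] = None,
        fix_tau2_effect: Optional[float] = None,
    ):
        self.moderator = moderator
        self.intercept = intercept
        self.fix_tau2_study = fix_tau2_study
        self.fix_tau2_effect = fix_tau2_effect

    def get_params(self, deep: bool = True) -> dict:
        return {
            "moderator": self.moderator,
            "intercept": self.intercept,
            "fix_tau2_study": self.fix_tau2_study,
            "fix_tau2_effect": self.fix_tau2_effect,
        }

    def set_params(self, **params) -> "ThreeLevelMetaAnalysis":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _design(self, rows: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        n = len(rows)
        if self.moderator is None:
            return np.ones((n, 1)), ["intercept"]
        labels = rows[self.moderator].astype(str).to_numpy()
        cats = sorted(pd.unique(labels))
        counts = pd.Series(labels).value_counts()
        small = [c for c in cats if counts[c] < 2]
        if small:
            raise ValueError(
                f"moderator {self.moderator!r}: categories with < 2 effects: {small}"
            )
        if self.intercept:
            if len(cats) < 2:
                raise ValueError(
                    f"moderator {self.moderator!r}: need >= 2 categories, got {cats}"
                )
            X = np.ones((n, len(cats)))
            for j, c in enumerate(cats[1:], start=1):
                X[:, j] = (labels == c).astype(float)
            return X, ["intercept"] + [str(c) for c in cats[1:]]
        X = np.zeros((n, len(cats)))
        for j, c in enumerate(cats):
            X[:, j] = (labels == c).astype(float)
        return X, [str(c) for c in cats]

    def fit(
        self,
        rows: pd.DataFrame,
        effect_col: str = "effect",
        variance_col: str = "variance",
        study_col: str = "study_id",
    ) -> "ThreeLevelMetaAnalysis":
        y = pd.to_numeric(rows[effect_col]).to_numpy(dtype=float)
        v = pd.to_numeric(rows[variance_col]).to_numpy(dtype=float)
        if y.size == 0:
            raise ValueError("fit: empty effect table")
        if np.any(~np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("fit: every row needs a finite variance > 0 (impute first)")
        study = rows[study_col].astype(str).to_numpy()
        X, names = self._design(rows)
        dat = _REMLData(y, v, X, study)

        if dat.n <= dat.p:
            # saturated design: no residual information, components pinned at 0
            ts = self.fix_tau2_study or 0.0
            te = self.fix_tau2_effect or 0.0
            res = _reml_core(dat, ts, te)
            if res is None:
                raise ValueError("fit: singular design")
            ll = res[0]
        else:
            ts, te, ll = _optimize_reml(dat, self.fix_tau2_study, self.fix_tau2_effect)
            res = _reml_core(dat, ts, te)
            if res is None:
                raise RuntimeError("fit: singular GLS system at the REML estimates")
        _, beta, XtViX = res
        cov = np.linalg.inv(XtViX)

        self.tau2_study_, self.tau2_effect_ = float(ts), float(te)
        self.loglik_reml_ = float(ll)
        self.beta_ = beta
        self.cov_beta_ = cov
        self.coef_names_ = names
        self.k_ = int(dat.n)
        self.n_studies_ = int(dat.n_studies)
        self._rows = rows
        self._cols = (effect_col, variance_col, study_col)

        se = np.sqrt(np.diag(cov))
        if self.moderator is None:
            self.mu_ = float(beta[0])
            self.se_ = float(se[0])
        else:
            self.mu_ = float("nan")
            self.se_ = float("nan")
        self.ci_low_ = self.mu_ - _Z975 * self.se_
        self.ci_high_ = self.mu_ + _Z975 * self.se_

        self.q_m_ = self.q_m_df_ = self.q_m_p_ = None
        self.category_estimates_ = None
        if self.moderator is not None:
            idx = slice(1, None) if self.intercept else slice(None)
            b = beta[idx]
            C = cov[idx, idx]
            self.q_m_ = float(b @ np.linalg.solve(C, b))
            self.q_m_df_ = int(b.size)
            self.q_m_p_ = float(stats.chi2.sf(self.q_m_, self.q_m_df_))
            if not self.intercept:
                labels = rows[self.moderator].astype(str)
                ks = labels.value_counts()
                nstud = rows.groupby(labels)[study_col].nunique()
                self.category_estimates_ = pd.DataFrame(
                    {
                        "label": names,
                        "mean": beta,
                        "ci_low": beta - _Z975 * se,
                        "ci_high": beta + _Z975 * se,
                        "k": [int(ks[c]) for c in names],
                        "n_studies": [int(nstud[c]) for c in names],
                    }
                )
        return self

    def to_result(self) -> MetaFit:
        return MetaFit(
            mu=self.mu_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            tau2_study=self.tau2_study_,
            tau2_effect=self.tau2_effect_,
            k=self.k_,
            n_studies=self.n_studies_,
            loglik_reml=self.loglik_reml_,
            moderator=self.moderator,
            intercept=self.intercept,
            beta=self.beta_,
            cov_beta=self.cov_beta_,
            coef_names=self.coef_names_,
            q_m=self.q_m_,
            q_m_df=self.q_m_df_,
            q_m_p=self.q_m_p_,
            category_estimates=self.category_estimates_,
        )


def fit_three_level(
    rows: pd.DataFrame,
    moderator: Optional[str] = None,
    intercept: bool = True,
    **kwargs,
) -> MetaFit:
    """Fit the three-level model and return a :class:`MetaFit` summary."""
    est = ThreeLevelMetaAnalysis(moderator=moderator, intercept=intercept, **kwargs)
    est.fit(rows)
    return est.to_result()


def omnibus_test(fit: MetaFit) -> tuple[float, int, float]:
    """Q_M omnibus moderator test (Wald chi-square on moderator coefficients)."""
    if fit.moderator is None or fit.q_m is None:
        raise ValueError("omnibus_test: fit has no moderator")
    return fit.q_m, fit.q_m_df, fit.q_m_p


def category_estimates(fit: MetaFit) -> pd.DataFrame:
    """Per-category means and CIs from a no-intercept (cell-means) fit."""
    if fit.intercept or fit.category_estimates is None:
        raise ValueError("category_estimates: requires a no-intercept moderator fit")
    return fit.category_estimates


@dataclass
class SubcategoryComparison:
    """Per-subcategory pooled fits plus a rank-sum test on raw debt ratios."""

    labels: tuple[str, str]
    fits: dict
    p_value: float
    n: dict


def compare_subcategories(
    rows: pd.DataFrame,
    split: tuple[str, str],
    submetric_col: str = "submetric",
    effect_col: str = "effect",
) -> SubcategoryComparison:
    """Compare two submetric groups (e.g. richness vs diversity indexes).

    Fits a no-moderator three-level model to each side and runs a two-sided
    Mann-Whitney rank-sum test on the raw debt ratios; skewed sample sizes
    between subcategories make Wald contrasts unreliable, hence the rank
    test.
    """
    fits, n = {}, {}
    sides = []
    for lab in split:
        sub = rows[rows[submetric_col] == lab]
        if len(sub) < 2:
            raise ValueError(f"compare_subcategories: {lab!r} has {len(sub)} effects (< 2)")
        fits[lab] = fit_three_level(sub)
        n[lab] = len(sub)
        sides.append(pd.to_numeric(sub[effect_col]).to_numpy(dtype=float))
    p = mann_whitney_p(sides[0], sides[1])
    return SubcategoryComparison(labels=tuple(split), fits=fits, p_value=p, n=n)
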