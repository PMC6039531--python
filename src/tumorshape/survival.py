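"""Cox survival modeling: screening, elastic net, risk groups, validation.

The prognostic workflow mirrors standard practice in survival-based image
biomarker studies:

1. each of the 22 shape features, on its reporting scale, is screened with
   a univariate Cox proportional-hazards model; features with two-sided
   Wald p <= 0.05 pass;
2. the selected features enter a Cox model with an elastic-net penalty,
   with the penalty strength chosen by 10-fold cross-validated
   partial-likelihood deviance;
3. the linear predictor of the fitted model is each patient's risk score;
   a cohort is dichotomized at its median score, and the resulting groups
   are compared by Kaplan-Meier curves and a log-rank test, plus a
   multivariate Cox model adjusting for age, sex, smoking, and stage.

The unpenalized fitter is a Newton-Raphson maximizer of the partial
likelihood with Efron (default) or Breslow tie handling and standard
errors from the inverse observed information.  The penalized fitter is a
glmnet-style cyclic coordinate descent over a warm-started, decreasing
lambda path with Breslow ties, on the objective

    -(1/n) loglik(beta) + lambda * (alpha ||beta||_1 + (1-alpha)/2 ||beta||_2^2)

(the 1/n convention of glmnet, so lambda values interoperate with the R
ecosystem).  Features are standardized internally; coefficients are
returned on the original scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_SCALES

__all__ = [
    "CoxFitResult",
    "CoxnetModel",
    "RiskAssignment",
    "cox_fit",
    "univariate_screen",
    "coxnet_fit",
    "cv_select_lambda",
    "risk_assign",
    "km_curve",
    "logrank",
    "multivariate_cox",
]


# ---------------------------------------------------------------------------
# partial likelihood machinery


def _sort_by_time(X, time, event):
    order = np.argsort(time, kind="stable")
    return X[order], time[order], event[order], order


def _partial_loglik_derivs(X, time, event, beta, ties="efron"):
    """Partial log-likelihood, gradient, and Hessian (w.r.t. beta).

    Expects inputs sorted by ascending time.  Tied event times share one
    risk set; Efron's correction progressively discounts the tied deaths,
    Breslow's does not.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # guard overflow; partial likelihood is shift-invariant
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    rw = np.cumsum(w[::-1])[::-1]
    rwx = np.cumsum(wx[::-1], axis=0)[::-1]
    rwxx = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    g = np.zeros(p)
    H = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        D = np.arange(i, j)[event[i:j] > 0]
        d = len(D)
        if d:
            R, Rx, Rxx = rw[i], rwx[i], rwxx[i]
            ll += eta[D].sum()
            g += X[D].sum(axis=0)
            if ties == "breslow":
                ll -= d * np.log(R)
                g -= d * Rx / R
                H -= d * (Rxx / R - np.outer(Rx, Rx) / R**2)
            else:  # efron
                sD = w[D].sum()
                sDx = wx[D].sum(axis=0)
                sDxx = wxx[D].sum(axis=0)
                for l in range(d):
                    f = l / d
                    Rl = R - f * sD
                    Rlx = Rx - f * sDx
                    Rlxx = Rxx - f * sDxx
                    ll -= np.log(Rl)
                    g -= Rlx / Rl
                    H -= Rlxx / Rl - np.outer(Rlx, Rlx) / Rl**2
        i = j
    return ll, g, H


def partial_loglik(X, time, event, beta, ties="efron") -> float:
    """Cox partial log-likelihood at a fixed coefficient vector."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    Xs, ts, es, _ = _sort_by_time(X, np.asarray(time, float),
                                  np.asarray(event, int))
    return _partial_loglik_derivs(Xs, ts, es, np.asarray(beta, float), ties)[0]


@dataclass
class CoxFitResult:
    """Result of an (unpenalized) Cox proportional-hazards fit."""

    names: list
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties: str
    converged: bool
    n_iter: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def ci(self) -> np.ndarray:
        """95% confidence intervals for the hazard ratios, (p, 2)."""
        with np.errstate(over="ignore"):
            lo = np.exp(self.beta - 1.96 * self.se)
            hi = np.exp(self.beta + 1.96 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p(self) -> np.ndarray:
        """Two-sided Wald p-values."""
        z = self.beta / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def summary(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "hr": self.hr,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.p,
            },
            index=pd.Index(self.names, name="covariate"),
        )


def _validate_survival(X, time, event):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(np.asarray(time)):
        X = X.T
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("survival times must be > 0")
    if event.sum() == 0:
        raise ValueError("no events in the data")
    return X, time, event


def cox_fit(X, time, event, ties: str = "efron", names=None,
            max_iter: int = 50, tol: float = 1e-8) -> CoxFitResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Maximizes the partial likelihood with the chosen tie correction,
    stopping when the largest coefficient step falls below ``tol`` (or
    after ``max_iter`` Newton iterations, in which case ``converged`` is
    False).  Standard errors come from the inverse observed information.
    A monotone likelihood (coefficients running away, as with a perfectly
    separating covariate) is flagged as non-converged rather than raised.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    X, time, event = _validate_survival(X, time, event)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {names[j]!r} is constant")
    Xs, ts, es, _ = _sort_by_time(X, time, event)

    beta = np.zeros(p)
    converged = False
    it = 0
    ll = -np.inf
    for it in range(1, max_iter + 1):
        ll, g, H = _partial_loglik_derivs(Xs, ts, es, beta, ties)
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError:
            break
        # step halving keeps the likelihood non-decreasing
        scale = 1.0
        while scale > 1e-10:
            cand = beta + scale * step
            if _partial_loglik_derivs(Xs, ts, es, cand, ties)[0] >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    # a monotone likelihood (perfect separation) never meets the step
    # tolerance: the coefficient keeps drifting, so converged stays False
    ll, g, H = _partial_loglik_derivs(Xs, ts, es, beta, ties)
    with np.errstate(all="ignore"):
        try:
            cov = np.linalg.inv(-H)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
    # monotone likelihood (perfect separation): the information collapses
    # and standard errors explode relative to the coefficients
    if converged and (
        not np.isfinite(se).all()
        or np.any(se > 1e3 * (1.0 + np.abs(beta)))
    ):
        converged = False
    if not converged:
        warnings.warn("Cox fit did not converge; estimates are flagged",
                      stacklevel=2)
    return CoxFitResult(
        names=list(names), beta=beta, se=se, loglik=float(ll), n=n,
        n_events=int(event.sum()), ties=ties, converged=converged, n_iter=it,
    )


# ---------------------------------------------------------------------------
# univariate screening


def univariate_screen(features: pd.DataFrame, time, event,
                      alpha: float = 0.05, scales: dict | None = None):
    """Screen each feature with a univariate Cox model.

    Each column is first divided by its reporting scale (defaults to the
    canonical per-1000 / per-100 / per-0.10 units), fitted alone, and
    selected iff its two-sided Wald p-value is at or below ``alpha``
    (inclusive).  Constant columns are excluded with a warning.  Returns
    ``(table, selected)``: a per-feature summary DataFrame and the list of
    selected feature names.
    """
    if scales is None:
        scales = FEATURE_SCALES
    rows = []
    selected = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        if np.ptp(x[np.isfinite(x)]) == 0 or not np.isfinite(x).all():
            warnings.warn(f"feature {col!r} is constant or non-finite; "
                          "excluded from screening", stacklevel=2)
            rows.append({"feature": col, "beta": np.nan, "hr": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "selected": False})
            continue
        xs = x / scales.get(col, 1.0)
        fit = cox_fit(xs[:, None], time, event, names=[col])
        pval = float(fit.p[0])
        sel = bool(pval <= alpha) and fit.converged
        if sel:
            selected.append(col)
        ci = fit.ci
        rows.append({"feature": col, "beta": float(fit.beta[0]),
                     "hr": float(fit.hr[0]), "ci_low": float(ci[0, 0]),
                     "ci_high": float(ci[0, 1]), "p": pval, "selected": sel})
    return pd.DataFrame(rows).set_index("feature"), selected


# ---------------------------------------------------------------------------
# elastic-net Cox (glmnet-style coordinate descent, Breslow ties)


def _risk_groups(time):
    """Start index and size of each tied-time group (time sorted ascending)."""
    n = len(time)
    starts = np.flatnonzero(np.r_[True, np.diff(time) != 0])
    counts = np.diff(np.r_[starts, n])
    return starts, counts


def _eta_derivs_breslow(eta, time, event):
    """Gradient and Hessian diagonal of the Breslow partial log-likelihood
    with respect to the linear predictor eta (inputs sorted by time)."""
    shift = eta.max()
    w = np.exp(eta - shift)
    rw = np.cumsum(w[::-1])[::-1]
    starts, counts = _risk_groups(time)
    d = np.add.reduceat(event.astype(float), starts)
    W = rw[starts]
    with np.errstate(divide="ignore"):
        ll = float(
            (eta[event > 0] - shift).sum() - (d * np.log(W))[d > 0].sum()
        )
    Acum = np.repeat(np.cumsum(d / W), counts)
    Bcum = np.repeat(np.cumsum(d / W**2), counts)
    g = event - w * Acum
    h = np.maximum(w * Acum - w**2 * Bcum, 1e-12)
    return ll, g, h


def _breslow_loglik_eta(eta, time, event):
    """Breslow partial log-likelihood only (inputs sorted by time)."""
    shift = eta.max()
    w = np.exp(eta - shift)
    rw = np.cumsum(w[::-1])[::-1]
    starts, counts = _risk_groups(time)
    d = np.add.reduceat(event.astype(float), starts)
    W = rw[starts]
    return float(
        (eta[event > 0] - shift).sum() - (d * np.log(W))[d > 0].sum()
    )


@dataclass
class CoxnetModel:
    """Elastic-net Cox model with its lambda path.

    ``beta`` (original scale) corresponds to ``lam``; ``path_coefs`` holds
    the original-scale coefficients for every lambda on ``path_lambdas``.
    ``cv_mean``/``cv_se`` are filled by cross-validation when used.
    """

    feature_names: list
    beta: np.ndarray
    lam: float
    alpha_mix: float
    path_lambdas: np.ndarray
    path_coefs: np.ndarray  # (n_lambdas, p), original scale
    center: np.ndarray
    scale: np.ndarray
    cv_mean: np.ndarray | None = None
    cv_se: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def predict_score(self, X) -> np.ndarray:
        """Linear predictor x' beta on the original feature scale."""
        X = np.asarray(X, dtype=float)
        return X @ self.beta

    def to_json_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "beta": self.beta.tolist(),
            "lambda": float(self.lam),
            "alpha_mix": float(self.alpha_mix),
            "path_lambdas": self.path_lambdas.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "extras": self.extras,
        }


def _lambda_max(Xs, time, event, alpha_mix):
    _, g0, _ = _eta_derivs_breslow(np.zeros(len(time)), time, event)
    denom = max(alpha_mix, 1e-3)  # glmnet's convention when alpha ~ 0
    return float(np.max(np.abs(Xs.T @ g0)) / (len(time) * denom))


@numba.njit(cache=False)
def _cd_quad_solve(G, c, diag, beta, l1, l2, tol, max_cycles):  # pragma: no cover
    """Solve the penalized quadratic subproblem by cyclic coordinate descent.

    Minimizes (1/2) beta' G beta - c' beta + l1 ||beta||_1 + (l2/2)||beta||^2
    in place: full sweeps alternate with sweeps over the active (nonzero)
    set until the largest coefficient change of a full sweep is below tol.
    """
    p = beta.size
    cycles = 0
    while cycles < max_cycles:
        # full sweep
        maxd = 0.0
        for j in range(p):
            bj = beta[j]
            rho = c[j] + diag[j] * bj
            for k in range(p):
                rho -= G[j, k] * beta[k]
            anew = abs(rho) - l1
            bnew = (anew / (diag[j] + l2)) * np.sign(rho) if anew > 0 else 0.0
            if bnew != bj:
                beta[j] = bnew
                if abs(bnew - bj) > maxd:
                    maxd = abs(bnew - bj)
        cycles += 1
        if maxd < tol:
            return cycles
        # active-set sweeps
        while cycles < max_cycles:
            maxd = 0.0
            for j in range(p):
                bj = beta[j]
                if bj == 0.0:
                    continue
                rho = c[j] + diag[j] * bj
                for k in range(p):
                    rho -= G[j, k] * beta[k]
                anew = abs(rho) - l1
                bnew = (anew / (diag[j] + l2)) * np.sign(rho) if anew > 0 else 0.0
                if bnew != bj:
                    beta[j] = bnew
                    if abs(bnew - bj) > maxd:
                        maxd = abs(bnew - bj)
            cycles += 1
            if maxd < tol:
                break
    return cycles


def _cd_solve(Xs, time, event, lam, alpha_mix, beta0, n,
              tol=1e-8, max_outer=50, max_inner=100_000):
    """One elastic-net Cox solution by IRLS + cyclic coordinate descent.

    Each outer pass takes the quadratic (working-response) approximation of
    the Breslow partial log-likelihood at the current coefficients; the
    compiled inner loop solves it by covariance-updating coordinate descent.
    """
    beta = beta0.copy()
    l1 = lam * alpha_mix
    l2 = lam * (1.0 - alpha_mix)
    for _ in range(max_outer):
        eta = Xs @ beta
        _, g, h = _eta_derivs_breslow(eta, time, event)
        G = (Xs * h[:, None]).T @ Xs / n
        c = Xs.T @ (h * eta + g) / n
        diag = np.diag(G).copy()
        beta_outer = beta.copy()
        _cd_quad_solve(G, c, diag, beta, l1, l2, tol, max_inner)
        if np.max(np.abs(beta - beta_outer)) < max(tol, 1e-8):
            break
    return beta


def _standardize(X):
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    if np.any(scale == 0):
        raise ValueError("constant feature in the design matrix")
    return (X - center) / scale, center, scale


def default_lambda_path(Xs, time, event, alpha_mix, n_lambdas: int = 100):
    """Decreasing log-spaced lambda path from lambda_max down to
    0.01*lambda_max (0.05 when n < p)."""
    lmax = _lambda_max(Xs, time, event, alpha_mix)
    n, p = Xs.shape
    ratio = 0.05 if n < p else 0.01
    return np.geomspace(lmax, ratio * lmax, n_lambdas)


def coxnet_fit(X, time, event, lam: float | None = None,
               alpha_mix: float = 0.5, names=None,
               n_lambdas: int = 100) -> CoxnetModel:
    """Fit an elastic-net-penalized Cox model (Breslow ties).

    The solver walks a decreasing, warm-started lambda path; ``lam`` (the
    requested penalty) is appended to the path if not already on it, and
    the returned ``beta`` is the solution at ``lam``.  ``lam=None`` keeps
    the whole path with ``beta`` at the smallest lambda; ``lam=0`` runs the
    path to the unpenalized solution.  Coefficients are computed on
    standardized features and returned on the original scale.
    """
    if not 0.0 <= alpha_mix <= 1.0:
        raise ValueError("alpha_mix must be in [0, 1]")
    X, time, event = _validate_survival(X, time, event)
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    Xs_all, center, scale = _standardize(X)
    Xs, ts, es, _ = _sort_by_time(Xs_all, time, event)

    path = default_lambda_path(Xs, ts, es, alpha_mix, n_lambdas)
    if path[0] <= 0:
        raise ValueError("degenerate lambda path (no events or no signal)")
    target = path[-1] if lam is None else float(lam)
    lambdas = list(path[path > target]) + [target] if target < path[0] else [target]
    if lam is not None and lam > path[0]:
        lambdas = [lam]

    coefs = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for i, l in enumerate(lambdas):
        if l == 0.0:
            # the quadratic subproblem with no penalty is Newton's method
            beta = _cd_solve(Xs, ts, es, 0.0, alpha_mix, beta, n,
                             max_outer=200)
        else:
            beta = _cd_solve(Xs, ts, es, l, alpha_mix, beta, n)
        coefs[i] = beta / scale  # original scale
    return CoxnetModel(
        feature_names=list(names),
        beta=coefs[-1].copy(),
        lam=float(lambdas[-1]),
        alpha_mix=alpha_mix,
        path_lambdas=np.asarray(lambdas, dtype=float),
        path_coefs=coefs,
        center=center,
        scale=scale,
    )


def _event_stratified_folds(event, k, rng):
    """Fold labels stratified by event status; every fold gets events
    whenever n_events >= k."""
    n = len(event)
    folds = np.empty(n, dtype=int)
    for val in (0, 1):
        idx = np.flatnonzero(event == val)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(len(idx)) % k
    return folds


def cv_select_lambda(X, time, event, k: int = 10, seed: int = 0,
                     alpha_mix: float = 0.5, names=None,
                     n_lambdas: int = 100) -> CoxnetModel:
    """Choose the penalty by k-fold cross-validated deviance.

    Folds are seeded and stratified by event status.  The held-out
    partial-likelihood deviance follows Verweij & van Houwelingen:
    ``-2 * (loglik_full(beta_k) - loglik_without_fold(beta_k))`` summed
    over folds, evaluated along the shared full-data lambda path.  The
    returned model is the full-data fit at the minimizing lambda, with the
    CV curve (mean and SE per lambda) attached.
    """
    X, time, event = _validate_survival(X, time, event)
    n, p = X.shape
    if k > n:
        raise ValueError("more folds than observations")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    rng = np.random.default_rng(seed)
    n_events = int(event.sum())
    folds = _event_stratified_folds(event, k, rng)
    if n_events >= k:
        # resample until every fold holds at least one event (stratification
        # already guarantees this; loop kept as a safety net)
        for _ in range(100):
            if all((event[folds != f].sum() > 0) for f in range(k)):
                break
            folds = _event_stratified_folds(event, k, rng)

    full = coxnet_fit(X, time, event, lam=None, alpha_mix=alpha_mix,
                      names=names, n_lambdas=n_lambdas)
    lambdas = full.path_lambdas
    Xs_all = (X - full.center) / full.scale

    dev = np.zeros((k, len(lambdas)))
    for f in range(k):
        train = folds != f
        if event[train].sum() == 0:
            continue
        Xtr, ttr, etr, _ = _sort_by_time(Xs_all[train], time[train],
                                         event[train])
        Xf, tf, ef, _ = _sort_by_time(Xs_all, time, event)
        beta = np.zeros(p)
        for i, l in enumerate(lambdas):
            beta = _cd_solve(Xtr, ttr, etr, l, alpha_mix, beta, int(train.sum()))
            ll_full = _breslow_loglik_eta(Xf @ beta, tf, ef)
            ll_train = _breslow_loglik_eta(Xtr @ beta, ttr, etr)
            dev[f, i] = -2.0 * (ll_full - ll_train)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(k)
    best = int(np.argmin(cv_mean))
    model = coxnet_fit(X, time, event, lam=float(lambdas[best]),
                       alpha_mix=alpha_mix, names=names, n_lambdas=n_lambdas)
    model.cv_mean = cv_mean
    model.cv_se = cv_se
    model.extras["cv_lambdas"] = lambdas.tolist()
    model.extras["cv_folds"] = k
    model.extras["cv_seed"] = seed
    return model


# ---------------------------------------------------------------------------
# risk groups and validation


@dataclass
class RiskAssignment:
    """Per-patient risk scores and median-split groups."""

    scores: np.ndarray
    high: np.ndarray  # boolean
    cutoff: float

    @property
    def groups(self) -> np.ndarray:
        return np.where(self.high, "high", "low")


def risk_assign(X, model: CoxnetModel) -> RiskAssignment:
    """Score patients and dichotomize at the cohort median.

    The score is the linear predictor on the original feature scale; a
    patient is high-risk iff score > median (scores exactly at the median
    go low).  All-identical scores yield an all-low assignment with a
    warning.
    """
    scores = model.predict_score(X)
    cutoff = float(np.median(scores))
    if np.ptp(scores) == 0:
        warnings.warn("all risk scores identical; assigning every patient "
                      "to the low-risk group", stacklevel=2)
        high = np.zeros(len(scores), dtype=bool)
    else:
        high = scores > cutoff
    return RiskAssignment(scores=scores, high=high, cutoff=cutoff)


def km_curve(time, event) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as a tidy step table."""
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, float), np.asarray(event, int))
    surv = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    )


def logrank(groups, time, event):
    """Two-group log-rank test: returns (chi2, df, p)."""
    from lifelines.statistics import logrank_test

    groups = np.asarray(groups)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two non-empty groups are required")
    a = groups == levels[0]
    res = logrank_test(time[a], time[~a], event[a], event[~a])
    return float(res.test_statistic), 1, float(res.p_value)


def multivariate_cox(risk_high, clinical: pd.DataFrame, time, event) -> CoxFitResult:
    """Adjusted Cox model: risk group plus clinical covariates.

    Covariates are high-vs-low risk, age (continuous), male-vs-female,
    ever-vs-never smoking, and stage II/III/IV dummies against stage I.
    Empty levels drop their dummy with a warning.  Efron ties.
    """
    risk_high = np.asarray(risk_high).astype(int)
    cols = {"risk_high_vs_low": risk_high.astype(float),
            "age": clinical["age"].to_numpy(dtype=float),
            "sex_male_vs_female":
                (clinical["sex"].astype(str) == "male").to_numpy(float),
            "smoking_ever_vs_never":
                (clinical["smoking"].astype(str) == "ever").to_numpy(float)}
    stage = clinical["stage"].astype(str)
    for lvl in ("II", "III", "IV"):
        dummy = (stage == lvl).to_numpy(float)
        if dummy.sum() == 0:
            warnings.warn(f"no stage-{lvl} patients; dummy dropped",
                          stacklevel=2)
            continue
        cols[f"stage_{lvl}_vs_I"] = dummy
    design = pd.DataFrame(cols)
    keep = [c for c in design.columns if np.ptp(design[c].to_numpy()) > 0]
    dropped = set(design.columns) - set(keep)
    if dropped:
        warnings.warn(f"constant covariates dropped: {sorted(dropped)}",
                      stacklevel=2)
    design = design[keep]
    return cox_fit(design.to_numpy(), time, event, ties="efron",
                   names=list(design.columns))
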