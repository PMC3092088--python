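"""Binomial-logistic model fitting and nested-model deviance tests.

This module is the numerical core of the package: a small, robust IRLS
(iteratively reweighted least squares) fitter for the logistic model

    logit P(y_i = 1) = x_i' beta,

plus the two analysis-of-deviance tests that the LD-independence screen
and the stepwise profile builder alternate between:

* the *sequential* test (SAS "type I"): significance of a predictor block
  given only the blocks entered before it, and
* the *partial* test (SAS "type III"): significance of a predictor given
  every other predictor in the model.

Both are likelihood-ratio (deviance-difference) tests by default; Wald
versions are available where speed matters.  Nagelkerke's pseudo-R² and
Wald odds-ratio confidence limits round out the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "NestedTestResult",
    "RankDeficientError",
    "DegenerateOutcomeError",
    "fit_logistic",
    "lr_test_sequential",
    "lr_test_partial",
    "nagelkerke_r2",
    "wald_ci",
]

#: Log-odds magnitude beyond which a non-converged fit is flagged as
#: (quasi-)separated; coefficients are capped at this value.
SEPARATION_CAP = 15.0


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix has linearly dependent columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


class DegenerateOutcomeError(ValueError):
    """Outcome vector is constant (all cases or all controls)."""


@dataclass
class DesignMatrix:
    """Dense design matrix with an explicit all-ones intercept column."""

    values: np.ndarray
    predictor_names: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.values.shape[1] != len(self.predictor_names):
            raise ValueError("predictor_names length mismatch")
        if self.values.shape[1] < 1:
            raise ValueError("design matrix needs at least one column")
        if np.isnan(self.values).any():
            raise ValueError("design matrix contains missing values")
        if not np.all(self.values[:, 0] == 1.0):
            raise ValueError("first column must be the all-ones intercept")

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> int:
        try:
            return self.predictor_names.index(name)
        except ValueError:
            raise KeyError(f"no predictor named {name!r}") from None

    def drop(self, name: str) -> "DesignMatrix":
        j = self.column(name)
        keep = [k for k in range(self.values.shape[1]) if k != j]
        return DesignMatrix(
            self.values[:, keep],
            [self.predictor_names[k] for k in keep],
            self.sample_ids,
        )


@dataclass
class GlmFit:
    """A fitted binomial-logistic model (log-odds scale)."""

    coefficients: np.ndarray
    predictor_names: list[str]
    covariance: np.ndarray
    log_likelihood: float
    n_obs: int
    converged: bool
    n_iter: int
    separation: bool = False

    @property
    def deviance(self) -> float:
        # saturated log-likelihood is 0 for ungrouped binary data
        return -2.0 * self.log_likelihood

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.predictor_names.index(name)])

    def se(self, name: str) -> float:
        j = self.predictor_names.index(name)
        return float(np.sqrt(self.covariance[j, j]))


@dataclass
class NestedTestResult:
    """Chi-square test of a predictor (block) in a nested-model comparison."""

    name: str
    statistic: float
    df: int
    p_value: float
    kind: str  # "sequential" (type I) or "partial" (type III)


def _check_rank(X: np.ndarray, names) -> None:
    # pivoted QR exposes the dependent columns by tiny diagonal entries of R
    _, R, piv = _qr_pivot(X)
    d = np.abs(np.diag(R))
    if d.size == 0 or d[0] == 0.0:
        raise RankDeficientError(names)
    bad = piv[np.flatnonzero(d < d[0] * 1e-9 * max(X.shape))]
    if bad.size:
        raise RankDeficientError([names[j] for j in sorted(bad)])


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


def fit_logistic(
    X: DesignMatrix | np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = 50,
    tol: float = 1e-10,
    check_rank: bool = True,
) -> GlmFit:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    Parameters
    ----------
    X
        Design matrix whose first column is the intercept.
    y
        Binary outcome vector (0 = control, 1 = case).
    tol
        Convergence declared when the relative deviance change falls
        below this value.

    Raises
    ------
    DegenerateOutcomeError
        If ``y`` is constant (the MLE does not exist).
    RankDeficientError
        If columns of ``X`` are linearly dependent; offending columns are
        named in the message.

    Notes
    -----
    Complete or quasi-complete separation makes the likelihood monotone in
    some coefficient; the fit is then returned with ``converged=False``,
    ``separation=True`` and coefficients capped at ±15 on the log-odds
    scale rather than silently reported as converged.
    """
    if isinstance(X, DesignMatrix):
        names = X.predictor_names
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xv.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if Xv.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateOutcomeError(
            "outcome is constant (no cases or no controls); logistic MLE undefined"
        )
    if check_rank:
        _check_rank(Xv, names)

    n, p = Xv.shape
    beta = np.zeros(p)
    eta = Xv @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    dev = _deviance(y, mu)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        XtW = Xv.T * w
        H = XtW @ Xv
        g = Xv.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step-halving: never accept an increase in deviance
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            mu_new = 1.0 / (1.0 + np.exp(-(Xv @ beta_new)))
            dev_new = _deviance(y, mu_new)
            if dev_new <= dev + 1e-12:
                break
            scale *= 0.5
        else:
            beta_new, mu_new, dev_new = beta, mu, dev
        delta = dev - dev_new
        if np.max(np.abs(beta_new)) > SEPARATION_CAP:
            # (quasi-)separation: the likelihood is monotone in some
            # direction.  Walk the last step only up to the ±cap boundary
            # so the returned iterate is honest, then stop.
            d_vec = beta_new - beta
            t = 1.0
            for bj, dj in zip(beta, d_vec):
                if dj != 0.0:
                    lim = (np.sign(dj) * SEPARATION_CAP - bj) / dj
                    if lim > 0:
                        t = min(t, lim)
            beta = beta + t * d_vec
            mu = 1.0 / (1.0 + np.exp(-(Xv @ beta)))
            dev = _deviance(y, mu)
            separation = True
            converged = False
            break
        beta, mu = beta_new, mu_new
        dev = dev_new
        if abs(delta) < tol * (abs(dev) + 0.1):
            converged = True
            break

    w = np.maximum(mu * (1.0 - mu), 1e-12)
    H = (Xv.T * w) @ Xv
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    return GlmFit(
        coefficients=beta,
        predictor_names=list(names),
        covariance=cov,
        log_likelihood=-0.5 * dev,
        n_obs=n,
        converged=converged,
        n_iter=it,
        separation=separation,
    )


def lr_test_sequential(
    X_ordered: DesignMatrix,
    y: np.ndarray,
    block_boundaries: list[int],
    *,
    block_names: list[str] | None = None,
) -> list[NestedTestResult]:
    """Sequential (type I) analysis-of-deviance over ordered predictor blocks.

    ``block_boundaries`` are cumulative column counts delimiting the blocks,
    e.g. ``[3, 4, 5]`` for a 3-column covariate block followed by two
    single-column marker blocks.  The k-th statistic is the deviance drop
    from adding block k to the model holding blocks 1..k-1 (the intercept
    always belongs to block 1); it does not depend on later blocks.
    """
    bounds = list(block_boundaries)
    if bounds[-1] != X_ordered.values.shape[1]:
        raise ValueError("last boundary must equal the number of columns")
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("block boundaries must be strictly increasing")
    if block_names is None:
        block_names = [
            "+".join(X_ordered.predictor_names[lo:hi])
            for lo, hi in zip([0] + bounds[:-1], bounds)
        ]

    devs = []
    for hi in bounds:
        sub = DesignMatrix(
            X_ordered.values[:, :hi],
            X_ordered.predictor_names[:hi],
            X_ordered.sample_ids,
        )
        try:
            devs.append(fit_logistic(sub, y).deviance)
        except (RankDeficientError, DegenerateOutcomeError) as exc:
            raise type(exc)(
                f"fit failed at block ending column {hi}: {exc}"
            ) from exc

    out = []
    prev = None
    for k, (hi, dev) in enumerate(zip(bounds, devs)):
        lo = 0 if k == 0 else bounds[k - 1]
        if k == 0:
            prev = dev
            continue  # first block (covariates + intercept) is the baseline
        stat = max(prev - dev, 0.0)
        df = hi - lo
        out.append(
            NestedTestResult(
                name=block_names[k],
                statistic=stat,
                df=df,
                p_value=float(stats.chi2.sf(stat, df)),
                kind="sequential",
            )
        )
        prev = dev
    return out


def lr_test_partial(
    X_full: DesignMatrix,
    y: np.ndarray,
    target_predictor: str,
    *,
    full_fit: GlmFit | None = None,
) -> NestedTestResult:
    """Partial (type III) deviance test of one predictor given all others."""
    if full_fit is None:
        full_fit = fit_logistic(X_full, y)
    reduced = X_full.drop(target_predictor)
    red_fit = fit_logistic(reduced, y)
    stat = max(red_fit.deviance - full_fit.deviance, 0.0)
    return NestedTestResult(
        name=target_predictor,
        statistic=stat,
        df=1,
        p_value=float(stats.chi2.sf(stat, 1)),
        kind="partial",
    )


def nagelkerke_r2(fit: GlmFit, null_fit: GlmFit) -> float:
    """Nagelkerke's pseudo-R² of ``fit`` against an intercept-only null.

    Cox–Snell R² = 1 − exp((D_full − D_null)/n) rescaled by its maximum
    attainable value 1 − exp(−D_null/n), so a perfectly predictive model
    scores 1 and the null model scores 0.
    """
    if fit.n_obs != null_fit.n_obs:
        raise ValueError("fits computed on different numbers of observations")
    n = fit.n_obs
    d_null = null_fit.deviance
    if d_null <= 0:
        raise ValueError("null deviance is zero: outcome is degenerate")
    cs = 1.0 - np.exp((fit.deviance - d_null) / n)
    cs_max = 1.0 - np.exp(-d_null / n)
    return float(np.clip(cs / cs_max, 0.0, 1.0))


def wald_ci(
    fit: GlmFit, predictor: str, level: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio and Wald confidence limits for one predictor.

    Returns ``(odds_ratio, lower_CL, upper_CL)`` with limits
    exp(beta ± z·SE) at the requested two-sided coverage.
    """
    if not fit.converged:
        raise ValueError("Wald interval requested from a non-converged fit")
    beta = fit.coef(predictor)
    se = fit.se(predictor)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
    )
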