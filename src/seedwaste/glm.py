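"""Binomial occupancy GLM and the Hosmer-Lemeshow goodness-of-fit test.

Models plant presence in vegetation plots as a logistic function of the
modelled habitat suitability.  The logit fit is maximum likelihood via
iteratively reweighted least squares (IRLS); Hosmer-Lemeshow groups
observations into g near-equal bins of fitted probability and compares
observed with expected event counts on a chi-square scale with g - 2
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = ["GlmFit", "HosmerLemeshowResult", "PerfectSeparationError", "fit_logistic", "hosmer_lemeshow"]


class PerfectSeparationError(RuntimeError):
    """Raised when the covariate perfectly separates the outcome classes."""


@dataclass
class GlmFit:
    """Maximum-likelihood logit fit of presence on one covariate."""

    coef: np.ndarray           # (intercept, slope)
    se: np.ndarray
    null_deviance: float
    deviance: float
    n: int
    fitted: np.ndarray
    x: np.ndarray
    y: np.ndarray
    n_iter: int

    @property
    def z_values(self) -> np.ndarray:
        return self.coef / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z_values))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return expit(self.coef[0] + self.coef[1] * np.asarray(x, dtype=float))


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    return float(-2.0 * np.sum(y * np.log(np.clip(p, eps, 1)) + (1 - y) * np.log(np.clip(1 - p, eps, 1))))


def fit_logistic(
    presence: np.ndarray,
    suitability: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Fit presence ~ suitability by IRLS.

    Convergence when the deviance change drops below ``tol``.  Perfect
    separation (coefficients diverging while fitted probabilities pin to
    0/1) raises :class:`PerfectSeparationError` with the diverging slope
    in the message.
    """
    y = np.asarray(presence, dtype=float).ravel()
    x = np.asarray(suitability, dtype=float).ravel()
    if y.size != x.size:
        raise ValueError("presence and suitability must have equal length")
    if y.size < 3:
        raise ValueError("at least three observations are required")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both outcome classes must be present")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    dev = _deviance(y, np.full_like(y, y.mean()))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        XtW = X.T * w
        beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        dev_new = _deviance(y, expit(X @ beta_new))
        beta = beta_new
        if abs(dev - dev_new) < tol:
            dev = dev_new
            break
        dev = dev_new
    p = expit(X @ beta)
    if np.abs(beta).max() > 1e3 or np.all((p < 1e-8) | (p > 1 - 1e-8)):
        raise PerfectSeparationError(
            f"covariate separates the classes perfectly (slope diverging at {beta[1]:.3g})"
        )
    w = np.clip(p * (1 - p), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X)
    p_null = np.full_like(y, y.mean())
    return GlmFit(
        coef=beta,
        se=np.sqrt(np.diag(cov)),
        null_deviance=_deviance(y, p_null),
        deviance=dev,
        n=y.size,
        fitted=p,
        x=x,
        y=y,
        n_iter=n_iter,
    )


@dataclass
class HosmerLemeshowResult:
    statistic: float
    groups: int
    p_value: float
    table: list[dict]

    @property
    def df(self) -> int:
        return self.groups - 2


def hosmer_lemeshow(fit: GlmFit, g: int = 10) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow chi-square test on ``g`` fitted-probability groups.

    Observations are sorted by fitted probability and split at the
    quantiles of the fitted values; ties stay in a single group, so the
    effective number of groups may be reduced (this is logged in the
    result's ``groups``).  The statistic is
    ``sum_g (O_g - n_g pbar_g)^2 / (n_g pbar_g (1 - pbar_g))`` with
    ``df = groups - 2``.  A group whose mean fitted probability is 0 or
    1 makes the expected counts degenerate and raises ``ValueError``.
    """
    if g < 3:
        raise ValueError("need at least 3 groups")
    p = fit.fitted
    y = fit.y
    edges = np.unique(np.quantile(p, np.linspace(0, 1, g + 1)[1:-1]))
    group = np.digitize(p, edges, right=True)
    ids = np.unique(group)
    statistic = 0.0
    table = []
    for gid in ids:
        sel = group == gid
        n_g = int(sel.sum())
        obs = float(y[sel].sum())
        pbar = float(p[sel].mean())
        if pbar <= 0.0 or pbar >= 1.0:
            raise ValueError("degenerate group with mean fitted probability 0 or 1")
        exp_g = n_g * pbar
        statistic += (obs - exp_g) ** 2 / (exp_g * (1 - pbar))
        table.append({"n": n_g, "observed": obs, "expected": exp_g, "mean_fitted": pbar})
    groups = len(ids)
    df = groups - 2
    if df < 1:
        raise ValueError(f"too few distinct fitted-value groups ({groups}) for the test")
    return HosmerLemeshowResult(
        statistic=float(statistic),
        groups=groups,
        p_value=float(stats.chi2.sf(statistic, df)),
        table=table,
    )
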