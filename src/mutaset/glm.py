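"""Quasi-Poisson models of per-gene mutation counts.

Counts per gene (or per gene's pooled CDS) are regressed on sequence
length, expression and GC content with a log-link Poisson mean model whose
standard errors are inflated by the Pearson dispersion (quasi-likelihood).
Effect sizes are reported as rate ratios per interquartile-range increase
of each covariate, exp(beta_j * IQR_j), with Wald 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class GlmFit:
    """A fitted quasi-Poisson regression.

    `coefficients`/`standard_errors` are on the log-rate scale; SEs are
    already scaled by sqrt(dispersion).  `dispersion` is Pearson chi-square
    over residual degrees of freedom; exactly-fitting degenerate data give
    dispersion 0 and `degenerate=True`.
    """

    response_level: str
    coefficients: pd.Series
    standard_errors: pd.Series
    dispersion: float
    n_observations: int
    iqr: pd.Series
    covariate_means: pd.Series
    degenerate: bool = False

    def rate_ratios(self) -> pd.DataFrame:
        """RR per IQR with 95% CI for every non-intercept covariate."""
        rows = []
        for name in self.coefficients.index:
            if name == "intercept":
                continue
            rows.append(iqr_rate_ratio(self, name)._asdict_row())
        return pd.DataFrame(rows).set_index("covariate")


class RateRatio(NamedTuple):
    covariate: str
    rr: float
    ci_low: float
    ci_high: float
    iqr: float

    def _asdict_row(self):
        return {
            "covariate": self.covariate,
            "rr": self.rr,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "iqr": self.iqr,
        }


def fit_quasipoisson(
    covariates: pd.DataFrame,
    counts,
    response_level: str = "gene",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> GlmFit:
    """Fit log mu = X beta by IRLS to the Poisson score equations, then
    estimate the dispersion phi = sum((y - mu)^2 / mu) / (n - p) and scale
    the standard errors by sqrt(phi).

    Rows with any missing covariate or count are dropped before fitting.
    Rank-deficient designs and non-convergence are hard errors.
    """
    X = pd.DataFrame(covariates).astype(float)
    y = pd.Series(np.asarray(counts, dtype=float), index=X.index)
    keep = ~(X.isna().any(axis=1) | y.isna())
    X, y = X.loc[keep], y.loc[keep]
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")

    design = sm.add_constant(X, prepend=True, has_constant="raise")
    design = design.rename(columns={"const": "intercept"})
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear covariates)")

    model = sm.GLM(y, design, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=tol, scale=1.0)
    if not getattr(res, "converged", True):
        raise RuntimeError(f"IRLS did not converge within {maxiter} iterations")

    mu = res.fittedvalues.to_numpy()
    resid = y.to_numpy() - mu
    df_resid = len(y) - design.shape[1]
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    pearson = float(np.sum(resid**2 / mu))
    phi = pearson / df_resid
    degenerate = phi < np.finfo(float).eps * 100
    if degenerate:
        warnings.warn(
            "zero Pearson dispersion: counts are exactly fitted (degenerate)",
            stacklevel=2,
        )
    se = pd.Series(res.bse, index=design.columns) * np.sqrt(max(phi, 0.0))
    return GlmFit(
        response_level=response_level,
        coefficients=pd.Series(res.params, index=design.columns),
        standard_errors=se,
        dispersion=phi,
        n_observations=len(y),
        iqr=X.quantile(0.75) - X.quantile(0.25),
        covariate_means=X.mean(),
        degenerate=degenerate,
    )


def iqr_rate_ratio(fit: GlmFit, covariate: str) -> RateRatio:
    """RR = exp(beta_j * IQR_j); CI = exp((beta_j +/- 1.96 SE_j) * IQR_j).

    A zero-IQR covariate is uninformative: RR = 1 with a warning.
    """
    if covariate not in fit.coefficients.index or covariate == "intercept":
        raise KeyError(f"covariate {covariate!r} not in fit")
    iqr = float(fit.iqr[covariate])
    if iqr == 0:
        warnings.warn(f"covariate {covariate!r} has zero IQR; RR set to 1", stacklevel=2)
        return RateRatio(covariate, 1.0, 1.0, 1.0, 0.0)
    beta = float(fit.coefficients[covariate])
    se = float(fit.standard_errors[covariate])
    lo = np.exp((beta - Z_95 * se) * iqr)
    hi = np.exp((beta + Z_95 * se) * iqr)
    return RateRatio(covariate, float(np.exp(beta * iqr)), float(min(lo, hi)), float(max(lo, hi)), iqr)


def centered_rr_curve(fit: GlmFit, covariate: str, grid) -> pd.DataFrame:
    """Rate ratio of a unit at covariate value x versus one at the covariate
    mean, other covariates held fixed: RR(x) = exp(beta_j (x - mean_j)),
    with a Wald 95% band from SE_j.  RR is exactly 1 at the mean.
    """
    if covariate not in fit.coefficients.index or covariate == "intercept":
        raise KeyError(f"covariate {covariate!r} not in fit")
    x = np.asarray(grid, dtype=float)
    dx = x - float(fit.covariate_means[covariate])
    beta = float(fit.coefficients[covariate])
    se = float(fit.standard_errors[covariate])
    rr = np.exp(beta * dx)
    a = np.exp((beta - Z_95 * se) * dx)
    b = np.exp((beta + Z_95 * se) * dx)
    return pd.DataFrame(
        {
            "x": x,
            "rr": rr,
            "ci_low": np.minimum(a, b),
            "ci_high": np.maximum(a, b),
        }
    )
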