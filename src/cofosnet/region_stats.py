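"""Region-wise negative-binomial group comparison of c-Fos counts.

For each brain region, counts across subjects are modelled as negative
binomial with a log link and a two-level group contrast, dummy coded
(0 = reference level, 1 = comparison level):

    log mu_i = beta0 + beta1 * group_i,      Var(y) = mu + mu^2 / alpha

The coefficients and the dispersion ``alpha`` are maximum-likelihood
estimates obtained by iteratively reweighted least squares for the
coefficients alternated with one-dimensional likelihood maximisation for
``alpha`` (the glm.nb fitting scheme). The reported z statistic is
``beta1`` divided by its standard error from the Fisher information; the
two-sided normal p-values are corrected across regions by
Benjamini-Hochberg. A significant (q < 0.05 by the caller's threshold)
``beta1`` means group status is related to the region's cell count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .datasets import CountMatrix

_MAX_IRLS = 100
_MAX_OUTER = 100
_LOG_ALPHA_BOUNDS = (-10.0, 16.0)


@dataclass
class RegionTestResult:
    """One region's NB group-contrast fit (q filled after BH)."""

    region_id: str
    beta: float
    se_beta: float
    z: float
    dispersion_alpha: float
    p: float
    q: float = np.nan
    converged: bool = True
    note: str = ""


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood with size ``alpha`` (variance mu + mu^2/alpha)."""
    mu = np.maximum(mu, 1e-12)
    return float(
        np.sum(
            gammaln(y + alpha)
            - gammaln(alpha)
            - gammaln(y + 1)
            + alpha * np.log(alpha / (alpha + mu))
            + y * np.log(mu / (alpha + mu))
        )
    )


def _irls_coefs(
    y: np.ndarray, X: np.ndarray, alpha: float, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS for the NB GLM coefficients at fixed dispersion.

    Returns (beta, expected-information matrix X'WX, converged).
    """
    eta = np.clip(X @ beta, -30, 30)
    mu = np.exp(eta)
    ok = False
    xtwx = np.eye(X.shape[1])
    for _ in range(_MAX_IRLS):
        w = mu / (1.0 + mu / alpha)  # Fisher weights for log link
        zwork = eta + (y - mu) / mu
        xtwx = X.T @ (w[:, None] * X)
        new_beta = np.linalg.solve(xtwx, X.T @ (w * zwork))
        step = np.max(np.abs(new_beta - beta))
        beta = new_beta
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        if step < 1e-12:
            ok = True
            break
    return beta, xtwx, ok


def fit_region_nb(
    counts_for_region: np.ndarray, group_dummy: np.ndarray, region_id: str = ""
) -> RegionTestResult:
    """Fit the NB group contrast for one region.

    Degenerate inputs (a group with all-zero counts, or non-convergence)
    yield a flagged sentinel result (``converged=False``, NaN statistics)
    rather than an exception, so a whole-brain screen stays total.
    """
    y = np.asarray(counts_for_region, dtype=float)
    g = np.asarray(group_dummy, dtype=float)
    if y.shape != g.shape:
        raise ValueError("counts and dummy must have equal length")
    if not set(np.unique(g)) <= {0.0, 1.0}:
        raise ValueError("group_dummy must be 0/1")
    if (g == 0).sum() < 2 or (g == 1).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")

    sentinel = RegionTestResult(
        region_id, np.nan, np.nan, np.nan, np.nan, np.nan, converged=False
    )
    if y.sum() == 0:
        sentinel.note = "all counts zero"
        return sentinel
    if y[g == 0].sum() == 0 or y[g == 1].sum() == 0:
        sentinel.note = "one group all zero; fit degenerates"
        return sentinel

    X = np.column_stack([np.ones_like(g), g])
    mu0 = np.maximum((y + y.mean()) / 2.0, 1e-8)
    beta = np.linalg.lstsq(X, np.log(mu0), rcond=None)[0]

    # moment start for the dispersion
    m, v = y.mean(), y.var()
    alpha = m * m / (v - m) if v > m else 1e6
    alpha = float(np.clip(alpha, 1e-3, 1e6))

    last_ll = -np.inf
    converged = False
    xtwx = np.eye(2)
    for _ in range(_MAX_OUTER):
        beta, xtwx, _ = _irls_coefs(y, X, alpha, beta)
        mu = np.exp(np.clip(X @ beta, -30, 30))
        res = optimize.minimize_scalar(
            lambda la: -nb_loglik(y, mu, np.exp(la)),
            bounds=_LOG_ALPHA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-10},
        )
        alpha = float(np.exp(res.x))
        ll = nb_loglik(y, mu, alpha)
        # relative tolerance: at the dispersion bound (quasi-Poisson data)
        # the profile is flat and the bounded optimiser jitters at ~1e-7
        if abs(ll - last_ll) < 1e-8 * (abs(ll) + 1.0):
            converged = True
            break
        last_ll = ll
    if not converged:
        sentinel.note = "IRLS did not converge"
        return sentinel

    cov = np.linalg.inv(xtwx)
    se = float(np.sqrt(cov[1, 1]))
    b1 = float(beta[1])
    z = b1 / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return RegionTestResult(region_id, b1, se, z, alpha, p)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_region_screen(
    matrix: CountMatrix, contrast: tuple[str, str, str]
) -> list[RegionTestResult]:
    """NB screen of every region for one metadata contrast.

    ``contrast = (field, level0, level1)``: subjects at ``level0`` are coded
    0 and ``level1`` coded 1. Results are ordered by region id; q-values are
    BH-adjusted across the converged fits only (sentinels keep q = NaN).
    """
    field, level0, level1 = contrast
    ids0 = matrix.subject_ids_where(field, level0)
    ids1 = matrix.subject_ids_where(field, level1)
    if len(ids0) < 2 or len(ids1) < 2:
        raise ValueError(f"contrast level with <2 subjects: {contrast}")
    sub = matrix.subset_subjects(ids0 + ids1)
    dummy = np.array([0] * len(ids0) + [1] * len(ids1), dtype=float)

    results = []
    for region in sorted(sub.region_ids):
        y = sub.counts.loc[region].to_numpy()
        results.append(fit_region_nb(y, dummy, region_id=region))

    fitted = [r for r in results if r.converged]
    skipped = len(results) - len(fitted)
    if skipped:
        warnings.warn(f"{skipped} region(s) excluded from BH (degenerate fits)")
    if fitted:
        q = bh_adjust(np.array([r.p for r in fitted]))
        for r, qi in zip(fitted, q):
            r.q = float(qi)
    return results


def screen_to_frame(results: list[RegionTestResult]):
    """Results as a tidy table (region, beta, se, z, alpha, p, q, converged)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "region": r.region_id,
                "beta": r.beta,
                "se": r.se_beta,
                "z": r.z,
                "dispersion_alpha": r.dispersion_alpha,
                "p": r.p,
                "q": r.q,
                "converged": r.converged,
            }
            for r in results
        ]
    )
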