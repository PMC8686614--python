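"""Negative-binomial expression modelling: dispersion trend, reduced fit,
and the distilled z-statistic.

The test statistic for a (gene, gRNA) pair is the Wald z-score of the
gRNA indicator in a negative binomial regression of gene UMI counts on
the indicator and the cell-level technical factors,

    Y_i ~ NegBin(mu_i, alpha),  log mu_i = beta0 + X_i beta + Z_i' gamma,

with the dispersion convention Var(Y) = mu + alpha * mu^2. Rather than
refitting this joint model for every resample of X, the statistic is
*distilled*: the covariate-only model (no gRNA term) is fit once, its
fitted linear predictor is frozen as a per-cell offset, and only the
scalar gRNA coefficient is refit against that offset. Because cells
without the gRNA contribute a constant to the offset-model likelihood,
the refit needs only the cells carrying the gRNA — typically a few
dozen out of thousands — which is what makes resampling-based testing
affordable.

Per-gene dispersions are estimated by pooling across genes: raw
method-of-moments estimates are smoothed against mean expression by
Gaussian-kernel regression on the log-log scale, and each gene's final
dispersion is the trend value at its mean (Hafemeister-style
regularization).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

logger = logging.getLogger("crtscreen")

DISPERSION_FLOOR = 0.01
GLM_MAXITER = 100
GLM_TOL = 1e-8
_NEWTON_TOL = 1e-10
_NEWTON_MAXITER = 100
_NEWTON_STEP_CAP = 3.0


def _nb_family(alpha: float) -> sm.families.NegativeBinomial:
    # log link is non-canonical for NB; statsmodels warns but it is the
    # standard choice here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.families.NegativeBinomial(alpha=alpha, link=sm.families.links.Log())


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionFit:
    """Per-gene dispersion estimates: raw, trend, and trend-projected final."""

    mean_expression: np.ndarray
    raw_dispersion: np.ndarray
    fitted_trend: np.ndarray
    final_dispersion: np.ndarray

    def to_frame(self, gene_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "mean": self.mean_expression,
                "raw": self.raw_dispersion,
                "final": self.final_dispersion,
            }
        )
        if gene_ids is not None:
            df.insert(0, "gene_id", list(gene_ids))
        return df


def moment_dispersion(y, floor: float = DISPERSION_FLOOR) -> float:
    """Method-of-moments NB dispersion, floored at ``floor``.

    Solves Var = m + alpha * m^2 for alpha using the sample mean and
    variance; equi- or under-dispersed genes hit the floor.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    m = y.mean()
    if m == 0:
        raise ValueError("gene is unexpressed (mean 0); filter before estimating")
    s2 = y.var(ddof=1)
    return max(floor, (s2 - m) / m**2)


def estimate_dispersions(
    means,
    raw,
    bandwidth: float | None = None,
    floor: float = DISPERSION_FLOOR,
) -> DispersionFit:
    """Smooth raw dispersions against mean expression and project onto the trend.

    Nadaraya-Watson regression of log(raw) on log(mean) with a Gaussian
    kernel; bandwidth defaults to Silverman's rule on the log-means. The
    final per-gene dispersion is exp(trend) evaluated at that gene's
    log-mean, floored.
    """
    means = np.asarray(means, dtype=float)
    raw = np.asarray(raw, dtype=float)
    if means.shape != raw.shape or means.ndim != 1 or means.size == 0:
        raise ValueError("means and raw must be aligned 1-d vectors")
    if np.any(means <= 0) or np.any(raw <= 0):
        raise ValueError("means and raw dispersions must be positive")

    if means.size == 1:
        logger.info("single gene: dispersion trend degenerates to the raw estimate")
        trend = raw.copy()
        return DispersionFit(means, raw, trend, np.maximum(floor, trend))

    lx = np.log(means)
    ly = np.log(raw)
    if bandwidth is None:
        sd = lx.std(ddof=1)
        bandwidth = 1.06 * sd * lx.size ** (-1 / 5) if sd > 0 else 1.0
        bandwidth = max(bandwidth, 1e-6)
    w = np.exp(-0.5 * ((lx[:, None] - lx[None, :]) / bandwidth) ** 2)
    trend_log = (w @ ly) / w.sum(axis=1)
    trend = np.exp(trend_log)
    return DispersionFit(means, raw, trend, np.maximum(floor, trend))


def dispersions_from_matrix(counts, gene_ids=None, bandwidth=None, floor=DISPERSION_FLOOR) -> DispersionFit:
    """Raw + trend dispersion estimation straight from a gene-by-cell matrix."""
    counts = np.asarray(counts.todense() if hasattr(counts, "todense") else counts, dtype=float)
    means = counts.mean(axis=1)
    if np.any(means == 0):
        raise ValueError("unexpressed genes present; filter before dispersion estimation")
    s2 = counts.var(axis=1, ddof=1)
    raw = np.maximum(floor, (s2 - means) / means**2)
    return estimate_dispersions(means, raw, bandwidth=bandwidth, floor=floor)


def write_dispersions_tsv(fit: DispersionFit, gene_ids, path: str) -> None:
    fit.to_frame(gene_ids).to_csv(path, sep="\t", index=False)


def read_dispersions_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Reduced (covariate-only) NB fit
# ---------------------------------------------------------------------------

@dataclass
class ReducedNBFit:
    """Covariate-only NB fit whose linear predictor becomes the frozen offset."""

    intercept: float
    covariate_coefficients: np.ndarray
    offsets: np.ndarray  # beta0 + Z_i' gamma, one per cell
    dispersion: float
    converged: bool


def fit_reduced_nb(y, Z, alpha: float, maxiter: int = GLM_MAXITER, tol: float = GLM_TOL) -> ReducedNBFit:
    """Fit the NB model of counts on covariates alone (no gRNA term).

    IRLS maximum likelihood with the dispersion held fixed. The returned
    per-cell offsets o_i = beta0 + Z_i' gamma are what the distilled
    statistic conditions on.
    """
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != y.size:
        Z = Z.T
    if Z.shape[0] != y.size:
        raise ValueError("Z row count must equal length of y")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if y.sum() == 0:
        raise ValueError("all-zero counts: gene unexpressed")

    design = sm.add_constant(Z, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design, family=_nb_family(alpha))
        res = model.fit(maxiter=maxiter, tol=tol)
    params = np.asarray(res.params, dtype=float)
    converged = bool(res.converged) and np.all(np.isfinite(params))
    if not converged:
        logger.warning("reduced NB fit did not converge")
    offsets = design @ params
    return ReducedNBFit(
        intercept=float(params[0]),
        covariate_coefficients=params[1:].copy(),
        offsets=offsets,
        dispersion=float(alpha),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Distilled statistic (offset model, treated cells only)
# ---------------------------------------------------------------------------

@dataclass
class DistilledStat:
    beta_hat: float
    z_value: float
    n_treated: int


def _newton_beta(y, offsets, alpha, tol=_NEWTON_TOL, maxiter=_NEWTON_MAXITER):
    """Scalar Newton MLE of beta in log mu_i = beta + o_i, fixed alpha.

    Score: sum (y - mu) / (1 + alpha mu); observed information:
    sum mu (1 + alpha y) / (1 + alpha mu)^2. Returns (beta, se, converged),
    with the SE from the observed information at the optimum.
    """
    y = np.asarray(y, dtype=float)
    o = np.asarray(offsets, dtype=float)
    if y.sum() == 0:
        return -np.inf, np.nan, False
    # Poisson-style closed-form start is near the NB optimum
    beta = np.log(y.sum()) - np.log(np.exp(o).sum())
    converged = False
    for _ in range(maxiter):
        mu = np.exp(beta + o)
        score = np.sum((y - mu) / (1 + alpha * mu))
        info = np.sum(mu * (1 + alpha * y) / (1 + alpha * mu) ** 2)
        if info <= 0 or not np.isfinite(info):
            return beta, np.nan, False
        step = np.clip(score / info, -_NEWTON_STEP_CAP, _NEWTON_STEP_CAP)
        beta += step
        if abs(step) < tol:
            converged = True
            break
    mu = np.exp(beta + o)
    info = np.sum(mu * (1 + alpha * y) / (1 + alpha * mu) ** 2)
    se = 1 / np.sqrt(info) if info > 0 else np.nan
    return float(beta), float(se), converged


def distilled_z(y, x, offsets, alpha: float) -> DistilledStat:
    """Distilled NB z-score: refit only the gRNA coefficient against frozen offsets.

    Uses only the cells carrying the gRNA; the z-value is the Wald
    statistic beta / SE with the SE from the observed information of the
    univariate offset-model likelihood.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    offsets = np.asarray(offsets, dtype=float)
    treated = np.flatnonzero(x)
    if treated.size == 0:
        raise ValueError("no cells carry the gRNA (x is all zeros)")
    beta, se, conv = _newton_beta(y[treated], offsets[treated], alpha)
    if not conv or not np.isfinite(se):
        raise FloatingPointError("distilled NB fit failed to converge")
    return DistilledStat(beta_hat=beta, z_value=beta / se, n_treated=int(treated.size))


def distilled_z_resamples(y, offsets, alpha: float, resample_indices) -> np.ndarray:
    """Vectorized distilled z across many resampled gRNA indicator vectors.

    ``resample_indices`` is a sequence of treated-cell index arrays, one
    per resample. All univariate Newton solves run simultaneously via
    segment sums. Resamples with no treated cells or with all-zero
    treated counts yield NaN (callers drop them with a count).
    """
    y = np.asarray(y, dtype=float)
    o = np.asarray(offsets, dtype=float)
    B = len(resample_indices)
    z = np.full(B, np.nan)
    sizes = np.array([len(ix) for ix in resample_indices])
    valid = sizes > 0
    if not valid.any():
        return z
    cat = np.concatenate([np.asarray(resample_indices[b]) for b in np.flatnonzero(valid)])
    seg = np.repeat(np.arange(int(valid.sum())), sizes[valid])
    yv = y[cat]
    ov = o[cat]
    nb = int(valid.sum())
    ysum = np.bincount(seg, weights=yv, minlength=nb)
    esum = np.bincount(seg, weights=np.exp(ov), minlength=nb)
    ok = ysum > 0
    beta = np.where(ok, np.log(np.maximum(ysum, 1e-300)) - np.log(esum), np.nan)
    active = ok.copy()
    for _ in range(_NEWTON_MAXITER):
        if not active.any():
            break
        mu = np.exp(np.where(np.isfinite(beta[seg]), beta[seg], 0.0) + ov)
        score = np.bincount(seg, weights=(yv - mu) / (1 + alpha * mu), minlength=nb)
        info = np.bincount(seg, weights=mu * (1 + alpha * yv) / (1 + alpha * mu) ** 2, minlength=nb)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.clip(score / info, -_NEWTON_STEP_CAP, _NEWTON_STEP_CAP)
        step = np.where(active & (info > 0), step, 0.0)
        beta = beta + step
        active &= np.abs(step) >= _NEWTON_TOL
    mu = np.exp(np.where(np.isfinite(beta[seg]), beta[seg], 0.0) + ov)
    info = np.bincount(seg, weights=mu * (1 + alpha * yv) / (1 + alpha * mu) ** 2, minlength=nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        zv = np.where(ok & (info > 0), beta * np.sqrt(info), np.nan)
    z[np.flatnonzero(valid)] = zv
    return z


def distilled_z_all_cells(y, x, offsets, alpha: float) -> DistilledStat:
    """All-cells route to the distilled statistic.

    Maximizes the offset-model likelihood summed over *every* cell, with
    x as the single regressor in the linear predictor (log mu_i =
    x_i beta + o_i). Cells without the gRNA contribute a constant, so
    this must agree with the treated-cells-only acceleration; it is kept
    as the cross-check for that shortcut.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    o = np.asarray(offsets, dtype=float)
    if x.sum() == 0:
        raise ValueError("no cells carry the gRNA (x is all zeros)")
    if np.sum(x * y) == 0:
        raise FloatingPointError("treated-cell counts are all zero; beta diverges")
    beta = np.log(np.sum(x * y)) - np.log(np.sum(x * np.exp(o)))
    converged = False
    for _ in range(_NEWTON_MAXITER):
        mu = np.exp(x * beta + o)
        score = np.sum(x * (y - mu) / (1 + alpha * mu))
        info = np.sum(x * mu * (1 + alpha * y) / (1 + alpha * mu) ** 2)
        step = np.clip(score / info, -_NEWTON_STEP_CAP, _NEWTON_STEP_CAP)
        beta += step
        if abs(step) < _NEWTON_TOL:
            converged = True
            break
    if not converged:
        raise FloatingPointError("all-cells distilled NB fit failed to converge")
    mu = np.exp(x * beta + o)
    info = np.sum(x * mu * (1 + alpha * y) / (1 + alpha * mu) ** 2)
    return DistilledStat(beta_hat=float(beta), z_value=float(beta * np.sqrt(info)), n_treated=int(x.sum()))


def full_nb_z(y, x, Z, alpha: float) -> float:
    """Wald z for the gRNA coefficient in the joint NB regression on (x, Z).

    The non-distilled statistic; also serves as the plain parametric NB
    comparison method when its z is referred to a standard normal.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != y.size:
        Z = Z.T
    if x.sum() == 0:
        raise ValueError("no cells carry the gRNA (x is all zeros)")
    if y.sum() == 0:
        raise ValueError("all-zero counts: gene unexpressed")
    design = sm.add_constant(np.column_stack([x, Z]), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, design, family=_nb_family(alpha)).fit(maxiter=GLM_MAXITER, tol=GLM_TOL)
    return float(res.params[1] / res.bse[1])


def parametric_pvalue(z: float, tail: str = "two") -> float:
    """Standard-normal tail probability for a z-score.

    two-sided = 2 * min(left, right), capped at 1.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    left = scipy.stats.norm.cdf(z)
    right = scipy.stats.norm.sf(z)
    if tail == "left":
        p = left
    elif tail == "right":
        p = right
    elif tail == "two":
        p = 2 * min(left, right)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(min(max(p, np.nextafter(0, 1)), 1.0))
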