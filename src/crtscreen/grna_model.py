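"""gRNA propensity modelling and conditional resampling.

In a high-MOI screen, whether a gRNA is detected in a cell depends on
technical factors (sequencing depth, batch, ...) that also drive
measured expression — the confounding the conditional randomization
test removes. This module fits the per-cell probability of gRNA
presence by logistic regression of the binary indicator X on the
technical covariates Z,

    X_i ~ Bernoulli(pi_i),  logit(pi_i) = tau0 + Z_i' tau,

and draws independent Bernoulli resamples of X from the fitted
probabilities, holding Y and Z fixed. The propensity fit depends only
on (X, Z), so one fit per gRNA serves every gene paired with it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

logger = logging.getLogger("crtscreen")

PROB_CLIP = 1e-8  # keeps log(pi) and log(1-pi) finite in diagnostics
DEFAULT_RIDGE = 1e-4
_SEPARATION_COEF_LIMIT = 30.0  # |coef| on standardized covariates beyond this => separation


@dataclass
class GrnaPropensityFit:
    intercept: float
    coefficients: np.ndarray
    probabilities: np.ndarray  # strictly inside (0, 1), one per cell
    regularization_used: bool


def _standardize(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (Z - mean) / sd, mean, sd


def fit_grna_propensity(x, Z, ridge: float = DEFAULT_RIDGE) -> GrnaPropensityFit:
    """Logistic MLE of gRNA presence on technical covariates.

    Falls back to a small ridge penalty (``ridge``, applied on
    standardized covariates) when the unpenalized fit shows separation
    — diverging coefficients or non-convergence — which rare gRNAs
    crossed with small batches can produce. Set ``ridge=0`` to disable
    the fallback (separation then raises). Fitted probabilities are
    clipped away from 0 and 1.
    """
    x = np.asarray(x, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.size == 0:
        Z = Z.reshape(x.size, 0)
    elif Z.shape[0] != x.size:
        Z = Z.T
    if Z.shape[0] != x.size:
        raise ValueError("Z row count must equal length of x")
    n1 = x.sum()
    if n1 == 0 or n1 == x.size:
        raise ValueError("x is constant; propensity model is undefined")

    if Z.shape[1] == 0:
        p = n1 / x.size
        probs = np.full(x.size, p)
        return GrnaPropensityFit(
            intercept=float(np.log(p / (1 - p))),
            coefficients=np.empty(0),
            probabilities=np.clip(probs, PROB_CLIP, 1 - PROB_CLIP),
            regularization_used=False,
        )

    Zs, mean, sd = _standardize(Z)
    design = sm.add_constant(Zs, has_constant="add")
    params = None
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(x, design, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
        params = np.asarray(res.params, dtype=float)
        if (not res.converged or not np.all(np.isfinite(params))
                or np.any(np.abs(params[1:]) > _SEPARATION_COEF_LIMIT)):
            separated = True
    except Exception:
        separated = True

    used_ridge = False
    if separated:
        if ridge <= 0:
            raise ValueError("separation detected and ridge fallback disabled")
        logger.warning("separation detected in propensity fit; refitting with ridge %.1e", ridge)
        clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=1000)
        clf.fit(Zs, x)
        params = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        used_ridge = True

    # map standardized-scale coefficients back to the original covariate scale
    coef = params[1:] / sd
    intercept = params[0] - np.sum(params[1:] * mean / sd)
    eta = intercept + Z @ coef
    probs = np.clip(1.0 / (1.0 + np.exp(-eta)), PROB_CLIP, 1 - PROB_CLIP)
    return GrnaPropensityFit(
        intercept=float(intercept),
        coefficients=coef,
        probabilities=probs,
        regularization_used=used_ridge,
    )


def resample_grna(probabilities, B: int, seed) -> np.ndarray:
    """Draw B independent Bernoulli resamples of the gRNA indicator vector.

    Each row b is one resampled indicator vector: X~b_i ~ Ber(pi_i)
    independently across cells, with Y and Z untouched by construction.
    Deterministic given the seed (an int or a numpy Generator).
    """
    probs = np.asarray(probabilities, dtype=float)
    if B < 1:
        raise ValueError("B must be >= 1")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return (rng.random((B, probs.size)) < probs).astype(np.int8)
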