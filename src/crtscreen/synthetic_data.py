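"""Synthetic screens with confounded gRNA presence and ZINB expression.

The generator reproduces the statistical structure the conditional
randomization test is built for, in its simplest honest form: two
technical confounders per cell (a binary batch indicator and a
log-scale sequencing depth), gRNA presence drawn from a logistic model
on those confounders, and expression drawn from a zero-inflated
negative binomial whose mean depends on the same confounders — so gRNA
presence and expression are dependent even when the gRNA has no effect.

Defaults follow the calibration study design: tau = (-7, -2, 0.5) and
beta = (-2.5, -2, 0.5), with the depth distribution (lognormal,
log-mean 8.9, log-sd 0.3) calibrated once by Monte Carlo so that the
design's two stated properties hold — mean gRNA presence probability
about 0.04 and mean expression about 4 across cells. Four study
settings vary the true dispersion and zero-inflation rate while the
analysis dispersion stays fixed at 1, so the count model is correctly
specified only in the first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import special

from .crt_engine import crt_pvalue, fit_skew_t
from .data_io import CellData, CovariateTable, ExpressionMatrix, build_grna_matrix
from .expression_model import distilled_z, distilled_z_resamples, fit_reduced_nb, full_nb_z, parametric_pvalue
from .grna_model import fit_grna_propensity, resample_grna
from .pairs_and_calibration import ks_uniformity

logger = logging.getLogger("crtscreen")

# (zero-inflation rate lambda, true dispersion alpha); the analysis
# dispersion is fixed at 1, so only setting 1 is correctly specified
CALIBRATION_SETTINGS = {
    1: (0.0, 1.0),
    2: (0.0, 5.0),
    3: (0.0, 0.2),
    4: (0.25, 1.0),
}
ANALYSIS_DISPERSION = 1.0


@dataclass
class SimConfig:
    """Generative parameters for one synthetic screen."""

    n_cells: int = 1000
    tau: tuple = (-7.0, -2.0, 0.5)      # gRNA propensity: intercept, batch, log-depth
    beta: tuple = (-2.5, -2.0, 0.5)     # expression mean: intercept, batch, log-depth
    alpha: float = 1.0                  # true NB dispersion
    lam: float = 0.0                    # zero-inflation rate
    batch_prob: float = 0.5
    depth_log_mean: float = 8.9         # natural-log scale of the lognormal depth
    depth_log_sd: float = 0.3
    n_sim: int = 500
    B: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.lam <= 1) or not (0 <= self.batch_prob <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_covariates(n: int, config: SimConfig | None = None, seed=0) -> np.ndarray:
    """Draw the confounder matrix Z = [batch, log-depth], one row per cell."""
    cfg = config or SimConfig()
    rng = _rng(seed)
    batch = rng.binomial(1, cfg.batch_prob, n).astype(float)
    log_depth = rng.normal(cfg.depth_log_mean, cfg.depth_log_sd, n)
    return np.column_stack([batch, log_depth])


def gen_grna_indicators(Z, tau, seed=0) -> np.ndarray:
    """Draw gRNA presence X_i ~ Ber(logistic(tau0 + Z_i' tau))."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    tau = np.asarray(tau, dtype=float)
    if tau.size != 1 + Z.shape[1]:
        raise ValueError("tau must have one intercept plus one entry per covariate")
    rng = _rng(seed)
    eta = tau[0] + Z @ tau[1:]
    pi = special.expit(eta)
    return rng.binomial(1, pi).astype(np.int8)


def gen_zinb_expression(Z, x, beta, alpha: float, lam: float, effect: float = 0.0, seed=0) -> np.ndarray:
    """Draw counts from the zero-inflated NB: lambda*delta0 + (1-lambda)*NB(mu, alpha).

    log mu_i = beta0 + Z_i' beta + x_i * effect; effect = 0 gives the
    null in which gRNA presence never touches expression. NB draws use
    the gamma-Poisson mixture with shape 1/alpha, matching
    Var = mu + alpha * mu^2.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    x = np.asarray(x, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (0 <= lam <= 1):
        raise ValueError("lambda must lie in [0, 1]")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rng = _rng(seed)
    mu = np.exp(beta[0] + Z @ beta[1:] + x * effect)
    gam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    y = rng.poisson(gam)
    if lam > 0:
        y[rng.random(y.size) < lam] = 0
    return y.astype(np.int64)


# ---------------------------------------------------------------------------
# Whole-screen generation (round-trips through data_io formats)
# ---------------------------------------------------------------------------

def gen_screen(
    n_cells: int = 1000,
    n_genes: int = 20,
    n_grnas: int = 4,
    config: SimConfig | None = None,
    seed: int = 0,
) -> CellData:
    """Generate a small multi-gene, multi-gRNA screen as a CellData bundle.

    Every gene is null with respect to every gRNA; genes share the
    generative betas up to jittered intercepts so expression levels
    vary. gRNA UMI counts are emitted so that thresholding at the
    default reproduces the simulated assignments.
    """
    cfg = config or SimConfig(n_cells=n_cells)
    rng = _rng(seed)
    Z = gen_covariates(n_cells, cfg, rng)
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    gene_ids = [f"gene{j:04d}" for j in range(n_genes)]
    grna_ids = [f"grna{k:03d}" for k in range(n_grnas)]

    x_rows = [gen_grna_indicators(Z, cfg.tau, rng) for _ in grna_ids]
    # carrier cells get a UMI count safely above the assignment threshold
    umi = np.vstack([x * (5 + rng.poisson(10, n_cells)) for x in x_rows])
    grna = build_grna_matrix(sp.csr_matrix(umi), grna_ids, cell_ids, threshold=5)

    counts = np.vstack(
        [
            gen_zinb_expression(
                Z, np.zeros(n_cells),
                (cfg.beta[0] + rng.normal(0, 0.3),) + tuple(cfg.beta[1:]),
                cfg.alpha, cfg.lam, seed=rng,
            )
            for _ in gene_ids
        ]
    )
    # guarantee no empty cells so covariate logs are defined
    empty = counts.sum(axis=0) == 0
    counts[0, empty] = 1
    expr = ExpressionMatrix(sp.csr_matrix(counts), gene_ids, cell_ids)

    table = pd.DataFrame(
        {
            "batch": pd.Categorical(np.where(Z[:, 0] > 0, "batch2", "batch1")),
            "log_total_umis": np.log(counts.sum(axis=0)),
            "log_n_genes_expressed": np.log((counts > 0).sum(axis=0)),
            "pct_mito": np.zeros(n_cells),
            "log_n_grnas": np.log1p(np.asarray(grna.assignments.sum(axis=0)).ravel()),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return CellData(expr=expr, grna=grna, covariates=CovariateTable(table))


# ---------------------------------------------------------------------------
# Calibration study
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Per-method p-value matrices and summary diagnostics for the study."""

    p_values: dict           # (setting, method) -> array of p-values
    ks: pd.DataFrame         # columns: setting, method, ks_stat, ks_pvalue
    type_i_error: pd.DataFrame  # columns: setting, method, nominal, rate, n
    n_failed: dict           # (setting, method) -> excluded repetitions


def simulate_null_pvalue(
    cfg: SimConfig,
    rng: np.random.Generator,
    analysis_alpha: float = ANALYSIS_DISPERSION,
    tail: str = "two",
    methods: tuple = ("sceptre", "nb_parametric"),
    known_propensity: bool = False,
) -> dict:
    """One calibration repetition: simulate a null pair, return each method's p-value.

    ``known_propensity`` resamples from the true generative pi_i instead
    of refitting the logistic model (used to isolate the resampling
    null's validity from propensity estimation).
    """
    Z = gen_covariates(cfg.n_cells, cfg, rng)
    x = gen_grna_indicators(Z, cfg.tau, rng)
    y = gen_zinb_expression(Z, x, cfg.beta, cfg.alpha, cfg.lam, effect=0.0, seed=rng)
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("degenerate repetition (no carriers or all-zero counts)")
    out = {}
    if "nb_parametric" in methods:
        out["nb_parametric"] = parametric_pvalue(full_nb_z(y, x, Z, analysis_alpha), tail)
    if "sceptre" in methods:
        reduced = fit_reduced_nb(y, Z, analysis_alpha)
        obs = distilled_z(y, x, reduced.offsets, analysis_alpha)
        if known_propensity:
            tau = np.asarray(cfg.tau)
            probs = special.expit(tau[0] + Z @ tau[1:])
        else:
            probs = fit_grna_propensity(x, Z).probabilities
        resamples = resample_grna(probs, cfg.B, rng)
        idx = [np.flatnonzero(row) for row in resamples]
        z_null = distilled_z_resamples(y, reduced.offsets, analysis_alpha, idx)
        z_null = z_null[np.isfinite(z_null)]
        null = fit_skew_t(z_null)
        p, _ = crt_pvalue(obs.z_value, null, tail)
        out["sceptre"] = p
    return out


def run_calibration_study(
    settings=(1, 2, 3, 4),
    n_sim: int = 500,
    methods: tuple = ("sceptre", "nb_parametric"),
    seed: int = 0,
    n_cells: int = 1000,
    B: int = 500,
    analysis_alpha: float = ANALYSIS_DISPERSION,
    tail: str = "two",
    nominal_levels: tuple = (0.01, 0.05, 0.1),
) -> CalibrationResult:
    """Run the four-setting null calibration study.

    For each setting, ``n_sim`` independent null screens are simulated
    and analyzed by each method at the fixed analysis dispersion; the
    result collects p-value vectors, KS uniformity diagnostics, and
    empirical type-I error at the nominal levels. Repetitions whose
    fits fail are excluded with logged counts.
    """
    bad = set(methods) - {"sceptre", "nb_parametric"}
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    p_values: dict = {(s, m): [] for s in settings for m in methods}
    n_failed: dict = {(s, m): 0 for s in settings for m in methods}
    master = np.random.SeedSequence(seed)
    for s, child in zip(settings, master.spawn(len(settings))):
        lam, alpha_true = CALIBRATION_SETTINGS[s]
        cfg = SimConfig(n_cells=n_cells, alpha=alpha_true, lam=lam, B=B)
        rng = np.random.default_rng(child)
        for _ in range(n_sim):
            try:
                rep = simulate_null_pvalue(cfg, rng, analysis_alpha, tail, methods)
            except (ValueError, FloatingPointError) as exc:
                logger.info("setting %d repetition failed: %s", s, exc)
                for m in methods:
                    n_failed[(s, m)] += 1
                continue
            for m in methods:
                p_values[(s, m)].append(rep[m])

    ks_rows, t1_rows = [], []
    for (s, m), plist in p_values.items():
        p = np.asarray(plist)
        p_values[(s, m)] = p
        stat, pval = ks_uniformity(p)
        ks_rows.append({"setting": s, "method": m, "ks_stat": stat, "ks_pvalue": pval})
        for t in nominal_levels:
            t1_rows.append(
                {"setting": s, "method": m, "nominal": t,
                 "rate": float(np.mean(p <= t)), "n": p.size}
            )
        if n_failed[(s, m)]:
            logger.warning("setting %d, %s: %d repetitions excluded", s, m, n_failed[(s, m)])
    return CalibrationResult(
        p_values=p_values,
        ks=pd.DataFrame(ks_rows),
        type_i_error=pd.DataFrame(t1_rows),
        n_failed=n_failed,
    )
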