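"""Second-stage regression of architecture measures on dimorphism.

Each trait contributes a joint posterior over an architecture measure
(Fisher-z rfmK, log variance ratio, or log Riemannian distance) and
the SD index. To propagate that uncertainty, many resampled datasets
are formed — each takes one joint posterior draw per trait — a short
Bayesian simple-regression chain is run on each, and inference pools
the concatenated chains. The pooled intercept is the measure expected
at monomorphism (SD index 0).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from sexarch.core_data import AnalysisConfig

logger = logging.getLogger(__name__)

MEASURES = ("fisher_z_rfmk", "log_variance_ratio", "log_riemann_distance")


def sample_measure_datasets(trait_posteriors: list[pd.DataFrame],
                            measure: str = "fisher_z_rfmk",
                            n_draws: int = 500, *, seed: int = 0
                            ) -> np.ndarray:
    """Resample joint (SD index, measure) datasets from trait posteriors.

    ``trait_posteriors`` holds one draw-aligned table per trait (see
    ``derived.TraitSummaries.measure_draws``) with columns for the
    measures and ``sd_index``. Traits whose SD index was not computed
    are excluded with a logged count. Each of the ``n_draws`` output
    datasets takes one independent joint draw per trait, preserving
    the within-trait posterior correlation of measure and dimorphism.
    Returns an array shaped (n_draws, n_traits, 2) ordered (x=sd_index,
    y=measure).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; options: {MEASURES}")
    usable = []
    n_dropped = 0
    for tp in trait_posteriors:
        if measure not in tp.columns or "sd_index" not in tp.columns \
                or tp["sd_index"].isna().all():
            n_dropped += 1
            continue
        usable.append(tp[["sd_index", measure]].dropna().to_numpy(float))
    if n_dropped:
        logger.info("excluding %d trait(s) without an SD index", n_dropped)
    if len(usable) < 3:
        raise ValueError("need at least 3 traits with joint posteriors")

    rng = np.random.default_rng(seed)
    out = np.empty((n_draws, len(usable), 2))
    for t, arr in enumerate(usable):
        idx = rng.integers(len(arr), size=n_draws)
        out[:, t, :] = arr[idx]
    return out


def _halft_logpost_update(rng, resid, nu, a, scale):
    """One inverse-gamma expansion update of a half-t residual variance."""
    n = len(resid)
    sig2 = (nu / a + 0.5 * float(resid @ resid)) / rng.gamma(0.5 * (nu + n))
    a = (nu / sig2 + 1.0 / scale**2) / rng.gamma(0.5 * (nu + 1.0))
    return sig2, a


def _regression_chain(x: np.ndarray, y: np.ndarray, n_keep: int, warmup: int,
                      rng: np.random.Generator) -> np.ndarray:
    """One Gibbs chain of y ~ a + b x with weakly informative priors.

    Priors: slope N(0, 2.5 sd(y)/sd(x)), intercept N(mean(y),
    2.5 sd(y)), residual sd half-t(5, sd(y)). Returns (n_keep, 2)
    draws of (intercept, slope).
    """
    n = len(y)
    sdx = float(np.std(x)) or 1.0
    sdy = float(np.std(y)) or 1.0
    prior_mean = np.array([float(np.mean(y)), 0.0])
    prior_prec = np.diag([1.0 / (2.5 * sdy) ** 2, 1.0 / (2.5 * sdy / sdx) ** 2])
    X = np.column_stack([np.ones(n), x])
    XtX = X.T @ X
    Xty = X.T @ y

    sig2 = max(sdy**2, 1e-12)
    a_aux = 1.0
    nu = 5.0
    out = np.empty((n_keep, 2))
    for it in range(warmup + n_keep):
        prec = XtX / sig2 + prior_prec
        mean = np.linalg.solve(prec, Xty / sig2 + prior_prec @ prior_mean)
        L = np.linalg.cholesky(prec)
        beta = mean + np.linalg.solve(L.T, rng.standard_normal(2))
        resid = y - X @ beta
        sig2, a_aux = _halft_logpost_update(rng, resid, nu, a_aux, sdy)
        sig2 = max(sig2, 1e-30)
        if it >= warmup:
            out[it - warmup] = beta
    return out


def fit_pooled_regression(datasets: np.ndarray,
                          config: AnalysisConfig | None = None,
                          *, n_keep: int = 1000, warmup: int = 200,
                          seed: int = 0, max_failure_frac: float = 0.10
                          ) -> dict:
    """Pool short regression chains across resampled datasets.

    Runs one chain per dataset and concatenates the draws; the pooled
    posterior mixes over the trait-level uncertainty the datasets
    carry. Individual chain failures are dropped with a warning; more
    than ``max_failure_frac`` failing is an error. Returns medians and
    95% CIs of slope and intercept plus the pooled draws.
    """
    datasets = np.asarray(datasets, float)
    if datasets.ndim != 3 or datasets.shape[0] < 2:
        raise ValueError("need a (n_datasets, n_traits, 2) array with >= 2 datasets")
    seeds = np.random.SeedSequence(seed).spawn(datasets.shape[0])
    chains = []
    n_failed = 0
    for d, ss in zip(datasets, seeds):
        try:
            chains.append(_regression_chain(d[:, 0], d[:, 1], n_keep, warmup,
                                            np.random.default_rng(ss)))
        except np.linalg.LinAlgError as err:
            n_failed += 1
            logger.warning("dropping failed chain: %s", err)
    if n_failed > max_failure_frac * datasets.shape[0]:
        raise RuntimeError(f"{n_failed} of {datasets.shape[0]} chains failed")

    pooled = np.concatenate(chains, axis=0)
    inter, slope = pooled[:, 0], pooled[:, 1]
    lo_i, hi_i = np.percentile(inter, [2.5, 97.5])
    lo_s, hi_s = np.percentile(slope, [2.5, 97.5])
    return {
        "slope_median": float(np.median(slope)),
        "slope_lo95": float(lo_s), "slope_hi95": float(hi_s),
        "intercept_median": float(np.median(inter)),
        "intercept_lo95": float(lo_i), "intercept_hi95": float(hi_i),
        "n_datasets": int(datasets.shape[0] - n_failed),
        "draws": pooled,
    }
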