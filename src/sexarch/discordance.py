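"""Concordant/discordant genotype effects across traits.

The shrunken per-genotype sex-specific effects (u_f, u_m) from each
trait's model are rotated 45 degrees so the concordant axis is the
positive diagonal (female = male) and the discordant axis the
negative diagonal (female = -male); absolute positions along both
axes are converted to percentile ranks within each trait and
posterior draw. Genotypes tested on enough traits are then classified
as more or less discordant than average by whether the credible
interval of their cross-trait mean rank clears the 50th percentile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

MORE_DISCORDANT = "more_discordant"
LESS_DISCORDANT = "less_discordant"
INDISTINGUISHABLE = "indistinguishable"

_SQRT2 = np.sqrt(2.0)


@dataclass
class RankResult:
    """Cross-trait average percentile ranks of one genotype."""

    genotype_id: str
    n_traits_tested: int
    mean_concordant_rank: float
    mean_discordant_rank: float
    concordant_ci: tuple[float, float]
    discordant_ci: tuple[float, float]
    discordance_class: str
    concordance_class: str

    def to_row(self) -> dict:
        return {
            "genotype_id": self.genotype_id,
            "n_traits_tested": self.n_traits_tested,
            "mean_concordant_rank": self.mean_concordant_rank,
            "mean_discordant_rank": self.mean_discordant_rank,
            "concordant_lo95": self.concordant_ci[0],
            "concordant_hi95": self.concordant_ci[1],
            "discordant_lo95": self.discordant_ci[0],
            "discordant_hi95": self.discordant_ci[1],
            "discordance_class": self.discordance_class,
            "concordance_class": self.concordance_class,
        }


def rotate_effects(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Absolute concordant and discordant components of (u_f, u_m).

    ``concordant = |u_f + u_m| / sqrt(2)``, ``discordant =
    |u_f - u_m| / sqrt(2)``; the rotation is orthogonal, so
    concordant^2 + discordant^2 = u_f^2 + u_m^2.
    """
    u = np.asarray(u, float)
    conc = np.abs(u[..., 0] + u[..., 1]) / _SQRT2
    disc = np.abs(u[..., 0] - u[..., 1]) / _SQRT2
    return conc, disc


def rotate_and_rank(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Percentile ranks of both axes within one trait, per posterior draw.

    ``u`` has shape (draws, J, 2); returns two (draws, J) arrays of
    percentile ranks on (0, 100], average ranks at ties. Ranks are
    invariant to any positive rescaling of the axes.
    """
    if u.ndim != 3 or u.shape[1] < 2:
        raise ValueError("need draws of (u_f, u_m) for at least 2 genotypes")
    conc, disc = rotate_effects(u)
    J = u.shape[1]
    conc_rank = rankdata(conc, axis=1, method="average") / J * 100.0
    disc_rank = rankdata(disc, axis=1, method="average") / J * 100.0
    return conc_rank, disc_rank


def _classify(ci: tuple[float, float]) -> str:
    if ci[0] > 50.0:
        return MORE_DISCORDANT
    if ci[1] < 50.0:
        return LESS_DISCORDANT
    return INDISTINGUISHABLE


def aggregate_and_classify(per_trait_ranks: dict[str, tuple[np.ndarray, np.ndarray, list[str]]],
                           min_traits: int = 100, n_rank_draws: int = 100,
                           *, seed: int = 0) -> list[RankResult]:
    """Average ranks across traits and classify against the median rank.

    ``per_trait_ranks`` maps trait name to ``(concordant_ranks,
    discordant_ranks, genotype_ids)`` with rank arrays shaped
    (draws, J). Only genotypes tested on at least ``min_traits`` traits
    are assessed. Point estimates average the per-trait posterior-mean
    ranks; 95% CIs resample ``n_rank_draws`` joint posterior draws,
    using the same draw fraction across traits to preserve cross-trait
    dependence within a genotype.
    """
    counts: dict[str, int] = {}
    for _, (_, _, ids) in per_trait_ranks.items():
        for g in ids:
            counts[g] = counts.get(g, 0) + 1
    eligible = sorted(g for g, c in counts.items() if c >= min_traits)
    if not eligible:
        logger.warning("no genotype tested on >= %d traits", min_traits)
        return []

    rng = np.random.default_rng(seed)
    fracs = rng.uniform(size=n_rank_draws)

    results = []
    col = {g: i for i, g in enumerate(eligible)}
    n_eligible = len(eligible)
    sum_conc = np.zeros(n_eligible)
    sum_disc = np.zeros(n_eligible)
    n_traits = np.zeros(n_eligible, dtype=int)
    res_conc = np.zeros((n_rank_draws, n_eligible))
    res_disc = np.zeros((n_rank_draws, n_eligible))

    for trait, (conc, disc, ids) in per_trait_ranks.items():
        idx = [(col[g], j) for j, g in enumerate(ids) if g in col]
        if not idx:
            continue
        cols = np.array([c for c, _ in idx])
        js = np.array([j for _, j in idx])
        n_draws = conc.shape[0]
        sum_conc[cols] += conc[:, js].mean(axis=0)
        sum_disc[cols] += disc[:, js].mean(axis=0)
        n_traits[cols] += 1
        draw_idx = np.minimum((fracs * n_draws).astype(int), n_draws - 1)
        res_conc[:, cols] += conc[draw_idx][:, js]
        res_disc[:, cols] += disc[draw_idx][:, js]

    for g in eligible:
        i = col[g]
        nt = int(n_traits[i])
        if nt < min_traits:
            continue
        conc_ci = tuple(np.percentile(res_conc[:, i] / nt, [2.5, 97.5]))
        disc_ci = tuple(np.percentile(res_disc[:, i] / nt, [2.5, 97.5]))
        disc_mean = sum_disc[i] / nt
        conc_mean = sum_conc[i] / nt
        conc_class = ("more_concordant" if conc_ci[0] > 50.0 else
                      "less_concordant" if conc_ci[1] < 50.0 else
                      INDISTINGUISHABLE)
        results.append(RankResult(
            genotype_id=g, n_traits_tested=nt,
            mean_concordant_rank=float(conc_mean),
            mean_discordant_rank=float(disc_mean),
            concordant_ci=(float(conc_ci[0]), float(conc_ci[1])),
            discordant_ci=(float(disc_ci[0]), float(disc_ci[1])),
            discordance_class=_classify(disc_ci),
            concordance_class=conc_class,
        ))
    return results


def approximate_effect_posterior(data, gcov, sigma_resid: float,
                                 n_draws: int = 200, *, seed: int = 0
                                 ) -> tuple[np.ndarray, list[str]]:
    """Conditional genotype-effect posterior at known hyperparameters.

    Removes per-sex means by least squares, then samples each
    genotype's (u_f, u_m) from its exact bivariate-normal conditional
    given the G matrix and residual SD: precision ``G^{-1} +
    diag(n_f, n_m)/sigma^2`` and mean pulled from the cell sums. This
    is the shrinkage (BLUP-style) posterior the full model produces
    when the hyperparameters are well identified, at a fraction of the
    cost; environmental structure is absorbed into the residual.
    Returns draws shaped (n_draws, J, 2) and the genotype order.
    """
    df = data.table
    y = df["phenotype"].to_numpy(float)
    male = (df["sex"] == "male").to_numpy()
    y = y - np.where(male, y[male].mean(), y[~male].mean())

    geno = df["genotype_id"].astype("category")
    ids = list(geno.cat.categories)
    J = len(ids)
    cell = 2 * geno.cat.codes.to_numpy().astype(np.int64) + male.astype(np.int64)
    counts = np.bincount(cell, minlength=2 * J).reshape(J, 2)
    S = np.bincount(cell, weights=y, minlength=2 * J).reshape(J, 2)

    ginv = np.linalg.inv(gcov.as_matrix())
    sig2 = sigma_resid**2
    l00 = ginv[0, 0] + counts[:, 0] / sig2
    l11 = ginv[1, 1] + counts[:, 1] / sig2
    l01 = ginv[0, 1]
    det = l00 * l11 - l01 * l01
    c00, c11, c01 = l11 / det, l00 / det, -l01 / det
    mf = (c00 * S[:, 0] + c01 * S[:, 1]) / sig2
    mm = (c01 * S[:, 0] + c11 * S[:, 1]) / sig2
    ch00 = np.sqrt(c00)
    ch10 = c01 / ch00
    ch11 = np.sqrt(np.maximum(c11 - ch10**2, 1e-300))

    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal((n_draws, J))
    z2 = rng.standard_normal((n_draws, J))
    u = np.empty((n_draws, J, 2))
    u[:, :, 0] = mf + ch00 * z1
    u[:, :, 1] = mm + ch10 * z1 + ch11 * z2
    return u, ids


def ranks_from_posteriors(trait_draws: dict[str, "PosteriorDraws"]
                          ) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
    """Convenience: rotate-and-rank every trait's genotype-effect draws."""
    out = {}
    for trait, draws in trait_draws.items():
        conc, disc = rotate_and_rank(draws.stacked_u())
        out[trait] = (conc, disc, list(draws.genotype_ids))
    return out


def results_frame(results: list[RankResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
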