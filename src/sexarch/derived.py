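"""Derived measures of sex-specific genetic architecture.

From the joint posterior of the mixed model this module computes, per
trait: the between-sex genetic correlation rfmK and its Fisher
z-transform; the ratio of sex-specific genetic variances (ordered
larger/smaller, and male/female); the Riemannian distance of the
scaled G matrix from the perfect-correlation null; and the sexual
dimorphism (SD) index — the larger-sex wild-type mean over the
smaller-sex mean, minus one — classified against a region of practical
equivalence (ROPE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexarch.core_data import AnalysisConfig, StandardizationSpec, TraitDataset
from sexarch.hier_model import GeneticCovariance, PosteriorDraws
from sexarch.transform import TransformSpec, invert_transform

logger = logging.getLogger(__name__)

CI_LEVELS = (50, 80, 95)

DIMORPHIC = "dimorphic"
MONOMORPHIC = "monomorphic"
UNCLASSIFIED = "unclassified"
NOT_COMPUTED = "not_computed"


@dataclass(frozen=True)
class PosteriorSummary:
    """Median and central credible intervals of one scalar posterior."""

    median: float
    intervals: dict[int, tuple[float, float]]

    @classmethod
    def from_draws(cls, x: np.ndarray, levels=CI_LEVELS) -> "PosteriorSummary":
        x = np.asarray(x, float)
        ivs = {}
        for lev in levels:
            half = (100 - lev) / 2
            lo, hi = np.percentile(x, [half, 100 - half])
            ivs[lev] = (float(lo), float(hi))
        return cls(float(np.median(x)), ivs)

    def ci(self, level: int = 95) -> tuple[float, float]:
        return self.intervals[level]


def summarize_rfmk(draws: PosteriorDraws) -> tuple[PosteriorSummary, PosteriorSummary]:
    """Posterior summaries of rho and of its Fisher z-transform atanh(rho)."""
    rho = draws.stacked("rho")
    z = np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12))
    return PosteriorSummary.from_draws(rho), PosteriorSummary.from_draws(z)


def variance_ratio(draws: PosteriorDraws, mode: str = "ordered"
                   ) -> tuple[PosteriorSummary, PosteriorSummary]:
    """Per-draw ratio of sex-specific genetic variances, plus its log.

    ``ordered`` folds the ratio so the larger variance is always on
    top (ratio >= 1 in every draw); ``m_over_f`` keeps the male/female
    orientation.
    """
    vf = np.square(draws.stacked("sigma_f"))
    vm = np.square(draws.stacked("sigma_m"))
    bad = (vf <= 0) | (vm <= 0)
    if bad.any():
        logger.warning("excluding %d draw(s) with zero genetic variance",
                       int(bad.sum()))
        vf, vm = vf[~bad], vm[~bad]
    if mode == "ordered":
        ratio = np.maximum(vf, vm) / np.minimum(vf, vm)
    elif mode == "m_over_f":
        ratio = vm / vf
    else:
        raise ValueError("mode must be 'ordered' or 'm_over_f'")
    return (PosteriorSummary.from_draws(ratio),
            PosteriorSummary.from_draws(np.log(ratio)))


def riemannian_distance(sigma_f, sigma_m, rho, epsilon: float = 1e-3
                        ) -> np.ndarray | float:
    """Affine-invariant distance of the scaled G matrix from the null.

    G is scaled by the mean of its diagonal, so equal variances with
    rho -> 1 approach the all-ones matrix; the singular null is
    regularized to [[1, 1-eps], [1-eps, 1]]. The distance is
    ``||log(N^{-1/2} S N^{-1/2})||_F``, computed from the generalized
    eigenvalues of (S, N). Accepts scalars or aligned draw arrays.
    """
    sf = np.asarray(sigma_f, float)
    sm = np.asarray(sigma_m, float)
    r = np.asarray(rho, float)
    scale = 0.5 * (sf**2 + sm**2)
    s00 = sf**2 / scale
    s11 = sm**2 / scale
    s01 = r * sf * sm / scale
    det_s = s00 * s11 - s01 * s01
    if np.any(det_s <= 0):
        raise ValueError("scaled G matrix is not positive definite")
    one = 1.0 - epsilon
    det_n = 1.0 - one * one
    tr = (s00 + s11 - 2.0 * one * s01) / det_n
    det_m = det_s / det_n
    disc = np.sqrt(np.maximum(tr * tr - 4.0 * det_m, 0.0))
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    d = np.sqrt(np.log(lam1) ** 2 + np.log(lam2) ** 2)
    return float(d) if d.ndim == 0 else d


def riemannian_summary(draws: PosteriorDraws, epsilon: float = 1e-3
                       ) -> tuple[PosteriorSummary, PosteriorSummary]:
    """Posterior summary of the distance and of its log."""
    d = riemannian_distance(draws.stacked("sigma_f"), draws.stacked("sigma_m"),
                            draws.stacked("rho"), epsilon)
    d = np.maximum(d, 1e-300)
    return PosteriorSummary.from_draws(d), PosteriorSummary.from_draws(np.log(d))


@dataclass
class SDResult:
    """Wild-type dimorphism posteriors on the raw measurement scale."""

    sd_index: PosteriorSummary | None
    sd_ratio_fm: PosteriorSummary | None
    frac_flagged: float
    computed: bool
    sd_index_draws: np.ndarray | None = None


def wildtype_sd_index(draws: PosteriorDraws, spec: TransformSpec | None,
                      std: StandardizationSpec, data: TraitDataset,
                      *, max_flagged: float = 0.05) -> SDResult:
    """Posterior of wild-type sexual dimorphism on the original scale.

    Per draw, the female and male marginal means are predicted for
    each control genotype at average body mass, averaged across
    control backgrounds, and mapped back to the raw scale
    (inverse-transform, then un-standardize). The SD index
    larger/smaller - 1 needs a ratio-scale trait; the signed
    female/male ratio is computed alongside. Draws whose
    back-transformed mean is not positive are flagged; if more than
    ``max_flagged`` of draws are flagged the index is not computed.
    """
    ctrl = draws.control_mask
    if not ctrl.any():
        raise ValueError("no control genotypes in the fitted model")
    mu = draws.stacked("mu")
    beta_sex = draws.stacked("beta_sex")
    u = draws.stacked_u()[:, ctrl, :]            # (draws, n_ctrl, 2)
    female = mu + u[:, :, 0].mean(axis=1)
    male = mu + beta_sex + u[:, :, 1].mean(axis=1)

    def back(v: np.ndarray) -> np.ndarray:
        if spec is not None:
            v = invert_transform(v, spec)
        return np.asarray(std.unstandardize_phenotype(v))

    raw_f, raw_m = back(female), back(male)
    ratio_fm = PosteriorSummary.from_draws(raw_f / raw_m)

    if not data.ratio_scale:
        return SDResult(None, ratio_fm, 0.0, False)

    flagged = (raw_f <= 0) | (raw_m <= 0)
    frac = float(flagged.mean())
    if frac > max_flagged:
        logger.warning("trait %r: %.1f%% of draws back-transform to "
                       "non-positive means; SD index not computed",
                       data.trait_name, 100 * frac)
        return SDResult(None, ratio_fm, frac, False)
    f, m = raw_f[~flagged], raw_m[~flagged]
    idx = np.maximum(f, m) / np.minimum(f, m) - 1.0
    return SDResult(PosteriorSummary.from_draws(idx), ratio_fm, frac, True,
                    sd_index_draws=idx)


def rope_classify(sd: PosteriorSummary | None,
                  rope: tuple[float, float] = (0.0, 0.05)) -> str:
    """Equivalence-test the SD index 95% CI against the ROPE.

    Dimorphic when the whole CI exceeds the ROPE's upper bound;
    monomorphic when it lies entirely below it (the index is
    nonnegative, so containment reduces to the upper bound).
    """
    if sd is None:
        return NOT_COMPUTED
    lo, hi = sd.ci(95)
    if lo > rope[1]:
        return DIMORPHIC
    if hi < rope[1]:
        return MONOMORPHIC
    return UNCLASSIFIED


@dataclass
class TraitSummaries:
    """All per-trait derived posteriors plus the ROPE class."""

    trait_name: str
    rfmk: PosteriorSummary
    fisher_z: PosteriorSummary
    var_ratio_ordered: PosteriorSummary
    log_var_ratio_ordered: PosteriorSummary
    var_ratio_mf: PosteriorSummary
    log_var_ratio_mf: PosteriorSummary
    riemann: PosteriorSummary
    log_riemann: PosteriorSummary
    sd: SDResult
    rope_class: str
    measure_draws: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def to_row(self) -> dict:
        def unpack(prefix: str, s: PosteriorSummary | None) -> dict:
            if s is None:
                return {f"{prefix}_median": np.nan,
                        f"{prefix}_lo95": np.nan, f"{prefix}_hi95": np.nan}
            lo95, hi95 = s.ci(95)
            out = {f"{prefix}_median": s.median,
                   f"{prefix}_lo95": lo95, f"{prefix}_hi95": hi95}
            if 80 in s.intervals:
                out[f"{prefix}_lo80"], out[f"{prefix}_hi80"] = s.ci(80)
            if 50 in s.intervals:
                out[f"{prefix}_lo50"], out[f"{prefix}_hi50"] = s.ci(50)
            return out

        row = {"trait_name": self.trait_name}
        row.update(unpack("rfmk", self.rfmk))
        row.update(unpack("fisher_z", self.fisher_z))
        row.update(unpack("var_ratio_ordered", self.var_ratio_ordered))
        row.update(unpack("var_ratio_mf", self.var_ratio_mf))
        row.update(unpack("riemann", self.riemann))
        row.update(unpack("sd_index", self.sd.sd_index))
        row.update(unpack("sd_ratio_fm", self.sd.sd_ratio_fm))
        row["rope_class"] = self.rope_class
        return row


def compute_trait_summaries(draws: PosteriorDraws, data: TraitDataset,
                            spec: TransformSpec | None,
                            std: StandardizationSpec,
                            config: AnalysisConfig | None = None,
                            *, epsilon: float = 1e-3) -> TraitSummaries:
    """Assemble every derived measure for one fitted trait.

    ``measure_draws`` carries the aligned per-draw values the
    meta-regression resamples from (Fisher z, log variance ratio, log
    Riemannian distance, SD index).
    """
    config = config or AnalysisConfig()
    rfmk, fisher = summarize_rfmk(draws)
    vro, lvro = variance_ratio(draws, "ordered")
    vrm, lvrm = variance_ratio(draws, "m_over_f")
    rie, lrie = riemannian_summary(draws, epsilon)
    sd = wildtype_sd_index(draws, spec, std, data)
    rope_class = rope_classify(sd.sd_index, config.rope)

    rho = draws.stacked("rho")
    vf = np.square(draws.stacked("sigma_f"))
    vm = np.square(draws.stacked("sigma_m"))
    ratio = np.maximum(vf, vm) / np.minimum(vf, vm)
    dist = riemannian_distance(draws.stacked("sigma_f"),
                               draws.stacked("sigma_m"), rho, epsilon)
    md = pd.DataFrame({
        "fisher_z_rfmk": np.arctanh(np.clip(rho, -1 + 1e-12, 1 - 1e-12)),
        "log_variance_ratio": np.log(ratio),
        "log_riemann_distance": np.log(np.maximum(dist, 1e-300)),
    })
    if sd.computed and sd.sd_index_draws is not None \
            and len(sd.sd_index_draws) == len(md):
        md["sd_index"] = sd.sd_index_draws
    elif sd.computed:
        # some draws were flagged: align by padding with the median
        full = np.full(len(md), sd.sd_index.median)
        full[:len(sd.sd_index_draws)] = sd.sd_index_draws
        md["sd_index"] = full
    else:
        md["sd_index"] = np.nan

    return TraitSummaries(
        trait_name=data.trait_name, rfmk=rfmk, fisher_z=fisher,
        var_ratio_ordered=vro, log_var_ratio_ordered=lvro,
        var_ratio_mf=vrm, log_var_ratio_mf=lvrm,
        riemann=rie, log_riemann=lrie, sd=sd, rope_class=rope_class,
        measure_draws=md)
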