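"""End-to-end per-trait analysis and stratified orchestration.

One call takes a raw trait table through standardization, transform
estimation, the mixed-model fit, convergence checks, and the derived
measures. The stratified runner repeats the analysis independently
per stratum (e.g., body mass by age week).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

from sexarch.core_data import (AnalysisConfig, StandardizationSpec,
                               TraitDataset, split_by_stratum,
                               standardize_and_prepare)
from sexarch.derived import TraitSummaries, compute_trait_summaries
from sexarch.hier_model import (Diagnostics, PosteriorDraws, PriorSpec,
                                diagnostics, fit_model, model_criticism)
from sexarch.transform import TransformSpec, apply_transform, estimate_transform

logger = logging.getLogger(__name__)


@dataclass
class TraitAnalysis:
    """Everything one trait's analysis produced."""

    summaries: TraitSummaries
    draws: PosteriorDraws
    transform_spec: TransformSpec | None
    standardization: StandardizationSpec
    diagnostics: Diagnostics
    criticism_passed: bool
    criticism_reasons: list[str]


def analyze_trait(data: TraitDataset, config: AnalysisConfig | None = None,
                  priors: PriorSpec | None = None, *,
                  use_transform: bool = True,
                  run_diagnostics: bool = True) -> TraitAnalysis:
    """Standardize, transform, fit, check, and summarize one trait."""
    config = config or AnalysisConfig()
    data.check_genotype_count(config)

    std_data, std_spec = standardize_and_prepare(data, config)
    tspec = None
    if use_transform:
        tspec = estimate_transform(std_data, config)
        table = std_data.table.copy()
        table["phenotype"] = apply_transform(
            table["phenotype"].to_numpy(float), tspec)
        std_data = TraitDataset(std_data.trait_name, table,
                                ratio_scale=std_data.ratio_scale,
                                standardization=std_spec)

    draws = fit_model(std_data, spec=tspec, priors=priors, config=config)
    if run_diagnostics:
        diag = diagnostics(draws)
        passed, reasons = model_criticism(diag, config)
        if not passed:
            logger.warning("trait %r fails model criticism: %s",
                           data.trait_name, ", ".join(reasons))
    else:
        diag = Diagnostics(None, None, None)
        passed, reasons = True, []

    summaries = compute_trait_summaries(draws, std_data, tspec, std_spec,
                                        config)
    return TraitAnalysis(summaries=summaries, draws=draws,
                         transform_spec=tspec, standardization=std_spec,
                         diagnostics=diag, criticism_passed=passed,
                         criticism_reasons=reasons)


def analyze_strata(data: TraitDataset, config: AnalysisConfig | None = None,
                   **kwargs) -> dict[str, TraitAnalysis | None]:
    """Run the per-trait analysis independently for every stratum.

    Strata that fail validation are reported as None; each stratum
    gets a distinct seed derived from the configured one.
    """
    config = config or AnalysisConfig()
    out: dict[str, TraitAnalysis | None] = {}
    for i, (name, subset) in enumerate(sorted(split_by_stratum(data).items())):
        if subset is None:
            out[name] = None
            continue
        sub_cfg = dataclasses.replace(config, seed=config.seed + 1000 * (i + 1))
        try:
            out[name] = analyze_trait(subset, sub_cfg, **kwargs)
        except Exception as err:  # noqa: BLE001 - per-stratum isolation
            logger.warning("stratum %r failed: %s", name, err)
            out[name] = None
    return out
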