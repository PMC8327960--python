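"""Shared fixtures: small synthetic panels and one reusable model fit."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sexarch.core_data import AnalysisConfig, TraitDataset, standardize_and_prepare
from sexarch.hier_model import PosteriorDraws, fit_model
from sexarch.synthetic_data import SimulationConfig, simulate_trait


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table() -> pd.DataFrame:
    return pd.DataFrame({
        "phenotype": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "sex": ["female", "male", "female", "male", "female", "male"],
        "genotype_id": ["g1", "g1", "g2", "g2", "wt", "wt"],
        "is_control": [False, False, False, False, True, True],
        "body_mass": [20.0, 25.0, 21.0, 24.0, 19.0, 26.0],
    })


@pytest.fixture
def toy_dataset(toy_table) -> TraitDataset:
    return TraitDataset("toy", toy_table)


@pytest.fixture(scope="session")
def desk_config() -> AnalysisConfig:
    return AnalysisConfig(seed=7).desk_scale()


@pytest.fixture(scope="session")
def fitted_trait(desk_config):
    """One simulated trait (J=150, rho=0.65) with its desk-scale fit.

    Shared across test modules; tests must not mutate the returned
    objects.
    """
    cfg = SimulationConfig(seed=42, intercept=10.0, beta_sex=1.0)
    data, truth = simulate_trait(cfg)
    std, spec = standardize_and_prepare(data, desk_config)
    draws = fit_model(std, config=desk_config)
    return {"data": data, "std": std, "spec": spec, "truth": truth,
            "draws": draws, "sim_config": cfg}


def make_draws(params: dict[str, np.ndarray], u: np.ndarray | None = None,
               genotype_ids: list[str] | None = None,
               control_mask: np.ndarray | None = None,
               chains: int = 2) -> PosteriorDraws:
    """Assemble a PosteriorDraws object from plain arrays for unit tests."""
    first = next(iter(params.values()))
    n = len(np.atleast_1d(first))
    if n % chains:
        raise ValueError("draw count must divide evenly into chains")
    shaped = {k: np.asarray(v, float).reshape(chains, n // chains)
              for k, v in params.items()}
    if u is None:
        u = np.zeros((n, 2, 2))
    J = u.shape[1]
    u = np.asarray(u, float).reshape(chains, n // chains, J, 2)
    if genotype_ids is None:
        genotype_ids = [f"g{j}" for j in range(J)]
    if control_mask is None:
        control_mask = np.zeros(J, bool)
        control_mask[-1] = True
    return PosteriorDraws(params=shaped, u=u, env_effects={},
                          genotype_ids=genotype_ids,
                          control_mask=np.asarray(control_mask, bool),
                          env_levels={}, n_records=0, seed=0)
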