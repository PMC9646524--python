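"""Shared fixtures: cached two-phase solutions and actin ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from viscocell import actin, twophase


@pytest.fixture(scope="session")
def core_params() -> twophase.TwoPhaseParams:
    return twophase.TwoPhaseParams()


@pytest.fixture(scope="session")
def lv_solution(core_params) -> twophase.TwoPhaseSolution:
    return twophase.solve_steady_state(core_params, twophase.LV_REGIME)


@pytest.fixture(scope="session")
def hv_solution(core_params) -> twophase.TwoPhaseSolution:
    return twophase.solve_steady_state(core_params, twophase.HV_REGIME)


@pytest.fixture(scope="session")
def knockdown_solutions(core_params) -> dict[str, twophase.TwoPhaseSolution]:
    kd = twophase.knockdown_nhe1(core_params)
    return {
        "LV": twophase.solve_steady_state(kd, twophase.LV_REGIME),
        "HV": twophase.solve_steady_state(kd, twophase.HV_REGIME),
    }


@pytest.fixture(scope="session")
def actin_ensembles() -> dict[float, actin.EnsembleDensity]:
    """20-replicate ensembles across the experimental viscosity sweep."""
    return {
        cp: actin.ensemble_density(
            actin.ActinSimParams.from_cp(cp), n_rep=20, base_seed=11
        )
        for cp in (0.8, 2.0, 5.0, 8.0)
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
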