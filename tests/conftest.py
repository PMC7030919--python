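"""Shared fixtures: synthetic REUS datasets reused across test modules.

The expensive fixtures are session-scoped so the sampling cost is paid
once; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

import lipidpmf as lp


@pytest.fixture(scope="session")
def pot1() -> lp.ModelPotential:
    """Default two-well ground truth, one lipid per leaflet."""
    return lp.default_potential(1)


@pytest.fixture(scope="session")
def flat_potential() -> lp.ModelPotential:
    """Zero-depth (flat marginal) ground truth."""
    return lp.make_model_potential([0.9], [0.0])


@pytest.fixture(scope="session")
def config() -> lp.AnalysisConfig:
    # longer chains + frequent exchanges: high-quality reference ensemble
    return lp.AnalysisConfig(
        protocol=lp.UmbrellaProtocol(n_steps=200_000, seed=101,
                                     exchange_interval=200),
        area_A=40.0)


@pytest.fixture(scope="session")
def reus_run(pot1, config) -> lp.REUSResult:
    """One full-size REUS run on the default ground truth."""
    return lp.run_reus(pot1, config.protocol)


@pytest.fixture(scope="session")
def post_burn(reus_run, config) -> list[lp.CVTrajectory]:
    return [lp.apply_burn_in(t, config) for t in reus_run.trajectories]


@pytest.fixture(scope="session")
def pmf_aligned(post_burn, config) -> lp.PMFProfile:
    pmf = lp.wham_1d(post_burn, config.protocol, config)
    return lp.align_pmf(pmf, config.plateau_region)


@pytest.fixture(scope="session")
def weights(post_burn, config, pmf_aligned) -> lp.FrameWeights:
    return lp.frame_weights(post_burn, config.protocol, pmf_aligned)


def make_profile(x, F, temperature=323.0, convention="plateau-zero",
                 counts=None) -> lp.PMFProfile:
    """Build a PMFProfile directly from arrays (for analytic tests)."""
    x = np.asarray(x, float)
    F = np.asarray(F, float)
    if counts is None:
        counts = np.ones((1, len(x))) * 1000
    return lp.PMFProfile(
        bin_centers=x, free_energy=F, zero_convention=convention,
        window_offsets=np.zeros(counts.shape[0]), counts=counts,
        temperature=temperature)
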