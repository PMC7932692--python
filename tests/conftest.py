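import numpy as np
import pytest

import sistermem as sm
from sistermem.pipeline import AnalysisParams, analyze_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """A small but structurally complete experiment configuration."""
    return sm.get_preset("LB-default", n_traps=40, n_generations=12, seed=11)


@pytest.fixture(scope="session")
def small_df(small_cfg):
    return sm.simulate_experiment(small_cfg)


@pytest.fixture(scope="session")
def small_lineages(small_df):
    return sm.build_lineages(sm.segment_cycles(small_df))


@pytest.fixture(scope="session")
def noise_free_cfg():
    """Deterministic growth: every noise source disabled."""
    return sm.get_preset(
        "LB-default", n_traps=4, n_generations=8, seed=3,
        sigma_delta_rel=0.0, sigma_r=0.0, sigma_hT=0.0, sigma_hL=0.0,
        kappa=0.0, sigma_xi=0.0, sigma_env_static=0.0, sigma_env_dyn=0.0,
        sigma_f_intr=0.0, sigma_meas_L=0.0, sigma_meas_f=0.0,
    )


@pytest.fixture(scope="session")
def noise_free_df(noise_free_cfg):
    return sm.simulate_experiment(noise_free_cfg)


@pytest.fixture(scope="session")
def full_bundle():
    """Full-scale LB-default run at the study's ensemble sizes.

    Shared by the acceptance tests; one simulation plus one analysis.
    """
    cfg = sm.get_preset("LB-default", seed=1)
    df = sm.simulate_experiment(cfg)
    params = AnalysisParams(n_sc_max=122, n_boot=300, seed=1)
    bundle = analyze_dataset(df, params)
    return {"cfg": cfg, "df": df, "params": params, "bundle": bundle}
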