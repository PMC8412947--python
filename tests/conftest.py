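import pytest
from hypothesis import HealthCheck, settings

import mtulab

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_curve():
    return mtulab.reference_efficiency_curve()


@pytest.fixture(scope="session")
def soleus_trial():
    """Noiseless soleus-like stance trial."""
    cfg = mtulab.SyntheticTrialConfig.from_preset("soleus_like", seed=1, noise_sd=0.0)
    return mtulab.generate_trial(cfg)


@pytest.fixture(scope="session")
def vl_trial():
    """Noiseless vastus-lateralis-like stance trial."""
    cfg = mtulab.SyntheticTrialConfig.from_preset("vl_like", seed=1, noise_sd=0.0)
    return mtulab.generate_trial(cfg)


@pytest.fixture(scope="session")
def soleus_report(soleus_trial):
    cfg = soleus_trial.config
    mvc = mtulab.generate_mvc_dataset(cfg.L0_mm, cfg.Fmax_N, curvature=cfg.fl_curvature)
    ac = mtulab.AnalysisConfig.for_synthetic(soleus_trial)
    return mtulab.analyze_trial(soleus_trial, mvc, ac)


@pytest.fixture(scope="session")
def vl_report(vl_trial):
    cfg = vl_trial.config
    mvc = mtulab.generate_mvc_dataset(cfg.L0_mm, cfg.Fmax_N, curvature=cfg.fl_curvature)
    ac = mtulab.AnalysisConfig.for_synthetic(vl_trial)
    return mtulab.analyze_trial(vl_trial, mvc, ac)
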