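import pytest

import lucikin as lk


@pytest.fixture(scope="session")
def wt_ctz() -> lk.KineticParams:
    """Wild-type enzyme with coelenterazine: strong product inhibition."""
    return lk.KineticParams(k_cat=2.48, K_m=0.57, K_p=0.256)


@pytest.fixture(scope="session")
def wt_fmz() -> lk.KineticParams:
    """Wild-type enzyme with furimazine: fast turnover, mild product inhibition."""
    return lk.KineticParams(k_cat=7.88, K_m=0.123, K_p=0.56)


@pytest.fixture(scope="session")
def noiseless_wt_ctz_study(wt_ctz) -> lk.StudyBundle:
    """Zero-noise five-level concentration series, single replicate."""
    return lk.generate_study(
        [lk.StudyEntry("NanoLuc", "CTZ", wt_ctz, scaling_f=1e6)],
        design=lk.SeriesDesign(replicates=1),
        noise=lk.NoiseModel(0.0, 0.0, seed=1),
        E0=0.01,
        read_interval_s=2.0,
    )
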