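import numpy as np
import pandas as pd
import pytest

from streamprod.synthetic import SimulationConfig, TaxonSpec, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A reduced study: 4 streams, 6 sampling dates, 2 taxa."""
    return SimulationConfig(
        n_streams=4,
        mean_annual_temp_C=(5.0, 10.0, 18.0, 27.0),
        sampling_dates=tuple(range(30, 331, 60)),
        taxa=(
            TaxonSpec("chiro", lm_a=0.002, lm_b=2.6, cohort_synchronous=True,
                      relative_abundance=0.6, mean_length_mm=4.0, sd_length_mm=1.2),
            TaxonSpec("snail", lm_a=0.01, lm_b=2.8, cohort_synchronous=False,
                      relative_abundance=0.4, mean_length_mm=6.0, sd_length_mm=2.0),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, n_growth_obs=200)


@pytest.fixture(scope="session")
def study_dir(small_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    small_study.write(out)
    return out


@pytest.fixture()
def noise_free_growth():
    """Chamber observations generated exactly from ln g = b0 + a lnM + E x."""
    from streamprod.scaling import standardize_temperature

    rng = np.random.default_rng(4)
    b0, a, e = -3.5, -0.25, 0.65
    m = rng.uniform(0.05, 5.0, size=40)
    temp = rng.uniform(5.0, 28.0, size=40)
    x = standardize_temperature(temp)
    g = np.exp(b0 + a * np.log(m) + e * x)
    dt = rng.uniform(7, 15, size=40)
    return pd.DataFrame({
        "taxon_id": "t1",
        "stream_id": "s1",
        "method": "chamber",
        "date_t": "2011-06-01",
        "date_t_dt": "2011-06-11",
        "W_t_mg": m,
        "W_t_dt_mg": m * np.exp(g * dt),
        "dt_days": dt,
        "temp_C": temp,
    })
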