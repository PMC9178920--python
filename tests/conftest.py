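import numpy as np
import pytest

from cityaq import SynthSpec, generate, run_baseline
from cityaq.meteorology import MetHour


@pytest.fixture(scope="session")
def small_city(tmp_path_factory):
    """A 3x3 synthetic city with a short met record — fast enough for the
    whole suite, but it exercises every source kind and both receptor rules."""
    out = tmp_path_factory.mktemp("city")
    spec = SynthSpec(nx=3, ny=3, n_hours=240, seed=7)
    cfg = generate(spec, out)
    cfg.met_options.n_rep = 12
    return spec, cfg


@pytest.fixture(scope="session")
def small_baseline(small_city):
    _, cfg = small_city
    return run_baseline(cfg)


@pytest.fixture()
def met_hour():
    return MetHour(wind_speed=5.0, wind_dir=270.0, stability="D", mixing_height=1000.0, roughness=1.0)


@pytest.fixture()
def receptor_line():
    """Receptors strung downwind (east) of the origin at breathing height."""
    x = np.array([200.0, 500.0, 1000.0, 2000.0])
    return x, np.zeros_like(x), np.full_like(x, 1.8)


def two_regime_year(n_hours: int, split: float, seed: int) -> list[MetHour]:
    """Hours drawn from the SW-D / NW-B mixture used across the met tests;
    the mixture proportions are the oracle for weight recovery."""
    rng = np.random.default_rng(seed)
    hours = []
    n1 = int(round(split * n_hours))
    for k in range(n_hours):
        if k < n1:
            hours.append(MetHour(5.0 * rng.lognormal(0, 0.1), (225 + rng.normal(0, 6)) % 360, "D", 800.0))
        else:
            hours.append(MetHour(3.0 * rng.lognormal(0, 0.1), (315 + rng.normal(0, 6)) % 360, "B", 1200.0))
    order = rng.permutation(n_hours)
    return [hours[i] for i in order]
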