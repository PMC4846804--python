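import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermaldev as td

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# Temperatures from the rearing design that sit above each stage's fitted
# threshold (L1/L2 thresholds exceed 15 °C; pupae were only reared to 21 °C).
VIABLE_TEMPS = {
    td.Stage.egg: (15.0, 18.0, 21.0, 25.0),
    td.Stage.L1: (18.0, 21.0, 25.0),
    td.Stage.L2: (18.0, 21.0, 25.0),
    td.Stage.L3: (15.0, 18.0, 21.0, 25.0),
    td.Stage.pupa: (15.0, 18.0, 21.0),
}


@pytest.fixture(scope="session")
def stage_params():
    return dict(td.WATSONI_STAGE_PARAMS)


@pytest.fixture(scope="session")
def width_models():
    return sorted(td.WATSONI_HEAD_WIDTHS.values(), key=lambda m: m.instar)


@pytest.fixture()
def rng():
    return np.random.default_rng(20160421)


def make_observations(stage, k, t, temps, n_per_temp=5, cv=0.0, seed=0):
    """Durations on (or scattered around) D = k/(T−t) for one stage."""
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    obs = []
    for temp in temps:
        base = k / (temp - t)
        noise = np.exp(rng.normal(0, sigma, n_per_temp)) if sigma else np.ones(n_per_temp)
        obs.extend(
            td.DevelopmentObservation(f"s{temp:g}-{j}", stage, temp, base * e)
            for j, e in enumerate(noise)
        )
    return obs


def perpendicular_ls_line(points):
    """Independent oracle: minimize summed perpendicular squared distances
    by scanning the line's angle (line constrained through the centroid,
    which holds for the perpendicular least-squares optimum)."""
    import scipy.optimize as opt

    pts = np.asarray(points, float)
    x, y = pts[:, 0], pts[:, 1]
    xm, ym = x.mean(), y.mean()

    def cost(theta):
        b = np.tan(theta)
        return np.sum((y - ym - b * (x - xm)) ** 2) / (1.0 + b**2)

    thetas = np.linspace(-np.pi / 2 + 1e-4, np.pi / 2 - 1e-4, 20001)
    best = thetas[int(np.argmin([cost(th) for th in thetas]))]
    h = thetas[1] - thetas[0]
    res = opt.minimize_scalar(
        cost, bounds=(best - 2 * h, best + 2 * h), method="bounded",
        options={"xatol": 1e-13},
    )
    slope = float(np.tan(res.x))
    return slope, float(ym - slope * xm)
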