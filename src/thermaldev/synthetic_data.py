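"""Synthetic rearing-study generator.

Emulates a constant-temperature development study on a necrophagous beetle:
per-individual stage durations drawn from the thermal summation law with
multiplicative log-normal noise, head-capsule widths per instar from
truncated normals, daily growth trajectories, and chamber/field temperature
records.  Defaults reproduce the reference study design — temperatures
{15, 18, 21, 25} °C, stages egg/L1/L2/L3/pupa with the published (k, t),
instar width moments with the published picture counts — so the fitting and
classification code can be exercised end to end with no external data.

Everything is driven by ``numpy.random.Generator``; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .instar_model import LARVAL_INSTARS, InstarSizeModel, WidthTrajectory
from .ma_fit import DevelopmentObservation, observations_to_frame
from .reference import WATSONI_HEAD_WIDTHS, WATSONI_STAGE_PARAMS
from .thermal_model import Stage, TemperatureSeries, ThermalSummationParams

__all__ = [
    "SimulationConfig",
    "StudyDataset",
    "gen_development_durations",
    "gen_head_widths",
    "gen_growth_trajectory",
    "gen_temperature_series",
    "gen_study_dataset",
]

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURES = (15.0, 18.0, 21.0, 25.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    duration_noise_cv is the coefficient of variation of the multiplicative
    log-normal noise on durations (0.05 by default — modest biological
    spread around the thermal-summation mean).  n_per_temperature defaults
    to 50 individuals per chamber.  Width-model n values default to the
    published per-instar photograph counts (591/500/640).
    """

    stage_params: dict[Stage, ThermalSummationParams] = field(
        default_factory=lambda: dict(WATSONI_STAGE_PARAMS)
    )
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    n_per_temperature: int = 50
    duration_noise_cv: float = 0.05
    width_models: dict[Stage, InstarSizeModel] = field(
        default_factory=lambda: dict(WATSONI_HEAD_WIDTHS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_noise_cv < 0:
            raise ValidationError("duration_noise_cv must be >= 0")
        if self.n_per_temperature < 0:
            raise ValidationError("n_per_temperature must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class StudyDataset:
    """Bundle of generated tables mirroring the package's CSV schemas."""

    observations: pd.DataFrame  # specimen_id, stage, temp_c, duration_h
    widths: pd.DataFrame        # specimen_id, instar, width_mm
    trajectories: pd.DataFrame  # specimen_id, day, width_mm

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.observations.to_csv(out / "observations.csv", index=False)
        self.widths.to_csv(out / "widths.csv", index=False)
        self.trajectories.to_csv(out / "trajectories.csv", index=False)


def _noise_sigma(cv: float) -> float:
    # CV of exp(N(0, s)) is sqrt(e^{s^2} - 1); invert for s.
    return float(np.sqrt(np.log1p(cv**2)))


def gen_development_durations(
    cfg: SimulationConfig,
    stage: Stage,
    rng: np.random.Generator | None = None,
) -> list[DevelopmentObservation]:
    """Per-individual durations D = k/(T−t)·exp(ε) at each viable temperature.

    ε ~ N(0, σ) with σ chosen so the duration CV equals
    cfg.duration_noise_cv.  Temperatures at or below the stage's threshold
    are skipped with a warning — the synthetic analogue of chambers where
    the beetles failed to develop.
    """
    stage = Stage.parse(stage)
    params = cfg.stage_params[stage]
    rng = cfg.rng() if rng is None else rng
    sigma = _noise_sigma(cfg.duration_noise_cv)
    out: list[DevelopmentObservation] = []
    for temp in cfg.temperatures:
        if temp <= params.t:
            logger.warning(
                "skipping %.1f °C for stage %s: at or below its threshold %.3f °C",
                temp, stage.name, params.t,
            )
            continue
        d0 = params.k / (temp - params.t)
        eps = rng.normal(0.0, sigma, size=cfg.n_per_temperature) if sigma > 0 \
            else np.zeros(cfg.n_per_temperature)
        for j, d in enumerate(d0 * np.exp(eps)):
            out.append(
                DevelopmentObservation(
                    specimen_id=f"{stage.name}-T{temp:g}-{j:03d}",
                    stage=stage,
                    temperature=temp,
                    duration=float(d),
                )
            )
    return out


def gen_head_widths(
    cfg: SimulationConfig,
    instar: Stage,
    n: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Head widths (mm) from the instar's normal truncated to its observed
    [min, max] by rejection; n defaults to the model's own count."""
    instar = Stage.parse(instar)
    model = cfg.width_models[instar]
    n = model.n if n is None else int(n)
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = cfg.rng() if rng is None else rng
    out = np.empty(0)
    while len(out) < n:
        draw = rng.normal(model.mean, model.sd, size=max(n - len(out), 16))
        out = np.concatenate([out, draw[(draw >= model.min) & (draw <= model.max)]])
    return out[:n]


def gen_growth_trajectory(
    cfg: SimulationConfig,
    days_per_instar: int = 3,
    noise_sd: float = 0.0,
    specimen_id: str = "sim-larva",
    rng: np.random.Generator | None = None,
) -> WidthTrajectory:
    """Daily-width trajectory: each instar holds its mean width (plus
    optional Gaussian measurement noise) for a block of days."""
    if days_per_instar < 1:
        raise ValidationError("days_per_instar must be >= 1")
    rng = cfg.rng() if rng is None else rng
    days, widths = [], []
    day = 1
    for instar in LARVAL_INSTARS:
        mean = cfg.width_models[instar].mean
        for _ in range(days_per_instar):
            w = mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            days.append(day)
            widths.append(max(w, 1e-6))
            day += 1
    return WidthTrajectory(
        specimen_id=specimen_id, days=tuple(days), widths=tuple(widths)
    )


def gen_temperature_series(
    kind: str,
    mean: float,
    span_h: float,
    step_h: float = 1.0,
    amplitude: float = 0.0,
    jitter_sd: float = 0.0,
    start: str = "2015-06-01T00:00:00",
    rng: np.random.Generator | None = None,
) -> TemperatureSeries:
    """Constant-chamber or diurnal (24 h sinusoid) temperature record.

    ``diurnal`` oscillates mean ± amplitude with a 24-hour period; optional
    Gaussian jitter roughens either kind (off unless jitter_sd > 0).
    """
    if step_h <= 0:
        raise ValidationError("step_h must be positive")
    hours = np.arange(0.0, span_h + 0.5 * step_h, step_h)
    if kind == "constant":
        temps = np.full(len(hours), float(mean))
    elif kind == "diurnal":
        temps = mean + amplitude * np.sin(2 * np.pi * hours / 24.0)
    else:
        raise ValidationError(f"unknown series kind {kind!r}")
    if jitter_sd > 0:
        rng = np.random.default_rng(0) if rng is None else rng
        temps = temps + rng.normal(0.0, jitter_sd, size=len(temps))
    times = pd.Timestamp(start) + pd.to_timedelta(hours, unit="h")
    return TemperatureSeries(times, temps)


def gen_study_dataset(
    cfg: SimulationConfig,
    survival: dict[Stage, float] | None = None,
    stages: Sequence[Stage] | None = None,
    n_trajectories: int = 10,
) -> StudyDataset:
    """Full synthetic study: durations for every stage and temperature,
    labelled head widths per instar, and daily growth trajectories.

    ``survival`` optionally thins each stage's individuals binomially
    (default: no thinning; the study printed no usable mortality rates).
    Fully reproducible from cfg.seed.
    """
    rng = cfg.rng()
    stages = [Stage.parse(s) for s in stages] if stages else list(cfg.stage_params)
    obs: list[DevelopmentObservation] = []
    for stage in sorted(stages):
        stage_obs = gen_development_durations(cfg, stage, rng=rng)
        if survival and stage in survival:
            p = survival[stage]
            if not 0.0 <= p <= 1.0:
                raise ValidationError("survival probabilities must be in [0, 1]")
            keep = rng.random(len(stage_obs)) < p
            stage_obs = [o for o, k in zip(stage_obs, keep) if k]
        obs.extend(stage_obs)

    width_rows = []
    for instar in LARVAL_INSTARS:
        if instar not in cfg.width_models:
            continue
        for j, w in enumerate(gen_head_widths(cfg, instar, rng=rng)):
            width_rows.append((f"{instar.name}-w{j:04d}", instar.name, round(w, 4)))

    traj_rows = []
    for i in range(n_trajectories):
        traj = gen_growth_trajectory(
            cfg, noise_sd=0.005, specimen_id=f"larva-{i:03d}", rng=rng
        )
        traj_rows.extend(
            (traj.specimen_id, d, round(w, 4))
            for d, w in zip(traj.days, traj.widths)
        )

    return StudyDataset(
        observations=observations_to_frame(obs),
        widths=pd.DataFrame(width_rows, columns=["specimen_id", "instar", "width_mm"]),
        trajectories=pd.DataFrame(traj_rows, columns=["specimen_id", "day", "width_mm"]),
    )
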