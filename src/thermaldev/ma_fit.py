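"""Estimation of thermal summation constants by model-II regression.

Per-individual durations D (hours) at constant temperatures T (°C) are
mapped through the Ikemoto–Takai transform

    x = D,    y = D * T,

on which the thermal summation law becomes the straight line
``y = k + t x``: the slope estimates the lower developmental threshold and
the intercept the thermal constant.  Because both coordinates carry the
duration's measurement error, the line is fitted by MAJOR-AXIS regression —
the principal axis of the sample covariance matrix, minimizing perpendicular
rather than vertical squared distances.  The transform also de-weights the
extreme ends of the temperature range relative to fitting rates directly.

Standard errors come from nonparametric case bootstrap (resample
individuals, refit, take the spread of the replicate estimates).  The
ordinary least-squares fit of rate on temperature (1/D = −t/k + T/k) is
provided as the classical comparison method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateGeometryError, NoThermalResponseError, ValidationError
from .thermal_model import Stage

__all__ = [
    "DevelopmentObservation",
    "ThermalFit",
    "BootConfig",
    "ikemoto_takai_points",
    "fit_major_axis",
    "fit_thermal_params",
    "fit_rate_ols",
    "bootstrap_se",
    "observations_from_frame",
    "observations_to_frame",
    "fits_to_frame",
    "fits_from_frame",
]


@dataclass(frozen=True)
class DevelopmentObservation:
    """One individual's development duration for one stage at one constant
    rearing temperature."""

    specimen_id: str
    stage: Stage
    temperature: float  # °C
    duration: float  # hours

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", Stage.parse(self.stage))
        if not (self.duration > 0 and math.isfinite(self.duration)):
            raise ValidationError(
                f"duration must be positive and finite, got {self.duration} "
                f"(specimen {self.specimen_id})"
            )
        if not math.isfinite(self.temperature):
            raise ValidationError(f"temperature must be finite (specimen {self.specimen_id})")


@dataclass(frozen=True)
class ThermalFit:
    """Fitted thermal summation constants for one stage.

    k, se_k in degree-hours; t, se_t in °C; r2 is the squared Pearson
    correlation of the transformed (D, DT) pairs; df = n − 2; p is the
    two-sided test of zero correlation on df degrees of freedom.
    """

    stage: Stage
    k: float
    se_k: float
    t: float
    se_t: float
    r2: float
    df: int
    p: float
    temp_range: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage", Stage.parse(self.stage))
        if self.se_k < 0 or self.se_t < 0:
            raise ValidationError("standard errors must be non-negative")
        if not 0.0 <= self.r2 <= 1.0:
            raise ValidationError(f"r2 must lie in [0, 1], got {self.r2}")
        if not 0.0 < self.p <= 1.0:
            raise ValidationError(f"p must lie in (0, 1], got {self.p}")
        if self.n != self.df + 2:
            raise ValidationError(f"n ({self.n}) must equal df + 2 ({self.df + 2})")


@dataclass(frozen=True)
class BootConfig:
    """Bootstrap settings: replicate count B and RNG seed."""

    B: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValidationError(f"bootstrap needs B >= 100, got {self.B}")


def _check_single_stage(obs: Sequence[DevelopmentObservation]) -> Stage:
    if not obs:
        raise ValidationError("no observations supplied")
    stages = {o.stage for o in obs}
    if len(stages) > 1:
        raise ValidationError(
            f"observations mix stages {sorted(s.name for s in stages)}; "
            "fit one stage at a time"
        )
    return next(iter(stages))


def ikemoto_takai_points(obs: Sequence[DevelopmentObservation]) -> np.ndarray:
    """Map single-stage observations to (x, y) = (D, D·T); shape (n, 2)."""
    _check_single_stage(obs)
    d = np.array([o.duration for o in obs])
    t = np.array([o.temperature for o in obs])
    return np.column_stack([d, d * t])


def fit_major_axis(points: np.ndarray) -> tuple[float, float]:
    """Major-axis (principal-axis) line through 2-D points.

    Returns (slope, intercept).  The slope is the root

        b = (s_yy − s_xx + sqrt((s_yy − s_xx)² + 4 s_xy²)) / (2 s_xy)

    of the major axis of the sample covariance matrix (its sign follows
    s_xy); the line passes through the centroid.  Degenerate geometry —
    fewer than 3 points, constant x, or s_xy = 0 — is rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    n = pts.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"major-axis fit needs >= 3 points, got {n}")
    x, y = pts[:, 0], pts[:, 1]
    xm, ym = x.mean(), y.mean()
    s_xx = np.sum((x - xm) ** 2) / (n - 1)
    s_yy = np.sum((y - ym) ** 2) / (n - 1)
    s_xy = np.sum((x - xm) * (y - ym)) / (n - 1)
    if s_xx == 0:
        raise DegenerateGeometryError("all x values identical; slope unidentifiable")
    if s_xy == 0:
        raise DegenerateGeometryError("zero covariance; major-axis slope undefined")
    slope = (s_yy - s_xx + math.hypot(s_yy - s_xx, 2.0 * s_xy)) / (2.0 * s_xy)
    intercept = ym - slope * xm
    return float(slope), float(intercept)


def fit_rate_ols(obs: Sequence[DevelopmentObservation]) -> tuple[float, float]:
    """Classical rate regression: OLS of 1/D on T.

    The fitted line 1/D = −t/k + T/k yields k = 1/slope, t = −intercept·k.
    Provided as the comparison method for the major-axis fit; a fitted
    slope ≤ 0 (rate not increasing with temperature) is an error.
    """
    _check_single_stage(obs)
    d = np.array([o.duration for o in obs])
    temp = np.array([o.temperature for o in obs])
    if len(d) < 3:
        raise DegenerateGeometryError(f"rate fit needs >= 3 points, got {len(d)}")
    if np.ptp(temp) == 0:
        raise DegenerateGeometryError("all temperatures identical")
    slope, intercept = np.polyfit(temp, 1.0 / d, 1)
    if slope <= 0:
        raise NoThermalResponseError(
            f"rate regression slope {slope:.3g} <= 0: no thermal response"
        )
    k = 1.0 / slope
    t = -intercept * k
    return float(k), float(t)


def _fit_kt(obs: Sequence[DevelopmentObservation]) -> tuple[float, float]:
    """(k, t) from the major-axis fit on the Ikemoto–Takai transform."""
    slope, intercept = fit_major_axis(ikemoto_takai_points(obs))
    return intercept, slope


def bootstrap_se(
    obs: Sequence[DevelopmentObservation],
    B: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Nonparametric case-bootstrap standard errors (se_k, se_t).

    Observations are resampled with replacement, each replicate refitted by
    major axis on the transform, and the SEs are the standard deviations of
    the B replicate estimates.  A degenerate replicate (single temperature,
    zero covariance) is redrawn; after B total redraws the data are deemed
    too fragile to bootstrap.
    """
    cfg = BootConfig(B=B, seed=seed)
    _check_single_stage(obs)
    n = len(obs)
    rng = np.random.default_rng(cfg.seed)
    ks = np.empty(cfg.B)
    ts = np.empty(cfg.B)
    retries = 0
    b = 0
    while b < cfg.B:
        idx = rng.integers(0, n, size=n)
        try:
            ks[b], ts[b] = _fit_kt([obs[i] for i in idx])
        except DegenerateGeometryError:
            retries += 1
            if retries >= cfg.B:
                raise DegenerateGeometryError(
                    f"bootstrap abandoned after {retries} degenerate resamples"
                ) from None
            continue
        b += 1
    return float(ks.std(ddof=1)), float(ts.std(ddof=1))


def fit_thermal_params(
    obs: Sequence[DevelopmentObservation],
    boot: BootConfig = BootConfig(),
) -> ThermalFit:
    """Full per-stage fit: (k, t) by major axis, bootstrap SEs, R², df, p.

    R² is the squared Pearson correlation of the transformed (D, DT) pairs
    and p the two-sided correlation test on df = n − 2 degrees of freedom.
    Fewer than 3 distinct temperatures triggers a warning (threshold and
    constant are then poorly separated) but not an error.
    """
    stage = _check_single_stage(obs)
    pts = ikemoto_takai_points(obs)
    n_temps = len({o.temperature for o in obs})
    if n_temps < 3:
        warnings.warn(
            f"only {n_temps} distinct temperature(s); "
            "threshold and thermal constant are weakly identified",
            UserWarning,
            stacklevel=2,
        )
    k, t = _fit_kt(obs)
    se_k, se_t = bootstrap_se(obs, B=boot.B, seed=boot.seed)
    n = len(obs)
    r, p = stats.pearsonr(pts[:, 0], pts[:, 1])
    temps = [o.temperature for o in obs]
    return ThermalFit(
        stage=stage,
        k=k,
        se_k=se_k,
        t=t,
        se_t=se_t,
        r2=min(float(r) ** 2, 1.0),
        df=n - 2,
        p=float(p) if p > 0 else np.finfo(float).tiny,
        temp_range=(min(temps), max(temps)),
        n=n,
    )


# ---------------------------------------------------------------------------
# CSV plumbing

OBS_COLUMNS = ["specimen_id", "stage", "temp_c", "duration_h"]
FIT_COLUMNS = [
    "stage", "temp_min_c", "temp_max_c", "r2", "df", "p",
    "k", "k_se", "t", "t_se", "n",
]


def observations_from_frame(df: pd.DataFrame) -> list[DevelopmentObservation]:
    """Parse an observations table; errors carry 1-based CSV line numbers
    (header = line 1)."""
    missing = set(OBS_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"observations CSV lacks columns: {sorted(missing)}")
    out = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line = pos + 2
        try:
            out.append(
                DevelopmentObservation(
                    specimen_id=str(row["specimen_id"]),
                    stage=Stage.parse(row["stage"]),
                    temperature=float(row["temp_c"]),
                    duration=float(row["duration_h"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"line {line}: {exc}") from None
    return out


def observations_to_frame(obs: Iterable[DevelopmentObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.specimen_id, o.stage.name, o.temperature, o.duration) for o in obs],
        columns=OBS_COLUMNS,
    )


def fits_to_frame(fits: Iterable[ThermalFit]) -> pd.DataFrame:
    rows = [
        (f.stage.name, f.temp_range[0], f.temp_range[1], f.r2, f.df, f.p,
         f.k, f.se_k, f.t, f.se_t, f.n)
        for f in sorted(fits, key=lambda f: f.stage)
    ]
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def fits_from_frame(df: pd.DataFrame) -> list[ThermalFit]:
    missing = set(FIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"parameter CSV lacks columns: {sorted(missing)}")
    return [
        ThermalFit(
            stage=Stage.parse(row["stage"]),
            k=float(row["k"]), se_k=float(row["k_se"]),
            t=float(row["t"]), se_t=float(row["t_se"]),
            r2=float(row["r2"]), df=int(row["df"]), p=float(row["p"]),
            temp_range=(float(row["temp_min_c"]), float(row["temp_max_c"])),
            n=int(row["n"]),
        )
        for _, row in df.iterrows()
    ]
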