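"""Published reference parameters for *Sciodrepoides watsoni*.

Thermal summation constants (k, degree-hours; lower threshold t, °C) fitted
per stage by major-axis regression at constant rearing temperatures, and
head-capsule width statistics (mm) per larval instar.  These serve as the
package defaults and as the generating truth for the synthetic test bed.

Note the L1/L2 fitted thresholds exceed 15 °C even though 15 °C was inside
the rearing range — a known quirk of linear threshold extrapolation; the
model functions therefore treat T ≤ t as "no development" rather than as an
error.
"""

from __future__ import annotations

from .instar_model import InstarSizeModel
from .ma_fit import ThermalFit
from .thermal_model import Stage, ThermalSummationParams

__all__ = [
    "WATSONI_THERMAL_FITS",
    "WATSONI_STAGE_PARAMS",
    "WATSONI_HEAD_WIDTHS",
    "REARING_TEMPERATURES",
]

# Constant-temperature treatments of the rearing study; 12 and 28 °C
# produced no larvae and enter no fit.
REARING_TEMPERATURES = (12.0, 15.0, 18.0, 21.0, 25.0, 28.0)

WATSONI_THERMAL_FITS: dict[Stage, ThermalFit] = {
    f.stage: f
    for f in (
        ThermalFit(Stage.egg, k=929.354, se_k=49.111, t=11.400, se_t=0.368,
                   r2=0.8134, df=220, p=2.20e-16, temp_range=(15.0, 25.0), n=222),
        ThermalFit(Stage.L1, k=233.683, se_k=27.031, t=15.437, se_t=0.305,
                   r2=0.9375, df=171, p=2.20e-16, temp_range=(15.0, 25.0), n=173),
        ThermalFit(Stage.L2, k=243.945, se_k=45.301, t=15.689, se_t=0.410,
                   r2=0.8768, df=206, p=2.20e-16, temp_range=(15.0, 25.0), n=208),
        ThermalFit(Stage.L3, k=2602.996, se_k=297.464, t=9.375, se_t=0.846,
                   r2=0.8199, df=27, p=1.49e-11, temp_range=(15.0, 25.0), n=29),
        ThermalFit(Stage.pupa, k=1207.431, se_k=489.288, t=12.535, se_t=1.624,
                   r2=0.8563, df=10, p=1.61e-05, temp_range=(15.0, 21.0), n=12),
    )
}

WATSONI_STAGE_PARAMS: dict[Stage, ThermalSummationParams] = {
    s: ThermalSummationParams(stage=s, k=f.k, t=f.t)
    for s, f in WATSONI_THERMAL_FITS.items()
}

# Head-capsule widths (mm); n = usable daily photographs per instar.
WATSONI_HEAD_WIDTHS: dict[Stage, InstarSizeModel] = {
    m.instar: m
    for m in (
        InstarSizeModel(Stage.L1, mean=0.329, sd=0.017,
                        min=0.270, max=0.392, n=591),
        InstarSizeModel(Stage.L2, mean=0.421, sd=0.021,
                        min=0.350, max=0.479, n=500),
        InstarSizeModel(Stage.L3, mean=0.522, sd=0.021,
                        min=0.451, max=0.582, n=640),
    )
}
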