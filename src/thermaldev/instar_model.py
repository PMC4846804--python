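"""Size-based larval instar determination from head-capsule widths.

The head capsule is sclerotized: its width is constant within an instar and
steps up at each molt, which makes it the classic size character for instar
assignment.  Each instar's widths are summarized as a Gaussian (mean, sd)
plus the observed range; a new width is assigned by comparing prior-weighted
normal densities, which also yields posteriors, the decision boundaries
between adjacent instars, and the closed-form misclassification risk that
the densities' overlap implies.  Brooks–Dyar ratios (successive mean
ratios, near-constant under geometric growth) summarize the progression.

Molt detection on daily width trajectories uses the field rule that a jump
of more than 0.1 mm marks a molt; the jump is measured against the running
mean of the current instar's readings so one noisy frame cannot fake a molt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ThermalDevError, ValidationError
from .thermal_model import LARVAL_INSTARS, Stage

__all__ = [
    "InstarSizeModel",
    "WidthTrajectory",
    "ClassificationResult",
    "MoltEvent",
    "MoltResult",
    "BrooksDyarResult",
    "fit_size_model",
    "classify_width",
    "decision_boundaries",
    "misclassification_matrix",
    "brooks_dyar",
    "detect_molts",
    "size_models_to_frame",
    "size_models_from_frame",
]


@dataclass(frozen=True)
class InstarSizeModel:
    """Per-instar head-width statistics (mm): mean, sample sd, observed
    min/max, and the number of measurements behind them."""

    instar: Stage
    mean: float
    sd: float
    min: float
    max: float
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "instar", Stage.parse(self.instar))
        if not self.min <= self.mean <= self.max:
            raise ValidationError(
                f"{self.instar.name}: need min <= mean <= max, got "
                f"({self.min}, {self.mean}, {self.max})"
            )
        if not self.sd > 0:
            raise ValidationError(
                f"{self.instar.name}: sd must be > 0 (got {self.sd}); "
                "degenerate width distribution"
            )
        if self.n < 2:
            raise ValidationError(f"{self.instar.name}: need n >= 2, got {self.n}")


@dataclass(frozen=True)
class WidthTrajectory:
    """Daily head-width readings (mm) of one larva; days strictly increase."""

    specimen_id: str
    days: tuple[int, ...]
    widths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.widths):
            raise ValidationError("days and widths differ in length")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValidationError("days must be strictly increasing")
        if any(w <= 0 for w in self.widths):
            raise ValidationError("widths must be positive")


@dataclass(frozen=True)
class ClassificationResult:
    assigned: Stage
    posterior: dict[Stage, float]  # sums to 1
    out_of_range: bool  # width outside the assigned instar's observed [min, max]


@dataclass(frozen=True)
class MoltEvent:
    day: int
    width: float
    previous_mean: float  # running mean the jump was measured against


@dataclass(frozen=True)
class MoltResult:
    specimen_id: str
    molts: tuple[MoltEvent, ...]

    @property
    def instar_count(self) -> int:
        return len(self.molts) + 1


@dataclass(frozen=True)
class BrooksDyarResult:
    """Successive mean-width ratios and their coefficient of variation
    (0 for an exactly geometric progression)."""

    ratios: tuple[float, ...]
    constancy: float


def fit_size_model(
    widths: Iterable[tuple[Stage | str, float]]
) -> list[InstarSizeModel]:
    """Summarize labelled widths into per-instar Gaussian models.

    Sample sd uses the n−1 denominator; an instar with fewer than two
    readings, or with zero spread, is rejected.
    """
    by_instar: dict[Stage, list[float]] = {}
    for instar, w in widths:
        by_instar.setdefault(Stage.parse(instar), []).append(float(w))
    if not by_instar:
        raise ValidationError("no width measurements supplied")
    models = []
    for instar in sorted(by_instar):
        vals = np.asarray(by_instar[instar])
        if len(vals) < 2:
            raise ValidationError(
                f"{instar.name}: need >= 2 widths, got {len(vals)}"
            )
        sd = float(vals.std(ddof=1))
        if sd == 0:
            raise ValidationError(
                f"{instar.name}: all {len(vals)} widths identical; sd must be > 0"
            )
        models.append(
            InstarSizeModel(
                instar=instar,
                mean=float(vals.mean()),
                sd=sd,
                min=float(vals.min()),
                max=float(vals.max()),
                n=len(vals),
            )
        )
    return models


def _normalized_priors(
    models: Sequence[InstarSizeModel], priors: dict[Stage, float] | None
) -> np.ndarray:
    if priors is None:
        return np.full(len(models), 1.0 / len(models))
    p = np.array([float(priors[m.instar]) for m in models])
    if (p < 0).any() or p.sum() <= 0:
        raise ValidationError("priors must be non-negative and not all zero")
    return p / p.sum()


def classify_width(
    models: Sequence[InstarSizeModel],
    width: float,
    priors: dict[Stage, float] | None = None,
) -> ClassificationResult:
    """Assign an instar to a head width by prior-weighted normal densities.

    Posteriors are normalized over the supplied models; exact ties go to the
    earlier instar (the conservative choice for PMImin use).  Widths outside
    the assigned instar's observed range are flagged, not rejected.
    """
    if len(models) < 2:
        raise ValidationError("classification needs models for >= 2 instars")
    if not width > 0:
        raise ValidationError(f"width must be positive, got {width}")
    models = sorted(models, key=lambda m: m.instar)
    pri = _normalized_priors(models, priors)
    logpost = np.array(
        [math.log(p) + stats.norm.logpdf(width, m.mean, m.sd)
         for p, m in zip(pri, models)]
    )
    post = np.exp(logpost - logpost.max())
    post /= post.sum()
    best = int(np.argmax(post))  # argmax takes the first max: earlier instar wins ties
    assigned = models[best]
    return ClassificationResult(
        assigned=assigned.instar,
        posterior={m.instar: float(q) for m, q in zip(models, post)},
        out_of_range=not (assigned.min <= width <= assigned.max),
    )


def _log_density_diff(x, a: InstarSizeModel, b: InstarSizeModel, log_prior_ratio: float):
    return (
        log_prior_ratio
        + stats.norm.logpdf(x, a.mean, a.sd)
        - stats.norm.logpdf(x, b.mean, b.sd)
    )


def _pair_boundary(
    a: InstarSizeModel, b: InstarSizeModel, log_prior_ratio: float
) -> float:
    """Width in (mean_a, mean_b) where the weighted densities cross.

    Equating log densities gives a quadratic in x; the root inside the open
    interval is taken, falling back to bisection when root selection is
    ambiguous.  Two exactly identical models have equal densities
    everywhere; their common mean is returned as the degenerate boundary
    (complete confusion splits 50/50 around it).
    """
    if (a.mean, a.sd) == (b.mean, b.sd) and log_prior_ratio == 0.0:
        return a.mean  # identical models: densities equal everywhere
    if a.mean >= b.mean:
        raise ValidationError("instar models must be ordered by increasing mean")
    # quadratic coefficients of log f_a - log f_b + log_prior_ratio = 0
    qa = 1.0 / (2 * b.sd**2) - 1.0 / (2 * a.sd**2)
    qb = a.mean / a.sd**2 - b.mean / b.sd**2
    qc = (
        log_prior_ratio
        + math.log(b.sd / a.sd)
        + b.mean**2 / (2 * b.sd**2)
        - a.mean**2 / (2 * a.sd**2)
    )
    lo, hi = a.mean, b.mean
    roots: list[float] = []
    if qa == 0.0:
        if qb != 0.0:
            roots = [-qc / qb]
    else:
        disc = qb**2 - 4 * qa * qc
        if disc >= 0:
            r = math.sqrt(disc)
            roots = [(-qb - r) / (2 * qa), (-qb + r) / (2 * qa)]
    inside = sorted(r for r in roots if lo < r < hi)
    if len(inside) == 1:
        return inside[0]
    # ambiguous or no analytic root: bisect the log-density difference
    eps = 1e-9 * (hi - lo)
    f_lo = _log_density_diff(lo + eps, a, b, log_prior_ratio)
    f_hi = _log_density_diff(hi - eps, a, b, log_prior_ratio)
    if f_lo * f_hi > 0:
        raise ThermalDevError(
            f"no density crossing between {a.instar.name} and {b.instar.name} "
            f"means ({lo}, {hi}); pathological size models"
        )
    return float(
        optimize.brentq(
            _log_density_diff, lo + eps, hi - eps,
            args=(a, b, log_prior_ratio), xtol=1e-12,
        )
    )


def decision_boundaries(
    models: Sequence[InstarSizeModel],
    priors: dict[Stage, float] | None = None,
) -> list[float]:
    """Boundary widths (mm) between each adjacent instar pair.

    With equal sds and priors the boundary is the midpoint of the means.
    """
    if len(models) < 2:
        raise ValidationError("boundaries need >= 2 instar models")
    models = sorted(models, key=lambda m: m.instar)
    pri = _normalized_priors(models, priors)
    return [
        _pair_boundary(a, b, math.log(pa / pb))
        for (a, pa), (b, pb) in zip(zip(models, pri), zip(models[1:], pri[1:]))
    ]


def misclassification_matrix(
    models: Sequence[InstarSizeModel],
    priors: dict[Stage, float] | None = None,
) -> pd.DataFrame:
    """P(assigned instar j | true instar i) as closed-form normal integrals.

    The boundaries partition the width axis into one region per instar;
    entry (i, j) is the probability mass of true instar i's density over
    region j.  Rows sum to 1.  Indexed true-instar by rows, assigned by
    columns.
    """
    models = sorted(models, key=lambda m: m.instar)
    bounds = decision_boundaries(models, priors)
    edges = [-np.inf, *bounds, np.inf]
    names = [m.instar.name for m in models]
    mat = np.empty((len(models), len(models)))
    for i, m in enumerate(models):
        cdf = stats.norm.cdf(edges, m.mean, m.sd)
        mat[i] = np.diff(cdf)
    mat /= mat.sum(axis=1, keepdims=True)
    return pd.DataFrame(mat, index=names, columns=names)


def brooks_dyar(models: Sequence[InstarSizeModel]) -> BrooksDyarResult:
    """Brooks–Dyar growth ratios mean_{i+1}/mean_i and their CV.

    The CV (population sd / mean of the ratios) is 0 when head widths grow
    exactly geometrically, the idealized Dyar pattern.
    """
    if len(models) < 2:
        raise ValidationError("Brooks-Dyar ratios need >= 2 instars")
    models = sorted(models, key=lambda m: m.instar)
    means = np.array([m.mean for m in models])
    ratios = means[1:] / means[:-1]
    constancy = float(ratios.std(ddof=0) / ratios.mean())
    return BrooksDyarResult(ratios=tuple(float(r) for r in ratios),
                            constancy=constancy)


def detect_molts(traj: WidthTrajectory, threshold: float = 0.1) -> MoltResult:
    """Detect molts on a daily width trajectory.

    A molt is recorded when a reading exceeds the running mean of the
    current instar's readings by strictly more than ``threshold`` (default
    0.1 mm, the classic clear-molt criterion); the reference then resets to
    the triggering reading.  Instar count = molts + 1.

    Note the default sits between typical adjacent-instar gaps for small
    larvae — e.g. a 0.092 mm L1→L2 step is missed while a 0.101 mm L2→L3
    step is caught — so the threshold is exposed rather than hard-coded.
    """
    if len(traj.widths) < 2:
        raise ValidationError("molt detection needs >= 2 readings")
    if not threshold > 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    molts: list[MoltEvent] = []
    ref_sum, ref_n = traj.widths[0], 1
    for day, w in zip(traj.days[1:], traj.widths[1:]):
        ref_mean = ref_sum / ref_n
        if w - ref_mean > threshold:
            molts.append(MoltEvent(day=day, width=w, previous_mean=ref_mean))
            ref_sum, ref_n = w, 1
        else:
            ref_sum += w
            ref_n += 1
    return MoltResult(specimen_id=traj.specimen_id, molts=tuple(molts))


# ---------------------------------------------------------------------------
# CSV plumbing

SIZE_COLUMNS = ["instar", "max_mm", "min_mm", "mean_mm", "sd_mm", "n"]


def size_models_to_frame(models: Iterable[InstarSizeModel]) -> pd.DataFrame:
    rows = [
        (m.instar.name, m.max, m.min, m.mean, m.sd, m.n)
        for m in sorted(models, key=lambda m: m.instar)
    ]
    return pd.DataFrame(rows, columns=SIZE_COLUMNS)


def size_models_from_frame(df: pd.DataFrame) -> list[InstarSizeModel]:
    missing = set(SIZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"size-model CSV lacks columns: {sorted(missing)}")
    return [
        InstarSizeModel(
            instar=Stage.parse(row["instar"]),
            mean=float(row["mean_mm"]), sd=float(row["sd_mm"]),
            min=float(row["min_mm"]), max=float(row["max_mm"]),
            n=int(row["n"]),
        )
        for _, row in df.iterrows()
    ]
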