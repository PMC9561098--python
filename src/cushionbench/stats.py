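"""Performance parameters and interval estimation.

Two parameters summarise a cushion's pressure management:

*   the redistribution parameter — the fraction of total surface-sensor
    pressure borne by the sensors under the substructure's bony
    protuberances (``%Bony``); lower means more load shifted away from
    high-risk tissue, and

*   the magnitude parameter — the sum of the three internal sensors
    (``SumInt``), which represents loading at the tips of the bony
    prominences and is analysed as a ratio of the test cushion's mean to a
    reference foam's mean.

Each parameter is computed per trial, then the six trials at each of the two
loads are pooled into a single sample of (nominally) twelve values.  Pooling
across loads is deliberate: a cushion that supports different body masses
similarly earns a tighter interval.  The interval is mean ± z·sd/sqrt(n) with
z = 1 by default (configurable to 1.96 or a t quantile).

The ratio of means is interval-estimated by Fieller's construction by
default, with a delta-method and a seeded percentile-bootstrap interval
available as cross-checks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .core import (
    BModel,
    IntervalEstimate,
    SensorLayout,
    ThresholdConfig,
    TrialRecord,
    default_layout,
)


class Parameter(str, Enum):
    BONY_FRACTION = "bony_fraction"
    SUM_INTERNAL = "sum_internal"
    TOTAL_SURFACE = "total_surface"


@dataclass
class ParameterSamples:
    """Per-trial values of one parameter for one cushion and model."""

    cushion_id: str
    model: BModel
    parameter: Parameter
    values: list[tuple[float, int, float]]  # (load kg, trial index, value)

    @property
    def n(self) -> int:
        return len(self.values)

    def array(self) -> np.ndarray:
        return np.array([v for _, _, v in self.values], dtype=float)


@dataclass(frozen=True)
class RatioEstimate:
    """Test-mean / reference-mean ratio with its interval."""

    ratio: float
    lower: float
    upper: float
    method: str
    n_test: int
    n_ref: int
    unbounded: bool = False


class UnboundedRatioWarning(UserWarning):
    """Fieller denominator not significantly away from zero; interval unbounded."""


# --- per-trial parameters -------------------------------------------------

def bony_fraction(trial: TrialRecord, layout: SensorLayout | None = None) -> float:
    """Fraction of total surface pressure under the bony sensor set."""
    layout = layout or default_layout()
    total = sum(trial.surface[c] for c in layout.surface_ids)
    if total == 0:
        raise ZeroDivisionError(
            f"trial {trial.trial_index} ({trial.cushion_id}): "
            f"total surface pressure is zero"
        )
    bony = sum(trial.surface[c] for c in layout.bony_ids)
    return bony / total


def sum_internal(trial: TrialRecord, layout: SensorLayout | None = None) -> float:
    """Sum of the three internal sensors (mmHg)."""
    layout = layout or default_layout()
    missing = set(layout.internal_ids) - set(trial.internal)
    if missing:
        raise KeyError(f"missing internal channels: {sorted(missing)}")
    return float(sum(trial.internal[c] for c in layout.internal_ids))


def total_surface(trial: TrialRecord, layout: SensorLayout | None = None) -> float:
    """Sum of all twelve surface sensors (mmHg)."""
    layout = layout or default_layout()
    return float(sum(trial.surface[c] for c in layout.surface_ids))


_PARAM_FUNCS = {
    Parameter.BONY_FRACTION: bony_fraction,
    Parameter.SUM_INTERNAL: lambda t, layout: sum_internal(t, layout),
    Parameter.TOTAL_SURFACE: total_surface,
}


def collect_parameters(
    trials: Iterable[TrialRecord],
    layout: SensorLayout | None = None,
) -> dict[tuple[BModel, Parameter], ParameterSamples]:
    """Per-trial parameter values grouped by model, excluding dropped trials."""
    layout = layout or default_layout()
    out: dict[tuple[BModel, Parameter], ParameterSamples] = {}
    for rec in trials:
        if rec.excluded:
            continue
        for param, func in _PARAM_FUNCS.items():
            key = (rec.model, param)
            if key not in out:
                out[key] = ParameterSamples(rec.cushion_id, rec.model, param, [])
            out[key].values.append((rec.load, rec.trial_index, func(rec, layout)))
    return out


# --- interval estimation --------------------------------------------------

def pooled_interval(
    samples: ParameterSamples | Sequence[float],
    config: ThresholdConfig | None = None,
) -> IntervalEstimate:
    """Pool all trial values (both loads) into mean ± z·sd/sqrt(n).

    The sample SD uses the n-1 denominator.  Pooling the two load conditions
    into one sample inflates the SD for load-sensitive cushions, which is the
    intended penalty.
    """
    config = config or ThresholdConfig()
    values = samples.array() if isinstance(samples, ParameterSamples) else np.asarray(
        samples, dtype=float
    )
    n = values.size
    if n < 2:
        raise ValueError(f"need at least 2 trial values to form an interval, got {n}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    half = config.ci_multiplier * sd / math.sqrt(n)
    return IntervalEstimate(mean=mean, sd=sd, n=n, lower=mean - half, upper=mean + half)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample SD over mean — the repeatability metric of the procedure."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ZeroDivisionError("mean is zero; CV undefined")
    return float(arr.std(ddof=1) / mean)


def _moments(values: np.ndarray) -> tuple[float, float, int]:
    n = values.size
    return float(values.mean()), float(values.std(ddof=1)), n


def ratio_interval(
    test: ParameterSamples | Sequence[float],
    ref: ParameterSamples | Sequence[float],
    method: str = "fieller",
    config: ThresholdConfig | None = None,
    seed: int | None = None,
) -> RatioEstimate:
    """Interval for the ratio of the test mean to the reference mean.

    fieller
        Fieller's construction for a ratio of independent normal means, with
        the same z multiplier as the pooled interval.  Exact under normality
        and respects positivity.  When the reference mean is not
        significantly away from zero at z (g >= 1) the interval is
        unbounded: infinite bounds are returned with ``unbounded=True`` so
        the classifier can record a warning.
    delta
        First-order propagation: ratio·(1 ± z·sqrt(cv_t²/n_t + cv_r²/n_r)).
    bootstrap
        Seeded percentile interval over 2000 resamples of the trial-level
        values, at the two-sided normal coverage implied by z.
    """
    config = config or ThresholdConfig()
    x = test.array() if isinstance(test, ParameterSamples) else np.asarray(test, float)
    y = ref.array() if isinstance(ref, ParameterSamples) else np.asarray(ref, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    mx, sx, nx = _moments(x)
    my, sy, ny = _moments(y)
    if my <= 0:
        raise ValueError(f"reference mean must be > 0, got {my}")
    rho = mx / my
    z = config.ci_multiplier

    if method == "fieller":
        se2x = sx * sx / nx
        se2y = sy * sy / ny
        g = z * z * se2y / (my * my)
        if g >= 1:
            return RatioEstimate(rho, -math.inf, math.inf, method, nx, ny, True)
        disc = se2x + rho * rho * se2y - g * se2x
        half = (z / my) * math.sqrt(max(disc, 0.0))
        lower = (rho - half) / (1 - g)
        upper = (rho + half) / (1 - g)
        return RatioEstimate(rho, lower, upper, method, nx, ny)

    if method == "delta":
        if mx == 0:
            cv_t = 0.0
        else:
            cv_t = sx / mx
        cv_r = sy / my
        half = z * math.sqrt(cv_t * cv_t / nx + cv_r * cv_r / ny)
        return RatioEstimate(rho, rho * (1 - half), rho * (1 + half), method, nx, ny)

    if method == "bootstrap":
        if seed is None:
            raise ValueError("bootstrap method requires a seed")
        B = 2000
        rng = np.random.default_rng(seed)
        bx = x[rng.integers(0, nx, size=(B, nx))].mean(axis=1)
        by = y[rng.integers(0, ny, size=(B, ny))].mean(axis=1)
        ratios = bx / by
        # two-sided coverage matching the normal z multiplier
        alpha = 2.0 * (1.0 - 0.5 * (1.0 + math.erf(z / math.sqrt(2.0))))
        lower, upper = np.quantile(ratios, [alpha / 2.0, 1.0 - alpha / 2.0])
        lower = min(float(lower), rho)
        upper = max(float(upper), rho)
        return RatioEstimate(rho, lower, upper, method, nx, ny)

    raise ValueError(f"unknown ratio-interval method {method!r}")


# --- equivalence-limit derivation -----------------------------------------

@dataclass(frozen=True)
class LiteratureIPMRecord:
    """One published interface-pressure result: mean, SD, and cohort size."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"{self.label}: mean must be > 0")
        if self.sd < 0:
            raise ValueError(f"{self.label}: sd must be >= 0")
        if self.n < 2:
            raise ValueError(f"{self.label}: n must be >= 2")


def derive_equivalence_limit(records: Sequence[LiteratureIPMRecord]) -> float:
    """Average normalised CI half-width, 1.96·SEM/mean, over published cushions.

    This quantifies how wide a human-subject interface-pressure confidence
    interval typically is relative to its mean; the equivalence limits on the
    bench ratio are then set somewhat tighter, since model-based data carry
    less variance than human-subject data.
    """
    if not records:
        raise ValueError("need at least one record")
    ratios = [1.96 * (r.sd / math.sqrt(r.n)) / r.mean for r in records]
    return float(np.mean(ratios))
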