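"""Core domain types shared by every stage of the cushion bench-test pipeline.

The test procedure loads a compliant buttock model (an elastomer shell over a
rigid skeletal substructure) onto a wheelchair cushion and records calibrated
pressures, in mmHg, from 12 surface sensors and 3 internal sensors.  Two model
shapes are used — an elliptical profile representing typical buttock tissue
bulk and a trigonometric (peaked) profile representing atrophied tissue — each
loaded at two masses to span a range of user body weight.

This module defines the sensor-layout registry, the per-trial record, the
threshold configuration, and the interval-estimate container used by the
statistics and classification stages.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping


class BModel(str, Enum):
    """The two compliant buttock-model shapes used by the bench test."""

    ELLIPTICAL = "elliptical"
    TRIGONOMETRIC = "trigonometric"

    @classmethod
    def parse(cls, token: str) -> "BModel":
        try:
            return cls(token)
        except ValueError:
            accepted = ", ".join(m.value for m in cls)
            raise ValueError(
                f"unknown buttock model {token!r}; accepted tokens: {accepted}"
            ) from None


#: Surface channels sitting under the substructure's protuberances (the
#: "bony" set of the redistribution ratio); the remaining six surface
#: channels sample regions outside the substructure footprint.
BONY_SURFACE_IDS = frozenset({1, 2, 7, 8, 9, 10})

#: Internal channel identifiers.  I1 and I2 instrument two substructure
#: elements at the substructure-elastomer interface; I3 instruments the
#: coccyx-analog protuberance.  The internal-pressure parameter only ever
#: uses their sum, so no per-channel anatomical role is relied upon.
INTERNAL_IDS = ("I1", "I2", "I3")


@dataclass(frozen=True)
class SensorLayout:
    """Registry of sensor channels and their roles.

    Surface sensors are placed at six axisymmetric (left/right mirrored)
    locations, two sensors per buttock location; each pair is homogeneous in
    role (both bony or both non-bony).  The pairing is what makes single-
    channel outlier recovery possible: a flagged reading can be replaced by
    its partner's value without discarding the trial.
    """

    surface_ids: tuple[int, ...] = tuple(range(1, 13))
    bony_ids: frozenset[int] = BONY_SURFACE_IDS
    nonbony_ids: frozenset[int] = frozenset({3, 4, 5, 6, 11, 12})
    axisymmetric_pairs: tuple[tuple[int, int], ...] = (
        (1, 2), (3, 4), (5, 6), (7, 8), (9, 10), (11, 12),
    )
    internal_ids: tuple[str, ...] = INTERNAL_IDS

    def __post_init__(self) -> None:
        surface = set(self.surface_ids)
        if self.bony_ids | self.nonbony_ids != surface:
            raise ValueError("bony and nonbony ids must partition the surface ids")
        if self.bony_ids & self.nonbony_ids:
            raise ValueError("bony and nonbony ids overlap")
        if len(self.bony_ids) != 6:
            raise ValueError("exactly 6 bony surface channels are required")
        paired = [c for pair in self.axisymmetric_pairs for c in pair]
        if sorted(paired) != sorted(self.surface_ids):
            raise ValueError("every surface id must appear in exactly one pair")
        for a, b in self.axisymmetric_pairs:
            if (a in self.bony_ids) != (b in self.bony_ids):
                raise ValueError(f"pair ({a},{b}) mixes bony and nonbony roles")
        if len(self.internal_ids) != 3:
            raise ValueError("exactly 3 internal channels are required")

    def partner(self, channel: int) -> int:
        """Return the axisymmetric partner of a surface channel."""
        for a, b in self.axisymmetric_pairs:
            if channel == a:
                return b
            if channel == b:
                return a
        raise KeyError(f"surface channel {channel} is not in any pair")


_DEFAULT_LAYOUT = SensorLayout()


def default_layout() -> SensorLayout:
    """The standard 12-surface / 3-internal sensor layout."""
    return _DEFAULT_LAYOUT


@dataclass
class TrialRecord:
    """One loading trial of one cushion with one model at one load.

    The surface and internal mappings hold the per-trial aggregate (mean of
    the recorded 1 Hz samples after the load-settling hold) of each channel,
    in mmHg.  ``excluded_flags`` lists channels whose values were flagged as
    outliers; ``excluded`` marks a trial dropped from parameter computation
    because both members of an axisymmetric pair were flagged.
    """

    cushion_id: str
    model: BModel
    load: float
    trial_index: int
    surface: dict[int, float]
    internal: dict[str, float]
    excluded_flags: frozenset = frozenset()
    excluded: bool = False

    def validate(self, layout: SensorLayout | None = None) -> None:
        layout = layout or default_layout()
        missing = set(layout.surface_ids) - set(self.surface)
        if missing:
            raise ValueError(
                f"trial {self.trial_index} ({self.cushion_id}, {self.model.value}, "
                f"{self.load} kg): missing surface channels {sorted(missing)}"
            )
        missing_int = set(layout.internal_ids) - set(self.internal)
        if missing_int:
            raise ValueError(
                f"trial {self.trial_index} ({self.cushion_id}, {self.model.value}, "
                f"{self.load} kg): missing internal channels {sorted(missing_int)}"
            )
        for cid, value in list(self.surface.items()) + list(self.internal.items()):
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"channel {cid}: pressure must be finite and >= 0, got {value}"
                )

    def copy(self) -> "TrialRecord":
        return replace(self, surface=dict(self.surface), internal=dict(self.internal))


def _as_model_map(value: Mapping) -> dict[BModel, float]:
    return {BModel.parse(str(getattr(k, "value", k))): float(v) for k, v in value.items()}


@dataclass
class ThresholdConfig:
    """All tunable thresholds of the evaluation procedure.

    redistribution_threshold
        Criterion fraction of surface pressure allowed under the bony set:
        0.50 for the elliptical model and 0.55 for the trigonometric model,
        whose peaked shape concentrates more load at the medial protuberance.
    lel, uel
        Lower/upper equivalence limits on the test/reference ratio of mean
        internal pressure sums (0.9 / 1.1, a 10% meaningful difference).
    ci_multiplier
        The z in CI = mean ± z·sd/sqrt(n).  Default 1.0, the interval form the
        procedure operates with; set 1.96 (or a t quantile) for a
        conventional 95% normal interval.
    outlier_fraction
        A surface datapoint is an outlier when it differs from its channel's
        condition median by at least this fraction of the median (0.5).
    borderline_tolerance
        How close (in threshold units) an interval bound must come to a
        criterion for the result to be flagged as borderline (0.02).
    loads, trials_per_load
        Applied masses in kg and repeat count per load: 50 and 60 kg, six
        trials each, for the 41-43 cm cushion-width class.
    """

    redistribution_threshold: dict[BModel, float] = field(
        default_factory=lambda: {BModel.ELLIPTICAL: 0.50, BModel.TRIGONOMETRIC: 0.55}
    )
    lel: float = 0.9
    uel: float = 1.1
    ci_multiplier: float = 1.0
    outlier_fraction: float = 0.5
    borderline_tolerance: float = 0.02
    loads: tuple[float, ...] = (50.0, 60.0)
    trials_per_load: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.lel < 1 < self.uel:
            raise ValueError(f"equivalence limits must satisfy 0 < lel < 1 < uel, "
                             f"got lel={self.lel}, uel={self.uel}")
        for model, tau in self.redistribution_threshold.items():
            if not 0 < tau < 1:
                raise ValueError(f"redistribution threshold for {model} must be in (0,1)")
        if self.outlier_fraction <= 0:
            raise ValueError("outlier_fraction must be > 0")
        if self.ci_multiplier <= 0:
            raise ValueError("ci_multiplier must be > 0")
        if self.borderline_tolerance < 0:
            raise ValueError("borderline_tolerance must be >= 0")
        if self.trials_per_load < 1:
            raise ValueError("trials_per_load must be >= 1")
        self.loads = tuple(float(x) for x in self.loads)

    def to_dict(self) -> dict:
        return {
            "redistribution_threshold": {
                m.value: t for m, t in self.redistribution_threshold.items()
            },
            "lel": self.lel,
            "uel": self.uel,
            "ci_multiplier": self.ci_multiplier,
            "outlier_fraction": self.outlier_fraction,
            "borderline_tolerance": self.borderline_tolerance,
            "loads": list(self.loads),
            "trials_per_load": self.trials_per_load,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ThresholdConfig":
        kwargs = dict(data)
        if "redistribution_threshold" in kwargs:
            kwargs["redistribution_threshold"] = _as_model_map(
                kwargs["redistribution_threshold"]
            )
        if "loads" in kwargs:
            kwargs["loads"] = tuple(float(x) for x in kwargs["loads"])
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class IntervalEstimate:
    """A pooled parameter estimate: mean, spread, and interval bounds.

    For the standard pooled form the interval is mean ± z·sd/sqrt(n), hence
    symmetric about the mean.
    """

    mean: float
    sd: float
    n: int
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        tol = 1e-12 * max(1.0, abs(self.mean))
        if not (self.lower <= self.mean + tol and self.mean <= self.upper + tol):
            raise ValueError(
                f"interval bounds must bracket the mean: "
                f"[{self.lower}, {self.upper}] vs {self.mean}"
            )

    @property
    def half_width(self) -> float:
        return (self.upper - self.lower) / 2.0
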