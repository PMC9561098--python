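"""Seeded synthetic-trial generator: a virtual test rig for the pipeline.

Physical bench testing loads an instrumented buttock model onto a cushion and
records sensor pressures.  This module replaces the rig with a parametric
virtual cushion: the user designs the quantities the analysis is supposed to
recover — the bony-load fraction per model shape, the internal-pressure ratio
relative to a reference foam — and the generator emits trial records whose
noise-free channel values realise those designs exactly, then perturbs each
channel with multiplicative noise of a chosen coefficient of variation (CV).

Noise is multiplicative (a unit-mean lognormal factor) rather than additive:
sensor pressures are nonnegative by construction and bench repeatability for
this procedure is characterised as a CV, which maps directly onto a
multiplicative model.  Within each role class the surface budget is split
equally across channels; the redistribution parameter depends only on class
sums, so per-channel spatial structure is not modelled.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import BModel, SensorLayout, ThresholdConfig, TrialRecord, default_layout


class SpecValidationError(ValueError):
    """A virtual-cushion spec field failed validation."""


def _both_models(value: float) -> dict[BModel, float]:
    return {BModel.ELLIPTICAL: float(value), BModel.TRIGONOMETRIC: float(value)}


def default_surface_budget(load: float) -> float:
    """Total surface-sensor pressure budget in mmHg at an applied load in kg.

    Scales linearly with load from a nominal 55 mmHg mean per sensor at
    50 kg (12 sensors -> 660 mmHg total), a magnitude typical of interface
    pressures measured under a loaded buttock model.
    """
    return 13.2 * load


@dataclass
class VirtualCushionSpec:
    """Design parameters of a simulated cushion.

    bony_fraction
        Designed fraction of total surface pressure under the bony sensor
        set, per model shape; this is the quantity the redistribution
        analysis estimates.
    internal_ratio
        Designed ratio of this cushion's expected internal-pressure sum to
        ``internal_reference_mean``; the magnitude analysis estimates it.
    internal_reference_mean
        Expected internal-pressure sum (mmHg) of the reference material the
        ratio is designed against, per model.
    total_surface_load
        Total surface pressure budget (mmHg) per (model, load); defaults to
        :func:`default_surface_budget`.
    channel_cv
        Per-channel noise CV by channel class.  Defaults (internal 0.02,
        surface 0.05) sit at the scale of the procedure's bench
        repeatability: internal-sum CVs under 4% and surface-sum CVs under
        7% per condition.
    load_shift
        Additive change in bony fraction per +10 kg of load (default 0, a
        load-insensitive cushion); nonzero values widen the pooled interval,
        emulating cushions whose redistribution degrades with load.
    outlier_prob, outlier_scale
        Each surface datapoint is independently replaced by ``outlier_scale``
        times its value with probability ``outlier_prob``, emulating the
        erroneous readings discontinuous cushion surfaces can produce.
    """

    cushion_id: str
    bony_fraction: dict[BModel, float]
    internal_ratio: dict[BModel, float]
    internal_reference_mean: dict[BModel, float]
    total_surface_load: dict[tuple[BModel, float], float] | None = None
    channel_cv: dict[str, float] = field(
        default_factory=lambda: {"surface": 0.05, "internal": 0.02}
    )
    load_shift: float = 0.0
    outlier_prob: float = 0.0
    outlier_scale: float = 2.0
    seed: int = 0

    def validate(self, loads: Sequence[float] = (50.0, 60.0)) -> None:
        for model in BModel:
            if model not in self.bony_fraction:
                raise SpecValidationError(f"bony_fraction missing model {model.value}")
            for load in loads:
                beta = self.bony_fraction[model] + self.load_shift * (load - 50.0) / 10.0
                if not 0 < beta < 1:
                    raise SpecValidationError(
                        f"bony_fraction: designed fraction {beta:.3f} for "
                        f"{model.value} at {load} kg is outside (0, 1)"
                    )
            if self.internal_ratio.get(model, 0) <= 0:
                raise SpecValidationError(
                    f"internal_ratio: must be > 0 for model {model.value}"
                )
            if self.internal_reference_mean.get(model, 0) <= 0:
                raise SpecValidationError(
                    f"internal_reference_mean: must be > 0 for model {model.value}"
                )
        for cls in ("surface", "internal"):
            if self.channel_cv.get(cls, -1) < 0:
                raise SpecValidationError(f"channel_cv: CV for {cls!r} must be >= 0")
        if not 0 <= self.outlier_prob <= 1:
            raise SpecValidationError("outlier_prob: must be in [0, 1]")
        if self.outlier_scale <= 0:
            raise SpecValidationError("outlier_scale: must be > 0")
        if self.total_surface_load is not None:
            for key, budget in self.total_surface_load.items():
                if budget <= 0:
                    raise SpecValidationError(
                        f"total_surface_load: budget for {key} must be > 0"
                    )

    def surface_budget(self, model: BModel, load: float) -> float:
        if self.total_surface_load is not None:
            key = (model, float(load))
            if key in self.total_surface_load:
                return self.total_surface_load[key]
        return default_surface_budget(load)

    # --- JSON sidecar -----------------------------------------------------

    def to_dict(self) -> dict:
        data = {
            "cushion_id": self.cushion_id,
            "bony_fraction": {m.value: v for m, v in self.bony_fraction.items()},
            "internal_ratio": {m.value: v for m, v in self.internal_ratio.items()},
            "internal_reference_mean": {
                m.value: v for m, v in self.internal_reference_mean.items()
            },
            "channel_cv": dict(self.channel_cv),
            "load_shift": self.load_shift,
            "outlier_prob": self.outlier_prob,
            "outlier_scale": self.outlier_scale,
            "seed": self.seed,
        }
        if self.total_surface_load is not None:
            data["total_surface_load"] = {
                f"{m.value}:{load:g}": v
                for (m, load), v in self.total_surface_load.items()
            }
        return data

    @classmethod
    def from_dict(cls, data: Mapping) -> "VirtualCushionSpec":
        kwargs = dict(data)
        for key in ("bony_fraction", "internal_ratio", "internal_reference_mean"):
            kwargs[key] = {BModel.parse(m): float(v) for m, v in kwargs[key].items()}
        if kwargs.get("total_surface_load") is not None:
            kwargs["total_surface_load"] = {
                (BModel.parse(k.split(":")[0]), float(k.split(":")[1])): float(v)
                for k, v in kwargs["total_surface_load"].items()
            }
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "VirtualCushionSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multiplicative factors with coefficient of variation cv.

    A lognormal with sigma^2 = ln(1 + cv^2) and mu = -sigma^2/2 has mean 1 and
    SD cv exactly; at cv = 0 the factor degenerates to 1.  The rng is always
    consumed so that toggling a CV to zero does not shift downstream draws.
    """
    draws = rng.standard_normal(size)
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(sigma * draws - 0.5 * sigma * sigma)


def simulate_trials(
    spec: VirtualCushionSpec,
    config: ThresholdConfig | None = None,
    layout: SensorLayout | None = None,
) -> list[TrialRecord]:
    """Generate the full trial battery for one virtual cushion.

    Emits ``trials_per_load`` records for each (model, load) combination in a
    fixed order.  Identical spec (including seed) and config always produce
    identical output.
    """
    config = config or ThresholdConfig()
    layout = layout or default_layout()
    if not config.loads:
        raise ValueError("config.loads must be nonempty")
    spec.validate(config.loads)

    rng = np.random.default_rng(spec.seed)
    bony = sorted(layout.bony_ids)
    nonbony = sorted(layout.nonbony_ids)
    records: list[TrialRecord] = []
    for model in BModel:
        exp_sumint = spec.internal_ratio[model] * spec.internal_reference_mean[model]
        for load in config.loads:
            beta = spec.bony_fraction[model] + spec.load_shift * (load - 50.0) / 10.0
            budget = spec.surface_budget(model, load)
            base_surface = {c: beta * budget / 6.0 for c in bony}
            base_surface.update({c: (1 - beta) * budget / 6.0 for c in nonbony})
            base_internal = {c: exp_sumint / 3.0 for c in layout.internal_ids}
            for trial in range(1, config.trials_per_load + 1):
                sf = _noise_factors(rng, spec.channel_cv["surface"], 12)
                surface = {
                    c: float(base_surface[c] * sf[i])
                    for i, c in enumerate(layout.surface_ids)
                }
                if spec.outlier_prob > 0:
                    hits = rng.random(12) < spec.outlier_prob
                    for i, c in enumerate(layout.surface_ids):
                        if hits[i]:
                            surface[c] *= spec.outlier_scale
                intf = _noise_factors(rng, spec.channel_cv["internal"], 3)
                internal = {
                    c: float(base_internal[c] * intf[i])
                    for i, c in enumerate(layout.internal_ids)
                }
                records.append(
                    TrialRecord(
                        cushion_id=spec.cushion_id,
                        model=model,
                        load=float(load),
                        trial_index=trial,
                        surface=surface,
                        internal=internal,
                    )
                )
    return records


# --- Reference foam presets ----------------------------------------------
#
# Flat high-resiliency HR45 foam blocks serve as the comparison standards:
# 3-inch foam for the skin-protection tier, 2-inch for general use.  The
# designed bony fractions reproduce the bench characterisation of these
# materials (elliptical/trigonometric 0.50/0.56 for 3", 0.52/0.64 for 2");
# the thinner 2" block bottoms out more, concentrating both surface load
# under the protuberances and internal pressure on the substructure, hence
# its higher expected internal sums.  Internal-sum magnitudes are nominal
# values consistent with bony-prominence loading under a seated model.

FOAM_PRESETS: dict[str, dict] = {
    "foam_3in": {
        "cushion_id": "HR45_3in",
        "bony_fraction": {BModel.ELLIPTICAL: 0.50, BModel.TRIGONOMETRIC: 0.56},
        "internal_reference_mean": {BModel.ELLIPTICAL: 210.0, BModel.TRIGONOMETRIC: 240.0},
    },
    "foam_2in": {
        "cushion_id": "HR45_2in",
        "bony_fraction": {BModel.ELLIPTICAL: 0.52, BModel.TRIGONOMETRIC: 0.64},
        "internal_reference_mean": {BModel.ELLIPTICAL: 270.0, BModel.TRIGONOMETRIC: 310.0},
    },
}


def reference_spec(
    thickness: str,
    seed: int = 0,
    channel_cv: Mapping[str, float] | None = None,
) -> VirtualCushionSpec:
    """Build the VirtualCushionSpec of a reference foam block."""
    try:
        preset = FOAM_PRESETS[thickness]
    except KeyError:
        raise ValueError(
            f"unknown reference thickness {thickness!r}; "
            f"expected one of {sorted(FOAM_PRESETS)}"
        ) from None
    cv = dict(channel_cv) if channel_cv is not None else {"surface": 0.05, "internal": 0.02}
    return VirtualCushionSpec(
        cushion_id=preset["cushion_id"],
        bony_fraction=dict(preset["bony_fraction"]),
        internal_ratio=_both_models(1.0),
        internal_reference_mean=dict(preset["internal_reference_mean"]),
        channel_cv=cv,
        seed=seed,
    )


def make_reference(
    thickness: str,
    seed: int = 0,
    config: ThresholdConfig | None = None,
    channel_cv: Mapping[str, float] | None = None,
) -> list[TrialRecord]:
    """Simulate the trial battery of a reference foam block (2" or 3" HR45)."""
    return simulate_trials(reference_spec(thickness, seed, channel_cv), config)


def cushion_spec(
    cushion_id: str,
    bony_fraction: Mapping[BModel, float],
    internal_ratio: Mapping[BModel, float],
    reference: str = "foam_3in",
    channel_cv: Mapping[str, float] | None = None,
    seed: int = 0,
    **kwargs,
) -> VirtualCushionSpec:
    """Convenience constructor: a cushion designed against a foam preset.

    ``internal_ratio`` is interpreted relative to the named preset's expected
    internal sums, so evaluating the cushion against trials from
    :func:`make_reference` for the same preset recovers the designed ratio.
    """
    preset = FOAM_PRESETS[reference]
    cv = dict(channel_cv) if channel_cv is not None else {"surface": 0.05, "internal": 0.02}
    return VirtualCushionSpec(
        cushion_id=cushion_id,
        bony_fraction={m: float(bony_fraction[m]) for m in BModel},
        internal_ratio={m: float(internal_ratio[m]) for m in BModel},
        internal_reference_mean=dict(preset["internal_reference_mean"]),
        channel_cv=cv,
        seed=seed,
        **kwargs,
    )
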