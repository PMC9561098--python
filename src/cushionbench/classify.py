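"""Trichotomous classification and the overall performance matrix.

Both performance parameters are classified by where a confidence interval
lies relative to a criterion, never by the point estimate alone:

*   redistribution — High when the entire interval falls below the model's
    criterion fraction (0.50 elliptical / 0.55 trigonometric), Low when it
    lies entirely above, Moderate when it includes the criterion.  The
    comparisons are strict, so an interval bound exactly on the criterion is
    Moderate.

*   magnitude — the test/reference ratio interval against equivalence limits
    0.9 and 1.1: Superior when the whole interval is <= the lower limit,
    Inferior when it is >= the upper limit, Comparable otherwise.  These
    comparisons are non-strict, mirroring the "less/greater than or equal"
    wording of the equivalence-band definitions.

Per-model classes then feed a five-tier overall matrix, from first-level
pressure management (High redistribution and Superior magnitude on both
model shapes against the 3" foam reference) down to below-minimum (Inferior
to the 2" foam on the elliptical model).  Intervals whose bounds come within
a tolerance of a criterion are flagged borderline, which motivates running
additional trials rather than accepting a knife-edge classification.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from .core import BModel, IntervalEstimate, ThresholdConfig
from .stats import RatioEstimate


class RedistributionClass(str, Enum):
    HIGH = "High"
    MODERATE = "Moderate"
    LOW = "Low"


class MagnitudeClass(str, Enum):
    SUPERIOR = "Superior"
    COMPARABLE = "Comparable"
    INFERIOR = "Inferior"


class OverallLevel(str, Enum):
    LEVEL1 = "Level1"
    LEVEL2 = "Level2"
    LEVEL3 = "Level3"
    GENERAL_USE = "GeneralUse"
    BELOW_MINIMUM = "BelowMinimum"
    INDETERMINATE = "Indeterminate"


# rank orders for "at least" comparisons in the matrix
_REDIS_RANK = {
    RedistributionClass.LOW: 0,
    RedistributionClass.MODERATE: 1,
    RedistributionClass.HIGH: 2,
}
_MAG_RANK = {
    MagnitudeClass.INFERIOR: 0,
    MagnitudeClass.COMPARABLE: 1,
    MagnitudeClass.SUPERIOR: 2,
}


def classify_redistribution(
    interval: IntervalEstimate,
    model: BModel,
    config: ThresholdConfig | None = None,
) -> RedistributionClass:
    """Classify a pooled %Bony interval against the model's criterion."""
    config = config or ThresholdConfig()
    tau = config.redistribution_threshold[model]
    if interval.upper < tau:
        return RedistributionClass.HIGH
    if interval.lower > tau:
        return RedistributionClass.LOW
    return RedistributionClass.MODERATE


def classify_magnitude(
    ratio: RatioEstimate,
    config: ThresholdConfig | None = None,
    warnings: list[str] | None = None,
) -> MagnitudeClass:
    """Classify a test/reference ratio interval against the equivalence limits.

    An unbounded (degenerate Fieller) interval cannot establish either a
    superior or an inferior difference, so it is Comparable; a warning is
    appended to ``warnings`` when provided.
    """
    config = config or ThresholdConfig()
    if ratio.unbounded:
        if warnings is not None:
            warnings.append(
                "ratio interval unbounded (reference mean not significant); "
                "classified Comparable by default"
            )
        return MagnitudeClass.COMPARABLE
    if ratio.upper <= config.lel:
        return MagnitudeClass.SUPERIOR
    if ratio.lower >= config.uel:
        return MagnitudeClass.INFERIOR
    return MagnitudeClass.COMPARABLE


def assign_level(
    redistribution: Mapping[BModel, RedistributionClass],
    magnitude_3in: Mapping[BModel, MagnitudeClass] | None = None,
    magnitude_2in: Mapping[BModel, MagnitudeClass] | None = None,
) -> OverallLevel:
    """Apply the classification matrix, highest tier first.

    Tiers (with High > Moderate > Low and Superior > Comparable > Inferior):

    * Level1 — High redistribution on both models and Superior magnitude on
      both models against the 3" reference.
    * Level2 — at least Moderate on both models and at least Comparable on
      both models against the 3" reference.
    * Level3 — at least Moderate and at least Comparable (vs 3") on the
      elliptical model alone.
    * GeneralUse — at least Comparable on the elliptical model against the
      2" reference (the matrix states no redistribution requirement here).
    * BelowMinimum — Inferior to the 2" reference on the elliptical model.

    A tier whose inputs are absent cannot be awarded; if no tier's inputs are
    available at all — or the available inputs cannot settle any tier — the
    result is Indeterminate.
    """
    magnitude_3in = magnitude_3in or {}
    magnitude_2in = magnitude_2in or {}
    e, t = BModel.ELLIPTICAL, BModel.TRIGONOMETRIC

    def redis_at_least(model: BModel, floor: RedistributionClass) -> bool:
        cls = redistribution.get(model)
        return cls is not None and _REDIS_RANK[cls] >= _REDIS_RANK[floor]

    def mag_at_least(
        table: Mapping[BModel, MagnitudeClass], model: BModel, floor: MagnitudeClass
    ) -> bool:
        cls = table.get(model)
        return cls is not None and _MAG_RANK[cls] >= _MAG_RANK[floor]

    if (
        redistribution.get(e) == RedistributionClass.HIGH
        and redistribution.get(t) == RedistributionClass.HIGH
        and magnitude_3in.get(e) == MagnitudeClass.SUPERIOR
        and magnitude_3in.get(t) == MagnitudeClass.SUPERIOR
    ):
        return OverallLevel.LEVEL1
    if (
        redis_at_least(e, RedistributionClass.MODERATE)
        and redis_at_least(t, RedistributionClass.MODERATE)
        and mag_at_least(magnitude_3in, e, MagnitudeClass.COMPARABLE)
        and mag_at_least(magnitude_3in, t, MagnitudeClass.COMPARABLE)
    ):
        return OverallLevel.LEVEL2
    if redis_at_least(e, RedistributionClass.MODERATE) and mag_at_least(
        magnitude_3in, e, MagnitudeClass.COMPARABLE
    ):
        return OverallLevel.LEVEL3
    if mag_at_least(magnitude_2in, e, MagnitudeClass.COMPARABLE):
        return OverallLevel.GENERAL_USE
    if magnitude_2in.get(e) == MagnitudeClass.INFERIOR:
        return OverallLevel.BELOW_MINIMUM
    return OverallLevel.INDETERMINATE


@dataclass(frozen=True)
class BorderlineFlag:
    """An interval bound within tolerance of a classification criterion."""

    parameter: str
    model: BModel | None
    threshold: float
    distance: float


def flag_borderline(
    interval: IntervalEstimate | RatioEstimate,
    thresholds: Sequence[float],
    config: ThresholdConfig | None = None,
    parameter: str = "",
    model: BModel | None = None,
) -> list[BorderlineFlag]:
    """Flag criteria whose nearest interval bound lies within the tolerance.

    The distance to a criterion is min(|upper - tau|, |lower - tau|); a
    criterion is flagged when that distance is below the configured
    tolerance, since shifting or shrinking the interval by so small an
    amount could change the classification.  Unbounded intervals are never
    flagged — their problem is width, not proximity.
    """
    config = config or ThresholdConfig()
    unbounded = getattr(interval, "unbounded", False)
    if unbounded:
        return []
    flags = []
    for tau in thresholds:
        distance = min(abs(interval.upper - tau), abs(interval.lower - tau))
        if distance < config.borderline_tolerance:
            flags.append(BorderlineFlag(parameter, model, tau, distance))
    return flags


@dataclass
class ModelResult:
    """Per-model classification outputs for one cushion."""

    redistribution_interval: IntervalEstimate | None = None
    redistribution_class: RedistributionClass | None = None
    magnitude_3in: RatioEstimate | None = None
    magnitude_3in_class: MagnitudeClass | None = None
    magnitude_2in: RatioEstimate | None = None
    magnitude_2in_class: MagnitudeClass | None = None


@dataclass
class CushionReport:
    """Complete evaluation result for one cushion."""

    cushion_id: str
    per_model: dict[BModel, ModelResult] = field(default_factory=dict)
    overall_level: OverallLevel = OverallLevel.INDETERMINATE
    borderline_flags: list[BorderlineFlag] = field(default_factory=list)
    retest_suggestions: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    config: ThresholdConfig | None = None

    def to_dict(self) -> dict:
        def _interval(iv):
            if iv is None:
                return None
            return {
                "mean": iv.mean, "sd": iv.sd, "n": iv.n,
                "lower": iv.lower, "upper": iv.upper,
            }

        def _ratio(r):
            if r is None:
                return None
            return {
                "ratio": r.ratio, "lower": r.lower, "upper": r.upper,
                "method": r.method, "n_test": r.n_test, "n_ref": r.n_ref,
                "unbounded": r.unbounded,
            }

        return {
            "cushion_id": self.cushion_id,
            "per_model": {
                m.value: {
                    "redistribution_interval": _interval(res.redistribution_interval),
                    "redistribution_class": (
                        res.redistribution_class.value
                        if res.redistribution_class else None
                    ),
                    "magnitude_3in": _ratio(res.magnitude_3in),
                    "magnitude_3in_class": (
                        res.magnitude_3in_class.value
                        if res.magnitude_3in_class else None
                    ),
                    "magnitude_2in": _ratio(res.magnitude_2in),
                    "magnitude_2in_class": (
                        res.magnitude_2in_class.value
                        if res.magnitude_2in_class else None
                    ),
                }
                for m, res in self.per_model.items()
            },
            "overall_level": self.overall_level.value,
            "borderline_flags": [
                {
                    "parameter": f.parameter,
                    "model": f.model.value if f.model else None,
                    "threshold": f.threshold,
                    "distance": f.distance,
                }
                for f in self.borderline_flags
            ],
            "retest_suggestions": list(self.retest_suggestions),
            "warnings": list(self.warnings),
            "config": self.config.to_dict() if self.config else None,
        }

    def to_markdown(self) -> str:
        """Render the report as a markdown table, one row per model."""
        lines = [
            f"## Cushion: {self.cushion_id}",
            "",
            "| Model | %Bony mean | CI- | CI+ | Redistribution "
            "| Ratio vs 3\" | Class vs 3\" | Ratio vs 2\" | Class vs 2\" |",
            "|---|---|---|---|---|---|---|---|---|",
        ]
        for model, res in self.per_model.items():
            iv = res.redistribution_interval

            def _f(x):
                return f"{x:.3f}" if x is not None else "-"

            r3 = res.magnitude_3in
            r2 = res.magnitude_2in
            lines.append(
                "| {m} | {mean} | {lo} | {hi} | {rc} | {r3} | {c3} | {r2} | {c2} |".format(
                    m=model.value,
                    mean=_f(iv.mean if iv else None),
                    lo=_f(iv.lower if iv else None),
                    hi=_f(iv.upper if iv else None),
                    rc=res.redistribution_class.value if res.redistribution_class else "-",
                    r3=_f(r3.ratio if r3 else None),
                    c3=res.magnitude_3in_class.value if res.magnitude_3in_class else "-",
                    r2=_f(r2.ratio if r2 else None),
                    c2=res.magnitude_2in_class.value if res.magnitude_2in_class else "-",
                )
            )
        lines += ["", f"**Overall level:** {self.overall_level.value}"]
        if self.borderline_flags:
            lines.append("")
            lines.append("Borderline criteria:")
            for f in self.borderline_flags:
                where = f" ({f.model.value})" if f.model else ""
                lines.append(
                    f"- {f.parameter}{where}: threshold {f.threshold:g}, "
                    f"distance {f.distance:.3f}"
                )
        if self.retest_suggestions:
            lines.append("")
            lines.append("Retest suggestions: " + ", ".join(self.retest_suggestions))
        return "\n".join(lines) + "\n"


def suggest_retests(report: CushionReport) -> list[str]:
    """Follow-up testing codes implied by a report.

    * ``compare_vs_3in`` — the cushion beat the 2" general-use reference on
      some model but was never compared against the stricter 3" reference;
      it may in fact be comparable to it.
    * ``add_trials`` — at least one classification is borderline; more
      trials would tighten the interval and could settle it.
    """
    codes: list[str] = []
    superior_vs_2 = any(
        res.magnitude_2in_class == MagnitudeClass.SUPERIOR
        for res in report.per_model.values()
    )
    has_3in = any(res.magnitude_3in is not None for res in report.per_model.values())
    if superior_vs_2 and not has_3in:
        codes.append("compare_vs_3in")
    if report.borderline_flags:
        codes.append("add_trials")
    return codes
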