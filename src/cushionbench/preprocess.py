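"""Cleaning of raw trial data: aggregation, outlier flagging, imputation.

Surface sensors on cushions with discontinuous loading surfaces (fluid
bladders, segmented air cells) can occasionally report erroneous values when
the surface deflects away from a sensor.  The cleaning rule is
median-referenced: within one model-load condition, a surface datapoint that
differs from its channel's median across the repeated trials by 50% or more
of that median is flagged.  A median reference is preferred over a z-score
with only six trials per condition.

Because every buttock location carries two axisymmetric sensors, a flagged
value is recovered by substituting its partner's reading from the same trial;
only when both members of a pair are flagged is the whole trial excluded from
parameter computation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

from .core import BModel, SensorLayout, ThresholdConfig, TrialRecord, default_layout

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutlierFlag:
    """One surface datapoint flagged as an outlier within its condition."""

    cushion_id: str
    model: BModel
    load: float
    trial_index: int
    channel_id: int
    observed: float
    condition_median: float


def aggregate_samples(samples: Sequence[float], window: int = 30) -> float:
    """Collapse a time-ordered 1 Hz pressure series to a per-trial value.

    Uses the arithmetic mean of the last ``window`` samples, by which point
    the load has settled after the hold period.
    """
    if len(samples) == 0:
        raise ValueError("sample series is empty")
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(samples):
        raise ValueError(
            f"window ({window}) exceeds series length ({len(samples)})"
        )
    tail = samples[-window:]
    return float(sum(tail)) / window


def _group_conditions(
    trials: Iterable[TrialRecord],
) -> dict[tuple[str, BModel, float], list[TrialRecord]]:
    groups: dict[tuple[str, BModel, float], list[TrialRecord]] = {}
    for rec in trials:
        groups.setdefault((rec.cushion_id, rec.model, rec.load), []).append(rec)
    return groups


def detect_outliers(
    trials: Sequence[TrialRecord],
    config: ThresholdConfig | None = None,
) -> list[OutlierFlag]:
    """Flag surface datapoints deviating >= outlier_fraction from the condition median.

    The median is taken per surface channel across the trials of one
    (cushion, model, load) condition.  Internal channels are never flagged:
    they sit at the substructure-elastomer interface and are not exposed to
    the discontinuous-surface artefact this rule targets.
    """
    config = config or ThresholdConfig()
    flags: list[OutlierFlag] = []
    for (cushion, model, load), group in _group_conditions(trials).items():
        if len(group) < 2:
            raise ValueError(
                f"condition ({cushion}, {model.value}, {load} kg) has fewer "
                f"than 2 trials; the median rule needs repeats"
            )
        channels = sorted(group[0].surface)
        for channel in channels:
            values = [rec.surface[channel] for rec in group]
            med = float(median(values))
            for rec in group:
                x = rec.surface[channel]
                if abs(x - med) >= config.outlier_fraction * med:
                    flags.append(
                        OutlierFlag(
                            cushion_id=cushion,
                            model=model,
                            load=load,
                            trial_index=rec.trial_index,
                            channel_id=channel,
                            observed=x,
                            condition_median=med,
                        )
                    )
    return flags


def impute_outliers(
    trials: Sequence[TrialRecord],
    flags: Sequence[OutlierFlag],
    layout: SensorLayout | None = None,
) -> list[TrialRecord]:
    """Replace flagged values by their axisymmetric partner; exclude unrecoverable trials.

    Each flagged surface value is overwritten with its partner sensor's value
    from the same trial (the partner samples the mirrored buttock location).
    If both members of a pair are flagged in one trial, no valid donor exists
    and the trial is marked ``excluded`` — a recorded outcome, logged as a
    warning, not an error.  Unflagged channels are never modified.
    """
    layout = layout or default_layout()
    flag_index: dict[tuple[str, BModel, float, int], set[int]] = {}
    for f in flags:
        key = (f.cushion_id, f.model, f.load, f.trial_index)
        flag_index.setdefault(key, set()).add(f.channel_id)

    cleaned: list[TrialRecord] = []
    for rec in trials:
        key = (rec.cushion_id, rec.model, rec.load, rec.trial_index)
        flagged = flag_index.get(key)
        if not flagged:
            cleaned.append(rec)
            continue
        new = rec.copy()
        new.excluded_flags = frozenset(rec.excluded_flags | flagged)
        dead_pair = False
        for channel in sorted(flagged):
            partner = layout.partner(channel)
            if partner in flagged:
                dead_pair = True
                continue
            new.surface[channel] = rec.surface[partner]
        if dead_pair:
            new.excluded = True
            logger.warning(
                "trial %d (%s, %s, %g kg): both members of an axisymmetric "
                "pair flagged; trial excluded from parameter computation",
                rec.trial_index, rec.cushion_id, rec.model.value, rec.load,
            )
        cleaned.append(new)
    return cleaned


def clean_trials(
    trials: Sequence[TrialRecord],
    config: ThresholdConfig | None = None,
    layout: SensorLayout | None = None,
) -> tuple[list[TrialRecord], list[OutlierFlag]]:
    """Detect and impute in one step; returns (cleaned trials, flags)."""
    flags = detect_outliers(trials, config)
    return impute_outliers(trials, flags, layout), flags
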