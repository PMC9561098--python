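"""End-to-end evaluation: raw trials in, classified cushion report out."""
from __future__ import annotations

import logging
from typing import Sequence

from .classify import (
    CushionReport,
    ModelResult,
    classify_magnitude,
    classify_redistribution,
    flag_borderline,
    suggest_retests,
)
from .core import BModel, SensorLayout, ThresholdConfig, TrialRecord, default_layout
from .preprocess import clean_trials
from .stats import Parameter, collect_parameters, pooled_interval, ratio_interval
from . import classify as _classify

logger = logging.getLogger(__name__)


def _reference_sumint(
    trials: Sequence[TrialRecord] | None,
    config: ThresholdConfig,
    layout: SensorLayout,
):
    """Clean a reference battery and return its SumInt samples per model."""
    if trials is None:
        return None
    cleaned, flags = clean_trials(trials, config, layout)
    if flags:
        logger.info("reference %s: %d outlier flag(s)", cleaned[0].cushion_id, len(flags))
    params = collect_parameters(cleaned, layout)
    return {
        model: params[(model, Parameter.SUM_INTERNAL)]
        for model in BModel
        if (model, Parameter.SUM_INTERNAL) in params
    }


def evaluate_cushion(
    test_trials: Sequence[TrialRecord],
    ref3_trials: Sequence[TrialRecord] | None = None,
    ref2_trials: Sequence[TrialRecord] | None = None,
    config: ThresholdConfig | None = None,
    seed: int = 0,
    method: str = "fieller",
    layout: SensorLayout | None = None,
) -> CushionReport:
    """Run the full analysis for one cushion.

    Stages: outlier detection and axisymmetric imputation; per-trial
    redistribution and internal-sum parameters; pooling of all trials from
    both loads into one interval per model; ratio intervals against each
    provided reference foam; trichotomous classes; the overall matrix level;
    borderline flags and retest suggestions.

    Either reference may be absent, in which case the corresponding
    magnitude classes are simply not produced and the overall level is
    decided from what remains (possibly Indeterminate).  The seed only
    matters for the bootstrap ratio method.
    """
    config = config or ThresholdConfig()
    layout = layout or default_layout()
    if not test_trials:
        raise ValueError("no test trials provided")

    cleaned, flags = clean_trials(test_trials, config, layout)
    excluded = [r for r in cleaned if r.excluded]
    report = CushionReport(cushion_id=cleaned[0].cushion_id, config=config)
    if flags:
        report.warnings.append(f"{len(flags)} surface datapoint(s) flagged as outliers")
    if excluded:
        report.warnings.append(
            f"{len(excluded)} trial(s) excluded (both sensors of a pair flagged)"
        )

    params = collect_parameters(cleaned, layout)
    ref_samples = {
        "3in": _reference_sumint(ref3_trials, config, layout),
        "2in": _reference_sumint(ref2_trials, config, layout),
    }

    redis_classes: dict[BModel, _classify.RedistributionClass] = {}
    mag3_classes: dict[BModel, _classify.MagnitudeClass] = {}
    mag2_classes: dict[BModel, _classify.MagnitudeClass] = {}
    for model in BModel:
        key = (model, Parameter.BONY_FRACTION)
        if key not in params:
            report.warnings.append(f"no trials for model {model.value}")
            continue
        result = ModelResult()
        interval = pooled_interval(params[key], config)
        result.redistribution_interval = interval
        result.redistribution_class = classify_redistribution(interval, model, config)
        redis_classes[model] = result.redistribution_class
        tau = config.redistribution_threshold[model]
        report.borderline_flags.extend(
            flag_borderline(interval, [tau], config,
                            parameter="redistribution", model=model)
        )

        sumint = params[(model, Parameter.SUM_INTERNAL)]
        for ref_name, classes, attr in (
            ("3in", mag3_classes, "magnitude_3in"),
            ("2in", mag2_classes, "magnitude_2in"),
        ):
            refs = ref_samples[ref_name]
            if refs is None or model not in refs:
                continue
            ratio = ratio_interval(sumint, refs[model], method, config, seed)
            cls = classify_magnitude(ratio, config, report.warnings)
            setattr(result, attr, ratio)
            setattr(result, attr + "_class", cls)
            classes[model] = cls
            report.borderline_flags.extend(
                flag_borderline(ratio, [config.lel, config.uel], config,
                                parameter=f"magnitude_vs_{ref_name}", model=model)
            )
        report.per_model[model] = result

    report.overall_level = _classify.assign_level(redis_classes, mag3_classes, mag2_classes)
    report.retest_suggestions = suggest_retests(report)
    return report
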