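"""Reading and writing the pipeline's file formats.

All tabular data travels as long (tidy) CSV: one row per channel reading,
whether per-trial aggregates or per-sample 1 Hz streams, so both share one
schema.  Channels are identified as ``1``..``12`` (surface) and ``I1``..``I3``
(internal).  Pressures are calibrated mmHg.
"""
from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import BModel, SensorLayout, TrialRecord, default_layout
from .preprocess import OutlierFlag, aggregate_samples
from .stats import LiteratureIPMRecord

TRIAL_COLUMNS = [
    "cushion_id", "model", "load_kg", "trial", "channel", "class", "pressure_mmhg",
]


class TrialFormatError(ValueError):
    """A trial CSV violates the expected schema."""


def _parse_channel(token: str, cls: str, layout: SensorLayout) -> int | str:
    if cls == "surface":
        try:
            channel = int(token)
        except ValueError:
            raise TrialFormatError(
                f"surface channel {token!r} is not an integer"
            ) from None
        if channel not in layout.surface_ids:
            raise TrialFormatError(f"unknown surface channel {channel}")
        return channel
    if cls == "internal":
        if token not in layout.internal_ids:
            raise TrialFormatError(f"unknown internal channel {token!r}")
        return token
    raise TrialFormatError(f"unknown channel class {cls!r}; expected surface or internal")


def read_trials(
    path: str | Path,
    layout: SensorLayout | None = None,
) -> list[TrialRecord]:
    """Read per-trial CSV into validated TrialRecords.

    Expects the exact header ``cushion_id,model,load_kg,trial,channel,class,
    pressure_mmhg``.  If the file instead carries a ``t_s`` time column
    (per-sample 1 Hz data), each channel's series is first collapsed with
    :func:`cushionbench.preprocess.aggregate_samples`.
    """
    layout = layout or default_layout()
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    per_sample = "t_s" in df.columns
    expected = TRIAL_COLUMNS + (["t_s"] if per_sample else [])
    if sorted(df.columns) != sorted(expected):
        raise TrialFormatError(
            f"{path.name}: expected columns {expected}, found {list(df.columns)}"
        )
    if per_sample:
        df = df.sort_values("t_s")
        window = min(30, df.groupby(TRIAL_COLUMNS[:5])["t_s"].transform("size").min())
        df = (
            df.groupby(TRIAL_COLUMNS[:6], sort=False)["pressure_mmhg"]
            .apply(lambda s: aggregate_samples(list(s), window=int(window)))
            .reset_index()
        )

    records: dict[tuple, TrialRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            model = BModel.parse(str(row.model))
        except ValueError as exc:
            raise TrialFormatError(f"{path.name} line {i}: {exc}") from None
        try:
            load = float(row.load_kg)
            trial = int(row.trial)
            pressure = float(row.pressure_mmhg)
            channel = _parse_channel(str(getattr(row, "channel")),
                                     str(getattr(row, "_5", row[5])), layout)
        except TrialFormatError as exc:
            raise TrialFormatError(f"{path.name} line {i}: {exc}") from None
        except (TypeError, ValueError) as exc:
            raise TrialFormatError(f"{path.name} line {i}: malformed row ({exc})") from None
        key = (str(row.cushion_id), model, load, trial)
        rec = records.get(key)
        if rec is None:
            rec = TrialRecord(
                cushion_id=str(row.cushion_id), model=model, load=load,
                trial_index=trial, surface={}, internal={},
            )
            records[key] = rec
        target = rec.surface if isinstance(channel, int) else rec.internal
        if channel in target:
            raise TrialFormatError(
                f"{path.name} line {i}: duplicate reading for channel {channel} "
                f"in trial {trial} ({key[0]}, {model.value}, {load} kg)"
            )
        target[channel] = pressure

    out = list(records.values())
    for rec in out:
        rec.validate(layout)
    return out


def write_trials(
    records: Sequence[TrialRecord],
    path: str | Path,
    layout: SensorLayout | None = None,
) -> None:
    """Write TrialRecords as the standard long CSV (deterministic row order)."""
    layout = layout or default_layout()
    rows = []
    for rec in records:
        for channel in layout.surface_ids:
            rows.append((rec.cushion_id, rec.model.value, rec.load, rec.trial_index,
                         str(channel), "surface", repr(float(rec.surface[channel]))))
        for channel in layout.internal_ids:
            rows.append((rec.cushion_id, rec.model.value, rec.load, rec.trial_index,
                         channel, "internal", repr(float(rec.internal[channel]))))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False)


def write_flags(flags: Sequence[OutlierFlag], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (f.cushion_id, f.model.value, f.load, f.trial_index, f.channel_id,
             f.observed, f.condition_median)
            for f in flags
        ],
        columns=["cushion_id", "model", "load_kg", "trial", "channel",
                 "observed_mmhg", "condition_median_mmhg"],
    )
    df.to_csv(path, index=False)


def read_ipm_table(path: str | Path) -> list[LiteratureIPMRecord]:
    """Read a literature interface-pressure table: ``label,mean_mmHg,sd_mmHg,n``."""
    df = pd.read_csv(path)
    required = ["label", "mean_mmHg", "sd_mmHg", "n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrialFormatError(
            f"{Path(path).name}: missing columns {missing}; expected {required}"
        )
    return [
        LiteratureIPMRecord(
            label=str(r.label), mean=float(r.mean_mmHg),
            sd=float(r.sd_mmHg), n=int(r.n),
        )
        for r in df.itertuples(index=False)
    ]


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file, for audit logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
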