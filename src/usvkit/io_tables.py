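"""CSV schemas shared by the CLI and the pipeline.

detections.csv  recording_id, call_class, onset_s, offset_s, duration_ms,
                n_flagged_frames, source_pass
annotations.csv recording_id, call_class, call_type, onset_s, offset_s, snr_db
sessions.csv    rat_id, litter_id, treatment, batch, day, order, n50, n22
play.csv        rat_id, litter_id, treatment, batch, pinnings_delivered,
                pinnings_received
periods.csv     session_id, period_type, start_s, end_s
rates.csv       rat_id, session_id, period_type, total_duration_s, count,
                rate_per_s
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .detection import Detection, TruthAnnotation
from .session_metrics import RateRecord

__all__ = [
    "detections_to_df",
    "df_to_detections",
    "truth_to_df",
    "df_to_truth",
    "rates_to_df",
    "require_columns",
]


def require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"{what}: missing column(s) {missing}; present: {list(df.columns)}. "
            "Provide a column-mapping config if your file uses other names."
        )


def detections_to_df(dets: Sequence[Detection], recording_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                recording_id=recording_id,
                call_class=d.call_class,
                onset_s=d.onset_s,
                offset_s=d.offset_s,
                duration_ms=d.duration_ms,
                n_flagged_frames=d.n_flagged_frames,
                source_pass=d.source,
            )
            for d in dets
        ],
        columns=[
            "recording_id", "call_class", "onset_s", "offset_s",
            "duration_ms", "n_flagged_frames", "source_pass",
        ],
    )


def df_to_detections(df: pd.DataFrame) -> list[Detection]:
    require_columns(df, ["call_class", "onset_s", "offset_s"], "detections table")
    return [
        Detection(
            onset_s=float(r.onset_s),
            offset_s=float(r.offset_s),
            call_class=str(r.call_class),
            n_flagged_frames=int(getattr(r, "n_flagged_frames", 0)),
            source=str(getattr(r, "source_pass", "pass0")),
        )
        for r in df.itertuples()
    ]


def truth_to_df(truth: Sequence[TruthAnnotation], recording_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                recording_id=recording_id,
                call_class=t.call_class,
                call_type=t.call_type,
                onset_s=t.onset_s,
                offset_s=t.offset_s,
                snr_db=t.snr_db,
            )
            for t in truth
        ],
        columns=["recording_id", "call_class", "call_type", "onset_s", "offset_s", "snr_db"],
    )


def df_to_truth(df: pd.DataFrame) -> list[TruthAnnotation]:
    require_columns(df, ["call_class", "onset_s", "offset_s"], "annotations table")
    return [
        TruthAnnotation(
            onset_s=float(r.onset_s),
            offset_s=float(r.offset_s),
            call_class=str(r.call_class),
            call_type=str(getattr(r, "call_type", "")),
            snr_db=float(getattr(r, "snr_db", float("nan"))),
        )
        for r in df.itertuples()
    ]


def rates_to_df(
    rates: Sequence[RateRecord], rat_id: str = "", session_id: str = ""
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                rat_id=rat_id,
                session_id=session_id,
                period_type=r.period_type,
                total_duration_s=r.total_duration_s,
                count=r.count,
                rate_per_s=r.rate_per_s,
            )
            for r in rates
        ]
    )
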