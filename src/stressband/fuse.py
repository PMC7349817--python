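"""Merging per-segment features from all modalities into one table.

Each modality emits rows keyed by ``(session_id, t_start, t_end)`` on a
shared segment grid; merging is an inner join, so segments missing any
required modality are dropped (and counted) rather than imputed.
"""

from __future__ import annotations

import warnings
from functools import reduce

import pandas as pd

from . import acc as _acc
from . import eda as _eda
from . import hrv as _hrv
from .io_e4 import Session, ValidationError, slice_session

__all__ = ["merge_features", "extract_features", "extract_cohort_features"]

KEYS = ["session_id", "t_start", "t_end"]


def merge_features(*tables: pd.DataFrame, label: str | None = None) -> pd.DataFrame:
    """Inner-join modality tables on (session_id, t_start, t_end).

    Raises on duplicate keys within a table; warns when the join is empty.
    """
    present = [t for t in tables if t is not None and len(t)]
    if not present:
        warnings.warn("no feature rows to merge", stacklevel=2)
        return pd.DataFrame(columns=KEYS)
    for t in present:
        if t.duplicated(subset=KEYS).any():
            raise ValidationError("duplicate (session_id, t_start, t_end) keys")
    merged = reduce(lambda a, b: a.merge(b, on=KEYS, how="inner"), present)
    if not len(merged):
        warnings.warn("merged feature table is empty (disjoint segments)", stacklevel=2)
    if label is not None:
        merged = merged.assign(label=label)
    return merged.sort_values(KEYS).reset_index(drop=True)


def extract_features(
    session: Session,
    length: float = 120.0,
    overlap: float = 0.5,
    hrv_cfg: _hrv.ArtifactRuleConfig | None = None,
    eda_artifact_cfg: _eda.EDAArtifactConfig | None = None,
    decomp_cfg: _eda.DecompositionConfig | None = None,
) -> pd.DataFrame:
    """Extract and merge all per-segment features for one session.

    All modalities are synchronized to the latest modality start time (the
    heart-activity stream typically starts with a delay), so every merged
    segment covers the same ``[t_start, t_end)`` window of wall time.
    Modalities absent from the session are omitted and the merge degrades
    to the available ones; the inner join drops segments any present
    modality could not cover.
    """
    starts = [c.start_time for c in session.channels.values()]
    if session.beats is not None:
        starts.append(session.beats.start_time)
    if not starts:
        raise ValidationError("session has no channels")
    t0 = max(starts)
    sess = slice_session(session, t0, session.end_time) if t0 > session.start_time else session

    tables = []
    if sess.beats is not None and len(sess.beats):
        tables.append(
            _hrv.hrv_feature_table(
                sess.beats, sess.id, hrv_cfg, length=length, overlap=overlap,
                duration=sess.end_time - sess.start_time,
            )
        )
    if "EDA" in sess.channels:
        tables.append(
            _eda.eda_feature_table(
                sess.channels["EDA"],
                sess.acc(),
                sess.channels.get("TEMP"),
                sess.id,
                length=length,
                overlap=overlap,
                artifact_cfg=eda_artifact_cfg,
                decomp_cfg=decomp_cfg,
            )
        )
    acc_ch = sess.acc()
    if acc_ch is not None:
        tables.append(
            _acc.acc_feature_table(*acc_ch, sess.id, length=length, overlap=overlap)
        )
    return merge_features(*tables, label=session.label)


def extract_cohort_features(sessions, **kwargs) -> pd.DataFrame:
    """Concatenate :func:`extract_features` over a list of sessions."""
    frames = [extract_features(s, **kwargs) for s in sessions]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=KEYS)
    return pd.concat(frames, ignore_index=True)
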