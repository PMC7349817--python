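"""Relaxation-method suggestion from predicted stress and activity context.

When high stress is detected, the wearer's physical-activity context picks
the intervention: a restricted, still context (classroom, meeting, public
transport) suggests a mobile relaxation method; a free, active context
suggests a traditional one (yoga, guided mindfulness).  Below high stress
no intervention is suggested.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import acc as _acc
from . import fuse as _fuse
from . import model as _model
from .io_e4 import STRESS_LABELS, Session, ValidationError

__all__ = ["Suggestion", "suggest", "run_pipeline"]


@dataclass(frozen=True)
class Suggestion:
    value: str  # "mobile_relaxation" | "traditional_relaxation" | "none"
    stress: str
    context: str


def suggest(stress: str, context: _acc.ContextLabel | str) -> Suggestion:
    """Map (stress level, activity context) to a relaxation suggestion.

    Pure function: high + still → mobile relaxation, high + active →
    traditional relaxation, anything below high stress → none.
    """
    if isinstance(context, _acc.ContextLabel):
        context = context.value
    if stress not in STRESS_LABELS:
        raise ValidationError(f"unknown stress level {stress!r}")
    if context not in ("still", "active"):
        raise ValidationError(f"unknown context {context!r}")
    if stress != "high":
        value = "none"
    elif context == "still":
        value = "mobile_relaxation"
    else:
        value = "traditional_relaxation"
    return Suggestion(value=value, stress=stress, context=context)


def run_pipeline(
    session: Session,
    classifier: _model.StressLevelClassifier,
    columns: list[str] | None = None,
    stillness_cfg: _acc.StillnessConfig | None = None,
    debounce_s: float | None = None,
    **extract_kwargs,
) -> pd.DataFrame:
    """End-to-end per-segment report for one session.

    Cleans and segments the session, extracts merged features, predicts a
    stress level per segment, derives the whole-session stillness context,
    and emits one row per segment: ``t_start, t_end, predicted_label,
    stillness_ratio, context, suggestion``.  ``columns`` must match the
    feature set the classifier was trained on (defaults to every feature
    column).  ``debounce_s`` suppresses a repeat of the same non-trivial
    suggestion within that many seconds.
    """
    feats = _fuse.extract_features(session, **extract_kwargs)
    if not len(feats):
        raise ValidationError(
            f"session {session.id}: no usable segments "
            f"(channels: {sorted(session.channels)}, "
            f"beats: {len(session.beats) if session.beats else 0})"
        )
    acc_ch = session.acc()
    if acc_ch is None:
        raise ValidationError("context analysis needs the 3-axis ACC channel")
    summary = _acc.stillness_minutes(*acc_ch, stillness_cfg)
    context = _acc.classify_context(summary, stillness_cfg)
    cols = columns or _model.feature_columns(feats)
    preds = classifier.predict(feats[cols].to_numpy(dtype=float))
    rows = []
    last_suggest_t: float | None = None
    for (_, row), pred in zip(feats.iterrows(), preds):
        s = suggest(str(pred), context)
        value = s.value
        if value != "none" and debounce_s is not None:
            if last_suggest_t is not None and row["t_start"] - last_suggest_t < debounce_s:
                value = "none"
            else:
                last_suggest_t = row["t_start"]
        rows.append(
            {
                "session_id": session.id,
                "t_start": row["t_start"],
                "t_end": row["t_end"],
                "predicted_label": str(pred),
                "stillness_ratio": summary.ratio,
                "context": context.value,
                "suggestion": value,
            }
        )
    return pd.DataFrame(rows)
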