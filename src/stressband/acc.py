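"""Accelerometer features and the stillness-based context signal.

Stillness is defined minute-by-minute: a minute counts as still when at
least 95% of its net-motion samples (deviation of the acceleration
magnitude from 1 g, so a motionless wrist is still despite gravity) fall
below 0.1 g.  The fraction of still minutes in a session is then
thresholded at 20% to label the wearer's context as still or active.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_e4 import SampledChannel, ValidationError

__all__ = [
    "ACCFeatures",
    "StillnessConfig",
    "StillnessSummary",
    "ContextLabel",
    "acc_features",
    "stillness_minutes",
    "classify_context",
    "acc_feature_table",
]


@dataclass
class ACCFeatures:
    mean_x: float = np.nan  # g
    mean_y: float = np.nan
    mean_z: float = np.nan
    mean_acc_mag: float = np.nan  # g
    energy: float = np.nan  # g², spectral energy of the DC-removed magnitude

    def as_dict(self, prefix: str = "acc_") -> dict[str, float]:
        return {prefix + k: v for k, v in self.__dict__.items()}


def magnitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    return np.sqrt(
        np.asarray(x, float) ** 2 + np.asarray(y, float) ** 2 + np.asarray(z, float) ** 2
    )


def acc_features(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> ACCFeatures:
    """Axis means, mean magnitude, and FFT energy of the magnitude.

    The energy is the spectral sum of squares of the mean-removed magnitude
    with Parseval-consistent normalization, so it equals the time-domain
    sum of squared deviations.
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if len(x) == 0 or len(x) != len(y) or len(x) != len(z):
        raise ValidationError("acc segment must be nonempty with equal-length axes")
    mag = magnitude(x, y, z)
    ac = mag - mag.mean()
    spec = np.fft.rfft(ac)
    # rfft halves the negative-frequency bins; double them to keep Parseval
    w = np.full(len(spec), 2.0)
    w[0] = 1.0
    if len(ac) % 2 == 0:
        w[-1] = 1.0
    energy = float(np.sum(w * np.abs(spec) ** 2) / len(ac))
    return ACCFeatures(
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        mean_z=float(z.mean()),
        mean_acc_mag=float(mag.mean()),
        energy=energy,
    )


@dataclass
class StillnessConfig:
    still_threshold: float = 0.1  # g, on net motion |mag - 1 g|
    frac_required: float = 0.95  # fraction of a minute below threshold
    ratio_threshold: float = 0.2  # still-minute ratio separating contexts
    net_motion: bool = True  # False: threshold the raw magnitude instead
    literal_rule: bool = False  # True: low still-minute ratio ⇒ "still"


@dataclass
class StillnessSummary:
    minute_flags: np.ndarray
    still_threshold: float
    frac_required: float

    def __post_init__(self) -> None:
        self.minute_flags = np.asarray(self.minute_flags, dtype=bool)

    @property
    def ratio(self) -> float:
        return float(np.mean(self.minute_flags))


@dataclass
class ContextLabel:
    value: str  # "still" | "active"
    ratio_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.value not in ("still", "active"):
            raise ValidationError("context must be 'still' or 'active'")


def stillness_minutes(
    x: SampledChannel,
    y: SampledChannel,
    z: SampledChannel,
    cfg: StillnessConfig | None = None,
) -> StillnessSummary:
    """Flag non-overlapping minutes (aligned to the channel start) as still.

    A minute is still when at least ``frac_required`` of its net-motion
    samples fall below ``still_threshold``; partial trailing minutes are
    ignored.
    """
    cfg = cfg or StillnessConfig()
    mag = magnitude(x.values, y.values, z.values)
    motion = np.abs(mag - 1.0) if cfg.net_motion else mag
    per_min = int(round(60.0 * x.fs))
    n_minutes = len(motion) // per_min
    if n_minutes < 1:
        raise ValidationError("need at least one full minute of acceleration")
    flags = np.empty(n_minutes, dtype=bool)
    for m in range(n_minutes):
        seg = motion[m * per_min: (m + 1) * per_min]
        flags[m] = np.mean(seg < cfg.still_threshold) >= cfg.frac_required
    return StillnessSummary(
        minute_flags=flags,
        still_threshold=cfg.still_threshold,
        frac_required=cfg.frac_required,
    )


def classify_context(
    summary: StillnessSummary, cfg: StillnessConfig | None = None
) -> ContextLabel:
    """Threshold the still-minute ratio at 20% into still vs active.

    Default orientation: a high still-minute ratio (≥ threshold) means the
    wearer is in a restricted, still context.  ``literal_rule`` inverts the
    direction for the alternative reading of the rule.
    """
    cfg = cfg or StillnessConfig()
    high_ratio = summary.ratio >= cfg.ratio_threshold
    still = (not high_ratio) if cfg.literal_rule else high_ratio
    return ContextLabel(
        value="still" if still else "active", ratio_threshold=cfg.ratio_threshold
    )


def acc_feature_table(
    x: SampledChannel,
    y: SampledChannel,
    z: SampledChannel,
    session_id: str = "",
    length: float = 120.0,
    overlap: float = 0.5,
) -> pd.DataFrame:
    """One accelerometer feature row per overlapping segment."""
    fs = x.fs
    duration = len(x.values) / fs
    step = length * (1.0 - overlap)
    rows = []
    k = 0
    while k * step + length <= duration + 1e-9:
        t0 = k * step
        k += 1
        i0, i1 = int(round(t0 * fs)), int(round((t0 + length) * fs))
        feats = acc_features(x.values[i0:i1], y.values[i0:i1], z.values[i0:i1])
        row = {"session_id": session_id, "t_start": t0, "t_end": t0 + length}
        row.update(feats.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
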