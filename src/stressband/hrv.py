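"""Heart-rate-variability processing for wrist-band inter-beat intervals.

The stages mirror a standard Kubios-style workflow: a percentage-rule
artifact sweep on the tachogram, cubic-spline replacement of flagged
intervals, segmentation into 2-minute windows with 50% overlap, and the
classic time-domain, geometric and frequency-domain HRV features per
segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import detrend as _detrend
from scipy.signal import periodogram

from .io_e4 import BeatSeries, ValidationError

__all__ = [
    "ArtifactRuleConfig",
    "RRSegment",
    "HRVFeatures",
    "UnusableSeriesError",
    "detect_rr_artifacts",
    "correct_rr",
    "segment_beats",
    "hrv_time_features",
    "hrv_geometric_features",
    "hrv_freq_features",
    "hrv_features",
    "hrv_feature_table",
]

#: geometric-HRV histogram bin width: 1/128 s, expressed in ms
HIST_BIN_MS = 1000.0 / 128.0

#: spectral band edges in Hz
VLF_BAND = (0.00, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


class UnusableSeriesError(ValueError):
    """Too much of the beat series is flagged to correct it reliably."""


@dataclass
class ArtifactRuleConfig:
    """Percentage-rule configuration.

    ``threshold`` is the relative deviation from the local average above
    which an interval is flagged (0.20 is the common literature choice);
    the local average is the median of the ``window`` nearest preceding
    accepted intervals, a robust causal variant of the rule.
    """

    threshold: float = 0.20
    window: int = 5
    interpolation: str = "cubic"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValidationError("threshold must lie in (0, 1)")
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be an odd count >= 3")


@dataclass
class RRSegment:
    """An artifact-corrected tachogram slice of fixed nominal length."""

    t_start: float
    t_end: float
    beat_times: np.ndarray  # offsets within the parent series, s
    ibis: np.ndarray  # ms
    n_interpolated: int = 0

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.ibis = np.asarray(self.ibis, dtype=float)
        if np.any(self.ibis <= 0):
            raise ValidationError("segment ibis must be positive")


@dataclass
class HRVFeatures:
    mean_rr: float = np.nan  # ms
    std_rr: float = np.nan  # ms
    pnn50: float = np.nan  # %
    rmssd: float = np.nan  # ms
    sdsd: float = np.nan  # ms
    hrv_ti: float = np.nan
    tinn: float = np.nan  # ms
    lf: float = np.nan  # ms^2
    hf: float = np.nan  # ms^2
    vlf: float = np.nan  # ms^2
    plf: float = np.nan  # Hz
    phf: float = np.nan  # Hz
    lf_hf: float = np.nan

    def as_dict(self, prefix: str = "hrv_") -> dict[str, float]:
        return {prefix + k: v for k, v in self.__dict__.items()}


def detect_rr_artifacts(
    beats: BeatSeries, cfg: ArtifactRuleConfig | None = None
) -> np.ndarray:
    """Flag intervals deviating more than ``threshold`` from the local average.

    Causal sweep: interval ``i`` is compared against the median of the
    ``window`` nearest *preceding accepted* intervals, so a run of ectopic
    beats cannot drag its own reference along.  The first interval is always
    accepted (it has no history).
    """
    cfg = cfg or ArtifactRuleConfig()
    ibis = beats.ibis
    mask = np.zeros(len(ibis), dtype=bool)
    if len(ibis) < cfg.window:
        warnings.warn(
            f"series of {len(ibis)} beats is shorter than window {cfg.window}; "
            "no artifacts flagged",
            stacklevel=2,
        )
        return mask
    accepted: list[float] = []
    for i, ibi in enumerate(ibis):
        if accepted:
            local = float(np.median(accepted[-cfg.window:]))
            if abs(ibi - local) / local > cfg.threshold:
                mask[i] = True
                continue
        accepted.append(float(ibi))
    return mask


def correct_rr(beats: BeatSeries, mask: np.ndarray) -> BeatSeries:
    """Replace flagged intervals with cubic-spline values over the clean tachogram.

    Flagged tachogram points are deleted and re-interpolated at their beat
    times from the surrounding accepted intervals; unflagged beats keep
    their number and position.  Raises :class:`UnusableSeriesError` when
    more than half of the series is flagged.
    """
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(beats.ibis):
        raise ValidationError("mask must align with ibis")
    if not mask.any():
        return BeatSeries(
            start_time=beats.start_time,
            beat_times=beats.beat_times.copy(),
            ibis=beats.ibis.copy(),
        )
    if mask.mean() > 0.5:
        raise UnusableSeriesError(
            f"{mask.mean():.0%} of intervals flagged; series unusable"
        )
    clean = ~mask
    if clean.sum() < 4:
        raise UnusableSeriesError("need at least 4 clean beats to interpolate")
    spline = CubicSpline(beats.beat_times[clean], beats.ibis[clean])
    ibis = beats.ibis.copy()
    ibis[mask] = spline(beats.beat_times[mask])
    if np.any(ibis <= 0):  # spline overshoot on pathological input
        ibis[ibis <= 0] = float(np.median(beats.ibis[clean]))
    return BeatSeries(
        start_time=beats.start_time, beat_times=beats.beat_times.copy(), ibis=ibis
    )


def segment_beats(
    beats: BeatSeries,
    length: float = 120.0,
    overlap: float = 0.5,
    interpolated: np.ndarray | None = None,
    min_beats: int = 30,
    max_interp_frac: float = 0.5,
    duration: float | None = None,
) -> list[RRSegment]:
    """Cut the beat series into overlapping fixed-length windows.

    Windows start at multiples of ``length * (1 - overlap)``; a trailing
    partial window is discarded.  ``duration`` is the recording length in
    seconds (defaults to the last beat time, which slightly undershoots
    when the recording ends between beats).  Windows with fewer than
    ``min_beats`` beats or more than ``max_interp_frac`` interpolated
    intervals are dropped as unusable.
    """
    if not 0 <= overlap < 1:
        raise ValidationError("overlap must lie in [0, 1)")
    if interpolated is None:
        interpolated = np.zeros(len(beats), dtype=bool)
    if duration is None:
        duration = beats.duration
    step = length * (1.0 - overlap)
    segments: list[RRSegment] = []
    k = 0
    while k * step + length <= duration + 1e-9:
        t0 = k * step
        t1 = t0 + length
        keep = (beats.beat_times >= t0) & (beats.beat_times < t1)
        k += 1
        if keep.sum() < min_beats:
            continue
        n_interp = int(interpolated[keep].sum())
        if n_interp > max_interp_frac * keep.sum():
            continue
        segments.append(
            RRSegment(
                t_start=t0,
                t_end=t1,
                beat_times=beats.beat_times[keep],
                ibis=beats.ibis[keep],
                n_interpolated=n_interp,
            )
        )
    return segments


def _successive_diffs(ibis: np.ndarray) -> np.ndarray:
    if len(ibis) < 2:
        raise ValidationError("need at least 2 intervals for HRV features")
    return np.diff(ibis)


def hrv_time_features(seg: RRSegment, ddof: int = 1) -> HRVFeatures:
    """Time-domain features: mean RR, STD RR, pNN50, RMSSD, SDSD.

    ``std_rr`` and ``sdsd`` use the sample (n−1) denominator by default.
    pNN50 counts successive differences strictly exceeding 50 ms.
    """
    ibis = np.asarray(seg.ibis, dtype=float)
    d = _successive_diffs(ibis)
    sdsd = float(np.std(d, ddof=ddof)) if len(d) > ddof else 0.0
    return HRVFeatures(
        mean_rr=float(np.mean(ibis)),
        std_rr=float(np.std(ibis, ddof=ddof)),
        pnn50=float(np.mean(np.abs(d) > 50.0) * 100.0),
        rmssd=float(np.sqrt(np.mean(d**2))),
        sdsd=sdsd,
    )


def _rr_histogram(ibis: np.ndarray, bin_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of RR intervals on a fixed 1/128 s grid, padded with two
    empty guard bins each side so a triangular fit can place its base."""
    lo = np.floor(ibis.min() / bin_ms) - 2
    hi = np.floor(ibis.max() / bin_ms) + 3
    edges = np.arange(lo, hi + 1) * bin_ms
    counts, _ = np.histogram(ibis, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(float), centers


def hrv_geometric_features(seg: RRSegment, bin_ms: float = HIST_BIN_MS) -> HRVFeatures:
    """Geometric features from the RR histogram on 1/128 s bins.

    The triangular index is the total beat count over the modal bin height.
    TINN is the baseline width of the least-squares triangle fitted to the
    histogram: the triangle rises from zero at N to the modal height at the
    modal bin and falls to zero at M; TINN = M − N, found by exhaustive
    search over bin centers.  Modal-bin ties break toward the lower bin.
    A single-bin histogram yields TINN = 0.
    """
    ibis = np.asarray(seg.ibis, dtype=float)
    if len(ibis) < 2:
        raise ValidationError("need at least 2 intervals for geometric features")
    counts, centers = _rr_histogram(ibis, bin_ms)
    peak = int(np.argmax(counts))  # argmax takes the first (lower) max bin
    y = counts[peak]
    hrv_ti = float(len(ibis) / y)
    if np.count_nonzero(counts) < 2:
        return HRVFeatures(hrv_ti=hrv_ti, tinn=0.0)
    best = (np.inf, 0.0)
    for n in range(0, peak):
        rise = np.zeros_like(counts)
        left = slice(n, peak + 1)
        rise[left] = y * (centers[left] - centers[n]) / (centers[peak] - centers[n])
        for m in range(peak + 1, len(counts)):
            q = rise.copy()
            right = slice(peak, m + 1)
            q[right] = y * (centers[m] - centers[right]) / (centers[m] - centers[peak])
            q[peak] = y
            q[m + 1:] = 0.0
            sse = float(np.sum((counts - q) ** 2))
            if sse < best[0] - 1e-12:
                best = (sse, float(centers[m] - centers[n]))
    return HRVFeatures(hrv_ti=hrv_ti, tinn=best[1])


def _band_power(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]
) -> tuple[float, float]:
    """Integrated power (ms²) and peak frequency (Hz) within a band."""
    sel = (freqs >= band[0]) & (freqs < band[1])
    if not sel.any():
        return 0.0, np.nan
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 0.0
    power = float(np.sum(psd[sel]) * df)
    peak = float(freqs[sel][np.argmax(psd[sel])])
    return power, peak


def hrv_freq_features(
    seg: RRSegment,
    resample_hz: float = 4.0,
    window: str = "hann",
    detrend: str = "linear",
) -> HRVFeatures:
    """Frequency-domain features from the evenly resampled tachogram.

    The irregular RR series is cubic-spline interpolated onto a uniform
    ``resample_hz`` grid, linearly detrended, and a single tapered
    periodogram is taken; VLF/LF/HF are integrated band powers in ms² and
    pLF/pHF the in-band peak frequencies.
    """
    t = np.asarray(seg.beat_times, dtype=float)
    ibis = np.asarray(seg.ibis, dtype=float)
    if len(ibis) < 4:
        raise ValidationError("need at least 4 beats for spectral features")
    spline = CubicSpline(t, ibis)
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    y = spline(grid)
    if detrend in ("linear", "constant"):
        y = _detrend(y, type=detrend)
    freqs, psd = periodogram(
        y, fs=resample_hz, window=window, detrend=False, scaling="density"
    )
    vlf, _ = _band_power(freqs, psd, VLF_BAND)
    lf, plf = _band_power(freqs, psd, LF_BAND)
    hf, phf = _band_power(freqs, psd, HF_BAND)
    return HRVFeatures(
        lf=lf, hf=hf, vlf=vlf, plf=plf, phf=phf,
        lf_hf=lf / hf if hf > 0 else np.nan,
    )


def hrv_features(seg: RRSegment, **freq_kwargs) -> HRVFeatures:
    """All Table-style HRV features for one segment."""
    out = hrv_time_features(seg)
    geo = hrv_geometric_features(seg)
    frq = hrv_freq_features(seg, **freq_kwargs)
    out.hrv_ti, out.tinn = geo.hrv_ti, geo.tinn
    for name in ("lf", "hf", "vlf", "plf", "phf", "lf_hf"):
        setattr(out, name, getattr(frq, name))
    return out


def hrv_feature_table(
    beats: BeatSeries,
    session_id: str,
    cfg: ArtifactRuleConfig | None = None,
    length: float = 120.0,
    overlap: float = 0.5,
    duration: float | None = None,
) -> pd.DataFrame:
    """Detect/correct artifacts, segment, and emit one feature row per segment."""
    mask = detect_rr_artifacts(beats, cfg)
    try:
        clean = correct_rr(beats, mask)
    except UnusableSeriesError:
        return pd.DataFrame()
    rows = []
    for seg in segment_beats(
        clean, length=length, overlap=overlap, interpolated=mask, duration=duration
    ):
        row = {"session_id": session_id, "t_start": seg.t_start, "t_end": seg.t_end}
        row.update(hrv_features(seg).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
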