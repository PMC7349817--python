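"""Synthetic labeled smart-band sessions with ground truth for every stage.

The generator emulates the statistical structure the pipeline assumes:

* an RR tachogram as mean level plus LF and HF sinusoidal modulation plus
  Gaussian noise, with class-dependent mean and spectral balance (a
  stressed heart beats faster with a higher LF/HF ratio);
* skin conductance as a drifting tonic level plus Poisson-arriving
  sudomotor events convolved with a biexponential kernel, with
  class-dependent event rate and amplitude;
* 3-axis acceleration as gravity along a class-dependent wrist orientation
  plus band-limited motion noise gated by a still/active bout schedule;
* injectable RR spikes and motion-coincident EDA steps with exact truth
  masks, for scoring the artifact detectors.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .eda import DecompositionConfig, bateman_kernel
from .io_e4 import BeatSeries, SampledChannel, Session, ValidationError

__all__ = [
    "ClassPhysiology",
    "SimConfig",
    "GroundTruth",
    "easy_config",
    "hard_config",
    "simulate_rr",
    "simulate_eda",
    "simulate_acc",
    "simulate_temp",
    "inject_artifacts",
    "simulate_session",
    "simulate_cohort",
    "load_config",
]


@dataclass
class ClassPhysiology:
    """Generative parameters for one stress class."""

    mean_rr: float  # ms
    lf_amp: float  # ms
    hf_amp: float  # ms
    rr_noise_sd: float  # ms
    scr_rate: float  # events/min
    scr_amp: float  # µS
    tonic_level: float  # µS
    tonic_drift: float  # µS/min
    motion_amp: float  # g, during active bouts
    active_frac: float  # fraction of session covered by active bouts
    orient: tuple[float, float, float] = (0.0, 0.0, 1.0)  # gravity direction
    lf_freq: float = 0.10  # Hz
    hf_freq: float = 0.25  # Hz
    eda_noise_sd: float = 0.01  # µS

    def __post_init__(self) -> None:
        if not (0 < self.lf_freq < 0.5 and 0 < self.hf_freq < 0.5):
            raise ValidationError("RR modulation frequencies must lie in (0, 0.5) Hz")
        if self.scr_rate < 0 or self.motion_amp < 0:
            raise ValidationError("rates and amplitudes must be nonnegative")


@dataclass
class SimConfig:
    """A cohort recipe: per-class physiology plus acquisition parameters."""

    classes: dict[str, ClassPhysiology]
    duration: float = 600.0  # s per session
    n_subjects: int = 15
    fs_eda: float = 4.0
    fs_acc: float = 32.0
    fs_temp: float = 4.0
    rr_spike_prob: float = 0.0
    eda_artifact_rate: float = 0.0  # events/min
    subject_rr_sd: float = 25.0  # ms, between-subject mean-RR spread
    subject_tonic_sd: float = 0.2  # µS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rr_spike_prob <= 1:
            raise ValidationError("rr_spike_prob must lie in [0, 1]")
        if self.eda_artifact_rate < 0:
            raise ValidationError("eda_artifact_rate must be nonnegative")


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline on a synthetic session."""

    label: str
    rr_artifact_mask: np.ndarray | None = None
    eda_epoch_flags: np.ndarray | None = None  # 5-s epochs
    eda_artifact_times: np.ndarray | None = None
    scr_event_times: np.ndarray | None = None
    still_minute_flags: np.ndarray | None = None
    method: str | None = None  # relaxation method for relax sessions
    extra: dict = field(default_factory=dict)


def easy_config(seed: int = 0, duration: float = 600.0, n_subjects: int = 15) -> SimConfig:
    """Well-separated class physiology: the pipeline's reference conditions.

    Directionally matches the field's findings — high stress shortens the
    mean RR, tilts the spectral balance toward LF, and raises the
    skin-conductance event rate — with wrist orientation and movement also
    differing by condition (sitting in a lecture, lying/standing in
    relaxation, gesturing during a presentation).
    """
    classes = {
        "relax": ClassPhysiology(
            mean_rr=880.0, lf_amp=15.0, hf_amp=45.0, rr_noise_sd=10.0,
            scr_rate=2.0, scr_amp=0.30, tonic_level=1.2, tonic_drift=0.02,
            motion_amp=0.03, active_frac=0.1, orient=(0.0, 0.0, 1.0),
        ),
        "mild": ClassPhysiology(
            mean_rr=780.0, lf_amp=30.0, hf_amp=25.0, rr_noise_sd=12.0,
            scr_rate=5.0, scr_amp=0.40, tonic_level=1.8, tonic_drift=0.03,
            motion_amp=0.15, active_frac=0.2, orient=(0.30, 0.0, 0.954),
        ),
        "high": ClassPhysiology(
            mean_rr=650.0, lf_amp=45.0, hf_amp=12.0, rr_noise_sd=15.0,
            scr_rate=10.0, scr_amp=0.60, tonic_level=2.5, tonic_drift=0.05,
            motion_amp=0.30, active_frac=0.35, orient=(0.50, 0.20, 0.842),
        ),
    }
    return SimConfig(classes=classes, duration=duration, n_subjects=n_subjects, seed=seed)


def hard_config(seed: int = 0, duration: float = 600.0, n_subjects: int = 15) -> SimConfig:
    """Overlapping class physiology: small contrasts, large noise.

    Between-subject offsets are turned off here: with one session per
    subject and class, subject-specific fingerprints let a segment-level
    cross-validation memorize sessions rather than physiology, which would
    mask the intended difficulty.
    """
    classes = {
        "relax": ClassPhysiology(
            mean_rr=800.0, lf_amp=22.0, hf_amp=28.0, rr_noise_sd=30.0,
            scr_rate=4.0, scr_amp=0.30, tonic_level=1.8, tonic_drift=0.03,
            motion_amp=0.10, active_frac=0.2,
        ),
        "mild": ClassPhysiology(
            mean_rr=790.0, lf_amp=25.0, hf_amp=25.0, rr_noise_sd=30.0,
            scr_rate=5.0, scr_amp=0.32, tonic_level=1.85, tonic_drift=0.03,
            motion_amp=0.10, active_frac=0.22,
        ),
        "high": ClassPhysiology(
            mean_rr=780.0, lf_amp=27.0, hf_amp=23.0, rr_noise_sd=30.0,
            scr_rate=6.0, scr_amp=0.34, tonic_level=1.9, tonic_drift=0.03,
            motion_amp=0.10, active_frac=0.25,
        ),
    }
    return SimConfig(
        classes=classes, duration=duration, n_subjects=n_subjects,
        subject_rr_sd=0.0, subject_tonic_sd=0.0, seed=seed,
    )


def simulate_rr(
    phys: ClassPhysiology, duration: float, rng: np.random.Generator
) -> BeatSeries:
    """Beat series with RR(t) = mean + LF·sin + HF·sin + Gaussian noise."""
    times, ibis = [], []
    t = 0.0
    floor = 0.25 * phys.mean_rr
    while True:
        rr = (
            phys.mean_rr
            + phys.lf_amp * np.sin(2 * np.pi * phys.lf_freq * t)
            + phys.hf_amp * np.sin(2 * np.pi * phys.hf_freq * t)
            + rng.normal(0.0, phys.rr_noise_sd)
        )
        if rr <= floor:
            raise ValidationError(
                "RR parameters yield non-positive intervals; reduce amplitudes/noise"
            )
        t += rr / 1000.0
        if t >= duration:
            break
        times.append(t)
        ibis.append(rr)
    return BeatSeries(start_time=0.0, beat_times=np.array(times), ibis=np.array(ibis))


def simulate_eda(
    phys: ClassPhysiology,
    duration: float,
    rng: np.random.Generator,
    fs: float = 4.0,
) -> tuple[SampledChannel, np.ndarray]:
    """Tonic drift plus Poisson SCR events through the Bateman kernel."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    tonic = phys.tonic_level + phys.tonic_drift * t / 60.0
    n_events = rng.poisson(phys.scr_rate * duration / 60.0)
    event_times = np.sort(rng.uniform(0.0, max(duration - 10.0, 1.0), size=n_events))
    driver = np.zeros(n)
    for et in event_times:
        amp = phys.scr_amp * rng.uniform(0.7, 1.3)
        driver[min(int(round(et * fs)), n - 1)] += amp
    h = bateman_kernel(fs, DecompositionConfig())
    phasic = np.convolve(driver, h)[:n]
    values = tonic + phasic + rng.normal(0.0, phys.eda_noise_sd, size=n)
    ch = SampledChannel(name="EDA", start_time=0.0, fs=fs, values=np.maximum(values, 0.0))
    return ch, event_times


def _bout_schedule(
    duration: float, active_frac: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Minute-aligned active bouts covering ~active_frac of the session."""
    n_minutes = int(duration // 60)
    n_active = int(round(active_frac * n_minutes))
    if n_active == 0:
        return []
    which = rng.choice(n_minutes, size=n_active, replace=False)
    return [(60.0 * m, 60.0 * (m + 1)) for m in sorted(which)]


def simulate_acc(
    duration: float,
    rng: np.random.Generator,
    bouts: list[tuple[float, float]] | None = None,
    motion_amp: float = 0.2,
    orient: tuple[float, float, float] = (0.0, 0.0, 1.0),
    fs: float = 32.0,
    still_noise_sd: float = 0.01,
    frac_required: float = 0.95,
) -> tuple[tuple[SampledChannel, SampledChannel, SampledChannel], np.ndarray]:
    """Gravity along ``orient`` plus bout-gated band-limited motion noise.

    Returns the three axis channels and the truth still-minute flags: a
    minute is still when active bouts cover at most ``1 - frac_required``
    of it.
    """
    bouts = bouts if bouts is not None else []
    prev_end = -np.inf
    for b0, b1 in bouts:
        if b1 <= b0 or b0 < prev_end:
            raise ValidationError("bouts must be ordered and non-overlapping")
        prev_end = b1
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    gate = np.zeros(n)
    for b0, b1 in bouts:
        gate[(t >= b0) & (t < b1)] = 1.0
    kernel = np.ones(5) / 5.0  # crude low-pass keeps motion band-limited
    channels = []
    for g_axis, name in zip(orient, ("ACC_X", "ACC_Y", "ACC_Z")):
        noise = np.convolve(rng.normal(0.0, 1.0, size=n), kernel, mode="same")
        values = (
            g_axis
            + rng.normal(0.0, still_noise_sd, size=n)
            + motion_amp * gate * noise
        )
        channels.append(SampledChannel(name=name, start_time=0.0, fs=fs, values=values))
    n_minutes = int(duration // 60)
    flags = np.ones(n_minutes, dtype=bool)
    for m in range(n_minutes):
        m0, m1 = 60.0 * m, 60.0 * (m + 1)
        covered = sum(max(0.0, min(b1, m1) - max(b0, m0)) for b0, b1 in bouts)
        flags[m] = covered <= (1.0 - frac_required) * 60.0
    return tuple(channels), flags


def simulate_temp(
    duration: float, rng: np.random.Generator, fs: float = 4.0, level: float = 33.0
) -> SampledChannel:
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    values = level + 0.3 * np.sin(2 * np.pi * t / duration) + rng.normal(0, 0.02, n)
    return SampledChannel(name="TEMP", start_time=0.0, fs=fs, values=values)


def inject_artifacts(
    session: Session,
    truth: GroundTruth,
    rng: np.random.Generator,
    rr_spike_prob: float = 0.0,
    eda_artifact_rate: float = 0.0,
    epoch_length: float = 5.0,
) -> tuple[Session, GroundTruth]:
    """Add RR spikes and motion-coincident EDA steps, with truth masks.

    Each inter-beat interval is independently multiplied by 1.5 or 0.5 with
    probability ``rr_spike_prob``.  EDA artifacts arrive as a Poisson
    process (``eda_artifact_rate`` per minute): a 2-second conductance step
    of 1.5–3 µS with a coincident acceleration burst.  Zero rates return
    the session unchanged.
    """
    if not 0 <= rr_spike_prob <= 1 or eda_artifact_rate < 0:
        raise ValidationError("artifact rates out of range")
    session = Session(
        id=session.id,
        channels=dict(session.channels),
        beats=session.beats,
        label=session.label,
        tags=session.tags,
    )
    truth = replace(truth)
    if rr_spike_prob > 0 and session.beats is not None:
        b = session.beats
        mask = rng.random(len(b)) < rr_spike_prob
        factors = np.where(rng.random(len(b)) < 0.5, 1.5, 0.5)
        ibis = b.ibis.copy()
        ibis[mask] = ibis[mask] * factors[mask]
        session.beats = BeatSeries(
            start_time=b.start_time, beat_times=b.beat_times.copy(), ibis=ibis
        )
        truth.rr_artifact_mask = mask
    if eda_artifact_rate > 0 and "EDA" in session.channels:
        eda = session.channels["EDA"]
        duration = eda.duration
        n_art = rng.poisson(eda_artifact_rate * duration / 60.0)
        times = np.sort(rng.uniform(0.0, max(duration - 5.0, 1.0), size=n_art))
        values = eda.values.copy()
        art_window = 2.0  # s
        for at in times:
            i0 = int(round(at * eda.fs))
            i1 = min(int(round((at + art_window) * eda.fs)), len(values))
            values[i0:i1] += rng.uniform(1.5, 3.0)
        session.channels["EDA"] = SampledChannel(
            name="EDA", start_time=eda.start_time, fs=eda.fs, values=values
        )
        acc = session.acc()
        if acc is not None:
            fs = acc[0].fs
            burst_sd = 0.4
            new_axes = []
            for ch in acc:
                v = ch.values.copy()
                for at in times:
                    j0 = int(round(at * fs))
                    j1 = min(int(round((at + art_window) * fs)), len(v))
                    v[j0:j1] += rng.normal(0.0, burst_sd, size=j1 - j0)
                new_axes.append(
                    SampledChannel(name=ch.name, start_time=ch.start_time, fs=fs, values=v)
                )
            for ch in new_axes:
                session.channels[ch.name] = ch
        n_epochs = int(duration // epoch_length)
        flags = np.zeros(n_epochs, dtype=bool)
        for at in times:
            e0 = int(at // epoch_length)
            e1 = int((at + art_window) // epoch_length)
            flags[e0: min(e1 + 1, n_epochs)] = True
        truth.eda_epoch_flags = flags
        truth.eda_artifact_times = times
    return session, truth


RELAX_METHODS = ("yoga", "mindfulness", "mobile")


def simulate_session(
    cfg: SimConfig,
    label: str,
    seed: int,
    session_id: str | None = None,
    phys: ClassPhysiology | None = None,
) -> tuple[Session, GroundTruth]:
    """One labeled synthetic session with its ground truth."""
    if phys is None:
        if label not in cfg.classes:
            raise ValidationError(f"no physiology configured for class {label!r}")
        phys = cfg.classes[label]
    rng = np.random.default_rng(seed)
    beats = simulate_rr(phys, cfg.duration, rng)
    eda, scr_times = simulate_eda(phys, cfg.duration, rng, cfg.fs_eda)
    bouts = _bout_schedule(cfg.duration, phys.active_frac, rng)
    acc_channels, still_flags = simulate_acc(
        cfg.duration, rng, bouts, phys.motion_amp, phys.orient, cfg.fs_acc
    )
    temp = simulate_temp(cfg.duration, rng, cfg.fs_temp)
    channels = {"EDA": eda, "TEMP": temp}
    for ch in acc_channels:
        channels[ch.name] = ch
    session = Session(
        id=session_id or f"sim_{label}_{seed}", channels=channels, beats=beats,
        label=label,
    )
    truth = GroundTruth(
        label=label, scr_event_times=scr_times, still_minute_flags=still_flags
    )
    if cfg.rr_spike_prob > 0 or cfg.eda_artifact_rate > 0:
        session, truth = inject_artifacts(
            session, truth, rng, cfg.rr_spike_prob, cfg.eda_artifact_rate
        )
    return session, truth


def simulate_cohort(cfg: SimConfig) -> tuple[list[Session], list[GroundTruth]]:
    """A cohort of ``n_subjects`` subjects × one session per class.

    Subjects get individual offsets on mean RR and tonic level (seeded), so
    between-subject variability is present without erasing the class
    contrasts.  Relax sessions cycle through the three relaxation methods
    (yoga, guided mindfulness, mobile mindfulness) in the truth metadata.
    """
    root = np.random.default_rng(cfg.seed)
    sessions, truths = [], []
    for subj in range(cfg.n_subjects):
        rr_off = root.normal(0.0, cfg.subject_rr_sd)
        tonic_off = root.normal(0.0, cfg.subject_tonic_sd)
        for label in sorted(cfg.classes):
            phys = replace(
                cfg.classes[label],
                mean_rr=cfg.classes[label].mean_rr + rr_off,
                tonic_level=max(0.3, cfg.classes[label].tonic_level + tonic_off),
            )
            child_seed = int(root.integers(0, 2**31 - 1))
            session, truth = simulate_session(
                cfg, label, child_seed,
                session_id=f"s{subj:02d}_{label}", phys=phys,
            )
            if label == "relax":
                truth.method = RELAX_METHODS[subj % len(RELAX_METHODS)]
            sessions.append(session)
            truths.append(truth)
    return sessions, truths


def load_config(path: str) -> SimConfig:
    """Read a SimConfig from a YAML file (keys mirror the dataclasses)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    classes = {
        name: ClassPhysiology(
            **{**params, "orient": tuple(params.get("orient", (0, 0, 1)))}
        )
        for name, params in raw.pop("classes").items()
    }
    return SimConfig(classes=classes, **raw)
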