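"""Electrodermal-activity processing: artifact epochs, tonic/phasic
decomposition, and skin-conductance features.

Skin conductance is modelled as a slow tonic level plus a phasic component
driven by sparse sudomotor-nerve bursts: ``y = tonic + driver ⊛ h + noise``
with ``h`` a biexponential (Bateman) kernel.  The decomposition solves a
regularized least-squares program — quadratic misfit, an L1 penalty that
keeps the nonnegative driver sparse, and a coarse B-spline tonic basis —
with a bound-constrained quasi-Newton solver (the objective is smooth
because the L1 term is linear once the driver is constrained nonnegative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize
from scipy.signal import find_peaks

from .io_e4 import SampledChannel, ValidationError

__all__ = [
    "EDAArtifactConfig",
    "ArtifactEpochMask",
    "DecompositionConfig",
    "EDADecomposition",
    "EDAFeatures",
    "SolverError",
    "epoch_features",
    "detect_eda_artifacts",
    "decompose_eda",
    "find_scr_peaks",
    "count_scr_events",
    "eda_features",
    "eda_feature_table",
]


class SolverError(RuntimeError):
    """The decomposition solver failed to converge."""


@dataclass
class EDAArtifactConfig:
    """Rule-based epoch screening thresholds.

    An epoch is flagged when the maximum absolute skin-conductance slope
    exceeds ``deriv_threshold`` (a step-like jump no sudomotor response can
    produce) or when wrist acceleration variance exceeds
    ``acc_var_threshold`` (vigorous motion tugging the electrodes).
    """

    epoch_length: float = 5.0  # s
    deriv_threshold: float = 2.5  # µS/s
    acc_var_threshold: float = 0.01  # g²


@dataclass
class ArtifactEpochMask:
    epoch_length: float
    flags: np.ndarray  # boolean, one per epoch

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    def sample_mask(self, n_samples: int, fs: float) -> np.ndarray:
        """Expand epoch flags to a per-sample boolean keep-mask (True = keep)."""
        idx = (np.arange(n_samples) / fs // self.epoch_length).astype(int)
        idx = np.clip(idx, 0, len(self.flags) - 1)
        return ~self.flags[idx]


def epoch_features(
    eda: SampledChannel,
    acc: tuple[SampledChannel, ...] | None = None,
    temp: SampledChannel | None = None,
    epoch_length: float = 5.0,
) -> pd.DataFrame:
    """Per-epoch screening features: max |dSC/dt|, SC range, ACC magnitude
    variance, and skin-temperature slope.  Missing modalities yield zeros."""
    n_per = int(round(epoch_length * eda.fs))
    if n_per < 2 or len(eda.values) < n_per:
        raise ValidationError("EDA shorter than one artifact epoch")
    n_epochs = len(eda.values) // n_per
    acc_mag = None
    if acc is not None:
        x, y, z = acc
        acc_mag = np.sqrt(x.values**2 + y.values**2 + z.values**2)
    rows = []
    for e in range(n_epochs):
        seg = eda.values[e * n_per: (e + 1) * n_per]
        deriv = np.abs(np.diff(seg)) * eda.fs
        row = {
            "t_start": e * epoch_length,
            "max_deriv": float(deriv.max()) if len(deriv) else 0.0,
            "amp_range": float(seg.max() - seg.min()),
            "acc_var": 0.0,
            "temp_slope": 0.0,
        }
        if acc_mag is not None:
            m = int(round(epoch_length * acc[0].fs))
            a = acc_mag[e * m: (e + 1) * m]
            if len(a):
                row["acc_var"] = float(np.var(a))
        if temp is not None:
            m = int(round(epoch_length * temp.fs))
            t = temp.values[e * m: (e + 1) * m]
            if len(t) > 1:
                row["temp_slope"] = float(np.polyfit(np.arange(len(t)) / temp.fs, t, 1)[0])
        rows.append(row)
    return pd.DataFrame(rows)


def detect_eda_artifacts(
    eda: SampledChannel,
    acc: tuple[SampledChannel, ...] | None = None,
    temp: SampledChannel | None = None,
    cfg: EDAArtifactConfig | None = None,
    classifier=None,
) -> ArtifactEpochMask:
    """Flag motion-contaminated 5-second EDA epochs.

    The default is the rule described on :class:`EDAArtifactConfig`; a
    fitted sklearn-style ``classifier`` over :func:`epoch_features` columns
    may be supplied instead to mimic a trained artifact detector.
    """
    cfg = cfg or EDAArtifactConfig()
    feats = epoch_features(eda, acc, temp, cfg.epoch_length)
    if classifier is not None:
        cols = ["max_deriv", "amp_range", "acc_var", "temp_slope"]
        flags = np.asarray(classifier.predict(feats[cols].to_numpy()), dtype=bool)
    else:
        flags = (feats["max_deriv"] > cfg.deriv_threshold).to_numpy() | (
            feats["acc_var"] > cfg.acc_var_threshold
        ).to_numpy()
    return ArtifactEpochMask(epoch_length=cfg.epoch_length, flags=flags)


@dataclass
class DecompositionConfig:
    """Deconvolution settings.

    ``tau_rise``/``tau_decay`` parameterize the Bateman kernel
    ``h(t) = exp(-t/tau_decay) - exp(-t/tau_rise)`` (normalized to unit peak
    so driver amplitudes are in µS); ``knot_spacing`` sets the tonic
    B-spline resolution; ``alpha`` weights driver sparsity and ``beta`` the
    tonic roughness.  ``alpha`` scales linearly with the signal amplitude.
    """

    tau_rise: float = 0.75  # s
    tau_decay: float = 2.0  # s
    knot_spacing: float = 10.0  # s
    alpha: float = 2e-2
    beta: float = 1e-2
    kernel_support: float = 16.0  # s; exp(-16/2) < 4e-4
    maxiter: int = 500


@dataclass
class EDADecomposition:
    """Tonic + phasic + residual = input, with the nonnegative driver whose
    convolution with the Bateman kernel gives the phasic component."""

    tonic: np.ndarray
    phasic: np.ndarray
    driver: np.ndarray
    residual: np.ndarray
    fs: float
    start_time: float = 0.0
    config: DecompositionConfig = field(default_factory=DecompositionConfig)

    @property
    def signal(self) -> np.ndarray:
        return self.tonic + self.phasic + self.residual

    @property
    def duration(self) -> float:
        return len(self.tonic) / self.fs

    def to_frame(self) -> pd.DataFrame:
        t = self.start_time + np.arange(len(self.tonic)) / self.fs
        return pd.DataFrame(
            {
                "time": t,
                "raw": self.signal,
                "tonic": self.tonic,
                "phasic": self.phasic,
                "driver": self.driver,
            }
        )


def bateman_kernel(fs: float, cfg: DecompositionConfig) -> np.ndarray:
    """Unit-peak biexponential SCR impulse response sampled at ``fs``."""
    t = np.arange(0.0, cfg.kernel_support, 1.0 / fs)
    h = np.exp(-t / cfg.tau_decay) - np.exp(-t / cfg.tau_rise)
    peak = h.max()
    if peak <= 0:
        raise ValidationError("tau_decay must exceed tau_rise")
    return h / peak


def _tonic_basis(n: int, fs: float, spacing: float):
    """Cubic B-spline design matrix with knots every ``spacing`` seconds."""
    t = np.arange(n) / fs
    T = t[-1] if n > 1 else 1.0
    interior = np.arange(spacing, T, spacing)
    knots = np.r_[[0.0] * 4, interior, [T + 1e-9] * 4]
    return BSpline.design_matrix(t, knots, 3).tocsr()


def decompose_eda(
    eda: SampledChannel, cfg: DecompositionConfig | None = None
) -> EDADecomposition:
    """Decompose skin conductance into tonic and phasic components.

    Minimizes ``‖y − h⊛q − Bc‖²/n + α·Σq/n + β·‖Δ²c‖²/k`` over the driver
    ``q ≥ 0`` and tonic spline coefficients ``c``, then reports
    ``tonic = Bc``, ``phasic = h⊛q`` and the residual.
    """
    cfg = cfg or DecompositionConfig()
    y = np.asarray(eda.values, dtype=float)
    n = len(y)
    if n < 8:
        raise ValidationError("EDA too short to decompose")
    h = bateman_kernel(eda.fs, cfg)
    B = _tonic_basis(n, eda.fs, cfg.knot_spacing)
    k = B.shape[1]

    def conv(q: np.ndarray) -> np.ndarray:
        return np.convolve(q, h)[:n]

    def conv_T(r: np.ndarray) -> np.ndarray:
        return np.convolve(r[::-1], h)[:n][::-1]

    D = np.diff(np.eye(k), 2, axis=0) if k > 2 else np.zeros((0, k))
    DtD = D.T @ D

    def objective(x: np.ndarray):
        q, c = x[:n], x[n:]
        r = conv(q) + B @ c - y
        f = (r @ r) / n + cfg.alpha * q.sum() / n
        gq = 2.0 * conv_T(r) / n + cfg.alpha / n
        gc = 2.0 * (B.T @ r) / n
        if k > 2:
            f += cfg.beta * float(c @ (DtD @ c)) / k
            gc += 2.0 * cfg.beta * (DtD @ c) / k
        return f, np.concatenate([gq, gc])

    # warm-start the tonic fit on the raw signal; driver starts at zero
    c0 = np.linalg.lstsq((B.T @ B).toarray() + 1e-9 * np.eye(k), B.T @ y, rcond=None)[0]
    x0 = np.concatenate([np.zeros(n), c0])
    bounds = [(0.0, None)] * n + [(None, None)] * k
    res = minimize(
        objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": cfg.maxiter, "ftol": 1e-12, "gtol": 1e-9},
    )
    if not res.success and "ITERATIONS" not in str(res.message).upper():
        raise SolverError(f"decomposition failed: {res.message}")
    q, c = res.x[:n], res.x[n:]
    phasic = conv(q)
    tonic = np.asarray(B @ c)
    return EDADecomposition(
        tonic=tonic,
        phasic=phasic,
        driver=q,
        residual=y - tonic - phasic,
        fs=eda.fs,
        start_time=eda.start_time,
        config=cfg,
    )


def find_scr_peaks(
    phasic: np.ndarray,
    fs: float,
    amp_threshold: float = 0.05,
    strong_threshold: float = 0.30,
) -> pd.DataFrame:
    """Locate skin-conductance responses as prominent phasic maxima.

    Returns one row per peak with its time (s), prominence (µS) and whether
    it clears the "strong" threshold.
    """
    idx, props = find_peaks(np.asarray(phasic, dtype=float), prominence=amp_threshold)
    prom = props["prominences"]
    return pd.DataFrame(
        {"time": idx / fs, "prominence": prom, "strong": prom >= strong_threshold}
    )


def count_scr_events(
    driver: np.ndarray,
    fs: float,
    min_amp: float = 0.05,
    min_separation: float = 0.5,
) -> np.ndarray:
    """Count sudomotor events as bursts in the deconvolved driver.

    Responses arriving close together merge into a single phasic maximum,
    so phasic peak counting undercounts dense activity; the sparse driver
    keeps them apart.  Returns the event times in seconds.
    """
    idx, _ = find_peaks(
        np.asarray(driver, dtype=float),
        height=min_amp,
        distance=max(1, int(round(min_separation * fs))),
    )
    return idx / fs


@dataclass
class EDAFeatures:
    quartdev: float = np.nan  # µS
    strong_peaks_per_100s: float = np.nan
    peaks_per_100s: float = np.nan
    perc20: float = np.nan  # µS
    perc80: float = np.nan  # µS
    mean_level: float = np.nan  # µS
    sd_level: float = np.nan  # µS

    def as_dict(self, prefix: str = "eda_") -> dict[str, float]:
        return {prefix + k: v for k, v in self.__dict__.items()}


def eda_features(
    decomp: EDADecomposition,
    keep: np.ndarray | None = None,
    level_component: str = "tonic",
    amp_threshold: float = 0.05,
    strong_threshold: float = 0.30,
) -> EDAFeatures:
    """Skin-conductance features on one (already segmented) decomposition.

    Level statistics (mean, SD, 20th/80th percentile, quartile deviation)
    are computed on ``level_component`` — tonic by default, "phasic" to
    follow the feature table text literally.  Peak rates are counted on the
    phasic component and normalized per 100 s of retained time.  ``keep``
    is a per-sample mask excluding artifact epochs.
    """
    if level_component not in ("tonic", "phasic"):
        raise ValidationError("level_component must be 'tonic' or 'phasic'")
    if keep is None:
        keep = np.ones(len(decomp.tonic), dtype=bool)
    keep = np.asarray(keep, dtype=bool)
    if not keep.any():
        raise ValidationError("segment is fully artifactual; features undefined")
    level = getattr(decomp, level_component)[keep]
    peaks = find_scr_peaks(decomp.phasic, decomp.fs, amp_threshold, strong_threshold)
    if len(peaks):
        p_idx = (peaks["time"].to_numpy() * decomp.fs).round().astype(int)
        valid = keep[np.clip(p_idx, 0, len(keep) - 1)]
        peaks = peaks[valid]
    retained_s = keep.sum() / decomp.fs
    p25, p75 = np.percentile(level, [25, 75])
    return EDAFeatures(
        quartdev=float(p75 - p25),
        strong_peaks_per_100s=float(peaks["strong"].sum()) / retained_s * 100.0,
        peaks_per_100s=float(len(peaks)) / retained_s * 100.0,
        perc20=float(np.percentile(level, 20)),
        perc80=float(np.percentile(level, 80)),
        mean_level=float(np.mean(level)),
        sd_level=float(np.std(level, ddof=1)) if len(level) > 1 else 0.0,
    )


def eda_feature_table(
    eda: SampledChannel,
    acc: tuple[SampledChannel, ...] | None = None,
    temp: SampledChannel | None = None,
    session_id: str = "",
    length: float = 120.0,
    overlap: float = 0.5,
    artifact_cfg: EDAArtifactConfig | None = None,
    decomp_cfg: DecompositionConfig | None = None,
    level_component: str = "tonic",
) -> pd.DataFrame:
    """Artifact-screen, decompose, and emit one EDA feature row per segment."""
    mask = detect_eda_artifacts(eda, acc, temp, artifact_cfg)
    decomp = decompose_eda(eda, decomp_cfg)
    keep_all = mask.sample_mask(len(eda.values), eda.fs)
    step = length * (1.0 - overlap)
    rows = []
    k = 0
    while k * step + length <= decomp.duration + 1e-9:
        t0 = k * step
        k += 1
        i0, i1 = int(round(t0 * eda.fs)), int(round((t0 + length) * eda.fs))
        sub = EDADecomposition(
            tonic=decomp.tonic[i0:i1],
            phasic=decomp.phasic[i0:i1],
            driver=decomp.driver[i0:i1],
            residual=decomp.residual[i0:i1],
            fs=decomp.fs,
            start_time=decomp.start_time + t0,
            config=decomp.config,
        )
        keep = keep_all[i0:i1]
        if not keep.any():
            continue
        row = {"session_id": session_id, "t_start": t0, "t_end": t0 + length}
        row.update(eda_features(sub, keep, level_component).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
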