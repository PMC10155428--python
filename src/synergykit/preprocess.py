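"""EMG preprocessing chain.

Raw signal -> Butterworth bandpass (zero-phase by default) -> optional
median filtering of stimulation-artifact channels -> RMS envelope over
non-overlapping windows -> segmentation by trial events -> time
normalization to a fixed number of points -> min-max amplitude
normalization -> ensemble averaging of the trials of each movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .config import MOVEMENTS, PipelineConfig
from .errors import NormalizationError, ParameterError, SegmentationError
from .session import SessionRecord

TrialKey = tuple[str, str, int]  # (movement_id, condition, trial_index)


@dataclass
class EnvelopeMatrix:
    """Ensemble-averaged, normalized envelope for one movement x condition.

    ``norm_offset`` / ``norm_scale`` record the per-muscle min-max mapping
    applied during amplitude normalization, so loadings estimated from the
    normalized envelope can be mapped back to physical envelope units.
    """

    values: np.ndarray                   # muscles x n_timepoints, in [0, 1]
    movement_id: str
    condition: str
    trial_indices: tuple[int, ...] = ()
    norm_offset: np.ndarray | None = None
    norm_scale: np.ndarray | None = None


def bandpass_filter(x: np.ndarray, fs: float, low: float, high: float,
                    order: int = 6, zero_phase: bool = True) -> np.ndarray:
    """Butterworth bandpass along the last axis.

    ``order`` is the overall bandpass order (even).  A high edge at or above
    Nyquist is capped at 0.99 x Nyquist; a bandpass designed up to Nyquist is
    degenerate.
    """
    if fs <= 0:
        raise ParameterError("fs must be positive")
    if not (0 < low < high):
        raise ParameterError("require 0 < low < high")
    if order <= 0 or order % 2:
        raise ParameterError("order must be a positive even integer")
    nyq = fs / 2.0
    if fs <= 2 * low:
        raise ParameterError("fs must exceed twice the low cutoff")
    high = min(high, 0.99 * nyq)
    sos = signal.butter(order // 2, [low, high], btype="bandpass",
                        fs=fs, output="sos")
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def median_filter_artifact(x: np.ndarray, kernel: int = 5) -> np.ndarray:
    """Running median along the last axis; removes isolated stimulus pulses."""
    if kernel % 2 == 0 or kernel < 3:
        raise ParameterError("kernel must be odd and >= 3")
    size = (1,) * (x.ndim - 1) + (kernel,)
    return ndimage.median_filter(x, size=size, mode="reflect")


def rms_envelope(x: np.ndarray, fs: float, window_ms: float = 100.0) -> np.ndarray:
    """RMS amplitude over non-overlapping windows along the last axis.

    The trailing incomplete window is dropped (floor semantics), so the
    output length is ``floor(n_samples / window_samples)``.
    """
    w = int(round(fs * window_ms / 1000.0))
    if w < 1:
        raise ParameterError("window spans less than one sample")
    n = x.shape[-1]
    if n < w:
        raise ParameterError(f"signal of {n} samples shorter than one {w}-sample window")
    nwin = n // w
    trimmed = x[..., : nwin * w]
    sq = trimmed.reshape(*x.shape[:-1], nwin, w) ** 2
    return np.sqrt(sq.mean(axis=-1))


def segment_and_time_normalize(
    envelope: np.ndarray,
    events,
    window_samples: int,
    n_points: int = 7000,
) -> dict[TrialKey, np.ndarray]:
    """Cut the envelope into per-trial matrices and resample each to
    ``n_points`` columns by linear interpolation on a uniform grid that
    includes both endpoints.

    ``events`` carry raw-sample windows; envelope sample ``i`` covers raw
    samples ``[i * window_samples, (i + 1) * window_samples)``.
    """
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    env = np.atleast_2d(envelope)
    n_env = env.shape[-1]
    out: dict[TrialKey, np.ndarray] = {}
    for e in events:
        lo = e.start_sample // window_samples
        hi = e.end_sample // window_samples
        label = f"{e.movement_id}/{e.condition}/trial{e.trial_index}"
        if hi > n_env:
            raise SegmentationError(f"{label}: event extends past the envelope")
        if hi - lo < 2:
            raise SegmentationError(f"{label}: fewer than 2 envelope samples")
        seg = env[:, lo:hi]
        src = np.arange(hi - lo, dtype=float)
        dst = np.linspace(0.0, hi - lo - 1, n_points)
        res = np.empty((env.shape[0], n_points))
        for ch in range(env.shape[0]):
            res[ch] = np.interp(dst, src, seg[ch])
        out[(e.movement_id, e.condition, e.trial_index)] = res
    return out


def amplitude_normalize(
    trials: dict[TrialKey, np.ndarray],
    scope: str = "per_muscle_session",
) -> tuple[dict[TrialKey, np.ndarray], np.ndarray, np.ndarray]:
    """Min-max normalize envelopes to [0, 1].

    per_muscle_session: one (min, max) per muscle over every trial of the
    session, so relative amplitude across movements and conditions is kept.
    per_trial: one (min, max) per muscle within each trial.

    Returns (normalized trials, offset, scale); for per_muscle_session the
    offset/scale are per-muscle vectors, for per_trial they are the stacked
    per-trial values of the last trial processed (kept for provenance, the
    per-trial mapping is not otherwise reusable).
    """
    if not trials:
        raise ParameterError("no trials to normalize")
    keys = list(trials)
    if scope == "per_muscle_session":
        stack = np.concatenate([trials[k] for k in keys], axis=1)
        lo = stack.min(axis=1)
        hi = stack.max(axis=1)
        span = hi - lo
        dead = np.flatnonzero(span <= 0)
        if dead.size:
            raise NormalizationError(
                f"muscle row(s) {dead.tolist()} constant across the session")
        out = {k: (v - lo[:, None]) / span[:, None] for k, v in trials.items()}
        return out, lo, span
    if scope == "per_trial":
        out = {}
        lo = hi = None
        for k, v in trials.items():
            lo = v.min(axis=1)
            hi = v.max(axis=1)
            span = hi - lo
            dead = np.flatnonzero(span <= 0)
            if dead.size:
                raise NormalizationError(
                    f"trial {k}: muscle row(s) {dead.tolist()} constant")
            out[k] = (v - lo[:, None]) / span[:, None]
        return out, lo, hi - lo
    raise ParameterError(f"unknown scope {scope!r}")


def ensemble_average(trials: list[np.ndarray] | tuple[np.ndarray, ...]) -> np.ndarray:
    """Element-wise mean of same-shape trial matrices."""
    if not trials:
        raise ParameterError("no trials to average")
    shapes = {t.shape for t in trials}
    if len(shapes) > 1:
        raise ParameterError(f"trial shape mismatch: {sorted(shapes)}")
    return np.mean(np.stack(trials), axis=0)


@dataclass
class PreprocessedSession:
    """All envelope products of one session."""

    trials_raw: dict[TrialKey, np.ndarray] = field(default_factory=dict)
    trials_normalized: dict[TrialKey, np.ndarray] = field(default_factory=dict)
    ensembles: list[EnvelopeMatrix] = field(default_factory=list)
    norm_offset: np.ndarray | None = None
    norm_scale: np.ndarray | None = None


def preprocess_session(record: SessionRecord,
                       config: PipelineConfig | None = None) -> PreprocessedSession:
    """Run the full preprocessing chain on one session.

    Produces per-trial time-normalized envelopes (both raw-scale, used for
    complexity analysis, and amplitude-normalized) and the ensemble-averaged
    normalized envelope per (movement, condition).
    """
    config = config or PipelineConfig()
    layout = config.layout
    emg = bandpass_filter(record.emg, record.fs, config.band_low_hz,
                          config.band_high_hz, config.filter_order,
                          config.zero_phase)
    idx = list(layout.artifact_indices)
    if idx:
        emg[idx] = median_filter_artifact(emg[idx], config.median_kernel)
    env = rms_envelope(emg, record.fs, config.rms_window_ms)
    w = int(round(record.fs * config.rms_window_ms / 1000.0))
    trials = segment_and_time_normalize(env, record.events, w, config.n_timepoints)
    normalized, off, scale = amplitude_normalize(trials, config.normalization_scope)
    ensembles = []
    for cond in record.conditions:
        for mov in MOVEMENTS:
            keys = sorted(k for k in normalized if k[0] == mov and k[1] == cond)
            if not keys:
                continue
            mean = ensemble_average([normalized[k] for k in keys])
            ensembles.append(EnvelopeMatrix(
                values=mean, movement_id=mov, condition=cond,
                trial_indices=tuple(k[2] for k in keys),
                norm_offset=None if off is None else off.copy(),
                norm_scale=None if scale is None else scale.copy(),
            ))
    return PreprocessedSession(
        trials_raw=trials, trials_normalized=normalized,
        ensembles=ensembles, norm_offset=off, norm_scale=scale,
    )
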