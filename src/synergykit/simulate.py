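"""Protocol-faithful synthetic EMG sessions with planted synergy structure.

A session emulates the cued-movement assessment: 6 voluntary movements x 3
trials per condition, one condition for controls and two (stim / no_stim)
for patients, recorded on the 10 canonical lower-limb channels at 600 Hz.

Signal model
------------
Each channel's raw trace is a broadband carrier amplitude-modulated by a
non-negative envelope that is a planted synergy mixture W A (columns of W
unit-norm, rows of A smooth raised-cosine bursts localized in each trial),
plus additive broadband noise and, optionally, periodic biphasic
stimulation-artifact pulses on the channels nearest the electrode.  The
carrier is a random-phase multisine on 10-250 Hz whose components are
harmonics of 10 Hz, so its RMS over the 100 ms analysis windows is exactly
constant and the RMS envelope of the clean signal reproduces the planted
mixture.  The no_stim patient condition is simulated as noise-only
(near-absent volitional EMG), reproducing the high-dimensionality regime
seen without stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MOVEMENTS, N_TRIALS_PER_MOVEMENT, ChannelLayout
from .errors import ParameterError
from .session import SessionRecord, TrialEvent


@dataclass(frozen=True)
class ArtifactSpec:
    """Periodic biphasic stimulation pulses (rate within the clinically
    preferred 28-44 Hz band)."""

    rate_hz: float = 30.0
    width_ms: float = 2.0
    amplitude: float = 4.0

    def __post_init__(self):
        if not 28.0 <= self.rate_hz <= 44.0:
            raise ParameterError("artifact rate must lie in [28, 44] Hz")
        if self.width_ms <= 0 or self.amplitude <= 0:
            raise ParameterError("artifact width and amplitude must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the generator.

    noise_sd is the additive-noise scale as a fraction of the clean-signal
    RMS; asymmetry in [0, 1] scales left-side loadings down by (1 -
    asymmetry).  Trial duration (6 s) and inter-trial rest (2 s) are
    generator defaults, not protocol constants.
    """

    n_synergies: int = 4
    noise_sd: float = 0.05
    artifact: ArtifactSpec | None = None
    asymmetry: float = 0.0
    trial_duration_s: float = 6.0
    rest_duration_s: float = 2.0
    fs: float = 600.0
    conditions: tuple[str, ...] = ("stim", "no_stim")
    seed: int = 0
    basis_seed: int | None = None   # share one planted basis across a cohort

    def __post_init__(self):
        if not 1 <= self.n_synergies <= 10:
            raise ParameterError("n_synergies must lie in [1, 10]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not 0 <= self.asymmetry <= 1:
            raise ParameterError("asymmetry must lie in [0, 1]")
        if self.trial_duration_s <= 0 or self.rest_duration_s < 0:
            raise ParameterError("durations must be positive")


@dataclass
class PlantedTruth:
    """Ground truth planted in a synthetic session."""

    W_true: np.ndarray            # muscles x k, unit-norm columns
    A_true: np.ndarray            # k x total samples (zero outside trials)
    seed: int

    def normalized_loadings(self) -> np.ndarray:
        """The planted loadings as they appear after per-muscle min-max
        normalization of the envelopes.

        Normalization divides each muscle's envelope by its session maximum,
        which cancels any per-channel gain of the measurement chain (and the
        amplitude attenuation of the artifact median filter), so the ground
        truth in normalized-envelope space is W_true with each row divided
        by that muscle's planted-mixture maximum.
        """
        mix_max = (self.W_true @ self.A_true).max(axis=1)
        mix_max = np.where(mix_max > 0, mix_max, 1.0)
        return self.W_true / mix_max[:, None]


def generate_synergy_basis(n_muscles: int, k: int, seed: int,
                           max_pairwise_cos: float = 0.8,
                           max_tries: int = 2000) -> np.ndarray:
    """Random non-negative basis with unit-norm, mutually distinct columns.

    Muscles are dealt into k near-disjoint support groups (sizes differing by
    at most one); each column loads its group strongly plus a small random
    background on every muscle, so columns are identifiable by construction.
    A draw whose pairwise cosines exceed ``max_pairwise_cos`` is rejected and
    redrawn.
    """
    if not 1 <= k <= n_muscles:
        raise ParameterError(f"k={k} outside [1, {n_muscles}]")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        perm = rng.permutation(n_muscles)
        groups = [perm[i::k] for i in range(k)]
        W = 0.02 * rng.random((n_muscles, k))     # small background loading
        for j, g in enumerate(groups):
            W[g, j] += 0.5 + rng.random(g.size)
        W /= np.linalg.norm(W, axis=0)
        G = W.T @ W
        off = G[~np.eye(k, dtype=bool)]
        if off.size == 0 or off.max() <= max_pairwise_cos:
            return W
    raise ParameterError(
        f"could not draw {k} columns with pairwise cosine <= "
        f"{max_pairwise_cos} in {max_tries} tries")


def raised_cosine_burst(n_samples: int, center: float, width: float,
                        amplitude: float) -> np.ndarray:
    """One smooth burst a/2 * (1 + cos(2 pi (t - c) / w)) on |t - c| <= w/2.

    The analytic area under the burst is amplitude * width / 2 samples.
    """
    if not 0 <= center < n_samples:
        raise ParameterError("burst center outside [0, n_samples)")
    if center - width / 2 < -0.5 or center + width / 2 > n_samples - 0.5:
        raise ParameterError("burst extends outside [0, n_samples)")
    t = np.arange(n_samples, dtype=float)
    out = np.zeros(n_samples)
    mask = np.abs(t - center) <= width / 2
    out[mask] = amplitude / 2 * (1 + np.cos(2 * np.pi * (t[mask] - center) / width))
    return out


def generate_activations(k: int, n_samples: int,
                         burst_spec: list[tuple[float, float, float]] | None = None,
                         seed: int = 0) -> np.ndarray:
    """Non-negative activation rows, one raised-cosine burst each.

    ``burst_spec`` lists (center, width, amplitude) per synergy in samples;
    by default bursts are staggered across the window with ~10% amplitude
    jitter so every synergy is active and separable within a trial.
    """
    if n_samples <= 0:
        raise ParameterError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    if burst_spec is None:
        width = 0.65 * n_samples / max(k, 1)
        centers = (np.arange(k) + 0.5) * n_samples / k
        burst_spec = [(float(c), float(width), float(1.0 + 0.1 * rng.standard_normal()))
                      for c in centers]
    if len(burst_spec) != k:
        raise ParameterError(f"need {k} burst specs, got {len(burst_spec)}")
    A = np.empty((k, n_samples))
    for i, (c, w, a) in enumerate(burst_spec):
        A[i] = raised_cosine_burst(n_samples, c, w, abs(a))
    return A


def _multisine_carrier(n_samples: int, fs: float, rng: np.random.Generator,
                       f_low: float = 10.0, f_high: float = 250.0,
                       f_step: float = 10.0) -> np.ndarray:
    """Unit-RMS broadband carrier from harmonics of ``f_step`` with random
    phases; its RMS over any full 1/f_step-second window is exactly 1."""
    freqs = np.arange(f_low, f_high + f_step / 2, f_step)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    t = np.arange(n_samples) / fs
    carrier = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    return carrier * np.sqrt(2.0 / freqs.size)


def _artifact_train(n_samples: int, fs: float, spec: ArtifactSpec) -> np.ndarray:
    period = int(round(fs / spec.rate_hz))
    width = max(2, int(round(fs * spec.width_ms / 1000.0)))
    half = width // 2
    pulse = np.concatenate([np.full(half, spec.amplitude),
                            np.full(width - half, -spec.amplitude)])
    out = np.zeros(n_samples)
    for start in range(0, n_samples - width, period):
        out[start:start + width] += pulse
    return out


def synthesize_session(
    gen: GeneratorConfig,
    group: str = "SCI",
    participant_id: str = "P0",
    session_index: int = 1,
    layout: ChannelLayout | None = None,
) -> tuple[SessionRecord, PlantedTruth]:
    """Build one synthetic session and its planted ground truth.

    Controls get one 18-trial condition ("control"); patients get the
    conditions in ``gen.conditions`` (default stim + no_stim, 36 trials).
    Movement drive is planted only in the stim and control conditions; the
    no_stim condition carries noise alone.
    """
    layout = layout or ChannelLayout()
    if group not in ("SCI", "control"):
        raise ParameterError(f"unknown group {group!r}")
    conditions = ("control",) if group == "control" else tuple(gen.conditions)
    fs = gen.fs
    trial_len = int(round(gen.trial_duration_s * fs))
    rest_len = int(round(gen.rest_duration_s * fs))
    block = trial_len + rest_len
    trials_per_cond = len(MOVEMENTS) * N_TRIALS_PER_MOVEMENT
    total = block * trials_per_cond * len(conditions)

    ss = np.random.SeedSequence(gen.seed)
    r_basis, r_act, r_carrier, r_noise = [
        np.random.default_rng(s) for s in ss.spawn(4)]

    m = layout.n_channels
    k = gen.n_synergies
    basis_seed = (gen.basis_seed if gen.basis_seed is not None
                  else int(r_basis.integers(2**31)))
    W = generate_synergy_basis(m, k, seed=basis_seed)
    if gen.asymmetry > 0:
        left = [i for i, c in enumerate(layout.names) if c.startswith("L-")]
        W[left] *= 1.0 - gen.asymmetry
        norms = np.linalg.norm(W, axis=0)
        W = W / np.where(norms > 0, norms, 1.0)

    A = np.zeros((k, total))
    events: list[TrialEvent] = []
    emg = np.empty((m, total))
    pos = 0
    for cond in conditions:
        for mov in MOVEMENTS:
            for tr in range(N_TRIALS_PER_MOVEMENT):
                start, end = pos, pos + trial_len
                events.append(TrialEvent(movement_id=mov, trial_index=tr,
                                         condition=cond, start_sample=start,
                                         end_sample=end))
                if cond != "no_stim":
                    A[:, start:end] = generate_activations(
                        k, trial_len, seed=int(r_act.integers(2**31)))
                pos += block

    envelope = W @ A                                  # muscles x total, >= 0
    active = envelope[:, envelope.any(axis=0)]
    signal_rms = float(np.sqrt(np.mean(active**2))) if active.size else 1.0
    for ch in range(m):
        carrier = _multisine_carrier(total, fs, r_carrier)
        emg[ch] = carrier * envelope[ch]
    if gen.noise_sd > 0:
        emg += gen.noise_sd * signal_rms * r_noise.standard_normal((m, total))
    if gen.artifact is not None and "stim" in conditions:
        train = _artifact_train(total, fs, gen.artifact)
        stim_mask = np.zeros(total, dtype=bool)
        for e in events:
            if e.condition == "stim":
                stim_mask[e.start_sample:e.end_sample] = True
        for ch in layout.artifact_indices:
            emg[ch] += train * stim_mask

    record = SessionRecord(
        emg=emg, fs=fs, events=events, participant_id=participant_id,
        session_index=session_index,
        group=group, channel_names=layout.names,
    )
    truth = PlantedTruth(W_true=W, A_true=A, seed=gen.seed)
    return record, truth
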