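"""Pipeline configuration.

All tunable parameters of the analysis chain live in one dataclass so a run
is fully described by (input sessions, myotomal chart, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ParameterError

#: Canonical lower-limb channel order (right side first, proximal to distal).
CHANNEL_NAMES = (
    "R-IL", "R-RF", "R-TA", "R-EHL", "R-G",
    "L-IL", "L-RF", "L-TA", "L-EHL", "L-G",
)

#: Channels close to the stimulation electrode, median-filtered by default.
DEFAULT_ARTIFACT_CHANNELS = ("R-IL", "L-IL")

#: The six cued voluntary movements of the BMCA protocol.
MOVEMENTS = ("BL-Hip", "R-Hip", "L-Hip", "BL-Ankle", "R-Ankle", "L-Ankle")

#: Recognized condition labels.
CONDITIONS = ("stim", "no_stim", "control")

N_TRIALS_PER_MOVEMENT = 3


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel identifiers plus the subset flagged for artifact removal."""

    names: tuple[str, ...] = CHANNEL_NAMES
    artifact_channels: tuple[str, ...] = DEFAULT_ARTIFACT_CHANNELS

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ParameterError("channel names must be unique")
        if len(self.names) != 10:
            raise ParameterError(f"expected 10 channels, got {len(self.names)}")
        unknown = set(self.artifact_channels) - set(self.names)
        if unknown:
            raise ParameterError(f"artifact channels not in layout: {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def artifact_indices(self) -> tuple[int, ...]:
        return tuple(self.names.index(c) for c in self.artifact_channels)


@dataclass
class PipelineConfig:
    """Every knob of the analysis chain, with the defaults used throughout.

    Parameters
    ----------
    band_low_hz, band_high_hz : float
        Butterworth bandpass edges. A high edge at or above Nyquist is capped
        at 0.99 x Nyquist at filter time (a digital bandpass to Nyquist is
        degenerate).
    filter_order : int
        Overall bandpass order (even); the design uses ``filter_order // 2``
        poles per edge.
    median_kernel : int
        Odd kernel length (samples) of the artifact median filter.
    rms_window_ms : float
        Non-overlapping RMS window length in milliseconds.
    n_timepoints : int
        Length of every time-normalized trial.
    vaf_threshold : float
        Minimum variance accounted for when selecting the synergy count.
    k_range : tuple
        Inclusive (min, max) factorization ranks scanned.
    n_restarts : int
        Random restarts per NNMF fit (best residual wins).
    hfd_kmax : int
        Largest delay k of the Higuchi curve-length family.
    normalization_scope : str
        "per_muscle_session" (min-max over all trials of a session, per
        muscle) or "per_trial" (min-max per muscle within each trial).
    r2_definition : str
        "centered_total" (1 - SSE/SST of the original data) or
        "reconstruction_centered" (denominator built from the reconstruction).
    """

    band_low_hz: float = 10.0
    band_high_hz: float = 300.0
    filter_order: int = 6
    zero_phase: bool = True
    median_kernel: int = 5
    rms_window_ms: float = 100.0
    n_timepoints: int = 7000
    vaf_threshold: float = 0.85
    k_range: tuple[int, int] = (1, 10)
    n_restarts: int = 100
    nnmf_tol: float = 1e-6
    nnmf_max_iter: int = 1000
    hfd_kmax: int = 64
    normalization_scope: str = "per_muscle_session"
    r2_definition: str = "centered_total"
    seed: int = 0
    layout: ChannelLayout = field(default_factory=ChannelLayout)

    def __post_init__(self):
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ParameterError("require 0 < band_low_hz < band_high_hz")
        if self.filter_order <= 0 or self.filter_order % 2:
            raise ParameterError("filter_order must be a positive even integer")
        if self.median_kernel < 3 or self.median_kernel % 2 == 0:
            raise ParameterError("median_kernel must be odd and >= 3")
        for name in ("rms_window_ms", "n_timepoints", "n_restarts",
                     "nnmf_tol", "nnmf_max_iter"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.vaf_threshold < 1:
            raise ParameterError("vaf_threshold must lie in (0, 1)")
        lo, hi = self.k_range
        if not (1 <= lo <= hi <= self.layout.n_channels):
            raise ParameterError("k_range must satisfy 1 <= lo <= hi <= n_channels")
        if self.hfd_kmax < 2:
            raise ParameterError("hfd_kmax must be >= 2")
        if self.normalization_scope not in ("per_muscle_session", "per_trial"):
            raise ParameterError(f"unknown normalization_scope {self.normalization_scope!r}")
        if self.r2_definition not in ("centered_total", "reconstruction_centered"):
            raise ParameterError(f"unknown r2_definition {self.r2_definition!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        d["layout"] = {
            "names": list(self.layout.names),
            "artifact_channels": list(self.layout.artifact_channels),
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "layout" in d:
            lay = d.pop("layout")
            d["layout"] = ChannelLayout(
                names=tuple(lay["names"]),
                artifact_channels=tuple(lay.get("artifact_channels", DEFAULT_ARTIFACT_CHANNELS)),
            )
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)
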