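"""Rostro-caudal spinal motor-output maps.

Muscle envelopes are projected onto lumbosacral spinal segments through a
myotomal chart: segment activity is the chart-weighted average

    S[j, s] = sum_i k_ij * E[i, s] / n_j

where k_ij in [0, 1] weights muscle i at segment j and n_j counts the
muscles with positive weight at segment j.  The chart ships as a CSV
(rows = muscles, columns = segments L1..S1) and the built-in default is an
implementation default assembled from published Sharrard-derived innervation
tables for the 10 recorded muscles; any user chart with the same shape is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CHANNEL_NAMES
from .errors import ChartError
from .preprocess import EnvelopeMatrix

SEGMENTS = ("L1", "L2", "L3", "L4", "L5", "S1")

# Implementation-default innervation weights (muscles x segments), derived
# from published Sharrard-type myotomal tables; mirrored left/right.
_DEFAULT_CHART_CSV = """\
muscle,L1,L2,L3,L4,L5,S1
R-IL,0.5,1.0,0.5,0.0,0.0,0.0
R-RF,0.0,0.5,1.0,0.5,0.0,0.0
R-TA,0.0,0.0,0.0,1.0,0.5,0.0
R-EHL,0.0,0.0,0.0,0.0,1.0,0.5
R-G,0.0,0.0,0.0,0.0,0.5,1.0
L-IL,0.5,1.0,0.5,0.0,0.0,0.0
L-RF,0.0,0.5,1.0,0.5,0.0,0.0
L-TA,0.0,0.0,0.0,1.0,0.5,0.0
L-EHL,0.0,0.0,0.0,0.0,1.0,0.5
L-G,0.0,0.0,0.0,0.0,0.5,1.0
"""


@dataclass
class MyotomalChart:
    """Validated muscle x segment weight table."""

    weights: pd.DataFrame          # index = muscles, columns = segments

    def __post_init__(self):
        w = self.weights
        if tuple(w.columns) != SEGMENTS:
            raise ChartError(
                f"chart columns must be {SEGMENTS}, got {tuple(w.columns)}")
        unknown = set(w.index) - set(CHANNEL_NAMES)
        if unknown:
            raise ChartError(f"unknown muscle(s) in chart: {sorted(unknown)}")
        missing = set(CHANNEL_NAMES) - set(w.index)
        if missing:
            raise ChartError(f"chart missing muscle(s): {sorted(missing)}")
        vals = w.to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or vals.min() < 0 or vals.max() > 1:
            raise ChartError("chart weights must lie in [0, 1]")
        if np.any((vals > 0).sum(axis=1) < 1):
            raise ChartError("every muscle needs at least one positive weight")
        if np.any((vals > 0).sum(axis=0) < 1):
            empty = [s for s, c in zip(SEGMENTS, (vals > 0).sum(axis=0)) if c < 1]
            raise ChartError(f"segment(s) with no contributing muscle: {empty}")
        # canonical muscle order
        self.weights = w.loc[list(CHANNEL_NAMES)]

    @property
    def matrix(self) -> np.ndarray:
        return self.weights.to_numpy(dtype=float)

    @property
    def n_j(self) -> np.ndarray:
        """Number of muscles with positive weight, per segment."""
        return (self.matrix > 0).sum(axis=0)

    def to_csv(self, path: str | Path) -> None:
        self.weights.rename_axis("muscle").to_csv(path)


@dataclass
class SpinalMap:
    """Estimated segment x time alpha-motor-neuron activity."""

    activity: np.ndarray          # segments x n_timepoints, >= 0
    movement_id: str
    condition: str
    segments: tuple[str, ...] = SEGMENTS


def load_chart(path: str | Path | None = None) -> MyotomalChart:
    """Load a myotomal chart CSV; None loads the built-in default."""
    if path is None:
        df = pd.read_csv(StringIO(_DEFAULT_CHART_CSV), index_col=0)
    else:
        df = pd.read_csv(path, index_col=0)
    df.columns = [str(c) for c in df.columns]
    return MyotomalChart(weights=df)


def map_to_segments(envelope: EnvelopeMatrix | np.ndarray,
                    chart: MyotomalChart) -> SpinalMap | np.ndarray:
    """Project a muscles x time envelope onto segments x time activity.

    Accepts either an :class:`EnvelopeMatrix` (returns a :class:`SpinalMap`)
    or a bare array (returns the bare activity array).
    """
    bare = not isinstance(envelope, EnvelopeMatrix)
    values = envelope if bare else envelope.values
    values = np.asarray(values, dtype=float)
    k = chart.matrix
    if values.shape[0] != k.shape[0]:
        raise ChartError(
            f"envelope has {values.shape[0]} muscles, chart has {k.shape[0]}")
    activity = (k.T @ values) / chart.n_j[:, None]
    if bare:
        return activity
    return SpinalMap(activity=activity, movement_id=envelope.movement_id,
                     condition=envelope.condition)


def plot_spinal_map(spinal_map: SpinalMap, ax=None):
    """Heatmap of segment x time activity (rostral segment on top)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(spinal_map.activity, aspect="auto", origin="upper",
                   cmap="viridis", interpolation="nearest")
    ax.set_yticks(range(len(spinal_map.segments)), spinal_map.segments)
    ax.set_xlabel("normalized time")
    ax.set_title(f"{spinal_map.movement_id} ({spinal_map.condition})")
    plt.colorbar(im, ax=ax, label="activity (norm. envelope units)")
    return ax
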