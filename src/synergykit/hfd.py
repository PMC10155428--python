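"""Higuchi fractal dimension of envelope time series.

For a series E(1..N) and delay k, k decimated sub-series are formed (one per
starting phase m = 1..k) and the normalized curve length of each is

    L_m(k) = (1/k) * [ sum_{i=1}^{n_mk} |E(m+ik) - E(m+(i-1)k)| ] * (N-1)/(n_mk * k)

with n_mk = int((N-m)/k).  L(k) is the mean of L_m(k) over m, and the
fractal dimension is the slope of the least-squares fit of ln L(k) against
ln(1/k).  Smooth curves give values near 1, white noise near 2, ordinary
Brownian motion near 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import MOVEMENTS
from .errors import DegenerateSeriesError, ParameterError
from .preprocess import TrialKey


@dataclass(frozen=True)
class HFDParams:
    """k_max: largest delay; fit_range: delays used in the slope fit
    (None = every k with a positive curve length)."""

    k_max: int = 64
    fit_range: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.k_max < 2:
            raise ParameterError("k_max must be >= 2")


def curve_lengths(series: np.ndarray, k_max: int) -> np.ndarray:
    """Normalized average curve lengths L(k) for k = 1..k_max.

    Requires N >= 2 * k_max so every delay has at least one increment.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if k_max < 1:
        raise ParameterError("k_max must be >= 1")
    if n < 2 * k_max:
        raise ParameterError(f"series of {n} samples too short for k_max={k_max}")
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        acc = 0.0
        for m in range(1, k + 1):
            sub = x[m - 1::k]
            n_mk = (n - m) // k
            if n_mk < 1:
                continue
            length = np.abs(np.diff(sub[: n_mk + 1])).sum()
            acc += length * (n - 1) / (n_mk * k) / k
        out[k - 1] = acc / k
    return out


def higuchi_fd(series: np.ndarray, params: HFDParams | None = None) -> float:
    """Fractal dimension as the regression slope of ln L(k) on ln(1/k)."""
    params = params or HFDParams()
    lk = curve_lengths(series, params.k_max)
    ks = np.arange(1, params.k_max + 1)
    if params.fit_range is not None:
        mask = np.isin(ks, params.fit_range)
        ks, lk = ks[mask], lk[mask]
    keep = np.isfinite(lk) & (lk > 0)
    if keep.sum() < 2:
        raise DegenerateSeriesError(
            "fewer than 2 positive curve lengths; series too flat")
    logx = np.log(1.0 / ks[keep])
    logy = np.log(lk[keep])
    slope, _ = np.polyfit(logx, logy, 1)
    return float(slope)


def complexity_table(
    trials: dict[TrialKey, np.ndarray],
    channel_names,
    params: HFDParams | None = None,
    participant_id: str = "P0",
    session_index: int = 1,
) -> pd.DataFrame:
    """Per-trial fractal dimension averaged over the trials of each
    (muscle, movement, condition).

    Degenerate trials are recorded as NaN, never imputed; the returned long
    table has one row per (muscle, movement, condition) with the number of
    trials that contributed.
    """
    params = params or HFDParams()
    rows = []
    groups: dict[tuple[str, str], list[int]] = {}
    for (mov, cond, tr) in trials:
        groups.setdefault((mov, cond), []).append(tr)
    for (mov, cond), trial_ids in sorted(groups.items(),
                                         key=lambda kv: (kv[0][1], MOVEMENTS.index(kv[0][0]))):
        mats = [trials[(mov, cond, t)] for t in sorted(trial_ids)]
        for ch, name in enumerate(channel_names):
            vals = []
            for mat in mats:
                try:
                    vals.append(higuchi_fd(mat[ch], params))
                except DegenerateSeriesError:
                    pass
            rows.append({
                "participant": participant_id,
                "session": session_index,
                "muscle": name,
                "movement": mov,
                "condition": cond,
                "hfd": float(np.mean(vals)) if vals else np.nan,
                "n_trials": len(vals),
            })
    return pd.DataFrame(rows)
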