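"""Muscle-synergy extraction by non-negative matrix factorization.

A movement's ensemble envelope E (muscles x time, non-negative) is modeled
as E ~ W A with W >= 0 the muscles x k synergy loadings and A >= 0 the
k x time activation coefficients.  Factors are fitted by the classic
multiplicative update rule for the Frobenius objective, restarted from many
random initializations (the best residual wins), and the number of synergies
is the smallest k whose variance-accounted-for crosses a threshold
(default 85%) over k = 1..10.

Implementation notes
--------------------
Restarts are batched: all initializations are iterated together as stacked
3-d arrays for a short burn-in, then only the best few are run to
convergence.  This is an exact multi-start strategy (every restart is
started; pruning only stops restarts that are already dominated), chosen for
throughput on long envelopes.  The per-iteration objective is evaluated with
the trace identity ||E - WA||^2 = ||E||^2 - 2<W, EA'> + <W'W, AA'> so no
full reconstruction is formed inside the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import ParameterError
from .preprocess import EnvelopeMatrix

_EPS = 1e-12


@dataclass
class SynergyFit:
    """Best factorization of one matrix at one rank."""

    W: np.ndarray                 # muscles x k, columns scaled to unit max
    A: np.ndarray                 # k x time
    residual: float               # Frobenius norm of E - W A
    k: int
    restart_index: int
    history: np.ndarray           # residual per iteration of the winning restart


@dataclass
class SynergySet:
    """Selected factorization plus the variance-accounted-for curve."""

    W: np.ndarray
    A: np.ndarray
    k: int
    r2_curve: np.ndarray          # indexed by rank, NaN where not computed
    ks: np.ndarray
    residual: float
    threshold_met: bool
    movement_id: str = ""
    condition: str = ""
    norm_offset: np.ndarray | None = None
    norm_scale: np.ndarray | None = None
    fits: dict[int, SynergyFit] = field(default_factory=dict, repr=False)


def _validate_input(E: np.ndarray, k: int) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if E.ndim != 2:
        raise ParameterError("E must be 2-d (muscles x time)")
    if np.any(E < 0):
        raise ParameterError("E must be non-negative")
    m = E.shape[0]
    if not 1 <= k <= m:
        raise ParameterError(f"k={k} outside [1, {m}]")
    # fully-zero rows/columns break multiplicative updates; nudge them
    E = E.copy()
    zr = ~E.any(axis=1)
    zc = ~E.any(axis=0)
    if zr.any():
        E[zr] = _EPS
    if zc.any():
        E[:, zc] = _EPS
    return E


def _batch_residuals(E, W, H):
    """Squared Frobenius residuals for stacked factors via the trace identity."""
    EHt = np.matmul(E, H.transpose(0, 2, 1))            # R x m x k
    WtW = np.matmul(W.transpose(0, 2, 1), W)            # R x k x k
    HHt = np.matmul(H, H.transpose(0, 2, 1))            # R x k x k
    ee = float(np.sum(E * E))
    cross = np.einsum("rmk,rmk->r", W, EHt)
    quad = np.einsum("rij,rij->r", WtW, HHt)
    return np.maximum(ee - 2.0 * cross + quad, 0.0)


def _mu_step(E, W, H):
    """One full multiplicative update (H then W) on stacked factors."""
    WtE = np.matmul(W.transpose(0, 2, 1), E)
    WtW = np.matmul(W.transpose(0, 2, 1), W)
    H *= WtE / (np.matmul(WtW, H) + _EPS)
    EHt = np.matmul(E, H.transpose(0, 2, 1))
    HHt = np.matmul(H, H.transpose(0, 2, 1))
    W *= EHt / (np.matmul(W, HHt) + _EPS)
    return W, H


def nnmf(
    E: np.ndarray,
    k: int,
    n_restarts: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    burn_iter: int = 60,
    keep_frac: float = 0.05,
) -> SynergyFit:
    """Best-of-restarts NNMF of a non-negative matrix at rank k.

    Every restart draws W, A entries uniformly from (0, 1] (A scaled to the
    data mean), runs ``burn_iter`` multiplicative updates, and the best
    ``keep_frac`` fraction (at least one) continues until the relative
    residual improvement per iteration falls below ``tol`` or ``max_iter``
    iterations.  Deterministic given ``seed``; ties broken by restart index.

    Returns the winning fit with W columns rescaled to unit maximum and the
    scale absorbed into A.
    """
    E = _validate_input(E, k)
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")
    m, n = E.shape
    rng = np.random.default_rng(seed)
    scale = max(float(E.mean()), _EPS)
    R = int(n_restarts)
    W = 1.0 - rng.random((R, m, k))
    H = (1.0 - rng.random((R, k, n))) * scale
    burn = min(burn_iter, max_iter)
    hist_burn = np.empty((R, burn))
    for it in range(burn):
        _mu_step(E, W, H)
        hist_burn[:, it] = np.sqrt(_batch_residuals(E, W, H))
    res = hist_burn[:, -1] if burn else np.sqrt(_batch_residuals(E, W, H))
    n_keep = max(1, int(np.ceil(keep_frac * R))) if R > 1 else 1
    keep = np.argsort(res, kind="stable")[:n_keep]
    Wk, Hk = W[keep].copy(), H[keep].copy()
    prev = res[keep].copy()
    active = np.ones(n_keep, dtype=bool)
    tails: list[list[float]] = [[] for _ in range(n_keep)]
    for _ in range(burn, max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Wa, Ha = Wk[idx], Hk[idx]
        _mu_step(E, Wa, Ha)
        cur = np.sqrt(_batch_residuals(E, Wa, Ha))
        Wk[idx], Hk[idx] = Wa, Ha
        for j, i in enumerate(idx):
            tails[i].append(float(cur[j]))
        improved = (prev[idx] - cur) / np.maximum(prev[idx], _EPS)
        done = improved < tol
        prev[idx] = cur
        active[idx[done]] = False
    order = np.argsort(prev, kind="stable")
    best_local = int(order[0])
    best_restart = int(keep[best_local])
    Wb, Hb = Wk[best_local], Hk[best_local]
    residual = float(prev[best_local])
    # absorb column scale: unit-max loadings
    cmax = Wb.max(axis=0)
    cmax = np.where(cmax > 0, cmax, 1.0)
    Wb = Wb / cmax
    Hb = Hb * cmax[:, None]
    history = np.concatenate([hist_burn[best_restart], np.asarray(tails[best_local])])
    return SynergyFit(W=Wb, A=Hb, residual=residual, k=k,
                      restart_index=best_restart, history=history)


def r_squared(E: np.ndarray, recon: np.ndarray,
              definition: str = "centered_total") -> float:
    """Variance accounted for by a reconstruction.

    centered_total: 1 - SSE / sum((E - mean(E))^2)  (mean over all entries).
    reconstruction_centered:  denominator built from the reconstruction and its
    per-muscle mean instead of the data; kept for comparison, can exceed 1.
    """
    E = np.asarray(E, dtype=float)
    recon = np.asarray(recon, dtype=float)
    sse = float(np.sum((E - recon) ** 2))
    if definition == "centered_total":
        sst = float(np.sum((E - E.mean()) ** 2))
    elif definition == "reconstruction_centered":
        sst = float(np.sum((recon - recon.mean(axis=1, keepdims=True)) ** 2))
    else:
        raise ParameterError(f"unknown r2 definition {definition!r}")
    if sst <= 0:
        raise ParameterError("zero total sum of squares; constant data")
    return 1.0 - sse / sst


def vaf_curve(
    E: np.ndarray,
    k_range: tuple[int, int] = (1, 10),
    n_restarts: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    r2_definition: str = "centered_total",
    stop_at: float | None = None,
) -> tuple[np.ndarray, np.ndarray, dict[int, SynergyFit]]:
    """R^2 of the best rank-k factorization for k over ``k_range``.

    ``stop_at`` enables early stopping: once a rank crosses that value the
    remaining ranks are left NaN (the selected order — the smallest crossing
    rank — is unchanged by the skipped fits).

    Returns (ks, r2 values, fits keyed by k).
    """
    lo, hi = k_range
    if lo < 1 or hi < lo:
        raise ParameterError(f"bad k_range {k_range}")
    ks = np.arange(lo, hi + 1)
    r2 = np.full(ks.shape, np.nan)
    fits: dict[int, SynergyFit] = {}
    children = np.random.SeedSequence(seed).spawn(len(ks))
    for i, k in enumerate(ks):
        sub_seed = int(children[i].generate_state(1)[0] % (2**31))
        fit = nnmf(E, int(k), n_restarts=n_restarts, seed=sub_seed,
                   tol=tol, max_iter=max_iter)
        fits[int(k)] = fit
        r2[i] = r_squared(E, fit.W @ fit.A, r2_definition)
        if stop_at is not None and r2[i] >= stop_at:
            break
    return ks, r2, fits


def select_order(r2_curve: np.ndarray, ks: np.ndarray | None = None,
                 threshold: float = 0.85) -> tuple[int, bool]:
    """Smallest rank whose R^2 meets the threshold.

    Returns (k, met).  If no computed rank crosses the threshold, the largest
    computed rank is returned with ``met=False``.
    """
    r2 = np.asarray(r2_curve, dtype=float)
    if ks is None:
        ks = np.arange(1, r2.size + 1)
    ks = np.asarray(ks)
    defined = np.isfinite(r2)
    if not defined.any():
        raise ParameterError("empty R^2 curve")
    crossing = defined & (r2 >= threshold)
    if crossing.any():
        return int(ks[crossing][0]), True
    return int(ks[defined][-1]), False


def extract_synergies(
    envelope: EnvelopeMatrix | np.ndarray,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    lazy_curve: bool = False,
) -> SynergySet:
    """Full extraction: VAF curve, order selection, factors at the order.

    With ``lazy_curve`` the curve is only computed up to the first threshold
    crossing (identical selected order, fewer fits).
    """
    config = config or PipelineConfig()
    is_env = isinstance(envelope, EnvelopeMatrix)
    E = envelope.values if is_env else np.asarray(envelope, dtype=float)
    use_seed = config.seed if seed is None else seed
    lo, hi = config.k_range
    hi = min(hi, E.shape[0])      # the channel count caps the rank scan
    ks, r2, fits = vaf_curve(
        E, k_range=(lo, hi), n_restarts=config.n_restarts,
        seed=use_seed, tol=config.nnmf_tol, max_iter=config.nnmf_max_iter,
        r2_definition=config.r2_definition,
        stop_at=config.vaf_threshold if lazy_curve else None,
    )
    k, met = select_order(r2, ks, config.vaf_threshold)
    fit = fits[k]
    return SynergySet(
        W=fit.W, A=fit.A, k=k, r2_curve=r2, ks=ks, residual=fit.residual,
        threshold_met=met,
        movement_id=envelope.movement_id if is_env else "",
        condition=envelope.condition if is_env else "",
        norm_offset=getattr(envelope, "norm_offset", None),
        norm_scale=getattr(envelope, "norm_scale", None),
        fits=fits,
    )


def denormalize_loadings(W: np.ndarray, norm_scale: np.ndarray) -> np.ndarray:
    """Map loadings estimated from min-max normalized envelopes back to
    physical envelope units (each muscle row multiplied by its span)."""
    return np.asarray(W) * np.asarray(norm_scale)[:, None]
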