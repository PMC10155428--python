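"""Cross-participant synergy comparison.

Synergy loadings are compared with cosine similarity; a cohort template is
the participant whose synergies best match everyone else's under the optimal
one-to-one assignment, and each participant's synergies are reordered to
that template.  Activation coefficients of matched synergies are compared
with the normalized zero-lag cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import DegenerateSeriesError, ParameterError
from .synergy import SynergySet


def cosine_similarity(w_a: np.ndarray, w_b: np.ndarray) -> float:
    """cos(theta) between two loading vectors; in [0, 1] for non-negative ones."""
    a = np.asarray(w_a, dtype=float).ravel()
    b = np.asarray(w_b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateSeriesError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def similarity_matrix(W_a: np.ndarray, W_b: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of the columns of two loading matrices."""
    A = np.asarray(W_a, dtype=float)
    B = np.asarray(W_b, dtype=float)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    if np.any(na == 0) or np.any(nb == 0):
        raise DegenerateSeriesError("zero loading column")
    return (A.T @ B) / np.outer(na, nb)


def match_and_reorder(W: np.ndarray, W_template: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one matching of ``W`` columns to template columns.

    Returns (perm, sims): ``perm[j]`` is the column of ``W`` assigned to
    template column j, and ``sims[j]`` its cosine similarity.  The
    assignment maximizes the summed similarity (Hungarian algorithm), so it
    equals the exhaustive-permutation optimum.
    """
    W = np.asarray(W, dtype=float)
    T = np.asarray(W_template, dtype=float)
    if W.shape[1] != T.shape[1]:
        raise ParameterError(
            f"synergy count mismatch: {W.shape[1]} vs {T.shape[1]}")
    S = similarity_matrix(T, W)                  # template rows x set columns
    rows, cols = linear_sum_assignment(-S)
    perm = np.empty(T.shape[1], dtype=int)
    perm[rows] = cols
    sims = S[np.arange(T.shape[1]), perm]
    return perm, sims


def assignment_score(W_a: np.ndarray, W_b: np.ndarray) -> float:
    """Total cosine similarity of the optimal column assignment."""
    _, sims = match_and_reorder(W_a, W_b)
    return float(sims.sum())


def choose_template(sets: list[SynergySet] | list[np.ndarray]) -> int:
    """Index of the set whose synergies best match all the others.

    Score of candidate p = sum over q != p of the optimal-assignment total
    cosine similarity; ties go to the lowest index.  All sets must share k.
    """
    Ws = [s.W if isinstance(s, SynergySet) else np.asarray(s) for s in sets]
    if len(Ws) < 2:
        raise ParameterError("need at least 2 synergy sets")
    kset = {W.shape[1] for W in Ws}
    if len(kset) > 1:
        raise ParameterError(f"synergy counts differ across sets: {sorted(kset)}; "
                             "re-extract at a common k before matching")
    scores = np.zeros(len(Ws))
    for p, Wp in enumerate(Ws):
        scores[p] = sum(assignment_score(Wq, Wp)
                        for q, Wq in enumerate(Ws) if q != p)
    return int(np.argmax(scores))  # argmax takes the first maximum: lowest index


def activation_correlation(a_row: np.ndarray, b_row: np.ndarray) -> float:
    """Normalized zero-lag cross-correlation (Pearson r at lag 0)."""
    a = np.asarray(a_row, dtype=float).ravel()
    b = np.asarray(b_row, dtype=float).ravel()
    if a.size != b.size:
        raise ParameterError("activation rows differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateSeriesError("correlation undefined for a constant row")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


@dataclass
class MatchResult:
    """Template choice plus per-set reordering against it."""

    template_index: int
    permutations: list[np.ndarray]        # one per set, template order -> set column
    similarities: list[np.ndarray]        # matched cosine per template synergy
    activation_correlations: list[np.ndarray]


def match_cohort(sets: list[SynergySet]) -> MatchResult:
    """Choose a template across a cohort and reorder every set against it."""
    t = choose_template(sets)
    template = sets[t]
    perms, sims, acorrs = [], [], []
    for s in sets:
        perm, sim = match_and_reorder(s.W, template.W)
        ac = np.full(template.k, np.nan)
        for j in range(template.k):
            try:
                ac[j] = activation_correlation(s.A[perm[j]], template.A[j])
            except DegenerateSeriesError:
                pass
        perms.append(perm)
        sims.append(sim)
        acorrs.append(ac)
    return MatchResult(template_index=t, permutations=perms,
                       similarities=sims, activation_correlations=acorrs)
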