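"""Nonparametric group statistics.

The battery used on complexity (HFD) tables and variance-accounted-for
values: a composite normality check (Lilliefors/Kolmogorov-Smirnov against a
fitted normal), Wilcoxon signed-rank for the paired stimulation contrast,
Mann-Whitney U for the control-vs-patient contrast, Bonferroni family-wise
correction, and a two-one-sided-tests (TOST) equivalence test on R^2 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.weightstats import ttost_ind

from .errors import DegenerateSeriesError, ParameterError


def ks_normality(sample) -> float:
    """p-value of the composite normality test (normal with estimated
    mean/SD; Lilliefors correction of the Kolmogorov-Smirnov statistic)."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 3:
        raise ParameterError("normality test needs n >= 3")
    _, p = lilliefors(x, dist="norm")
    return float(p)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded before ranking; n >= 5 pairs must remain.
    Exact p for n <= 25, normal approximation (tie-corrected, continuity
    correction) above.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ParameterError("paired samples differ in length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateSeriesError("all paired differences are zero")
    if d.size < 5:
        raise ParameterError(f"only {d.size} nonzero differences; need >= 5")
    method = "exact" if d.size <= 25 and np.unique(np.abs(d)).size == d.size \
        else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method,
                       correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; exact p for small tie-free samples,
    tie-corrected normal approximation otherwise."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class BonferroniThreshold:
    """Per-test significance threshold alpha/m with a display rounding."""

    alpha: float
    m: int
    exact: float
    display: float


def bonferroni_alpha(alpha: float, m: int) -> BonferroniThreshold:
    """Family-wise Bonferroni threshold alpha/m.

    ``display`` rounds the exact threshold to one significant figure, the
    convention used when quoting the threshold in reports (0.05 over 67
    tests prints as 0.0007).
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    exact = alpha / m
    digits = -int(np.floor(np.log10(exact)))
    display = float(np.round(exact, digits))
    if display > exact:  # keep the displayed threshold conservative
        display = float(np.floor(exact * 10 ** digits) / 10 ** digits)
    return BonferroniThreshold(alpha=alpha, m=m, exact=exact, display=display)


@dataclass(frozen=True)
class EquivalenceResult:
    equivalent: bool
    p: float                       # max of the two one-sided p-values
    p_lower: float
    p_upper: float
    margin: float
    alpha: float


def tost_equivalence(a, b, margin: float, alpha: float = 0.05) -> EquivalenceResult:
    """Independent-groups equivalence test (two one-sided t tests).

    The groups are declared equivalent if the mean difference is shown to lie
    within (-margin, +margin): both one-sided p-values below alpha.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if margin <= 0:
        raise ParameterError("margin must be positive")
    if a.size < 3 or b.size < 3:
        raise ParameterError("equivalence test needs n >= 3 per group")
    p, (t1, p_lower, _), (t2, p_upper, _) = ttost_ind(a, b, -margin, margin,
                                                      usevar="unequal")
    return EquivalenceResult(
        equivalent=bool(p < alpha), p=float(p),
        p_lower=float(p_lower), p_upper=float(p_upper),
        margin=float(margin), alpha=float(alpha),
    )


@dataclass
class StatsReport:
    """One row per comparison, plus the family-wise threshold and the R^2
    equivalence outcome."""

    comparisons: pd.DataFrame
    threshold: BonferroniThreshold
    equivalence: EquivalenceResult | None = None
    skipped: list[str] = field(default_factory=list)


def run_group_analysis(
    hfd_table: pd.DataFrame,
    r2_values: dict[str, np.ndarray] | None = None,
    alpha: float = 0.05,
    family_size: int | None = None,
    equivalence_margin: float = 0.05,
) -> StatsReport:
    """The full statistical battery on a long-format complexity table.

    ``hfd_table`` columns: participant, session, muscle, movement,
    condition, hfd.  Per (muscle, movement) cell the battery runs

    * paired Wilcoxon signed-rank of stim vs no_stim, paired on
      (participant, session);
    * unpaired Mann-Whitney U of control vs stim.

    ``r2_values`` maps group labels ("SCI", "control") to the R^2 values at
    the common synergy count; when both groups are present a TOST
    equivalence test with ``equivalence_margin`` (absolute R^2) is attached.

    ``family_size`` overrides the Bonferroni family size m (default: the
    number of comparisons actually run).
    """
    rows = []
    skipped = []
    cells = hfd_table.groupby(["muscle", "movement"], sort=True)
    for (muscle, movement), cell in cells:
        piv = cell.pivot_table(index=["participant", "session"],
                               columns="condition", values="hfd")
        if {"stim", "no_stim"} <= set(piv.columns):
            pair = piv[["stim", "no_stim"]].dropna()
            try:
                stat, p = wilcoxon_signed_rank(pair["stim"], pair["no_stim"])
                rows.append({"comparison": "stim_vs_no_stim", "muscle": muscle,
                             "movement": movement, "test": "wilcoxon",
                             "statistic": stat, "p": p,
                             "n1": len(pair), "n2": len(pair)})
            except (ParameterError, DegenerateSeriesError) as exc:
                skipped.append(f"stim_vs_no_stim {muscle}/{movement}: {exc}")
        ctrl = cell.loc[cell.condition == "control", "hfd"].dropna()
        stim = cell.loc[cell.condition == "stim", "hfd"].dropna()
        if len(ctrl) and len(stim):
            try:
                stat, p = mann_whitney_u(ctrl, stim)
                rows.append({"comparison": "control_vs_stim", "muscle": muscle,
                             "movement": movement, "test": "mann_whitney",
                             "statistic": stat, "p": p,
                             "n1": len(ctrl), "n2": len(stim)})
            except ParameterError as exc:
                skipped.append(f"control_vs_stim {muscle}/{movement}: {exc}")
    comparisons = pd.DataFrame(
        rows, columns=["comparison", "muscle", "movement", "test",
                       "statistic", "p", "n1", "n2"])
    m = family_size if family_size is not None else max(len(comparisons), 1)
    threshold = bonferroni_alpha(alpha, m)
    if not comparisons.empty:
        comparisons["significant"] = comparisons["p"] < threshold.exact
    equivalence = None
    if r2_values and {"SCI", "control"} <= set(r2_values):
        equivalence = tost_equivalence(r2_values["SCI"], r2_values["control"],
                                       margin=equivalence_margin, alpha=alpha)
    return StatsReport(comparisons=comparisons, threshold=threshold,
                       equivalence=equivalence, skipped=skipped)
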