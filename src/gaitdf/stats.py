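"""Group statistics: bin-wise waveform comparison and DF distribution tests.

Two families of inference are provided:

* :func:`binwise_compare` — at each of the 100 step-cycle bins, an
  unpaired Student's t-test (pooled variance) between the curves of two
  groups, with the *percent of step cycle changed* defined as the count
  of significant bins.  Step curves are the unit of analysis (SEM uses
  the number of curves); an animal-mean mode is available for the more
  conservative reading.  By default no correction is applied across the
  100 bins; a Benjamini–Hochberg option exists.

* DF distribution comparison — Lilliefors-corrected Kolmogorov–Smirnov
  normality per group, Kruskal–Wallis across groups (tie-corrected) and
  Dunn's post hoc z-tests on mean ranks, Bonferroni-adjusted over the
  tested pairs by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .records import N_BINS, NormalizedStepCurve

__all__ = [
    "BinwiseComparison",
    "GroupComparisonResult",
    "binwise_compare",
    "binwise_compare_arrays",
    "ks_normality",
    "kruskal_dunn",
]

TAILS = ("one_sided_auto", "two_sided")
CORRECTIONS = (None, "bh")


@dataclass
class BinwiseComparison:
    """Per-bin two-sample comparison of two groups of step curves."""

    joint: str
    side: str
    group_a: str
    group_b: str
    axis: str
    alpha: float
    tail: str
    correction: str | None
    n_a: int
    n_b: int
    mean_a: np.ndarray
    sem_a: np.ndarray
    mean_b: np.ndarray
    sem_b: np.ndarray
    t_stat: np.ndarray
    p: np.ndarray
    significant: np.ndarray

    @property
    def percent_changed(self) -> int:
        """Count of significant bins out of 100 = percent of cycle changed."""
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, N_BINS + 1),
                "mean_a": self.mean_a,
                "sem_a": self.sem_a,
                "mean_b": self.mean_b,
                "sem_b": self.sem_b,
                "t_stat": self.t_stat,
                "p": self.p,
                "significant": self.significant.astype(int),
            }
        )


def _sem(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    if n < 2:
        return np.full(values.shape[1], np.nan)
    return values.std(axis=0, ddof=1) / np.sqrt(n)


def binwise_compare_arrays(
    a: np.ndarray,
    b: np.ndarray,
    *,
    alpha: float = 0.05,
    tail: str = "one_sided_auto",
    correction: str | None = None,
    joint: str = "",
    side: str = "",
    group_a: str = "A",
    group_b: str = "B",
    axis_name: str = "y",
) -> BinwiseComparison:
    """Bin-wise comparison of two (n_curves, 100) value arrays.

    Pooled-variance (classic) two-sample t per bin.  Where both groups
    have zero variance and equal means the test is undefined; such bins
    report t = 0, p = 1, not significant.  ``tail="one_sided_auto"``
    halves the two-sided p in the direction of the observed mean
    difference (anti-conservative; see package docs).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != N_BINS or b.shape[1] != N_BINS:
        raise ValueError(f"inputs must be (n_curves, {N_BINS}) arrays")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 curves")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {CORRECTIONS}")

    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_two = sps.ttest_ind(a, b, axis=0, equal_var=True)
    t_stat = np.asarray(t_stat, dtype=float)
    p_two = np.asarray(p_two, dtype=float)

    # zero variance in both groups: equal means -> no evidence (p = 1);
    # unequal means -> infinitely strong evidence (p = 0)
    undefined = ~np.isfinite(t_stat)
    if undefined.any():
        mean_diff = a.mean(axis=0) - b.mean(axis=0)
        same = undefined & np.isclose(mean_diff, 0.0)
        t_stat[same] = 0.0
        p_two[same] = 1.0
        diff = undefined & ~np.isclose(mean_diff, 0.0)
        t_stat[diff] = np.sign(mean_diff[diff]) * np.inf
        p_two[diff] = 0.0

    p = p_two / 2.0 if tail == "one_sided_auto" else p_two

    if correction == "bh":
        significant = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    else:
        significant = p < alpha

    return BinwiseComparison(
        joint=joint,
        side=side,
        group_a=group_a,
        group_b=group_b,
        axis=axis_name,
        alpha=alpha,
        tail=tail,
        correction=correction,
        n_a=a.shape[0],
        n_b=b.shape[0],
        mean_a=a.mean(axis=0),
        sem_a=_sem(a),
        mean_b=b.mean(axis=0),
        sem_b=_sem(b),
        t_stat=t_stat,
        p=p,
        significant=np.asarray(significant, dtype=bool),
    )


def _curve_values(
    curves: Sequence[NormalizedStepCurve], axis: str, animal_means: bool
) -> np.ndarray:
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    values = np.stack([getattr(c, axis) for c in curves])
    if animal_means:
        ids = np.array([c.animal_id for c in curves])
        values = np.stack(
            [values[ids == a].mean(axis=0) for a in sorted(set(ids))]
        )
    return values


def binwise_compare(
    curves_a: Sequence[NormalizedStepCurve],
    curves_b: Sequence[NormalizedStepCurve],
    axis: str = "y",
    alpha: float = 0.05,
    tail: str = "one_sided_auto",
    correction: str | None = None,
    animal_means: bool = False,
) -> BinwiseComparison:
    """Bin-wise group comparison of normalized step curves.

    Both groups must share joint and side and contain at least 2 curves.
    With ``animal_means=True`` curves are first averaged within animal
    and animals become the unit of analysis.
    """
    if len(curves_a) < 2 or len(curves_b) < 2:
        raise ValueError("each group needs at least 2 curves")
    ref = curves_a[0]
    for c in list(curves_a) + list(curves_b):
        if c.joint != ref.joint or c.side != ref.side:
            raise ValueError(
                f"all curves must share joint/side "
                f"({ref.joint}/{ref.side}; found {c.joint}/{c.side})"
            )
    a = _curve_values(curves_a, axis, animal_means)
    b = _curve_values(curves_b, axis, animal_means)
    groups_a = {c.group for c in curves_a}
    groups_b = {c.group for c in curves_b}
    return binwise_compare_arrays(
        a,
        b,
        alpha=alpha,
        tail=tail,
        correction=correction,
        joint=ref.joint,
        side=ref.side,
        group_a=groups_a.pop() if len(groups_a) == 1 else "mixed",
        group_b=groups_b.pop() if len(groups_b) == 1 else "mixed",
        axis_name=axis,
    )


def ks_normality(values: Sequence[float]) -> tuple[float, float]:
    """Kolmogorov–Smirnov normality test with estimated mean and SD.

    Returns ``(statistic, p)``: the sup-distance between the empirical
    CDF and a normal CDF with the sample mean/SD, with the
    Lilliefors-corrected p-value (the reference distribution accounts
    for the estimated parameters).  Requires >= 5 values with nonzero
    spread.  Table-based p-values are clipped to [~1e-3, ~0.23] at the
    extremes.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError(f"need at least 5 values, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values identical")
    stat, p = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonResult:
    """Kruskal–Wallis / Dunn comparison of DF distributions."""

    groups: list[str]
    n: dict[str, int]
    kw_H: float
    kw_p: float
    dunn: pd.DataFrame
    normality: dict[str, tuple[float, float] | None]
    alpha: float
    p_adjust: str | None
    joint: str = ""
    side: str = ""

    def significant_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for ga, gb in combinations(self.groups, 2):
            if self.dunn.loc[ga, gb] < self.alpha:
                pairs.append((ga, gb))
        return pairs


def _dunn_pvalues(
    samples: Mapping[str, np.ndarray], p_adjust: str | None
) -> pd.DataFrame:
    """Dunn's z-tests on mean ranks with tie correction.

    z_{uv} = (Rbar_u - Rbar_v) / sqrt((N(N+1)/12 - T) (1/n_u + 1/n_v)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal
    p, optionally Bonferroni-multiplied by the number of tested pairs.
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_rank = {}
    start = 0
    for g in names:
        n = len(samples[g])
        mean_rank[g] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term

    table = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    pairs = list(combinations(names, 2))
    m = len(pairs)
    for ga, gb in pairs:
        denom = var_base * (1.0 / len(samples[ga]) + 1.0 / len(samples[gb]))
        if denom <= 0:  # all pooled values tied
            p = 1.0
        else:
            z = (mean_rank[ga] - mean_rank[gb]) / np.sqrt(denom)
            p = 2.0 * sps.norm.sf(abs(z))
            if p_adjust == "bonferroni":
                p = min(1.0, p * m)
        table.loc[ga, gb] = table.loc[gb, ga] = p
    return table


def kruskal_dunn(
    df_groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    p_adjust: str | None = "bonferroni",
    joint: str = "",
    side: str = "",
) -> GroupComparisonResult:
    """Kruskal–Wallis across named DF distributions with Dunn post hoc.

    Requires >= 2 groups with >= 2 values each.  If every value in
    every group is identical, H = 0 and all pairwise p = 1 (the
    degenerate no-information case).  Normality entries are None for
    groups too small or too degenerate for the KS test.
    """
    if p_adjust not in (None, "bonferroni"):
        raise ValueError("p_adjust must be None or 'bonferroni'")
    samples = {g: np.asarray(v, dtype=float) for g, v in df_groups.items()}
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")

    pooled = np.concatenate(list(samples.values()))
    if np.ptp(pooled) == 0:
        kw_H, kw_p = 0.0, 1.0
        names = list(samples)
        dunn = pd.DataFrame(
            np.ones((len(names), len(names))), index=names, columns=names
        )
    else:
        kw_H, kw_p = sps.kruskal(*samples.values())
        dunn = _dunn_pvalues(samples, p_adjust)

    normality: dict[str, tuple[float, float] | None] = {}
    for g, v in samples.items():
        try:
            normality[g] = ks_normality(v)
        except ValueError:
            normality[g] = None

    return GroupComparisonResult(
        groups=list(samples),
        n={g: len(v) for g, v in samples.items()},
        kw_H=float(kw_H),
        kw_p=float(kw_p),
        dunn=dunn,
        normality=normality,
        alpha=alpha,
        p_adjust=p_adjust,
        joint=joint,
        side=side,
    )
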