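"""Expression-change trends against per-gene covariates.

The central display is a 200-gene moving average: genes are sorted by a
covariate (wild-type mRNA abundance, transcriptional activity, transcript
length, plasticity, ...) and the mean expression change within each run of
`window` consecutive genes is plotted against the mean covariate.  The
dialect here is trailing windows of exactly `window` genes with step 1 and no
edge padding (n - window + 1 points); ties in the covariate are broken by
gene_id so curves are deterministic.

Association strength is summarized by the Pearson correlation with a
permutation p-value (all permutations enumerated when feasible, otherwise a
seeded add-one Monte-Carlo estimate), and extreme covariate groups are
compared with a two-sided Wilcoxon rank-sum test (exact enumeration with
midrank ties for small samples, normal approximation with continuity
correction otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendCurve",
    "moving_average_trend",
    "pearson_with_permutation",
    "rank_sum_compare",
    "quartile_stratified_trend",
]

EXACT_RANKSUM_MAX_N = 12


@dataclass
class TrendCurve:
    """Moving-average curve: mean covariate and mean response per window."""

    window: int
    x_points: np.ndarray
    y_points: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.x_points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window_index": np.arange(self.n_windows),
                "x": self.x_points,
                "y": self.y_points,
            }
        )


def _sorted_xy(x, y, ids=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if not np.isfinite(x).all():
        raise ValueError("covariate contains non-finite values")
    if ids is None:
        tie_break = np.arange(len(x))
    else:
        tie_break = np.asarray(ids)
        if tie_break.shape != x.shape:
            raise ValueError("ids must match x in length")
    order = np.lexsort((tie_break, x))
    return x[order], y[order]


def moving_average_trend(
    x: Sequence[float],
    y: Sequence[float],
    window: int = 200,
    ids: Optional[Sequence] = None,
) -> TrendCurve:
    """Trailing `window`-gene moving average of y against x.

    Genes are sorted by x ascending (ties broken by ``ids``, lexicographic);
    for each run of `window` consecutive genes the (mean x, mean y) pair is
    emitted.  No edge padding: the curve has n - window + 1 points.
    """
    xs, ys = _sorted_xy(x, y, ids)
    n = len(xs)
    if window < 1:
        raise ValueError("window must be >= 1")
    if n < window:
        raise ValueError(
            f"need at least window={window} genes, got {n}; use a smaller window"
        )
    kernel = np.ones(window) / window
    x_points = np.convolve(xs, kernel, mode="valid")
    y_points = np.convolve(ys, kernel, mode="valid")
    return TrendCurve(window=window, x_points=x_points, y_points=y_points)


def pearson_with_permutation(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Pearson r with a two-sided permutation p-value (y permuted).

    If n! <= n_perm every permutation is enumerated and
    p = #{|r_perm| >= |r|} / n! exactly (the identity permutation counts, so
    p > 0).  Otherwise ``n_perm`` random permutations give the add-one
    estimate p = (1 + #{|r_perm| >= |r|}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    r = float(xs @ ys / n)

    tol = 1e-12
    if math.factorial(n) <= n_perm:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r_perm = xs @ ys[list(perm)] / n
            if abs(r_perm) >= abs(r) - tol:
                count += 1
            total += 1
        return {"r": r, "p": count / total, "n_perm": total, "method": "exact"}

    if rng is None:
        rng = np.random.default_rng(seed)
    count = 0
    chunk = 512
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = rng.permuted(np.tile(ys, (b, 1)), axis=1)
        r_perm = perms @ xs / n
        count += int(np.sum(np.abs(r_perm) >= abs(r) - tol))
        done += b
    return {
        "r": r,
        "p": (1 + count) / (n_perm + 1),
        "n_perm": n_perm,
        "method": "sampled",
    }


def _exact_ranksum_pvalue(ranks: np.ndarray, n_a: int) -> float:
    """Two-sided exact p for the rank-sum of group A over all assignments.

    Uses the symmetric deviation |U - mean(U)|; valid with midrank ties.
    """
    n = len(ranks)
    mu = n_a * (n - n_a) / 2.0
    obs = abs(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0 - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        u = ranks[list(combo)].sum() - n_a * (n_a + 1) / 2.0
        if abs(u - mu) >= obs - 1e-9:
            count += 1
        total += 1
    return count / total


def rank_sum_compare(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test with midrank ties.

    Exact enumeration of all label assignments when the combined sample size
    is at most 12; otherwise the normal approximation with continuity and tie
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    u_a = float(ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0)
    if len(combined) <= EXACT_RANKSUM_MAX_N:
        p = _exact_ranksum_pvalue(ranks, len(a))
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        method = "normal_approx"
    return {"U": u_a, "p": min(p, 1.0), "method": method}


def quartile_stratified_trend(
    abundance: Sequence[float],
    plasticity: Sequence[float],
    slr: Sequence[float],
    window: int = 200,
    ids: Optional[Sequence] = None,
) -> list:
    """Moving-average SLR-vs-plasticity curves within abundance quartiles.

    Quartile 1 holds the highest-abundance genes.  Genes are ranked by
    abundance descending (ties broken by ids ascending, hence assigned to the
    lower quartile index); each quartile must hold at least ``window`` genes.
    """
    abundance = np.asarray(abundance, dtype=float)
    plasticity = np.asarray(plasticity, dtype=float)
    slr = np.asarray(slr, dtype=float)
    n = len(abundance)
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    order = np.lexsort((ids, -abundance))  # descending abundance, stable ties
    boundaries = [(4 * pos) // n for pos in range(n)]
    curves = []
    for q in range(4):
        sel = order[np.asarray(boundaries) == q]
        if len(sel) < window:
            raise ValueError(
                f"quartile {q + 1} has {len(sel)} genes, fewer than window={window}"
            )
        curves.append(
            moving_average_trend(plasticity[sel], slr[sel], window=window, ids=ids[sel])
        )
    return curves
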