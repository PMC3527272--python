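"""Gene-set overlap statistics and the compendium correlation screen.

Overlap between two gene sets drawn from a common universe is scored with
the upper-tail hypergeometric probability P(X >= k) (enrichment only;
depletion is not tested).  Flat functional categories are screened at a raw
p-value cutoff with a Bonferroni column reported for transparency; the
profile screen correlates a differential-expression vector against a library
of external profiles, reporting Pearson R with a permutation p-value and the
hypergeometric overlap p-value (P_o) between the most deregulated gene sets
of the two vectors (genes beyond the 5th/95th percentiles).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .trends import pearson_with_permutation

__all__ = [
    "hypergeometric_overlap",
    "annotation_enrichment",
    "percentile_deregulated",
    "compendium_correlation_screen",
]

logger = logging.getLogger(__name__)


def hypergeometric_overlap(k: int, set_a_size: int, set_b_size: int, universe: int) -> float:
    """Upper-tail overlap probability P(X >= k).

    X ~ Hypergeometric(universe, set_a_size, set_b_size): the overlap when
    ``set_b_size`` genes are drawn without replacement from a universe
    containing ``set_a_size`` marked genes.  Evaluated through the log
    survival function for numerical stability in far tails.
    """
    if not (0 <= set_a_size <= universe and 0 <= set_b_size <= universe):
        raise ValueError("set sizes must lie in [0, universe]")
    if not (0 <= k <= min(set_a_size, set_b_size)):
        raise ValueError("overlap k must lie in [0, min(set sizes)]")
    if k == 0:
        return 1.0
    logp = stats.hypergeom.logsf(k - 1, universe, set_a_size, set_b_size)
    return float(min(1.0, np.exp(logp)))


def annotation_enrichment(
    gene_set: Iterable,
    annotation_map: Mapping[str, Iterable],
    universe: Optional[Iterable] = None,
    p_cutoff: float = 1e-3,
) -> pd.DataFrame:
    """Category enrichment of a gene set at a raw hypergeometric cutoff.

    The universe defaults to the union of all annotated genes.  Categories
    with upper-tail p <= ``p_cutoff`` are returned sorted by p ascending, with
    k (overlap), f (category size), and a Bonferroni-adjusted column; no
    multiple-testing correction is applied to the cutoff itself.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    categories = {c: set(g) for c, g in annotation_map.items()}
    if universe is None:
        universe_set = set().union(*categories.values()) if categories else set()
    else:
        universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    gene_set &= universe_set
    n_cat = len(categories)
    records = []
    for cat, members in sorted(categories.items()):
        members = members & universe_set
        k = len(gene_set & members)
        p = hypergeometric_overlap(k, len(members), len(gene_set), len(universe_set))
        records.append(
            {
                "category_id": cat,
                "k": k,
                "f": len(members),
                "set_size": len(gene_set),
                "universe_size": len(universe_set),
                "p": p,
                "p_bonferroni": min(1.0, p * n_cat),
            }
        )
    frame = pd.DataFrame.from_records(records)
    frame = frame[frame["p"] <= p_cutoff].sort_values(
        ["p", "category_id"], kind="stable", ignore_index=True
    )
    return frame


def percentile_deregulated(
    slr: pd.Series, lower: float = 0.05, upper: float = 0.95
) -> pd.Index:
    """Genes in the extreme tails of the expression-change distribution.

    Union of genes with SLR at or below the ``lower`` rank percentile and at
    or above the ``upper`` one; ties at a threshold are included on the
    extreme side, so the set can exceed its nominal size.  A degenerate
    (all-equal) distribution returns every gene with a warning.
    """
    slr = slr.dropna()
    n = len(slr)
    if n == 0:
        raise ValueError("empty SLR table")
    if slr.nunique() == 1:
        warnings.warn(
            "degenerate SLR distribution: all values equal; returning all genes",
            stacklevel=2,
        )
        return slr.index
    ordered = np.sort(slr.to_numpy())
    k_low = max(int(np.floor(lower * n)), 1)
    k_high = max(int(np.floor((1.0 - upper) * n)), 1)
    low_threshold = ordered[k_low - 1]
    high_threshold = ordered[n - k_high]
    selected = slr.index[(slr <= low_threshold) | (slr >= high_threshold)]
    return selected


def compendium_correlation_screen(
    slr: pd.Series,
    profile_library: Mapping[str, pd.Series],
    min_overlap: int = 100,
    n_perm: int = 10000,
    seed: Optional[int] = None,
    lower: float = 0.05,
    upper: float = 0.95,
) -> pd.DataFrame:
    """Correlate an SLR vector against a library of expression profiles.

    Per profile (joined with the SLR vector by gene_id, skipped with a logged
    reason below ``min_overlap`` shared genes): Pearson R with a two-sided
    permutation p-value, and P_o — the hypergeometric overlap p-value between
    the percentile-deregulated gene sets of the two vectors over the joined
    universe.  Sorted by P then P_o.  Invariant to linear rescaling of a
    profile and to gene order.
    """
    slr = slr.dropna()
    rng = np.random.default_rng(seed)
    rows = []
    for name in sorted(profile_library):
        profile = profile_library[name].dropna()
        shared = slr.index.intersection(profile.index)
        if len(shared) < min_overlap:
            logger.info(
                "screen: skipping %s (only %d shared genes, need %d)",
                name,
                len(shared),
                min_overlap,
            )
            continue
        a = slr.loc[shared]
        b = profile.loc[shared]
        corr = pearson_with_permutation(
            a.to_numpy(), b.to_numpy(), n_perm=n_perm, rng=rng
        )
        set_a = percentile_deregulated(a, lower, upper)
        set_b = percentile_deregulated(b, lower, upper)
        k = len(set_a.intersection(set_b))
        p_o = hypergeometric_overlap(k, len(set_a), len(set_b), len(shared))
        rows.append(
            {
                "profile": name,
                "n": len(shared),
                "r": corr["r"],
                "p": corr["p"],
                "k_overlap": k,
                "p_overlap": p_o,
            }
        )
    frame = pd.DataFrame.from_records(
        rows, columns=["profile", "n", "r", "p", "k_overlap", "p_overlap"]
    )
    if len(frame):
        frame = frame.sort_values(
            ["p", "p_overlap", "profile"], kind="stable", ignore_index=True
        )
        frame["p_bh"] = stats.false_discovery_control(frame["p"], method="bh")
    return frame
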