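"""Derived per-gene covariates and group comparisons.

Transcriptional activity is a synthesis-rate proxy: steady-state mRNA
abundance divided by mRNA half-life, median-normalized across genes.
Responsiveness to environmental change (and its twin, transcriptional
plasticity, computed on a larger compendium) is the per-gene mean squared
log2 expression ratio across a condition compendium, standardized to mean 0
and sd 1 over genes — the dynamic range of a gene's expression program.
Groups of genes are compared with the pooled-variance two-sample t-test.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "transcriptional_activity",
    "responsiveness",
    "plasticity",
    "ingest_external_measure",
    "pooled_ttest",
    "group_feature_ttest",
    "telomere_distance",
]


def transcriptional_activity(
    abundance_wt: pd.Series, half_life: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Median-normalized activity = abundance / half-life.

    Genes with a missing or non-positive half-life (or missing abundance) are
    excluded and returned with a reason.  Median normalization makes the
    result invariant to a global rescaling of abundances.

    Returns (activity, rejected) where ``rejected`` maps gene_id -> reason.
    """
    abundance_wt = abundance_wt.astype(float)
    half_life = half_life.reindex(abundance_wt.index).astype(float)
    reasons = {}
    for gene in abundance_wt.index:
        hl = half_life.loc[gene]
        if pd.isna(abundance_wt.loc[gene]):
            reasons[gene] = "missing abundance"
        elif pd.isna(hl):
            reasons[gene] = "missing half-life"
        elif hl <= 0:
            reasons[gene] = "non-positive half-life"
    rejected = pd.Series(reasons, dtype=object)
    keep = abundance_wt.index.difference(rejected.index, sort=False)
    raw = abundance_wt.loc[keep] / half_life.loc[keep]
    activity = raw / raw.median()
    activity.name = "activity"
    return activity, rejected


def responsiveness(
    compendium: pd.DataFrame, max_missing: float = 0.5
) -> pd.Series:
    """Standardized mean squared log2 ratio per gene.

    m_i = mean over conditions of ratio^2, ignoring missing values; genes with
    more than ``max_missing`` missing conditions are dropped.  The output is
    z = (m - mean(m)) / sd(m) over the retained genes, with the sample sd
    (n-1 denominator); it has mean 0 and sd 1 by construction.
    """
    if compendium.shape[1] < 2:
        raise ValueError("compendium needs at least 2 conditions")
    missing_frac = compendium.isna().mean(axis=1)
    kept = compendium.loc[missing_frac <= max_missing]
    m = (kept ** 2).mean(axis=1, skipna=True)
    sd = m.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("degenerate compendium: zero variance of per-gene means")
    z = (m - m.mean()) / sd
    z.name = "responsiveness"
    return z


def plasticity(compendium: pd.DataFrame, max_missing: float = 0.5) -> pd.Series:
    """Transcriptional plasticity: same statistic as :func:`responsiveness`,
    conventionally computed on a larger, heterogeneous profile collection."""
    z = responsiveness(compendium, max_missing=max_missing)
    return z.rename("plasticity")


def ingest_external_measure(
    table: pd.DataFrame,
    target_genes: pd.Index,
    value_column: Optional[str] = None,
) -> tuple[pd.Series, float]:
    """Join an externally supplied per-gene measure onto ``target_genes``.

    ``table`` is a two-column frame (gene_id + value) or a frame indexed by
    gene_id.  Returns (values aligned to target_genes, join coverage).  A
    coverage below 50% warns; zero coverage is an error.
    """
    if "gene_id" in table.columns:
        table = table.set_index("gene_id")
    if value_column is None:
        value_column = table.columns[0]
    values = table[value_column].reindex(target_genes)
    coverage = float(values.notna().mean())
    if coverage == 0:
        raise ValueError("external measure shares no genes with the target table")
    if coverage < 0.5:
        warnings.warn(
            f"external measure covers only {coverage:.1%} of target genes",
            stacklevel=2,
        )
    return values, coverage


def pooled_ttest(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> dict:
    """Unpaired two-sample t-test assuming equal variances (pooled), df = nA+nB-2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance: t-statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return {
        "t": float(res.statistic),
        "df": len(a) + len(b) - 2,
        "p": float(res.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "n_a": len(a),
        "n_b": len(b),
    }


def group_feature_ttest(
    values: pd.Series,
    member_set: Iterable,
    alternative: str = "two-sided",
) -> dict:
    """Pooled t-test of a per-gene feature: member set vs the rest.

    ``alternative='greater'`` tests whether members have the higher mean
    (directional p-values, e.g. for higher responsiveness of a deregulated
    gene group).
    """
    values = values.dropna()
    members = values.index.intersection(pd.Index(member_set))
    rest = values.index.difference(members)
    return pooled_ttest(
        values.loc[members].to_numpy(),
        values.loc[rest].to_numpy(),
        alternative=alternative,
    )


def telomere_distance(
    annotation: pd.DataFrame, chrom_lengths: Mapping[str, int]
) -> pd.Series:
    """Distance (bp) from the TSS to the closest chromosome end."""
    lengths = annotation["chrom"].map(chrom_lengths)
    if lengths.isna().any():
        missing = sorted(set(annotation.loc[lengths.isna(), "chrom"]))
        raise ValueError(f"no chromosome length for: {', '.join(missing)}")
    tss = annotation["tss"].astype(float)
    if ((tss < 0) | (tss > lengths)).any():
        raise ValueError("TSS outside [0, chromosome length]")
    dist = np.minimum(tss, lengths - tss)
    dist.name = "telomere_distance"
    return dist
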