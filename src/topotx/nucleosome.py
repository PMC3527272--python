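"""TSS-aligned nucleosome occupancy meta-profiles and NFR statistics.

A binned genome occupancy track is re-anchored on each gene's transcription
start site, strand-corrected so that negative offsets are biologically
upstream for every gene.  Gene groups (e.g. the 100 most up-regulated, most
down-regulated and most unaffected genes of a differential table) are then
summarized as per-offset mean profiles with t-based 95% confidence
intervals, and promoter nucleosome-free-region (NFR) occupancy — the mean
occupancy over a window just upstream of the TSS — is compared between
groups with the pooled-variance two-sample t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .features import pooled_ttest

__all__ = [
    "NucleosomeTrack",
    "TssMatrix",
    "align_to_tss",
    "meta_profile",
    "select_extreme_genes",
    "nfr_occupancy_test",
]

logger = logging.getLogger(__name__)


@dataclass
class NucleosomeTrack:
    """Contiguous binned occupancy per chromosome (0-based, half-open bins)."""

    values: dict
    bin_size: int

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}
        for c, v in self.values.items():
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite occupancy on {c}")

    def chrom_length(self, chrom: str) -> int:
        return len(self.values[chrom]) * self.bin_size

    def to_bedgraph(self, path) -> None:
        parts = []
        for chrom in sorted(self.values):
            v = self.values[chrom]
            starts = np.arange(len(v)) * self.bin_size
            parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": starts + self.bin_size,
                        "value": np.round(v, 6),
                    }
                )
            )
        pd.concat(parts, ignore_index=True).to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bedgraph(cls, path) -> "NucleosomeTrack":
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"]
        )
        sizes = (frame["end"] - frame["start"]).unique()
        if len(sizes) != 1:
            raise ValueError("bedGraph bins are not uniform")
        bin_size = int(sizes[0])
        values = {}
        for chrom, sub in frame.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy()
            if starts[0] != 0 or not np.array_equal(
                starts, np.arange(len(starts)) * bin_size
            ):
                raise ValueError(f"bedGraph bins on {chrom} are not contiguous from 0")
            values[chrom] = sub["value"].to_numpy(dtype=float)
        return cls(values=values, bin_size=bin_size)

    @classmethod
    def from_simulation(cls, track_data) -> "NucleosomeTrack":
        return cls(values=dict(track_data.values), bin_size=track_data.bin_size)


@dataclass
class TssMatrix:
    """Gene x offset occupancy, strand-corrected around the TSS.

    ``data`` columns are integer offsets (bp, bin starts relative to the TSS;
    negative = upstream); minus-strand rows are reversed so upstream is
    consistent across genes.
    """

    data: pd.DataFrame
    bin_size: int
    upstream: int
    downstream: int
    dropped: pd.Series  # gene_id -> reason

    @property
    def offsets(self) -> np.ndarray:
        return self.data.columns.to_numpy(dtype=int)


def align_to_tss(
    track: NucleosomeTrack,
    annotation: pd.DataFrame,
    upstream: int = 500,
    downstream: int = 500,
) -> TssMatrix:
    """Extract per-gene occupancy rows covering [-upstream, +downstream).

    Plus-strand genes take the bins covering [tss - upstream, tss + downstream)
    directly; minus-strand genes take the mirror window and are reversed, so
    offset -x is biologically upstream for all genes.  Genes whose window
    leaves the chromosome are dropped with a logged reason; an unknown
    chromosome is an error naming it.
    """
    bs = track.bin_size
    n_up = upstream // bs
    n_down = downstream // bs
    offsets = (np.arange(-n_up, n_down) * bs).astype(int)
    rows = {}
    dropped = {}
    for gene, ann in annotation.iterrows():
        chrom = ann["chrom"]
        if chrom not in track.values:
            raise ValueError(f"unknown chromosome {chrom!r} for gene {gene}")
        values = track.values[chrom]
        anchor = int(ann["tss"]) // bs
        if ann["strand"] == "+":
            lo, hi = anchor - n_up, anchor + n_down
            if lo < 0 or hi > len(values):
                dropped[gene] = "window outside chromosome"
                continue
            rows[gene] = values[lo:hi]
        else:
            lo, hi = anchor - n_down + 1, anchor + n_up + 1
            if lo < 0 or hi > len(values):
                dropped[gene] = "window outside chromosome"
                continue
            rows[gene] = values[lo:hi][::-1]
    for gene, reason in dropped.items():
        logger.info("align_to_tss: dropped %s (%s)", gene, reason)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=offsets)
    data.index.name = "gene_id"
    return TssMatrix(
        data=data,
        bin_size=bs,
        upstream=upstream,
        downstream=downstream,
        dropped=pd.Series(dropped, dtype=object),
    )


def meta_profile(matrix: TssMatrix, group: Iterable) -> pd.DataFrame:
    """Per-offset group mean with a t-based 95% confidence interval."""
    genes = matrix.data.index.intersection(pd.Index(group))
    n = len(genes)
    if n < 2:
        raise ValueError("group shares fewer than 2 genes with the TSS matrix")
    sub = matrix.data.loc[genes]
    mean = sub.mean(axis=0)
    se = sub.std(axis=0, ddof=1) / np.sqrt(n)
    half = stats.t.ppf(0.975, n - 1) * se
    return pd.DataFrame(
        {
            "offset": matrix.offsets,
            "mean": mean.to_numpy(),
            "ci_low": (mean - half).to_numpy(),
            "ci_high": (mean + half).to_numpy(),
            "n": n,
        }
    )


def select_extreme_genes(diff_table: pd.DataFrame, n: int = 100) -> dict:
    """The n most up-regulated, most down-regulated and most unaffected genes.

    Ranked by SLR (ties broken by gene_id); the groups are disjoint, with
    conflicts resolved in priority order down > up > unaffected.
    """
    if len(diff_table) < 3 * n:
        raise ValueError(f"need at least {3 * n} genes, got {len(diff_table)}")
    slr = diff_table["slr"].dropna()
    if slr.nunique() == 1:
        warnings.warn(
            "degenerate SLR distribution: extreme-gene selection falls back to "
            "lexicographic gene order",
            stacklevel=2,
        )
    frame = slr.rename("slr").to_frame()
    frame.index.name = None
    frame["gene_id"] = frame.index

    down = frame.sort_values(["slr", "gene_id"], kind="stable").index[:n]
    taken = set(down)
    up_order = frame.sort_values(["slr", "gene_id"], ascending=[False, True], kind="stable").index
    up = [g for g in up_order if g not in taken][:n]
    taken.update(up)
    frame["abs_slr"] = frame["slr"].abs()
    flat_order = frame.sort_values(["abs_slr", "gene_id"], kind="stable").index
    unaffected = [g for g in flat_order if g not in taken][:n]
    return {
        "most_down": list(down),
        "most_up": list(up),
        "most_unaffected": list(unaffected),
    }


def _box_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
        "mean": float(values.mean()),
        "n": int(len(values)),
    }


def nfr_occupancy_test(
    matrix: TssMatrix,
    group_a: Iterable,
    group_b: Iterable,
    nfr_window: Tuple[int, int] = (-200, 0),
) -> dict:
    """Compare mean NFR occupancy between two gene groups.

    Per gene, NFR occupancy is the mean occupancy over offsets in
    ``[nfr_window[0], nfr_window[1])``; groups are compared with the
    pooled-variance two-sided t-test, and box-plot summaries are reported.
    """
    lo, hi = nfr_window
    cols = [o for o in matrix.offsets if lo <= o < hi]
    if not cols:
        raise ValueError(f"NFR window [{lo}, {hi}) holds no offsets of the matrix")
    per_gene = matrix.data[cols].mean(axis=1)
    a = per_gene.loc[matrix.data.index.intersection(pd.Index(group_a))]
    b = per_gene.loc[matrix.data.index.intersection(pd.Index(group_b))]
    test = pooled_ttest(a.to_numpy(), b.to_numpy(), alternative="two-sided")
    return {
        "nfr_a": a,
        "nfr_b": b,
        "summary_a": _box_stats(a.to_numpy()),
        "summary_b": _box_stats(b.to_numpy()),
        "mean_difference": float(a.mean() - b.mean()),
        "t": test["t"],
        "df": test["df"],
        "p": test["p"],
    }
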