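"""External (spike-in-anchored) normalization and signal log2 ratios.

When a mutant's total mRNA per cell differs from wild-type, conventional
per-array normalization (total-intensity or quantile scaling) silently erases
the global shift.  Anchoring each array to external spike-in RNAs added per
equal cell number preserves it: the per-array scale factor is the median over
spike-in rows of (reference intensity / array intensity), with the reference a
geometric-mean pseudo-array over the spike-ins.  The median-of-ratios anchor
is robust to individual outlier spike-ins.

Downstream statistics: the relative global mRNA level (total normalized
non-spike-in signal, wild-type set to 100%), the per-gene signal log2 ratio
(SLR, mean of replicate log2 intensities mutant minus wild-type), and the
fractions of genes beyond up/down SLR cutoffs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "NormalizationResult",
    "NormalizationError",
    "fit_spikein_scale",
    "global_mrna_level",
    "compute_slr",
    "replicate_slr",
    "deregulated_fraction",
]


class NormalizationError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene x array intensity matrix with spike-in flags and array metadata.

    intensities -- DataFrame, rows indexed by unique gene_id, columns named
        ``<strain>_<replicate>``.
    spikein -- boolean Series aligned to the rows.
    arrays -- DataFrame indexed by array name with columns ``strain`` and
        ``replicate``.
    """

    intensities: pd.DataFrame
    spikein: pd.Series
    arrays: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            raise NormalizationError("duplicate gene_ids in expression matrix")
        if not self.spikein.index.equals(self.intensities.index):
            self.spikein = self.spikein.reindex(self.intensities.index)
            if self.spikein.isna().any():
                raise NormalizationError("spikein flags do not cover all rows")
        self.spikein = self.spikein.astype(bool)
        if (self.intensities.to_numpy() < 0).any():
            raise NormalizationError("intensities must be non-negative")
        if not self.spikein.any():
            raise NormalizationError("expression matrix has no spike-in rows")
        if self.spikein.all():
            raise NormalizationError("expression matrix has no non-spike-in rows")
        pairs = list(zip(self.arrays["strain"], self.arrays["replicate"]))
        if len(set(pairs)) != len(pairs):
            raise NormalizationError("duplicate (strain, replicate) arrays")

    @property
    def gene_ids(self) -> pd.Index:
        return self.intensities.index

    def strains(self) -> list:
        return list(dict.fromkeys(self.arrays["strain"]))

    def arrays_for(self, strain: str) -> list:
        cols = self.arrays.index[self.arrays["strain"] == strain].tolist()
        if not cols:
            raise NormalizationError(f"strain {strain!r} not present in matrix")
        return cols

    # -- TSV dialect: gene_id, spikein, then one column per array ----------
    def to_tsv(self, path) -> None:
        out = self.intensities.copy()
        out.insert(0, "spikein", self.spikein.astype(bool))
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        spikein = frame.pop("spikein").astype(bool)
        meta = pd.DataFrame(
            {
                "strain": [c.rsplit("_", 1)[0] for c in frame.columns],
                "replicate": [int(c.rsplit("_", 1)[1]) for c in frame.columns],
            },
            index=pd.Index(frame.columns, name="array"),
        )
        return cls(intensities=frame.astype(float), spikein=spikein, arrays=meta)


@dataclass
class NormalizationResult:
    """Per-array scale factors, the scaled matrix, and the anchor description."""

    scale_factors: pd.Series
    normalized: ExpressionMatrix
    reference: str


def fit_spikein_scale(matrix: ExpressionMatrix) -> NormalizationResult:
    """Fit per-array scale factors against the spike-in pseudo-array.

    factor_a = median over spike-in rows i of (ref_i / intensity_ia), with
    ref_i the geometric mean of row i across arrays.  Normalized intensities
    are raw * factor.  Scale equivariance: multiplying all rows of one of K
    arrays by c > 0 rescales every normalized entry by the common reference
    shift c**(1/K) (that array's factor absorbs the rest of c), so every
    derived ratio statistic — scale-factor ratios, global mRNA level, SLR,
    deregulated fractions — is exactly invariant.
    """
    spikes = matrix.intensities.loc[matrix.spikein]
    zero_arrays = spikes.columns[(spikes <= 0).any(axis=0)]
    if len(zero_arrays):
        raise NormalizationError(
            f"non-positive spike-in intensity on array(s): {', '.join(zero_arrays)}"
        )
    log_spikes = np.log(spikes.to_numpy())
    reference = np.exp(log_spikes.mean(axis=1))  # per-row geometric mean
    ratios = reference[:, None] / spikes.to_numpy()
    factors = pd.Series(np.median(ratios, axis=0), index=spikes.columns, name="scale_factor")
    normalized = ExpressionMatrix(
        intensities=matrix.intensities * factors,
        spikein=matrix.spikein.copy(),
        arrays=matrix.arrays.copy(),
    )
    return NormalizationResult(
        scale_factors=factors,
        normalized=normalized,
        reference="median-of-ratios vs geometric-mean spike-in pseudo-array",
    )


def _strain_block(result: NormalizationResult, strain: str) -> pd.DataFrame:
    cols = result.normalized.arrays_for(strain)
    return result.normalized.intensities.loc[~result.normalized.spikein, cols]


def global_mrna_level(
    result: NormalizationResult,
    mutant_strain: str,
    wt_strain: str,
    floor: float = 1.0,
) -> dict:
    """Total-signal mRNA level of the mutant relative to wild-type (= 100%).

    Restricted to genes detectable in wild-type (mean normalized intensity >=
    ``floor``).  Per-replicate percentages (each mutant array against the
    wild-type replicate-mean total) are retained for an SD bar.
    """
    wt = _strain_block(result, wt_strain)
    mut = _strain_block(result, mutant_strain)
    detectable = wt.mean(axis=1) >= floor
    wt_total = wt.loc[detectable].sum(axis=0)
    mut_total = mut.loc[detectable].sum(axis=0)
    wt_mean_total = float(wt_total.mean())
    per_replicate = 100.0 * mut_total / wt_mean_total
    percent = 100.0 * float(mut_total.mean()) / wt_mean_total
    sd = float(per_replicate.std(ddof=1)) if len(per_replicate) > 1 else float("nan")
    return {
        "percent": percent,
        "per_replicate": per_replicate,
        "sd": sd,
        "n_genes": int(detectable.sum()),
    }


def _log2_floored(block: pd.DataFrame, floor: float) -> pd.DataFrame:
    return np.log2(block.clip(lower=floor))


def compute_slr(
    result: NormalizationResult,
    mutant_strain: str,
    wt_strain: str,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Per-gene signal log2 ratio (SLR) mutant vs wild-type.

    slr = mean over mutant replicates of log2(max(I, floor)) minus the same
    mean over wild-type replicates; se = standard error of the difference of
    the replicate log2 means under independence.  Returns a DataFrame indexed
    by gene_id with columns slr, se, mean_wt_intensity and a ``detectable``
    flag (mean wild-type intensity >= floor).
    """
    if floor <= 0:
        raise NormalizationError("floor must be > 0")
    wt = _strain_block(result, wt_strain)
    mut = _strain_block(result, mutant_strain)
    lw = _log2_floored(wt, floor)
    lm = _log2_floored(mut, floor)
    n_w, n_m = lw.shape[1], lm.shape[1]
    var_w = lw.var(axis=1, ddof=1) if n_w > 1 else pd.Series(np.nan, index=lw.index)
    var_m = lm.var(axis=1, ddof=1) if n_m > 1 else pd.Series(np.nan, index=lm.index)
    table = pd.DataFrame(
        {
            "slr": lm.mean(axis=1) - lw.mean(axis=1),
            "se": np.sqrt(var_m / n_m + var_w / n_w),
            "mean_wt_intensity": wt.mean(axis=1),
        }
    )
    table["detectable"] = table["mean_wt_intensity"] >= floor
    return table


def replicate_slr(
    result: NormalizationResult,
    mutant_strain: str,
    wt_strain: str,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Per-gene SLR of each mutant replicate against the wild-type log2 mean."""
    wt = _log2_floored(_strain_block(result, wt_strain), floor)
    mut = _log2_floored(_strain_block(result, mutant_strain), floor)
    return mut.sub(wt.mean(axis=1), axis=0)


def deregulated_fraction(
    slr: pd.Series,
    up_cutoff: float = 1.0,
    down_cutoff: float = -1.0,
    per_replicate: Optional[pd.DataFrame] = None,
) -> dict:
    """Fractions of genes at or beyond the up/down SLR cutoffs.

    ``per_replicate`` (genes x replicate SLR columns, e.g. from
    :func:`replicate_slr`) yields a standard error of the fraction across
    replicates.
    """
    if not up_cutoff > 0 > down_cutoff:
        raise NormalizationError("need up_cutoff > 0 > down_cutoff")
    slr = slr.dropna()
    n_total = len(slr)
    if n_total == 0:
        raise NormalizationError("empty SLR table")
    n_up = int((slr >= up_cutoff).sum())
    n_down = int((slr <= down_cutoff).sum())
    out = {
        "frac_up": n_up / n_total,
        "frac_down": n_down / n_total,
        "n_up": n_up,
        "n_down": n_down,
        "n_total": n_total,
    }
    if per_replicate is not None and per_replicate.shape[1] > 1:
        reps = per_replicate.dropna()
        k = reps.shape[1]
        fu = (reps >= up_cutoff).mean(axis=0)
        fd = (reps <= down_cutoff).mean(axis=0)
        out["se_up"] = float(fu.std(ddof=1) / np.sqrt(k))
        out["se_down"] = float(fd.std(ddof=1) / np.sqrt(k))
    return out
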