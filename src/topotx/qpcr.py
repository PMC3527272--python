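"""RT-qPCR relative quantities and ChIP-qPCR fold enrichment.

Quantities are recovered from averaged triplicate Ct values under the
exponential amplification model quantity = efficiency**(-Ct) (perfect
efficiency 2.0 by default: one cycle = one doubling).  ChIP fold enrichment
at a target region is the IP/background quantity ratio, normalized to the
same ratio at a control locus, which cancels global amplification offsets.
Time courses are normalized to a reference point (t = 0 set to 1, or a
reference series' latest point set to 100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "relative_quantity",
    "chip_fold_enrichment",
    "chip_timecourse",
    "expression_timecourse",
    "timecourse_normalize",
]


@dataclass(frozen=True)
class CtRecord:
    """Averaged triplicate qPCR measurement for one (locus, timepoint, channel)."""

    locus: str
    timepoint: float
    channel: str  # IP | background | input_cDNA
    region: str  # target | control
    ct_values: tuple

    def __post_init__(self) -> None:
        if len(self.ct_values) == 0:
            raise ValueError("empty Ct triplicate")
        if not np.isfinite(self.ct_values).all():
            raise ValueError("non-finite Ct value")


def relative_quantity(ct: CtRecord, efficiency: float = 2.0) -> dict:
    """quantity = efficiency**(-mean Ct), with the replicate sd propagated to
    a log2-scale standard error."""
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    values = np.asarray(ct.ct_values, dtype=float)
    mean_ct = values.mean()
    quantity = efficiency ** (-mean_ct)
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    log2_se = np.log2(efficiency) * sd / np.sqrt(len(values))
    return {"quantity": float(quantity), "log2_se": float(log2_se)}


def chip_fold_enrichment(
    ip: CtRecord,
    background: CtRecord,
    ip_ctrl: CtRecord,
    background_ctrl: CtRecord,
    efficiency: float = 2.0,
) -> float:
    """Control-locus-normalized ChIP fold enrichment.

    (IP/background at the target region) / (IP/background at the control
    region).  All four records must share a timepoint.  Adding a constant to
    every Ct (a global amplification offset) leaves the result unchanged.
    """
    timepoints = {r.timepoint for r in (ip, background, ip_ctrl, background_ctrl)}
    if len(timepoints) != 1:
        raise ValueError("all four records must share the same timepoint")
    q = {rec: relative_quantity(rec, efficiency)["quantity"]
         for rec in (ip, background, ip_ctrl, background_ctrl)}
    if q[background] == 0 or q[background_ctrl] == 0 or q[ip_ctrl] == 0:
        raise ValueError("zero denominator quantity")
    fold_target = q[ip] / q[background]
    fold_ctrl = q[ip_ctrl] / q[background_ctrl]
    return fold_target / fold_ctrl


def _records_from_rows(rows: pd.DataFrame) -> dict:
    ct_cols = [c for c in rows.columns if c.startswith("ct_")]
    out = {}
    for _, row in rows.iterrows():
        key = (row["channel"], row["region"])
        out[key] = CtRecord(
            locus=row["locus"],
            timepoint=float(row["timepoint_min"]),
            channel=row["channel"],
            region=row["region"],
            ct_values=tuple(float(row[c]) for c in ct_cols),
        )
    return out


def chip_timecourse(
    chip_table: pd.DataFrame,
    locus: str,
    strain: Optional[str] = None,
    efficiency: float = 2.0,
) -> pd.Series:
    """Normalized fold enrichment per timepoint from a tidy ChIP Ct table.

    Expects columns locus, timepoint_min, channel (IP/background), region
    (target/control), ct_1..ct_3 and optionally strain.
    """
    sub = chip_table[chip_table["locus"] == locus]
    if strain is not None and "strain" in sub.columns:
        sub = sub[sub["strain"] == strain]
    if sub.empty:
        raise ValueError(f"no ChIP rows for locus {locus!r}")
    folds = {}
    for t, rows in sub.groupby("timepoint_min"):
        rec = _records_from_rows(rows)
        folds[float(t)] = chip_fold_enrichment(
            rec[("IP", "target")],
            rec[("background", "target")],
            rec[("IP", "control")],
            rec[("background", "control")],
            efficiency=efficiency,
        )
    return pd.Series(folds, name=f"fold_{locus}").sort_index()


def expression_timecourse(
    expression_table: pd.DataFrame,
    locus: str,
    strain: Optional[str] = None,
    efficiency: float = 2.0,
) -> pd.Series:
    """Relative mRNA quantity per timepoint from a tidy expression Ct table."""
    sub = expression_table[expression_table["locus"] == locus]
    if strain is not None and "strain" in sub.columns:
        sub = sub[sub["strain"] == strain]
    if sub.empty:
        raise ValueError(f"no expression rows for locus {locus!r}")
    ct_cols = [c for c in sub.columns if c.startswith("ct_")]
    quantities = {}
    for t, rows in sub.groupby("timepoint_min"):
        row = rows.iloc[0]
        rec = CtRecord(
            locus=locus,
            timepoint=float(t),
            channel=str(row["channel"]),
            region=str(row["region"]),
            ct_values=tuple(float(row[c]) for c in ct_cols),
        )
        quantities[float(t)] = relative_quantity(rec, efficiency)["quantity"]
    return pd.Series(quantities, name=f"quantity_{locus}").sort_index()


def timecourse_normalize(
    series: pd.Series,
    mode: str = "t0_to_1",
    reference: Optional[object] = None,
) -> dict:
    """Normalize a time-course series to a reference point.

    Modes: ``t0_to_1`` divides by the earliest timepoint's value (set to 1);
    ``wt_max_100`` divides by the latest value of an external ``reference``
    series and scales to percent (reference maximum set to 100%);
    ``named_reference`` divides by an explicit scalar ``reference`` (scaled to
    percent when the scalar is passed as ``(value, 'percent')``).

    Also reports the raw fold increase last/first.
    """
    series = series.sort_index()
    first = float(series.iloc[0])
    last = float(series.iloc[-1])
    if mode == "t0_to_1":
        ref, scale = first, 1.0
    elif mode == "wt_max_100":
        if not isinstance(reference, pd.Series):
            raise ValueError("wt_max_100 requires a reference series")
        ref, scale = float(reference.sort_index().iloc[-1]), 100.0
    elif mode == "named_reference":
        if reference is None:
            raise ValueError("named_reference requires a reference value")
        if isinstance(reference, tuple):
            ref, scale = float(reference[0]), (100.0 if reference[1] == "percent" else 1.0)
        else:
            ref, scale = float(reference), 1.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if ref == 0:
        raise ValueError("zero reference value")
    normalized = series / ref * scale
    fold_increase = last / first if first != 0 else float("inf")
    return {"normalized": normalized, "fold_increase": fold_increase}
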