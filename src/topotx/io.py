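"""Plain-text readers/writers for the pipeline's tabular dialects."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "write_annotation",
    "read_annotation",
    "write_bed6",
    "write_config",
    "read_config",
    "sha256_of",
    "write_json",
]


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in ("tata", "saga"):
        if col in frame.columns:
            frame[col] = frame[col].astype(bool)
    return frame


def write_bed6(annotation: pd.DataFrame, path) -> None:
    """One BED6 interval per gene TSS (start = TSS for +, end-1 = TSS for -)."""
    with open(path, "w") as fh:
        for gene, row in annotation.iterrows():
            tss = int(row["tss"])
            fh.write(
                f"{row['chrom']}\t{tss}\t{tss + 1}\t{gene}\t0\t{row['strand']}\n"
            )


def write_config(config_dict: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True, default_flow_style=False)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
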