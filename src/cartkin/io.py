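"""Plain-text serialization of traces, datasets and result tables.

Traces travel as one tidy CSV (product_id, condition, et_ratio,
replicate, time_h, ci) with a JSON sidecar for per-product metadata and
outcomes; both directions are bit-stable round trips.  Result tables are
CSVs whose first line is a comment embedding the run's seed and a config
hash, so any output can be traced back to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import ImpedanceTrace, ProductDataset
from .cohort import OutcomeRecord

__all__ = [
    "traces_to_frame",
    "frame_to_datasets",
    "save_cohort",
    "load_cohort",
    "write_table",
    "read_table",
    "config_hash",
]

TRACE_COLUMNS = ("product_id", "condition", "et_ratio", "replicate", "time_h", "ci")


def traces_to_frame(datasets: Sequence[ProductDataset]) -> pd.DataFrame:
    """All traces of a cohort as one tidy frame."""
    chunks = []
    for ds in datasets:
        for tr in ds.traces:
            chunks.append(pd.DataFrame({
                "product_id": ds.product_id,
                "condition": tr.condition,
                "et_ratio": np.nan if tr.et_ratio is None else tr.et_ratio,
                "replicate": tr.replicate,
                "time_h": tr.times,
                "ci": tr.ci,
            }))
    return pd.concat(chunks, ignore_index=True)[list(TRACE_COLUMNS)]


def _metadata_entry(ds: ProductDataset) -> dict:
    return {
        "transduction_efficiency": ds.transduction_efficiency,
        "cd4_cd8_ratio": ds.cd4_cd8_ratio,
        "disease": ds.disease,
        "manufacturing_days": ds.manufacturing_days,
        "outcomes": None if ds.outcomes is None else ds.outcomes.to_dict(),
    }


def frame_to_datasets(frame: pd.DataFrame, metadata: dict) -> list:
    """Rebuild ProductDataset objects from the tidy frame + metadata map."""
    datasets = []
    for product_id, group in frame.groupby("product_id", sort=True):
        meta = metadata[str(product_id)]
        traces = []
        keys = group[["condition", "et_ratio", "replicate"]].drop_duplicates()
        for condition, et_ratio, replicate in keys.itertuples(index=False):
            sub = group[
                (group["condition"] == condition)
                & (group["replicate"] == replicate)
                & (group["et_ratio"].isna() if pd.isna(et_ratio)
                   else group["et_ratio"] == et_ratio)
            ].sort_values("time_h")
            traces.append(ImpedanceTrace(
                times=sub["time_h"].to_numpy(),
                ci=sub["ci"].to_numpy(),
                condition=condition,
                et_ratio=None if pd.isna(et_ratio) else float(et_ratio),
                replicate=int(replicate),
                product_id=str(product_id),
            ))
        outcomes = meta.get("outcomes")
        datasets.append(ProductDataset(
            traces=traces,
            transduction_efficiency=meta["transduction_efficiency"],
            cd4_cd8_ratio=meta.get("cd4_cd8_ratio"),
            disease=meta.get("disease"),
            manufacturing_days=meta.get("manufacturing_days"),
            outcomes=None if outcomes is None else OutcomeRecord(**outcomes),
            product_id=str(product_id),
        ))
    return datasets


def save_cohort(datasets: Sequence[ProductDataset], out_dir,
                meta: dict | None = None) -> None:
    """Write traces.csv + metadata.json for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(traces_to_frame(datasets), out / "traces.csv", meta or {})
    payload = {
        "products": {ds.product_id: _metadata_entry(ds) for ds in datasets},
        "run": meta or {},
    }
    (out / "metadata.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_cohort(in_dir) -> list:
    src = Path(in_dir)
    frame = read_table(src / "traces.csv")
    payload = json.loads((src / "metadata.json").read_text())
    return frame_to_datasets(frame, payload["products"])


def config_hash(config) -> str:
    """Stable short hash of any JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path, meta: dict | None = None) -> None:
    """CSV with a leading comment line carrying seed and config hash."""
    meta = meta or {}
    header = "# cartkin " + " ".join(
        f"{k}={v}" for k, v in sorted(meta.items())
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header.rstrip() + "\n")
        frame.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
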