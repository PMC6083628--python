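"""Reading and writing study datasets (CSV + YAML parameter sidecar)."""
from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml


def write_dataset(dataset: pd.DataFrame, path, config=None) -> None:
    """Write a long-format study dataset as CSV.

    When a configuration object is given, its parameters are written to a
    YAML sidecar ``<path>.params.yaml`` for provenance.
    """
    path = Path(path)
    out = dataset.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    if config is not None:
        params = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
        with open(path.with_suffix(path.suffix + ".params.yaml"), "w") as fh:
            yaml.safe_dump(_plain(params), fh, sort_keys=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a study dataset CSV, restoring dates and keeping raw series as strings."""
    df = pd.read_csv(path, dtype={"vo2_series": "string", "vco2_series": "string"})
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    for col in ("vo2_series", "vco2_series"):
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), other=float("nan"))
    return df


def _plain(obj):
    """Recursively convert tuples/numpy scalars so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
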