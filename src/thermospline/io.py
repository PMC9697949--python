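"""Plain-text artifact formats: sweep CSVs, manifests, feature tables, models.

One sweep per CSV file (columns ``heater_v,out_v``); a sidecar manifest CSV
ties files to their concentrations, replicate ids and seeds; the feature
table carries the 8 spline coefficients, the fit residual and the 6 final
knots per sweep; trained networks round-trip through JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ann_quant import MLPModel
from .sensor_model import AnalyteMix, SensorSweep
from .spline_compress import N_FEATURES

__all__ = [
    "write_sweep",
    "read_sweep",
    "write_manifest",
    "read_manifest",
    "feature_columns",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
]

MANIFEST_COLUMNS = ["file", "c_ethanol_pct", "c_acetone_pct", "replicate", "seed"]


def write_sweep(sweep: SensorSweep, path: str | Path) -> None:
    pd.DataFrame({"heater_v": sweep.heater_v, "out_v": sweep.out_v}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_sweep(
    path: str | Path, mix: AnalyteMix | None = None, replicate: int = 0
) -> SensorSweep:
    df = pd.read_csv(path)
    missing = {"heater_v", "out_v"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if mix is None:
        mix = AnalyteMix(0.0, 0.0)
    return SensorSweep(
        heater_v=df["heater_v"].to_numpy(),
        out_v=df["out_v"].to_numpy(),
        mix=mix,
        replicate=replicate,
    )


def write_manifest(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def feature_columns() -> list[str]:
    return [f"f{i}" for i in range(1, N_FEATURES + 1)]


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(feature_columns()) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: feature table missing columns {sorted(missing)}")
    return df


def save_model(model: MLPModel, path: str | Path, extra: dict | None = None) -> None:
    import json

    payload = json.loads(model.to_json())
    if extra:
        payload["metadata"] = extra
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> tuple[MLPModel, dict]:
    import json

    text = Path(path).read_text()
    payload = json.loads(text)
    meta = payload.pop("metadata", {})
    model = MLPModel.from_json(json.dumps(payload))
    return model, meta
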