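"""Plain-text serialization of curves and parameters.

Single curves travel as two-column CSV (``time_min,value``); parameter
objects as JSON objects keyed by field name.  Batched datasets use the
HDF5 containers in :mod:`aifcorr.data_factory`.
"""

from __future__ import annotations

import json

import pandas as pd

from .grid import ConcentrationCurve, TimeGrid
from .aif_population import AIFParams
from .tissue_kinetics import PKParams

__all__ = [
    "read_curve_csv",
    "write_curve_csv",
    "params_to_json",
    "params_from_json",
]


def read_curve_csv(path) -> ConcentrationCurve:
    """Read a curve from CSV with columns ``time_min`` and ``value``."""
    df = pd.read_csv(path)
    missing = {"time_min", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    grid = TimeGrid.from_times(df["time_min"].to_numpy())
    return ConcentrationCurve(grid, df["value"].to_numpy())


def write_curve_csv(path, curve: ConcentrationCurve) -> None:
    pd.DataFrame({"time_min": curve.grid.values, "value": curve.values}).to_csv(
        path, index=False
    )


def params_to_json(params: AIFParams | PKParams) -> str:
    return json.dumps(params.to_dict(), indent=1)


def params_from_json(text: str, kind: type) -> AIFParams | PKParams:
    data = json.loads(text)
    if kind is AIFParams:
        return AIFParams.from_dict(data)
    if kind is PKParams:
        return PKParams(**data)
    raise TypeError(f"unsupported parameter type {kind!r}")
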