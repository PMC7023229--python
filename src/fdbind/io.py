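"""Delimited-text matrix IO and model persistence.

Matrices travel as UTF-8 TSV (default) or CSV with a header row of
column IDs and a first column of row IDs, dot decimal separator.  Models
persist to a single JSON document; Python's shortest-repr float
serialization makes the round trip bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cpann import CPANNModel
from .errors import InputError
from .som import ColumnScaler, GridSpec, SOMModel, TrainConfig

__all__ = [
    "read_matrix",
    "write_matrix",
    "save_model",
    "load_model",
]

_SEPS = {".tsv": "\t", ".tab": "\t", ".txt": "\t", ".csv": ","}


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise InputError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return _SEPS.get(path.suffix.lower(), "\t")


def read_matrix(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a numeric matrix with row IDs and a header of column IDs."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such file: {p}")
    sep = _sep_for(p, dialect)
    try:
        df = pd.read_csv(p, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise InputError(f"{p}: malformed table ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{p}: duplicated row ID {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise InputError(f"{p}: duplicated column ID {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            cell = df.loc[row, col]
            hint = ""
            if isinstance(cell, str) and "," in cell:
                hint = " (comma decimal separator? use dot-decimal)"
            raise InputError(
                f"{p}: non-numeric cell {cell!r} at row {row!r}, column {col!r}{hint}"
            )
        if coerced.isna().any():
            row = df.index[coerced.isna()][0]
            raise InputError(f"{p}: missing value at row {row!r}, column {col!r}")
        df[col] = coerced
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, dialect: str | None = None) -> Path:
    """Write a matrix in the package dialect (6 significant digits)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(p, sep=_sep_for(p, dialect), float_format="%.6g")
    return p


def _scaler_to_dict(scaler: ColumnScaler | None) -> dict | None:
    if scaler is None:
        return None
    return {
        "columns": [str(c) for c in scaler.mins.index],
        "mins": scaler.mins.tolist(),
        "maxs": scaler.maxs.tolist(),
        "constant": scaler.constant.astype(bool).tolist(),
    }


def _scaler_from_dict(d: dict | None) -> ColumnScaler | None:
    if d is None:
        return None
    idx = pd.Index(d["columns"])
    return ColumnScaler(
        mins=pd.Series(d["mins"], index=idx),
        maxs=pd.Series(d["maxs"], index=idx),
        constant=pd.Series(d["constant"], index=idx),
    )


def _som_to_dict(model: SOMModel) -> dict:
    cfg = model.train_config
    return {
        "grid": {"nx": model.grid.nx, "ny": model.grid.ny},
        "train_config": {
            "epochs": cfg.epochs,
            "eta_start": cfg.eta_start,
            "eta_end": cfg.eta_end,
            "radius_start": cfg.radius_start,
            "radius_end": cfg.radius_end,
            "seed": cfg.seed,
        },
        "feature_names": model.feature_names,
        "weights": model.weights.tolist(),
        "trained": model.trained,
    }


def _som_from_dict(d: dict) -> SOMModel:
    return SOMModel(
        grid=GridSpec(**d["grid"]),
        weights=np.array(d["weights"], dtype=float),
        feature_names=list(d["feature_names"]),
        train_config=TrainConfig(**d["train_config"]),
        trained=bool(d["trained"]),
    )


def save_model(model: SOMModel | CPANNModel, path: str | Path) -> Path:
    """Persist a SOM or CPANN model as a JSON document."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(model, CPANNModel):
        doc = {
            "kind": "cpann",
            "som": _som_to_dict(model.som),
            "output_weights": model.output_weights.tolist(),
            "target_names": model.target_names,
            "target_scaler": _scaler_to_dict(model.target_scaler),
        }
    elif isinstance(model, SOMModel):
        doc = {"kind": "som", "som": _som_to_dict(model)}
    else:
        raise InputError(f"cannot persist object of type {type(model).__name__}")
    p.write_text(json.dumps(doc))
    return p


def load_model(path: str | Path) -> SOMModel | CPANNModel:
    p = Path(path)
    if not p.exists():
        raise InputError(f"no such model file: {p}")
    doc = json.loads(p.read_text())
    kind = doc.get("kind")
    if kind == "som":
        return _som_from_dict(doc["som"])
    if kind == "cpann":
        return CPANNModel(
            som=_som_from_dict(doc["som"]),
            output_weights=np.array(doc["output_weights"], dtype=float),
            target_names=list(doc["target_names"]),
            target_scaler=_scaler_from_dict(doc.get("target_scaler")),
        )
    raise InputError(f"{p}: unknown model kind {kind!r}")
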