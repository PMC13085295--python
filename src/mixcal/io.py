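"""Readers/writers for the canonical CSV formats and run configuration.

Canonical spectra CSV: first column ``wavelength_nm``, one subsequent
column per sample (header = sample id), values in AU.  The transposed
dialect (one row per sample, wavelength headers) is accepted via the
``dialect`` flag.  Design CSV: columns ``mixture_id, role, BUP, DEX, CBA,
DMA`` in ug/mL.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import SpectraMatrix, WavelengthGrid
from .design import DesignTable

__all__ = [
    "read_spectra", "write_spectra", "read_design", "write_design",
    "save_model", "load_model_record", "RunConfig",
]


def read_spectra(path, dialect: str = "wavelength_rows") -> SpectraMatrix:
    """Read a spectra CSV in either dialect into a :class:`SpectraMatrix`."""
    df = pd.read_csv(path)
    if df.isna().any().any():
        bad = int(np.flatnonzero(df.isna().any(axis=1))[0]) + 2  # header + 1-based
        raise ValueError(f"ragged/missing values near row {bad} of {path}")
    if dialect == "wavelength_rows":
        if df.columns[0] != "wavelength_nm":
            raise ValueError("first column must be 'wavelength_nm'")
        w = df["wavelength_nm"].to_numpy(dtype=float)
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        grid = WavelengthGrid.from_wavelengths(w)
        ids = [str(c) for c in df.columns[1:]]
        A = df.iloc[:, 1:].to_numpy(dtype=float).T
        return SpectraMatrix(ids, grid, A)
    if dialect == "sample_rows":
        ids = [str(s) for s in df.iloc[:, 0]]
        w = np.array([float(c) for c in df.columns[1:]])
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        grid = WavelengthGrid.from_wavelengths(w)
        return SpectraMatrix(ids, grid, df.iloc[:, 1:].to_numpy(dtype=float))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectra(spectra: SpectraMatrix, path, dialect: str = "wavelength_rows") -> None:
    """Write a spectra CSV (lossless round-trip at 12 significant digits)."""
    path = Path(path)
    if dialect == "wavelength_rows":
        df = pd.DataFrame({"wavelength_nm": spectra.wavelengths})
        for i, sid in enumerate(spectra.sample_ids):
            df[sid] = spectra.absorbance[i]
    elif dialect == "sample_rows":
        df = pd.DataFrame(spectra.absorbance,
                          columns=[repr(float(w)) for w in spectra.wavelengths])
        df.insert(0, "sample_id", spectra.sample_ids)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, index=False, float_format="%.12g")


def read_design(path, check_levels: bool = True) -> DesignTable:
    return DesignTable.from_frame(pd.read_csv(path), check_levels=check_levels)


def write_design(design: DesignTable, path) -> None:
    design.to_frame().to_csv(path, index=False, float_format="%.2f")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_model(model, path) -> None:
    """Serialize a fitted calibration model (PCR/PLS/ANN) to JSON text."""
    from .ann import AnnModel
    from .models import CalibrationModel

    if isinstance(model, CalibrationModel):
        rec = {
            "kind": model.kind,
            "n_lv": model.n_lv,
            "coef": model.coef,
            "x_mean": model.estimator.x_mean_,
            "y_mean": model.estimator.y_mean_,
            "training_meta": model.training_meta,
        }
    elif isinstance(model, AnnModel):
        rec = {
            "kind": "ANN",
            "layers": [model.n_input, model.n_hidden, model.n_output],
            "transfer": list(model.transfer),
            "W1": model.W1, "b1": model.b1, "W2": model.W2, "b2": model.b2,
            "x_mean": model.x_mean, "y_mean": model.y_mean, "seed": model.seed,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(_jsonify(rec), indent=1))


def load_model_record(path) -> dict:
    """Load a serialized model record (arrays back as numpy)."""
    rec = json.loads(Path(path).read_text())
    for key in ("coef", "x_mean", "y_mean", "W1", "b1", "W2", "b2"):
        if key in rec and rec[key] is not None:
            rec[key] = np.asarray(rec[key], dtype=float)
    return rec


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (one master seed reproduces all)."""

    window_lo_nm: float = 224.0
    window_hi_nm: float = 330.0
    models: tuple[str, ...] = ("PCR", "PLS", "MCR-ALS", "ANN")
    n_lv: dict = field(default_factory=lambda: {"PCR": 6, "PLS": 5})
    mcr_nonneg: bool = True
    mcr_unimodal: bool = False
    mcr_conv_threshold_percent: float = 0.1
    mcr_max_iter: int = 50
    ann_hidden: int = 10
    ann_split: tuple[float, float, float] = (0.7, 0.15, 0.15)
    ann_patience: int = 6
    ann_max_epochs: int = 1000
    noise_sd_frac: float = 0.005
    seed: int = 1
    output_dir: str = "mixcal_run"

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the master seed (stable hash of the
        stage name folded into the seed, kept below 2**31)."""
        h = sum((i + 1) * ord(c) for i, c in enumerate(stage))
        return (self.seed * 1000003 + h) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "models" in data:
            data["models"] = tuple(data["models"])
        if "ann_split" in data:
            data["ann_split"] = tuple(data["ann_split"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        rec = _jsonify(dataclasses.asdict(self))
        rec["models"] = list(rec["models"])
        rec["ann_split"] = list(rec["ann_split"])
        Path(path).write_text(yaml.safe_dump(rec, sort_keys=False))
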