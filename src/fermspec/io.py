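"""Readers and writers for the package's plain-text formats.

Spectra travel as wide delimiter-separated tables: header row =
``sample_id`` followed by wavelengths in nm, one row per sample. Reference
concentrations are ``sample_id`` plus one g/L column per analyte.
Comma and tab delimiters are auto-detected. All numeric output is written
with 17 significant digits so values round-trip bit-exactly.

Fitted models serialize to a JSON artifact embedding every matrix, the
centering vectors, the package version, and a hash of the preprocessing
configuration, so a reloaded model reproduces predictions bit-for-bit and a
model can be matched to the pipeline it was calibrated with.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import LinearModel, PLSRModel
from .datasets import (
    CalibrationDataset,
    ConcentrationTable,
    FermspecError,
    SpectraSet,
)
from .preprocess import PreprocessPipeline
from .synth import FermentationTrajectory

_FLOAT_FMT = "%.17g"


class IOError_(FermspecError, ValueError):
    """Malformed or inconsistent on-disk artifact."""


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


# --------------------------------------------------------------------------
# Spectra tables
# --------------------------------------------------------------------------

def write_spectra_table(spectra: SpectraSet, path: str | Path,
                        sep: str = ",") -> None:
    spectra.to_frame().to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def read_spectra_table(path: str | Path) -> SpectraSet:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such file: {path}")
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0,
                     float_precision="round_trip")
    try:
        wavelengths = df.columns.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise IOError_(f"{path}: non-numeric wavelength header: {exc}") from None
    if not np.all(np.diff(wavelengths) > 0):
        raise IOError_(f"{path}: non-monotone wavelengths in header")
    ids = df.index.astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise IOError_(f"{path}: duplicate sample ids {dupes}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        row, col = map(int, np.argwhere(np.isnan(values))[0])
        raise IOError_(
            f"{path}: missing/unparsable value at sample {ids[row]!r}, "
            f"wavelength {wavelengths[col]} nm"
        )
    return SpectraSet(wavelengths, values, ids)


# --------------------------------------------------------------------------
# Concentration tables
# --------------------------------------------------------------------------

def write_concentration_table(conc: ConcentrationTable, path: str | Path,
                              sep: str = ",") -> None:
    conc.to_frame().to_csv(path, sep=sep, float_format=_FLOAT_FMT)


def read_concentration_table(path: str | Path) -> ConcentrationTable:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such file: {path}")
    df = pd.read_csv(path, sep=_detect_sep(path), index_col=0,
                     float_precision="round_trip")
    ids = df.index.astype(str).tolist()
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        row, col = map(int, np.argwhere(values < 0)[0])
        raise IOError_(
            f"{path}: negative concentration for sample {ids[row]!r}, "
            f"analyte {df.columns[col]!r}"
        )
    return ConcentrationTable(list(df.columns.astype(str)), values, ids)


def join_dataset(spectra: SpectraSet,
                 conc: ConcentrationTable) -> CalibrationDataset:
    """Align a spectra table with a concentration table by sample id."""
    spec_ids, conc_ids = set(spectra.sample_ids), set(conc.sample_ids)
    unmatched = spec_ids ^ conc_ids
    if unmatched:
        raise IOError_(f"unmatched sample ids between spectra and "
                       f"concentrations: {sorted(unmatched)}")
    order = {s: i for i, s in enumerate(conc.sample_ids)}
    conc_aligned = conc.take([order[s] for s in spectra.sample_ids])
    return CalibrationDataset(spectra, conc_aligned)


def write_trajectory(traj: FermentationTrajectory, path: str | Path,
                     sep: str = ",") -> None:
    df = traj.to_frame()
    feed = np.zeros(len(df))
    for ev in traj.feed_events:
        feed[np.argmin(np.abs(traj.times - ev.time))] += ev.amount
    df["feed_g_per_L"] = feed
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


# --------------------------------------------------------------------------
# Model serialization
# --------------------------------------------------------------------------

def pipeline_hash(pipeline: PreprocessPipeline | None) -> str:
    cfg = [] if pipeline is None else pipeline.to_config()
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


_ARRAY_FIELDS = {
    "plsr": ("x_scores", "x_loadings", "y_scores", "y_loadings", "x_weights",
             "x_residuals", "y_residuals", "coefficients", "x_mean", "y_mean"),
    "pcr": ("coefficients", "x_mean", "y_mean"),
    "mlr": ("coefficients", "x_mean", "y_mean"),
}


def save_model(model: PLSRModel | LinearModel, path: str | Path,
               pipeline: PreprocessPipeline | None = None,
               extra_meta: dict[str, Any] | None = None) -> None:
    kind = model.kind
    payload: dict[str, Any] = {
        "format": "fermspec-model",
        "version": __version__,
        "kind": kind,
        "pipeline_hash": pipeline_hash(pipeline),
        "meta": {**{k: v for k, v in getattr(model, "meta", {}).items()
                    if not isinstance(v, np.ndarray)},
                 **(extra_meta or {})},
    }
    if kind == "plsr":
        payload["n_factors"] = model.n_factors
    for name in _ARRAY_FIELDS[kind]:
        payload[name] = np.asarray(getattr(model, name)).tolist()
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> PLSRModel | LinearModel:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise IOError_(f"{path}: cannot parse model artifact: {exc}") from None
    if not isinstance(payload, dict) or payload.get("format") != "fermspec-model":
        raise IOError_(f"{path}: not a fermspec model artifact")
    version = payload.get("version")
    if version != __version__:
        raise IOError_(
            f"{path}: model written by fermspec {version}, this is "
            f"{__version__}; refusing to coerce"
        )
    kind = payload.get("kind")
    if kind not in _ARRAY_FIELDS:
        raise IOError_(f"{path}: unknown model kind {kind!r}")
    try:
        arrays = {name: np.asarray(payload[name], dtype=float)
                  for name in _ARRAY_FIELDS[kind]}
    except KeyError as exc:
        raise IOError_(f"{path}: missing field {exc.args[0]!r}") from None
    meta = dict(payload.get("meta", {}))
    meta["pipeline_hash"] = payload.get("pipeline_hash")
    if kind == "plsr":
        return PLSRModel(n_factors=int(payload["n_factors"]), meta=meta,
                         **arrays)
    return LinearModel(kind=kind, meta=meta, **arrays)


def check_pipeline_match(model: PLSRModel | LinearModel,
                         pipeline: PreprocessPipeline | None) -> bool:
    """Warn when a model is applied with a different preprocessing
    configuration than it was calibrated with."""
    stored = getattr(model, "meta", {}).get("pipeline_hash")
    current = pipeline_hash(pipeline)
    if stored is not None and stored != current:
        warnings.warn(
            f"model was calibrated with pipeline config {stored} but is "
            f"being applied with {current}; predictions may be invalid",
            RuntimeWarning, stacklevel=2,
        )
        return False
    return True
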