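"""CSV/JSON readers and writers shared by all pipeline stages.

All on-disk formats are plain text for diff-ability: spectra are two-column
CSV (``wavenumber_cm1,value``), frequency sweeps are ``frequency_hz,amplitude``,
datasets are wide CSV with one ``wn_<wavenumber>`` column per grid point, and
models/manifests are JSON. Every stochastic run can emit a manifest with the
full configuration, seeds and file digests needed to reproduce it bit-exactly.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .acoustics import FrequencySweep
from .chemometrics import PLSDAModel
from .simulate import AcquisitionMode, Dataset, DatasetRecord
from .spectral import Spectrum, SpectrumKind

__all__ = [
    "read_spectrum_csv", "write_spectrum_csv",
    "read_sweep_csv", "write_sweep_csv",
    "read_dataset_csv", "write_dataset_csv",
    "read_model_json", "write_model_json",
    "write_manifest", "file_digest",
]

_META_COLUMNS = ["timestamp_min", "glucose_mg_dl", "glucose_smoothed", "label", "mode", "day"]


class ParseError(ValueError):
    """A malformed input file; the message names the offending row."""


def _read_two_column_csv(path, col0: str, col1: str) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != [col0, col1]:
        raise ParseError(f"{path}: expected header '{col0},{col1}', got {list(df.columns)} (line 1)")
    x = pd.to_numeric(df[col0], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df[col1], errors="coerce").to_numpy(dtype=float)
    for name, arr in ((col0, x), (col1, y)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise ParseError(f"{path}: non-finite {name} at data row {bad[0] + 1} "
                             f"(file line {bad[0] + 2})")
    if x.size > 1 and not np.all(np.diff(x) > 0):
        i = int(np.flatnonzero(np.diff(x) <= 0)[0])
        raise ParseError(f"{path}: {col0} not strictly ascending at data row {i + 2} "
                         f"(file line {i + 3})")
    return x, y


def read_spectrum_csv(path, kind: SpectrumKind | str = SpectrumKind.PAS_SIGNAL) -> Spectrum:
    """Read a two-column spectrum CSV; the kind comes from a sidecar JSON
    (``<path>.json`` with a ``"kind"`` key) when present, else the argument."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        kind = json.loads(sidecar.read_text())["kind"]
    wn, vals = _read_two_column_csv(path, "wavenumber_cm1", "value")
    return Spectrum(wn, vals, SpectrumKind(kind))


def write_spectrum_csv(spectrum: Spectrum, path, sidecar: bool = True) -> None:
    """Write a spectrum at full float precision, plus a kind sidecar JSON."""
    path = Path(path)
    df = pd.DataFrame({"wavenumber_cm1": spectrum.wavenumbers, "value": spectrum.values})
    df.to_csv(path, index=False)
    if sidecar:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"kind": spectrum.kind.value}) + "\n")


def read_sweep_csv(path) -> FrequencySweep:
    f, a = _read_two_column_csv(path, "frequency_hz", "amplitude")
    return FrequencySweep(f, a)


def write_sweep_csv(sweep: FrequencySweep, path) -> None:
    pd.DataFrame({"frequency_hz": sweep.frequencies_hz, "amplitude": sweep.amplitudes}) \
        .to_csv(path, index=False)


def write_dataset_csv(dataset: Dataset, path) -> None:
    """Wide CSV: metadata columns then one ``wn_<value>`` column per grid point."""
    grid = dataset.grid
    rows = []
    for r in dataset.records:
        row = {
            "timestamp_min": r.timestamp_min,
            "glucose_mg_dl": r.glucose_ref,
            "glucose_smoothed": r.glucose_smoothed,
            "label": r.label,
            "mode": r.mode.value,
            "day": r.day,
        }
        row.update({f"wn_{g:g}": v for g, v in zip(grid, r.spectrum.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dataset_csv(path) -> Dataset:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    wn_cols = [c for c in df.columns if c.startswith("wn_")]
    if not wn_cols:
        raise ParseError(f"{path}: no wn_* spectral columns")
    grid = np.asarray([float(c[3:]) for c in wn_cols])
    order = np.argsort(grid)
    grid = grid[order]
    spectra = df[wn_cols].to_numpy(dtype=float)[:, order]
    records = tuple(
        DatasetRecord(
            timestamp_min=float(row.timestamp_min),
            glucose_ref=float(row.glucose_mg_dl),
            glucose_smoothed=float(row.glucose_smoothed),
            label=int(row.label),
            mode=AcquisitionMode(row.mode),
            day=int(row.day),
            spectrum=Spectrum(grid, spectra[i], SpectrumKind.PAS_SIGNAL),
        )
        for i, row in enumerate(df.itertuples(index=False))
    )
    return Dataset(records)


def write_model_json(model: PLSDAModel, path, extra: dict | None = None) -> None:
    payload = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "regression_vector": model.regression_vector.tolist(),
        "n_latent": model.n_latent,
        "decision_threshold": model.decision_threshold,
    }
    if extra:
        payload["provenance"] = extra
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_model_json(path) -> PLSDAModel:
    d = json.loads(Path(path).read_text())
    return PLSDAModel(
        x_mean=np.asarray(d["x_mean"], dtype=float),
        y_mean=float(d["y_mean"]),
        weights=np.asarray(d["weights"], dtype=float),
        x_loadings=np.asarray(d["x_loadings"], dtype=float),
        y_loadings=np.asarray(d["y_loadings"], dtype=float),
        regression_vector=np.asarray(d["regression_vector"], dtype=float),
        n_latent=int(d["n_latent"]),
        decision_threshold=float(d["decision_threshold"]),
    )


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, subcommand: str, config: dict, seeds: dict,
                   inputs: list | None = None, outputs: list | None = None) -> None:
    """Run manifest: tool version, configuration snapshot, seeds, file digests."""
    from . import __version__

    def _jsonable(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return obj

    manifest = {
        "tool_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "subcommand": subcommand,
        "config": {k: _jsonable(v) for k, v in config.items()},
        "seeds": seeds,
        "inputs": {str(p): file_digest(p) for p in (inputs or [])},
        "outputs": {str(p): file_digest(p) for p in (outputs or [])},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str) + "\n")
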