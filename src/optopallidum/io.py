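"""On-disk persistence for datasets.

Two dialects:

* ``container`` -- a single HDF5 file with groups ``/cells/<id>/sweeps/<n>``;
  sample arrays are stored as float64 datasets (bit-exact round trip) and
  protocols, units and provenance travel as JSON attributes.
* ``tabular`` -- a plain two-column text file (header ``time_s,value``) for a
  single sweep; the sampling rate is inferred from the time column, which
  must be uniform.
"""

from __future__ import annotations

import json
import os
from typing import Union

import h5py
import numpy as np

from .model import (
    CellRecord,
    Dataset,
    TimeSeriesSweep,
    protocol_from_dict,
)

__all__ = ["save_dataset", "load_dataset", "DIALECTS"]

DIALECTS = ("container", "tabular")
_FORMAT_VERSION = 1


class FormatError(ValueError):
    """File is not a recognizable dataset container."""


def save_dataset(dataset: Dataset, path: Union[str, os.PathLike],
                 dialect: str = "container") -> None:
    """Write a dataset to ``path`` (see module docstring for dialects)."""
    if dialect == "container":
        _save_container(dataset, path)
    elif dialect == "tabular":
        _save_tabular(dataset, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_dataset(path: Union[str, os.PathLike],
                 dialect: str = "container") -> Dataset:
    """Read a dataset written by :func:`save_dataset`; all invariants are
    re-validated on load."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if dialect == "container":
        return _load_container(path)
    if dialect == "tabular":
        return _load_tabular(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# container (HDF5)


def _save_container(dataset: Dataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _FORMAT_VERSION
        f.attrs["metadata"] = json.dumps(dataset.metadata)
        cells = f.create_group("cells")
        for cell in dataset.cells:
            g = cells.create_group(cell.cell_id)
            g.attrs["projection_class"] = cell.projection_class
            g.attrs["cortical_source"] = cell.cortical_source
            g.attrs["marker_status"] = json.dumps(cell.marker_status)
            g.attrs["metadata"] = json.dumps(cell.metadata)
            if cell.series_resistance is not None:
                g.attrs["series_resistance"] = float(cell.series_resistance)
            if cell.location is not None:
                g.attrs["location"] = json.dumps(list(cell.location))
            g.attrs["protocols"] = json.dumps(
                {k: p.to_dict() for k, p in cell.protocols.items()})
            sg = g.create_group("sweeps")
            n = 0
            for label, sweeps in cell.sweeps.items():
                for sweep in sweeps:
                    d = sg.create_dataset(str(n), data=sweep.samples, dtype="f8")
                    d.attrs["group"] = label
                    d.attrs["sampling_rate"] = sweep.sampling_rate
                    d.attrs["clamp_mode"] = sweep.clamp_mode
                    d.attrs["t0"] = sweep.t0
                    if sweep.holding is not None:
                        d.attrs["holding"] = sweep.holding
                    n += 1


def _load_container(path) -> Dataset:
    with h5py.File(path, "r") as f:
        if "format_version" not in f.attrs or "metadata" not in f.attrs:
            raise FormatError("missing container metadata")
        metadata = json.loads(f.attrs["metadata"])
        cells = []
        for cell_id in sorted(f["cells"], key=str):
            g = f["cells"][cell_id]
            protocols = {k: protocol_from_dict(v)
                         for k, v in json.loads(g.attrs["protocols"]).items()}
            sweeps: dict = {}
            for n in sorted(g["sweeps"], key=int):
                d = g["sweeps"][n]
                sweep = TimeSeriesSweep(
                    d[()], float(d.attrs["sampling_rate"]),
                    str(d.attrs["clamp_mode"]), t0=float(d.attrs["t0"]),
                    holding=float(d.attrs["holding"]) if "holding" in d.attrs else None)
                sweeps.setdefault(str(d.attrs["group"]), []).append(sweep)
            cells.append(CellRecord(
                cell_id=cell_id,
                projection_class=str(g.attrs["projection_class"]),
                cortical_source=str(g.attrs["cortical_source"]),
                marker_status=json.loads(g.attrs["marker_status"]),
                sweeps=sweeps,
                protocols=protocols,
                series_resistance=(float(g.attrs["series_resistance"])
                                   if "series_resistance" in g.attrs else None),
                location=(tuple(json.loads(g.attrs["location"]))
                          if "location" in g.attrs else None),
                metadata=json.loads(g.attrs["metadata"]),
            ))
    return Dataset(cells=cells, metadata=metadata)


# ---------------------------------------------------------------------------
# tabular (two-column text)


def _single_sweep(dataset: Dataset) -> TimeSeriesSweep:
    if len(dataset.cells) != 1:
        raise ValueError("tabular dialect stores exactly one cell")
    cell = dataset.cells[0]
    sweeps = [s for group in cell.sweeps.values() for s in group]
    if len(sweeps) != 1:
        raise ValueError("tabular dialect stores exactly one sweep")
    return sweeps[0]


def _save_tabular(dataset: Dataset, path) -> None:
    sweep = _single_sweep(dataset)
    t = sweep.times()
    with open(path, "w") as fh:
        fh.write("time_s,value\n")
        for ti, vi in zip(t, sweep.samples):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def _load_tabular(path) -> Dataset:
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "time_s,value":
            raise FormatError("tabular file must start with header 'time_s,value'")
        data = np.loadtxt(fh, delimiter=",")
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise FormatError("tabular file must have two columns and >= 2 rows")
    t, v = data[:, 0], data[:, 1]
    dts = np.diff(t)
    if np.any(~np.isfinite(dts)) or np.any(dts <= 0):
        raise ValueError("time column must be strictly increasing")
    dt = float(np.median(dts))
    if np.max(np.abs(dts - dt)) > 1e-6 * dt + 1e-12:
        raise ValueError("non-uniform sampling in tabular file")
    sweep = TimeSeriesSweep(v, 1.0 / dt, "voltage_clamp", t0=float(t[0]))
    cell = CellRecord(cell_id="cell0", sweeps={"imported": [sweep]},
                      protocols={"imported": _ImportedProtocol()})
    return Dataset(cells=[cell], metadata={"source": "tabular"})


class _ImportedProtocol:
    """Placeholder protocol for sweeps imported from bare tabular files."""

    def to_dict(self) -> dict:
        return {"type": "imported"}

    @classmethod
    def from_dict(cls, d: dict) -> "_ImportedProtocol":
        return cls()


from .model import PROTOCOL_TYPES  # noqa: E402

PROTOCOL_TYPES["imported"] = _ImportedProtocol
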