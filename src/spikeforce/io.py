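"""Plain-text artifact I/O: rasters, traces, metrics and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

__all__ = [
    "write_raster", "read_raster", "write_trace", "write_json",
    "read_json", "config_hash", "write_manifest",
]


def write_raster(path, times: np.ndarray, ids: np.ndarray) -> None:
    """Two-column delimited text: time, neuron_id."""
    data = np.column_stack([np.asarray(times, dtype=float),
                            np.asarray(ids, dtype=float)])
    np.savetxt(path, data, fmt="%.6f %d", header="time neuron_id")


def read_raster(path):
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    return data[:, 0], data[:, 1].astype(np.int64)


def write_trace(path, t: np.ndarray, xhat: np.ndarray,
                x: np.ndarray | None = None) -> None:
    """Delimited columnar trace: t, xhat_1..m[, x_1..m]."""
    xhat = np.atleast_2d(np.asarray(xhat, dtype=float).T).T
    cols = [np.asarray(t, dtype=float), *xhat.T]
    header = ["t"] + [f"xhat_{i}" for i in range(xhat.shape[1])]
    if x is not None:
        x = np.atleast_2d(np.asarray(x, dtype=float).T).T
        cols += list(x.T)
        header += [f"x_{i}" for i in range(x.shape[1])]
    np.savetxt(path, np.column_stack(cols), delimiter=",",
               header=",".join(header), comments="")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, cls=_NumpyEncoder)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(outdir, preset: str, config: dict, seed: int) -> dict:
    from . import __version__
    manifest = {"preset": preset, "config": config, "seed": seed,
                "config_hash": config_hash(config),
                "version": __version__}
    write_json(Path(outdir) / "manifest.json", manifest)
    return manifest
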