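"""Readers and writers for the suite's plain-text interchange formats.

Rasters travel as two-column ASCII (``neuron_id  spike_time_ms``), the
de facto interchange format for spike data.  Tables are CSV with a fixed
numeric precision of 9 significant digits so that determinism can be
asserted byte-for-byte.  Every writer drops a JSON sidecar next to its
output recording the seed, a hash of the configuration, and the package
version.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MetaspikeError

FLOAT_FORMAT = "%.9g"
RASTER_HEADER = "# neuron_id\tspike_time_ms"


def _config_hash(config) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_sidecar(path: str | Path, *, seed=None, config=None) -> Path:
    """Write the metadata sidecar ``<path>.meta.json`` and return its path."""
    from . import __version__

    meta = {
        "seed": seed,
        "config_hash": _config_hash(config if config is not None else {}),
        "version": __version__,
    }
    sidecar = Path(str(path) + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return sidecar


def write_csv(df: pd.DataFrame, path: str | Path, *, seed=None, config=None) -> Path:
    """Write a DataFrame as CSV at fixed precision, with metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    write_sidecar(path, seed=seed, config=config)
    return path


def write_raster(trains: list[np.ndarray], path: str | Path, *, seed=None, config=None) -> Path:
    """Write spike trains as two-column ASCII; times are sorted per neuron."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [RASTER_HEADER]
    for i, t in enumerate(trains):
        for x in np.sort(np.asarray(t, dtype=float)):
            lines.append(f"{i}\t{FLOAT_FORMAT % x}")
    path.write_text("\n".join(lines) + "\n")
    write_sidecar(path, seed=seed, config=config)
    return path


def read_raster(path: str | Path, n_trains: int | None = None) -> list[np.ndarray]:
    """Read a two-column raster file back into per-neuron time arrays.

    ``n_trains`` pads the result with empty trains for silent neurons at
    the end of the id range; by default the largest id seen defines it.
    """
    ids, times = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                ids.append(int(parts[0]))
                times.append(float(parts[1]))
            except (IndexError, ValueError) as exc:
                raise MetaspikeError(
                    f"{path}: malformed raster line {lineno}: {line!r}"
                ) from exc
    n = n_trains if n_trains is not None else (max(ids) + 1 if ids else 0)
    trains = [np.empty(0) for _ in range(n)]
    ids_arr = np.asarray(ids, dtype=int)
    times_arr = np.asarray(times, dtype=float)
    for i in range(n):
        trains[i] = np.sort(times_arr[ids_arr == i])
    return trains
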