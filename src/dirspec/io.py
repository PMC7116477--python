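"""Delimited-text readers/writers and run configuration.

Time series are stored as tab-separated text: comment-prefixed metadata
header (``# key: value``), one column per channel, one row per sample.
Result tables use the same convention with a frequency column and one column
per (pair, component).  An optional binary container (NumPy ``.npz``) is
provided for large runs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mvar import TimeSeriesData

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_table",
    "read_table",
    "load_config",
    "config_hash",
]

_KNOWN_CONFIG_KEYS = {
    "experiment",
    "simulation",
    "observation",
    "estimation",
    "surrogates",
    "output",
}
_SIM_KEYS = {"n_nodes", "edges", "coupling", "osc_freq", "fs", "n_samples", "seed"}
_OBS_KEYS = {"snr_db", "delta_snr_db", "shared_variance", "band", "seed"}
_EST_KEYS = {"seg_len", "methods", "condition_on"}
_SURR_KEYS = {"n", "percentile", "seed"}


def _meta_lines(meta: dict) -> list[str]:
    lines = [f"# dirspec_version: {__version__}"]
    for key, value in meta.items():
        if isinstance(value, (dict, list, tuple)):
            value = json.dumps(value)
        lines.append(f"# {key}: {value}")
    return lines


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ": " in body:
                key, value = body.split(": ", 1)
                meta[key] = value
    return meta


def write_timeseries(path, x: TimeSeriesData, meta: dict | None = None) -> None:
    """Write a time series as tab-separated text (or ``.npz`` if so suffixed)."""
    path = Path(path)
    meta = {"fs": x.fs, "channels": list(x.names()), **(meta or {})}
    if path.suffix == ".npz":
        np.savez_compressed(path, data=x.data, fs=x.fs, meta=json.dumps(meta))
        return
    header = _meta_lines(meta)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("\t".join(x.names()) + "\n")
        np.savetxt(fh, x.data.T, delimiter="\t", fmt="%.10g")


def read_timeseries(path) -> TimeSeriesData:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            return TimeSeriesData(
                data=npz["data"], fs=float(npz["fs"]),
                channel_names=tuple(meta.get("channels") or ()) or None,
            )
    meta = _read_meta(path)
    if "fs" not in meta:
        raise ValueError(f"{path}: missing 'fs' metadata line")
    frame = pd.read_csv(path, sep="\t", comment="#")
    return TimeSeriesData(
        data=frame.to_numpy().T,
        fs=float(meta["fs"]),
        channel_names=tuple(frame.columns),
    )


def write_table(path, table: pd.DataFrame, meta: dict | None = None) -> None:
    """Write a result table as tab-separated text with a metadata header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n".join(_meta_lines(meta or {})) + "\n")
        table.to_csv(fh, sep="\t", index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = _read_meta(path)
    return pd.read_csv(path, sep="\t", comment="#"), meta


def load_config(path) -> dict:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError("configuration must be a mapping")
    _reject_unknown(config, _KNOWN_CONFIG_KEYS, "top level")
    _reject_unknown(config.get("simulation") or {}, _SIM_KEYS, "simulation")
    _reject_unknown(config.get("observation") or {}, _OBS_KEYS, "observation")
    _reject_unknown(config.get("estimation") or {}, _EST_KEYS, "estimation")
    _reject_unknown(config.get("surrogates") or {}, _SURR_KEYS, "surrogates")
    return config


def _reject_unknown(block: dict, known: set, where: str) -> None:
    if not isinstance(block, dict):
        raise ValueError(f"configuration block '{where}' must be a mapping")
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown configuration keys in {where}: {sorted(unknown)}")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration for provenance metadata."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
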