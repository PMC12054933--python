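"""Configuration, file formats and experiment manifests.

Formats: rasters as whitespace-delimited text ("time_seconds neuron_id",
sorted by time); weight snapshots as HDF5 (one dataset per snapshot time,
class metadata attached); indicator series as CSV with unit-suffixed column
names; manifests as JSON.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .params import NetworkParams, STDPParams, default_stdp_params

__all__ = [
    "ResolvedConfig",
    "load_config",
    "write_raster",
    "read_raster",
    "write_weights",
    "read_weights",
    "write_series",
    "read_series",
    "write_manifest",
]

_NETWORK_KEYS = {f.name for f in NetworkParams.__dataclass_fields__.values()}
_STDP_KEYS = {f.name for f in STDPParams.__dataclass_fields__.values()} - {"synapse_class"}
_EXPERIMENT_KEYS = {
    "M", "regime", "rest", "n_epochs", "consolidation", "alternation",
    "overlap", "untrained_fraction", "subset_fraction", "amplitude_jitter",
    "f0", "seed", "duration", "template_style",
}


@dataclass
class ResolvedConfig:
    """Fully resolved configuration: unspecified fields take the defaults."""

    network: NetworkParams
    stdp: dict[str, STDPParams]
    experiment: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "network": asdict(self.network),
            "stdp": {k: asdict(v) for k, v in self.stdp.items()},
            "experiment": dict(self.experiment),
        }


def load_config(path=None, overrides: dict | None = None) -> ResolvedConfig:
    """Load a YAML config; unknown keys fail closed.

    Sections: ``network`` (membrane/synapse/integration parameters),
    ``stdp`` with sub-sections ``e``/``hi``/``ai``, and ``experiment``
    (protocol phases, regime, number of memories M, seed). An empty or
    missing file resolves to the pure reference defaults (N=100, Ne=80,
    gamma_l=0.005, lambda=100, f=0.1).
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if overrides:
        for section, vals in overrides.items():
            raw.setdefault(section, {}).update(vals)

    unknown = set(raw) - {"network", "stdp", "experiment"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    net_raw = dict(raw.get("network") or {})
    bad = set(net_raw) - _NETWORK_KEYS
    if bad:
        raise ValueError(f"unknown network keys: {sorted(bad)}")
    network = NetworkParams(**net_raw)

    exp = dict(raw.get("experiment") or {})
    bad = set(exp) - _EXPERIMENT_KEYS
    if bad:
        raise ValueError(f"unknown experiment keys: {sorted(bad)}")

    stdp_raw = dict(raw.get("stdp") or {})
    bad = set(stdp_raw) - {"e", "hi", "ai"}
    if bad:
        raise ValueError(f"unknown stdp sections: {sorted(bad)}")
    stdp = default_stdp_params(M=int(exp.get("M", 2)), f0=float(exp.get("f0", 0.2)))
    for cls, vals in stdp_raw.items():
        vals = dict(vals or {})
        bad = set(vals) - _STDP_KEYS
        if bad:
            raise ValueError(f"unknown stdp.{cls} keys: {sorted(bad)}")
        stdp[cls] = stdp[cls].replace(**vals)

    return ResolvedConfig(network=network, stdp=stdp, experiment=exp)


# -- rasters ---------------------------------------------------------------

def write_raster(path, spike_times, spike_ids) -> None:
    """One "time_seconds neuron_id" line per spike, sorted by time."""
    times = np.asarray(spike_times, dtype=float)
    ids = np.asarray(spike_ids, dtype=np.intp)
    order = np.argsort(times, kind="stable")
    with open(path, "w") as fh:
        for t, j in zip(times[order], ids[order]):
            fh.write(f"{t:.9f} {int(j)}\n")


def read_raster(path) -> tuple[np.ndarray, np.ndarray]:
    times, ids = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'time id', got {line!r}")
            times.append(float(parts[0]))
            ids.append(int(parts[1]))
    return np.asarray(times), np.asarray(ids, dtype=np.intp)


# -- weight snapshots ------------------------------------------------------

def write_weights(path, snapshots: dict, class_of: np.ndarray,
                  mask: np.ndarray | None = None) -> None:
    """Dense snapshot matrices in HDF5, one dataset per snapshot time."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("class_of", data=np.asarray(class_of, dtype=np.int8))
        if mask is not None:
            fh.create_dataset("mask", data=np.asarray(mask, dtype=bool))
        grp = fh.create_group("snapshots")
        for t, w in sorted(snapshots.items()):
            ds = grp.create_dataset(f"t={float(t):.6f}", data=np.asarray(w))
            ds.attrs["time_s"] = float(t)


def read_weights(path):
    """Returns (snapshots dict, class_of, mask-or-None)."""
    with h5py.File(path, "r") as fh:
        class_of = fh["class_of"][...]
        mask = fh["mask"][...] if "mask" in fh else None
        snapshots = {float(ds.attrs["time_s"]): ds[...]
                     for ds in fh["snapshots"].values()}
    return snapshots, class_of, mask


# -- indicator series ------------------------------------------------------

def write_series(path, columns: dict) -> None:
    """CSV with unit-suffixed column names (e.g. time_s, rate_hz, R)."""
    pd.DataFrame(columns).to_csv(path, index=False)


def read_series(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- manifests -------------------------------------------------------------

def write_manifest(path, config: ResolvedConfig, seed: int,
                   outputs: dict | None = None, extra: dict | None = None) -> None:
    """JSON record sufficient to re-run the experiment bit-identically."""
    from . import __version__

    manifest = {
        "qifnet_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": int(seed),
        "config": config.to_dict(),
        "outputs": dict(outputs or {}),
        "wall_clock_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
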