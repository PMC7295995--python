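"""HDF5 containers, configuration loading and run provenance.

There is no community standard container for stepped M-scan OCT stacks, so
the framework defines a small versioned HDF5 schema: complex data stored as
paired float32 planes under ``/scan/data_real`` and ``/scan/data_imag`` with
acquisition metadata as attributes.  Phantom ground truth travels in an
optional ``/truth`` group.  Every CLI run emits a JSON manifest recording the
configuration hash, seeds and input digests so deterministic stages can be
reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import h5py
import numpy as np
import yaml

from .exceptions import SchemaError
from .pipeline import SteppedMScan
from .simulator import ScanTiming

SCHEMA_VERSION = "1.0"

REQUIRED_SCAN_ATTRS = ("ascan_period_s", "lateral_step_um", "axial_pixel_um",
                       "wavelength_nm")

__all__ = ["read_scan", "write_scan", "read_truth_rate", "load_config",
           "RunManifest", "write_manifest", "SCHEMA_VERSION"]


def write_scan(scan: SteppedMScan, path: str, truth: dict | None = None) -> None:
    """Write a stepped M-scan (and optional ground-truth arrays) to HDF5."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        g = f.create_group("scan")
        g.create_dataset("data_real", data=scan.data.real.astype(np.float32))
        g.create_dataset("data_imag", data=scan.data.imag.astype(np.float32))
        g.attrs["ascan_period_s"] = scan.timing.ascan_period_s
        g.attrs["n_samples"] = scan.timing.n_samples
        g.attrs["lateral_step_um"] = scan.lateral_step_um
        g.attrs["axial_pixel_um"] = scan.axial_pixel_um
        g.attrs["wavelength_nm"] = scan.wavelength_nm
        if scan.doppler_angle_deg is not None:
            g.attrs["doppler_angle_deg"] = scan.doppler_angle_deg
        if truth is not None:
            t = f.create_group("truth")
            for k, v in truth.items():
                if np.isscalar(v):
                    t.attrs[k] = v
                else:
                    t.create_dataset(k, data=np.asarray(v))


def read_scan(path: str) -> SteppedMScan:
    with h5py.File(path, "r") as f:
        if "scan" not in f:
            raise SchemaError("missing /scan group")
        g = f["scan"]
        for attr in REQUIRED_SCAN_ATTRS:
            if attr not in g.attrs:
                raise SchemaError(f"missing required attribute {attr!r}")
        if "data_real" not in g or "data_imag" not in g:
            raise SchemaError("missing data_real/data_imag datasets")
        data = (np.asarray(g["data_real"], dtype=np.float64)
                + 1j * np.asarray(g["data_imag"], dtype=np.float64))
        timing = ScanTiming(float(g.attrs["ascan_period_s"]),
                            int(g.attrs.get("n_samples", data.shape[2])))
        return SteppedMScan(
            data=data, timing=timing,
            lateral_step_um=float(g.attrs["lateral_step_um"]),
            axial_pixel_um=float(g.attrs["axial_pixel_um"]),
            wavelength_nm=float(g.attrs["wavelength_nm"]),
            doppler_angle_deg=(float(g.attrs["doppler_angle_deg"])
                               if "doppler_angle_deg" in g.attrs else None),
        )


def read_truth_rate(path: str) -> dict:
    """Ground-truth attributes/arrays of a phantom file, if present."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            return out
        t = f["truth"]
        out.update({k: t.attrs[k] for k in t.attrs})
        out.update({k: np.asarray(t[k]) for k in t})
    return out


def load_config(path: str) -> dict:
    """Load a YAML or JSON configuration file."""
    text = Path(path).read_text()
    if path.endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


@dataclasses.dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int | None
    input_digests: dict[str, str]
    timestamp: str
    schema_version: str = SCHEMA_VERSION


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_path: str, command: str, config: dict,
                   seed: int | None, inputs: list[str]) -> RunManifest:
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(
        command=command, config_hash=cfg_hash, seed=seed,
        input_digests={p: _digest(p) for p in inputs if Path(p).exists()},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    Path(out_path).write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    return manifest
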