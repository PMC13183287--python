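"""Run configuration and result I/O.

A run config mirrors the model's parameter table as YAML sections
(model, plasticity, protocol, hemodynamics, bands, sweep); unknown keys
are rejected and every loaded config can be re-serialized identically.
Results are written as CSV (one file per trace) or HDF5, always with a
JSON sidecar recording the resolved configuration, seed, and checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .hemo import HemodynamicParams
from .model import NodeParams, SigmoidParams, SubpopulationParams
from .plasticity import PlasticityParams
from .signals import BandDefinition, CANONICAL_BANDS
from .simulate import SimulationProtocol, SimulationResult

__all__ = ["RunConfig", "load_config", "save_config", "write_result"]


@dataclass
class RunConfig:
    """Fully resolved parameter set of one run; defaults reproduce the
    model's standard parameter table."""

    model: NodeParams = field(default_factory=NodeParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    protocol: SimulationProtocol = field(default_factory=SimulationProtocol)
    hemodynamics: HemodynamicParams = field(default_factory=HemodynamicParams)
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    seeds: tuple[int, ...] = (0,)

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": {
                "alpha": dataclasses.asdict(self.model.alpha),
                "gamma": dataclasses.asdict(self.model.gamma),
                "sigmoid": dataclasses.asdict(self.model.sigmoid),
                "C": self.model.C,
                "c1": self.model.c1,
                "c2": self.model.c2,
                "c3": self.model.c3,
                "c4_init": self.model.c4_init,
                "r_alpha": self.model.r_alpha,
            },
            "plasticity": dataclasses.asdict(self.plasticity),
            "protocol": dataclasses.asdict(self.protocol),
            "hemodynamics": dataclasses.asdict(self.hemodynamics),
            "bands": [dataclasses.asdict(b) for b in self.bands],
            "seeds": list(self.seeds),
        }


def _build(cls, section: dict[str, Any], name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    return cls(**section)


def load_config(path: str | Path | None = None, text: str | None = None) -> RunConfig:
    """Load a YAML config; missing sections/keys fall back to defaults,
    unknown keys raise, out-of-range values raise via each section's own
    invariant checks."""
    if text is None:
        text = Path(path).read_text() if path else ""
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {"model", "plasticity", "protocol", "hemodynamics", "bands", "seeds"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level section(s): {sorted(unknown)}")

    model_raw = dict(raw.get("model", {}))
    sub = {}
    for key, cls in (("alpha", SubpopulationParams), ("gamma", SubpopulationParams),
                     ("sigmoid", SigmoidParams)):
        if key in model_raw:
            sub[key] = _build(cls, model_raw.pop(key), f"model.{key}")
    model = _build(NodeParams, {**model_raw, **sub}, "model")
    cfg = RunConfig(
        model=model,
        plasticity=_build(PlasticityParams, raw.get("plasticity", {}), "plasticity"),
        protocol=_build(SimulationProtocol, raw.get("protocol", {}), "protocol"),
        hemodynamics=_build(
            HemodynamicParams, raw.get("hemodynamics", {}), "hemodynamics"
        ),
        bands=tuple(
            _build(BandDefinition, b, "bands") for b in raw["bands"]
        ) if "bands" in raw else CANONICAL_BANDS,
        seeds=tuple(int(s) for s in raw.get("seeds", [0])),
    )
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_result(
    result: SimulationResult,
    path: str | Path,
    format: str = "csv",
    config: RunConfig | None = None,
) -> dict[str, Any]:
    """Persist a simulation result plus a JSON manifest sidecar.

    ``format="csv"`` writes one file per trace next to ``path`` (stem
    suffixes _eeg/_rate/_c4); ``format="hdf5"`` writes a single container.
    The manifest records sampling rate, shapes, seed/config snapshot, and a
    sha256 checksum per file, and is returned as a dict.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    if format == "csv":
        for tag, arr in (
            ("eeg", result.eeg), ("rate", result.zeta_pyr), ("c4", result.c4_trace)
        ):
            f = path.with_name(f"{path.stem}_{tag}.csv")
            np.savetxt(f, np.asarray(arr), delimiter=",")
            files[tag] = f
    elif format == "hdf5":
        import h5py

        f = path if path.suffix in {".h5", ".hdf5"} else path.with_suffix(".h5")
        with h5py.File(f, "w") as h:
            h.create_dataset("eeg", data=result.eeg)
            h.create_dataset("zeta_pyr", data=result.zeta_pyr)
            h.create_dataset("c4_trace", data=result.c4_trace)
            h.attrs["fs"] = result.fs
        files["hdf5"] = f
    else:
        raise ValueError(f"unsupported format {format!r}")

    proto = result.meta.get("protocol")
    manifest = {
        "fs": result.fs,
        "n_nodes": int(result.eeg.shape[0]),
        "n_samples": int(result.eeg.shape[1]),
        "seed": getattr(proto, "seed", None),
        "protocol": dataclasses.asdict(proto) if proto is not None else None,
        "config": config.to_dict() if config is not None else None,
        "files": {tag: {"path": f.name, "sha256": _sha256(f)}
                  for tag, f in files.items()},
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(manifest, indent=2))
    return manifest
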