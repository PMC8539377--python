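"""TOML configuration loading and validation.

A simulation configuration has four blocks — ``beam``, ``sample``,
``geometry`` and ``grid`` — mirroring the domain types.  Unknown keys and
out-of-range values are reported with the offending block and key named.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

from .beam_optics import BeamParameters, WavenumberGrid
from .interferometry import SystemGeometry
from .sample_model import LayeredSample

__all__ = ["SimulationConfig", "load_config", "build_sample", "dump_toml"]


@dataclass
class SimulationConfig:
    beam: BeamParameters
    sample: LayeredSample
    geometry: SystemGeometry
    grid: WavenumberGrid


def _take(block: dict, name: str, key: str, default=None, required=False):
    if key in block:
        return block.pop(key)
    if required:
        raise ValueError(f"config block [{name}] is missing key '{key}'")
    return default


def _finish(block: dict, name: str):
    if block:
        raise ValueError(f"unknown key(s) {sorted(block)} in config block [{name}]")


def build_beam(block: dict) -> BeamParameters:
    block = dict(block)
    beam = BeamParameters(
        w0=float(_take(block, "beam", "w0_um", required=True)),
        r0=float(_take(block, "beam", "r0_um", 0.0)),
        polarization=tuple(_take(block, "beam", "polarization", (1.0, 0.0))),
        amplitude=complex(_take(block, "beam", "amplitude", 1.0)),
    )
    _finish(block, "beam")
    return beam


def build_sample(block: dict) -> LayeredSample:
    block = dict(block)
    kind = _take(block, "sample", "type", required=True)
    tilt = float(_take(block, "sample", "tilt_deg", 0.0))
    x3 = float(_take(block, "sample", "surface_x3_um", 0.0))
    if kind == "mirror":
        sample = LayeredSample.mirror(tilt_deg=tilt, surface_x3=x3)
    elif kind == "interface":
        n1 = float(_take(block, "sample", "n1", required=True))
        sample = LayeredSample.single_interface(n1, tilt_deg=tilt, surface_x3=x3)
    elif kind == "slab":
        n1 = float(_take(block, "sample", "n1", required=True))
        d = float(_take(block, "sample", "thickness_um", required=True))
        sample = LayeredSample.slab(n1, d, tilt_deg=tilt, surface_x3=x3)
    else:
        raise ValueError(f"unknown sample type '{kind}'"
                         " (expected mirror, interface or slab)")
    block.pop("n1", None)
    block.pop("thickness_um", None)
    _finish(block, "sample")
    return sample


def build_geometry(block: dict) -> SystemGeometry:
    block = dict(block)
    geometry = SystemGeometry(
        r_detector=float(_take(block, "geometry", "r_detector_um", 500.0)),
        x_ref_mirror=float(_take(block, "geometry", "x_ref_mirror_um", 0.0)),
        theta_max_deg=float(_take(block, "geometry", "theta_max_deg", 1.5709)),
        tau=complex(_take(block, "geometry", "tau", 1.0)),
        reference_amplitude=complex(
            _take(block, "geometry", "reference_amplitude", 1.0)),
    )
    _finish(block, "geometry")
    return geometry


def build_grid(block: dict) -> WavenumberGrid:
    block = dict(block)
    grid = WavenumberGrid(
        kmin=float(_take(block, "grid", "kmin", 4.7835)),
        kmax=float(_take(block, "grid", "kmax", 4.8973)),
        count=int(_take(block, "grid", "count", 700)),
    )
    _finish(block, "grid")
    return grid


def load_config(path) -> SimulationConfig:
    """Load and validate a TOML simulation configuration."""
    with Path(path).open("rb") as fh:
        raw = tomllib.load(fh)
    return SimulationConfig(
        beam=build_beam(raw.get("beam", {"w0_um": 14.15})),
        sample=build_sample(raw.get("sample", {"type": "mirror"})),
        geometry=build_geometry(raw.get("geometry", {})),
        grid=build_grid(raw.get("grid", {})),
    )


def dump_toml(path, table: dict):
    """Write a flat mapping as a minimal TOML file (strings and numbers)."""
    lines = []
    for key, value in table.items():
        if isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        elif isinstance(value, bool):
            lines.append(f"{key} = {str(value).lower()}")
        else:
            lines.append(f"{key} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
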