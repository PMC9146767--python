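"""Device and skin description for the microneedle-array impedance model.

Units are fixed throughout the package: lengths in micrometres (μm),
conductivities in S/m, drive voltage in volts, currents in microamperes.
Configuration files (YAML or JSON) use the field names of these dataclasses
verbatim; no unit parsing is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ArrayGeometry", "SkinModel", "SolverConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class ArrayGeometry:
    """Geometry of a metallic sheet microneedle array (lengths in μm).

    The array is a row of ``n_sheets`` parallel metal sheets, each carrying
    ``tips_per_sheet`` needle tips.  Defaults describe the reference device:
    100 μm sheet thickness, 200 μm wide and 800 μm long needles with a
    200 μm tip section, 800 μm tip and sheet pitch, inserted 600 μm deep.
    """

    n_sheets: int = 3
    tips_per_sheet: int = 3
    sheet_thickness: float = 100.0
    tip_width: float = 200.0
    needle_length: float = 800.0
    tip_section_length: float = 200.0
    tip_pitch: float = 800.0
    sheet_pitch: float = 800.0
    insertion_depth: float = 600.0

    def __post_init__(self) -> None:
        if self.n_sheets < 1 or self.tips_per_sheet < 1:
            raise ValueError("array must have at least one sheet and one tip")
        for name in (
            "sheet_thickness",
            "tip_width",
            "needle_length",
            "tip_section_length",
            "tip_pitch",
            "sheet_pitch",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.insertion_depth < 0:
            raise ValueError("insertion_depth must be >= 0")
        if self.insertion_depth > self.needle_length:
            raise ValueError("insertion_depth cannot exceed needle_length")
        if self.tip_section_length > self.needle_length:
            raise ValueError("tip_section_length cannot exceed needle_length")

    @property
    def extent_x(self) -> float:
        """Array bounding-box extent across sheets (μm)."""
        return (self.n_sheets - 1) * self.sheet_pitch + self.sheet_thickness

    @property
    def extent_y(self) -> float:
        """Array bounding-box extent along a sheet (μm)."""
        return (self.tips_per_sheet - 1) * self.tip_pitch + self.tip_width

    @property
    def label(self) -> str:
        return f"{self.n_sheets}x{self.tips_per_sheet}"

    @classmethod
    def square(cls, n: int, **overrides: Any) -> "ArrayGeometry":
        """n × n array with the reference default dimensions."""
        return cls(n_sheets=n, tips_per_sheet=n, **overrides)


@dataclass(frozen=True)
class SkinModel:
    """Two-layer skin block with contact-impedance coupling to the needles.

    The stratum corneum is a thin, highly resistive surface layer
    (100 μm, 0.0005 S/m); the viable epidermis and dermis are pooled into one
    conductive layer (1800 μm, 0.2 S/m).  The needle/skin interface is a
    contact-impedance boundary with an effective 20 μm surface thickness whose
    conductivity switches between the two layer values with the penetration
    flag.  The skin block's lateral area is ``footprint_ratio`` times the
    array footprint (default 9, i.e. 3× the array extent per axis) so the
    insulating outer boundary stays far from the current paths.
    """

    sc_thickness: float = 100.0
    sc_conductivity: float = 0.0005
    dermis_thickness: float = 1800.0
    dermis_conductivity: float = 0.2
    metal_conductivity: float = 1e7
    contact_thickness: float = 20.0
    footprint_ratio: float = 9.0

    def __post_init__(self) -> None:
        for name in ("sc_thickness", "dermis_thickness", "contact_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.sc_conductivity < self.dermis_conductivity < self.metal_conductivity):
            raise ValueError(
                "conductivities must satisfy 0 < sc < dermis < metal"
            )
        if self.footprint_ratio < 1:
            raise ValueError("footprint_ratio must be >= 1")

    @property
    def depth(self) -> float:
        """Total conductive depth (μm)."""
        return self.sc_thickness + self.dermis_thickness


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings of the finite-volume field solver.

    ``voxel_size`` defaults to 50 μm; 100 μm is the coarse option used for
    exhaustive sweeps.  The drive is DC: 1 V between the tested sheet pair.
    """

    drive_voltage: float = 1.0
    relative_tolerance: float = 1e-8
    max_iterations: int = 2000
    voxel_size: float = 50.0

    def __post_init__(self) -> None:
        if self.drive_voltage <= 0:
            raise ValueError("drive_voltage must be positive")
        if not (0 < self.relative_tolerance <= 1e-3):
            raise ValueError("relative_tolerance must be in (0, 1e-3]")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")


_SECTIONS = {
    "geometry": ArrayGeometry,
    "skin": SkinModel,
    "solver": SolverConfig,
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a geometry/skin/solver configuration from YAML or JSON.

    The file holds up to three blocks named ``geometry``, ``skin`` and
    ``solver``; missing blocks take defaults, unknown fields are rejected.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    out: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        block = raw.get(name, {})
        valid = {f.name for f in fields(cls)}
        bad = set(block) - valid
        if bad:
            raise ValueError(f"{path}: unknown fields in '{name}': {sorted(bad)}")
        out[name] = cls(**block)
    return out


def dump_config(config: dict[str, Any], path: str | Path) -> None:
    """Write a configuration mapping back to YAML or JSON."""
    path = Path(path)
    raw = {name: asdict(obj) for name, obj in config.items()}
    if path.suffix == ".json":
        path.write_text(json.dumps(raw, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False))
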