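"""Geometry of self-assembled DNA structures.

The partition model upstream of the fractionation simulator consumes a
single number per structure: its surface area A in nm². This module holds
a small catalog of idealised shape models for the structures studied with
water-in-water (W/W) droplet fractionation — origami sheets modelled as
thin prisms, helix bundles as cylinders, short strands as equivalent
spheres, tile tubes as open cylinders — and the mensuration that turns a
named shape plus dimensions into A.

Structures without a single defined size (hydrogels, microtubes of
variable length) yield an area *range* rather than a scalar; downstream
code draws these as lines on the efficiency landscape.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .errors import ConfigurationError, ValidationError

__all__ = [
    "StructureSpec",
    "surface_area",
    "builtin_catalog",
    "load_catalog",
    "get_structure",
    "SHAPES",
]

#: shape tag -> required dimension keys (nm)
SHAPES: dict[str, tuple[str, ...]] = {
    "sphere": ("diameter",),
    "disc": ("diameter", "thickness"),
    "regular_hexagonal_prism": ("diameter", "thickness"),
    "equilateral_triangular_prism": ("diameter", "thickness"),
    "cylinder": ("diameter", "length"),
    "open_tube": ("diameter", "length_min", "length_max"),
    "size_range": ("diameter_min", "diameter_max"),
}

#: shapes whose surface_area is an (A_min, A_max) interval
RANGE_SHAPES = frozenset({"open_tube", "size_range"})

AreaLike = Union[float, tuple[float, float]]


@dataclass(frozen=True)
class StructureSpec:
    """A named DNA structure with an idealised shape model.

    Parameters
    ----------
    name
        Catalog identifier.
    shape
        One of the tags in :data:`SHAPES`.
    dims
        Shape-specific linear dimensions in nm. Prisms and discs are
        specified by the circumscribed diameter of the face plus the
        slab thickness; tubes by diameter and a length range; size_range
        by min/max equivalent-sphere diameter.
    assumed_dims
        Dimension keys whose values are package defaults rather than
        measured/quoted sizes. Purely informational.
    description
        Free-text note shown by the CLI.
    """

    name: str
    shape: str
    dims: dict[str, float]
    assumed_dims: tuple[str, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ConfigurationError(
                f"unknown shape {self.shape!r} for structure {self.name!r}; "
                f"known shapes: {sorted(SHAPES)}"
            )
        required = SHAPES[self.shape]
        missing = [k for k in required if k not in self.dims]
        if missing:
            raise ConfigurationError(
                f"structure {self.name!r} ({self.shape}) missing dims {missing}"
            )
        for key in required:
            value = self.dims[key]
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValidationError(
                    f"structure {self.name!r}: dimension {key!r} must be a "
                    f"positive finite number, got {value!r}"
                )
        if self.shape == "size_range" and not self.dims["diameter_min"] < self.dims["diameter_max"]:
            raise ValidationError(
                f"structure {self.name!r}: diameter_min must be < diameter_max"
            )
        if self.shape == "open_tube" and not self.dims["length_min"] < self.dims["length_max"]:
            raise ValidationError(
                f"structure {self.name!r}: length_min must be < length_max"
            )

    @property
    def has_area_range(self) -> bool:
        return self.shape in RANGE_SHAPES

    def area(self) -> AreaLike:
        return surface_area(self)


def _sphere(d: float) -> float:
    return math.pi * d * d


def _disc(d: float, t: float) -> float:
    r = d / 2.0
    return 2.0 * math.pi * r * r + math.pi * d * t


def _hex_prism(d: float, t: float) -> float:
    # regular hexagon with circumradius s = d/2: face area (3√3/2)s², perimeter 6s
    s = d / 2.0
    face = 1.5 * math.sqrt(3.0) * s * s
    return 2.0 * face + 6.0 * s * t


def _tri_prism(d: float, t: float) -> float:
    # equilateral triangle with circumradius R = d/2: side a = R√3, face (√3/4)a²
    a = (d / 2.0) * math.sqrt(3.0)
    face = math.sqrt(3.0) / 4.0 * a * a
    return 2.0 * face + 3.0 * a * t


def _cylinder(d: float, length: float) -> float:
    r = d / 2.0
    return 2.0 * math.pi * r * r + math.pi * d * length


def _open_tube_at(d: float, length: float) -> float:
    # open-ended tube: inner + outer lateral surface, no end caps
    return 2.0 * math.pi * d * length


def surface_area(spec: StructureSpec) -> AreaLike:
    """Surface area of a structure in nm².

    Returns a scalar for fixed-size shapes and an ``(A_min, A_max)`` pair
    for ``open_tube`` (variable length) and ``size_range`` (equivalent
    sphere between two diameters). Deterministic and strictly increasing
    in every linear dimension; scaling all dimensions by c scales the
    area by c².
    """
    d = spec.dims
    if spec.shape == "sphere":
        return _sphere(d["diameter"])
    if spec.shape == "disc":
        return _disc(d["diameter"], d["thickness"])
    if spec.shape == "regular_hexagonal_prism":
        return _hex_prism(d["diameter"], d["thickness"])
    if spec.shape == "equilateral_triangular_prism":
        return _tri_prism(d["diameter"], d["thickness"])
    if spec.shape == "cylinder":
        return _cylinder(d["diameter"], d["length"])
    if spec.shape == "open_tube":
        return (
            _open_tube_at(d["diameter"], d["length_min"]),
            _open_tube_at(d["diameter"], d["length_max"]),
        )
    if spec.shape == "size_range":
        return (_sphere(d["diameter_min"]), _sphere(d["diameter_max"]))
    raise ConfigurationError(f"unknown shape {spec.shape!r}")  # pragma: no cover


def builtin_catalog() -> list[StructureSpec]:
    """The built-in structure catalog.

    Measured/quoted sizes: staples ~5 nm hydrodynamic diameter; hexagonal
    origami ~100 nm diameter, ~2 nm thickness; standard triangular origami
    ~100 nm; mini-triangle ~15 nm; 24-helix bundle ~80 nm long; hydrogels
    and tile microtubes span hundreds of nm to several µm. Dimensions not
    available from measurements carry package defaults and are listed in
    ``assumed_dims`` (24HB diameter 13 nm for a 24-helix honeycomb bundle;
    Y-motif treated as a staple-sized 5 nm sphere; tube diameters 8 nm for
    the 4-helix and 14 nm for the 13-helix tile; length/size ranges
    200 nm – 5 µm).
    """
    um = 1000.0
    return [
        StructureSpec(
            "staple", "sphere", {"diameter": 5.0},
            description="unbound staple strand, ~5 nm hydrodynamic diameter",
        ),
        StructureSpec(
            "hexagonal_origami", "regular_hexagonal_prism",
            {"diameter": 100.0, "thickness": 2.0},
            description="hexagonal DNA origami sheet, ~100 nm across, ~2 nm thick",
        ),
        StructureSpec(
            "triangular_origami", "equilateral_triangular_prism",
            {"diameter": 100.0, "thickness": 2.0},
            assumed_dims=("thickness",),
            description="standard-sized triangular DNA origami, ~100 nm",
        ),
        StructureSpec(
            "mini_triangle", "equilateral_triangular_prism",
            {"diameter": 15.0, "thickness": 2.0},
            description="mini-triangular origami from the M1.3 scaffold, ~15 nm",
        ),
        StructureSpec(
            "24hb", "cylinder", {"diameter": 13.0, "length": 80.0},
            assumed_dims=("diameter",),
            description="24-helix-bundle origami, ~80 nm long cylinder",
        ),
        StructureSpec(
            "y_motif", "sphere", {"diameter": 5.0},
            assumed_dims=("diameter",),
            description="sticky-end-less Y-motif, staple-like in size",
        ),
        StructureSpec(
            "dna_hydrogel", "size_range",
            {"diameter_min": 200.0, "diameter_max": 5.0 * um},
            assumed_dims=("diameter_min", "diameter_max"),
            description="Y-motif hydrogel network, hundreds of nm to several µm",
        ),
        StructureSpec(
            "microtube_4ht", "open_tube",
            {"diameter": 8.0, "length_min": 200.0, "length_max": 5.0 * um},
            assumed_dims=("diameter", "length_min", "length_max"),
            description="4-helix-tile DNA microtube, variable length",
        ),
        StructureSpec(
            "microtube_13ht", "open_tube",
            {"diameter": 14.0, "length_min": 200.0, "length_max": 5.0 * um},
            assumed_dims=("diameter", "length_min", "length_max"),
            description="13-helix-tile DNA microtube, variable length",
        ),
    ]


def get_structure(name: str, catalog: list[StructureSpec] | None = None) -> StructureSpec:
    """Look a structure up by name; raises :class:`ConfigurationError` if absent."""
    catalog = builtin_catalog() if catalog is None else catalog
    for spec in catalog:
        if spec.name == name:
            return spec
    known = ", ".join(s.name for s in catalog)
    raise ConfigurationError(f"no structure named {name!r} in catalog (known: {known})")


def load_catalog(path: str | Path) -> list[StructureSpec]:
    """Load a user catalog from a YAML or JSON list of {name, shape, dims}."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, list):
        raise ConfigurationError(f"catalog file {path} must contain a list of structures")
    specs = []
    for i, entry in enumerate(data):
        if not isinstance(entry, dict) or "name" not in entry or "shape" not in entry:
            raise ConfigurationError(f"catalog entry {i} must be a mapping with name/shape/dims")
        specs.append(
            StructureSpec(
                name=str(entry["name"]),
                shape=str(entry["shape"]),
                dims={k: float(v) for k, v in dict(entry.get("dims", {})).items()},
                assumed_dims=tuple(entry.get("assumed_dims", ())),
                description=str(entry.get("description", "")),
            )
        )
    return specs
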