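"""Basis materials, triangle domains, and the default six-material library.

Both decomposition methods share the same picture of dual-energy
attenuation space: each basis material is a point ``m = (HU_low,
HU_high)``, and an ordered set of three-material *domains* (triangles)
partitions the physiologically plausible region.  Within a domain, a
voxel's measurement is expressed as a barycentric combination of the
three vertex materials, and the weights are read as volume fractions.

The default library holds six materials (air, water, iodine,
hydroxyapatite, collagen, lipid) and five physiologically motivated
domains: air-soft tissue, fat-muscle, bone-soft tissue, iodine near air,
and calcified tissue with iodine.  Non-physiological triples such as
air-iodine-hydroxyapatite are deliberately absent.  Contrast vertices
(iodine, hydroxyapatite) are rod-calibrated: the vertex is the attenuation
of water carrying the reference concentration of solute (20 mg/mL iodine,
400 mg/mL hydroxyapatite), so volume fractions along the water-contrast
edge convert linearly to concentration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import attenuation

__all__ = [
    "DEGENERACY_TOL",
    "MaterialBasis",
    "MaterialDomain",
    "MaterialLibrary",
    "build_default_library",
    "augment_library",
    "library_vertices",
    "load_library",
    "save_library",
]

#: Minimum |signed area| (HU^2) for a domain triangle to count as valid.
#: Far below any physical triangle, far above double-precision round-off.
DEGENERACY_TOL = 1e-9

#: Default working energies (keV) of the low/high virtual monoenergetic pair.
DEFAULT_ENERGIES = (70.0, 150.0)


def _signed_area2(a, b, c) -> float:
    # local copy to avoid a circular import with geometry
    return 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))


@dataclasses.dataclass(frozen=True)
class MaterialBasis:
    """A basis material: a named point in dual-energy attenuation space.

    Parameters
    ----------
    name : str
        Identifier, unique within a library.
    attenuation_low, attenuation_high : float
        HU at the low / high energy.
    reference_concentration : float, optional
        mg/mL of solute at the vertex; present only for contrast
        materials (e.g. 20 mg/mL for the iodine rod vertex).
    """

    name: str
    attenuation_low: float
    attenuation_high: float
    reference_concentration: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.attenuation_low) and np.isfinite(self.attenuation_high)):
            raise ValueError(f"material {self.name!r}: attenuation must be finite")
        if self.reference_concentration is not None and self.reference_concentration <= 0:
            raise ValueError(
                f"material {self.name!r}: reference_concentration must be > 0"
            )

    @property
    def vertex(self) -> np.ndarray:
        return np.array([self.attenuation_low, self.attenuation_high], dtype=float)


@dataclasses.dataclass(frozen=True)
class MaterialDomain:
    """An ordered triple of material names spanning a triangle domain."""

    vertices: tuple[str, str, str]
    label: str = ""

    def __post_init__(self):
        verts = tuple(self.vertices)
        if len(verts) != 3 or len(set(verts)) != 3:
            raise ValueError(f"domain {self.label!r}: vertices must be 3 distinct materials")
        object.__setattr__(self, "vertices", verts)

    @property
    def vertex_set(self) -> frozenset:
        return frozenset(self.vertices)


@dataclasses.dataclass(frozen=True)
class MaterialLibrary:
    """Energies, basis materials, and the ordered list of triangle domains.

    Domain declaration order is deterministic and meaningful: it defines
    the first-feasible search priority of the barycentric benchmark
    method and the final tie-break of all selection rules.
    """

    energies: tuple[float, float]
    materials: tuple[MaterialBasis, ...]
    domains: tuple[MaterialDomain, ...]

    def __post_init__(self):
        object.__setattr__(self, "energies", tuple(float(e) for e in self.energies))
        object.__setattr__(self, "materials", tuple(self.materials))
        object.__setattr__(self, "domains", tuple(self.domains))
        names = [m.name for m in self.materials]
        if len(set(names)) != len(names):
            raise ValueError("duplicate material names")
        index = {n: i for i, n in enumerate(names)}
        for dom in self.domains:
            for v in dom.vertices:
                if v not in index:
                    raise ValueError(f"domain {dom.label!r} references unknown material {v!r}")
            tri = [self.material(v).vertex for v in dom.vertices]
            area = _signed_area2(*tri)
            if abs(area) <= DEGENERACY_TOL:
                raise ValueError(
                    f"domain {dom.label!r} is degenerate (|area| = {abs(area):.3g} HU^2)"
                )

    # -- lookups ---------------------------------------------------------
    @property
    def material_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.materials)

    def material(self, name: str) -> MaterialBasis:
        for m in self.materials:
            if m.name == name:
                return m
        raise KeyError(f"unknown material {name!r}")

    def material_index(self, name: str) -> int:
        return self.material_names.index(name)

    def vertex_matrix(self) -> np.ndarray:
        """(n_materials, 2) HU vertices in declaration order."""
        return np.array([[m.attenuation_low, m.attenuation_high] for m in self.materials])

    def domain_vertex_indices(self) -> np.ndarray:
        """(n_domains, 3) indices into the material list."""
        idx = {n: i for i, n in enumerate(self.material_names)}
        return np.array([[idx[v] for v in d.vertices] for d in self.domains], dtype=int)

    def triangles(self) -> np.ndarray:
        """(n_domains, 3, 2) triangle vertex coordinates in HU."""
        return self.vertex_matrix()[self.domain_vertex_indices()]

    def domain_index_by_vertices(self, names: Sequence[str]) -> int:
        target = frozenset(names)
        for i, d in enumerate(self.domains):
            if d.vertex_set == target:
                return i
        raise KeyError(f"no domain with vertices {sorted(target)}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        mats = []
        for m in self.materials:
            entry = {"name": m.name, "hu": [m.attenuation_low, m.attenuation_high]}
            if m.reference_concentration is not None:
                entry["reference_concentration"] = m.reference_concentration
            mats.append(entry)
        return {
            "energies": list(self.energies),
            "materials": mats,
            "domains": [
                {"label": d.label, "vertices": list(d.vertices)} for d in self.domains
            ],
        }

    @classmethod
    def from_dict(cls, spec: dict) -> "MaterialLibrary":
        materials = []
        for entry in spec["materials"]:
            if "hu" in entry:
                low, high = (float(x) for x in entry["hu"])
            elif "composition" in entry:
                # elemental recipe: mass fractions + density
                e_low, e_high = spec["energies"]
                rho = float(entry["density"])
                comp = {k: float(v) for k, v in entry["composition"].items()}
                low = attenuation.hounsfield(
                    attenuation.compound_mu_rho(comp, e_low) * rho, e_low
                )
                high = attenuation.hounsfield(
                    attenuation.compound_mu_rho(comp, e_high) * rho, e_high
                )
            else:
                raise ValueError(f"material {entry.get('name')!r}: need 'hu' or 'composition'")
            materials.append(
                MaterialBasis(
                    name=entry["name"],
                    attenuation_low=low,
                    attenuation_high=high,
                    reference_concentration=entry.get("reference_concentration"),
                )
            )
        domains = [
            MaterialDomain(vertices=tuple(d["vertices"]), label=d.get("label", ""))
            for d in spec["domains"]
        ]
        return cls(
            energies=tuple(spec["energies"]),
            materials=tuple(materials),
            domains=tuple(domains),
        )


def build_default_library(energies: tuple[float, float] = DEFAULT_ENERGIES) -> MaterialLibrary:
    """Six materials, five physiological domains, at 70/150 keV by default.

    Attenuation values come from the embedded mass-attenuation table
    (:mod:`pcammd.attenuation`).  Air and water are pinned to their HU
    definitions; iodine and hydroxyapatite are rod-calibrated vertices.
    """
    e_low, e_high = energies

    def bulk(name):
        return (
            attenuation.material_hu(name, e_low),
            attenuation.material_hu(name, e_high),
        )

    iodine = (
        attenuation.solution_hu("iodine", 20.0, e_low),
        attenuation.solution_hu("iodine", 20.0, e_high),
    )
    ha = (
        attenuation.solution_hu("hydroxyapatite", 400.0, e_low),
        attenuation.solution_hu("hydroxyapatite", 400.0, e_high),
    )
    materials = (
        MaterialBasis("air", -1000.0, -1000.0),
        MaterialBasis("water", 0.0, 0.0),
        MaterialBasis("lipid", *bulk("triolein")),
        MaterialBasis("collagen", *bulk("collagen")),
        MaterialBasis("iodine", *iodine, reference_concentration=20.0),
        MaterialBasis("hydroxyapatite", *ha, reference_concentration=400.0),
    )
    domains = (
        MaterialDomain(("air", "water", "collagen"), label="air-soft-tissue"),
        MaterialDomain(("lipid", "water", "collagen"), label="fat-muscle"),
        MaterialDomain(("water", "collagen", "hydroxyapatite"), label="bone-soft-tissue"),
        MaterialDomain(("water", "air", "iodine"), label="iodine-near-air"),
        MaterialDomain(("water", "iodine", "hydroxyapatite"), label="calcified-with-iodine"),
    )
    return MaterialLibrary(energies=energies, materials=materials, domains=domains)


def augment_library(lib: MaterialLibrary, domain: MaterialDomain) -> MaterialLibrary:
    """Return a new library with ``domain`` appended; ``lib`` is unmodified.

    Raises on unknown vertex materials or a degenerate triangle (the
    library constructor enforces both).
    """
    return MaterialLibrary(
        energies=lib.energies,
        materials=lib.materials,
        domains=lib.domains + (domain,),
    )


def library_vertices(lib: MaterialLibrary) -> np.ndarray:
    """(n_materials, 2) matrix of (HU_low, HU_high) in declaration order."""
    return lib.vertex_matrix()


def save_library(lib: MaterialLibrary, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(lib.to_dict(), sort_keys=False))


def load_library(path: str | Path) -> MaterialLibrary:
    return MaterialLibrary.from_dict(yaml.safe_load(Path(path).read_text()))
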