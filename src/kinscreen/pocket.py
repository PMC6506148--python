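"""Grid-based binding-pocket volumetrics for kinase model ensembles.

Type-II inhibitors bind the hydrophobic pocket opened by the DFG-out flip,
so the size of that pocket is a useful handle for picking, out of a large
homology-model ensemble, the members whose binding site is most open.  The
volume calculation here follows the classic occupancy-grid recipe: lay a
cubic lattice over a user-supplied inclusion region (a union of spheres
around the pocket), mark a lattice point free when it falls inside the
region and clears every atom's van der Waals sphere (optionally padded by
a probe radius), and report volume = free-point count x spacing^3.

The grid is anchored at the minimum corner of the region's bounding box,
so results are bit-reproducible for a given structure/region/spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "StructureModel",
    "InclusionRegion",
    "PocketGrid",
    "read_structure",
    "write_structure",
    "load_region",
    "save_region",
    "pocket_volume",
    "select_models_by_volume",
]

# Heavy-atom van der Waals radii (Angstrom); anything else falls back to carbon.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70
_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class StructureModel:
    """Heavy atoms of one protein model: elements, coordinates (A), radii (A)."""

    model_id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (N, 3)
    radii: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(coords) != len(self.elements) or len(radii) != len(self.elements):
            raise ValueError("elements, coords and radii must have equal length")
        if not np.isfinite(coords).all():
            raise ValueError("coordinates must be finite")
        if len(radii) and (radii <= 0).any():
            raise ValueError("radii must be positive")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "radii", radii)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class InclusionRegion:
    """Union of spheres delimiting the pocket search space."""

    centers: np.ndarray  # (K, 3)
    radii: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(centers) < 1 or len(centers) != len(radii):
            raise ValueError("region needs >= 1 sphere with matching centers/radii")
        if (radii <= 0).any():
            raise ValueError("sphere radii must be positive")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "radii", radii)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = (self.centers - self.radii[:, None]).min(axis=0)
        hi = (self.centers + self.radii[:, None]).max(axis=0)
        return lo, hi


@dataclass(frozen=True)
class PocketGrid:
    """Free lattice points of a pocket; volume = |points| * spacing^3."""

    spacing: float
    points: np.ndarray  # (P, 3) coordinates of free lattice points

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def volume(self) -> float:
        return self.n_points * self.spacing**3


def _read_text(source: str | Path | IO[str]) -> str:
    if hasattr(source, "read"):
        return source.read()
    path = Path(source)
    if path.exists():
        return path.read_text()
    text = str(source)
    if "ATOM" in text or "HETATM" in text:
        return text
    raise FileNotFoundError(f"no such PDB file: {source}")


def read_structure(
    source: str | Path | IO[str],
    model_id: str,
    skip_hydrogens: bool = True,
    skip_waters: bool = True,
) -> StructureModel:
    """Parse ATOM/HETATM records from PDB text into a StructureModel.

    Radii come from the built-in heavy-atom table; unknown elements get the
    carbon default with a warning.  Hydrogens and waters are skipped by
    default (flags to keep them).
    """
    text = _read_text(source)
    if "ATOM" not in text and "HETATM" not in text:
        raise ValueError(f"no ATOM/HETATM records in {model_id!r}")
    st = gemmi.read_pdb_string(text)
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    radii: list[float] = []
    for model in st:
        for chain in model:
            for residue in chain:
                if skip_waters and residue.name.strip() in _WATER_NAMES:
                    continue
                for atom in residue:
                    el = atom.element.name.upper()
                    if skip_hydrogens and el in ("H", "D"):
                        continue
                    if el not in VDW_RADII:
                        warnings.warn(
                            f"unknown element {el!r} in {model_id!r}; "
                            f"using default radius {DEFAULT_RADIUS} A",
                            stacklevel=2,
                        )
                    elements.append(el)
                    coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    radii.append(VDW_RADII.get(el, DEFAULT_RADIUS))
        break  # first MODEL only
    if not elements:
        warnings.warn(f"all atoms of {model_id!r} filtered out", stacklevel=2)
    return StructureModel(
        model_id=model_id,
        elements=tuple(elements),
        coords=np.array(coords, dtype=float).reshape(-1, 3),
        radii=np.array(radii, dtype=float),
    )


def write_structure(structure: StructureModel, dest: str | Path | IO[str]) -> None:
    """Write a minimal PDB (ATOM records only) for round-tripping fixtures."""
    lines = []
    for i, (el, xyz) in enumerate(zip(structure.elements, structure.coords), start=1):
        name = el[:2].rjust(2)
        lines.append(
            f"ATOM  {i:5d} {name:<4s}UNK A{((i - 1) % 9999) + 1:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          {el:>2s}"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def load_region(source: str | Path | IO[str]) -> InclusionRegion:
    """Read an inclusion region from delimited text, one ``x,y,z,r`` per line."""
    rows = np.atleast_2d(np.loadtxt(source, delimiter=",", comments="#", ndmin=2))
    if rows.shape[1] != 4:
        raise ValueError("region file must have four columns: x,y,z,r")
    return InclusionRegion(centers=rows[:, :3], radii=rows[:, 3])


def save_region(region: InclusionRegion, dest: str | Path | IO[str]) -> None:
    data = np.hstack([region.centers, region.radii[:, None]])
    np.savetxt(dest, data, delimiter=",", fmt="%.6f", header="x,y,z,r")


def _lattice(region: InclusionRegion, spacing: float) -> tuple[np.ndarray, tuple[int, int, int]]:
    lo, hi = region.bounding_box()
    counts = tuple(int(np.floor((hi[d] - lo[d]) / spacing + 1e-9)) + 1 for d in range(3))
    axes = [lo[d] + spacing * np.arange(counts[d]) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid, counts  # type: ignore[return-value]


def pocket_volume(
    structure: StructureModel,
    region: InclusionRegion,
    spacing: float = 1.0,
    probe_pad: float = 0.0,
    contiguity_seed: Sequence[float] | None = None,
) -> PocketGrid:
    """Occupancy-grid pocket volume.

    A lattice point (spacing-A cubic grid anchored at the region's
    bounding-box minimum corner) is free iff it lies inside at least one
    inclusion sphere and at distance > (atom radius + probe_pad) from
    every atom.  With ``contiguity_seed`` set, only the 26-connected
    component of free points containing the seed is retained.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if probe_pad < 0:
        raise ValueError("probe_pad must be non-negative")

    grid, counts = _lattice(region, spacing)
    free = np.zeros(len(grid), dtype=bool)
    for c, r in zip(region.centers, region.radii):
        d2 = np.einsum("ij,ij->i", grid - c, grid - c)
        free |= d2 <= r * r
    if structure.n_atoms and free.any():
        idx = np.flatnonzero(free)
        pts = grid[idx]
        blocked = np.zeros(len(pts), dtype=bool)
        # chunk over atoms to bound memory on large structures
        for start in range(0, structure.n_atoms, 512):
            ac = structure.coords[start : start + 512]
            ar = structure.radii[start : start + 512] + probe_pad
            d2 = ((pts[:, None, :] - ac[None, :, :]) ** 2).sum(axis=2)
            blocked |= (d2 <= (ar * ar)[None, :]).any(axis=1)
        free[idx[blocked]] = False

    if contiguity_seed is not None and free.any():
        mask = free.reshape(counts)
        labels, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        lo, _ = region.bounding_box()
        seed_idx = tuple(
            int(np.clip(round((contiguity_seed[d] - lo[d]) / spacing), 0, counts[d] - 1))
            for d in range(3)
        )
        seed_label = labels[seed_idx]
        keep = labels == seed_label if seed_label != 0 else np.zeros_like(mask)
        free = keep.reshape(-1)

    return PocketGrid(spacing=spacing, points=grid[free])


def select_models_by_volume(
    structures: Sequence[StructureModel],
    region: InclusionRegion,
    k: int,
    spacing: float = 1.0,
    probe_pad: float = 0.0,
) -> list[tuple[str, float]]:
    """The min(k, count) models with the largest pocket volume.

    Returns (model_id, volume) pairs sorted by descending volume, ties
    broken by model id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not structures:
        raise ValueError("no structures supplied")
    vols = [
        (s.model_id, pocket_volume(s, region, spacing=spacing, probe_pad=probe_pad).volume)
        for s in structures
    ]
    vols.sort(key=lambda mv: (-mv[1], mv[0]))
    return vols[:k]
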