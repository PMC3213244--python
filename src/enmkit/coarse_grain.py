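"""Build point models that define elastic-network node positions.

A :class:`PointModel` can come from direct atom selection, united-atom
centroids, greedy spherical coarse-graining, density-map contour picking,
or a mixed-resolution combination of an atomic region and a coarse region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import AtomRecord, DensityGrid, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "PointModel",
    "SelectionSpec",
    "select_points",
    "centroid_points",
    "spherical_coarse_grain",
    "density_to_points",
    "mixed_resolution_model",
    "write_points_table",
    "read_points_table",
    "points_to_structure",
]

# backbone atoms excluded from the side-chain group (OXT included)
_BACKBONE = {"N", "CA", "C", "O", "OXT"}
# sugar atom names in nucleotides (primes), used for base_and_sugar grouping
_SUGAR_SUFFIX = "'"
_PHOSPHATE = {"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}

_ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "MN": 54.938, "NA": 22.990, "K": 39.098, "CL": 35.45,
}


@dataclass
class PointModel:
    """N spatial nodes used as elastic-network masses.

    ``labels`` record per-node provenance (``chain/resname/resseq/icode/atom``
    for atoms, ``voxel(i,j,k)`` for density nodes); ``resolution_tag`` is
    'atomic' or 'coarse' per node.
    """

    coords: np.ndarray
    labels: list
    resolution_tag: np.ndarray
    bfactors: Optional[np.ndarray] = None
    source: str = "atoms"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("point coordinates must be finite")
        self.resolution_tag = np.asarray(self.resolution_tag, dtype=object)
        if len(self.labels) != len(self.coords) or len(self.resolution_tag) != len(self.coords):
            raise ValueError("labels/resolution_tag length must match coords")
        if self.bfactors is not None:
            self.bfactors = np.asarray(self.bfactors, dtype=float)
            if len(self.bfactors) != len(self.coords):
                raise ValueError("bfactors length must match coords")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, indices: Sequence[int]) -> "PointModel":
        idx = np.asarray(indices, dtype=int)
        return PointModel(
            coords=self.coords[idx],
            labels=[self.labels[i] for i in idx],
            resolution_tag=self.resolution_tag[idx],
            bfactors=None if self.bfactors is None else self.bfactors[idx],
            source=self.source,
        )


def _atom_label(atom: AtomRecord) -> str:
    return f"{atom.chain}/{atom.resname}/{atom.resseq}{atom.icode}/{atom.name}"


def _group_label(atom: AtomRecord, part: str) -> str:
    return f"{atom.chain}/{atom.resname}/{atom.resseq}{atom.icode}/{part}"


@dataclass
class SelectionSpec:
    """Atom selection criteria; all non-empty criteria must match."""

    names: Optional[set] = None
    chains: Optional[set] = None
    residue_ranges: Optional[list] = None  # list of (lo, hi) inclusive
    elements: Optional[set] = None
    record_types: Optional[set] = None

    def __post_init__(self) -> None:
        if not any([self.names, self.chains, self.residue_ranges,
                    self.elements, self.record_types]):
            raise ValueError("SelectionSpec requires at least one non-empty criterion")

    def matches(self, atom: AtomRecord) -> bool:
        if self.names is not None and atom.name not in self.names:
            return False
        if self.chains is not None and atom.chain not in self.chains:
            return False
        if self.elements is not None and atom.element.upper() not in {
            e.upper() for e in self.elements
        }:
            return False
        if self.record_types is not None and atom.record_type not in self.record_types:
            return False
        if self.residue_ranges is not None:
            if not any(lo <= atom.resseq <= hi for lo, hi in self.residue_ranges):
                return False
        return True


def select_points(structure: Structure, spec: SelectionSpec) -> PointModel:
    """Select atoms matching ``spec`` (file order) as coarse nodes."""
    if structure.n_atoms == 0:
        raise ValueError("structure is empty")
    picked = [a for a in structure.atoms if spec.matches(a)]
    if not picked:
        raise ValueError(f"selection matched no atoms: {spec}")
    return PointModel(
        coords=np.array([a.coords for a in picked]),
        labels=[_atom_label(a) for a in picked],
        resolution_tag=np.array(["coarse"] * len(picked), dtype=object),
        bfactors=np.array([a.bfactor for a in picked]),
        source="atoms",
    )


def _iter_residues(structure: Structure):
    """Yield (residue_key, [atoms]) preserving file order."""
    order: list = []
    groups: dict = {}
    for a in structure.atoms:
        key = a.residue_key
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)
    for key in order:
        yield key, groups[key]


def _centroid(atoms: list, weighting: str) -> np.ndarray:
    xyz = np.array([a.coords for a in atoms])
    if weighting == "mass":
        w = np.array([_ATOMIC_MASS.get(a.element.upper(), 12.011) for a in atoms])
    else:
        w = np.ones(len(atoms))
    return np.average(xyz, axis=0, weights=w)


def centroid_points(structure: Structure, grouping: str = "residue",
                    weighting: str = "uniform") -> PointModel:
    """United-atom model: one node per group at the (weighted) mean position.

    ``grouping`` is 'residue', 'sidechain', or 'base_and_sugar' (the latter
    yields two nodes per nucleotide).  Groups with no member atoms (e.g. a
    glycine side chain) fall back to the full residue centroid (logged).
    """
    if grouping not in ("residue", "sidechain", "base_and_sugar"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if weighting not in ("uniform", "mass"):
        raise ValueError(f"unknown weighting {weighting!r}")

    coords, labels, bf = [], [], []
    for key, atoms in _iter_residues(structure):
        if grouping == "residue":
            parts = [("res", atoms)]
        elif grouping == "sidechain":
            sc = [a for a in atoms if a.name not in _BACKBONE]
            if not sc:
                logger.info("residue %s has no side-chain atoms; using residue centroid", key)
                sc = atoms
            parts = [("sc", sc)]
        else:  # base_and_sugar
            sugar = [a for a in atoms
                     if a.name.endswith(_SUGAR_SUFFIX) or a.name in _PHOSPHATE]
            base = [a for a in atoms
                    if not a.name.endswith(_SUGAR_SUFFIX) and a.name not in _PHOSPHATE]
            parts = []
            if sugar:
                parts.append(("sugar", sugar))
            if base:
                parts.append(("base", base))
            if not parts:
                logger.info("residue %s: no sugar/base atoms; using residue centroid", key)
                parts = [("res", atoms)]
        for part_name, members in parts:
            coords.append(_centroid(members, weighting))
            labels.append(_group_label(members[0], part_name))
            bf.append(float(np.mean([a.bfactor for a in members])))

    return PointModel(
        coords=np.array(coords),
        labels=labels,
        resolution_tag=np.array(["coarse"] * len(coords), dtype=object),
        bfactors=np.array(bf),
        source="centroids",
    )


def spherical_coarse_grain(points: PointModel, radius: float,
                           seed_indices: Optional[Sequence[int]] = None) -> PointModel:
    """Greedy radius-packing: retain seeds, delete all unretained points
    within ``radius`` of the retained set, then retain the closest surviving
    point; repeat until nothing is left.

    "Closest" means closest to the entire retained set (ties broken by
    lowest node index).  The result is a maximal packing: retained points
    are pairwise > radius apart and every removed point is <= radius from
    some retained point.  Output preserves retention order.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    n = points.n_points
    if seed_indices is None or len(seed_indices) == 0:
        logger.info("empty seed list; defaulting to node 0")
        seed_indices = [0]
    seeds = [int(i) for i in seed_indices]
    for s in seeds:
        if not 0 <= s < n:
            raise IndexError(f"seed index {s} out of range for {n} points")

    xyz = points.coords
    retained: list = []
    state = np.zeros(n, dtype=int)  # 0 = candidate, 1 = retained, 2 = removed
    dmin = np.full(n, np.inf)

    def _retain(idx: int) -> None:
        state[idx] = 1
        retained.append(idx)
        d = np.linalg.norm(xyz - xyz[idx], axis=1)
        np.minimum(dmin, d, out=dmin)

    for s in seeds:
        if state[s] == 0:
            _retain(s)

    while True:
        removable = (state == 0) & (dmin <= radius)
        state[removable] = 2
        alive = np.nonzero(state == 0)[0]
        if alive.size == 0:
            break
        nxt = alive[int(np.argmin(dmin[alive]))]
        _retain(nxt)

    return points.subset(retained)


def density_to_points(grid: DensityGrid, threshold: float,
                      packing_radius: float) -> PointModel:
    """Pick elastic-network nodes from a density map.

    Candidates are the centers of all voxels with value >= threshold
    (filled volume); they are spherically coarse-grained at
    ``packing_radius``, seeded at the highest-density voxel.
    """
    if packing_radius <= 0:
        raise ValueError("packing_radius must be > 0")
    mask = grid.values >= threshold
    if not mask.any():
        raise ValueError(
            f"no voxel above threshold {threshold} (grid max {grid.values.max():g})"
        )
    idx = np.argwhere(mask)
    world = grid.origin + idx * grid.voxel_size
    dens = grid.values[mask]
    labels = [f"voxel({i},{j},{k})@{d:g}" for (i, j, k), d in zip(idx, dens)]
    candidates = PointModel(
        coords=world,
        labels=labels,
        resolution_tag=np.array(["coarse"] * len(world), dtype=object),
        source="density",
    )
    seed = int(np.argmax(dens))
    return spherical_coarse_grain(candidates, packing_radius, [seed])


def mixed_resolution_model(structure: Structure, detail_spec: SelectionSpec,
                           coarse_spec: SelectionSpec) -> PointModel:
    """Atomic detail in the region of interest, coarse nodes elsewhere.

    Nodes are the atoms matching ``detail_spec`` (tagged 'atomic') followed
    by the nodes of ``select_points(coarse_spec)`` (tagged 'coarse').  The
    two selections must be disjoint at the residue level.
    """
    detail_atoms = [a for a in structure.atoms if detail_spec.matches(a)]
    coarse_atoms = [a for a in structure.atoms if coarse_spec.matches(a)]
    if not coarse_atoms:
        raise ValueError(f"coarse selection matched no atoms: {coarse_spec}")
    detail_res = {a.residue_key for a in detail_atoms}
    overlap = detail_res & {a.residue_key for a in coarse_atoms}
    if overlap:
        raise ValueError(f"residues matched by both detail and coarse specs: {sorted(overlap)}")

    atoms = detail_atoms + coarse_atoms
    tags = ["atomic"] * len(detail_atoms) + ["coarse"] * len(coarse_atoms)
    return PointModel(
        coords=np.array([a.coords for a in atoms]),
        labels=[_atom_label(a) for a in atoms],
        resolution_tag=np.array(tags, dtype=object),
        bfactors=np.array([a.bfactor for a in atoms]),
        source="mixed" if detail_atoms else "atoms",
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_points_table(points: PointModel, path) -> None:
    """Write a PointModel as a plain-text table (index, x, y, z, tag, label)."""
    lines = [f"# source={points.source}", "# index\tx\ty\tz\ttag\tlabel\tbfactor"]
    bf = points.bfactors if points.bfactors is not None else np.zeros(points.n_points)
    for i in range(points.n_points):
        x, y, z = points.coords[i]
        lines.append(
            f"{i}\t{x:.6f}\t{y:.6f}\t{z:.6f}\t{points.resolution_tag[i]}"
            f"\t{points.labels[i]}\t{bf[i]:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_points_table(path) -> PointModel:
    source = "atoms"
    coords, labels, tags, bf = [], [], [], []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("# source="):
            source = raw.split("=", 1)[1].strip()
            continue
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        tags.append(parts[4])
        labels.append(parts[5])
        bf.append(float(parts[6]) if len(parts) > 6 else 0.0)
    return PointModel(coords=np.array(coords), labels=labels,
                      resolution_tag=np.array(tags, dtype=object),
                      bfactors=np.array(bf), source=source)


def points_to_structure(points: PointModel, bfactors=None) -> Structure:
    """Render nodes as CA pseudo-atoms (ALA, chain A) for viewer export."""
    bf = bfactors if bfactors is not None else (
        points.bfactors if points.bfactors is not None else np.zeros(points.n_points)
    )
    atoms = [
        AtomRecord(serial=i + 1, name="CA", altloc="", resname="ALA", chain="A",
                   resseq=i + 1, icode="", coords=points.coords[i],
                   occupancy=1.0, bfactor=float(bf[i]), element="C")
        for i in range(points.n_points)
    ]
    return Structure(atoms=atoms)
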