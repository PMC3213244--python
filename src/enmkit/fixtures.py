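"""Deterministic synthetic inputs: point lattices, toy helix structures,
mode-deformed ensembles, and Gaussian-blob density grids.

Every stochastic generator takes a mandatory seed so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .coarse_grain import PointModel
from .structure_io import AtomRecord, DensityGrid, Structure, StructureEnsemble

__all__ = [
    "make_lattice",
    "make_helix",
    "make_mode_ensemble",
    "make_blob_map",
    "make_line",
]


def make_lattice(n_per_side: int, spacing: float = 1.0) -> PointModel:
    """Cubic lattice of n^3 nodes with the given spacing (Angstrom)."""
    if n_per_side < 2:
        raise ValueError("n_per_side must be >= 2")
    axis = np.arange(n_per_side) * spacing
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    n = len(grid)
    return PointModel(
        coords=grid,
        labels=[f"lattice/{i}" for i in range(n)],
        resolution_tag=np.array(["coarse"] * n, dtype=object),
        source="atoms",
    )


def make_line(n_points: int, spacing: float = 1.0) -> PointModel:
    """Collinear points on the x-axis at 0, spacing, 2*spacing, ..."""
    coords = np.zeros((n_points, 3))
    coords[:, 0] = np.arange(n_points) * spacing
    return PointModel(
        coords=coords,
        labels=[f"line/{i}" for i in range(n_points)],
        resolution_tag=np.array(["coarse"] * n_points, dtype=object),
        source="atoms",
    )


def make_helix(n_residues: int, rise: float = 1.5, twist: float = 100.0,
               radius: float = 2.3, bfactors: Optional[Sequence[float]] = None
               ) -> Structure:
    """CA-only helical trace; defaults approximate an alpha-helix."""
    if n_residues < 3:
        raise ValueError("n_residues must be >= 3")
    atoms = []
    for i in range(n_residues):
        theta = np.deg2rad(twist) * i
        xyz = np.array([radius * np.cos(theta), radius * np.sin(theta), rise * i])
        b = float(bfactors[i]) if bfactors is not None else 10.0
        atoms.append(AtomRecord(serial=i + 1, name="CA", altloc="", resname="ALA",
                                chain="A", resseq=i + 1, icode="", coords=xyz,
                                occupancy=1.0, bfactor=b, element="C"))
    return Structure(atoms=atoms)


def make_mode_ensemble(points: PointModel, direction: np.ndarray,
                       amplitudes: Sequence[float], noise_sigma: float = 0.0,
                       seed: int = 0) -> StructureEnsemble:
    """Ensemble deformed along a fixed 3N direction.

    frame_k = base + amplitude_k * direction + N(0, sigma) noise.  A rank-1
    generative model, so PCA recovery of ``direction`` is checkable.
    """
    direction = np.asarray(direction, dtype=float).ravel()
    n = points.n_points
    if direction.shape != (3 * n,):
        raise ValueError(f"direction must be a 3N vector (N={n})")
    if abs(np.linalg.norm(direction) - 1.0) > 1e-8:
        raise ValueError("direction must be unit-normalized")
    rng = np.random.default_rng(seed)
    base = points.coords.ravel()
    frames = []
    for k, amp in enumerate(amplitudes):
        xyz = base + amp * direction
        if noise_sigma > 0:
            xyz = xyz + rng.normal(0.0, noise_sigma, size=3 * n)
        coords = xyz.reshape(n, 3)
        atoms = [AtomRecord(serial=i + 1, name="CA", altloc="", resname="ALA",
                            chain="A", resseq=i + 1, icode="", coords=coords[i],
                            occupancy=1.0, bfactor=0.0, element="C")
                 for i in range(n)]
        frames.append(Structure(atoms=atoms, model_id=k + 1))
    return StructureEnsemble(frames=frames)


def make_blob_map(grid_shape: Sequence[int], voxel_size,
                  centers: Sequence, sigmas: Sequence[float],
                  amplitudes: Sequence[float], origin=(0.0, 0.0, 0.0)
                  ) -> DensityGrid:
    """Sum of isotropic Gaussians evaluated at voxel centers."""
    grid_shape = tuple(int(s) for s in grid_shape)
    voxel_size = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    origin = np.asarray(origin, dtype=float)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if not (len(centers) == len(sigmas) == len(amplitudes)):
        raise ValueError("centers, sigmas, amplitudes must have equal length")

    idx = np.indices(grid_shape).reshape(3, -1).T
    world = origin + idx * voxel_size
    values = np.zeros(len(world))
    for c, s, a in zip(centers, sigmas, amplitudes):
        r2 = ((world - c) ** 2).sum(axis=1)
        values += a * np.exp(-r2 / (2.0 * s ** 2))
    return DensityGrid(values=values.reshape(grid_shape),
                       voxel_size=voxel_size, origin=origin)
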