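"""Ensemble superposition, principal component extraction, and mode-subspace
comparison metrics (overlap, cumulative overlap, RMSIP)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .mode_analysis import ModeSet
from .structure_io import StructureEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "OverlapReport",
    "CO_SIGNIFICANCE_THRESHOLD",
    "kabsch_rotation",
    "superpose",
    "pca",
    "variance_profile",
    "overlap",
    "cumulative_overlap",
    "rmsip",
    "compare_pca_modes",
    "compare_modesets",
]

# cumulative overlaps above this value are reported as significant
CO_SIGNIFICANCE_THRESHOLD = 0.5


@dataclass
class PCAResult:
    """Principal components of a superposed ensemble.

    ``components`` holds orthonormal 3N-vectors as columns, variances
    descending.
    """

    mean: np.ndarray          # (N, 3)
    components: np.ndarray    # (3N, K), orthonormal columns
    variances: np.ndarray     # (K,), descending, >= 0

    @property
    def total_variance(self) -> float:
        return float(self.variances.sum())

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def component(self, i: int) -> np.ndarray:
        return self.components[:, i]


@dataclass
class OverlapReport:
    """Pairwise overlaps between two orthonormal vector sets plus summaries.

    ``overlaps[i, j]`` = |P_i . M_j|; ``cumulative[i, k-1]`` = CO of vector
    i against the first k columns of the second set; ``flags`` marks the
    significant cumulative overlaps (CO > 0.5).
    """

    overlaps: np.ndarray       # (I, J)
    cumulative: np.ndarray     # (I, J)
    rmsip: float
    threshold: float = CO_SIGNIFICANCE_THRESHOLD

    @property
    def flags(self) -> np.ndarray:
        return self.cumulative > self.threshold


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal least-squares rotation aligning centered ``mobile`` onto
    centered ``reference`` (proper rotation, det = +1)."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    return vt.T @ diag @ u.T


def _frames_array(frames) -> np.ndarray:
    if isinstance(frames, StructureEnsemble):
        return frames.coordinates()
    arr = np.asarray(frames, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("frames must be (n_frames, n_atoms, 3)")
    return arr


def _check_nondegenerate(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("reference coordinates are collinear/degenerate")


def _align_to(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    ref_c = ref - ref.mean(axis=0)
    out = np.empty_like(frames)
    for k, fr in enumerate(frames):
        c = fr - fr.mean(axis=0)
        rot = kabsch_rotation(c, ref_c)
        out[k] = c @ rot.T + ref.mean(axis=0)
    return out


def superpose(frames, reference: Union[int, str] = "iterative_mean"):
    """Rigidly superpose ensemble frames.

    ``reference`` is a frame index or ``"iterative_mean"`` (align to the
    running mean until it moves < 1e-6 A, max 20 iterations).  Returns
    (aligned (M,N,3) array, per-frame RMSD to the reference).
    """
    arr = _frames_array(frames)
    m, n, _ = arr.shape
    if n < 3:
        raise ValueError("need at least 3 atoms")

    if reference == "iterative_mean":
        # anchor at the raw ensemble mean: already-aligned input is a fixed
        # point, making the operation idempotent to machine precision
        ref = arr.mean(axis=0)
        try:
            _check_nondegenerate(ref)
        except ValueError:
            ref = arr[0]
        _check_nondegenerate(ref)
        aligned = arr
        for _ in range(50):
            aligned = _align_to(arr, ref)
            new_ref = aligned.mean(axis=0)
            shift = np.abs(new_ref - ref).max()
            ref = new_ref
            if shift < 1e-10:
                break
    else:
        ref = arr[int(reference)]
        _check_nondegenerate(ref)
        aligned = _align_to(arr, ref)

    rmsd = np.sqrt(((aligned - ref) ** 2).sum(axis=(1, 2)) / n)
    return aligned, rmsd


def pca(aligned_frames) -> PCAResult:
    """Principal components of flattened coordinate deviations.

    Covariance of the (M, 3N) deviation matrix is diagonalized via SVD;
    at most min(3N, M-1) non-trivial components are returned.
    """
    arr = _frames_array(aligned_frames)
    m, n, _ = arr.shape
    if m < 2:
        raise ValueError("need at least 2 frames")
    flat = arr.reshape(m, 3 * n)
    mean = flat.mean(axis=0)
    dev = flat - mean
    if np.allclose(dev, 0.0):
        raise ValueError("frames are identical: no variance to decompose")

    _, s, vt = np.linalg.svd(dev, full_matrices=False)
    variances = s ** 2 / (m - 1)
    k = min(3 * n, m - 1)
    return PCAResult(mean=mean.reshape(n, 3),
                     components=vt[:k].T.copy(),
                     variances=variances[:k])


def variance_profile(result: PCAResult):
    """Per-component variance fractions and the cumulative curve."""
    total = result.total_variance
    if total <= 0:
        raise ValueError("total variance is zero")
    fractions = result.variances / total
    return fractions, np.cumsum(fractions)


def _as_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError(f"{name} is a zero vector")
    if abs(nrm - 1.0) > 1e-8:
        warnings.warn(f"{name} was not unit-normalized; renormalizing", stacklevel=3)
        v = v / nrm
    return v


def overlap(p: np.ndarray, m: np.ndarray) -> float:
    """|P . M| between two unit vectors (signs are arbitrary)."""
    p = _as_unit(p, "P")
    m = _as_unit(m, "M")
    return float(abs(p @ m))


def cumulative_overlap(p: np.ndarray, modes: np.ndarray) -> float:
    """Root-sum-square overlap of one unit vector with a set of orthonormal
    mode columns: CO(k) = sqrt(sum_j (P . M_j)^2)."""
    p = _as_unit(p, "P")
    modes = np.asarray(modes, dtype=float)
    if modes.ndim != 2:
        raise ValueError("modes must be a (dim, k) column matrix")
    if modes.shape[0] != len(p):
        raise ValueError("dimension mismatch between P and modes")
    dots = modes.T @ p
    return float(min(np.sqrt(np.sum(dots ** 2)), 1.0))


def rmsip(pcs: np.ndarray, modes: np.ndarray) -> float:
    """Root mean square inner product between two orthonormal column sets:
    sqrt((1/I) sum_i sum_j (P_i . M_j)^2)."""
    pcs = np.asarray(pcs, dtype=float)
    modes = np.asarray(modes, dtype=float)
    if pcs.ndim != 2 or modes.ndim != 2:
        raise ValueError("pcs and modes must be column matrices")
    if pcs.shape[1] == 0 or modes.shape[1] == 0:
        raise ValueError("empty vector set")
    if pcs.shape[0] != modes.shape[0]:
        raise ValueError("dimension mismatch")
    inner = pcs.T @ modes
    val = np.sqrt(np.sum(inner ** 2) / pcs.shape[1])
    return float(min(val, 1.0))


def _overlap_report(pset: np.ndarray, mset: np.ndarray) -> OverlapReport:
    inner = np.abs(pset.T @ mset)             # (I, J)
    cum = np.sqrt(np.cumsum(inner ** 2, axis=1))
    cum = np.minimum(cum, 1.0)
    return OverlapReport(overlaps=inner, cumulative=cum,
                         rmsip=rmsip(pset, mset))


def compare_pca_modes(pca_result: PCAResult, modes: ModeSet,
                      n_pcs: int, n_modes: int) -> OverlapReport:
    """Overlap report between the first I PCs and the first J non-zero modes."""
    q = modes.nonzero_eigenvectors()
    if n_modes > q.shape[1]:
        raise ValueError(f"only {q.shape[1]} non-zero modes available")
    if n_pcs > pca_result.n_components:
        raise ValueError(f"only {pca_result.n_components} components available")
    pset = pca_result.components[:, :n_pcs]
    mset = q[:, :n_modes]
    if pset.shape[0] != mset.shape[0]:
        raise ValueError("PCA and mode dimensions differ")
    return _overlap_report(pset, mset)


def compare_modesets(a: ModeSet, b: ModeSet, n_a: int, n_b: int) -> OverlapReport:
    """Overlap report between the non-zero modes of two models of the same
    kind and node count."""
    if a.kind != b.kind:
        raise ValueError("mode sets must have the same kind (both gnm or both anm)")
    if a.dim != b.dim:
        raise ValueError("mode sets have different dimensions")
    qa, qb = a.nonzero_eigenvectors(), b.nonzero_eigenvectors()
    if n_a > qa.shape[1] or n_b > qb.shape[1]:
        raise ValueError("requested more modes than available")
    return _overlap_report(qa[:, :n_a], qb[:, :n_b])
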