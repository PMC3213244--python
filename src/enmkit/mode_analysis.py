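"""Normal-mode solution and every downstream fluctuation quantity.

Eigen-decomposes stiffness matrices (dense or sparse lowest-k), forms the
spectral pseudo-inverse over non-zero modes, and derives mean-square
fluctuations, internal distance fluctuations, cross-correlations,
anisotropic displacement tensors, mode collectivity, subset directional
correlations, B-factor comparison, and mode-animation ensembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.stats import pearsonr

from .coarse_grain import PointModel, points_to_structure
from .enm_build import StiffnessMatrix
from .structure_io import Structure, StructureEnsemble

logger = logging.getLogger(__name__)

__all__ = [
    "ModeSet",
    "FluctuationResult",
    "ZERO_MODE_RTOL",
    "solve_modes",
    "pseudo_inverse",
    "mean_square_fluctuations",
    "internal_distance_fluctuations",
    "cross_correlations",
    "adp_tensors",
    "compare_adp",
    "collectivity",
    "subset_directional_correlation",
    "bfactor_comparison",
    "mode_animation",
]

# eigenvalues below ZERO_MODE_RTOL * lambda_max count as rigid-body modes
ZERO_MODE_RTOL = 1e-8

# B = (8 pi^2 / 3) <dR^2> links mean-square fluctuations to B-factors
B_FACTOR_PREFACTOR = 8.0 * np.pi ** 2 / 3.0


@dataclass
class ModeSet:
    """Eigen-solution of a stiffness matrix.

    Eigenvalues ascend; eigenvector columns are orthonormal and
    sign-fixed (largest-magnitude component positive).  ``n_zero`` counts
    the numerically zero (rigid-body) modes at the head of the spectrum.
    """

    kind: str                       # gnm | anm
    eigenvalues: np.ndarray         # (k,), ascending
    eigenvectors: np.ndarray        # (dim, k)
    n_zero: int
    n_nodes: int
    coords: np.ndarray              # (N, 3) snapshot
    partial: bool = False

    @property
    def dim(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def nonzero_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero:]

    def nonzero_eigenvectors(self) -> np.ndarray:
        return self.eigenvectors[:, self.n_zero:]

    def mode_vector(self, index: int) -> np.ndarray:
        """Eigenvector of mode ``index`` (0-based over the full set)."""
        return self.eigenvectors[:, index]


@dataclass
class FluctuationResult:
    """Per-node mean-square fluctuations plus optional B-factor fit."""

    msf: np.ndarray
    scale: Optional[float] = None       # c in B ~ (8 pi^2/3) c MSF
    pearson_r: Optional[float] = None


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def _count_zero(eigenvalues: np.ndarray, zero_rtol: float) -> int:
    lam_max = float(np.max(np.abs(eigenvalues))) if len(eigenvalues) else 0.0
    if lam_max == 0.0:
        return len(eigenvalues)
    return int(np.sum(eigenvalues < zero_rtol * lam_max))


def solve_modes(stiffness: StiffnessMatrix, n_modes="all", method: str = "dense",
                zero_rtol: float = ZERO_MODE_RTOL) -> ModeSet:
    """Eigen-decompose a stiffness matrix, lowest modes first.

    ``method='dense'`` computes the full spectrum with LAPACK;
    ``method='sparse_lowest'`` uses shift-invert Lanczos to obtain only the
    ``n_modes`` lowest modes (``n_modes`` must then be an integer smaller
    than the matrix dimension).
    """
    dim = stiffness.dim
    if method == "dense":
        vals, vecs = scipy.linalg.eigh(stiffness.dense())
        if n_modes != "all":
            k = int(n_modes)
            if not 1 <= k <= dim:
                raise ValueError(f"n_modes must be in [1, {dim}]")
            vals, vecs = vals[:k], vecs[:, :k]
        partial = n_modes != "all" and int(n_modes) < dim
    elif method == "sparse_lowest":
        if n_modes == "all":
            raise ValueError("sparse_lowest requires an integer n_modes < dim")
        k = int(n_modes)
        if not 1 <= k < dim:
            raise ValueError(f"n_modes must be in [1, {dim - 1}] for sparse_lowest")
        mat = stiffness.matrix if sp.issparse(stiffness.matrix) else sp.csr_matrix(
            stiffness.matrix)
        # shift slightly below zero so the singular matrix can be factorized
        try:
            vals, vecs = spla.eigsh(mat.tocsc(), k=k, sigma=-1e-6, which="LM")
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(
                f"sparse eigensolver failed to converge: "
                f"{len(exc.eigenvalues)}/{k} eigenpairs found"
            ) from exc
        # Rayleigh quotients from the converged vectors are far more accurate
        # than ARPACK's eigenvalue estimates near degeneracies
        vals = np.einsum("ij,ij->j", vecs, mat @ vecs)
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
        partial = True
    else:
        raise ValueError(f"unknown method {method!r}")

    vecs = _fix_signs(vecs)
    n_zero = _count_zero(vals, zero_rtol)
    return ModeSet(kind=stiffness.kind, eigenvalues=vals, eigenvectors=vecs,
                   n_zero=n_zero, n_nodes=stiffness.n_nodes,
                   coords=stiffness.coords, partial=partial)


def pseudo_inverse(modes: ModeSet) -> np.ndarray:
    """Spectral pseudo-inverse: sum of (1/lambda_i) Q_i Q_i^T over non-zero modes."""
    lam = modes.nonzero_eigenvalues()
    if len(lam) == 0:
        raise ValueError("no non-zero modes: pseudo-inverse undefined")
    q = modes.nonzero_eigenvectors()
    return (q / lam) @ q.T


def mean_square_fluctuations(modes: ModeSet) -> FluctuationResult:
    """Per-node MSF: covariance diagonal (gnm) or diagonal-block trace (anm)."""
    cov = pseudo_inverse(modes)
    if modes.kind == "gnm":
        msf = np.diag(cov).copy()
    else:
        d = np.diag(cov)
        msf = d.reshape(-1, 3).sum(axis=1)
    return FluctuationResult(msf=msf)


def internal_distance_fluctuations(modes: ModeSet, pairs: Sequence) -> np.ndarray:
    """Mean-square internal distance change for each requested node pair.

    For the isotropic model this is C_ii + C_jj - 2 C_ij; for the
    anisotropic model the same contraction of the 3x3 covariance blocks is
    projected onto the inter-node unit vector.
    """
    cov = pseudo_inverse(modes)
    out = np.empty(len(pairs))
    for p, (i, j) in enumerate(pairs):
        if i == j:
            raise ValueError(f"pair {p}: i == j == {i}")
        if modes.kind == "gnm":
            out[p] = cov[i, i] + cov[j, j] - 2.0 * cov[i, j]
        else:
            cii = cov[3 * i: 3 * i + 3, 3 * i: 3 * i + 3]
            cjj = cov[3 * j: 3 * j + 3, 3 * j: 3 * j + 3]
            cij = cov[3 * i: 3 * i + 3, 3 * j: 3 * j + 3]
            e = modes.coords[j] - modes.coords[i]
            e = e / np.linalg.norm(e)
            out[p] = float(e @ (cii + cjj - cij - cij.T) @ e)
    return out


def cross_correlations(modes: ModeSet) -> np.ndarray:
    """Normalized fluctuation correlation matrix, diagonal 1, entries in [-1, 1]."""
    cov = pseudo_inverse(modes)
    if modes.kind == "gnm":
        inner = cov
    else:
        n = modes.n_nodes
        inner = np.trace(
            cov.reshape(n, 3, n, 3), axis1=1, axis2=3
        )
    d = np.diag(inner).copy()
    zero = d <= 0
    if zero.any():
        logger.warning("%d nodes have zero MSF; correlations set to 0", zero.sum())
        d[zero] = 1.0
    c = inner / np.sqrt(np.outer(d, d))
    if zero.any():
        c[zero, :] = 0.0
        c[:, zero] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def adp_tensors(modes: ModeSet) -> np.ndarray:
    """Per-node 3x3 displacement tensors (anisotropic models only)."""
    if modes.kind != "anm":
        raise ValueError("ADP tensors require an anisotropic model")
    cov = pseudo_inverse(modes)
    n = modes.n_nodes
    return np.stack([cov[3 * i: 3 * i + 3, 3 * i: 3 * i + 3] for i in range(n)])


def compare_adp(computed: np.ndarray, experimental: np.ndarray):
    """Compare two per-node tensor sets.

    Returns (per_node_similarity, global_pearson): the per-node normalized
    tensor dot product tr(AB)/sqrt(tr(A^2) tr(B^2)), and the Pearson
    correlation over the 6 unique tensor elements across nodes after
    least-squares scaling of the computed set onto the experimental one.
    """
    computed = np.asarray(computed, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if computed.shape != experimental.shape:
        raise ValueError("tensor sets must have the same shape")
    num = np.einsum("nij,nij->n", computed, experimental)
    den = np.sqrt(np.einsum("nij,nij->n", computed, computed)
                  * np.einsum("nij,nij->n", experimental, experimental))
    per_node = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    iu = np.triu_indices(3)
    a = computed[:, iu[0], iu[1]].ravel()
    b = experimental[:, iu[0], iu[1]].ravel()
    scale = float(a @ b / (a @ a)) if a @ a > 0 else 0.0
    r = float(pearsonr(scale * a, b)[0]) if np.std(a) > 0 and np.std(b) > 0 else np.nan
    return per_node, r


def _per_node_weights(modes: ModeSet, mode_index: int) -> np.ndarray:
    v = modes.mode_vector(mode_index)
    if modes.kind == "anm":
        u2 = (v.reshape(-1, 3) ** 2).sum(axis=1)
    else:
        u2 = v ** 2
    return u2 / u2.sum()


def collectivity(modes: ModeSet, mode_index: int) -> float:
    """Exponential-entropy participation measure kappa in (0, 1].

    kappa = exp(-sum u_i^2 ln u_i^2) / N with u_i^2 the per-node squared
    displacement fractions; 1/N for a delta-localized mode, 1 for a
    uniformly collective one.
    """
    if mode_index < modes.n_zero:
        raise ValueError(f"mode {mode_index} is a rigid-body (zero) mode")
    u2 = _per_node_weights(modes, mode_index)
    nz = u2 > 0
    entropy = -float(np.sum(u2[nz] * np.log(u2[nz])))
    return float(np.exp(entropy) / modes.n_nodes)


def subset_directional_correlation(modes: ModeSet, mode_index: int,
                                   partition: Sequence[Sequence[int]]) -> np.ndarray:
    """Cosine similarity of mean displacement vectors between node subsets.

    Entry (a, b) is the cosine of the angle between the average 3-vector
    displacements of subsets a and b in the chosen mode; subsets must be
    disjoint and non-empty.
    """
    if modes.kind != "anm":
        raise ValueError("directional correlations require an anisotropic model")
    if mode_index < modes.n_zero:
        raise ValueError(f"mode {mode_index} is a rigid-body (zero) mode")
    seen: set = set()
    for s, sub in enumerate(partition):
        if len(sub) == 0:
            raise ValueError(f"subset {s} is empty")
        if seen & set(sub):
            raise ValueError("partition subsets must be disjoint")
        seen |= set(sub)

    disp = modes.mode_vector(mode_index).reshape(-1, 3)
    means = np.array([disp[list(sub)].mean(axis=0) for sub in partition])
    norms = np.linalg.norm(means, axis=1)
    s = len(partition)
    out = np.zeros((s, s))
    for a in range(s):
        for b in range(s):
            if norms[a] == 0 or norms[b] == 0:
                logger.warning("subset %d has zero mean displacement; entry set to 0",
                               a if norms[a] == 0 else b)
                out[a, b] = 0.0
            else:
                out[a, b] = float(means[a] @ means[b] / (norms[a] * norms[b]))
    np.fill_diagonal(out, 1.0)
    return np.clip(out, -1.0, 1.0)


def bfactor_comparison(msf: FluctuationResult, experimental_b: Sequence[float]
                       ) -> FluctuationResult:
    """Pearson correlation and least-squares scale between MSF and B-factors.

    Fits c in B_i ~ (8 pi^2 / 3) c MSF_i; the correlation itself is
    prefactor-invariant.
    """
    b = np.asarray(experimental_b, dtype=float)
    m = msf.msf
    if len(b) != len(m):
        raise ValueError("experimental B length must equal node count")
    if len(b) < 3:
        raise ValueError("need at least 3 nodes")
    if np.std(b) == 0:
        raise ValueError("experimental B-factors are constant; correlation undefined")
    r = float(pearsonr(m, b)[0])
    scale = float((m @ b) / (B_FACTOR_PREFACTOR * (m @ m)))
    return FluctuationResult(msf=m, scale=scale, pearson_r=r)


def mode_animation(points: PointModel, modes: ModeSet, mode_index: int,
                   amplitude: float, n_frames: int) -> StructureEnsemble:
    """Oscillate the structure along one mode over a full period.

    Frame t displaces the coordinates by ``amplitude * sin(2 pi t / n_frames)``
    along the mode shape, normalized so its largest per-node displacement is
    1; the sweep covers both the negative and positive mode directions.  The
    peak displacement equals ``amplitude`` exactly when n_frames is a
    multiple of 4.  Per-atom B columns carry the relative node mobility so
    viewers can color by it.
    """
    if modes.kind != "anm":
        raise ValueError("animation requires an anisotropic model")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if mode_index < modes.n_zero:
        raise ValueError(f"mode {mode_index} is a rigid-body (zero) mode")

    shape = modes.mode_vector(mode_index).reshape(-1, 3)
    max_norm = np.linalg.norm(shape, axis=1).max()
    shape = shape / max_norm
    mobility = np.linalg.norm(shape, axis=1)

    frames = []
    base = points.coords
    for t in range(n_frames):
        factor = amplitude * np.sin(2.0 * np.pi * t / n_frames)
        moved = PointModel(coords=base + factor * shape, labels=points.labels,
                           resolution_tag=points.resolution_tag, source=points.source)
        st = points_to_structure(moved, bfactors=mobility)
        st.model_id = t + 1
        frames.append(st)
    return StructureEnsemble(frames=frames)
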