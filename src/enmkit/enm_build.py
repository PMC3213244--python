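"""Stiffness-matrix construction for the supported elastic-network flavors.

Contact assignment schemes:

* ``cutoff``      — uniform spring gamma for every pair within r_c
* ``weighted``    — every pair connected, k_ij = gamma / d_ij**p
* ``nearest_neighbor`` — coarse nodes connected when any atom pair of their
  parent residues is within an atomic-distance cutoff
* ``mixed``       — per-region cutoffs; cross-region pairs use the geometric
  mean of the two cutoffs

From a contact map either the N x N Kirchhoff (graph Laplacian) matrix or
the 3N x 3N anisotropic Hessian is assembled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .coarse_grain import PointModel
from .structure_io import Structure

__all__ = [
    "DEFAULT_CUTOFF",
    "ENMDefinition",
    "ContactMap",
    "StiffnessMatrix",
    "contact_map_cutoff",
    "contact_map_nearest_neighbor",
    "contact_map_weighted",
    "contact_map_mixed",
    "assemble_gnm",
    "assemble_anm",
    "build_stiffness",
    "write_edge_list",
    "read_edge_list",
]

# default interaction cutoffs (Angstrom): 7.3 for the isotropic model,
# 13 for the anisotropic model (upper end of the usual 10-13 band)
DEFAULT_CUTOFF = {"gnm": 7.3, "anm": 13.0}
DEFAULT_ATOMIC_CONTACT_CUTOFF = 4.5


@dataclass
class ENMDefinition:
    """Parameter bundle describing one elastic-network model."""

    kind: str = "anm"                     # gnm | anm
    scheme: str = "cutoff"                # cutoff | weighted | nearest_neighbor | mixed
    cutoff: Optional[float] = None        # r_c, scheme=cutoff (None -> kind default)
    gamma: float = 1.0
    exponent: float = 2.0                 # p, scheme=weighted
    atomic_contact_cutoff: float = DEFAULT_ATOMIC_CONTACT_CUTOFF
    cutoff_pair: Optional[tuple] = None   # (r_atomic, r_coarse), scheme=mixed

    def __post_init__(self) -> None:
        if self.kind not in ("gnm", "anm"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.scheme not in ("cutoff", "weighted", "nearest_neighbor", "mixed"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.atomic_contact_cutoff <= 0:
            raise ValueError("atomic_contact_cutoff must be > 0")
        if self.cutoff_pair is not None:
            if len(self.cutoff_pair) != 2 or any(c <= 0 for c in self.cutoff_pair):
                raise ValueError("cutoff_pair must be two positive lengths")

    @property
    def effective_cutoff(self) -> float:
        return self.cutoff if self.cutoff is not None else DEFAULT_CUTOFF[self.kind]


@dataclass
class ContactMap:
    """Pair list (i, j, k_ij) with i < j; symmetric by construction."""

    i: np.ndarray
    j: np.ndarray
    k: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=int)
        self.j = np.asarray(self.j, dtype=int)
        self.k = np.asarray(self.k, dtype=float)
        if not (len(self.i) == len(self.j) == len(self.k)):
            raise ValueError("i, j, k must have equal length")
        if np.any(self.i == self.j):
            raise ValueError("self-contacts are not allowed")
        if np.any(self.k <= 0):
            raise ValueError("spring constants must be > 0")
        # canonical i < j ordering
        swap = self.i > self.j
        self.i[swap], self.j[swap] = self.j[swap], self.i[swap]

    @property
    def n_contacts(self) -> int:
        return len(self.i)

    def pair_set(self) -> set:
        return set(zip(self.i.tolist(), self.j.tolist()))


def _check_no_coincident(coords: np.ndarray) -> None:
    tree = cKDTree(coords)
    dup = tree.query_pairs(1e-9)
    if dup:
        i, j = sorted(dup)[0]
        raise ValueError(f"coincident nodes {i} and {j} (zero distance)")


def contact_map_cutoff(points: PointModel, r_c: float, gamma: float = 1.0) -> ContactMap:
    """Uniform springs between every pair with d_ij <= r_c (inclusive)."""
    if r_c <= 0:
        raise ValueError("cutoff must be > 0")
    xyz = points.coords
    _check_no_coincident(xyz)
    pairs = cKDTree(xyz).query_pairs(r_c, output_type="ndarray")
    if pairs.size == 0:
        pairs = pairs.reshape(0, 2)
    return ContactMap(i=pairs[:, 0], j=pairs[:, 1],
                      k=np.full(len(pairs), float(gamma)), n_nodes=len(xyz))


_LABEL_RE = re.compile(r"^(?P<chain>[^/]*)/(?P<resname>[^/]*)/(?P<resseq>-?\d+)(?P<icode>[A-Za-z]?)/")


def _residue_key_from_label(label: str):
    m = _LABEL_RE.match(label)
    if m is None:
        return None
    return (m.group("chain"), int(m.group("resseq")), m.group("icode"))


def contact_map_nearest_neighbor(cg_points: PointModel, atomic: Structure,
                                 atomic_cutoff: float = DEFAULT_ATOMIC_CONTACT_CUTOFF,
                                 gamma: float = 1.0) -> ContactMap:
    """Coarse-grained connectivity determined from an atomic model.

    Coarse nodes i, j are in contact iff any pair of atoms drawn from their
    parent residues lies within ``atomic_cutoff``.
    """
    if atomic_cutoff <= 0:
        raise ValueError("atomic_cutoff must be > 0")
    _check_no_coincident(cg_points.coords)

    node_of_residue: dict = {}
    for ni, label in enumerate(cg_points.labels):
        key = _residue_key_from_label(label)
        if key is None:
            raise ValueError(f"node {ni} label {label!r} does not resolve to a residue")
        node_of_residue[key] = ni

    atom_xyz, atom_node = [], []
    for a in atomic.atoms:
        ni = node_of_residue.get(a.residue_key)
        if ni is not None:
            atom_xyz.append(a.coords)
            atom_node.append(ni)
    missing = set(node_of_residue.values()) - set(atom_node)
    if missing:
        raise ValueError(f"coarse nodes with no atoms in the atomic model: {sorted(missing)}")

    atom_xyz = np.asarray(atom_xyz)
    atom_node = np.asarray(atom_node)
    pairs = cKDTree(atom_xyz).query_pairs(atomic_cutoff, output_type="ndarray")
    contacts = set()
    for a, b in pairs:
        ni, nj = atom_node[a], atom_node[b]
        if ni != nj:
            contacts.add((min(ni, nj), max(ni, nj)))
    if contacts:
        ij = np.array(sorted(contacts))
        i, j = ij[:, 0], ij[:, 1]
    else:
        i = j = np.empty(0, dtype=int)
    return ContactMap(i=i, j=j, k=np.full(len(i), float(gamma)),
                      n_nodes=cg_points.n_points)


def contact_map_weighted(points: PointModel, gamma: float = 1.0,
                         exponent: float = 2.0) -> ContactMap:
    """All pairs in contact with distance-dependent springs k = gamma / d**p."""
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    xyz = points.coords
    _check_no_coincident(xyz)
    n = len(xyz)
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(xyz[iu] - xyz[ju], axis=1)
    return ContactMap(i=iu, j=ju, k=gamma / d ** exponent, n_nodes=n)


def contact_map_mixed(points: PointModel, r_atomic: float, r_coarse: float,
                      gamma: float = 1.0) -> ContactMap:
    """Per-pair cutoffs by resolution tag: r_atomic within the atomic region,
    r_coarse within the coarse region, sqrt(r_atomic * r_coarse) across."""
    if r_atomic <= 0 or r_coarse <= 0:
        raise ValueError("both cutoffs must be > 0")
    xyz = points.coords
    _check_no_coincident(xyz)
    r_cross = float(np.sqrt(r_atomic * r_coarse))
    r_max = max(r_atomic, r_coarse, r_cross)
    is_atomic = np.asarray(points.resolution_tag) == "atomic"

    pairs = cKDTree(xyz).query_pairs(r_max, output_type="ndarray")
    if pairs.size == 0:
        return ContactMap(i=np.empty(0, int), j=np.empty(0, int),
                          k=np.empty(0), n_nodes=len(xyz))
    d = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
    ai, aj = is_atomic[pairs[:, 0]], is_atomic[pairs[:, 1]]
    r_pair = np.where(ai & aj, r_atomic, np.where(~ai & ~aj, r_coarse, r_cross))
    keep = d <= r_pair
    pairs = pairs[keep]
    return ContactMap(i=pairs[:, 0], j=pairs[:, 1],
                      k=np.full(len(pairs), float(gamma)), n_nodes=len(xyz))


@dataclass
class StiffnessMatrix:
    """Kirchhoff (N x N) or Hessian (3N x 3N) matrix plus build context."""

    kind: str
    matrix: object            # scipy sparse or dense ndarray, symmetric PSD
    coords: np.ndarray
    definition: ENMDefinition

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sp.issparse(m) else np.asarray(m)


def assemble_gnm(contacts: ContactMap, coords: np.ndarray,
                 definition: Optional[ENMDefinition] = None) -> StiffnessMatrix:
    """Kirchhoff matrix: off-diagonal -k_ij for contacts, diagonal = row degree."""
    n = contacts.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    i, j, k = contacts.i, contacts.j, contacts.k
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    vals = np.concatenate([-k, -k, k, k])
    gamma_mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    if definition is None:
        definition = ENMDefinition(kind="gnm")
    return StiffnessMatrix(kind="gnm", matrix=gamma_mat,
                           coords=np.asarray(coords, dtype=float), definition=definition)


def assemble_anm(contacts: ContactMap, coords: np.ndarray,
                 definition: Optional[ENMDefinition] = None) -> StiffnessMatrix:
    """3N x 3N Hessian from 3x3 super-elements.

    Off-diagonal block H_ij = -(k_ij / d_ij^2) * r_ij r_ij^T for contacting
    pairs; diagonal blocks make each row-block sum to zero.
    """
    coords = np.asarray(coords, dtype=float)
    n = contacts.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if coords.shape != (n, 3):
        raise ValueError("coords must be (n_nodes, 3)")

    i, j, k = contacts.i, contacts.j, contacts.k
    rij = coords[j] - coords[i]
    d2 = np.einsum("ij,ij->i", rij, rij)
    if np.any(d2 <= 1e-18):
        raise ValueError("coincident contacting nodes")
    # per-contact 3x3 block (k/d^2) * outer(r, r)
    blocks = (k / d2)[:, None, None] * np.einsum("ci,cj->cij", rij, rij)

    rows, cols, vals = [], [], []
    bx, by = np.meshgrid(np.arange(3), np.arange(3), indexing="ij")
    bx, by = bx.ravel(), by.ravel()
    for c in range(len(i)):
        bi, bj = 3 * i[c], 3 * j[c]
        b = blocks[c].ravel()
        rows.extend((bi + bx).tolist() + (bj + bx).tolist()
                    + (bi + bx).tolist() + (bj + bx).tolist())
        cols.extend((bj + by).tolist() + (bi + by).tolist()
                    + (bi + by).tolist() + (bj + by).tolist())
        vals.extend((-b).tolist() + (-b).tolist() + b.tolist() + b.tolist())
    hess = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()
    if definition is None:
        definition = ENMDefinition(kind="anm")
    return StiffnessMatrix(kind="anm", matrix=hess, coords=coords, definition=definition)


def build_stiffness(points: PointModel, definition: ENMDefinition,
                    atomic: Optional[Structure] = None) -> StiffnessMatrix:
    """One-call pipeline: contact map per ``definition.scheme``, then assembly."""
    if definition.scheme == "cutoff":
        cm = contact_map_cutoff(points, definition.effective_cutoff, definition.gamma)
    elif definition.scheme == "weighted":
        cm = contact_map_weighted(points, definition.gamma, definition.exponent)
    elif definition.scheme == "nearest_neighbor":
        if atomic is None:
            raise ValueError("nearest_neighbor scheme requires an atomic Structure")
        cm = contact_map_nearest_neighbor(points, atomic,
                                          definition.atomic_contact_cutoff,
                                          definition.gamma)
    else:  # mixed
        if definition.cutoff_pair is None:
            raise ValueError("mixed scheme requires cutoff_pair=(r_atomic, r_coarse)")
        cm = contact_map_mixed(points, *definition.cutoff_pair, definition.gamma)

    assemble = assemble_gnm if definition.kind == "gnm" else assemble_anm
    sm = assemble(cm, points.coords, definition)
    if definition.scheme == "weighted":
        sm.matrix = sm.dense()  # complete graph: dense storage
    return sm


def write_edge_list(contacts: ContactMap, path) -> None:
    """3-column text edge list (i, j, k_ij), 0-based indices."""
    lines = [f"# n_nodes={contacts.n_nodes}"]
    for i, j, k in zip(contacts.i, contacts.j, contacts.k):
        lines.append(f"{i}\t{j}\t{k:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path) -> ContactMap:
    n_nodes = None
    i, j, k = [], [], []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("# n_nodes="):
            n_nodes = int(raw.split("=", 1)[1])
            continue
        if not raw.strip() or raw.startswith("#"):
            continue
        a, b, c = raw.split("\t")
        i.append(int(a)); j.append(int(b)); k.append(float(c))
    if n_nodes is None:
        n_nodes = max(max(i, default=0), max(j, default=0)) + 1
    return ContactMap(i=np.array(i, int), j=np.array(j, int),
                      k=np.array(k), n_nodes=n_nodes)
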