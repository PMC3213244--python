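"""Readers and writers for the structure formats the toolkit touches.

Supports fixed-column PDB (ATOM/HETATM/ANISOU, multi-MODEL) and MRC/CCP4
density maps.  The PDB writer emits multi-MODEL files suitable for
animation playback in any molecular viewer.

All coordinates are in Angstrom; no unit conversion is performed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "Structure",
    "StructureEnsemble",
    "DensityGrid",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "read_density_map",
    "write_density_map",
]


class PDBParseError(ValueError):
    """Raised when a fixed-column PDB record cannot be parsed."""


@dataclass
class AtomRecord:
    """A single ATOM/HETATM record with an optional anisotropic U tensor.

    ``anisou`` stores (U11, U22, U33, U12, U13, U23) in A^2, i.e. the file's
    integer values divided by 1e4.
    """

    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    anisou: Optional[np.ndarray] = None
    record_type: str = "ATOM"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.anisou is not None:
            self.anisou = np.asarray(self.anisou, dtype=float)
            if self.anisou.shape != (6,):
                raise ValueError("anisou must be a 6-vector (U11,U22,U33,U12,U13,U23)")

    @property
    def u_tensor(self) -> Optional[np.ndarray]:
        """The 3x3 symmetric displacement tensor in A^2, or None."""
        if self.anisou is None:
            return None
        u11, u22, u33, u12, u13, u23 = self.anisou
        return np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])

    @property
    def residue_key(self) -> tuple:
        return (self.chain, self.resseq, self.icode)


@dataclass
class Structure:
    """An ordered collection of atoms from one MODEL of a PDB file."""

    atoms: list
    model_id: int = 1

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def bfactors(self) -> np.ndarray:
        return np.array([a.bfactor for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class StructureEnsemble:
    """An ordered list of Structure frames (multi-MODEL file / trajectory)."""

    frames: list

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def corresponding(self) -> bool:
        """True when every frame matches frame 0 in atom count and identity."""
        if not self.frames:
            return False
        ref = [(a.name, a.resseq, a.chain) for a in self.frames[0].atoms]
        for fr in self.frames[1:]:
            if [(a.name, a.resseq, a.chain) for a in fr.atoms] != ref:
                return False
        return True

    def coordinates(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array; requires correspondence."""
        if not self.corresponding:
            raise ValueError("frames do not share an atom correspondence")
        return np.stack([fr.coords for fr in self.frames])


@dataclass
class DensityGrid:
    """A scalar density grid.  ``values`` is indexed [ix, iy, iz] (x fastest
    in memory order of the first axis); world position of voxel (i,j,k) is
    ``origin + (i,j,k) * voxel_size``."""

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    axis_order: tuple = (1, 2, 3)  # original file MAPC/MAPR/MAPS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D array with all dims >= 1")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be > 0")

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (nvox, 3)."""
        nx, ny, nz = self.values.shape
        idx = np.indices((nx, ny, nz)).reshape(3, -1).T
        return self.origin + idx * self.voxel_size


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_KEPT_ALTLOCS = ("", " ", "A")


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip()
        resseq = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    occ_s = line[54:60].strip()
    b_s = line[60:66].strip()
    occupancy = float(occ_s) if occ_s else 1.0
    bfactor = float(b_s) if b_s else 0.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to first alphabetic character of the atom name
        for ch in name:
            if ch.isalpha():
                element = ch.upper()
                break
    return AtomRecord(
        serial=serial, name=name, altloc=altloc, resname=resname, chain=chain,
        resseq=resseq, icode=icode, coords=np.array([x, y, z]),
        occupancy=occupancy, bfactor=bfactor, element=element,
        record_type=line[:6].strip(),
    )


def _parse_anisou_line(line: str, lineno: int) -> tuple:
    try:
        serial = int(line[6:11])
        vals = [int(line[28 + 7 * i: 35 + 7 * i]) for i in range(6)]
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed ANISOU record: {exc}") from exc
    return serial, np.array(vals, dtype=float) / 1.0e4


def read_pdb(path, model_policy: str = "first"):
    """Read a fixed-column PDB file.

    Parameters
    ----------
    path : file path
    model_policy : "first" or "all"
        "first" returns a single :class:`Structure` (the first MODEL);
        "all" returns a :class:`StructureEnsemble` with one frame per
        MODEL record (a single frame if the file has no MODEL records).

    ANISOU rows are attached to the preceding ATOM/HETATM with the same
    serial; the file's integers are interpreted as U x 1e4 A^2.  Alternate
    locations other than blank or 'A' are dropped (counts logged).
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    path = Path(path)
    frames: list = []
    atoms: list = []
    model_id = 1
    in_model = False
    saw_model = False
    n_altloc_dropped = 0
    last_atom: Optional[AtomRecord] = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                in_model = True
                try:
                    model_id = int(raw.split()[1])
                except (IndexError, ValueError):
                    model_id = len(frames) + 1
                atoms = []
                last_atom = None
            elif rec.startswith("ENDMDL"):
                frames.append(Structure(atoms=atoms, model_id=model_id))
                if model_policy == "first":
                    break
                atoms = []
                in_model = False
                last_atom = None
            elif rec.startswith(("ATOM", "HETATM")):
                atom = _parse_atom_line(raw, lineno)
                if atom.altloc not in _KEPT_ALTLOCS:
                    n_altloc_dropped += 1
                    last_atom = None
                    continue
                atoms.append(atom)
                last_atom = atom
            elif rec.startswith("ANISOU"):
                serial, u = _parse_anisou_line(raw, lineno)
                if last_atom is not None and last_atom.serial == serial:
                    last_atom.anisou = u
                else:
                    logger.warning(
                        "line %d: ANISOU serial %d has no matching ATOM; dropped",
                        lineno, serial,
                    )

    if atoms and (not saw_model or in_model):
        frames.append(Structure(atoms=atoms, model_id=model_id))
    if n_altloc_dropped:
        logger.info("dropped %d alternate-location atoms (kept blank/'A')", n_altloc_dropped)
    if not frames:
        raise PDBParseError(f"{path}: no atoms found")

    if model_policy == "first":
        return frames[0]
    return StructureEnsemble(frames=frames)


def _format_atom_name(name: str) -> str:
    # standard rule: names shorter than 4 chars start in column 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _atom_line(atom: AtomRecord, serial: int, bfactor: float) -> str:
    x, y, z = atom.coords
    if max(abs(x), abs(y), abs(z)) >= 10000.0:
        raise ValueError(
            f"coordinate magnitude >= 10000 A breaks fixed columns (atom serial {atom.serial})"
        )
    rec = atom.record_type if atom.record_type in ("ATOM", "HETATM") else "ATOM"
    return (
        f"{rec:<6s}{serial:>5d} {_format_atom_name(atom.name)}{atom.altloc or ' ':1s}"
        f"{atom.resname:>3s} {atom.chain or 'A':1s}{atom.resseq:>4d}{atom.icode or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{bfactor:6.2f}"
        f"          {atom.element:>2s}"
    )


def _anisou_line(atom: AtomRecord, serial: int) -> str:
    ints = np.rint(atom.anisou * 1.0e4).astype(int)
    body = "".join(f"{v:7d}" for v in ints)
    return (
        f"ANISOU{serial:>5d} {_format_atom_name(atom.name)}{atom.altloc or ' ':1s}"
        f"{atom.resname:>3s} {atom.chain or 'A':1s}{atom.resseq:>4d}{atom.icode or ' ':1s} "
        f"{body}      {atom.element:>2s}"
    )


def write_pdb(obj, path, bfactor_override: Optional[Sequence[float]] = None) -> None:
    """Write a Structure or StructureEnsemble as a fixed-column PDB file.

    Multi-frame input is wrapped in MODEL/ENDMDL pairs numbered from 1.
    ``bfactor_override`` replaces every frame's per-atom B column.
    """
    if isinstance(obj, Structure):
        frames = [obj]
        multi = False
    elif isinstance(obj, StructureEnsemble):
        frames = obj.frames
        multi = True
    else:
        raise TypeError("expected Structure or StructureEnsemble")

    if bfactor_override is not None:
        bfactor_override = np.asarray(bfactor_override, dtype=float)
        for fr in frames:
            if len(bfactor_override) != fr.n_atoms:
                raise ValueError("bfactor_override length must equal atom count")

    lines = []
    for k, fr in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {k:>4d}")
        for i, atom in enumerate(fr.atoms):
            b = float(bfactor_override[i]) if bfactor_override is not None else atom.bfactor
            lines.append(_atom_line(atom, atom.serial, b))
            if atom.anisou is not None:
                lines.append(_anisou_line(atom, atom.serial))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MRC / CCP4 density maps
# ---------------------------------------------------------------------------

_SUPPORTED_MODES = {0, 1, 2, 6, 12}


def read_density_map(path) -> DensityGrid:
    """Read an MRC/CCP4 density map into a :class:`DensityGrid`.

    The grid is reordered so the first array axis is X regardless of the
    file's MAPC/MAPR/MAPS convention; the original order is recorded in
    ``axis_order``.  Only orthogonal cells are supported.
    """
    import mrcfile

    with mrcfile.open(str(path), permissive=True) as mrc:
        header = mrc.header
        mode = int(header.mode)
        if mode not in _SUPPORTED_MODES:
            raise ValueError(f"unsupported MRC mode {mode}")
        angles = np.array([header.cellb.alpha, header.cellb.beta, header.cellb.gamma])
        if not np.allclose(angles, 90.0, atol=1e-3):
            raise ValueError("non-orthogonal cells are unsupported")

        mapc, mapr, maps_ = int(header.mapc), int(header.mapr), int(header.maps)
        data = np.asarray(mrc.data, dtype=float)  # indexed [sections, rows, cols]
        # axis i of `data` corresponds to crystal axis (maps_, mapr, mapc)[i]
        file_axes = (maps_, mapr, mapc)
        perm = [file_axes.index(ax) for ax in (1, 2, 3)]  # put x,y,z in order
        values = np.transpose(data, axes=perm)

        vx = np.array(mrc.voxel_size.tolist(), dtype=float)
        origin = np.array(mrc.header.origin.tolist(), dtype=float)
        nstart = np.array(
            [int(header.nxstart), int(header.nystart), int(header.nzstart)], dtype=float
        )
        if np.allclose(origin, 0.0) and np.any(nstart != 0):
            origin = nstart * vx

    return DensityGrid(values=values, voxel_size=vx, origin=origin,
                       axis_order=(mapc, mapr, maps_))


def write_density_map(grid: DensityGrid, path) -> None:
    """Write a DensityGrid to an MRC file (mode 2, X-fastest convention)."""
    import mrcfile

    data = np.transpose(grid.values, (2, 1, 0)).astype(np.float32)  # -> [z, y, x]
    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(data)
        mrc.voxel_size = tuple(grid.voxel_size)
        mrc.header.origin = tuple(grid.origin)
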