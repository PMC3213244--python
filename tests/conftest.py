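import numpy as np
import pytest

from enmkit import coarse_grain as cg
from enmkit import enm_build as eb
from enmkit import fixtures as fx
from enmkit import mode_analysis as ma
from enmkit.structure_io import AtomRecord, Structure


def point_model(coords, tags=None, bfactors=None):
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    return cg.PointModel(
        coords=coords,
        labels=[f"p/{i}" for i in range(n)],
        resolution_tag=np.array(tags if tags is not None else ["coarse"] * n,
                                dtype=object),
        bfactors=bfactors,
        source="atoms",
    )


def simple_atom(serial, name="CA", resseq=None, chain="A", coords=(0, 0, 0),
                bfactor=10.0, element="C", resname="ALA"):
    return AtomRecord(serial=serial, name=name, altloc="", resname=resname,
                      chain=chain, resseq=resseq if resseq is not None else serial,
                      icode="", coords=np.asarray(coords, float),
                      occupancy=1.0, bfactor=bfactor, element=element)


@pytest.fixture
def path3_gnm_modes():
    """3 collinear nodes at x = 0, 5, 10; contacts (0,1), (1,2); gamma = 1."""
    pts = point_model([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
    contacts = eb.contact_map_cutoff(pts, 7.3, 1.0)
    stiff = eb.assemble_gnm(contacts, pts.coords)
    return ma.solve_modes(stiff)


@pytest.fixture
def lattice27():
    return fx.make_lattice(3, 1.0)


@pytest.fixture
def lattice27_anm_modes(lattice27):
    d = eb.ENMDefinition(kind="anm", scheme="cutoff", cutoff=2.0)
    return ma.solve_modes(eb.build_stiffness(lattice27, d))


@pytest.fixture
def helix10():
    rng = np.random.default_rng(7)
    return fx.make_helix(10, bfactors=10.0 + rng.uniform(0, 5, 10))
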