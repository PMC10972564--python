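import numpy as np
import pytest

from erksel.geometry import Atom, StructureModel
from erksel.synthetic import default_panel, default_peptides, default_probes


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def peptides():
    return default_peptides()


@pytest.fixture(scope="session")
def probes():
    return default_probes()


@pytest.fixture(scope="session")
def conformation_segments(peptides):
    """The DFG and P+1 peptides used for classification."""
    return [p for p in peptides if p.name in ("DFG", "P+1")]


def make_ca_model(resnums, coords, chain="A"):
    return StructureModel(
        [
            Atom(chain, int(r), "ALA", "CA", "C", 1.0, tuple(map(float, c)))
            for r, c in zip(resnums, coords)
        ]
    )


def rigid_transform(coords, angle_deg=30.0, axis=(0.0, 0.0, 1.0), shift=(1.0, -2.0, 3.0)):
    """Apply a known proper rigid transform to an (n, 3) array."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
    return coords @ rot.T + np.asarray(shift, float)


def pdb_atom_line(serial, name, resname, chain, resnum, xyz, occ=1.0, altloc=" ",
                  element=None):
    element = element or name[0]
    x, y, z = xyz
    padded_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {padded_name}{altloc}{resname:<3s} {chain}{resnum:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2s}"
    )
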