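"""Shared fixtures: minimal PDB texts and randomized toy structures."""

from __future__ import annotations

import numpy as np
import pytest

from phdelta.fixtures import _PosedResidue
from phdelta.pka import assign_model_pkas
from phdelta.structure_model import StructureModel, parse_structure, write_pdb


def pdb_atom_line(serial, name, res_name, chain, res_seq, x, y, z,
                  b=20.0, element=None, alt_loc=" ", occupancy=1.00):
    element = element or name[0]
    padded = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (f"ATOM  {serial:>5d} {padded}{alt_loc}{res_name:>3s} {chain}"
            f"{res_seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{b:6.2f}"
            f"          {element:>2s}")


def glycine_lines(chain="A", res_seq=1, offset=(0.0, 0.0, 0.0), b=20.0, serial0=1):
    ox, oy, oz = offset
    coords = {"N": (0.0, 0.0, 0.0), "CA": (1.46, 0.0, 0.0),
              "C": (2.0, 1.4, 0.0), "O": (1.4, 2.4, 0.3)}
    return [
        pdb_atom_line(serial0 + i, name, "GLY", chain, res_seq,
                      x + ox, y + oy, z + oz, b=b)
        for i, (name, (x, y, z)) in enumerate(coords.items())
    ]


@pytest.fixture
def glycine_pdb():
    return "\n".join(glycine_lines()) + "\nEND\n"


@pytest.fixture
def tripeptide_pdb():
    """Three glycines along x with B-factors 90 / 60 / 90."""
    lines = []
    for i, b in enumerate([90.0, 60.0, 90.0]):
        lines += glycine_lines(res_seq=i + 1, offset=(4.0 * i, 0, 0),
                               b=b, serial0=1 + 4 * i)
    return "\n".join(lines) + "\nEND\n"


# --- randomized structures for oracle comparisons -----------------------------

ORACLE_RESIDUES = ["ASP", "GLU", "LYS", "ARG", "HIS", "SER", "PHE", "TYR", "TRP"]


def random_model(rng: np.random.Generator, n_residues: int = 8,
                 box: float = 14.0) -> StructureModel:
    """Residues with ideal internal geometry, random pose, random spread.

    Residue numbers advance by random gaps of 1-4 so the sequence-adjacency
    exclusion is exercised.  Emitted as PDB text and re-read through the
    public parser so the oracle comparisons exercise the real I/O path.
    """
    from scipy.spatial.transform import Rotation

    residues = []
    serial = 1
    res_seq = 2
    for i in range(n_residues):
        name = ORACLE_RESIDUES[rng.integers(len(ORACLE_RESIDUES))]
        posed = _PosedResidue(name, hydrogens=False)
        rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        posed.coords = posed.coords @ rot.T + rng.uniform(0, box, size=3)
        res = posed.to_residue("A", res_seq, serial)
        res_seq += int(rng.integers(1, 5))
        serial += len(posed.names)
        residues.append(res)
    draft = StructureModel(structure_id="random", chains={"A": tuple(residues)})
    return parse_structure(write_pdb(draft), structure_id="random")


@pytest.fixture
def make_random_system():
    def _make(seed: int, n_residues: int = 8):
        rng = np.random.default_rng(seed)
        model = random_model(rng, n_residues)
        pkas = assign_model_pkas(model)
        ph = float(rng.uniform(2.0, 12.0))
        return model, pkas, ph
    return _make
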