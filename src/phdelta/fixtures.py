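"""Programmatic toy structures and peptides with controlled geometry.

Every interaction detector and the whole structure pipeline can be
exercised on structures built here: pairs of residues posed at an exact
inter-group distance, ring stacks, and clusters of titratable residues.
Internal residue geometry comes from ideal residue templates (chemical
component dictionary coordinates bundled with biotite); the requested
inter-group distance is then realized to better than 0.01 A by translating
one residue along the approach axis and verifying the measured distance on
the emitted structure.

Fixtures are emitted as genuine PDB text and re-read through the public
parser, so tests exercise the real I/O path rather than internal
constructors.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np

from .interactions import ARG_GUANIDINIUM, RING_ATOMS
from .pka import GroupKey, PkaEntry, PkaSet, SIDE_CHAIN, assign_model_pkas
from .sequence_charge import IONIZABLE_RESIDUES
from .structure_model import (
    Atom, Residue, StructureModel, parse_structure, write_pdb,
)

MOTIFS = ("salt_bridge_pair", "hbond_pair", "ring_stack",
          "cation_pi_pair", "shifting_cluster")

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one toy structure.

    ``distance`` is the controlled inter-group distance in Angstrom (for
    ``shifting_cluster`` the pairwise ring-centroid spacing of the cluster
    members); ``pka_overrides`` maps author residue numbers to side-chain
    pKa values that replace the model-table defaults in the returned pKa
    set; ``hydrogens`` keeps the template hydrogens in the emitted PDB.
    """

    motif: str
    distance: float = 4.0
    n_members: int = 3                      # shifting_cluster only
    pka_overrides: dict[int, float] = field(default_factory=dict)
    hydrogens: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif not in MOTIFS:
            raise ValueError(f"unknown motif {self.motif!r}; choose from {MOTIFS}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


def _template_coords(res_name: str, hydrogens: bool) -> tuple[list[str], list[str], np.ndarray]:
    import biotite.structure.info as info

    arr = info.residue(res_name)
    keep = [i for i, (name, elem) in enumerate(zip(arr.atom_name, arr.element))
            if name not in ("OXT", "HXT", "H2") and (hydrogens or elem != "H")]
    names = [str(arr.atom_name[i]) for i in keep]
    elements = [str(arr.element[i]) for i in keep]
    return names, elements, np.asarray(arr.coord[keep], dtype=float)


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit direction of a onto unit direction of b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


class _PosedResidue:
    """A residue template with helpers to orient and translate it."""

    def __init__(self, res_name: str, hydrogens: bool = False):
        self.res_name = res_name
        self.names, self.elements, self.coords = _template_coords(res_name, hydrogens)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def anchor(self, atom_names: tuple[str, ...]) -> np.ndarray:
        idx = [self.index(n) for n in atom_names]
        return self.coords[idx].mean(axis=0)

    def orient(self, anchor_names: tuple[str, ...], direction: np.ndarray) -> None:
        """Put the anchor at the origin with (anchor - CA) along direction."""
        anchor = self.anchor(anchor_names)
        ca = self.coords[self.index("CA")]
        rot = _rotation_onto(anchor - ca, np.asarray(direction, dtype=float))
        self.coords = (self.coords - anchor) @ rot.T

    def translate(self, shift: np.ndarray) -> None:
        self.coords = self.coords + np.asarray(shift, dtype=float)

    def to_residue(self, chain_id: str, res_seq: int, serial0: int) -> Residue:
        atoms = tuple(
            Atom(name=n, element=e.upper(), coords=tuple(float(v) for v in xyz),
                 b_factor=90.0, serial=serial0 + i)
            for i, (n, e, xyz) in enumerate(zip(self.names, self.elements, self.coords))
        )
        return Residue(chain_id, res_seq, "", self.res_name, atoms)


#: (res_a, anchor_a, group_a) / (res_b, anchor_b, group_b) per pair motif;
#: group atoms are the ones over which the controlled minimum distance is taken.
_PAIR_MOTIFS = {
    "salt_bridge_pair": (
        ("ARG", ("NH1",), ("NH1", "NH2", "NE")),
        ("GLU", ("OE1",), ("OE1", "OE2")),
    ),
    "hbond_pair": (
        ("SER", ("OG",), ("OG",)),
        ("HIS", ("NE2",), ("NE2",)),
    ),
    "ring_stack": (
        ("HIS", RING_ATOMS["HIS"]["ring"], None),
        ("HIS", RING_ATOMS["HIS"]["ring"], None),
    ),
    "cation_pi_pair": (
        ("ARG", ARG_GUANIDINIUM, None),
        ("HIS", RING_ATOMS["HIS"]["ring"], None),
    ),
}


def _group_min_distance(res_a: Residue, group_a, res_b: Residue, group_b) -> float:
    """Minimum distance between two atom groups (None = centroid anchor)."""

    def points(res: Residue, group) -> np.ndarray:
        if group is None:
            return np.array([[0.0, 0.0, 0.0]])  # unused
        return np.array([res.atom(n).coords for n in group])

    return float(np.min(np.linalg.norm(
        points(res_a, group_a)[:, None, :] - points(res_b, group_b)[None, :, :],
        axis=-1)))


def measure_motif_distance(model: StructureModel, spec: FixtureSpec) -> float:
    """Recompute the controlled distance on an emitted model (verification)."""
    residues = [r for r in model.residues()]
    if spec.motif == "shifting_cluster":
        centroids = [
            np.mean([r.atom(n).coords for n in RING_ATOMS[r.res_name]["ring"]], axis=0)
            for r in residues
        ]
        # nearest-neighbour ring-centroid spacing (= polygon side length)
        return min(
            float(np.linalg.norm(centroids[i] - centroids[j]))
            for i in range(len(centroids)) for j in range(i + 1, len(centroids))
        )
    (name_a, anchor_a, group_a), (name_b, anchor_b, group_b) = _PAIR_MOTIFS[spec.motif]
    res_a, res_b = residues[0], residues[1]
    if group_a is None or group_b is None:
        cen_a = np.mean([res_a.atom(n).coords for n in anchor_a], axis=0)
        cen_b = np.mean([res_b.atom(n).coords for n in anchor_b], axis=0)
        return float(np.linalg.norm(cen_a - cen_b))
    return _group_min_distance(res_a, group_a, res_b, group_b)


_MIN_CONTACT_DIST = 1.5  # Angstrom: below this the groups would sterically overlap


def _build_pair(spec: FixtureSpec) -> list[Residue]:
    if spec.distance < _MIN_CONTACT_DIST:
        raise ValueError(
            f"{spec.motif} at {spec.distance} A is not achievable: the groups "
            f"would interpenetrate (minimum {_MIN_CONTACT_DIST} A)"
        )
    (name_a, anchor_a, group_a), (name_b, anchor_b, group_b) = _PAIR_MOTIFS[spec.motif]
    a = _PosedResidue(name_a, spec.hydrogens)
    b = _PosedResidue(name_b, spec.hydrogens)
    a.orient(anchor_a, np.array([1.0, 0.0, 0.0]))
    b.orient(anchor_b, np.array([-1.0, 0.0, 0.0]))
    b.translate([spec.distance, 0.0, 0.0])

    res_a = a.to_residue("A", 2, 1)
    res_b = b.to_residue("A", 10, 1 + len(a.names))
    if group_a is not None:
        # adjust until the measured group-minimum distance hits the target
        # (the minimum is 1-Lipschitz in the translation, so this converges)
        for _ in range(50):
            err = spec.distance - _group_min_distance(res_a, group_a, res_b, group_b)
            if abs(err) < 1e-4:
                break
            b.translate([err, 0.0, 0.0])
            res_b = b.to_residue("A", 10, 1 + len(a.names))
        else:
            raise ValueError(
                f"cannot realize {spec.motif} at {spec.distance} A with ideal "
                "residue geometry (residues would interpenetrate)"
            )
    return [res_a, res_b]


def _build_cluster(spec: FixtureSpec) -> list[Residue]:
    if spec.n_members < 2:
        raise ValueError("shifting_cluster needs at least 2 members")
    if spec.distance < _MIN_CONTACT_DIST:
        raise ValueError(
            f"cluster spacing {spec.distance} A is not achievable without "
            f"steric overlap (minimum {_MIN_CONTACT_DIST} A)"
        )
    # ring centroids on a regular polygon with side length == spec.distance
    n = spec.n_members
    circumradius = spec.distance / (2.0 * np.sin(np.pi / n))
    residues = []
    serial = 1
    for i in range(n):
        angle = 2.0 * np.pi * i / n
        target = np.array([circumradius * np.cos(angle),
                           circumradius * np.sin(angle), 0.0])
        posed = _PosedResidue("HIS", spec.hydrogens)
        posed.orient(RING_ATOMS["HIS"]["ring"], np.array([0.0, 0.0, 1.0]))
        posed.translate(target)
        res = posed.to_residue("A", 2 + 8 * i, serial)
        serial += len(posed.names)
        residues.append(res)
    return residues


def make_motif(spec: FixtureSpec) -> tuple[StructureModel, PkaSet]:
    """Build the requested motif, emit it as PDB text and re-parse it.

    Returns the parsed model together with a pKa set: model-table values
    with the spec's per-residue overrides applied.  The controlled distance
    is verified on the parsed model to 0.01 A.
    """
    if spec.motif == "shifting_cluster":
        residues = _build_cluster(spec)
    else:
        residues = _build_pair(spec)
    draft = StructureModel(structure_id=f"fixture_{spec.motif}",
                           chains={"A": tuple(residues)})
    model = parse_structure(write_pdb(draft), structure_id=draft.structure_id)

    measured = measure_motif_distance(model, spec)
    expected = spec.distance
    tolerance = 0.01 if spec.motif != "shifting_cluster" else 0.02
    if abs(measured - expected) > tolerance:
        raise ValueError(
            f"{spec.motif} geometry verification failed: requested "
            f"{expected:.3f} A, emitted {measured:.3f} A"
        )

    pkas = assign_model_pkas(model)
    for res_seq, pka in spec.pka_overrides.items():
        key = GroupKey(next(r.key for r in model.residues() if r.res_seq == res_seq),
                       SIDE_CHAIN)
        if key not in pkas.entries:
            raise ValueError(f"residue {res_seq} has no ionizable side chain")
        pkas.entries[key] = replace(pkas.entries[key], pka=float(pka))
    return model, pkas


def make_random_peptide(
    n: int,
    seed: int = 0,
    *,
    composition: str = "any",
) -> str:
    """Reproducible random peptide of length ``n``.

    ``composition`` is ``any``, ``ionizable_rich`` (each position drawn from
    the titratable residues with probability 0.7) or ``ionizable_free`` (no
    titratable residues at all).
    """
    if n < 1:
        raise ValueError("peptide length must be >= 1")
    rng = random.Random(seed)
    ionizable = sorted(IONIZABLE_RESIDUES)
    neutral = sorted(set(_AA20) - IONIZABLE_RESIDUES)
    if composition == "any":
        return "".join(rng.choice(_AA20) for _ in range(n))
    if composition == "ionizable_rich":
        return "".join(
            rng.choice(ionizable) if rng.random() < 0.7 else rng.choice(neutral)
            for _ in range(n)
        )
    if composition == "ionizable_free":
        return "".join(rng.choice(neutral) for _ in range(n))
    raise ValueError(f"unknown composition {composition!r}")
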