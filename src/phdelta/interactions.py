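"""State-conditioned noncovalent bond detection on a static structure.

Four bond classes are detected under a given protonation assignment:

* salt bridges — charged-nitrogen to charged-carboxylate/terminal-oxygen
  contacts within a distance cutoff;
* hydrogen bonds — donor/acceptor heavy-atom contacts, with an explicit
  D-H...A angle test when hydrogens are present in the input;
* pi-pi — aromatic ring centroid contacts (a protonated histidine ring is
  no longer a neutral pi system and is excluded);
* cation-pi — cation site to ring centroid contacts (Lys ammonium, Arg
  guanidinium, and the imidazolium ring of a protonated histidine, which
  acts only as a cation, never simultaneously as a pi partner).

Which atoms can participate, and with which role, is read from the
protonation assignment, so the bond inventory of the same structure differs
between two pH values exactly where groups titrate in between.  All
geometric thresholds are parameters with residue-interaction-network-style
defaults.  Intra-residue and sequence-adjacent pairs are excluded as
covalently constrained.  Detection uses a k-d tree for candidate pruning
and is deterministic: identical inputs give identical record sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .pka import GroupKey, C_TERM, N_TERM, SIDE_CHAIN
from .protonation import ProtonationAssignment
from .structure_model import Atom, Residue, ResidueKey, StructureModel

logger = logging.getLogger(__name__)

SALT_BRIDGE = "salt_bridge"
HYDROGEN_BOND = "hydrogen_bond"
PI_PI = "pi_pi"
CATION_PI = "cation_pi"


@dataclass(frozen=True)
class GeometryParams:
    """Distance/angle thresholds for all detectors (Angstrom, degrees)."""

    salt_bridge_max_dist: float = 4.0   # min N-O distance
    hbond_max_dist: float = 3.5         # donor-acceptor heavy-atom distance
    hbond_min_angle: float = 120.0      # D-H...A, applied only with explicit H
    pi_pi_max_dist: float = 7.0         # ring centroid-centroid
    cation_pi_max_dist: float = 6.0     # cation site-ring centroid
    min_seq_separation: int = 2         # same-chain |res_seq| gap required

    def __post_init__(self) -> None:
        for name in ("salt_bridge_max_dist", "hbond_max_dist",
                     "pi_pi_max_dist", "cation_pi_max_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_GEOMETRY = GeometryParams()


@dataclass(frozen=True)
class InteractionRecord:
    """One detected noncovalent bond, canonicalized by partner order."""

    kind: str
    key_a: ResidueKey
    key_b: ResidueKey
    label_a: str   # atom name or ring/centroid label
    label_b: str
    distance: float
    angle: float | None = None
    state_dependent: bool = True

    @property
    def identity(self) -> tuple:
        """Geometry-free identity used for cross-pH set comparison."""
        return (self.kind, self.key_a, self.label_a, self.key_b, self.label_b)

    def involves(self, key: ResidueKey) -> bool:
        return key in (self.key_a, self.key_b)


def _canonical(kind, key_a, label_a, key_b, label_b, distance, angle=None,
               state_dependent=True) -> InteractionRecord:
    if (key_b, label_b) < (key_a, label_a):
        key_a, key_b = key_b, key_a
        label_a, label_b = label_b, label_a
    return InteractionRecord(kind, key_a, key_b, label_a, label_b,
                             round(float(distance), 3), angle, state_dependent)


@dataclass(frozen=True)
class InteractionSet:
    """All detected bonds of one structure at one pH."""

    ph: float
    records: tuple[InteractionRecord, ...]
    geometry_params: GeometryParams = DEFAULT_GEOMETRY

    def by_kind(self, kind: str) -> tuple[InteractionRecord, ...]:
        return tuple(r for r in self.records if r.kind == kind)

    def identities(self) -> set[tuple]:
        return {r.identity for r in self.records}


# --- residue chemistry tables -------------------------------------------------

RING_ATOMS: dict[str, dict[str, tuple[str, ...]]] = {
    "HIS": {"ring": ("CG", "ND1", "CD2", "CE1", "NE2")},
    "PHE": {"ring": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "TYR": {"ring": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    "TRP": {"ring5": ("CG", "CD1", "CD2", "NE1", "CE2"),
            "ring6": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")},
}

ARG_GUANIDINIUM = ("CZ", "NE", "NH1", "NH2")

#: cation nitrogen atoms usable in salt bridges, by residue
_CATION_N = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
#: anion oxygen atoms usable in salt bridges, by residue
_ANION_O = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

#: pH-independent polar side-chain atoms: name -> (donor, acceptor)
_STATIC_SIDECHAIN_POLAR = {
    "SER": {"OG": (True, True)},
    "THR": {"OG1": (True, True)},
    "ASN": {"OD1": (False, True), "ND2": (True, False)},
    "GLN": {"OE1": (False, True), "NE2": (True, False)},
    "TRP": {"NE1": (True, False)},
}

#: atoms of ionizable side chains whose role follows the protonation state
_STATE_SIDECHAIN_POLAR = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "CYS": ("SG",),
    "TYR": ("OH",),
}

_COVALENT_H_MAX = 1.3  # Angstrom: H belongs to the nearest heavy atom within this


def _ionizable_state(states: ProtonationAssignment, res: Residue):
    return states.get(GroupKey(res.key, SIDE_CHAIN))


class _Site:
    """A participating point: an atom or a centroid, tied to a residue."""

    __slots__ = ("res", "label", "coord")

    def __init__(self, res: Residue, label: str, coord: np.ndarray):
        self.res = res
        self.label = label
        self.coord = coord


def _excluded_pair(a: Residue, b: Residue, params: GeometryParams) -> bool:
    if a.key == b.key:
        return True
    if a.chain_id == b.chain_id and abs(a.res_seq - b.res_seq) < params.min_seq_separation:
        return True
    return False


def _site_pairs_within(sites_a: list[_Site], sites_b: list[_Site],
                       cutoff: float) -> Iterable[tuple[_Site, _Site, float]]:
    """All cross pairs within cutoff, via k-d tree pruning."""
    if not sites_a or not sites_b:
        return
    coords_a = np.array([s.coord for s in sites_a])
    coords_b = np.array([s.coord for s in sites_b])
    tree = cKDTree(coords_b)
    for i, neighbours in enumerate(tree.query_ball_point(coords_a, cutoff)):
        for j in neighbours:
            d = float(np.linalg.norm(coords_a[i] - coords_b[j]))
            if 0.0 < d <= cutoff:
                yield sites_a[i], sites_b[j], d


def _terminal_residues(model: StructureModel) -> tuple[dict, dict]:
    n_terms = {rs[0].key: rs[0] for rs in model.chains.values()}
    c_terms = {rs[-1].key: rs[-1] for rs in model.chains.values()}
    return n_terms, c_terms


# --- salt bridges -------------------------------------------------------------

def _salt_bridge_sites(model, states):
    """Charged nitrogen sites and charged oxygen sites under the assignment."""
    n_terms, c_terms = _terminal_residues(model)
    cations: list[_Site] = []
    anions: list[_Site] = []
    for res in model.residues():
        st = _ionizable_state(states, res)
        if res.res_name in _CATION_N and st is not None and st.formal_charge > 0:
            for name in _CATION_N[res.res_name]:
                atom = res.atom(name)
                if atom is not None:
                    cations.append(_Site(res, name, np.array(atom.coords)))
        if res.res_name in _ANION_O and st is not None and st.formal_charge < 0:
            for name in _ANION_O[res.res_name]:
                atom = res.atom(name)
                if atom is not None:
                    anions.append(_Site(res, name, np.array(atom.coords)))
        if res.key in n_terms:
            nst = states.get(GroupKey(res.key, N_TERM))
            if nst is not None and nst.formal_charge > 0:
                atom = res.atom("N")
                if atom is not None:
                    cations.append(_Site(res, "N", np.array(atom.coords)))
        if res.key in c_terms:
            cst = states.get(GroupKey(res.key, C_TERM))
            if cst is not None and cst.formal_charge < 0:
                for name in ("OXT", "O"):
                    atom = res.atom(name)
                    if atom is not None:
                        anions.append(_Site(res, name, np.array(atom.coords)))
    return cations, anions


def detect_salt_bridges(
    model: StructureModel,
    states: ProtonationAssignment,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> list[InteractionRecord]:
    """Salt bridges: charged N to charged O within the distance cutoff.

    One record per residue pair, carrying the minimum N-O distance and the
    atom names realizing it.  Both groups must be charged under ``states``.
    """
    cations, anions = _salt_bridge_sites(model, states)
    best: dict[tuple, tuple] = {}
    for ca, an, d in _site_pairs_within(cations, anions, params.salt_bridge_max_dist):
        if _excluded_pair(ca.res, an.res, params):
            continue
        pair = tuple(sorted((ca.res.key, an.res.key)))
        if pair not in best or d < best[pair][0]:
            best[pair] = (d, ca, an)
    records = [
        _canonical(SALT_BRIDGE, ca.res.key, ca.label, an.res.key, an.label, d)
        for d, ca, an in best.values()
    ]
    return sorted(records, key=lambda r: r.identity)


# --- hydrogen bonds -----------------------------------------------------------

def _polar_sites(model, states):
    """(donor sites, acceptor sites, state_dependent atom keys)."""
    n_terms, c_terms = _terminal_residues(model)
    donors: list[_Site] = []
    acceptors: list[_Site] = []
    state_dep: set[tuple[ResidueKey, str]] = set()

    for res in model.residues():
        # backbone
        n_atom = res.atom("N")
        if n_atom is not None and res.res_name != "PRO" and res.key not in n_terms:
            donors.append(_Site(res, "N", np.array(n_atom.coords)))
        o_atom = res.atom("O")
        if o_atom is not None and res.key not in c_terms:
            acceptors.append(_Site(res, "O", np.array(o_atom.coords)))

        # terminal groups (state-dependent)
        if res.key in n_terms and n_atom is not None:
            nst = states.get(GroupKey(res.key, N_TERM))
            donors.append(_Site(res, "N", np.array(n_atom.coords)))
            if nst is not None and not nst.protonated:
                acceptors.append(_Site(res, "N", np.array(n_atom.coords)))
            state_dep.add((res.key, "N"))
        if res.key in c_terms:
            cst = states.get(GroupKey(res.key, C_TERM))
            for name in ("O", "OXT"):
                atom = res.atom(name)
                if atom is None:
                    continue
                acceptors.append(_Site(res, name, np.array(atom.coords)))
                if cst is not None and cst.protonated:
                    donors.append(_Site(res, name, np.array(atom.coords)))
                state_dep.add((res.key, name))

        # pH-independent polar side chains
        for name, (don, acc) in _STATIC_SIDECHAIN_POLAR.get(res.res_name, {}).items():
            atom = res.atom(name)
            if atom is None:
                continue
            if don:
                donors.append(_Site(res, name, np.array(atom.coords)))
            if acc:
                acceptors.append(_Site(res, name, np.array(atom.coords)))

        # ionizable side chains: role follows the protonation state
        if res.res_name in _STATE_SIDECHAIN_POLAR:
            st = _ionizable_state(states, res)
            if st is None:
                continue  # e.g. disulfide-locked Cys: no polar role
            for name in _STATE_SIDECHAIN_POLAR[res.res_name]:
                atom = res.atom(name)
                if atom is None:
                    continue
                if st.donor_capable:
                    donors.append(_Site(res, name, np.array(atom.coords)))
                if st.acceptor_capable:
                    acceptors.append(_Site(res, name, np.array(atom.coords)))
                state_dep.add((res.key, name))
    return donors, acceptors, state_dep


def _hydrogens_of(res: Residue, heavy: Atom) -> list[np.ndarray]:
    hv = np.array(heavy.coords)
    return [np.array(a.coords) for a in res.atoms
            if a.is_hydrogen and np.linalg.norm(np.array(a.coords) - hv) <= _COVALENT_H_MAX]


def _dha_angle(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray) -> float:
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hydrogen_bonds(
    model: StructureModel,
    states: ProtonationAssignment,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> list[InteractionRecord]:
    """Hydrogen bonds: capable donor to capable acceptor within cutoff.

    When the donor carries explicit hydrogens the best D-H...A angle must
    reach ``hbond_min_angle``; without hydrogens the heavy-atom distance
    criterion alone applies (usable on raw PDB files).  Atom pairs that
    already form a salt bridge are suppressed.
    """
    donors, acceptors, state_dep = _polar_sites(model, states)

    cations, anions = _salt_bridge_sites(model, states)
    sb_atom_pairs = set()
    for ca, an, d in _site_pairs_within(cations, anions, params.salt_bridge_max_dist):
        if not _excluded_pair(ca.res, an.res, params):
            sb_atom_pairs.add(frozenset(((ca.res.key, ca.label), (an.res.key, an.label))))

    seen: dict[tuple, InteractionRecord] = {}
    for don, acc, d in _site_pairs_within(donors, acceptors, params.hbond_max_dist):
        if _excluded_pair(don.res, acc.res, params):
            continue
        if frozenset(((don.res.key, don.label), (acc.res.key, acc.label))) in sb_atom_pairs:
            continue
        angle = None
        hydrogens = _hydrogens_of(don.res, don.res.atom(don.label))
        if hydrogens:
            angle = max(_dha_angle(don.coord, h, acc.coord) for h in hydrogens)
            if angle < params.hbond_min_angle:
                continue
        dep = (don.res.key, don.label) in state_dep or (acc.res.key, acc.label) in state_dep
        rec = _canonical(HYDROGEN_BOND, don.res.key, don.label,
                         acc.res.key, acc.label, d,
                         angle=round(angle, 1) if angle is not None else None,
                         state_dependent=dep)
        prev = seen.get(rec.identity)
        if prev is None or rec.distance < prev.distance:
            seen[rec.identity] = rec
    return sorted(seen.values(), key=lambda r: r.identity)


# --- aromatic interactions ----------------------------------------------------

def _ring_sites(model, states) -> list[_Site]:
    """Neutral aromatic ring centroids (protonated His rings excluded)."""
    rings: list[_Site] = []
    for res in model.residues():
        ring_defs = RING_ATOMS.get(res.res_name)
        if not ring_defs:
            continue
        if res.res_name == "HIS":
            st = _ionizable_state(states, res)
            if st is not None and not st.aromatic_ring_neutral:
                continue  # imidazolium: cation, not a pi system
        for label, names in ring_defs.items():
            atoms = [res.atom(n) for n in names]
            if any(a is None for a in atoms):
                logger.warning("incomplete %s ring in %s; skipped", label, res.key)
                continue
            centroid = np.mean([a.coords for a in atoms], axis=0)
            rings.append(_Site(res, label, centroid))
    return rings


def _cation_sites(model, states) -> list[_Site]:
    """Cation sites for cation-pi: Lys NZ, Arg guanidinium, His imidazolium."""
    sites: list[_Site] = []
    for res in model.residues():
        st = _ionizable_state(states, res)
        if st is None or st.formal_charge <= 0:
            continue
        if res.res_name == "LYS":
            atom = res.atom("NZ")
            if atom is not None:
                sites.append(_Site(res, "NZ", np.array(atom.coords)))
        elif res.res_name == "ARG":
            atoms = [res.atom(n) for n in ARG_GUANIDINIUM]
            if all(a is not None for a in atoms):
                sites.append(_Site(res, "guanidinium",
                                   np.mean([a.coords for a in atoms], axis=0)))
        elif res.res_name == "HIS":
            names = RING_ATOMS["HIS"]["ring"]
            atoms = [res.atom(n) for n in names]
            if all(a is not None for a in atoms):
                sites.append(_Site(res, "ring+",
                                   np.mean([a.coords for a in atoms], axis=0)))
    return sites


def detect_aromatic(
    model: StructureModel,
    states: ProtonationAssignment,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> list[InteractionRecord]:
    """Pi-pi and cation-pi interactions via ring-centroid geometry.

    A protonated histidine ring acts only as a cation (cation-pi donor side)
    and never as a pi partner, so protonating a His recategorizes its ring
    contacts from pi-pi to cation-pi.
    """
    rings = _ring_sites(model, states)
    cations = _cation_sites(model, states)

    records: dict[tuple, InteractionRecord] = {}
    for a, b, d in _site_pairs_within(rings, rings, params.pi_pi_max_dist):
        if _excluded_pair(a.res, b.res, params):
            continue
        dep = "HIS" in (a.res.res_name, b.res.res_name)
        rec = _canonical(PI_PI, a.res.key, a.label, b.res.key, b.label, d,
                         state_dependent=dep)
        records.setdefault(rec.identity, rec)
    for ca, ring, d in _site_pairs_within(cations, rings, params.cation_pi_max_dist):
        if _excluded_pair(ca.res, ring.res, params):
            continue
        rec = _canonical(CATION_PI, ca.res.key, ca.label,
                         ring.res.key, ring.label, d)
        records.setdefault(rec.identity, rec)
    return sorted(records.values(), key=lambda r: r.identity)


def detect_all(
    model: StructureModel,
    states: ProtonationAssignment,
    params: GeometryParams = DEFAULT_GEOMETRY,
) -> InteractionSet:
    """Union of all detectors, canonicalized and deduplicated.

    Salt bridges take precedence over hydrogen bonds on the same atom pair.
    """
    records = (detect_salt_bridges(model, states, params)
               + detect_hydrogen_bonds(model, states, params)
               + detect_aromatic(model, states, params))
    sb_pairs = {frozenset(((r.key_a, r.label_a), (r.key_b, r.label_b)))
                for r in records if r.kind == SALT_BRIDGE}
    unique: dict[tuple, InteractionRecord] = {}
    for rec in records:
        if rec.kind == HYDROGEN_BOND and frozenset(
                ((rec.key_a, rec.label_a), (rec.key_b, rec.label_b))) in sb_pairs:
            continue
        unique.setdefault(rec.identity, rec)
    ordered = tuple(sorted(unique.values(), key=lambda r: r.identity))
    return InteractionSet(ph=states.ph, records=ordered, geometry_params=params)
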