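"""Cross-pH comparison: created/destroyed bonds and pH-sensitive patches.

The delta view compares the bond inventories detected at the two pH values
on geometry-free record identity (kind + partner residues + atom/centroid
labels): a record present only at the pH of interest is "created", one
present only at the reference pH "destroyed".  When a histidine ring is
recategorized by protonation (pi-pi partner at high pH, cation at low pH)
the two views each contribute a record, so the delta reports one destroyed
pi-pi plus one created cation-pi.

A pH-sensitive patch is a spatial cluster of residues that all change
protonation state between the two pH values: edges connect shifting
residues closer than a radius (default 8 A, minimum side-chain heavy-atom
distance), and patches are the connected components with at least
``min_size`` members (default 3, i.e. each patch residue is linked into a
group of at least two other shifting residues).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .interactions import InteractionRecord, InteractionSet
from .protonation import ShiftReport
from .structure_model import Residue, ResidueKey, StructureModel

SIDE_CHAIN_MODE = "side_chain"
ANY_ATOM_MODE = "any_atom"
CENTROID_MODE = "centroid"

DEFAULT_PATCH_RADIUS = 8.0
DEFAULT_MIN_PATCH_SIZE = 3

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class InteractionDelta:
    """Bonds present at only one of the two analyzed pH values."""

    ph_ref: float
    ph_int: float
    created: tuple[InteractionRecord, ...]    # present only at ph_int
    destroyed: tuple[InteractionRecord, ...]  # present only at ph_ref

    def per_residue_summary(self) -> dict[ResidueKey, Counter]:
        """Counts of created/destroyed records per residue, by kind."""
        summary: dict[ResidueKey, Counter] = {}
        for label, records in (("created", self.created),
                               ("destroyed", self.destroyed)):
            for rec in records:
                for key in (rec.key_a, rec.key_b):
                    summary.setdefault(key, Counter())[(label, rec.kind)] += 1
        return summary

    def changed_residues(self) -> set[ResidueKey]:
        return {k for rec in self.created + self.destroyed
                for k in (rec.key_a, rec.key_b)}


def interaction_delta(set_ref: InteractionSet, set_int: InteractionSet) -> InteractionDelta:
    """Set difference of two bond inventories on canonical record identity.

    ``set_ref`` is the reference-pH inventory and ``set_int`` the inventory
    at the pH of interest; both must come from the same structure with
    identical geometry parameters, otherwise the difference is meaningless.
    Swapping the arguments swaps created and destroyed exactly.
    """
    if set_ref.geometry_params != set_int.geometry_params:
        raise ValueError(
            "interaction sets were computed with different geometry parameters"
        )
    ids_ref = set_ref.identities()
    ids_int = set_int.identities()
    created = tuple(sorted((r for r in set_int.records if r.identity not in ids_ref),
                           key=lambda r: r.identity))
    destroyed = tuple(sorted((r for r in set_ref.records if r.identity not in ids_int),
                             key=lambda r: r.identity))
    return InteractionDelta(ph_ref=set_ref.ph, ph_int=set_int.ph,
                            created=created, destroyed=destroyed)


def _residue_points(res: Residue, mode: str) -> np.ndarray:
    heavy = res.heavy_atoms()
    if mode == SIDE_CHAIN_MODE:
        side = [a for a in heavy if a.name not in _BACKBONE]
        atoms = side or list(heavy)  # Gly: fall back to backbone
    elif mode == ANY_ATOM_MODE:
        atoms = list(heavy)
    elif mode == CENTROID_MODE:
        return np.mean([a.coords for a in heavy], axis=0).reshape(1, 3)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return np.array([a.coords for a in atoms])


def build_patch_graph(
    model: StructureModel,
    shifting: ShiftReport,
    radius: float = DEFAULT_PATCH_RADIUS,
    distance_mode: str = SIDE_CHAIN_MODE,
    *,
    include_termini: bool = False,
) -> nx.Graph:
    """Adjacency graph over protonation-shifting residues.

    Nodes are the shifting residues of the report (terminal-only shifts are
    excluded unless ``include_termini``); an edge joins two residues whose
    minimum pairwise distance under ``distance_mode`` is at most ``radius``.
    """
    if radius <= 0:
        raise ValueError("patch radius must be positive")
    if include_termini:
        node_keys = sorted({r.key.residue for r in shifting.shifting})
    else:
        node_keys = sorted(set(shifting.side_chain_keys()))
    graph = nx.Graph()
    residues = []
    for key in node_keys:
        res = model.residue(key)
        if res is None:
            continue  # shifted residue trimmed away or absent
        graph.add_node(key)
        residues.append(res)

    # k-d tree over all member points, then pair residues whose point sets come
    # within radius of one another
    points, owner = [], []
    for idx, res in enumerate(residues):
        pts = _residue_points(res, distance_mode)
        points.extend(pts)
        owner.extend([idx] * len(pts))
    if not points:
        return graph
    points = np.asarray(points, dtype=float)
    tree = cKDTree(points)
    for i, j in tree.query_pairs(radius):
        a, b = owner[i], owner[j]
        if a != b:
            graph.add_edge(residues[a].key, residues[b].key)
    return graph


@dataclass(frozen=True)
class Patch:
    """A connected cluster of protonation-shifting residues."""

    members: tuple[ResidueKey, ...]
    radius_used: float
    min_size_used: int
    centroid: tuple[float, float, float]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PatchResult:
    patches: tuple[Patch, ...]
    #: connected components below min_size, reported as near-patch residues
    near_patch: tuple[tuple[ResidueKey, ...], ...] = ()


def find_patches(
    graph: nx.Graph,
    model: StructureModel,
    radius: float = DEFAULT_PATCH_RADIUS,
    min_size: int = DEFAULT_MIN_PATCH_SIZE,
) -> PatchResult:
    """Connected components of the shift graph with at least min_size members.

    Patches are sorted by decreasing size, ties by first member key; smaller
    components are reported separately, not silently dropped.
    """
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    patches, near = [], []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        if len(members) < min_size:
            near.append(members)
            continue
        coords = []
        for key in members:
            res = model.residue(key)
            coords.extend(a.coords for a in res.heavy_atoms())
        centroid = tuple(float(v) for v in np.mean(coords, axis=0))
        patches.append(Patch(members=members, radius_used=radius,
                             min_size_used=min_size, centroid=centroid))
    patches.sort(key=lambda p: (-p.size, p.members[0]))
    near.sort(key=lambda m: (-len(m), m[0]))
    return PatchResult(patches=tuple(patches), near_patch=tuple(near))
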