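"""Brute-force reference detectors, independent of the package internals.

Plain O(n^2) loops over re-derived chemistry tables: no spatial indexing,
no reuse of the implementation's site extraction.  Used to cross-check the
interaction detectors and patch clustering on randomized toy structures.
"""

from __future__ import annotations

import math
from collections import deque

# --- chemistry tables, re-typed from the underlying conventions ---------------

RINGS = {
    "HIS": {"ring": ["CG", "ND1", "CD2", "CE1", "NE2"]},
    "PHE": {"ring": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
    "TYR": {"ring": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]},
    "TRP": {"ring5": ["CG", "CD1", "CD2", "NE1", "CE2"],
            "ring6": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]},
}
POS_N = {"ARG": ["NH1", "NH2", "NE"], "LYS": ["NZ"], "HIS": ["ND1", "NE2"]}
NEG_O = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}
ACID_RESNAMES = {"ASP", "GLU", "CYS", "TYR"}
BASE_RESNAMES = {"HIS", "LYS", "ARG"}


def dist(p, q):
    return math.dist(p, q)


def coords(res, name):
    atom = res.atom(name)
    return atom.coords if atom else None


def centroid(res, names):
    pts = [coords(res, n) for n in names]
    if any(p is None for p in pts):
        return None
    return tuple(sum(c[i] for c in pts) / len(pts) for i in range(3))


def protonated_map(pkas, ph):
    """group key -> protonated flag, via the tie rule pH < pKa."""
    return {key: ph < entry.pka for key, entry in pkas}


def side_chain_charge(res, prot):
    """Formal side-chain charge given the residue's protonated flag."""
    if prot is None:
        return 0
    if res.res_name in ACID_RESNAMES:
        return 0 if prot else -1
    if res.res_name in BASE_RESNAMES:
        return 1 if prot else 0
    return 0


def _prot(pkas, ph, res, group="side_chain"):
    from phdelta.pka import GroupKey

    entry = pkas.get(GroupKey(res.key, group))
    return None if entry is None else ph < entry.pka


def _adjacent(a, b, min_sep=2):
    return a.key == b.key or (
        a.chain_id == b.chain_id and abs(a.res_seq - b.res_seq) < min_sep)


def _chain_ends(model):
    n_terms = {rs[0].key for rs in model.chains.values()}
    c_terms = {rs[-1].key for rs in model.chains.values()}
    return n_terms, c_terms


def _canon(kind, key_a, label_a, key_b, label_b):
    if (key_b, label_b) < (key_a, label_a):
        key_a, label_a, key_b, label_b = key_b, label_b, key_a, label_a
    return (kind, key_a, label_a, key_b, label_b)


def _charged_sites(model, pkas, ph):
    """(positive N sites, negative O sites) as (residue, atom name) pairs."""
    n_terms, c_terms = _chain_ends(model)
    pos, neg = [], []
    for res in model.residues():
        prot = _prot(pkas, ph, res)
        charge = side_chain_charge(res, prot)
        if charge > 0:
            for name in POS_N[res.res_name]:
                if coords(res, name):
                    pos.append((res, name))
        if charge < 0 and res.res_name in NEG_O:
            for name in NEG_O[res.res_name]:
                if coords(res, name):
                    neg.append((res, name))
        if res.key in n_terms and _prot(pkas, ph, res, "n_term") and coords(res, "N"):
            pos.append((res, "N"))
        if res.key in c_terms:
            cprot = _prot(pkas, ph, res, "c_term")
            if cprot is False:
                for name in ("OXT", "O"):
                    if coords(res, name):
                        neg.append((res, name))
    return pos, neg


def salt_bridges(model, pkas, ph, cutoff=4.0):
    pos, neg = _charged_sites(model, pkas, ph)
    best = {}
    for res_p, name_p in pos:
        for res_n, name_n in neg:
            if _adjacent(res_p, res_n):
                continue
            d = dist(coords(res_p, name_p), coords(res_n, name_n))
            if d <= cutoff:
                pair = tuple(sorted((res_p.key, res_n.key)))
                if pair not in best or d < best[pair][0]:
                    best[pair] = (d, _canon("salt_bridge", res_p.key, name_p,
                                            res_n.key, name_n))
    return {v[1] for v in best.values()}


def _donors_acceptors(model, pkas, ph):
    n_terms, c_terms = _chain_ends(model)
    donors, acceptors = [], []
    for res in model.residues():
        if coords(res, "N") and res.res_name != "PRO":
            donors.append((res, "N"))
        if res.key in n_terms and _prot(pkas, ph, res, "n_term") is False \
                and coords(res, "N"):
            acceptors.append((res, "N"))
        if coords(res, "O"):
            acceptors.append((res, "O"))
        if res.key in c_terms:
            cprot = _prot(pkas, ph, res, "c_term")
            for name in ("O", "OXT"):
                if coords(res, name):
                    if cprot:
                        donors.append((res, name))
                    if name == "OXT":
                        acceptors.append((res, name))

        name3 = res.res_name
        static = {"SER": [("OG", True, True)], "THR": [("OG1", True, True)],
                  "ASN": [("OD1", False, True), ("ND2", True, False)],
                  "GLN": [("OE1", False, True), ("NE2", True, False)],
                  "TRP": [("NE1", True, False)]}
        for name, don, acc in static.get(name3, []):
            if coords(res, name):
                if don:
                    donors.append((res, name))
                if acc:
                    acceptors.append((res, name))

        prot = _prot(pkas, ph, res)
        if prot is None:
            continue
        if name3 in ("ASP", "GLU"):
            for name in NEG_O[name3]:
                if coords(res, name):
                    acceptors.append((res, name))
                    if prot:
                        donors.append((res, name))
        elif name3 == "HIS":
            for name in ("ND1", "NE2"):
                if coords(res, name):
                    donors.append((res, name))
                    if not prot:
                        acceptors.append((res, name))
        elif name3 == "LYS":
            if coords(res, "NZ"):
                donors.append((res, "NZ"))
                if not prot:
                    acceptors.append((res, "NZ"))
        elif name3 == "ARG":
            for name in ("NE", "NH1", "NH2"):
                if coords(res, name):
                    donors.append((res, name))
                    if not prot:
                        acceptors.append((res, name))
        elif name3 == "CYS":
            if coords(res, "SG"):
                acceptors.append((res, "SG"))
                if prot:
                    donors.append((res, "SG"))
        elif name3 == "TYR":
            if coords(res, "OH"):
                acceptors.append((res, "OH"))
                if prot:
                    donors.append((res, "OH"))
    return donors, acceptors


def hydrogen_bonds(model, pkas, ph, cutoff=3.5, sb_cutoff=4.0):
    donors, acceptors = _donors_acceptors(model, pkas, ph)
    pos, neg = _charged_sites(model, pkas, ph)
    sb_atoms = set()
    for res_p, name_p in pos:
        for res_n, name_n in neg:
            if not _adjacent(res_p, res_n) and \
                    dist(coords(res_p, name_p), coords(res_n, name_n)) <= sb_cutoff:
                sb_atoms.add(frozenset(((res_p.key, name_p), (res_n.key, name_n))))
    found = set()
    for res_d, name_d in donors:
        for res_a, name_a in acceptors:
            if _adjacent(res_d, res_a):
                continue
            if (res_d.key, name_d) == (res_a.key, name_a):
                continue
            if frozenset(((res_d.key, name_d), (res_a.key, name_a))) in sb_atoms:
                continue
            if dist(coords(res_d, name_d), coords(res_a, name_a)) <= cutoff:
                found.add(_canon("hydrogen_bond", res_d.key, name_d,
                                 res_a.key, name_a))
    return found


def aromatics(model, pkas, ph, pipi_cutoff=7.0, catpi_cutoff=6.0):
    rings, cations = [], []
    for res in model.residues():
        prot = _prot(pkas, ph, res)
        if res.res_name in RINGS:
            if res.res_name == "HIS" and prot:
                pass  # imidazolium: not a pi system
            else:
                for label, names in RINGS[res.res_name].items():
                    c = centroid(res, names)
                    if c:
                        rings.append((res, label, c))
        charge = side_chain_charge(res, prot)
        if charge > 0:
            if res.res_name == "LYS" and coords(res, "NZ"):
                cations.append((res, "NZ", coords(res, "NZ")))
            elif res.res_name == "ARG":
                c = centroid(res, ["CZ", "NE", "NH1", "NH2"])
                if c:
                    cations.append((res, "guanidinium", c))
            elif res.res_name == "HIS":
                c = centroid(res, RINGS["HIS"]["ring"])
                if c:
                    cations.append((res, "ring+", c))
    found = set()
    for i, (res_a, lab_a, c_a) in enumerate(rings):
        for res_b, lab_b, c_b in rings[i + 1:]:
            if _adjacent(res_a, res_b):
                continue
            if dist(c_a, c_b) <= pipi_cutoff:
                found.add(_canon("pi_pi", res_a.key, lab_a, res_b.key, lab_b))
    for res_c, lab_c, c_c in cations:
        for res_r, lab_r, c_r in rings:
            if _adjacent(res_c, res_r):
                continue
            if dist(c_c, c_r) <= catpi_cutoff:
                found.add(_canon("cation_pi", res_c.key, lab_c, res_r.key, lab_r))
    return found


def all_bonds(model, pkas, ph):
    return salt_bridges(model, pkas, ph) | hydrogen_bonds(model, pkas, ph) \
        | aromatics(model, pkas, ph)


# --- patch clustering oracle --------------------------------------------------

def patch_components(residues, radius, min_size, mode="side_chain"):
    """BFS components over naive all-pairs min-distance thresholding."""
    backbone = {"N", "CA", "C", "O", "OXT"}

    def points(res):
        heavy = [a for a in res.heavy_atoms()]
        if mode == "side_chain":
            side = [a for a in heavy if a.name not in backbone]
            heavy = side or heavy
        elif mode == "centroid":
            c = tuple(sum(a.coords[i] for a in heavy) / len(heavy)
                      for i in range(3))
            return [c]
        return [a.coords for a in heavy]

    pts = {res.key: points(res) for res in residues}
    keys = sorted(pts)
    adjacency = {k: set() for k in keys}
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if min(dist(p, q) for p in pts[a] for q in pts[b]) <= radius:
                adjacency[a].add(b)
                adjacency[b].add(a)
    seen, components = set(), []
    for start in keys:
        if start in seen:
            continue
        queue, comp = deque([start]), set()
        while queue:
            node = queue.popleft()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adjacency[node] - comp)
        seen |= comp
        components.append(tuple(sorted(comp)))
    edges = {frozenset((a, b)) for a in adjacency for b in adjacency[a]}
    big = sorted((c for c in components if len(c) >= min_size),
                 key=lambda c: (-len(c), c[0]))
    return edges, big
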