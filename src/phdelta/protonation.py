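"""Discrete protonation states at a given pH, and pH-shift detection.

Structure mode uses discrete (not fractional) states: a group is protonated
iff ``pH < pKa`` (the tie at pH == pKa counts as deprotonated).  The formal
charge follows the group polarity — a protonated acid is neutral, a
deprotonated acid is -1; a protonated base is +1, a deprotonated base
neutral.  The state also fixes hydrogen-bond donor/acceptor capability of
the group's polar atoms and whether a histidine imidazole still counts as
an aromatic pi system (a protonated imidazolium is treated as a cation, not
a pi partner).

A residue "shifts" between two pH values exactly when its pKa falls in the
half-open interval (min pH, max pH]: on one side of its pKa it is
protonated, on the other it is not.  That interval is the direct
consequence of the tie convention above, which is chosen so that the two
formulations agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pka import GroupKey, PkaSet, C_TERM, N_TERM, SIDE_CHAIN
from .sequence_charge import ACIDIC, BASIC

#: polarity by one-letter code for side chains; termini handled separately
_SIDE_CHAIN_POLARITY = {
    "ASP": ACIDIC, "GLU": ACIDIC, "CYS": ACIDIC, "TYR": ACIDIC,
    "HIS": BASIC, "LYS": BASIC, "ARG": BASIC,
}


def group_polarity(group: str, res_name: str) -> str:
    if group == N_TERM:
        return BASIC
    if group == C_TERM:
        return ACIDIC
    return _SIDE_CHAIN_POLARITY[res_name]


@dataclass(frozen=True)
class GroupState:
    """Protonation state of one titratable group at one pH."""

    formal_charge: int        # -1, 0 or +1
    protonated: bool
    donor_capable: bool
    acceptor_capable: bool
    aromatic_ring_neutral: bool  # meaningful for His only; True elsewhere


def _state_for(group: str, res_name: str, protonated: bool) -> GroupState:
    polarity = group_polarity(group, res_name)
    if polarity == ACIDIC:
        charge = 0 if protonated else -1
        # protonated acid: the O-H is a donor (carbonyl O still accepts);
        # carboxylate/thiolate/phenolate: acceptor only.
        donor, acceptor = (True, True) if protonated else (False, True)
        ring_neutral = True
    else:
        charge = 1 if protonated else 0
        if res_name == "HIS" and group == SIDE_CHAIN:
            # imidazolium: both ring nitrogens N-H donors, ring is a cation;
            # neutral imidazole: one N-H donor, one lone-pair acceptor
            # (tautomer-agnostic: either nitrogen may play either role).
            donor, acceptor = (True, False) if protonated else (True, True)
            ring_neutral = not protonated
        elif res_name == "ARG" and group == SIDE_CHAIN:
            # guanidinium keeps its N-H donors in either state
            donor, acceptor = True, not protonated
            ring_neutral = True
        else:  # Lys NZ, N-terminus
            donor, acceptor = True, not protonated
            ring_neutral = True
    return GroupState(
        formal_charge=charge,
        protonated=protonated,
        donor_capable=donor,
        acceptor_capable=acceptor,
        aromatic_ring_neutral=ring_neutral,
    )


@dataclass(frozen=True)
class ProtonationAssignment:
    """Discrete states of every titratable group at one pH."""

    ph: float
    states: dict[GroupKey, GroupState] = field(default_factory=dict)

    def get(self, key: GroupKey) -> GroupState | None:
        return self.states.get(key)

    def total_formal_charge(self) -> int:
        return sum(s.formal_charge for s in self.states.values())


def assign_states(pkas: PkaSet, ph: float) -> ProtonationAssignment:
    """Assign a discrete protonation state to every group of a pKa set."""
    if not (0.0 < ph < 14.0):
        raise ValueError(f"pH must lie in (0, 14), got {ph}")
    states = {
        key: _state_for(key.group, entry.res_name, protonated=ph < entry.pka)
        for key, entry in pkas
    }
    return ProtonationAssignment(ph=ph, states=states)


@dataclass(frozen=True)
class ShiftRecord:
    """One group whose protonation state differs between the two pH values."""

    key: GroupKey
    res_name: str
    pka: float
    state_low: GroupState   # state at the lower pH
    state_high: GroupState  # state at the higher pH

    @property
    def delta_formal_charge(self) -> int:
        """Charge at the higher pH minus charge at the lower pH."""
        return self.state_high.formal_charge - self.state_low.formal_charge

    @property
    def is_terminal(self) -> bool:
        return self.key.group in (N_TERM, C_TERM)


@dataclass(frozen=True)
class ShiftReport:
    """Groups that change protonation state between two pH values."""

    ph_low: float
    ph_high: float
    shifting: tuple[ShiftRecord, ...]

    def side_chain_keys(self):
        """Residue keys of shifting side chains (termini excluded)."""
        return [r.key.residue for r in self.shifting if not r.is_terminal]

    def keys(self):
        return [r.key for r in self.shifting]


def shifting_residues(pkas: PkaSet, ph_a: float, ph_b: float) -> ShiftReport:
    """Groups whose discrete state differs between ``ph_a`` and ``ph_b``.

    Equivalent to comparing the two full assignments key by key; under the
    protonation rule a group shifts iff its pKa lies in
    (min(ph_a, ph_b), max(ph_a, ph_b)].  Symmetric in its pH arguments.
    """
    if ph_a == ph_b:
        raise ValueError("the two pH values must differ")
    ph_low, ph_high = sorted((ph_a, ph_b))
    low = assign_states(pkas, ph_low)
    high = assign_states(pkas, ph_high)
    shifting = tuple(
        ShiftRecord(key, entry.res_name, entry.pka,
                    low.states[key], high.states[key])
        for key, entry in sorted(pkas, key=lambda kv: (kv[0].residue, kv[0].group))
        if low.states[key] != high.states[key]
    )
    return ShiftReport(ph_low=ph_low, ph_high=ph_high, shifting=shifting)
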