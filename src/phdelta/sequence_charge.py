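"""Sequence-mode pH sensitivity analysis.

Every ionizable group in a protein titrates with pH according to its pKa.
In the absence of structural information the protonated fraction of a group
follows the Henderson-Hasselbalch relation, so the mean (fractional) charge
of an acidic group is ``-1 / (1 + 10**(pKa - pH))`` and of a basic group
``+1 / (1 + 10**(pH - pKa))``.  This module evaluates those fractional
charges per residue at two pH values, reports the per-residue charge
differences, condenses them into a per-protein "overall charge score"
(difference of summed charges normalized by chain length), and ranks whole
sequence collections by that score over a pH grid.

The model deliberately ignores the structural micro-environment of each side
chain; every residue of a given type titrates with the same table pKa.
Structure-aware per-residue pKas are the job of the :mod:`phdelta.pka`
module.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import SequenceError, UnknownResidueError

logger = logging.getLogger(__name__)

#: Residues whose side chain carries a titratable proton.
IONIZABLE_RESIDUES = frozenset("DECYHKR")

#: The 20 standard one-letter codes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / rare codes accepted as non-ionizable in lenient mode.
AMBIGUOUS_AA = frozenset("XBZUO")

ACIDIC = "acidic"
BASIC = "basic"

#: Default soft cap on batch size for collection-level scans.
DEFAULT_RECORD_CAP = 10_000


@dataclass(frozen=True)
class PkaTable:
    """Model pKa values for the titratable groups of a polypeptide.

    Defaults are the model pKas used by the PROPKA3 empirical predictor, so
    that sequence mode and structure mode agree in the limit where the
    structural environment perturbs nothing.
    """

    side_chain: dict[str, float] = field(
        default_factory=lambda: {
            "D": 3.80,
            "E": 4.50,
            "H": 6.50,
            "C": 9.00,
            "Y": 10.00,
            "K": 10.50,
            "R": 12.50,
        }
    )
    n_terminus: float = 8.00
    c_terminus: float = 3.20

    #: polarity of each group: acids release a proton to become -1,
    #: bases bind a proton to become +1.
    polarity: dict[str, str] = field(
        default_factory=lambda: {
            "D": ACIDIC,
            "E": ACIDIC,
            "C": ACIDIC,
            "Y": ACIDIC,
            "H": BASIC,
            "K": BASIC,
            "R": BASIC,
            "n_term": BASIC,
            "c_term": ACIDIC,
        }
    )

    def __post_init__(self) -> None:
        for name, value in [*self.side_chain.items(),
                            ("n_term", self.n_terminus),
                            ("c_term", self.c_terminus)]:
            if not (0.0 < value < 14.0):
                raise ValueError(f"pKa of {name} must lie in (0, 14), got {value}")
        for aa in self.side_chain:
            if aa not in IONIZABLE_RESIDUES:
                raise ValueError(f"{aa!r} is not an ionizable residue code")

    def pka_of(self, group: str) -> float:
        if group == "n_term":
            return self.n_terminus
        if group == "c_term":
            return self.c_terminus
        return self.side_chain[group]


DEFAULT_PKA_TABLE = PkaTable()


def _group_charge(polarity: str, pka: float, ph: float) -> float:
    """Henderson-Hasselbalch mean charge of one titratable group."""
    if polarity == ACIDIC:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - pka))


def _check_ph(ph: float) -> None:
    # 14 is included so that a full 1..14 titration scan is expressible
    if not (0.0 < ph <= 14.0) or math.isnan(ph):
        raise ValueError(f"pH must lie in (0, 14], got {ph}")


def residue_partial_charge(
    aa: str,
    ph: float,
    table: PkaTable = DEFAULT_PKA_TABLE,
    *,
    strict: bool = False,
) -> float:
    """Fractional side-chain charge of residue ``aa`` at ``ph``.

    Acidic residues return a value in [-1, 0], basic residues in [0, +1],
    non-ionizable residues exactly 0.  Terminal group contributions are not
    included here; see :func:`sequence_charge_profile`.

    Parameters
    ----------
    aa:
        One-letter residue code.  ``X/B/Z/U/O`` are treated as
        non-ionizable with a warning unless ``strict`` is set.
    ph:
        Solution pH, in (0, 14).
    table:
        pKa table; defaults to the predictor model values.
    strict:
        Reject ambiguity codes instead of zeroing them.
    """
    _check_ph(ph)
    aa = aa.upper()
    if aa in IONIZABLE_RESIDUES:
        return _group_charge(table.polarity[aa], table.pka_of(aa), ph)
    if aa in STANDARD_AA:
        return 0.0
    if aa in AMBIGUOUS_AA and not strict:
        logger.warning("treating non-standard residue code %r as non-ionizable", aa)
        return 0.0
    raise UnknownResidueError(f"unknown residue code {aa!r}")


@dataclass(frozen=True)
class ResidueCharge:
    """Charge state of one residue at the two analyzed pH values."""

    position: int          # 1-based
    aa: str
    charge_ref: float
    charge_int: float

    @property
    def delta(self) -> float:
        return self.charge_int - self.charge_ref


@dataclass(frozen=True)
class SequenceChargeProfile:
    """Per-residue fractional charges of one sequence at two pH values."""

    sequence_id: str
    ph_ref: float
    ph_int: float
    residues: tuple[ResidueCharge, ...]
    include_termini: bool

    @property
    def overall_charge_score(self) -> float:
        """(sum of charges at pH of interest - sum at reference pH) / length."""
        n = len(self.residues)
        return sum(r.charge_int for r in self.residues) / n - sum(
            r.charge_ref for r in self.residues
        ) / n


def sequence_charge_profile(
    seq: str,
    ph_ref: float,
    ph_int: float,
    table: PkaTable = DEFAULT_PKA_TABLE,
    *,
    include_termini: bool = True,
    sequence_id: str = "",
    strict: bool = False,
) -> SequenceChargeProfile:
    """Per-residue Henderson-Hasselbalch charge profile at two pH values.

    When ``include_termini`` is set (the default) the free alpha-amino and
    alpha-carboxyl group contributions are added to the first and last
    residue respectively, on top of any side-chain charge.
    """
    _check_ph(ph_ref)
    _check_ph(ph_int)
    seq = "".join(seq.split()).upper().replace("-", "")
    if not seq:
        raise SequenceError("empty sequence")

    residues = []
    last = len(seq) - 1
    for i, aa in enumerate(seq):
        c_ref = residue_partial_charge(aa, ph_ref, table, strict=strict)
        c_int = residue_partial_charge(aa, ph_int, table, strict=strict)
        if include_termini:
            if i == 0:
                c_ref += _group_charge(BASIC, table.n_terminus, ph_ref)
                c_int += _group_charge(BASIC, table.n_terminus, ph_int)
            if i == last:
                c_ref += _group_charge(ACIDIC, table.c_terminus, ph_ref)
                c_int += _group_charge(ACIDIC, table.c_terminus, ph_int)
        residues.append(ResidueCharge(i + 1, aa, c_ref, c_int))
    return SequenceChargeProfile(
        sequence_id=sequence_id,
        ph_ref=ph_ref,
        ph_int=ph_int,
        residues=tuple(residues),
        include_termini=include_termini,
    )


def overall_charge_score(profile: SequenceChargeProfile) -> float:
    """Overall charge score of a profile.

    Sum of per-residue charges at the pH of interest minus the sum at the
    reference pH, normalized by the number of residues.  Raising the pH can
    only deprotonate groups, so scores for ph_int > ph_ref are non-positive.
    """
    if not profile.residues:
        raise SequenceError("profile has no residues")
    return profile.overall_charge_score


@dataclass(frozen=True)
class ScanEntry:
    """Scan result for one sequence: per-shift scores and their mean."""

    sequence_id: str
    shift_scores: tuple[float, ...]
    mean_score: float
    rank: int


@dataclass(frozen=True)
class RankedScanResult:
    """pH-scan ranking of a sequence collection.

    ``entries`` are sorted by descending ``abs(mean_score)`` with ties broken
    by sequence id; ``skipped`` lists (id, reason) for records that failed
    validation.
    """

    grid: tuple[float, ...]
    entries: tuple[ScanEntry, ...]
    skipped: tuple[tuple[str, str], ...] = ()


DEFAULT_SCAN_GRID: tuple[float, ...] = tuple(float(p) for p in range(1, 15))


def ph_scan_rank(
    records: Iterable[tuple[str, str]],
    grid: Sequence[float] = DEFAULT_SCAN_GRID,
    table: PkaTable = DEFAULT_PKA_TABLE,
    *,
    include_termini: bool = True,
    strict: bool = False,
    record_cap: int | None = DEFAULT_RECORD_CAP,
) -> RankedScanResult:
    """Rank sequences by mean overall charge score over a pH grid.

    For each consecutive grid pair the lower value is the reference pH and
    the higher the pH of interest; the mean of the per-shift scores is the
    per-protein pH-responsiveness statistic.  Ranking is by descending
    absolute mean score (all shifts on an increasing grid carry the same
    sign, so responsiveness is a magnitude notion); the signed mean is
    reported alongside.  Ties are broken by sequence id, making the ranking
    deterministic and permutation-invariant in input order.
    """
    grid = tuple(float(p) for p in grid)
    if len(grid) < 2 or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("pH grid must be strictly increasing with >= 2 points")
    records = list(records)
    if not records:
        raise SequenceError("no records to scan")
    if record_cap is not None and len(records) > record_cap:
        raise SequenceError(
            f"{len(records)} records exceed the cap of {record_cap}; "
            "raise record_cap (or pass --force on the CLI) to override"
        )
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SequenceError(f"duplicate sequence ids: {dupes}")

    scored: list[tuple[str, tuple[float, ...], float]] = []
    skipped: list[tuple[str, str]] = []
    for rid, seq in records:
        try:
            shift_scores = tuple(
                sequence_charge_profile(
                    seq, lo, hi, table,
                    include_termini=include_termini, strict=strict,
                ).overall_charge_score
                for lo, hi in zip(grid, grid[1:])
            )
        except (SequenceError, UnknownResidueError) as exc:
            logger.warning("skipping record %r: %s", rid, exc)
            skipped.append((rid, str(exc)))
            continue
        scored.append((rid, shift_scores, statistics.fmean(shift_scores)))
    if not scored:
        raise SequenceError("no valid records after filtering")

    scored.sort(key=lambda t: (-abs(t[2]), t[0]))
    entries = tuple(
        ScanEntry(rid, shifts, mean, rank)
        for rank, (rid, shifts, mean) in enumerate(scored, start=1)
    )
    return RankedScanResult(grid=grid, entries=entries, skipped=tuple(skipped))


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA file into (id, sequence) pairs.

    The id is the first whitespace-delimited token of the description line;
    gaps and whitespace are stripped from sequences.
    """
    from Bio import SeqIO

    records = [
        (rec.id, str(rec.seq).replace("-", "").replace(" ", ""))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records
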