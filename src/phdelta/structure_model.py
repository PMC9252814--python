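"""PDB structure ingestion and manipulation.

Wraps Biopython's PDB parser into a small immutable-ish model holding just
what the pH analysis needs: chains, residues, heavy/hydrogen atoms with
coordinates and B-factors.  For predicted models (AlphaFold convention) the
B-factor column carries the per-atom pLDDT confidence score, which enables
trimming of low-confidence regions before interaction analysis.

Only the first MODEL of multi-model files is used: the analysis treats the
input as a single static structure.  HETATM records, waters and nucleic
acids are excluded (selenomethionine is kept, as it substitutes for a
standard residue).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

from .errors import StructureParseError

logger = logging.getLogger(__name__)

EXPERIMENTAL = "experimental"
PREDICTED = "predicted-model"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
STANDARD_RESNAMES = frozenset(THREE_TO_ONE)

#: common substitutions mapped back to their parent residue when the
#: ``common_substitutions`` flag of :func:`extract_sequence` is set.
SUBSTITUTION_PARENT = {"MSE": "M", "SEC": "C", "PYL": "K"}


class ResidueKey(NamedTuple):
    """Unique residue identifier: chain id, author residue number, icode."""

    chain: str
    res_seq: int
    icode: str

    def __str__(self) -> str:  # e.g. "A:38" or "A:38A"
        return f"{self.chain}:{self.res_seq}{self.icode.strip()}"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    b_factor: float
    serial: int
    alt_loc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass(frozen=True)
class Residue:
    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atoms: tuple[Atom, ...]

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.res_seq, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_RESNAMES

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    @property
    def mean_b_factor(self) -> float:
        return sum(a.b_factor for a in self.atoms) / len(self.atoms)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if not a.is_hydrogen)


@dataclass(frozen=True)
class StructureModel:
    """Chains of residues from one PDB model block."""

    structure_id: str
    chains: dict[str, tuple[Residue, ...]]
    provenance: str = EXPERIMENTAL
    #: residue keys removed by confidence trimming, for gap bookkeeping
    trimmed: tuple[ResidueKey, ...] = ()

    def residues(self) -> Iterable[Residue]:
        for chain_id in self.chains:
            yield from self.chains[chain_id]

    def residue(self, key: ResidueKey) -> Residue | None:
        for res in self.chains.get(key.chain, ()):
            if res.key == key:
                return res
        return None

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains.values() for r in c)

    def per_residue_confidence(self) -> dict[ResidueKey, float]:
        """Mean B-factor (pLDDT for predicted models) per residue."""
        return {r.key: r.mean_b_factor for r in self.residues()}


def _select_altloc(bio_atom):
    """Resolve a possibly disordered atom to its best conformer.

    Highest occupancy wins; ties prefer the blank altloc, then 'A', then
    alphabetical order.
    """
    if not bio_atom.is_disordered():
        return bio_atom
    children = list(bio_atom.child_dict.values())
    children.sort(key=lambda a: (-(a.get_occupancy() or 0.0),
                                 a.get_altloc() not in (" ", ""),
                                 a.get_altloc()))
    return children[0]


def parse_structure(
    pdb_text: str,
    chain_filter: set[str] | None = None,
    *,
    structure_id: str = "structure",
    provenance: str = EXPERIMENTAL,
) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only ATOM records of the first MODEL block are used; HETATM records are
    dropped except selenomethionine (MSE).  Alternate locations are resolved
    to the highest-occupancy conformer.

    Parameters
    ----------
    pdb_text:
        Full PDB-format text.
    chain_filter:
        If given, keep only these chain ids.
    provenance:
        ``"experimental"`` or ``"predicted-model"``; the latter marks the
        B-factor column as holding pLDDT scores and enables
        :func:`trim_by_confidence`.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    if provenance not in (EXPERIMENTAL, PREDICTED):
        raise ValueError(f"unknown provenance {provenance!r}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(structure_id, io.StringIO(pdb_text))
    except (PDBConstructionException, ValueError) as exc:
        raise StructureParseError(f"malformed PDB input: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise StructureParseError("no MODEL/ATOM records found")
    first = models[0]

    chains: dict[str, list[Residue]] = {}
    for bio_chain in first:
        chain_id = bio_chain.id
        if chain_filter is not None and chain_id not in chain_filter:
            continue
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, res_seq, icode = bio_res.id
            res_name = bio_res.get_resname().strip()
            if hetflag.strip() and res_name not in SUBSTITUTION_PARENT:
                continue  # HETATM, waters, ligands
            if res_name not in STANDARD_RESNAMES and res_name not in SUBSTITUTION_PARENT:
                continue  # nucleic acids etc.
            atoms = []
            seen_names: set[str] = set()
            for bio_atom in bio_res:
                atom = _select_altloc(bio_atom)
                name = atom.get_name().strip()
                if name in seen_names:
                    continue
                seen_names.add(name)
                x, y, z = (float(v) for v in atom.get_coord())
                atoms.append(Atom(
                    name=name,
                    element=(atom.element or "").strip().upper() or name[0],
                    coords=(x, y, z),
                    b_factor=float(atom.get_bfactor() or 0.0),
                    serial=int(atom.get_serial_number() or 0),
                    alt_loc=(atom.get_altloc() or "").strip(),
                ))
            if atoms:
                residues.append(Residue(chain_id, int(res_seq), icode.strip(),
                                        res_name, tuple(atoms)))
        if residues:
            residues.sort(key=lambda r: (r.res_seq, r.icode))
            chains[chain_id] = residues

    model = StructureModel(
        structure_id=structure_id,
        chains={c: tuple(rs) for c, rs in chains.items()},
        provenance=provenance,
    )
    if not any(r.is_standard for r in model.residues()):
        wanted = f" in chains {sorted(chain_filter)}" if chain_filter else ""
        raise StructureParseError(f"no standard amino-acid residues found{wanted}")
    return model


def trim_by_confidence(
    model: StructureModel,
    threshold: float,
    keep_ranges: Iterable[tuple[str, int, int]] = (),
) -> StructureModel:
    """Remove residues of a predicted model with mean pLDDT below threshold.

    ``keep_ranges`` are (chain, start, end) author-numbering intervals
    (inclusive) exempt from trimming, e.g. an inter-domain linker that is
    flexible rather than wrong.  Removed residue keys are recorded on the
    returned model for gap bookkeeping.
    """
    if model.provenance != PREDICTED:
        raise ValueError(
            "confidence trimming requires a predicted model "
            "(parse with provenance='predicted-model')"
        )
    keep_ranges = list(keep_ranges)

    def kept(res: Residue) -> bool:
        if res.mean_b_factor >= threshold:
            return True
        return any(c == res.chain_id and s <= res.res_seq <= e
                   for c, s, e in keep_ranges)

    new_chains: dict[str, tuple[Residue, ...]] = {}
    removed: list[ResidueKey] = []
    for chain_id, residues in model.chains.items():
        keep = tuple(r for r in residues if kept(r))
        removed.extend(r.key for r in residues if not kept(r))
        if keep:
            new_chains[chain_id] = keep
    if not new_chains:
        raise StructureParseError(
            f"confidence trimming at pLDDT {threshold} removed every residue"
        )
    if removed:
        logger.info("trimmed %d residues below pLDDT %.1f", len(removed), threshold)
    return replace(model, chains=new_chains,
                   trimmed=model.trimmed + tuple(removed))


def extract_sequence(
    model: StructureModel, *, common_substitutions: bool = False
) -> dict[str, str]:
    """One-letter sequence per chain, ordered by residue numbering.

    Nonstandard residues map to ``X``; with ``common_substitutions`` set,
    MSE/SEC/PYL map to their parent residue letters instead.
    """
    seqs = {}
    for chain_id, residues in model.chains.items():
        letters = []
        for res in residues:
            if res.is_standard:
                letters.append(res.one_letter)
            elif common_substitutions and res.res_name in SUBSTITUTION_PARENT:
                letters.append(SUBSTITUTION_PARENT[res.res_name])
            else:
                letters.append("X")
        seqs[chain_id] = "".join(letters)
    return seqs


def write_pdb(model: StructureModel) -> str:
    """Serialize a model back to minimal PDB-format text (ATOM/TER/END)."""
    lines = []
    serial = 0
    for chain_id, residues in model.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # column-13 alignment rule: 1-char element names start in col 14
                padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                x, y, z = atom.coords
                lines.append(
                    f"ATOM  {serial:>5d} {padded}{'':1s}{res.res_name:>3s} "
                    f"{chain_id:1s}{res.res_seq:>4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{atom.b_factor:6.2f}"
                    f"          {atom.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:>5d}      {residues[-1].res_name:>3s} "
                     f"{chain_id:1s}{residues[-1].res_seq:>4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"
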