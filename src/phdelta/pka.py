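"""Per-residue pKa values for a structure, from pluggable sources.

Three providers populate the same :class:`PkaSet` container:

* :func:`assign_model_pkas` — environment-free baseline using the fixed
  model pKa table (identical to sequence mode per-residue behaviour);
* :func:`parse_predictor_output` — reads the ``SUMMARY OF THIS PREDICTION``
  block of a PROPKA ``.pka`` output file, so archived predictor runs can be
  reused without the executable;
* :func:`run_predictor` — invokes the PROPKA executable on a written copy
  of the model and parses its output.

The empirical predictor itself is wrapped, never reimplemented: everything
this package contributes sits downstream of the pKa values.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from .errors import PkaParseError, PredictorNotFoundError, PredictorRunError
from .sequence_charge import DEFAULT_PKA_TABLE, PkaTable
from .structure_model import StructureModel, ResidueKey, write_pdb

logger = logging.getLogger(__name__)

SIDE_CHAIN = "side_chain"
N_TERM = "n_term"
C_TERM = "c_term"

#: three-letter names of ionizable side chains
IONIZABLE_RESNAMES = {
    "ASP": "D", "GLU": "E", "CYS": "C", "TYR": "Y",
    "HIS": "H", "LYS": "K", "ARG": "R",
}

#: PROPKA convention for cysteines locked in disulfide bridges
DISULFIDE_SENTINEL = 99.0

MODEL_TABLE = "model_table"
PREDICTOR_FILE = "predictor_file"
PREDICTOR_RUN = "predictor_run"


class GroupKey(NamedTuple):
    """One titratable group: a residue plus which of its groups titrates."""

    residue: ResidueKey
    group: str  # side_chain | n_term | c_term


@dataclass(frozen=True)
class PkaEntry:
    pka: float
    source: str
    res_name: str  # 3-letter code of the carrying residue


@dataclass
class PkaSet:
    """pKa values for every titratable group of a bound structure."""

    entries: dict[GroupKey, PkaEntry] = field(default_factory=dict)
    predictor_version: str | None = None

    def __iter__(self):
        return iter(self.entries.items())

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, key: GroupKey) -> PkaEntry | None:
        return self.entries.get(key)

    def side_chain_pka(self, residue: ResidueKey) -> float | None:
        entry = self.entries.get(GroupKey(residue, SIDE_CHAIN))
        return entry.pka if entry else None


def _terminal_keys(model: StructureModel) -> list[tuple[GroupKey, str]]:
    keys = []
    for chain_id, residues in model.chains.items():
        keys.append((GroupKey(residues[0].key, N_TERM), residues[0].res_name))
        keys.append((GroupKey(residues[-1].key, C_TERM), residues[-1].res_name))
    return keys


def assign_model_pkas(
    model: StructureModel, table: PkaTable = DEFAULT_PKA_TABLE
) -> PkaSet:
    """Assign fixed model pKas to every ionizable group of the structure.

    One entry per ionizable side chain (Asp, Glu, Cys, Tyr, His, Lys, Arg)
    plus N-/C-terminal entries for the first and last residue of each chain.
    Deterministic and pH-independent.
    """
    entries: dict[GroupKey, PkaEntry] = {}
    for res in model.residues():
        code = IONIZABLE_RESNAMES.get(res.res_name)
        if code is not None:
            entries[GroupKey(res.key, SIDE_CHAIN)] = PkaEntry(
                table.pka_of(code), MODEL_TABLE, res.res_name
            )
    for gkey, res_name in _terminal_keys(model):
        pka = table.n_terminus if gkey.group == N_TERM else table.c_terminus
        entries[gkey] = PkaEntry(pka, MODEL_TABLE, res_name)
    return PkaSet(entries=entries)


# Summary line, e.g. "   ASP  38 A     3.85       3.80"
# or terminal lines "   N+    1 A     7.93       8.00".
_SUMMARY_LINE = re.compile(
    r"^\s*(?P<name>[A-Z]{3}|N\+|C-)\s+(?P<num>\d+)\s*(?P<icode>[A-Z]?)\s+"
    r"(?P<chain>\S)\s+(?P<pka>-?\d+\.\d+)"
)


def parse_predictor_output(pka_text: str, model: StructureModel) -> PkaSet:
    """Parse the SUMMARY block of PROPKA ``.pka`` output against a model.

    Lines that do not match a residue of the (possibly trimmed) model are
    skipped with a warning; duplicate lines for the same group (alternate
    conformations) keep the first occurrence; disulfide-locked cysteines
    (pKa 99.99 convention) are treated as non-ionizable and dropped.
    """
    lines = pka_text.splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if "SUMMARY OF THIS PREDICTION" in l)
    except StopIteration:
        raise PkaParseError("no 'SUMMARY OF THIS PREDICTION' section found")

    version = None
    for line in lines:
        m = re.search(r"propka\s*(\d[\w.]*)", line, re.IGNORECASE)
        if m:
            version = m.group(1)
            break

    model_keys = {res.key: res for res in model.residues()}
    terminal = dict(_terminal_keys(model))
    n_term_by_chain = {k.residue.chain: k for k in terminal if k.group == N_TERM}
    c_term_by_chain = {k.residue.chain: k for k in terminal if k.group == C_TERM}

    entries: dict[GroupKey, PkaEntry] = {}
    parsed_any = False
    for line in lines[start + 1:]:
        if line.strip().startswith("---") or "Group" in line:
            continue
        if not line.strip():
            if parsed_any:
                break
            continue
        m = _SUMMARY_LINE.match(line)
        if m is None:
            if parsed_any:
                break  # end of summary block
            continue
        parsed_any = True
        name = m.group("name")
        res_key = ResidueKey(m.group("chain"), int(m.group("num")),
                             m.group("icode"))
        pka = float(m.group("pka"))

        if name == "N+":
            gkey = n_term_by_chain.get(res_key.chain)
        elif name == "C-":
            gkey = c_term_by_chain.get(res_key.chain)
        else:
            if name not in IONIZABLE_RESNAMES:
                logger.warning("skipping non-ionizable summary line: %s", line.strip())
                continue
            res = model_keys.get(res_key)
            if res is None:
                logger.warning("summary residue %s %s absent from model; skipped",
                               name, res_key)
                continue
            if res.res_name != name:
                raise PkaParseError(
                    f"summary line names {name} at {res_key} but the model has "
                    f"{res.res_name} there"
                )
            if name == "CYS" and pka >= DISULFIDE_SENTINEL:
                logger.info("cysteine %s marked disulfide-bonded; treated as "
                            "non-ionizable", res_key)
                continue
            gkey = GroupKey(res_key, SIDE_CHAIN)
        if gkey is None or gkey.residue not in model_keys:
            logger.warning("terminal summary line has no matching chain end: %s",
                           line.strip())
            continue
        if gkey in entries:
            logger.warning("duplicate summary line for %s; keeping first", gkey)
            continue
        entries[gkey] = PkaEntry(pka, PREDICTOR_FILE,
                                 model_keys[gkey.residue].res_name)
    if not entries:
        raise PkaParseError("SUMMARY section contained no parsable pKa lines")
    return PkaSet(entries=entries, predictor_version=version)


PREDICTOR_EXECUTABLES = ("propka3", "propka")


def run_predictor(
    model: StructureModel,
    workdir: str | Path,
    *,
    executable: str | None = None,
) -> PkaSet:
    """Run the PROPKA executable on the model and parse its ``.pka`` output.

    Raises :class:`PredictorNotFoundError` with a pointer to the
    ``--pka-file`` fallback when no executable is discoverable.
    """
    candidates = (executable,) if executable else PREDICTOR_EXECUTABLES
    exe = next((shutil.which(c) for c in candidates if shutil.which(c)), None)
    if exe is None:
        raise PredictorNotFoundError(
            f"no pKa predictor executable found (tried {', '.join(candidates)}); "
            "install propka, or supply an archived .pka output via "
            "parse_predictor_output / --pka-source file --pka-file PATH"
        )
    workdir = Path(workdir)
    try:
        workdir.mkdir(parents=True, exist_ok=True)
        pdb_path = workdir / f"{model.structure_id}.pdb"
        pdb_path.write_text(write_pdb(model))
    except OSError as exc:
        raise PredictorRunError(f"cannot write model to {workdir}: {exc}") from exc
    proc = subprocess.run(
        [exe, pdb_path.name], cwd=workdir,
        capture_output=True, text=True,
    )
    pka_path = workdir / f"{model.structure_id}.pka"
    if proc.returncode != 0 or not pka_path.exists():
        raise PredictorRunError(
            f"pKa predictor failed (exit {proc.returncode}):\n{proc.stderr}"
        )
    pka_set = parse_predictor_output(pka_path.read_text(), model)
    return PkaSet(entries={k: PkaEntry(e.pka, PREDICTOR_RUN, e.res_name)
                           for k, e in pka_set.entries.items()},
                  predictor_version=pka_set.predictor_version)
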