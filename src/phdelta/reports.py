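"""Machine-readable report writers: TSV, JSON mirrors and a PyMOL script.

Every file starts with ``#``-prefixed provenance lines recording the
parameters that produced it, so any report is auditable on its own.
Outputs are deterministic: identical inputs give byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

from .delta_patches import InteractionDelta, PatchResult
from .interactions import InteractionSet
from .protonation import ShiftReport
from .sequence_charge import RankedScanResult, SequenceChargeProfile


def _header(params: Mapping[str, object]) -> list[str]:
    return [f"# {key} = {value}" for key, value in params.items()]


def _write(path: Path, header_params: Mapping[str, object],
           columns: list[str], rows: Iterable[Iterable[object]]) -> None:
    lines = _header(header_params)
    lines.append("\t".join(columns))
    lines.extend("\t".join(str(v) for v in row) for row in rows)
    path.write_text("\n".join(lines) + "\n")


def _fmt(x: float) -> str:
    return f"{x:.6f}"


# --- sequence mode ------------------------------------------------------------

def write_profile_tsv(profiles: list[SequenceChargeProfile], path: Path,
                      params: Mapping[str, object]) -> None:
    rows = [
        (p.sequence_id, r.position, r.aa,
         _fmt(r.charge_ref), _fmt(r.charge_int), _fmt(r.delta))
        for p in profiles for r in p.residues
    ]
    _write(path, params,
           ["id", "position", "aa", "charge_ref", "charge_int", "delta"], rows)


def write_profile_json(profiles: list[SequenceChargeProfile], path: Path,
                       params: Mapping[str, object]) -> None:
    payload = {
        "params": dict(params),
        "profiles": [
            {
                "id": p.sequence_id,
                "ph_ref": p.ph_ref,
                "ph_int": p.ph_int,
                "overall_charge_score": p.overall_charge_score,
                "residues": [
                    {"position": r.position, "aa": r.aa,
                     "charge_ref": r.charge_ref, "charge_int": r.charge_int,
                     "delta": r.delta}
                    for r in p.residues
                ],
            }
            for p in profiles
        ],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")


def write_ranking_tsv(result: RankedScanResult, path: Path,
                      params: Mapping[str, object]) -> None:
    shift_cols = [f"score_{lo:g}to{hi:g}"
                  for lo, hi in zip(result.grid, result.grid[1:])]
    rows = [
        (e.sequence_id, *(_fmt(s) for s in e.shift_scores),
         _fmt(e.mean_score), e.rank)
        for e in result.entries
    ]
    _write(path, params, ["id", *shift_cols, "mean_score", "rank"], rows)


def write_ranking_json(result: RankedScanResult, path: Path,
                       params: Mapping[str, object]) -> None:
    payload = {
        "params": dict(params),
        "grid": list(result.grid),
        "entries": [
            {"id": e.sequence_id, "shift_scores": list(e.shift_scores),
             "mean_score": e.mean_score, "rank": e.rank}
            for e in result.entries
        ],
        "skipped": [{"id": rid, "reason": reason} for rid, reason in result.skipped],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")


# --- structure mode -----------------------------------------------------------

def write_shift_tsv(report: ShiftReport, path: Path,
                    params: Mapping[str, object]) -> None:
    rows = [
        (r.key.residue.chain, r.key.residue.res_seq, r.res_name, r.key.group,
         f"{r.pka:.2f}", r.state_low.formal_charge, r.state_high.formal_charge)
        for r in report.shifting
    ]
    _write(path, params,
           ["chain", "res_seq", "res_name", "group", "pka",
            f"charge_pH{report.ph_low:g}", f"charge_pH{report.ph_high:g}"], rows)


def write_interactions_tsv(iset: InteractionSet, path: Path,
                           params: Mapping[str, object]) -> None:
    rows = [
        (r.kind, r.key_a.chain, r.key_a.res_seq, r.label_a,
         r.key_b.chain, r.key_b.res_seq, r.label_b,
         f"{r.distance:.3f}", "" if r.angle is None else f"{r.angle:.1f}",
         int(r.state_dependent))
        for r in iset.records
    ]
    _write(path, params,
           ["kind", "chain_a", "res_a", "label_a", "chain_b", "res_b",
            "label_b", "distance", "angle", "state_dependent"], rows)


def write_delta_tsv(delta: InteractionDelta, path: Path,
                    params: Mapping[str, object]) -> None:
    rows = [
        (change, r.kind, r.key_a.chain, r.key_a.res_seq, r.label_a,
         r.key_b.chain, r.key_b.res_seq, r.label_b, f"{r.distance:.3f}")
        for change, records in (("created", delta.created),
                                ("destroyed", delta.destroyed))
        for r in records
    ]
    _write(path, params,
           ["change", "kind", "chain_a", "res_a", "label_a",
            "chain_b", "res_b", "label_b", "distance"], rows)


def write_patches_tsv(result: PatchResult, path: Path,
                      params: Mapping[str, object]) -> None:
    rows = []
    for i, patch in enumerate(result.patches, start=1):
        rows.append((f"patch_{i}", patch.size,
                     ",".join(str(k) for k in patch.members),
                     patch.radius_used, patch.min_size_used))
    for i, members in enumerate(result.near_patch, start=1):
        rows.append((f"near_{i}", len(members),
                     ",".join(str(k) for k in members), "", ""))
    _write(path, params,
           ["patch_id", "size", "members", "radius", "min_size"], rows)


def write_structure_json(shift: ShiftReport, sets: list[InteractionSet],
                         delta: InteractionDelta, patches: PatchResult,
                         path: Path, params: Mapping[str, object]) -> None:
    def rec(r):
        return {"kind": r.kind,
                "a": str(r.key_a), "label_a": r.label_a,
                "b": str(r.key_b), "label_b": r.label_b,
                "distance": r.distance, "angle": r.angle,
                "state_dependent": r.state_dependent}

    payload = {
        "params": dict(params),
        "shifting": [
            {"residue": str(s.key.residue), "group": s.key.group,
             "res_name": s.res_name, "pka": s.pka,
             "charge_low": s.state_low.formal_charge,
             "charge_high": s.state_high.formal_charge}
            for s in shift.shifting
        ],
        "interactions": {f"pH{s.ph:g}": [rec(r) for r in s.records] for s in sets},
        "delta": {"created": [rec(r) for r in delta.created],
                  "destroyed": [rec(r) for r in delta.destroyed]},
        "patches": [
            {"members": [str(k) for k in p.members], "size": p.size,
             "radius": p.radius_used, "min_size": p.min_size_used}
            for p in patches.patches
        ],
        "near_patch": [[str(k) for k in members] for members in patches.near_patch],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")


def write_pml(shift: ShiftReport, delta: InteractionDelta,
              patches: PatchResult, path: Path,
              params: Mapping[str, object]) -> None:
    """PyMOL coloring script: shifting residues yellow, residues with
    created/destroyed bonds orange, patch members green."""

    def selection(keys) -> str:
        return " or ".join(
            f"(chain {k.chain} and resi {k.res_seq}{k.icode})" for k in keys
        ) or "none"

    lines = _header(params)
    shifting_keys = sorted({r.key.residue for r in shift.shifting})
    delta_keys = sorted(delta.changed_residues())
    patch_keys = sorted({k for p in patches.patches for k in p.members})
    lines += [
        f"select shifting, {selection(shifting_keys)}",
        "color yellow, shifting",
        f"select delta_bonds, {selection(delta_keys)}",
        "color orange, delta_bonds",
        f"select patches, {selection(patch_keys)}",
        "color green, patches",
        "show spheres, patches and name CA",
    ]
    for i, r in enumerate(delta.created + delta.destroyed):
        lines.append(
            f"distance delta_{i}, "
            f"(chain {r.key_a.chain} and resi {r.key_a.res_seq}), "
            f"(chain {r.key_b.chain} and resi {r.key_b.res_seq})"
        )
    path.write_text("\n".join(lines) + "\n")
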