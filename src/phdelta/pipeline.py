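"""End-to-end sequence- and structure-mode runs behind the CLI.

A :class:`RunConfig` gathers every knob of a run; the two ``run_*_mode``
functions read the inputs, execute the analysis and write the full report
bundle (TSV + JSON, and a PyMOL script in structure mode).  All outputs
carry their parameters in a provenance header and are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import reports
from .delta_patches import (
    DEFAULT_MIN_PATCH_SIZE, DEFAULT_PATCH_RADIUS, SIDE_CHAIN_MODE,
    build_patch_graph, find_patches, interaction_delta,
)
from .errors import ConfigError
from .interactions import GeometryParams, detect_all
from .pka import assign_model_pkas, parse_predictor_output, run_predictor
from .protonation import assign_states, shifting_residues
from .sequence_charge import (
    DEFAULT_PKA_TABLE, DEFAULT_RECORD_CAP, PkaTable, ph_scan_rank,
    read_fasta, sequence_charge_profile,
)
from .structure_model import (
    EXPERIMENTAL, PREDICTED, parse_structure, trim_by_confidence,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All parameters of one analysis run."""

    mode: str                       # "sequence" | "structure"
    ph_ref: float = 7.0
    ph_int: float = 7.0
    input_path: str | None = None
    output_dir: str = "phdelta_out"

    # sequence mode
    include_termini: bool = True
    strict_residues: bool = False
    scan_grid: tuple[float, ...] | None = None
    record_cap: int | None = DEFAULT_RECORD_CAP

    # structure mode
    chains: tuple[str, ...] | None = None
    provenance: str = EXPERIMENTAL
    plddt_trim: float | None = None
    keep_ranges: tuple[tuple[str, int, int], ...] = ()
    pka_source: str = "model"       # model | file | run
    pka_file: str | None = None
    geometry: GeometryParams = field(default_factory=GeometryParams)
    patch_radius: float = DEFAULT_PATCH_RADIUS
    min_patch_size: int = DEFAULT_MIN_PATCH_SIZE
    patch_distance_mode: str = SIDE_CHAIN_MODE
    patch_include_termini: bool = False
    pml_output: bool = True

    table: PkaTable = field(default_factory=lambda: DEFAULT_PKA_TABLE)

    def validate(self) -> None:
        if self.mode not in ("sequence", "structure"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for ph in (self.ph_ref, self.ph_int):
            if not (0.0 < ph < 14.0):
                raise ConfigError(f"pH {ph} outside (0, 14)")
        if self.input_path is None:
            raise ConfigError("an input path is required")
        if self.patch_radius <= 0 or self.min_patch_size < 2:
            raise ConfigError("patch radius must be > 0 and min size >= 2")
        if self.pka_source not in ("model", "file", "run"):
            raise ConfigError(f"unknown pka source {self.pka_source!r}")
        if self.pka_source == "file" and not self.pka_file:
            raise ConfigError("--pka-file is required with pka source 'file'")

    def provenance_params(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        d.pop("table")
        return d


def run_sequence_mode(config: RunConfig) -> dict:
    """Sequence mode: per-residue charge profiles and, when a scan grid is
    configured, the collection ranking.  Returns the in-memory results and
    the written file paths."""
    config.validate()
    records = read_fasta(config.input_path)
    if config.record_cap is not None and len(records) > config.record_cap:
        raise ConfigError(
            f"{len(records)} records exceed the cap of {config.record_cap}; "
            "use --force to override"
        )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.provenance_params()

    profiles, skipped = [], []
    for rid, seq in records:
        try:
            profiles.append(sequence_charge_profile(
                seq, config.ph_ref, config.ph_int, config.table,
                include_termini=config.include_termini,
                sequence_id=rid, strict=config.strict_residues,
            ))
        except Exception as exc:
            logger.warning("skipping record %r: %s", rid, exc)
            skipped.append((rid, str(exc)))

    written = {}
    reports.write_profile_tsv(profiles, outdir / "profiles.tsv", params)
    reports.write_profile_json(profiles, outdir / "profiles.json", params)
    written["profiles_tsv"] = outdir / "profiles.tsv"
    written["profiles_json"] = outdir / "profiles.json"

    ranking = None
    if config.scan_grid is not None:
        ranking = ph_scan_rank(
            records, config.scan_grid, config.table,
            include_termini=config.include_termini,
            strict=config.strict_residues, record_cap=config.record_cap,
        )
        reports.write_ranking_tsv(ranking, outdir / "ranking.tsv", params)
        reports.write_ranking_json(ranking, outdir / "ranking.json", params)
        written["ranking_tsv"] = outdir / "ranking.tsv"
        written["ranking_json"] = outdir / "ranking.json"

    logger.info("sequence mode: %d records processed, %d skipped",
                len(profiles), len(skipped))
    return {"profiles": profiles, "ranking": ranking,
            "skipped": skipped, "written": written}


def _resolve_pkas(config: RunConfig, model):
    if config.pka_source == "model":
        return assign_model_pkas(model, config.table)
    if config.pka_source == "file":
        return parse_predictor_output(Path(config.pka_file).read_text(), model)
    return run_predictor(model, Path(config.output_dir) / "predictor")


def run_structure_mode(config: RunConfig) -> dict:
    """Structure mode: protonation shifts, per-pH bond inventories, the
    created/destroyed delta, pH-sensitive patches, and the report bundle."""
    config.validate()
    pdb_text = Path(config.input_path).read_text()
    model = parse_structure(
        pdb_text,
        chain_filter=set(config.chains) if config.chains else None,
        structure_id=Path(config.input_path).stem,
        provenance=config.provenance,
    )
    if config.plddt_trim is not None:
        if config.provenance != PREDICTED:
            raise ConfigError("--plddt-trim requires a predicted model input")
        model = trim_by_confidence(model, config.plddt_trim, config.keep_ranges)

    pkas = _resolve_pkas(config, model)
    states_ref = assign_states(pkas, config.ph_ref)
    states_int = assign_states(pkas, config.ph_int)
    set_ref = detect_all(model, states_ref, config.geometry)
    set_int = detect_all(model, states_int, config.geometry)
    delta = interaction_delta(set_ref, set_int)
    shift = shifting_residues(pkas, config.ph_ref, config.ph_int)
    graph = build_patch_graph(model, shift, config.patch_radius,
                              config.patch_distance_mode,
                              include_termini=config.patch_include_termini)
    patches = find_patches(graph, model, config.patch_radius,
                           config.min_patch_size)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.provenance_params()
    params["predictor_version"] = pkas.predictor_version
    written = {}
    try:
        reports.write_shift_tsv(shift, outdir / "shifting.tsv", params)
        written["shifting_tsv"] = outdir / "shifting.tsv"
        for label, iset in (("ref", set_ref), ("int", set_int)):
            p = outdir / f"interactions_pH{iset.ph:g}_{label}.tsv"
            reports.write_interactions_tsv(iset, p, params)
            written[f"interactions_{label}"] = p
        reports.write_delta_tsv(delta, outdir / "delta.tsv", params)
        written["delta_tsv"] = outdir / "delta.tsv"
        reports.write_patches_tsv(patches, outdir / "patches.tsv", params)
        written["patches_tsv"] = outdir / "patches.tsv"
        reports.write_structure_json(shift, [set_ref, set_int], delta, patches,
                                     outdir / "structure.json", params)
        written["structure_json"] = outdir / "structure.json"
        if config.pml_output:
            reports.write_pml(shift, delta, patches, outdir / "views.pml", params)
            written["pml"] = outdir / "views.pml"
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise

    return {"model": model, "pkas": pkas, "shift": shift,
            "set_ref": set_ref, "set_int": set_int,
            "delta": delta, "graph": graph, "patches": patches,
            "written": written}
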