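"""Pipeline orchestration, table export, and the data-quality report.

``run_pipeline`` wires the full flow — register sources, build the
hierarchy, classify drug properties, aggregate onto parents, map trials,
derive indications — and writes the output tables.  Exports use the
database-style table and column names (molecule_dictionary,
compound_records, molecule_hierarchy, drug_indication, drug_warning) as
CSV with a literal ``\\N`` for NULL, or a single-file SQLite database.
"""

from __future__ import annotations

import csv
import json
import logging
import sqlite3
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

from drugcure import classifiers, hierarchy, trials as trials_mod
from drugcure.core import (
    Registry,
    SRC_FDA_ORANGE_BOOK,
    SRC_CANDIDATES,
    normalize_name,
)
from drugcure.fixtures import FixtureBundle
from drugcure.ontology import load_ontology
from drugcure.registration import IncomingCompound, register_compound
from drugcure.trials import (
    DrugIndication,
    derive_indications,
    disentangle_trial,
    filter_trials,
    flag_redundant_conditions,
    map_condition,
    map_intervention,
    parse_trial_feed,
)

log = logging.getLogger("drugcure")

NULL = r"\N"


@dataclass
class QualityReport:
    """Uniqueness / consistency metrics over the current registry."""

    duplicate_pref_name_pairs: int = 0
    synonyms_multi_mapped: int = 0
    same_name_diff_structure: int = 0
    per_source_counts: dict[str, int] = field(default_factory=dict)
    details: dict[str, list] = field(default_factory=dict)


def quality_report(registry: Registry, links=None) -> QualityReport:
    """Compute the uniqueness and consistency metrics on a registry.

    duplicate_pref_name_pairs counts drug form / parent pairs sharing one
    pref_name (legacy naming); synonyms_multi_mapped counts synonyms or
    trade names attached to more than one drug form;
    same_name_diff_structure counts names shared across entries whose
    InChIKeys differ.
    """
    from drugcure.registration import reconcile_conflicts

    report = QualityReport()

    pref_to_ids: dict[str, set[int]] = {}
    for entry in registry:
        if entry.pref_name:
            pref_to_ids.setdefault(normalize_name(entry.pref_name), set()).add(
                entry.molregno
            )
    dup_pairs = []
    for name, ids in sorted(pref_to_ids.items()):
        if len(ids) > 1:
            if links is not None:
                fams = {links[m].parent_molregno for m in ids if m in links}
                if len(fams) > 1 and len(ids) == len(fams):
                    continue  # distinct families: cross-family duplicate,
                    # counted under same_name_diff_structure instead
            dup_pairs.append((name, sorted(ids)))
    report.duplicate_pref_name_pairs = len(dup_pairs)
    report.details["duplicate_pref_name_pairs"] = dup_pairs

    syn_to_ids: dict[str, set[int]] = {}
    for entry in registry:
        for syn in entry.synonyms:
            syn_to_ids.setdefault(syn.normalized, set()).add(entry.molregno)
    multi = [(s, sorted(ids)) for s, ids in sorted(syn_to_ids.items()) if len(ids) > 1]
    report.synonyms_multi_mapped = len(multi)
    report.details["synonyms_multi_mapped"] = multi

    conflicts = [
        (c.name, list(c.molregnos))
        for c in reconcile_conflicts(registry)
        if c.kind == "name_shared_structure_differs"
    ]
    report.same_name_diff_structure = len(conflicts)
    report.details["same_name_diff_structure"] = conflicts

    from drugcure.core import SRC_NAMES

    per_src: dict[str, set[int]] = {}
    for rec in registry.records:
        label = SRC_NAMES.get(rec.src_id, str(rec.src_id))
        per_src.setdefault(label, set()).add(rec.molregno)
    report.per_source_counts = {k: len(v) for k, v in sorted(per_src.items())}
    return report


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineResult:
    registry: Registry
    links: dict[int, hierarchy.HierarchyLink]
    trial_records: list
    intervention_mappings: list
    condition_mappings: list
    indications: list[DrugIndication]
    manual_queue: dict[str, list] = field(default_factory=dict)
    quality: Optional[QualityReport] = None


def run_pipeline(config: dict) -> PipelineResult:
    """Execute register -> hierarchy -> classify -> trials-map -> indications.

    ``config`` keys: ``source_feed`` (path to a tab-separated feed:
    src_id, pref_name, smiles), ``trials`` (JSON feed path), ``ontology``
    (OBO path), ``efo_to_mesh`` (TSV path), optional ``window`` (start,
    end ISO dates), ``dictionary``/``blocklist`` for the trials mapper,
    ``out`` directory.  Missing input files raise a config error naming
    the path.  Every automatic decision is logged with a rule tag.
    """
    for key in ("source_feed", "trials", "ontology"):
        if key in config and not Path(config[key]).exists():
            raise FileNotFoundError(f"config input missing: {config[key]}")

    registry = Registry()
    if "source_feed" in config:
        with open(config["source_feed"], encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                src_id, pref_name, smiles = (line.split("\t") + ["", ""])[:3]
                incoming = IncomingCompound(
                    src_id=int(src_id),
                    pref_name=pref_name or None,
                    structure_raw=smiles or None,
                )
                outcome = register_compound(registry, incoming)
                log.info("[register] %s -> %s", pref_name, outcome.decision)

    links = hierarchy.build_families(registry)

    # per-form classification then family aggregation
    for entry in list(registry):
        srcs = registry.sources_for(entry.molregno)
        family_srcs = set()
        parent = links[entry.molregno].parent_molregno
        for member, link in links.items():
            if link.parent_molregno == parent:
                family_srcs |= registry.sources_for(member)
        phase, review = classifiers.resolve_max_phase(srcs, family_srcs)
        entry.max_phase = phase
        entry.max_phase_review = review
        if entry.structure is not None:
            entry.inorganic_flag = classifiers.compute_inorganic_flag(entry.structure)
            entry.polymer_flag = classifiers.compute_polymer_flag(
                entry.pref_name, entry.structure
            )
        entry.molecule_type, _ = classifiers.assign_molecule_type(
            entry.pref_name, entry.structure
        )
        entry.chirality, _ = classifiers.assign_chirality(
            entry.structure, entry.pref_name, entry.is_biotherapeutic
        )
        entry.availability_type = classifiers.assign_availability_type(
            SRC_FDA_ORANGE_BOOK in srcs, None, entry.withdrawn_flag, bool(srcs)
        )
    hierarchy.aggregate_family_properties(registry, links)
    hierarchy.propagate_prodrug(registry, links)

    trial_records: list = []
    imaps: list = []
    cmaps: list = []
    indication_rows: list[DrugIndication] = []
    queue: dict[str, list] = {"interventions": [], "conditions": [], "trials": []}
    if "trials" in config and "ontology" in config:
        ontology = load_ontology(config["ontology"])
        feed = parse_trial_feed(Path(config["trials"]).read_text("utf-8"))
        window = None
        if config.get("window"):
            start, end = config["window"]
            window = (date.fromisoformat(start), date.fromisoformat(end))
        trial_records = filter_trials(feed, window)
        dictionary = config.get("dictionary", {})
        blocklist = config.get("blocklist", [])
        for trial in trial_records:
            t_imaps, t_cmaps = [], []
            for name in trial.intervention_names:
                mapping, cands = map_intervention(
                    trial.nct_id, name, registry, dictionary, blocklist
                )
                t_imaps.append(mapping)
                if cands:
                    queue["interventions"].append((trial.nct_id, name, cands))
            for cond in trial.conditions:
                mapping, cands = map_condition(
                    trial.nct_id, cond, ontology, dictionary, blocklist
                )
                t_cmaps.append(mapping)
                if cands:
                    queue["conditions"].append((trial.nct_id, cond, cands))
            t_cmaps, queued = disentangle_trial(
                trial, t_imaps, t_cmaps, ontology,
                threshold=config.get("threshold", 0.85),
            )
            if queued:
                queue["trials"].append(trial.nct_id)
            flag_redundant_conditions(t_cmaps, ontology)
            # drug/candidate provenance for mapped interventions
            for m in t_imaps:
                if isinstance(m.outcome, int):
                    from drugcure.registration import attach_source_record

                    attach_source_record(registry, m.outcome, SRC_CANDIDATES)
            imaps.extend(t_imaps)
            cmaps.extend(t_cmaps)
        efo_to_mesh: dict[str, str] = {}
        if "efo_to_mesh" in config and Path(config["efo_to_mesh"]).exists():
            for line in Path(config["efo_to_mesh"]).read_text("utf-8").splitlines():
                if line.strip() and not line.startswith("#"):
                    efo, mesh = line.split("\t")[:2]
                    efo_to_mesh[efo] = mesh
        indication_rows = derive_indications(
            trial_records, imaps, cmaps, efo_to_mesh,
            config.get("approved_pairs", ()),
        )
        # trial evidence feeds back into max_phase
        phase_by_mol: dict[int, list[str]] = {}
        for trial in trial_records:
            for m in imaps:
                if m.nct_id == trial.nct_id and isinstance(m.outcome, int):
                    phase_by_mol.setdefault(m.outcome, []).append(trial.phase)
        for molregno, phases in phase_by_mol.items():
            entry = registry.get(molregno)
            srcs = registry.sources_for(molregno)
            phase, review = classifiers.resolve_max_phase(srcs, srcs, phases)
            if phase is not None and (
                entry.max_phase is None
                or hierarchy.PHASE_ORDER.get(phase, 0)
                > hierarchy.PHASE_ORDER.get(entry.max_phase, 0)
            ):
                entry.max_phase = phase
                entry.max_phase_review = review
        hierarchy.aggregate_family_properties(registry, links)

    result = PipelineResult(
        registry=registry,
        links=links,
        trial_records=trial_records,
        intervention_mappings=imaps,
        condition_mappings=cmaps,
        indications=indication_rows,
        manual_queue=queue,
    )
    result.quality = quality_report(registry, links)
    if config.get("out"):
        export_tables(result, config["out"], config.get("format", "csv"))
        _write_queues(queue, config["out"])
    return result


def _write_queues(queue: dict[str, list], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for kind, rows in queue.items():
        path = outdir / f"review_{kind}.tsv"
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                if isinstance(row, tuple):
                    nct, text, cands = row
                    cand_text = ";".join(f"{n}={t}" for n, t in cands)
                    fh.write(f"{nct}\t{text}\t{cand_text}\n")
                else:
                    fh.write(f"{row}\n")


# ---------------------------------------------------------------------------
# table export


def _null(value) -> str:
    if value is None:
        return NULL
    if isinstance(value, bool):
        return str(int(value))
    return str(value)


def _tables(result: PipelineResult) -> dict[str, tuple[list[str], list[list[str]]]]:
    registry, links = result.registry, result.links
    md_cols = [
        "molregno", "pref_name", "max_phase", "molecule_type", "chirality",
        "prodrug", "first_in_class", "oral", "parenteral", "topical",
        "availability_type", "therapeutic_flag", "withdrawn_flag",
        "black_box_warning", "dosed_ingredient", "first_approval",
        "usan_year", "usan_stem", "orphan", "veterinary", "inorganic_flag",
        "polymer_flag", "canonical_smiles", "standard_inchi_key",
    ]
    md_rows = []
    for m in sorted(registry.entries):
        e = registry.get(m)
        md_rows.append([
            _null(e.molregno), _null(e.pref_name), _null(e.max_phase),
            _null(e.molecule_type), _null(e.chirality), _null(e.prodrug),
            _null(e.first_in_class), _null(e.oral), _null(e.parenteral),
            _null(e.topical), _null(e.availability_type),
            _null(e.therapeutic_flag), _null(e.withdrawn_flag),
            _null(e.black_box_warning), _null(e.dosed_ingredient),
            _null(e.first_approval), _null(e.usan_year), _null(e.usan_stem),
            _null(e.orphan), _null(e.veterinary), _null(e.inorganic_flag),
            _null(e.polymer_flag),
            _null(e.structure.canonical_smiles if e.structure else None),
            _null(e.structure.std_inchikey if e.structure else None),
        ])
    cr_cols = ["record_id", "molregno", "src_id", "source_name", "extraction_date"]
    cr_rows = [
        [_null(r.record_id), _null(r.molregno), _null(r.src_id),
         _null(r.source_name), _null(r.extraction_date)]
        for r in sorted(registry.records, key=lambda r: r.record_id)
    ]
    mh_cols = ["molregno", "parent_molregno", "active_molregno"]
    mh_rows = [
        [_null(l.molregno), _null(l.parent_molregno), _null(l.active_molregno)]
        for l in sorted(links.values(), key=lambda l: l.molregno)
    ]
    di_cols = ["molregno", "mesh_id", "efo_id", "max_phase_for_ind", "nct_ids"]
    di_rows = [
        [_null(i.molregno), _null(i.mesh_id), _null(i.efo_id),
         _null(i.max_phase_for_ind), ";".join(i.nct_ids)]
        for i in result.indications
    ]
    return {
        "molecule_dictionary": (md_cols, md_rows),
        "compound_records": (cr_cols, cr_rows),
        "molecule_hierarchy": (mh_cols, mh_rows),
        "drug_indication": (di_cols, di_rows),
    }


def export_tables(
    result: PipelineResult, outdir: str | Path, fmt: str = "csv"
) -> list[Path]:
    """Write the output tables as CSV files or one SQLite database."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = _tables(result)
    written: list[Path] = []
    if fmt == "csv":
        for name, (cols, rows) in tables.items():
            path = outdir / f"{name}.csv"
            with open(path, "w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh)
                writer.writerow(cols)
                writer.writerows(rows)
            written.append(path)
    elif fmt == "sqlite":
        path = outdir / "drugcure.db"
        if path.exists():
            path.unlink()
        con = sqlite3.connect(path)
        for name, (cols, rows) in tables.items():
            col_defs = ", ".join(f'"{c}" TEXT' for c in cols)
            con.execute(f'CREATE TABLE "{name}" ({col_defs})')
            con.executemany(
                f'INSERT INTO "{name}" VALUES ({",".join("?" * len(cols))})',
                rows,
            )
        con.commit()
        con.close()
        written.append(path)
    else:
        raise ValueError(f"unsupported export format: {fmt!r}")
    return written


def read_table(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Re-import an exported CSV table (round-trip check helper)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    return rows[0], rows[1:]
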