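"""Orchestrate the full analysis as one reproducible run.

Stages: simulate (or load real tables) -> validate -> community -> associate
-> strains -> taxfun.  Every stage writes plain tab-delimited or JSON output
under the run directory and the run ends with a machine-readable manifest
(config snapshot, seed, per-stage output digests, timings, package version).
One global seed is expanded deterministically into per-stage seeds, so
rerunning with identical config and seed reproduces identical digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association, community_analysis, strain_fingerprint, taxon_function
from .profile_io import (
    ProfileFormatError,
    read_carriage_matrix,
    read_marker_profiles,
    read_metadata,
    read_module_profile,
    read_taxonomic_profile,
    validate_cohort_tables,
    write_marker_profiles,
    write_table,
)
from .synthetic_cohort import CohortConfig, PlantedEffect, SyntheticCohort, generate_cohort

__all__ = ["run_pipeline", "report", "load_config", "MissingInputError"]

log = logging.getLogger("twinmeta")

STAGES = ("simulate", "validate", "community", "associate", "strains", "taxfun")


class MissingInputError(FileNotFoundError):
    """A configured input file does not exist (CLI exit code 2)."""


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ProfileFormatError("config needs either a 'simulate' or an 'inputs' block")
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_cohort(cohort: SyntheticCohort, data_dir: Path) -> None:
    data_dir.mkdir(parents=True, exist_ok=True)
    write_table(cohort.abundance, data_dir / "abundance.tsv")
    write_table(cohort.functions, data_dir / "modules.tsv")
    write_table(cohort.metadata, data_dir / "metadata.tsv")
    write_table(cohort.carriage, data_dir / "carriage.tsv")
    write_marker_profiles(cohort.markers, data_dir / "markers")
    truth = {
        "planted_effects": [list(e) for e in cohort.truth.planted_effects],
        "pair_of_subject": cohort.truth.pair_of_subject,
        "cooccurrence_group": cohort.truth.cooccurrence_group,
        "barcodes": {
            sp: {s: [int(x) for x in bc] for s, bc in by_sample.items()}
            for sp, by_sample in cohort.truth.barcodes.items()
        },
    }
    (data_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def simulate_to_dir(sim_cfg: dict, out_dir, seed: int | None = None) -> SyntheticCohort:
    """Build a cohort from a config mapping and write its tables to ``out_dir``."""
    sim_cfg = dict(sim_cfg)
    effects = [PlantedEffect(*e) for e in sim_cfg.pop("planted_effects", [])]
    if seed is not None and "seed" not in sim_cfg:
        sim_cfg["seed"] = seed
    cohort = generate_cohort(CohortConfig(planted_effects=tuple(effects), **sim_cfg))
    _write_cohort(cohort, Path(out_dir))
    return cohort


def _load_inputs(inputs: dict):
    paths = {k: Path(v) for k, v in inputs.items()}
    for name, p in paths.items():
        if not p.exists():
            raise MissingInputError(f"{name} input not found: {p}")
    abundance = read_taxonomic_profile(paths["abundance"], rank="species")
    functions = read_module_profile(paths["modules"]) if "modules" in paths else None
    markers = read_marker_profiles(paths["markers"]) if "markers" in paths else None
    metadata = read_metadata(paths["metadata"])
    carriage = read_carriage_matrix(paths["carriage"]) if "carriage" in paths else None
    return abundance, functions, markers, metadata, carriage


def run_pipeline(config, out_dir) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stage_seeds = {
        stage: int(s.generate_state(1)[0] % (2**31))
        for stage, s in zip(STAGES, np.random.SeedSequence(seed).spawn(len(STAGES)))
    }
    manifest: dict = {
        "config": config,
        "seed": seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
    }
    timings: dict[str, float] = {}

    def stage_done(name: str, files: list[Path], t0: float) -> None:
        timings[name] = round(time.time() - t0, 3)
        manifest["stages"][name] = {
            "seconds": timings[name],
            "outputs": {str(f.relative_to(out)): _digest(f) for f in files},
        }
        log.info("stage %s done in %.2fs (%d outputs)", name, timings[name], len(files))

    # --- simulate or load ---------------------------------------------------
    t0 = time.time()
    data_dir = out / "data"
    if "simulate" in config:
        cohort = simulate_to_dir(config["simulate"], data_dir, seed=stage_seeds["simulate"])
        abundance, functions, markers, metadata, carriage = (
            cohort.abundance,
            cohort.functions,
            cohort.markers,
            cohort.metadata,
            cohort.carriage,
        )
        stage_done("simulate", sorted(p for p in data_dir.rglob("*") if p.is_file()), t0)
    else:
        abundance, functions, markers, metadata, carriage = _load_inputs(config["inputs"])
        stage_done("simulate", [], t0)

    # --- validate -----------------------------------------------------------
    t0 = time.time()
    validate_cohort_tables(abundance, functions, markers, metadata, carriage)
    stage_done("validate", [], t0)

    # --- community ----------------------------------------------------------
    t0 = time.time()
    comm_dir = out / "community"
    comm_dir.mkdir(exist_ok=True)
    dm = community_analysis.distance_matrix(abundance)
    dm.to_frame().to_csv(comm_dir / "bray_curtis.tsv", sep="\t")
    ord_res = community_analysis.ordinate(dm, k=min(2, len(dm.ids) - 1))
    ord_res.coordinates.to_csv(comm_dir / "ordination.tsv", sep="\t")
    pairs = community_analysis.enumerate_pairs(metadata)
    groups_out: dict = {}
    dist_vals = community_analysis.pair_distance_values(pairs, dm)
    contrasts = [c for c in community_analysis.DEFAULT_CONTRASTS
                 if len(dist_vals.get(c[0], [])) >= 2 and len(dist_vals.get(c[1], [])) >= 2]
    if contrasts:
        gc = community_analysis.compare_groups(dist_vals, contrasts=contrasts)
        groups_out["bray_curtis"] = {
            "means": gc.means,
            "tests": {f"{a}_vs_{b}": {"t": t, "p": p} for (a, b), (t, p) in gc.tests.items()},
        }
        if "bmi" in metadata.data.columns:
            bmi_vals = community_analysis.pair_difference_values(pairs, metadata, "bmi")
            gb = community_analysis.compare_groups(bmi_vals, contrasts=contrasts)
            groups_out["abs_bmi_difference"] = {
                "means": gb.means,
                "tests": {f"{a}_vs_{b}": {"t": t, "p": p} for (a, b), (t, p) in gb.tests.items()},
            }
    (comm_dir / "group_comparisons.json").write_text(json.dumps(groups_out, indent=1))
    summary = community_analysis.summarize_cohort(abundance)
    summary.table.to_csv(comm_dir / "cohort_summary.tsv", sep="\t")
    stage_done("community", sorted(comm_dir.glob("*")), t0)

    # --- associate ----------------------------------------------------------
    t0 = time.time()
    assoc_cfg = association.AssociationConfig(
        seed=stage_seeds["associate"], **config.get("associate", {})
    )
    results = association.run_association(abundance, metadata, assoc_cfg)
    if functions is not None:
        fn_results = association.run_association(functions, metadata, assoc_cfg)
        results = pd.concat([results, fn_results], ignore_index=True)
        results["q"] = association.fdr_bh(results["p"].to_numpy()) if len(results) else results["q"]
    results.to_csv(out / "associations.tsv", sep="\t", index=False)
    stage_done("associate", [out / "associations.tsv"], t0)

    # --- strains ------------------------------------------------------------
    t0 = time.time()
    strain_dir = out / "strains"
    strain_dir.mkdir(exist_ok=True)
    strain_files: list[Path] = []
    if markers is not None:
        strain_cfg = config.get("strains", {})
        comparisons = strain_fingerprint.strain_comparisons(
            markers, pairs, min_median_rpk=strain_cfg.get("min_median_rpk", 5.0)
        )
        comp_df = pd.DataFrame(
            [(c.species, c.sample_a, c.sample_b, c.pair_type, c.distance) for c in comparisons],
            columns=["species", "sample_a", "sample_b", "pair_type", "distance"],
        )
        comp_df.to_csv(strain_dir / "comparisons.tsv", sep="\t", index=False)
        strain_fingerprint.species_mean_divergence(comparisons).to_csv(
            strain_dir / "species_divergence.tsv", sep="\t", index=False
        )
        strain_fingerprint.barcode_discordance_table(markers, comparisons).to_csv(
            strain_dir / "barcode_diff.tsv", sep="\t", index=False
        )
        by_type = comp_df.groupby("pair_type").size().to_dict()
        ok = [c for c in (("unrelated", "twin"), ("twin", "self"))
              if by_type.get(c[0], 0) >= 2 and by_type.get(c[1], 0) >= 2]
        tests_out: dict = {}
        if ok:
            gc = strain_fingerprint.compare_strain_groups(comparisons, contrasts=ok)
            tests_out = {
                "means": gc.means,
                "tests": {f"{a}_vs_{b}": {"t": t, "p": p} for (a, b), (t, p) in gc.tests.items()},
            }
        (strain_dir / "group_tests.json").write_text(json.dumps(tests_out, indent=1))
        strain_files = sorted(strain_dir.glob("*"))
    stage_done("strains", strain_files, t0)

    # --- taxfun -------------------------------------------------------------
    t0 = time.time()
    tf_files: list[Path] = []
    if functions is not None and carriage is not None:
        tf_dir = out / "taxfun"
        tf_dir.mkdir(exist_ok=True)
        tf_cfg = config.get("taxfun", {})
        records = taxon_function.correlation_matrix(abundance, functions)
        network = taxon_function.cooccurrence_network(abundance)
        records = taxon_function.classify_correlations(
            records, carriage, network, encoded_threshold=tf_cfg.get("encoded_threshold", 0.5)
        )
        records.to_csv(tf_dir / "records.tsv", sep="\t", index=False)
        edges = pd.DataFrame(sorted(tuple(sorted(e)) for e in network.edges), columns=["taxon_a", "taxon_b"])
        edges.to_csv(tf_dir / "network_edges.tsv", sep="\t", index=False)
        tf_files = sorted(tf_dir.glob("*"))
    stage_done("taxfun", tf_files, t0)

    manifest["outputs"] = {
        str(p.relative_to(out)): _digest(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest


def report(out_dir) -> dict:
    """Human-readable and machine-readable summary of a completed run."""
    out = Path(out_dir)
    required = ["manifest.json", "associations.tsv", "community/group_comparisons.json"]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise MissingInputError(f"incomplete run directory, missing: {missing}")
    manifest = json.loads((out / "manifest.json").read_text())
    assoc = pd.read_csv(out / "associations.tsv", sep="\t")
    q_thr = manifest["config"].get("associate", {}).get("q_threshold", 0.2)
    summary: dict = {
        "version": manifest.get("version"),
        "seed": manifest.get("seed"),
        "associations": {
            "tested": int(len(assoc)),
            "significant": int((assoc["q"] < q_thr).sum()) if len(assoc) else 0,
            "q_threshold": q_thr,
        },
        "community": json.loads((out / "community/group_comparisons.json").read_text()),
    }
    strain_file = out / "strains/group_tests.json"
    if strain_file.exists():
        summary["strains"] = json.loads(strain_file.read_text())
    records_file = out / "taxfun/records.tsv"
    if records_file.exists():
        records = pd.read_csv(records_file, sep="\t")
        summary["taxon_function"] = {
            "records": int(len(records)),
            "classes": records["class"].value_counts().to_dict(),
        }
    lines = [f"twinmeta run (seed={summary['seed']}, version {summary['version']})"]
    a = summary["associations"]
    if a["tested"] == 0 or a["significant"] == 0:
        lines.append(f"associations: none significant (q < {a['q_threshold']}, {a['tested']} tested)")
    else:
        lines.append(
            f"associations: {a['significant']} significant of {a['tested']} tested (q < {a['q_threshold']})"
        )
    if "strains" in summary and summary["strains"]:
        for name, test in summary["strains"].get("tests", {}).items():
            lines.append(f"strain contrast {name}: p = {test['p']:.3g}")
    if "taxon_function" in summary:
        tf = summary["taxon_function"]
        lines.append(f"taxon-function: {tf['records']} records, classes {tf['classes']}")
    summary["text"] = "\n".join(lines)
    return summary
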