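"""End-to-end pipeline orchestration from a single JSON config.

Stages: curate -> sample groups -> NN analysis -> dataset conditions ->
diagnostic ML (per model x condition) -> analog statistics -> target
network.  Every stage writes its artifact into the output directory and
logs timings to stderr; a stage failure aborts with the stage name.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from promidiag.activity_data import (
    AssayFilterConfig,
    filter_assays,
    read_activity_triplets,
    read_compound_library,
    remove_flagged_compounds,
    write_activity_triplets,
)
from promidiag.chem_similarity import (
    MT,
    ST,
    export_nn_table,
    nn_profile,
    read_fingerprints,
)
from promidiag.dataset_conditions import (
    Condition,
    ConditionConfig,
    nn_removal,
    random_removal,
    write_removal_manifest,
)
from promidiag.diagnostic_ml import (
    CVProtocol,
    KNNConfig,
    MODELS,
    RFConfig,
    SVMConfig,
    run_double_cv,
    summarize_trials,
    write_trial_results,
)
from promidiag.errors import ConfigError, PipelineStageError
from promidiag.group_sampling import GroupSamplingConfig, build_groups, write_groups
from promidiag.structure_analysis import (
    analog_fraction_from_series,
    build_target_network,
    write_edge_list,
    write_graphml,
)
from promidiag.synthetic_data import read_ground_truth

logger = logging.getLogger("promidiag")

SCHEMA_VERSION = 1

_TOP_KEYS = {
    "schema_version",
    "inputs",
    "curation",
    "sampling",
    "conditions",
    "conditions_config",
    "protocol",
    "grids",
    "models",
    "analogs",
    "network",
    "out_dir",
    "seed",
}


@dataclass
class PipelineConfig:
    matrix_path: Path
    fingerprints_path: Path
    flags_path: Optional[Path] = None
    smiles_path: Optional[Path] = None
    ground_truth_path: Optional[Path] = None
    assay_filter: AssayFilterConfig = field(default_factory=AssayFilterConfig)
    apply_hit_rate_filter: bool = True
    sampling: GroupSamplingConfig = field(default_factory=GroupSamplingConfig)
    conditions: Sequence[Condition] = (Condition.FULL, Condition.RANDOM_REMOVAL, Condition.NN_REMOVAL)
    protocol: CVProtocol = field(default_factory=CVProtocol)
    knn_config: KNNConfig = field(default_factory=KNNConfig)
    rf_config: RFConfig = field(default_factory=RFConfig)
    svm_config: SVMConfig = field(default_factory=SVMConfig)
    models: Sequence[str] = MODELS
    network_min_shared: int = 50
    out_dir: Path = Path("promidiag_out")
    seed: int = 0


def validate_config(path) -> PipelineConfig:
    """Load and schema-check a JSON pipeline config, filling defaults.

    All violations are collected and reported together.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    problems: List[str] = []

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown top-level keys: {sorted(unknown)}")
    if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        problems.append(f"unsupported schema_version {raw.get('schema_version')}")

    inputs = raw.get("inputs", {})
    if "matrix" not in inputs or "fingerprints" not in inputs:
        problems.append("inputs must define 'matrix' and 'fingerprints' paths")

    def resolve(key: str) -> Optional[Path]:
        if key not in inputs:
            return None
        p = Path(inputs[key])
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            problems.append(f"input file does not exist: {p}")
        return p

    matrix_path = resolve("matrix")
    fingerprints_path = resolve("fingerprints")
    flags_path = resolve("flags")
    smiles_path = resolve("smiles")
    ground_truth_path = resolve("ground_truth")

    curation = raw.get("curation", {})
    try:
        assay_filter = AssayFilterConfig(
            max_hit_rate=curation.get("max_hit_rate", 0.02),
            exclude_flags=curation.get(
                "exclude_flags", ["PAINS", "AGGREGATOR", "LIABILITY", "FLUC", "CYTOTOXIC"]
            ),
        )
    except (ConfigError, ValueError) as exc:
        problems.append(f"curation: {exc}")
        assay_filter = AssayFilterConfig()
    apply_hit_rate_filter = bool(curation.get("apply_hit_rate_filter", True))

    seed = int(raw.get("seed", 0))
    sampling_raw = raw.get("sampling", {})
    try:
        sampling = GroupSamplingConfig(
            pd_threshold=sampling_raw.get("pd_threshold", 5),
            rng_seed=sampling_raw.get("rng_seed", seed),
        )
    except ConfigError as exc:
        problems.append(f"sampling: {exc}")
        sampling = GroupSamplingConfig()

    cond_names = raw.get("conditions", ["FULL", "RANDOM_REMOVAL", "NN_REMOVAL"])
    conditions: List[Condition] = []
    for name in cond_names:
        try:
            conditions.append(Condition(name))
        except ValueError:
            problems.append(f"unknown condition {name!r}")
    cond_raw = raw.get("conditions_config", {})  # reserved; kept strict below
    try:
        # validate the removal fractions even when defaults are used
        ConditionConfig(
            condition=Condition.NN_REMOVAL,
            removal_fraction=cond_raw.get("removal_fraction", 0.5),
            nn_fraction_mt=cond_raw.get("nn_fraction_mt", 0.25),
            nn_fraction_st=cond_raw.get("nn_fraction_st", 0.25),
        )
    except ConfigError as exc:
        problems.append(f"conditions: {exc}")

    proto_raw = raw.get("protocol", {})
    try:
        protocol = CVProtocol(
            n_external_trials=proto_raw.get("n_external_trials", 10),
            test_fraction=proto_raw.get("test_fraction", 0.2),
            n_internal_trials=proto_raw.get("n_internal_trials", 10),
            internal_test_fraction=proto_raw.get("internal_test_fraction", 0.2),
            rng_seed=proto_raw.get("rng_seed", seed),
        )
    except ConfigError as exc:
        problems.append(f"protocol: {exc}")
        protocol = CVProtocol()

    models = raw.get("models", list(MODELS))
    for m in models:
        if m not in MODELS:
            problems.append(f"unknown model {m!r}")

    grids = raw.get("grids", {})
    knn_config, rf_config, svm_config = KNNConfig(), RFConfig(), SVMConfig()
    try:
        if "knn_k" in grids:
            knn_config = KNNConfig(k_grid=tuple(grids["knn_k"]))
        if "rf_n_estimators" in grids or "rf_min_samples_split" in grids:
            rf_config = RFConfig(
                n_estimators_grid=tuple(grids.get("rf_n_estimators", RFConfig().n_estimators_grid)),
                min_samples_split_grid=tuple(
                    grids.get("rf_min_samples_split", RFConfig().min_samples_split_grid)
                ),
            )
        if "svm_c" in grids or "svm_kernels" in grids:
            svm_config = SVMConfig(
                c_grid=tuple(grids.get("svm_c", SVMConfig().c_grid)),
                kernels=tuple(grids.get("svm_kernels", SVMConfig().kernels)),
            )
    except ConfigError as exc:
        problems.append(f"grids: {exc}")

    network = raw.get("network", {})
    min_shared = int(network.get("min_shared", 50))

    if problems:
        raise ConfigError("invalid pipeline config:\n  - " + "\n  - ".join(problems))

    return PipelineConfig(
        matrix_path=matrix_path,
        fingerprints_path=fingerprints_path,
        flags_path=flags_path,
        smiles_path=smiles_path,
        ground_truth_path=ground_truth_path,
        assay_filter=assay_filter,
        apply_hit_rate_filter=apply_hit_rate_filter,
        sampling=sampling,
        conditions=tuple(conditions),
        protocol=protocol,
        knn_config=knn_config,
        rf_config=rf_config,
        svm_config=svm_config,
        models=tuple(models),
        network_min_shared=min_shared,
        out_dir=Path(raw.get("out_dir", "promidiag_out")),
        seed=seed,
    )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute all stages and return a run report (paths + summary rows)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {"out_dir": str(out_dir), "stages": []}

    @_stage("curate")
    def curate():
        matrix = read_activity_triplets(config.matrix_path)
        if config.flags_path is not None:
            library = read_compound_library(
                smiles_path=config.smiles_path, flags_path=config.flags_path
            )
            known = {r.id for r in library}
            from promidiag.activity_data import CompoundRecord

            records = list(library) + [
                CompoundRecord(id=c) for c in sorted(matrix.compounds - known)
            ]
            matrix, curation_report = remove_flagged_compounds(matrix, records, config.assay_filter)
            with (out_dir / "curation_report.json").open("w", encoding="utf-8") as fh:
                json.dump(
                    {
                        "n_original": curation_report.n_original,
                        "n_final": curation_report.n_final,
                        "n_removed": curation_report.n_removed,
                        "removed_by_flag": {
                            f.value: n for f, n in curation_report.removed_by_flag.items()
                        },
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
        if config.apply_hit_rate_filter:
            matrix = filter_assays(matrix, config.assay_filter)
        write_activity_triplets(matrix, out_dir / "curated_triplets.tsv")
        return matrix

    matrix = curate()
    report["stages"].append("curate")

    @_stage("groups")
    def sample():
        groups = build_groups(matrix, config.sampling)
        if not groups:
            raise ValueError("no MT-/ST-CPD groups could be sampled from the curated matrix")
        write_groups(groups, out_dir / "groups.jsonl")
        return groups

    groups = sample()
    report["stages"].append("groups")
    report["n_groups"] = len(groups)

    fingerprints = read_fingerprints(config.fingerprints_path)

    @_stage("nn")
    def nn_stage():
        labels = {g.mt: MT for g in groups}
        for g in groups:
            for st in g.st_compounds:
                labels.setdefault(st, ST)
        profile = nn_profile({c: fingerprints[c] for c in labels}, labels)
        export_nn_table(profile, out_dir / "nn_table.tsv")
        return profile

    nn_stage()
    report["stages"].append("nn")

    cond_groups: Dict[Condition, List] = {}

    @_stage("reduce")
    def reduce_stage():
        for condition in config.conditions:
            cfg = ConditionConfig(condition=condition, rng_seed=config.seed)
            if condition is Condition.FULL:
                cond_groups[condition] = list(groups)
                continue
            if condition is Condition.RANDOM_REMOVAL:
                cond_groups[condition] = random_removal(
                    groups, cfg, np.random.default_rng(cfg.rng_seed)
                )
            else:
                survivors, manifest = nn_removal(groups, fingerprints, cfg, return_manifest=True)
                cond_groups[condition] = survivors
                write_removal_manifest(manifest, out_dir / "nn_removal_manifest.tsv")
            write_groups(cond_groups[condition], out_dir / f"groups_{condition.value.lower()}.jsonl")

    reduce_stage()
    report["stages"].append("reduce")

    summary_rows: List[Dict[str, object]] = []

    @_stage("ml")
    def ml_stage():
        for condition in config.conditions:
            for model in config.models:
                results = run_double_cv(
                    cond_groups[condition],
                    model,
                    fingerprints,
                    protocol=config.protocol,
                    knn_config=config.knn_config,
                    rf_config=config.rf_config,
                    svm_config=config.svm_config,
                )
                write_trial_results(
                    results,
                    out_dir / f"trials_{model.lower()}_{condition.value.lower()}.tsv",
                    condition=condition.value,
                )
                stats = summarize_trials(results)
                row: Dict[str, object] = {"condition": condition.value, "model": model}
                for measure in ("ba", "f1", "mcc", "precision", "recall"):
                    mean, sd = stats[measure]
                    row[f"{measure}_mean"] = mean
                    row[f"{measure}_sd"] = sd
                summary_rows.append(row)

    ml_stage()
    report["stages"].append("ml")

    @_stage("analogs")
    def analogs_stage():
        if config.ground_truth_path is None:
            return None
        truth = read_ground_truth(config.ground_truth_path)
        mt_ids = {g.mt for g in groups}
        st_ids = {st for g in groups for st in g.st_compounds}
        stats = {
            "mt_analog_fraction": analog_fraction_from_series(
                {c: truth.series[c] for c in sorted(mt_ids)}
            ),
            "st_analog_fraction": analog_fraction_from_series(
                {c: truth.series[c] for c in sorted(st_ids)}
            ),
        }
        with (out_dir / "analog_stats.json").open("w", encoding="utf-8") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True)
        return stats

    analog_stats = analogs_stage()
    report["stages"].append("analogs")
    if analog_stats:
        report["analog_stats"] = analog_stats

    @_stage("network")
    def network_stage():
        mt_target_map = {g.mt: set(g.targets) for g in groups if len(g.targets) >= 2}
        graph = build_target_network(mt_target_map, min_shared=config.network_min_shared)
        write_edge_list(graph, out_dir / "target_network_edges.tsv")
        write_graphml(graph, out_dir / "target_network.graphml")
        return graph

    network_stage()
    report["stages"].append("network")

    with (out_dir / "summary.tsv").open("w", encoding="utf-8") as fh:
        measures = ("ba", "f1", "mcc", "precision", "recall")
        fh.write("condition\tmodel\t" + "\t".join(m.upper() for m in measures) + "\n")
        for row in summary_rows:
            cells = [
                f"{row[f'{m}_mean']:.3f} ± {row[f'{m}_sd']:.3f}" for m in measures
            ]
            fh.write(f"{row['condition']}\t{row['model']}\t" + "\t".join(cells) + "\n")
    report["summary"] = summary_rows
    with (out_dir / "run_report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
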