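"""End-to-end orchestration: simulate -> normalize -> rhythm -> classify -> select.

A :class:`RunConfig` captures every tunable of the study in one declarative,
versioned structure; :func:`validate_config` fills defaults (DE alpha 0.001,
FDR 0.05, fold-change gate 0.8/1.2, tau 24 h, Grubbs alpha 0.1) and rejects
unknown keys with their path. :func:`run_study` executes the whole analysis
in memory; :func:`run_pipeline` additionally writes each stage's tables into
numbered subdirectories with config-hash headers and returns a run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import normalize as _normalize
from . import rhythm as _rhythm
from . import select as _select
from . import simulate as _simulate
from .errors import ConfigError, StageError
from .io import write_gene_list, write_json, write_tsv

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class DesignSection:
    stages: tuple[str, ...] = _simulate.STAGES
    protocols: tuple[str, ...] = _simulate.PROTOCOLS
    zts: tuple[int, ...] = _simulate.DEFAULT_ZTS
    baseline_replicates: int = 4
    shifted_replicates: int = 2

    def replicates(self) -> dict[str, int]:
        return {
            stage: self.baseline_replicates if stage == "baseline" else self.shifted_replicates
            for stage in self.stages
        }


@dataclass(frozen=True)
class GenesSection:
    n_null: int = 1790
    n_circadian: int = 200
    n_crd: int = 10
    n_crd_secreted: int = 5
    mesor: float = 8.0
    amplitude: float = 1.0
    rec14_fold_change: float = 1.5
    persistence: float = 1.0
    noise_sd: float = 0.1
    spot_noise_sd: float = 0.1
    probe_offset_sd: float = 0.3
    probes_per_gene: int = 1
    n_age_listed_null: int = 50


@dataclass(frozen=True)
class ThresholdsSection:
    de_alpha: float = 0.001
    fdr: float = 0.05
    fc_low: float = 0.8
    fc_high: float = 1.2
    tau: float = 24.0
    grubbs_alpha: float = 0.1


@dataclass(frozen=True)
class ClassifySection:
    methods: tuple[str, ...] = _classify.METHODS
    top_k: int = 50
    majority: float = 0.5
    n_trees: int = 1000
    svm_c: float = 1.0
    train_nd_stages: tuple[str, ...] = ("baseline",)
    train_crd_stages: tuple[str, ...] = ("rec14",)
    predict_stages: tuple[str, ...] = ("shift1", "shift6", "rec5")


@dataclass(frozen=True)
class SerumSection:
    corticosterone_tau: float = 12.0
    corticosterone_amplitude: float = 30.0
    corticosterone_mesor: float = 100.0
    corticosterone_noise_sd: float = 15.0
    corticosterone_outliers: int = 5
    cd36_mesor: float = 100.0
    cd36_noise_sd: float = 15.0
    cd36_shift_ccw: float = 0.18
    cd36_shift_cw: float = 0.11
    n_baseline_per_cell: int = 4
    n_shifted_per_cell: int = 5


@dataclass(frozen=True)
class PathsSection:
    age_list: str | None = None
    secreted_list: str | None = None
    plasma_list: str | None = None


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    schema_version: int = SCHEMA_VERSION
    design: DesignSection = field(default_factory=DesignSection)
    genes: GenesSection = field(default_factory=GenesSection)
    thresholds: ThresholdsSection = field(default_factory=ThresholdsSection)
    classify: ClassifySection = field(default_factory=ClassifySection)
    serum: SerumSection = field(default_factory=SerumSection)
    paths: PathsSection = field(default_factory=PathsSection)


_SECTIONS = {
    "design": DesignSection,
    "genes": GenesSection,
    "thresholds": ThresholdsSection,
    "classify": ClassifySection,
    "serum": SerumSection,
    "paths": PathsSection,
}


def _build_section(cls, data: Mapping[str, Any], path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(f'{path}.{k}' for k in unknown)}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except TypeError as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}") from exc


def validate_config(raw: str | Mapping[str, Any] | None) -> RunConfig:
    """Parse and validate a config mapping or YAML text; fill defaults.

    An empty config yields the full default study configuration. Unknown
    keys are rejected with their field path; threshold ranges are checked.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - (set(_SECTIONS) | {"seed", "schema_version"})
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    sections = {
        name: _build_section(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    config = RunConfig(
        seed=int(raw.get("seed", 0)),
        schema_version=int(raw.get("schema_version", SCHEMA_VERSION)),
        **sections,
    )
    _check_ranges(config)
    return config


def _check_ranges(config: RunConfig) -> None:
    th = config.thresholds
    for name in ("de_alpha", "fdr", "grubbs_alpha"):
        value = getattr(th, name)
        if not 0 < value < 1:
            raise ConfigError(f"thresholds.{name} must lie in (0, 1); got {value}")
    if not th.fc_low < 1 < th.fc_high:
        raise ConfigError("thresholds require fc_low < 1 < fc_high")
    if th.tau <= 0:
        raise ConfigError("thresholds.tau must be > 0")
    if not 0 <= config.classify.majority < 1:
        raise ConfigError("classify.majority must lie in [0, 1)")
    g = config.genes
    if min(g.n_null, g.n_circadian, g.n_crd) < 0 or g.n_crd_secreted > g.n_crd:
        raise ConfigError("genes section: counts must be >= 0 and n_crd_secreted <= n_crd")
    unknown_methods = set(config.classify.methods) - set(_classify.METHODS)
    if unknown_methods:
        raise ConfigError(f"classify.methods contains unknown method(s): {sorted(unknown_methods)}")


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def gene_config_from(config: RunConfig, seed: int) -> _simulate.GeneConfig:
    g = config.genes
    genes = _simulate.make_gene_table(
        g.n_null,
        g.n_circadian,
        g.n_crd,
        mesor=g.mesor,
        amplitude=g.amplitude,
        rec14_fold_change=g.rec14_fold_change,
        persistence=g.persistence,
        n_crd_secreted=g.n_crd_secreted,
        seed=seed,
    )
    return _simulate.GeneConfig(
        genes=genes,
        noise_sd=g.noise_sd,
        spot_noise_sd=g.spot_noise_sd,
        probe_offset_sd=g.probe_offset_sd,
        probes_per_gene=g.probes_per_gene,
        seed=seed + 1,
    )


def synthetic_gene_lists(config: RunConfig, truth: pd.DataFrame) -> dict[str, set[str]]:
    """Derive the three filter gene lists from planted truth.

    The secreted list is exactly the planted secreted genes; the ageing list
    marks the first ``n_age_listed_null`` null genes (exercising the filter
    without touching planted markers); the plasma list is left empty.
    """
    secreted = set(truth[truth["secreted"]]["gene"])
    nulls = truth[truth["archetype"] == "null"]["gene"].tolist()
    age = set(nulls[: config.genes.n_age_listed_null])
    return {"age": age, "secreted": secreted, "plasma": set()}


@dataclass
class StudyResult:
    config: RunConfig
    seed: int
    design: pd.DataFrame
    gene_config: _simulate.GeneConfig
    truth: pd.DataFrame
    probe_matrix: pd.DataFrame
    matrix: pd.DataFrame
    screens: dict[str, pd.DataFrame]
    consensus: _classify.ConsensusSet
    external_predictions: pd.DataFrame
    ledger: pd.DataFrame
    counts: dict[str, int]
    candidates: list[str]
    marker_report: pd.DataFrame
    marker_counts: dict[str, int]


def run_study(config: RunConfig, seed: int | None = None) -> StudyResult:
    """Execute the full synthetic study in memory (no file output)."""
    if seed is None:
        seed = config.seed
    design = _simulate.generate_design(
        config.design.stages,
        config.design.protocols,
        config.design.zts,
        config.design.replicates(),
    )
    gene_config = gene_config_from(config, seed)
    truth = _simulate.ground_truth_table(gene_config)
    probe_matrix = _simulate.generate_expression(design, gene_config)
    matrix = _normalize.normalize_two_channel(probe_matrix)
    annotation = _simulate.probe_annotation(gene_config)

    screens = _rhythm.screen_all_stages(
        matrix, design, tau=config.thresholds.tau, fdr=config.thresholds.fdr
    )

    cl = config.classify
    specs = _classify.default_specs(
        cl.methods, top_k=cl.top_k, n_trees=cl.n_trees, svm_c=cl.svm_c, seed=seed
    )
    consensus = _classify.evaluate_blocked_cv(
        matrix,
        design,
        specs,
        nd_stages=cl.train_nd_stages,
        crd_stages=cl.train_crd_stages,
        majority=cl.majority,
        annotation=annotation,
    )
    if consensus.consensus_probes:
        external = _classify.predict_external_stages(
            matrix,
            design,
            consensus.consensus_probes,
            specs,
            train_nd_stages=cl.train_nd_stages,
            train_crd_stages=cl.train_crd_stages,
            predict_stages=cl.predict_stages,
        )
    else:
        external = pd.DataFrame(columns=["stage", "protocol", "method", "n", "frac_crd"])

    lists = synthetic_gene_lists(config, truth)
    if config.paths.age_list:
        lists["age"] = _select.read_gene_list(config.paths.age_list)
    if config.paths.secreted_list:
        lists["secreted"] = _select.read_gene_list(config.paths.secreted_list)
    if config.paths.plasma_list:
        lists["plasma"] = _select.read_gene_list(config.paths.plasma_list)

    ledger, counts = _select.run_selection_cascade(
        matrix,
        design,
        annotation,
        screens,
        lists["age"],
        lists["secreted"],
        lists["plasma"],
        alpha=config.thresholds.de_alpha,
        fc_low=config.thresholds.fc_low,
        fc_high=config.thresholds.fc_high,
        consensus_genes=consensus.consensus_genes,
        protocols=tuple(config.design.protocols)[:2],
    )
    candidates = sorted(ledger.index[ledger["blood_candidate"]])
    report, marker_counts = _select.build_marker_report(
        candidates, consensus.consensus_genes or []
    )
    return StudyResult(
        config=config,
        seed=seed,
        design=design,
        gene_config=gene_config,
        truth=truth,
        probe_matrix=probe_matrix,
        matrix=matrix,
        screens=screens,
        consensus=consensus,
        external_predictions=external,
        ledger=ledger,
        counts=counts,
        candidates=candidates,
        marker_report=report,
        marker_counts=marker_counts,
    )


def run_serum_analysis(config: RunConfig, seed: int | None = None) -> dict[str, Any]:
    """Simulate and analyse the two serum analytes.

    Corticosterone-like: rhythmic (12-h period at baseline), screened for
    outliers per (stage, protocol) group with Grubbs at the configured
    alpha, then cosinor-fitted at baseline. CD36-like: non-rhythmic with a
    planted recovery-stage level increase per protocol, compared to baseline
    with the equal-variance t-test.
    """
    if seed is None:
        seed = config.seed
    design = _simulate.generate_design(
        config.design.stages, config.design.protocols, config.design.zts, 1
    )
    s = config.serum
    cort_config = _simulate.SerumConfig(
        name="corticosterone",
        rhythmic=True,
        mesor=s.corticosterone_mesor,
        amplitude=s.corticosterone_amplitude,
        acrophase=0.0,
        tau=s.corticosterone_tau,
        noise_sd=s.corticosterone_noise_sd,
        n_per_cell={"baseline": s.n_baseline_per_cell},
        outlier_count=s.corticosterone_outliers,
        outlier_magnitude=5.0,
        seed=seed + 11,
    )
    # shifted stages get n_shifted_per_cell
    cort_config = dataclasses.replace(
        cort_config,
        n_per_cell={
            stage: (s.n_baseline_per_cell if stage == "baseline" else s.n_shifted_per_cell)
            for stage in config.design.stages
        },
    )
    cort, cort_outliers = _simulate.generate_serum(design, cort_config)
    alpha = config.thresholds.grubbs_alpha
    # Outliers are screened on rhythm-adjusted residuals (value minus its
    # time-point cell mean) so the circadian waveform does not mask extremes.
    cell_means = cort.groupby(["stage", "protocol", "zt"])["value"].transform("mean")
    cort = cort.assign(residual=cort["value"] - cell_means)
    flagged = 0
    for _, group in cort.groupby(["stage", "protocol"], sort=False):
        result = _rhythm.grubbs_screen(group["residual"].to_numpy(), alpha=alpha)
        flagged += result.n_flagged
    base = cort[cort["stage"] == "baseline"]
    cort_fit = _rhythm.cosinor_fit(
        base["zt"].to_numpy(float), base["value"].to_numpy(float), tau=s.corticosterone_tau
    )

    cd36_config = _simulate.SerumConfig(
        name="cd36",
        rhythmic=False,
        mesor=s.cd36_mesor,
        amplitude=0.0,
        noise_sd=s.cd36_noise_sd,
        stage_shift={("rec14", "CCW"): s.cd36_shift_ccw, ("rec14", "CW"): s.cd36_shift_cw},
        n_per_cell={
            stage: (s.n_baseline_per_cell if stage == "baseline" else s.n_shifted_per_cell)
            for stage in config.design.stages
        },
        seed=seed + 13,
    )
    cd36, _ = _simulate.generate_serum(design, cd36_config)
    baseline_values = cd36[cd36["stage"] == "baseline"]["value"].to_numpy()
    comparisons = {}
    for protocol in config.design.protocols:
        grp = cd36[(cd36["stage"] == "rec14") & (cd36["protocol"] == protocol)]
        comparisons[protocol] = _rhythm.serum_group_compare(
            baseline_values, grp["value"].to_numpy()
        )
    return {
        "corticosterone": {
            "n_samples": len(cort),
            "outliers_injected": len(cort_outliers),
            "outliers_flagged": flagged,
            "baseline_fit": dataclasses.asdict(cort_fit),
            "series": cort,
            "outlier_sidecar": cort_outliers,
        },
        "cd36": {"series": cd36, "comparisons": comparisons},
    }


def run_pipeline(
    config: RunConfig, out_dir, seed: int | None = None, include_serum: bool = True
) -> dict[str, Any]:
    """Run the study and write every stage's outputs under ``out_dir``.

    Stage subdirectories are numbered in execution order; every table
    carries the resolved config hash and seed in its header. Returns the
    run report (also written as ``run_report.json``).
    """
    t0 = time.monotonic()
    out = Path(out_dir)
    if seed is None:
        seed = config.seed
    meta = {"config_sha": config_hash(config), "seed": seed, "schema_version": config.schema_version}

    def _stage(name, fn):
        try:
            return fn()
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc

    result = _stage("simulate+analyse", lambda: run_study(config, seed))

    sim_dir = out / "01_simulate"
    write_tsv(result.design, sim_dir / "design.tsv", meta, index=False)
    write_tsv(
        _simulate.probe_matrix_to_long(result.probe_matrix),
        sim_dir / "spots.tsv",
        meta,
        index=False,
    )
    write_tsv(result.truth, sim_dir / "ground_truth.tsv", meta, index=False)
    lists = synthetic_gene_lists(config, result.truth)
    write_gene_list(lists["age"], sim_dir / "age_genes.txt", "synthetic ageing-gene list")
    write_gene_list(lists["secreted"], sim_dir / "secreted_genes.txt", "synthetic secreted list")
    write_gene_list(lists["plasma"], sim_dir / "plasma_genes.txt", "synthetic plasma list")
    annotation = _simulate.probe_annotation(result.gene_config)
    write_tsv(
        pd.DataFrame(
            {"probe_id": list(annotation), "gene": list(annotation.values())}
        ),
        sim_dir / "annotation.tsv",
        meta,
        index=False,
    )

    write_tsv(result.matrix, out / "02_normalize" / "expression_matrix.tsv", meta)

    for stage_name, screen in result.screens.items():
        write_tsv(screen, out / "03_rhythm" / f"screen_{stage_name}.tsv", meta)

    consensus_payload = {
        "fold_sets": {m: [sorted(s) for s in fs] for m, fs in result.consensus.fold_sets.items()},
        "majority_sets": {m: sorted(s) for m, s in result.consensus.majority_sets.items()},
        "consensus_probes": sorted(result.consensus.consensus_probes),
        "consensus_genes": result.consensus.consensus_genes,
        "accuracies": result.consensus.accuracies,
        "majority_threshold": result.consensus.majority_threshold,
    }
    write_json(consensus_payload, out / "04_classify" / "consensus.json")
    write_tsv(
        result.external_predictions, out / "04_classify" / "external_predictions.tsv",
        meta, index=False,
    )

    write_tsv(result.ledger, out / "05_select" / "candidate_table.tsv", meta)
    write_tsv(result.marker_report, out / "05_select" / "marker_report.tsv", meta, index=False)
    write_json(
        {"counts": result.counts, "marker_counts": result.marker_counts,
         "thresholds": dataclasses.asdict(config.thresholds)},
        out / "05_select" / "selection_summary.json",
    )

    serum_summary = None
    if include_serum:
        serum = _stage("serum", lambda: run_serum_analysis(config, seed))
        write_tsv(serum["corticosterone"]["series"], out / "06_serum" / "corticosterone.tsv",
                  meta, index=False)
        write_tsv(serum["corticosterone"]["outlier_sidecar"],
                  out / "06_serum" / "corticosterone_outliers.tsv", meta, index=False)
        write_tsv(serum["cd36"]["series"], out / "06_serum" / "cd36.tsv", meta, index=False)
        serum_summary = {
            "corticosterone_outliers_flagged": serum["corticosterone"]["outliers_flagged"],
            "corticosterone_baseline_fit": serum["corticosterone"]["baseline_fit"],
            "cd36_comparisons": serum["cd36"]["comparisons"],
        }

    report = {
        "config_sha": meta["config_sha"],
        "seed": seed,
        "schema_version": config.schema_version,
        "n_samples": len(result.design),
        "n_probes": int(result.matrix.shape[0]),
        "screen_rhythmic_counts": {
            stage: int(screen["rhythmic"].sum()) for stage, screen in result.screens.items()
        },
        "consensus_sizes": {m: len(s) for m, s in result.consensus.majority_sets.items()},
        "consensus_probe_count": len(result.consensus.consensus_probes),
        "accuracies": result.consensus.accuracies,
        "selection_counts": result.counts,
        "candidates": result.candidates,
        "marker_counts": result.marker_counts,
        "serum": serum_summary,
        "wall_time_s": round(time.monotonic() - t0, 3),
    }
    write_json(report, out / "run_report.json")
    return report
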