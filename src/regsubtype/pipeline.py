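"""End-to-end pipeline: expression → enrichment → clusters → subtypes.

One validated configuration drives all stages; a single global seed
derives per-stage seeds through a documented SeedSequence scheme, stage
outputs are plain TSV/JSON written deterministically (fixed float format,
sorted keys), and a run manifest records the configuration, seed and
sha256 checksums so that a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .activity import cluster_activity_matrix
from .expression import (
    compute_log_ratios,
    preprocess,
    read_expression,
    read_probe_map,
    variance_support_check,
)
from .network import load_network
from .regulators import cluster_with_optimal_k, regulator_distance_matrix
from .snea import SneaConfig, snea_all_samples
from .subtyping import (
    adjusted_rand_index,
    bootstrap_stability,
    cluster_samples,
    select_features_pairwise,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


class ConfigError(ValueError):
    pass


class SneaSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    top_n: int = Field(100, ge=1)
    p_threshold: float = Field(0.05, gt=0.0, le=1.0)
    min_targets: int = Field(3, ge=1)
    weighting: Literal["connectivity", "downstream", "none"] = "connectivity"
    alternative: Literal["two_sided", "greater", "less"] = "two_sided"
    exclude_targets_from_background: bool = False
    exact_limit: int = Field(10_000, ge=1)


class RegulatorClusteringSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_min: int = Field(2, ge=2)
    k_max: Optional[int] = None
    linkage: Literal["ward", "average"] = "ward"


class SampleClusteringSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k: int | Literal["auto"] = "auto"
    k_min: int = Field(2, ge=2)
    k_max: int = Field(10, ge=2)


class EvaluationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_boot: int = Field(1000, ge=1)
    fraction: float = Field(0.9, gt=0.0, le=1.0)
    n_perm: int = Field(1000, ge=1)
    n_runs: int = Field(100, ge=1)
    alpha: float = Field(0.05, gt=0.0, le=1.0)
    stability_threshold: float = Field(0.9, ge=0.0, le=1.0)


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")
    expression: Path
    groups: Path
    network: Path
    control_label: str
    outdir: Path
    network_format: Literal["edge_list", "gmt"] = "edge_list"
    relation_filter: list[Literal["Expression", "PromoterBinding"]] = Field(
        default_factory=lambda: ["Expression", "PromoterBinding"]
    )
    already_logged: bool = False
    log_base: float = Field(2.0, gt=1.0)
    probe_map: Optional[Path] = None
    feature_source: Literal["activity", "genes"] = "activity"
    snea: SneaSettings = Field(default_factory=SneaSettings)
    regulator_clustering: RegulatorClusteringSettings = Field(
        default_factory=RegulatorClusteringSettings
    )
    sample_clustering: SampleClusteringSettings = Field(
        default_factory=SampleClusteringSettings
    )
    evaluation: EvaluationSettings = Field(default_factory=EvaluationSettings)
    seed: int = 0
    run_label: str = "run"

    def check_paths(self) -> None:
        for name in ("expression", "groups", "network"):
            p: Path = getattr(self, name)
            if not p.is_file():
                raise ConfigError(f"{name} file not found: {p}")
        if self.probe_map is not None and not self.probe_map.is_file():
            raise ConfigError(f"probe_map file not found: {self.probe_map}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration file."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        cfg = PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.check_paths()
    return cfg


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Derive a per-stage seed: SeedSequence(global_seed, spawn_key=(i,))."""
    ss = np.random.SeedSequence(global_seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageWriter:
    """Write stage files under ``.partial`` names, renamed on stage success."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.pending: list[tuple[Path, Path]] = []

    def path(self, name: str) -> Path:
        final = self.outdir / name
        partial = self.outdir / (name + ".partial")
        self.pending.append((partial, final))
        return partial

    def commit(self) -> list[Path]:
        done = []
        for partial, final in self.pending:
            partial.replace(final)
            done.append(final)
        self.pending.clear()
        return done


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest.

    Stages: preprocess → log-ratios → per-sample enrichment → regulator
    clustering → activity matrix → sample clustering + bootstrap →
    feature selection.  Any stage error aborts with the stage name;
    completed files keep their names, the failing stage's partial files
    keep a ``.partial`` suffix.
    """
    config.check_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "run_label": config.run_label,
        "seed": config.seed,
        "package_version": __version__,
        "config": json.loads(config.model_dump_json()),
        "stages": {},
        "summary": {},
    }
    outputs: dict[str, list[str]] = {}

    def run_stage(name, fn):
        writer = _StageWriter(outdir)
        try:
            result = fn(writer)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        files = writer.commit()
        outputs[name] = [f.name for f in files]
        return result

    # 1 — preprocessing
    def _preprocess(w):
        matrix = read_expression(config.expression, config.groups, config.control_label)
        probe_map = read_probe_map(config.probe_map) if config.probe_map else None
        std = preprocess(
            matrix,
            log_base=config.log_base,
            already_logged=config.already_logged,
            probe_to_gene=probe_map,
        )
        _write_tsv(std.values, w.path("preprocessed.tsv"), index_label="gene")
        try:
            manifest["summary"]["variance_support_fraction"] = variance_support_check(std)
        except ValueError:
            pass  # too few samples for the check
        return std

    std = run_stage("preprocess", _preprocess)

    # 2 — log-ratios vs averaged control
    def _logratios(w):
        lrm = compute_log_ratios(std)
        _write_tsv(lrm.values, w.path("log_ratios.tsv"), index_label="gene")
        return lrm

    lrm = run_stage("log_ratios", _logratios)

    # 3 — per-sample enrichment
    network = load_network(
        config.network, format=config.network_format,
        relation_filter=config.relation_filter,
    )
    snea_cfg = SneaConfig(**config.snea.model_dump())

    def _snea(w):
        res = snea_all_samples(lrm, network, snea_cfg)
        _write_tsv(res.to_frame().set_index("sample"), w.path("snea_records.tsv"))
        return res

    snea_res = run_stage("snea", _snea)

    # 4 — regulator clustering
    def _reg_cluster(w):
        regs = snea_res.regulators
        if len(regs) < 3:
            raise ValueError(f"only {len(regs)} significant regulators; need >= 3")
        dist = regulator_distance_matrix(regs, network, lrm.gene_ids)
        rc = cluster_with_optimal_k(
            dist,
            k_min=config.regulator_clustering.k_min,
            k_max=config.regulator_clustering.k_max,
            linkage=config.regulator_clustering.linkage,
        )
        frame = rc.to_frame()
        frame["n_targets_measured"] = [
            len(network.downstream_targets(r, lrm.gene_ids))
            for r in frame["regulator"]
        ]
        _write_tsv(frame.set_index("regulator"), w.path("regulator_clusters.tsv"))
        _write_tsv(rc.silhouette_frame().set_index("k"), w.path("regulator_silhouette.tsv"))
        w.path("regulator_dendrogram.nwk").write_text(rc.to_newick() + "\n")
        return rc

    reg_clust = run_stage("cluster_regulators", _reg_cluster)
    manifest["summary"]["n_regulators"] = len(reg_clust.regulator_ids)
    manifest["summary"]["n_regulator_clusters"] = reg_clust.k

    # 5 — activity matrix
    def _activity(w):
        am = cluster_activity_matrix(reg_clust, lrm, network)
        _write_tsv(am.k_values, w.path("k_values.tsv"), index_label="regulator")
        _write_tsv(am.c_values, w.path("c_values.tsv"), index_label="cluster")
        return am

    am = run_stage("activity", _activity)

    # 6 — sample clustering + stability
    features = am.c_values if config.feature_source == "activity" else lrm.values
    reference = lrm.sample_groups

    def _subtype(w):
        sc_cfg = config.sample_clustering
        sc = cluster_samples(
            features,
            k=sc_cfg.k,
            k_range=(sc_cfg.k_min, sc_cfg.k_max),
        )
        _write_tsv(sc.to_frame().set_index("sample"), w.path("sample_clusters.tsv"))
        report: dict = {"k_samples": sc.k,
                        "silhouette_by_k": {str(k): v for k, v in sc.silhouette_by_k.items()}}
        if reference.nunique() >= 2:
            report["ari_vs_reference"] = adjusted_rand_index(
                reference, pd.Series(sc.sample_labels)
            )
        boot = bootstrap_stability(
            features,
            pd.Series(sc.sample_labels),
            n_runs=config.evaluation.n_boot,
            fraction=config.evaluation.fraction,
            k=sc.k,
            seed=stage_seed(config.seed, 6),
        )
        report["bootstrap"] = boot.summary()
        freq = boot.assignment_frequency.round(6)
        report["per_sample_assignment_frequency"] = {
            s: {str(c): float(freq.loc[s, c]) for c in freq.columns}
            for s in freq.index
        }
        _write_json(report, w.path("subtyping.json"))
        return sc, report

    sc, subtype_report = run_stage("subtype", _subtype)
    manifest["summary"]["k_samples"] = sc.k
    if "ari_vs_reference" in subtype_report:
        manifest["summary"]["ari_vs_reference"] = subtype_report["ari_vs_reference"]
    manifest["summary"]["bootstrap_ari_mean"] = subtype_report["bootstrap"]["ari_mean"]

    # 7 — feature selection (true groups if multi-class, else found clusters)
    def _features(w):
        if reference.nunique() >= 2:
            classes = reference
        else:
            classes = pd.Series(sc.sample_labels).astype(str)
        results = select_features_pairwise(
            am.c_values,
            classes,
            n_runs=config.evaluation.n_runs,
            run_fraction=config.evaluation.fraction,
            n_perm=config.evaluation.n_perm,
            alpha=config.evaluation.alpha,
            stability_threshold=config.evaluation.stability_threshold,
            seed=stage_seed(config.seed, 7),
        )
        rows = []
        for (ca, cb), res in sorted(results.items()):
            t = res.table.reset_index()
            t.insert(0, "class_a", ca)
            t.insert(1, "class_b", cb)
            rows.append(t)
        table = pd.concat(rows, ignore_index=True)
        _write_tsv(table.set_index("class_a"), w.path("feature_selection.tsv"))
        return results

    fs = run_stage("select_features", _features)
    manifest["summary"]["n_selected_features"] = int(
        sum(len(r.selected) for r in fs.values())
    )

    manifest["stages"] = {
        name: {f: _sha256(outdir / f) for f in files}
        for name, files in outputs.items()
    }
    manifest_path = outdir / "manifest.json"
    _write_json(manifest, manifest_path)
    return manifest
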