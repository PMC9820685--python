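"""End-to-end orchestration: simulate -> normalize -> DE -> diagnostics ->
target scoring -> hub networks, with a machine-readable run report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import call_signature, de_test
from .diagnostics import clustering_matrix, cut_k, hclust_complete, roc_auc_table
from .errors import DomainError, MirsigError
from .io import (
    ExpressionDataset,
    background_stats,
    normalize_housekeeping,
    read_counts,
    write_counts,
    write_normalized,
)
from .network import build_hub, export_network, load_edges
from .simulate import (
    SimulationParams,
    build_default_design,
    build_default_panel,
    default_signature,
    simulate,
)
from .targets import ScoringConfig, rank_genes, read_targetscan, summarize_gene_targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to/from YAML."""

    alpha: float = 0.05
    cluster_k: int = 2
    standardize_rows: bool = True
    weighting_mode: str = "simple"
    cumulative_threshold: float = 0.01
    count_mode: str = "neighbors"
    seed: int = 0
    # simulation
    nb_dispersion: float = 10.0
    background_mean: float = 12.0
    patient_effect_sd: float = 0.25
    librarysize_sd: float = 0.3
    # paths (None = not provided)
    counts: str | None = None
    meta: str | None = None
    targets: str | None = None
    edges: str | None = None
    out_dir: str = "mirsig-out"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha must be in (0, 1), got {self.alpha}")
        paths = [p for p in (self.counts, self.meta, self.targets, self.edges) if p]
        if len(set(paths)) != len(paths):
            raise DomainError("input paths must be distinct")

    def sim_params(self) -> SimulationParams:
        return SimulationParams(
            nb_dispersion=self.nb_dispersion,
            background_mean=self.background_mean,
            patient_effect_sd=self.patient_effect_sd,
            librarysize_sd=self.librarysize_sd,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """All pipeline outputs plus provenance; identical for identical runs."""

    config: dict
    provenance: dict
    signature: pd.DataFrame
    cluster_all: pd.DataFrame
    cluster_signature: pd.DataFrame | None
    auc: pd.DataFrame
    ranked_genes: pd.DataFrame | None
    hubs: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)

    def to_json_dict(self) -> dict:
        def df_records(df):
            return json.loads(df.to_json(orient="table"))["data"]

        return {
            "config": self.config,
            "provenance": self.provenance,
            "signature": df_records(self.signature),
            "cluster_all": df_records(self.cluster_all),
            "cluster_signature": (
                df_records(self.cluster_signature)
                if self.cluster_signature is not None
                else None
            ),
            "auc_signature_probes": df_records(self.auc),
            "ranked_genes": (
                df_records(self.ranked_genes)
                if self.ranked_genes is not None
                else None
            ),
            "hubs": {
                group: df_records(net.nodes.reset_index()) for group, net in self.hubs.items()
            },
            "skipped": self.skipped,
        }


def cmd_simulate(config: PipelineConfig) -> dict:
    """Write a synthetic cohort (counts, metadata, truth) to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("simulating default cohort with seed=%d", config.seed)
    sim = simulate(
        build_default_panel(),
        build_default_design(),
        default_signature(),
        config.sim_params(),
    )
    counts_path = out / "counts.csv"
    meta_path = out / "samples.csv"
    truth_path = out / "truth.csv"
    write_counts(sim.dataset, counts_path, meta_path)
    with open(truth_path, "w", encoding="utf-8", newline="\n") as fh:
        sim.signature.truth_table().to_csv(fh, index=False, lineterminator="\n")
    logger.info("wrote %s (%d x %d)", counts_path, *sim.counts.shape)
    return {
        "counts": str(counts_path),
        "meta": str(meta_path),
        "truth": str(truth_path),
    }


def _load_or_simulate(config: PipelineConfig) -> ExpressionDataset:
    if config.counts and config.meta:
        logger.info("reading counts from %s", config.counts)
        return read_counts(config.counts, config.meta)
    logger.info("no input counts given; simulating with seed=%d", config.seed)
    sim = simulate(
        build_default_panel(),
        build_default_design(),
        default_signature(),
        config.sim_params(),
    )
    return sim.dataset


def cmd_run_all(config: PipelineConfig, write_outputs: bool = True) -> RunReport:
    """Run every stage and emit a report (JSON + CSV sidecars).

    Target scoring and hub networks run only when the corresponding input
    tables are configured; otherwise those sections are marked skipped.
    Stage failures raise :class:`~mirsig.errors.MirsigError` naming the
    stage, and no partial outputs are left in out_dir.
    """
    out = Path(config.out_dir)
    staged: list[Path] = []

    def stage(name):
        logger.info("stage: %s", name)
        return name

    try:
        name = stage("load")
        ds = _load_or_simulate(config)
        logger.info("dataset: %d probes x %d samples", *ds.counts.shape)

        name = stage("normalize")
        norm = normalize_housekeeping(ds)
        background = background_stats(ds)

        name = stage("differential_expression")
        de = de_test(norm, alpha=config.alpha)
        signature = call_signature(de, ds.probe_info)
        logger.info(
            "DE: %d/%d probes significant at FDR<%g -> %d signature miRNAs",
            len(de.significant_probes), len(de.table), config.alpha, len(signature),
        )

        name = stage("diagnostics")
        mat_all = clustering_matrix(norm, standardize=config.standardize_rows)
        cut_all = cut_k(
            hclust_complete(mat_all), config.cluster_k, ds.sample_meta
        )
        cluster_signature = None
        sig_probes = list(de.significant_probes)
        if len(sig_probes) >= 1:
            mat_sig = clustering_matrix(
                norm, probes=sig_probes, standardize=config.standardize_rows
            )
            if mat_sig.shape[0] >= 1:
                cut_sig = cut_k(
                    hclust_complete(mat_sig), config.cluster_k, ds.sample_meta
                )
                cluster_signature = cut_sig.composition
        auc = roc_auc_table(norm, sig_probes) if sig_probes else pd.DataFrame(
            columns=["auc", "orientation"]
        )

        ranked = None
        hubs: dict = {}
        skipped: list[str] = []
        if config.targets and not signature.empty:
            name = stage("target_scoring")
            parsed = read_targetscan(config.targets)
            summaries = summarize_gene_targets(
                parsed.interactions,
                signature,
                ScoringConfig(
                    weighting_mode=config.weighting_mode,
                    cumulative_threshold=config.cumulative_threshold,
                ),
            )
            ranked = rank_genes(summaries)
            logger.info("target scoring: %d genes retained", len(ranked))
        else:
            skipped.append("target_scoring")

        if config.edges and ranked is not None:
            name = stage("hub_networks")
            edges = load_edges(config.edges).edges
            for group, gene_dir in (("up", "down_in_bm"), ("down", "up_in_bm")):
                genes = set(ranked.index[ranked["predicted_direction"] == gene_dir])
                if genes:
                    hubs[group] = build_hub(
                        genes, group, edges, count_mode=config.count_mode
                    )
        else:
            skipped.append("hub_networks")

        name = stage("report")
        report = RunReport(
            config=config.to_dict(),
            provenance={
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "mirsig_version": __version__,
            },
            signature=signature,
            cluster_all=cut_all.composition,
            cluster_signature=cluster_signature,
            auc=auc,
            ranked_genes=ranked,
            hubs=hubs,
            skipped=skipped,
        )
        if write_outputs:
            out.mkdir(parents=True, exist_ok=True)
            p = out / "report.json"
            with open(p, "w", encoding="utf-8", newline="\n") as fh:
                json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
                fh.write("\n")
            staged.append(p)
            for fname, df in (
                ("de_results.csv", de.table),
                ("signature.csv", signature),
                ("auc.csv", auc),
                ("background_thresholds.csv", background.to_frame()),
            ):
                p = out / fname
                df.to_csv(p, lineterminator="\n")
                staged.append(p)
            p = out / "normalized.csv"
            write_normalized(norm, p)
            staged.append(p)
            if ranked is not None:
                p = out / "ranked_genes.csv"
                ranked.to_csv(p, lineterminator="\n")
                staged.append(p)
            for group, net in hubs.items():
                p = out / f"hub_{group}.graphml"
                export_network(net, p, format="graphml")
                staged.append(p)
        return report
    except MirsigError as exc:
        for p in staged:  # remove partial outputs
            p.unlink(missing_ok=True)
        raise MirsigError(f"stage {name!r} failed: {exc}") from exc
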