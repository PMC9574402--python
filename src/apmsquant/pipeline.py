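"""End-to-end orchestration: quantify -> enrich -> summaries -> phospho -> network/PCA.

Every stage reads and writes plain TSV so intermediate results diff cleanly
and subcommand-by-subcommand runs reproduce a monolithic run byte for byte.
The report records every analysis decision actually applied (imputation
mode, thresholds, counting mode) plus provenance: a config echo, input
checksums, and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .enrich import EnrichConfig, enrich_proteins, filter_all_replicates, write_enrichment
from .errors import ApmsError, StageError
from .io import (
    read_annotation_table,
    read_fasta,
    read_interaction_table,
    read_psm_table,
    drop_invalid,
    validate_against_reference,
)
from .netpca import (
    DEFAULT_NODE_THRESHOLD,
    build_network,
    filter_network_nodes,
    pca_replicates,
    write_network,
    write_pca,
)
from .phospho import occupancy_profile, summarize_profile
from .quantify import build_quant_matrix
from .stoichiometry import pie_summary, write_pie

log = logging.getLogger("apmsquant")


@dataclass
class PipelineConfig:
    psm_table: str
    out_dir: str
    fasta: str | None = None
    interaction_table: str | None = None
    annotation_table: str | None = None
    bait_labels: list[str] | None = None  # default: every bait label in the table
    alpha: float = 0.05
    zero_fill: bool = True
    multiple_testing: str | None = None
    node_threshold: float = DEFAULT_NODE_THRESHOLD
    other_threshold: float = 0.02
    phospho_count_mode: str = "psm"
    phospho_proteins: list[str] = field(default_factory=list)  # default: auto-detect
    reference_check: str = "warn"  # "warn" drops flagged PSMs, "fail" aborts
    log_level: str = "INFO"

    def enrich_config(self) -> EnrichConfig:
        return EnrichConfig(
            alpha=self.alpha, zero_fill=self.zero_fill, multiple_testing=self.multiple_testing
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except ApmsError as exc:
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle into ``out_dir``.

    On a stage failure, partial outputs are retained and a ``FAILED`` marker
    naming the stage is written next to them before the error propagates.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(config)}
    try:
        _run_stages(config, out, report)
    except StageError as exc:
        (out / "FAILED").write_text(f"{exc.stage}: {exc.cause}\n")
        raise
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _provenance(config: PipelineConfig) -> dict:
    checksums = {}
    for key in ("psm_table", "fasta", "interaction_table", "annotation_table"):
        path = getattr(config, key)
        if path:
            if not Path(path).exists():
                raise StageError("config", ApmsError(f"{key} path {path!r} does not exist"))
            checksums[key] = _sha256(path)
    return {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": checksums,
        "decisions": {
            "undetected_imputation": "zero_fill" if config.zero_fill else "pairwise_deletion",
            "multiple_testing": config.multiple_testing or "none (raw per-protein p-values)",
            "alpha": config.alpha,
            "node_threshold_strict": config.node_threshold,
            "pie_other_threshold": config.other_threshold,
            "phospho_count_mode": config.phospho_count_mode,
        },
    }


def _run_stages(config: PipelineConfig, out: Path, report: dict) -> None:
    psms, proteome = _stage("load")(_load)(config, report)
    matrix = _stage("quantify")(_quantify)(psms, out, report)

    bait_labels = config.bait_labels or sorted(
        set(matrix.runs.loc[matrix.runs["condition"] == "bait", "bait_label"])
    )
    enrichments: dict[str, pd.DataFrame] = {}
    for label in bait_labels:
        enrichments[label] = _stage("enrich")(_enrich)(matrix, label, config, out, report)
        _stage("compose")(_compose)(enrichments[label], label, config, out, report)
        _stage("network")(_network)(enrichments[label], label, config, out, report)
    _stage("pca")(_pca)(matrix, enrichments, out, report)
    if proteome is not None:
        _stage("phospho")(_phospho)(psms, proteome, config, out, report)


def _load(config: PipelineConfig, report: dict):
    psms = read_psm_table(config.psm_table)
    proteome = read_fasta(config.fasta) if config.fasta else None
    if proteome is not None:
        check = validate_against_reference(psms, proteome)
        report["reference_check"] = check.summary()
        if not check.ok:
            if config.reference_check == "fail":
                raise ApmsError(check.summary())
            log.warning("%s; dropping flagged PSMs", check.summary())
            psms = drop_invalid(psms, check)
    report["n_psms"] = len(psms)
    return psms, proteome


def _quantify(psms, out: Path, report: dict):
    matrix = build_quant_matrix(psms)
    matrix.to_dir(out / "quant")
    report["n_proteins"] = len(matrix.proteins)
    report["n_runs"] = len(matrix.run_ids)
    return matrix


def _enrich(matrix, label: str, config: PipelineConfig, out: Path, report: dict):
    records = enrich_proteins(matrix, bait_label=label, config=config.enrich_config())
    write_enrichment(records, out / f"enrichment_{label}.tsv")
    core = filter_all_replicates(records)
    report.setdefault("enrichment", {})[label] = {
        "n_tested": int(len(records)),
        "n_significant": int(records["significant"].sum()),
        "n_enriched": int(records["enriched"].sum()),
        "n_significant_all_replicates": int(core["significant"].sum()),
        "n_enriched_all_replicates": int(core["enriched"].sum()),
    }
    return records


def _compose(records, label: str, config: PipelineConfig, out: Path, report: dict):
    core = filter_all_replicates(records)
    selected = core[core["significant"]]
    if len(selected) == 0 or not (selected["mean_si_gi"] > 0).any():
        report.setdefault("pie", {})[label] = None
        return
    pie = pie_summary(selected, other_threshold=config.other_threshold)
    write_pie(pie, out / f"pie_{label}.tsv")
    report.setdefault("pie", {})[label] = {
        "explicit": dict(pie.entries),
        "other": pie.other,
        "other_count": pie.other_count,
    }


def _network(records, label: str, config: PipelineConfig, out: Path, report: dict):
    nodes = filter_network_nodes(records, node_threshold=config.node_threshold)
    interactions = (
        read_interaction_table(config.interaction_table) if config.interaction_table else None
    )
    annotations = (
        read_annotation_table(config.annotation_table) if config.annotation_table else None
    )
    graph = build_network(nodes, interactions, annotations)
    write_network(graph, out / f"network_nodes_{label}.tsv", out / f"network_edges_{label}.tsv")
    report.setdefault("network", {})[label] = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
    }


def _pca(matrix, enrichments: dict[str, pd.DataFrame], out: Path, report: dict):
    features: list[str] = []
    for records in enrichments.values():
        core = filter_all_replicates(records)
        features.extend(core.loc[core["significant"], "protein"])
    features = sorted(set(features))
    bait_runs = matrix.run_ids_where(condition="bait")
    if len(features) < 2 or len(bait_runs) < 3:
        report["pca"] = None
        return
    result = pca_replicates(matrix, features=features, run_ids=bait_runs)
    write_pca(result, out / "pca_scores.tsv", out / "pca_variance.tsv")
    report["pca"] = {
        "n_features": len(result.features),
        "variance_fractions": [float(v) for v in result.variance_fractions],
    }


def _phospho(psms, proteome, config: PipelineConfig, out: Path, report: dict):
    targets = config.phospho_proteins or sorted(
        {
            rec.protein
            for rec in psms.itertuples(index=False)
            if any(kind == "phospho" for _, kind in rec.modifications)
        }
    )
    tables = []
    for protein in targets:
        profile = occupancy_profile(
            psms, protein, proteome, count_mode=config.phospho_count_mode
        )
        if len(profile):
            tables.append(profile)
    if not tables:
        report["phospho"] = None
        return
    profile = pd.concat(tables, ignore_index=True)
    profile.to_csv(out / "phospho_runs.tsv", sep="\t", index=False)
    summary = summarize_profile(profile)
    summary.to_csv(out / "phospho_sites.tsv", sep="\t", index=False)
    report["phospho"] = {
        "n_sites": int(len(summary)),
        "sites": {
            f"{r.protein}:{r.site_label}": None
            if pd.isna(r.mean_occupancy)
            else round(float(r.mean_occupancy), 4)
            for r in summary.itertuples(index=False)
        },
    }
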