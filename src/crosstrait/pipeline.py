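"""End-to-end orchestration of the five analysis stages.

Order: locus selection -> eQTL mapping -> gene-set overlap null ->
co-expression expansion -> enrichment clustering. A single config (YAML,
JSON or dict) names the four inputs — or a synthetic-generation block —
and surfaces every threshold as a named, defaulted parameter. The run is
deterministic under a fixed seed and produces a machine-readable report
with per-stage input/output counts plus TSV/JSON/GraphML artifacts per
stage.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import yaml

from . import __version__
from ._util import ConfigurationError, CrosstraitError
from . import coexpression as cx
from . import enrichment as en
from . import eqtl as eq
from . import locus
from . import overlap as ov
from .synthetic import SimulationConfig, generate_dataset

log = logging.getLogger(__name__)


@dataclass
class DisorderConfig:
    label: str
    trait_labels: tuple[str, ...]
    p_threshold: float = locus.DEFAULT_P_THRESHOLD


@dataclass
class PipelineConfig:
    """Full pipeline configuration; every study threshold is a named field."""

    disorders: tuple[DisorderConfig, ...] = ()
    # inputs: either explicit paths or a synthetic block
    gwas_path: str | None = None
    eqtl_path: str | None = None
    expression_path: str | None = None
    gmt_path: str | None = None
    synthetic: SimulationConfig | None = None
    # stage parameters
    fdr_threshold: float = eq.DEFAULT_FDR_THRESHOLD
    overlap_reps_a: int = 1000
    overlap_reps_b: int = 1000
    overlap_universe_path: str | None = None
    overlap_size_convention: str = "pairs"  # pairs | genes
    coexpression_alpha: float = cx.DEFAULT_ALPHA
    correlation_method: str = "pearson"
    module_method: str = "components"
    enrichment_p_threshold: float = en.DEFAULT_P_THRESHOLD
    enrichment_min_overlap: int = en.DEFAULT_MIN_OVERLAP
    enrichment_min_factor: float = en.DEFAULT_MIN_FACTOR
    similarity_threshold: float = en.DEFAULT_SIMILARITY_THRESHOLD
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        disorders = tuple(
            DisorderConfig(
                label=d["label"],
                trait_labels=tuple(d["trait_labels"]),
                p_threshold=float(d.get("p_threshold", locus.DEFAULT_P_THRESHOLD)),
            )
            for d in raw.pop("disorders", [])
        )
        synth = raw.pop("synthetic", None)
        if synth is not None and not isinstance(synth, SimulationConfig):
            synth = dict(synth)
            if "module_spec" in synth:
                synth["module_spec"] = tuple(tuple(m) for m in synth["module_spec"])
            if "term_size_range" in synth:
                synth["term_size_range"] = tuple(synth["term_size_range"])
            synth = SimulationConfig(**synth)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(disorders=disorders, synthetic=synth, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_config(config: PipelineConfig) -> list[str]:
    """Return one problem string per violated constraint; empty iff runnable."""
    problems: list[str] = []
    if len(config.disorders) != 2:
        problems.append(f"exactly two disorder blocks required, found {len(config.disorders)}")
    for d in config.disorders:
        if not d.trait_labels:
            problems.append(f"disorder {d.label!r}: trait_labels must be non-empty")
        if not 0 < d.p_threshold < 1:
            problems.append(f"disorder {d.label!r}: p_threshold must be in (0, 1)")
    if not 0 < config.fdr_threshold < 1:
        problems.append("fdr_threshold must be in (0, 1)")
    if config.overlap_reps_a < 1 or config.overlap_reps_b < 1:
        problems.append("overlap reps must be >= 1")
    if config.overlap_size_convention not in ("pairs", "genes"):
        problems.append("overlap_size_convention must be 'pairs' or 'genes'")
    if not 0 < config.coexpression_alpha < 1:
        problems.append("coexpression alpha must be in (0, 1)")
    if not 0 < config.enrichment_p_threshold < 1:
        problems.append("enrichment_p_threshold must be in (0, 1)")
    if config.enrichment_min_overlap < 0:
        problems.append("enrichment_min_overlap must be >= 0")
    if config.enrichment_min_factor < 0:
        problems.append("enrichment_min_factor must be >= 0")
    if not 0 < config.similarity_threshold < 1:
        problems.append("similarity_threshold must be in (0, 1)")
    have_paths = all(
        p is not None
        for p in (config.gwas_path, config.eqtl_path, config.expression_path, config.gmt_path)
    )
    if not have_paths and config.synthetic is None:
        problems.append("either all four input paths or a synthetic block must be given")
    if config.synthetic is not None:
        problems.extend(f"synthetic: {p}" for p in config.synthetic.validate())
    return problems


class StageError(CrosstraitError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineArtifacts:
    """In-memory stage outputs of one run."""

    snp_sets: dict[str, locus.SnpSet] = field(default_factory=dict)
    pairs: dict[str, list[eq.SnpGenePair]] = field(default_factory=dict)
    gene_sets: dict[str, eq.GeneSet] = field(default_factory=dict)
    overlap: ov.OverlapTestResults | None = None
    coexpression: dict[str, cx.CoexpressionResults] = field(default_factory=dict)
    enrichment: en.EnrichmentResults | None = None


def _report_counts(config: PipelineConfig, art: PipelineArtifacts) -> dict[str, Any]:
    counts: dict[str, Any] = {}
    for label in sorted(art.snp_sets):
        d: dict[str, Any] = {"snps_retained": len(art.snp_sets[label])}
        if label in art.pairs:
            d["pairs_retained"] = len(art.pairs[label])
            d["unique_genes"] = len(art.gene_sets[label].genes)
            d["distance_classes"] = eq.class_counts(art.pairs[label])
            d["found_in_proximity"] = sum(
                p.found_in_proximity for p in art.pairs[label]
            )
        if label in art.coexpression:
            res = art.coexpression[label]
            d["network_nodes"] = res.network.number_of_nodes()
            d["network_edges"] = res.network.number_of_edges()
            d["coexpression_tests"] = res.n_tests
            d["modules"] = len([m for m in res.modules if len(m) > 1])
        counts[label] = d
    if art.overlap is not None:
        counts["overlap"] = art.overlap.to_dict()
    if art.enrichment is not None:
        sig = {
            label: sum(r.significant for r in results)
            for label, results in art.enrichment.results_by_query.items()
        }
        counts["enrichment"] = {
            "significant_terms": sig,
            "clusters": len(art.enrichment.clusters),
            "shared_clusters": sum(c.shared for c in art.enrichment.clusters),
        }
    return counts


def run_pipeline(config: PipelineConfig) -> tuple[dict[str, Any], PipelineArtifacts]:
    """Execute all stages; returns (run report dict, in-memory artifacts).

    Identical config + seed give an identical report. If ``out_dir`` is
    set, stage artifacts and the report are written there; on a stage
    failure, partial outputs are retained next to a FAILED marker naming
    the stage.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("; ".join(problems))
    out_dir = Path(config.out_dir) if config.out_dir else None
    art = PipelineArtifacts()
    try:
        report = _run_stages(config, art, out_dir)
    except Exception as exc:
        stage = exc.stage if isinstance(exc, StageError) else "unknown"
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            (out_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise
    if out_dir is not None:
        emit_outputs(report, art, out_dir)
    return report, art


def _run_stages(
    config: PipelineConfig, art: PipelineArtifacts, out_dir: Path | None
) -> dict[str, Any]:
    # inputs
    universe_path = config.overlap_universe_path
    try:
        if config.synthetic is not None and config.gwas_path is None:
            dataset = generate_dataset(
                config.synthetic,
                trait_labels=[d.trait_labels[0] for d in config.disorders],
            )
            if out_dir is not None:
                target = out_dir / "synthetic_inputs"
            else:
                import tempfile

                target = Path(tempfile.mkdtemp(prefix="crosstrait-"))
            paths = dataset.write(target)
            gwas_path, eqtl_path = paths["gwas"], paths["eqtl"]
            expression_path, gmt_path = paths["expression"], paths["gmt"]
            if universe_path is None:
                universe_path = paths["universe"]
        else:
            gwas_path, eqtl_path = config.gwas_path, config.eqtl_path
            expression_path, gmt_path = config.expression_path, config.gmt_path
    except Exception as exc:
        raise StageError("synthetic_data", exc) from exc

    # stage 1: locus selection
    try:
        records = locus.read_associations(gwas_path)
        for d in config.disorders:
            filtered = locus.filter_by_traits(records, list(d.trait_labels))
            art.snp_sets[d.label] = locus.select_suggestive_snps(
                filtered, p_threshold=d.p_threshold, disorder_label=d.label
            )
            log.info(
                "locus_selection[%s]: %d records -> %d SNPs",
                d.label, len(filtered), len(art.snp_sets[d.label]),
            )
    except Exception as exc:
        raise StageError("locus_selection", exc) from exc

    # stage 2: eQTL mapping
    try:
        eqtl_records = eq.read_eqtl_table(eqtl_path)
        for d in config.disorders:
            pairs = eq.join_significant(
                art.snp_sets[d.label], eqtl_records, fdr_threshold=config.fdr_threshold
            )
            art.pairs[d.label] = pairs
            art.gene_sets[d.label] = eq.unique_gene_set(pairs, d.label)
            log.info(
                "eqtl_mapping[%s]: %d pairs, %d unique genes (%s)",
                d.label, len(pairs), len(art.gene_sets[d.label].genes),
                eq.class_counts(pairs),
            )
    except Exception as exc:
        raise StageError("eqtl_mapping", exc) from exc

    # stage 3: overlap null
    try:
        label_a, label_b = (d.label for d in config.disorders)
        gs_a, gs_b = art.gene_sets[label_a], art.gene_sets[label_b]
        if universe_path:
            universe = [
                line.strip()
                for line in Path(universe_path).read_text().splitlines()
                if line.strip()
            ]
        else:
            # all genes with any eQTL effect in the supplied table
            universe = sorted({r.gene_key for r in eqtl_records})
        if config.overlap_size_convention == "pairs":
            size_a, size_b = gs_a.n_pairs, gs_b.n_pairs
        else:
            size_a, size_b = len(gs_a.genes), len(gs_b.genes)
        model = ov.GeneSetOverlapTest(
            gs_a.genes, gs_b.genes, universe,
            size_a=size_a, size_b=size_b, labels=(label_a, label_b),
        )
        art.overlap = model.fit(
            reps_a=config.overlap_reps_a, reps_b=config.overlap_reps_b, seed=config.seed
        )
        log.info(
            "overlap_null: J=%.5f exceedance=%.4f",
            art.overlap.observed_j, art.overlap.exceed_fraction,
        )
    except Exception as exc:
        raise StageError("overlap_null", exc) from exc

    # stage 4: co-expression expansion
    try:
        matrix = cx.read_expression(expression_path)
        for d in config.disorders:
            screen = cx.CoexpressionScreen(
                matrix, sorted(art.gene_sets[d.label].genes), label=d.label
            )
            art.coexpression[d.label] = screen.fit(
                alpha=config.coexpression_alpha,
                method=config.correlation_method,
                module_method=config.module_method,
            )
            log.info(
                "coexpression[%s]: %d nodes, %d modules",
                d.label,
                art.coexpression[d.label].network.number_of_nodes(),
                len(art.coexpression[d.label].modules),
            )
    except Exception as exc:
        raise StageError("coexpression", exc) from exc

    # stage 5: enrichment clustering
    try:
        terms = en.read_gmt(gmt_path)
        queries = {
            d.label: set(art.coexpression[d.label].nodes) for d in config.disorders
        }
        analysis = en.EnrichmentAnalysis(queries, terms)
        art.enrichment = analysis.fit(
            p_threshold=config.enrichment_p_threshold,
            min_overlap=config.enrichment_min_overlap,
            min_factor=config.enrichment_min_factor,
            similarity_threshold=config.similarity_threshold,
        )
        log.info(
            "enrichment: %d clusters, %d shared",
            len(art.enrichment.clusters),
            sum(c.shared for c in art.enrichment.clusters),
        )
    except Exception as exc:
        raise StageError("enrichment_clustering", exc) from exc

    config_echo = dataclasses.asdict(config)
    if config.synthetic is not None:
        config_echo["synthetic"] = dataclasses.asdict(config.synthetic)
    return {
        "software": {"name": "crosstrait", "version": __version__},
        "seed": config.seed,
        "config": config_echo,
        "counts": _report_counts(config, art),
    }


def emit_outputs(
    report: dict[str, Any], art: PipelineArtifacts, out_dir: str | Path
) -> dict[str, Any]:
    """Write all stage artifacts plus the run report; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {}

    def _write_tsv(name: str, frame) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest[name] = {"rows": int(len(frame))}

    for label in sorted(art.snp_sets):
        safe = label.replace(" ", "_").replace("/", "_")
        _write_tsv(f"snp_set_{safe}.tsv", locus.snp_set_frame(art.snp_sets[label]))
        if label in art.pairs:
            _write_tsv(f"eqtl_pairs_{safe}.tsv", eq.pairs_frame(art.pairs[label]))
        if label in art.coexpression:
            res = art.coexpression[label]
            _write_tsv(f"coexpression_edges_{safe}.tsv", res.retained)
            _write_tsv(f"coexpression_modules_{safe}.tsv", res.module_frame())
            path = out / f"coexpression_network_{safe}.graphml"
            nx.write_graphml(res.network, path)
            manifest[path.name] = {"rows": res.network.number_of_nodes()}
    if art.overlap is not None:
        path = out / "overlap_report.json"
        with open(path, "w") as fh:
            json.dump(art.overlap.to_dict(), fh, indent=1, sort_keys=True)
        manifest[path.name] = {"rows": 1}
    if art.enrichment is not None:
        _write_tsv("enrichment_results.tsv", art.enrichment.to_frame())
        _write_tsv("enrichment_clusters.tsv", art.enrichment.cluster_frame())
        term_net = art.enrichment.term_network()
        path = out / "term_network.graphml"
        nx.write_graphml(term_net, path)
        manifest[path.name] = {"rows": term_net.number_of_nodes()}
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    manifest["run_report.json"] = {"rows": 1}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
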