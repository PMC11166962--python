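"""Synthetic inputs with planted, recoverable structure.

Generates the four pipeline inputs — a GWAS-catalog-style association
table, a brain-eQTL summary table, a genes x samples expression matrix and
a GMT annotation collection — entirely from a seeded configuration, with a
ground-truth record of everything planted: which SNPs are significant,
which genes each disorder's eQTLs hit (including an exact number of shared
genes), the intended cis/trans label of every pair, the co-expression
module memberships, and which annotation terms were made enriched in both
disorders' gene lists. Every downstream stage therefore has an exact
recovery target without any external download.

The defaults mirror the scale of the study conditions: two disorders with
planted significant SNP-gene pair sets of 101 and 487 pairs collapsing to
70 and 278 unique genes of which exactly 6 are shared, a 17,000-gene eQTL
universe, and a 192-sample expression matrix.

Everything is a pure function of (config, seed): each generator draws from
its own RNG stream derived from the master seed by a fixed label, so
adding one generator never perturbs another's output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import ConfigurationError, rng_stream
from .enrichment import GeneSetTerm, write_gmt

GWAS_P_THRESHOLD = 5e-5
N_CHROMOSOMES = 22

DEFAULT_TRAIT_LABELS = ("disorder A", "disorder B")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    ``n_genes_a`` / ``n_genes_b`` are the unique-gene counts the planted
    pair sets collapse to (pairs reuse genes the way several SNPs can
    regulate one gene); they default to the pair counts when None.
    """

    seed: int = 0
    # GWAS table
    n_snps_per_trait: int = 700
    frac_significant: float = 0.85
    n_decoy_snps: int = 50
    # eQTL table
    universe_size: int = 17_000
    n_eqtl_pairs_a: int = 101
    n_eqtl_pairs_b: int = 487
    n_genes_a: int | None = 70
    n_genes_b: int | None = 278
    planted_shared_genes: int = 6
    frac_trans: float = 0.05
    frac_prox: float = 0.3
    n_nonsig_eqtl_rows: int = 200
    n_decoy_eqtl_rows: int = 50
    # expression matrix
    n_samples: int = 192
    module_spec: tuple[tuple[int, float], ...] = ((30, 0.8), (25, 0.8), (20, 0.75))
    n_background_genes: int = 100
    # annotations
    n_terms: int = 60
    term_size_range: tuple[int, int] = (10, 60)
    planted_enriched_terms: int = 3
    planted_term_fraction: float = 0.8
    n_annotation_universe: int = 4000

    def resolved_genes_a(self) -> int:
        return self.n_eqtl_pairs_a if self.n_genes_a is None else self.n_genes_a

    def resolved_genes_b(self) -> int:
        return self.n_eqtl_pairs_b if self.n_genes_b is None else self.n_genes_b

    def validate(self) -> list[str]:
        """Return one message per violated constraint (empty iff valid)."""
        problems: list[str] = []
        if self.n_snps_per_trait < 1:
            problems.append("n_snps_per_trait must be >= 1")
        if not 0 <= self.frac_significant <= 1:
            problems.append("frac_significant must be in [0, 1]")
        if self.n_samples < 3:
            problems.append("n_samples must be >= 3 (correlation p-value undefined below)")
        for i, (size, rho) in enumerate(self.module_spec):
            if size < 2:
                problems.append(f"module_spec[{i}]: module size must be >= 2")
            if not 0 <= rho < 1:
                problems.append(f"module_spec[{i}]: rho must satisfy 0 <= rho < 1")
        na, nb = self.resolved_genes_a(), self.resolved_genes_b()
        if na > self.n_eqtl_pairs_a:
            problems.append("n_genes_a cannot exceed n_eqtl_pairs_a")
        if nb > self.n_eqtl_pairs_b:
            problems.append("n_genes_b cannot exceed n_eqtl_pairs_b")
        if self.planted_shared_genes > min(na, nb):
            problems.append(
                "planted_shared_genes cannot exceed the smaller planted gene set"
            )
        if self.planted_shared_genes < 0:
            problems.append("planted_shared_genes must be >= 0")
        if self.universe_size < na + nb - self.planted_shared_genes:
            problems.append("universe_size smaller than the union of planted gene sets")
        if not 0 <= self.frac_trans <= 1:
            problems.append("frac_trans must be in [0, 1]")
        if self.n_terms < 0 or self.planted_enriched_terms > self.n_terms:
            problems.append("planted_enriched_terms cannot exceed n_terms")
        lo, hi = self.term_size_range
        if lo < 3:
            problems.append("term_size_range lower bound must be >= 3")
        if hi < lo:
            problems.append("term_size_range must be (min, max) with min <= max")
        if not 0 <= self.planted_term_fraction <= 1:
            problems.append("planted_term_fraction must be in [0, 1]")
        return problems

    def require_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise ConfigurationError("; ".join(problems))


def _gene_key(i: int) -> str:
    return f"ENSG{i:011d}"


def _gene_id(i: int) -> str:
    return f"{_gene_key(i)}.{(i % 17) + 1}"


def _hgnc(i: int) -> str:
    return f"G{i:05d}"


def _n_significant(config: SimulationConfig) -> int:
    return round(config.frac_significant * config.n_snps_per_trait)


def _sig_snp_ids(trait_index: int, n: int) -> list[str]:
    return [f"rs{trait_index + 1}{i:05d}" for i in range(n)]


@dataclass
class PlantedPair:
    snp_id: str
    gene_index: int
    distance_class: str  # intended label: cis | trans
    prox: bool


@dataclass
class EqtlTruth:
    """What the eQTL generator planted, sufficient to score recovery."""

    trait_labels: tuple[str, str]
    sig_snps: dict[str, list[str]]
    gene_sets: dict[str, list[str]]       # unique gene_keys per trait
    hgnc_sets: dict[str, list[str]]
    shared_genes: list[str]
    pairs: dict[str, list[PlantedPair]] = field(repr=False, default_factory=dict)


def _plant(config: SimulationConfig, trait_labels: Sequence[str]) -> EqtlTruth:
    """Deterministic planted structure shared by the GWAS and eQTL generators."""
    config.require_valid()
    if len(trait_labels) != 2:
        raise ConfigurationError("eQTL planting requires exactly two trait labels")
    n_sig = _n_significant(config)
    for label, n_pairs in zip(trait_labels, (config.n_eqtl_pairs_a, config.n_eqtl_pairs_b)):
        if n_pairs > n_sig:
            raise ConfigurationError(
                f"n_eqtl_pairs for {label!r} ({n_pairs}) exceeds the significant SNP "
                f"count round(frac_significant * n_snps_per_trait) = {n_sig}"
            )
    rng = rng_stream(config.seed, "plant")

    na, nb = config.resolved_genes_a(), config.resolved_genes_b()
    shared = config.planted_shared_genes
    n_needed = na + nb - shared
    chosen = rng.choice(config.universe_size, size=n_needed, replace=False)
    shared_idx = chosen[:shared]
    a_only = chosen[shared: shared + (na - shared)]
    b_only = chosen[shared + (na - shared):]
    genes_a = np.concatenate([shared_idx, a_only]).astype(int)
    genes_b = np.concatenate([shared_idx, b_only]).astype(int)

    truth = EqtlTruth(
        trait_labels=tuple(trait_labels),
        sig_snps={}, gene_sets={}, hgnc_sets={},
        shared_genes=sorted(_gene_key(i) for i in shared_idx),
        pairs={},
    )
    for t, (label, gene_idx, n_pairs) in enumerate(
        zip(trait_labels, (genes_a, genes_b), (config.n_eqtl_pairs_a, config.n_eqtl_pairs_b))
    ):
        snps = _sig_snp_ids(t, n_sig)
        truth.sig_snps[label] = snps
        truth.gene_sets[label] = sorted(_gene_key(i) for i in gene_idx)
        truth.hgnc_sets[label] = sorted(_hgnc(i) for i in gene_idx)
        # every planted gene gets >= 1 pair; surplus pairs reuse random genes
        assigned = list(gene_idx) + [
            int(gene_idx[j]) for j in rng.integers(0, len(gene_idx), size=n_pairs - len(gene_idx))
        ]
        n_trans = round(config.frac_trans * n_pairs)
        trans_pos = set(rng.choice(n_pairs, size=n_trans, replace=False).tolist())
        prox_pos = set(
            rng.choice(n_pairs, size=round(config.frac_prox * n_pairs), replace=False).tolist()
        )
        truth.pairs[label] = [
            PlantedPair(
                snp_id=snps[j],
                gene_index=int(assigned[j]),
                distance_class="trans" if j in trans_pos else "cis",
                prox=j in prox_pos,
            )
            for j in range(n_pairs)
        ]
    return truth


def _gene_coords(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (chromosome, TSS) per universe gene, from its own stream."""
    rng = rng_stream(config.seed, "gene-coords")
    chrom = rng.integers(1, N_CHROMOSOMES + 1, size=config.universe_size)
    tss = rng.integers(6_000_000, 200_000_000, size=config.universe_size)
    return chrom, tss


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), size=size)


def generate_gwas_table(
    config: SimulationConfig,
    trait_labels: Sequence[str] = DEFAULT_TRAIT_LABELS,
    prox_map: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """GWAS-catalog-style association table.

    Per trait: ``n_snps_per_trait`` primary rows of which exactly
    round(frac_significant * n) have p < 5e-5 (significant p log-uniform on
    [1e-30, 5e-5), the rest log-uniform on [5e-5, 1]), plus duplicate
    re-reports of a few significant SNPs under a second study accession
    (at non-significant p, so the per-trait sub-threshold row count stays
    exact) and a decoy trait. ``prox_map`` optionally supplies HGNC symbols
    to place in MAPPED_GENE for given SNPs (used by the combined generator
    to plant proximity-known genes).
    """
    if not trait_labels:
        raise ConfigurationError("trait_labels must be non-empty")
    config.require_valid()
    rng = rng_stream(config.seed, "gwas")
    prox_map = prox_map or {}
    n = config.n_snps_per_trait
    n_sig = _n_significant(config)
    rows = []

    def mapped_genes_for(snp: str, k: int) -> str:
        if snp in prox_map:
            return ", ".join(sorted(prox_map[snp]))
        style = k % 3
        if style == 0:
            return f"NEAR{k}"
        if style == 1:
            return f"NEAR{k} - NEAR{k + 1}"
        return f"NEAR{k}, NEAR{k + 1}"

    for t, label in enumerate(trait_labels):
        uri = f"http://www.ebi.ac.uk/efo/EFO_{t + 1:07d}"
        sig_ids = _sig_snp_ids(t, n_sig)
        sig_p = _log_uniform(rng, 1e-30, GWAS_P_THRESHOLD, n_sig)
        sig_p = np.minimum(sig_p, GWAS_P_THRESHOLD * (1 - 1e-12))
        nonsig_p = _log_uniform(rng, GWAS_P_THRESHOLD, 1.0, n - n_sig)
        nonsig_p = np.maximum(nonsig_p, GWAS_P_THRESHOLD)
        for i, snp in enumerate(sig_ids):
            rows.append((snp, label, uri, sig_p[i], str(rng.integers(1, 23)),
                         int(rng.integers(1, 2 * 10**8)), mapped_genes_for(snp, i),
                         f"GCST{t + 1}00001"))
        for i in range(n - n_sig):
            snp = f"rs9{t}{i:05d}"
            rows.append((snp, label, uri, nonsig_p[i], str(rng.integers(1, 23)),
                         int(rng.integers(1, 2 * 10**8)), mapped_genes_for(snp, n_sig + i),
                         f"GCST{t + 1}00001"))
        # duplicate re-reports of a few significant SNPs in a second study
        for i, snp in enumerate(sig_ids[: min(5, n_sig)]):
            rows.append((snp, label, uri, float(10 ** rng.uniform(-4, -1)),
                         str(rng.integers(1, 23)), int(rng.integers(1, 2 * 10**8)),
                         mapped_genes_for(snp, i), f"GCST{t + 1}00002"))
    # decoy trait rows, never selected downstream
    for i in range(config.n_decoy_snps):
        rows.append((f"rs8{i:05d}", "Synthetic decoy trait",
                     "http://www.ebi.ac.uk/efo/EFO_9999999",
                     float(10 ** rng.uniform(-8, 0)), str(rng.integers(1, 23)),
                     int(rng.integers(1, 2 * 10**8)), f"NEAR{i}", "GCST999999"))
    return pd.DataFrame(
        rows,
        columns=["SNPS", "DISEASE/TRAIT", "MAPPED_TRAIT_URI", "P-VALUE",
                 "CHR_ID", "CHR_POS", "MAPPED_GENE", "STUDY ACCESSION"],
    )


def generate_eqtl_table(
    config: SimulationConfig,
    trait_labels: Sequence[str] = DEFAULT_TRAIT_LABELS,
) -> tuple[pd.DataFrame, EqtlTruth]:
    """eQTL summary table plus the planted ground truth.

    Planted significant pairs (FDR drawn below 0.05) realise the configured
    per-trait pair and unique-gene counts with exactly
    ``planted_shared_genes`` genes common to both traits. Coordinates are
    generated so the intended cis/trans label is recoverable: cis SNPs sit
    within 1 Mb of their gene's TSS on the same chromosome, trans SNPs on a
    different chromosome. Non-significant rows (FDR >= 0.05) and
    significant rows for decoy SNPs absent from any disorder SNP set are
    mixed in as noise.
    """
    truth = _plant(config, trait_labels)
    rng = rng_stream(config.seed, "eqtl")
    chrom_of, tss_of = _gene_coords(config)
    rows = []

    def z_from_p(p: float) -> float:
        from scipy.stats import norm

        mag = float(norm.isf(p / 2))
        return mag if rng.random() < 0.5 else -mag

    def add_row(snp, gi, fdr, p):
        g_chrom, g_tss = int(chrom_of[gi]), int(tss_of[gi])
        planted = planted_class.get((snp, gi))
        if planted == "cis" or (planted is None and rng.random() < 0.7):
            s_chrom = g_chrom
            offset = int(rng.integers(1, 1_000_000))
            s_pos = g_tss + offset if rng.random() < 0.5 else max(1, g_tss - offset)
        else:
            s_chrom = int(rng.integers(1, N_CHROMOSOMES + 1))
            while s_chrom == g_chrom:
                s_chrom = int(rng.integers(1, N_CHROMOSOMES + 1))
            s_pos = int(rng.integers(1, 2 * 10**8))
        allele = "".join(rng.choice(list("ACGT"), size=2, replace=False))
        rows.append((snp, _gene_id(gi), _hgnc(gi), p, fdr, z_from_p(p),
                     f"{allele[0]}/{allele[1]}", str(s_chrom), s_pos,
                     str(g_chrom), g_tss))

    planted_class: dict[tuple[str, int], str] = {}
    for label in truth.trait_labels:
        for pair in truth.pairs[label]:
            planted_class[(pair.snp_id, pair.gene_index)] = pair.distance_class
    for label in truth.trait_labels:
        for pair in truth.pairs[label]:
            fdr = float(_log_uniform(rng, 1e-20, 0.05, 1)[0]) * (1 - 1e-9)
            p = float(_log_uniform(rng, 1e-30, 1e-6, 1)[0])
            add_row(pair.snp_id, pair.gene_index, fdr, p)
    # non-significant noise rows on disorder SNPs: removed by the FDR gate
    all_sig_snps = [s for label in truth.trait_labels for s in truth.sig_snps[label]]
    for _ in range(config.n_nonsig_eqtl_rows):
        snp = all_sig_snps[int(rng.integers(0, len(all_sig_snps)))]
        gi = int(rng.integers(0, config.universe_size))
        add_row(snp, gi, float(rng.uniform(0.05, 1.0)), float(rng.uniform(1e-5, 1.0)))
    # significant rows on decoy SNPs: removed by the SNP-set join
    for i in range(config.n_decoy_eqtl_rows):
        gi = int(rng.integers(0, config.universe_size))
        add_row(f"rs7{i:05d}", gi, float(_log_uniform(rng, 1e-10, 0.05, 1)[0]) * (1 - 1e-9),
                float(_log_uniform(rng, 1e-20, 1e-6, 1)[0]))
    frame = pd.DataFrame(
        rows,
        columns=["SNPName", "GeneID", "HGNC", "PValue", "FDR", "OverallZ",
                 "AlleleAssessed", "SNPChr", "SNPPos", "GeneChr", "GeneTSS"],
    )
    return frame, truth


def generate_expression(
    config: SimulationConfig, seed_genes: Sequence[str]
) -> tuple[pd.DataFrame, list[frozenset[str]]]:
    """Expression matrix with planted co-expression modules.

    Each module in ``module_spec`` is seeded with one gene from
    ``seed_genes`` (round-robin over the sorted list) plus newly named
    co-member genes; within a module every gene is sqrt(rho) * shared
    latent factor + sqrt(1-rho) * independent noise, giving exact pairwise
    population correlation rho. Remaining seed genes and background genes
    are independent standard normals.
    """
    config.require_valid()
    seeds = list(dict.fromkeys(seed_genes))  # caller's order decides module anchors
    if config.module_spec and len(seeds) < len(config.module_spec):
        raise ConfigurationError(
            f"module_spec has {len(config.module_spec)} modules but only "
            f"{len(seeds)} seed genes are available to anchor them"
        )
    rng = rng_stream(config.seed, "expression")
    n = config.n_samples
    gene_rows: dict[str, np.ndarray] = {}
    modules: list[frozenset[str]] = []
    for m, (size, rho) in enumerate(config.module_spec):
        members = [seeds[m]] + [f"CX{m + 1:02d}G{j:03d}" for j in range(size - 1)]
        factor = rng.standard_normal(n)
        for g in members:
            noise = rng.standard_normal(n)
            gene_rows[g] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * noise
        modules.append(frozenset(members))
    for g in seeds:
        if g not in gene_rows:
            gene_rows[g] = rng.standard_normal(n)
    for j in range(config.n_background_genes):
        gene_rows[f"BG{j:04d}"] = rng.standard_normal(n)
    frame = pd.DataFrame(
        gene_rows, index=[f"S{i + 1:04d}" for i in range(n)]
    ).T
    frame.index.name = "gene"
    return frame, modules


def generate_annotations(
    config: SimulationConfig,
    gene_universe: Sequence[str],
    planted_gene_sets: Sequence[Sequence[str]] | None = None,
) -> tuple[list[GeneSetTerm], list[str]]:
    """GMT annotation collection with planted enriched terms.

    The first ``planted_enriched_terms`` terms draw
    ``planted_term_fraction`` of their members from the planted gene sets
    (split evenly across the sets, so such terms are enriched in *both*
    disorders' lists); the rest of their members, and all members of every
    other term, are drawn uniformly from the universe.
    """
    config.require_valid()
    universe = sorted(dict.fromkeys(gene_universe))
    if not universe:
        raise ConfigurationError("gene_universe must be non-empty")
    lo, hi = config.term_size_range
    if hi > len(universe):
        raise ConfigurationError(
            f"term_size_range upper bound {hi} exceeds the universe size {len(universe)}"
        )
    rng = rng_stream(config.seed, "annotations")
    sets = [sorted(set(s) & set(universe)) for s in (planted_gene_sets or [])]
    terms: list[GeneSetTerm] = []
    planted_ids: list[str] = []
    # Planted terms take sizes from the top third of the range: a term is
    # only a credible enrichment plant when its planted member count is
    # well above the chance expectation for the larger query set.
    planted_lo = max(lo, hi - (hi - lo) // 3)
    for i in range(config.n_terms):
        planted = i < config.planted_enriched_terms and sets
        size = int(rng.integers(planted_lo if planted else lo, hi + 1))
        members: set[str] = set()
        if planted:
            n_planted = round(config.planted_term_fraction * size)
            per_set = [n_planted // len(sets)] * len(sets)
            per_set[0] += n_planted - sum(per_set)
            for s, k in zip(sets, per_set):
                k = min(k, len(s))
                members |= set(rng.choice(s, size=k, replace=False).tolist())
        while len(members) < size:
            members.add(universe[int(rng.integers(0, len(universe)))])
        term_id = f"TERM{i:04d}"
        terms.append(
            GeneSetTerm(
                term_id=term_id,
                name=(f"planted shared pathway {i}" if planted else f"synthetic pathway {i}"),
                source="custom",
                members=frozenset(members),
            )
        )
        if planted:
            planted_ids.append(term_id)
    return terms, planted_ids


@dataclass
class SyntheticDataset:
    """All four generated inputs plus the composed ground truth."""

    config: SimulationConfig
    gwas: pd.DataFrame
    eqtl: pd.DataFrame
    eqtl_truth: EqtlTruth
    expression: pd.DataFrame
    modules: list[frozenset[str]]
    terms: list[GeneSetTerm]
    enriched_term_ids: list[str]
    expanded_sets: dict[str, set[str]]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the four input files plus a ground-truth JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gwas": out / "gwas_associations.tsv",
            "eqtl": out / "eqtl_summary.tsv",
            "expression": out / "expression.tsv",
            "gmt": out / "annotations.gmt",
            "universe": out / "eqtl_gene_universe.txt",
            "truth": out / "ground_truth.json",
        }
        # all genes that exhibit eQTL effects anywhere in the synthetic
        # genome: the universe the overlap null should draw from
        paths["universe"].write_text(
            "\n".join(_gene_key(i) for i in range(self.config.universe_size)) + "\n"
        )
        self.gwas.to_csv(paths["gwas"], sep="\t", index=False)
        self.eqtl.to_csv(paths["eqtl"], sep="\t", index=False)
        self.expression.to_csv(paths["expression"], sep="\t")
        write_gmt(self.terms, paths["gmt"])
        truth = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "trait_labels": list(self.eqtl_truth.trait_labels),
            "shared_genes": self.eqtl_truth.shared_genes,
            "gene_sets": self.eqtl_truth.gene_sets,
            "pairs": {
                label: [asdict(p) for p in pairs]
                for label, pairs in self.eqtl_truth.pairs.items()
            },
            "modules": [sorted(m) for m in self.modules],
            "enriched_term_ids": self.enriched_term_ids,
            "expanded_sets": {k: sorted(v) for k, v in self.expanded_sets.items()},
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        return paths


def generate_dataset(
    config: SimulationConfig,
    trait_labels: Sequence[str] = DEFAULT_TRAIT_LABELS,
) -> SyntheticDataset:
    """Generate all four inputs with mutually consistent planted structure.

    The GWAS table carries the eQTL-planted proximity genes in its
    MAPPED_GENE column; the expression matrix uses both disorders' planted
    eQTL genes as module seeds; the annotation collection plants terms
    enriched in both disorders' expanded (eQTL + co-expressed) gene lists.
    """
    eqtl_frame, truth = generate_eqtl_table(config, trait_labels)
    prox_map: dict[str, list[str]] = {}
    for label in truth.trait_labels:
        for pair in truth.pairs[label]:
            if pair.prox:
                prox_map.setdefault(pair.snp_id, [])
                sym = _hgnc(pair.gene_index)
                if sym not in prox_map[pair.snp_id]:
                    prox_map[pair.snp_id].append(sym)
    gwas = generate_gwas_table(config, trait_labels, prox_map=prox_map)

    # Interleave the two disorders' genes so module anchors (taken in order)
    # alternate between them: both disorders then recover planted modules.
    set_a = truth.gene_sets[truth.trait_labels[0]]
    set_b = [g for g in truth.gene_sets[truth.trait_labels[1]] if g not in set(set_a)]
    interleaved: list[str] = []
    for i in range(max(len(set_a), len(set_b))):
        if i < len(set_a):
            interleaved.append(set_a[i])
        if i < len(set_b):
            interleaved.append(set_b[i])
    expression, modules = generate_expression(config, interleaved)

    expanded: dict[str, set[str]] = {}
    for label in truth.trait_labels:
        genes = set(truth.gene_sets[label])
        for module in modules:
            if module & genes:
                genes |= module
        expanded[label] = genes
    # Annotation background is wider than the expression matrix: expanded
    # disease lists must stay a small fraction of it for enrichment to be
    # detectable, as with a genome-wide annotation collection.
    gene_universe = sorted(
        set(expression.index)
        | set().union(*expanded.values())
        | {_gene_key(i) for i in range(min(config.n_annotation_universe, config.universe_size))}
    )
    terms, planted_ids = generate_annotations(
        config, gene_universe,
        planted_gene_sets=[sorted(expanded[label]) for label in truth.trait_labels],
    )
    return SyntheticDataset(
        config=config,
        gwas=gwas,
        eqtl=eqtl_frame,
        eqtl_truth=truth,
        expression=expression,
        modules=modules,
        terms=terms,
        enriched_term_ids=planted_ids,
        expanded_sets=expanded,
    )
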