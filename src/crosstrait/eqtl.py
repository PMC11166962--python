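"""Brain eQTL mapping: join disorder SNP sets to eQTL summary statistics.

Significant effects (FDR < 0.05, strict) are retained, classified as cis
(same chromosome, SNP-TSS distance < 1 Mb), trans (different chromosome or
distance > 5 Mb) or ambiguous (the 1-5 Mb gap, which neither definition
covers), and collapsed to unique gene sets on version-stripped gene ids.
A proximity flag records whether each gene was already proximity-mapped in
the GWAS catalog, i.e. whether the eQTL adds a novel candidate.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import FormatError
from .locus import SnpSet

log = logging.getLogger(__name__)

CIS_MAX_DISTANCE = 1_000_000
TRANS_MIN_DISTANCE = 5_000_000
DEFAULT_FDR_THRESHOLD = 0.05

#: Columns of the eQTL summary TSV dialect (MetaBrain-like).
EQTL_COLUMNS = (
    "SNPName",
    "GeneID",
    "HGNC",
    "PValue",
    "FDR",
    "OverallZ",
    "AlleleAssessed",
    "SNPChr",
    "SNPPos",
    "GeneChr",
    "GeneTSS",
)

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def strip_version(gene_id: str) -> str:
    """Drop a trailing annotation-version suffix: ENSG00000203710.11 -> ENSG00000203710.

    Idempotent; ids without a suffix pass through unchanged.
    """
    return _VERSION_SUFFIX.sub("", gene_id)


@dataclass(frozen=True)
class EqtlRecord:
    """One SNP-gene eQTL summary row."""

    snp_id: str
    gene_id: str
    hgnc: str
    p_value: float
    fdr: float
    z: float
    allele_assessed: str
    snp_chrom: str
    snp_pos: int | None
    gene_chrom: str
    gene_tss: int | None

    @property
    def gene_key(self) -> str:
        return strip_version(self.gene_id)


@dataclass(frozen=True)
class SnpGenePair:
    """A retained significant SNP-gene effect with distance class and novelty flag."""

    snp_id: str
    gene_id: str
    gene_key: str
    hgnc: str
    p_value: float
    fdr: float
    z: float
    snp_chrom: str
    snp_pos: int | None
    gene_chrom: str
    gene_tss: int | None
    distance_class: str  # cis | trans | ambiguous
    found_in_proximity: bool


@dataclass(frozen=True)
class GeneSet:
    """Unique genes (version-stripped ids) of a disorder's retained pairs."""

    disorder_label: str
    genes: frozenset[str]
    n_pairs: int
    hgnc_by_key: tuple[tuple[str, str], ...] = ()

    def hgnc_symbols(self) -> frozenset[str]:
        return frozenset(h for _, h in self.hgnc_by_key if h)


def read_eqtl_table(
    path: str | Path, row_errors: list[str] | None = None
) -> list[EqtlRecord]:
    """Read an eQTL summary TSV; bad numeric fields are reported and the row skipped."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in EQTL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[EqtlRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        try:
            p = float(d["PValue"])
            fdr = float(d["FDR"])
            z = float(d["OverallZ"])
        except (TypeError, ValueError):
            msg = f"row {i}: non-numeric PValue/FDR/OverallZ"
            log.warning("%s: %s (row skipped)", path, msg)
            if row_errors is not None:
                row_errors.append(msg)
            continue
        if not 0 <= fdr <= 1:
            msg = f"row {i}: FDR {fdr} outside [0, 1]"
            log.warning("%s: %s (row skipped)", path, msg)
            if row_errors is not None:
                row_errors.append(msg)
            continue

        def _pos(key: str) -> int | None:
            try:
                return int(float(d[key]))
            except (TypeError, ValueError):
                return None

        records.append(
            EqtlRecord(
                snp_id=str(d["SNPName"]).strip(),
                gene_id=str(d["GeneID"]).strip(),
                hgnc=str(d["HGNC"]).strip(),
                p_value=p,
                fdr=fdr,
                z=z,
                allele_assessed=str(d["AlleleAssessed"]).strip(),
                snp_chrom=str(d["SNPChr"]).strip(),
                snp_pos=_pos("SNPPos"),
                gene_chrom=str(d["GeneChr"]).strip(),
                gene_tss=_pos("GeneTSS"),
            )
        )
    return records


def classify_distance(
    snp_chrom: str, snp_pos: int | None, gene_chrom: str, gene_tss: int | None
) -> str:
    """Classify a SNP-gene pair as cis, trans or ambiguous by genomic distance.

    Different chromosomes are trans: the >5 Mb rule has no within-chromosome
    distance to measure there. Missing coordinates give ambiguous.
    """
    if not snp_chrom or not gene_chrom or snp_pos is None or gene_tss is None:
        log.warning("missing coordinates; classifying pair as ambiguous")
        return "ambiguous"
    if snp_chrom != gene_chrom:
        return "trans"
    dist = abs(snp_pos - gene_tss)
    if dist < CIS_MAX_DISTANCE:
        return "cis"
    if dist > TRANS_MIN_DISTANCE:
        return "trans"
    return "ambiguous"


def flag_proximity(hgnc: str, snp_set: SnpSet) -> bool:
    """True iff the gene symbol was already proximity-mapped for this disorder's SNPs."""
    return bool(hgnc) and hgnc in snp_set.mapped_gene_union


def join_significant(
    snp_set: SnpSet,
    records: Iterable[EqtlRecord],
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> list[SnpGenePair]:
    """Retain pairs with SNP in the disorder set and FDR strictly below threshold.

    (snp_id, gene_key) pairs are unique; duplicates keep the smallest
    (fdr, p) record.
    """
    if not 0 < fdr_threshold < 1:
        raise ValueError(f"fdr_threshold must be in (0, 1), got {fdr_threshold}")
    best: dict[tuple[str, str], EqtlRecord] = {}
    for r in records:
        if r.snp_id not in snp_set or not r.fdr < fdr_threshold:
            continue
        key = (r.snp_id, r.gene_key)
        prev = best.get(key)
        if prev is None or (r.fdr, r.p_value) < (prev.fdr, prev.p_value):
            best[key] = r
    pairs = []
    for (snp, gene_key), r in sorted(best.items()):
        pairs.append(
            SnpGenePair(
                snp_id=snp,
                gene_id=r.gene_id,
                gene_key=gene_key,
                hgnc=r.hgnc,
                p_value=r.p_value,
                fdr=r.fdr,
                z=r.z,
                snp_chrom=r.snp_chrom,
                snp_pos=r.snp_pos,
                gene_chrom=r.gene_chrom,
                gene_tss=r.gene_tss,
                distance_class=classify_distance(
                    r.snp_chrom, r.snp_pos, r.gene_chrom, r.gene_tss
                ),
                found_in_proximity=flag_proximity(r.hgnc, snp_set),
            )
        )
    return pairs


def unique_gene_set(pairs: Sequence[SnpGenePair], disorder_label: str) -> GeneSet:
    """Collapse pairs to their distinct version-stripped gene ids."""
    hgnc_by_key: dict[str, str] = {}
    for p in pairs:
        hgnc_by_key.setdefault(p.gene_key, p.hgnc)
    return GeneSet(
        disorder_label=disorder_label,
        genes=frozenset(p.gene_key for p in pairs),
        n_pairs=len(pairs),
        hgnc_by_key=tuple(sorted(hgnc_by_key.items())),
    )


def class_counts(pairs: Sequence[SnpGenePair]) -> dict[str, int]:
    counts = {"cis": 0, "trans": 0, "ambiguous": 0}
    for p in pairs:
        counts[p.distance_class] += 1
    return counts


def pairs_frame(pairs: Sequence[SnpGenePair]) -> pd.DataFrame:
    """Tabular view mirroring the input dialect plus distance_class and novelty flag."""
    cols = [
        "snp_id", "gene_id", "gene_key", "hgnc", "p_value", "fdr", "z",
        "snp_chrom", "snp_pos", "gene_chrom", "gene_tss",
        "distance_class", "found_in_proximity",
    ]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in pairs], columns=cols)
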