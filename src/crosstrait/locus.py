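"""GWAS-catalog locus selection.

Parses association tables in the GWAS-catalog TSV dialect, filters records
to the trait labels of interest, and applies a suggestive-significance
p-value threshold (default p < 5e-5) to build per-disorder unique SNP sets.
Duplicate reports of the same SNP across studies collapse to one entry
keeping the best (minimum) p-value and the union of proximity-mapped genes.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import FormatError, norm_label

log = logging.getLogger(__name__)

#: Required columns of the GWAS-catalog association dialect.
REQUIRED_COLUMNS = (
    "SNPS",
    "DISEASE/TRAIT",
    "MAPPED_TRAIT_URI",
    "P-VALUE",
    "CHR_ID",
    "CHR_POS",
    "MAPPED_GENE",
    "STUDY ACCESSION",
)

#: Default suggestive-association threshold (strict <).
DEFAULT_P_THRESHOLD = 5e-5

# MAPPED_GENE may hold several symbols separated by "," or " - ".
_GENE_SEP = re.compile(r"\s*,\s*|\s+-\s+")


@dataclass(frozen=True)
class AssociationRecord:
    """One GWAS-catalog association row."""

    snp_id: str
    chrom: str
    pos: int | None
    trait_label: str
    efo_uri: str
    p_value: float
    mapped_genes: tuple[str, ...]
    study_id: str


@dataclass
class SnpSet:
    """Per-disorder unique SNP set with best p and unioned mapped genes."""

    disorder_label: str
    best_p: dict[str, float] = field(default_factory=dict)
    mapped_genes: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def snps(self) -> frozenset[str]:
        return frozenset(self.best_p)

    @property
    def mapped_gene_union(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.mapped_genes.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.best_p)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.best_p


def _split_genes(raw: object) -> tuple[str, ...]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ()
    parts = [p.strip() for p in _GENE_SEP.split(str(raw))]
    return tuple(p for p in parts if p and p.upper() != "NR")


def read_associations(
    path: str | Path, row_errors: list[str] | None = None
) -> list[AssociationRecord]:
    """Read a GWAS-catalog-style association TSV.

    Rows with unparseable or non-positive p-values are skipped with a logged
    warning; if ``row_errors`` is given, one message per bad row (with its
    1-based data-row number) is appended to it.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    records: list[AssociationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            p = float(row_d["P-VALUE"])
        except (TypeError, ValueError):
            msg = f"row {i}: unparseable p-value {row_d['P-VALUE']!r}"
            log.warning("%s: %s (row skipped)", path, msg)
            if row_errors is not None:
                row_errors.append(msg)
            continue
        if not p > 0:
            msg = f"row {i}: p-value {p} not in (0, 1]"
            log.warning("%s: %s (row skipped)", path, msg)
            if row_errors is not None:
                row_errors.append(msg)
            continue
        try:
            pos = int(float(row_d["CHR_POS"]))
        except (TypeError, ValueError):
            pos = None
        records.append(
            AssociationRecord(
                snp_id=str(row_d["SNPS"]).strip(),
                chrom=str(row_d["CHR_ID"] if pd.notna(row_d["CHR_ID"]) else "").strip(),
                pos=pos,
                trait_label=str(row_d["DISEASE/TRAIT"]).strip(),
                efo_uri=str(row_d["MAPPED_TRAIT_URI"] if pd.notna(row_d["MAPPED_TRAIT_URI"]) else "").strip(),
                p_value=p,
                mapped_genes=_split_genes(row_d["MAPPED_GENE"]),
                study_id=str(row_d["STUDY ACCESSION"]).strip(),
            )
        )
    return records


def filter_by_traits(
    records: Iterable[AssociationRecord],
    allowed_trait_labels: Sequence[str],
    allowed_efo_uris: Sequence[str] | None = None,
) -> list[AssociationRecord]:
    """Keep records whose trait label equals an allowed label.

    Matching is case-insensitive with whitespace collapsed; an optional EFO
    URI list widens the match (label equality remains the primary key).
    """
    if not allowed_trait_labels:
        raise ValueError("allowed_trait_labels must be non-empty")
    allowed = {norm_label(t) for t in allowed_trait_labels}
    uris = {u.strip() for u in allowed_efo_uris} if allowed_efo_uris else set()
    return [
        r
        for r in records
        if norm_label(r.trait_label) in allowed or (uris and r.efo_uri in uris)
    ]


def select_suggestive_snps(
    records: Iterable[AssociationRecord],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    disorder_label: str = "",
) -> SnpSet:
    """Collapse records to a unique SNP set with p strictly below threshold.

    A SNP enters the set if *any* of its records is below threshold; its best
    (minimum) p is retained and mapped genes are unioned across its retained
    records.
    """
    if not 0 < p_threshold < 1:
        raise ValueError(f"p_threshold must be in (0, 1), got {p_threshold}")
    out = SnpSet(disorder_label=disorder_label)
    for r in records:
        if r.p_value < p_threshold:
            prev = out.best_p.get(r.snp_id)
            if prev is None or r.p_value < prev:
                out.best_p[r.snp_id] = r.p_value
            out.mapped_genes[r.snp_id] = out.mapped_genes.get(
                r.snp_id, frozenset()
            ) | frozenset(r.mapped_genes)
    return out


def snp_set_frame(snp_set: SnpSet) -> pd.DataFrame:
    """Tabular view of a SnpSet (sorted for deterministic output)."""
    rows = [
        {
            "snp_id": snp,
            "best_p": snp_set.best_p[snp],
            "mapped_genes": ",".join(sorted(snp_set.mapped_genes.get(snp, ()))),
        }
        for snp in sorted(snp_set.best_p)
    ]
    return pd.DataFrame(rows, columns=["snp_id", "best_p", "mapped_genes"])
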