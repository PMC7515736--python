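"""Bound and regulated target-gene determination.

A gene's regulatory region runs from 3 kb upstream of the TSS to 1 kb
downstream of the TTS (strand-aware). A gene is bound when any peak
overlaps that region by at least 1 bp. Differential-expression tables are
filtered at |logFC| > 1 and FDR < 0.05 and combined by set union; when two
regulators are involved, an optional directional filter keeps only genes
regulated in the same direction by both. Overlap significance between gene
sets uses the hypergeometric upper tail, computed in log space so that the
astronomically small p-values typical of bound/regulated intersections
survive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "RegulatoryRegion",
    "DEGeneSet",
    "regulatory_regions",
    "bound_genes",
    "de_gene_sets",
    "overlap_significance",
]

UPSTREAM = 3000
DOWNSTREAM = 1000
LOGFC_MIN = 1.0
FDR_MAX = 0.05


@dataclass(frozen=True)
class RegulatoryRegion:
    gene_id: str
    interval: GenomicInterval


@dataclass
class DEGeneSet:
    """Filtered DE genes with their direction and provenance."""

    genes: dict[str, int]  # gene_id -> direction (+1 / -1)
    provenance: dict[str, set[str]] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def ids(self) -> set[str]:
        return set(self.genes)


def regulatory_regions(
    genes: Sequence[GeneModel],
    upstream: int = UPSTREAM,
    downstream: int = DOWNSTREAM,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[RegulatoryRegion]:
    """Strand-aware genic regions: TSS − 3 kb through TTS + 1 kb.

    + strand gene -> [TSS−upstream, TTS+downstream); − strand mirrored.
    Regions are clipped at 0 and at the chromosome end (logged).
    """
    out = []
    for g in genes:
        if g.strand == "+":
            start, end = g.tss - upstream, g.tts + downstream
        else:
            start, end = g.tts - downstream, g.tss + upstream
        if start < 0:
            logger.info("region for %s clipped at chromosome start", g.gene_id)
            start = 0
        if chrom_sizes is not None:
            size = chrom_sizes.get(g.chrom)
            if size is not None and end > size:
                logger.info("region for %s clipped at chromosome end", g.gene_id)
                end = size
        out.append(RegulatoryRegion(g.gene_id, GenomicInterval(g.chrom, start, end)))
    return out


def bound_genes(
    peaks: Sequence[GenomicInterval],
    regions: Sequence[RegulatoryRegion],
) -> set[str]:
    """Genes whose regulatory region is overlapped by >= 1 bp of any peak.

    A peak overlapping two genes' regions counts for both.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for lst in by_chrom.values():
        lst.sort()
    bound: set[str] = set()
    for r in regions:
        lst = by_chrom.get(r.interval.chrom)
        if not lst:
            continue
        for a, b in lst:
            if a >= r.interval.end:
                break
            if b > r.interval.start:
                bound.add(r.gene_id)
                break
    return bound


def filter_de_table(
    table: pd.DataFrame,
    logfc_min: float = LOGFC_MIN,
    fdr_max: float = FDR_MAX,
) -> pd.DataFrame:
    """Apply the DE thresholds: |logFC| > logfc_min and FDR < fdr_max."""
    required = {"gene_id", "logFC", "FDR"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table lacks columns {sorted(missing)}")
    kept = table[(table["logFC"].abs() > logfc_min) & (table["FDR"] < fdr_max)]
    logger.info("DE filter: %d of %d genes kept", len(kept), len(table))
    return kept


def de_gene_sets(
    tables: Sequence[tuple[str, pd.DataFrame]],
    direction_filter: str = "off",
    logfc_min: float = LOGFC_MIN,
    fdr_max: float = FDR_MAX,
) -> DEGeneSet:
    """Filter each (label, table) and combine by union.

    Tables sharing a label belong to one regulator (list concatenation =
    union after per-list filtering). With direction_filter="same_direction"
    a gene seen under two different regulator labels is kept only when the
    directions agree. Conflicting directions within one regulator keep the
    gene but flag it ambiguous (logged).
    """
    if direction_filter not in ("off", "same_direction"):
        raise ValueError("direction_filter must be 'off' or 'same_direction'")
    per_regulator: dict[str, dict[str, int]] = {}
    ambiguous: set[str] = set()
    for label, table in tables:
        kept = filter_de_table(table, logfc_min, fdr_max)
        reg = per_regulator.setdefault(label, {})
        for gid, lfc in zip(kept["gene_id"], kept["logFC"]):
            direction = 1 if lfc > 0 else -1
            if gid in reg and reg[gid] != direction:
                ambiguous.add(gid)
                logger.warning(
                    "gene %s has conflicting DE directions within %r; kept, "
                    "flagged ambiguous", gid, label,
                )
            reg[gid] = direction
    genes: dict[str, int] = {}
    provenance: dict[str, set[str]] = {}
    drop: set[str] = set()
    for label, reg in per_regulator.items():
        for gid, direction in reg.items():
            if gid in genes and genes[gid] != direction:
                if direction_filter == "same_direction" and gid not in ambiguous:
                    drop.add(gid)
            genes.setdefault(gid, direction)
            provenance.setdefault(gid, set()).add(label)
    if direction_filter == "same_direction":
        for gid in drop:
            del genes[gid]
            logger.info("gene %s dropped: opposite directions across regulators", gid)
    return DEGeneSet(genes=genes, provenance=provenance, ambiguous=ambiguous)


def overlap_significance(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe_size: int,
) -> tuple[int, float, float]:
    """(overlap count, hypergeometric upper-tail p, −log10 p).

    p = P(X >= overlap) with X ~ Hypergeom(universe, |A|, |B|), computed in
    log space so that vanishing p-values keep a meaningful −log10.
    """
    a, b = set(set_a), set(set_b)
    if universe_size < len(a | b):
        raise ValueError(
            f"universe ({universe_size}) smaller than |A ∪ B| ({len(a | b)})"
        )
    k = len(a & b)
    dist = stats.hypergeom(universe_size, len(a), len(b))
    if k == 0:
        return 0, 1.0, 0.0
    logsf = dist.logsf(k - 1)
    p = float(np.exp(logsf))
    neg_log10_p = float(-logsf / math.log(10.0))
    return k, p, neg_log10_p


def read_de_table(path) -> pd.DataFrame:
    """Read a DE TSV with columns gene_id, logFC, FDR."""
    return pd.read_csv(path, sep="\t")


def write_gene_set(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def venn_counts(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Counts per region of a 2- or 3-set Venn partition, as a table."""
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("venn_counts supports 2 or 3 sets")
    rows = []
    from itertools import product

    for mask in product([True, False], repeat=len(names)):
        if not any(mask):
            continue
        inc = [sets[n] for n, m in zip(names, mask) if m]
        exc = [sets[n] for n, m in zip(names, mask) if not m]
        region = set.intersection(*inc) - (set.union(*exc) if exc else set())
        rows.append(
            {"region": "&".join(n for n, m in zip(names, mask) if m),
             "count": len(region)}
        )
    return pd.DataFrame(rows)
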