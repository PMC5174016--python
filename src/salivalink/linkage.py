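"""Genome-function linkage and dominance statistics.

Links every annotated gene to its originating genome, yielding a
genome x function count matrix per hierarchy level alongside per-genome
mapped-read abundances.  From this "linkage database" the module
derives the dominance structure of a community: the top-k genomes by
read abundance, the top-k functional categories by gene-sequence hits,
each genome's functional diversity (fraction of observed categories it
encodes), the contribution of dominant genomes to each category, the
rank correlation between genome abundance and functional diversity, and
how many genomes each category originates from (functional redundancy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .profiles import GeneRecord, N_LEVELS, _check_level

__all__ = [
    "LinkageDatabase",
    "build_linkage_db",
    "dominant_genomes",
    "dominant_functions",
    "genome_function_diversity",
    "dominant_contribution",
    "diversity_abundance_trend",
    "originating_genome_breadth",
]


@dataclass
class LinkageDatabase:
    """Genome x function gene-count matrices plus genome read abundances.

    ``matrices[level]`` is a genomes-by-categories DataFrame of
    gene-sequence hit counts at that hierarchy level.  ``abundances``
    are mapped-read counts normalised over all mapped reads.  Genes that
    could not be assigned an originating genome are excluded from the
    matrices and reported as ``unassigned_fraction`` of hit counts.
    """

    genomes: list[str]
    read_counts: pd.Series
    abundances: pd.Series
    matrices: dict[int, pd.DataFrame] = field(default_factory=dict)
    unassigned_fraction: float = 0.0

    def matrix(self, level: int) -> pd.DataFrame:
        _check_level(level)
        return self.matrices[level]


def build_linkage_db(
    records: Sequence[GeneRecord], genome_read_counts: Mapping[str, int]
) -> LinkageDatabase:
    """Aggregate genome-assigned gene records into the linkage database."""
    if any(n < 0 for n in genome_read_counts.values()):
        raise ValueError("negative genome read counts")
    genomes = sorted(genome_read_counts)
    for r in records:
        if r.genome_id is not None and r.genome_id not in genome_read_counts:
            raise ValueError(f"gene {r.gene_id}: genome {r.genome_id!r} has no read count")

    counts = pd.Series(genome_read_counts, dtype=float).reindex(genomes)
    total_reads = counts.sum()
    abundances = counts / total_reads if total_reads > 0 else counts * 0.0

    assigned = [r for r in records if r.genome_id is not None and not r.is_unknown]
    total_hits = sum(r.count for r in records)
    unassigned = total_hits - sum(r.count for r in assigned)
    unassigned_fraction = unassigned / total_hits if total_hits else 0.0

    matrices: dict[int, pd.DataFrame] = {}
    for level in range(1, N_LEVELS + 1):
        cells: dict[tuple[str, str], int] = {}
        for r in assigned:
            key = (r.genome_id, r.path[level - 1])
            cells[key] = cells.get(key, 0) + r.count
        cats = sorted({c for _, c in cells})
        M = pd.DataFrame(0, index=genomes, columns=cats, dtype=int)
        for (g, c), n in cells.items():
            M.at[g, c] = n
        matrices[level] = M
    return LinkageDatabase(genomes, counts.astype(int), abundances, matrices, unassigned_fraction)


def dominant_genomes(db: LinkageDatabase, k: int = 5) -> list[str]:
    """Top-k genomes by mapped-read abundance; ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(db.genomes, key=lambda g: (-db.abundances[g], g))
    return order[: min(k, len(order))]


def dominant_functions(db: LinkageDatabase, level: int, k: int = 5) -> list[str]:
    """Top-k categories by total gene-sequence hits at a level."""
    if k < 1:
        raise ValueError("k must be >= 1")
    totals = db.matrix(level).sum(axis=0)
    order = sorted(totals.index, key=lambda c: (-totals[c], c))
    return order[: min(k, len(order))]


def genome_function_diversity(db: LinkageDatabase, level: int) -> pd.Series:
    """Fraction of the microbiota's observed categories each genome encodes."""
    M = db.matrix(level)
    observed = (M.sum(axis=0) > 0).sum()
    if M.empty or observed == 0:
        raise ValueError("empty linkage database: no observed functions")
    return (M > 0).sum(axis=1) / observed


@dataclass(frozen=True)
class ContributionReport:
    per_category: pd.Series  # fraction of each category's hits from dominant genomes
    minimum: float
    maximum: float
    omitted: tuple[str, ...]  # zero-total categories


def dominant_contribution(db: LinkageDatabase, level: int, k: int = 5) -> ContributionReport:
    """Fraction of each category's gene sequences contributed by the top-k genomes."""
    M = db.matrix(level)
    dom = dominant_genomes(db, k)
    totals = M.sum(axis=0)
    omitted = tuple(totals.index[totals == 0])
    keep = totals.index[totals > 0]
    frac = M.loc[dom, keep].sum(axis=0) / totals[keep]
    if frac.empty:
        raise ValueError("no non-empty categories at this level")
    return ContributionReport(frac, float(frac.min()), float(frac.max()), omitted)


def _rank_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average-rank ties; 0 for a constant margin."""
    rx, ry = rankdata(x), rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def diversity_abundance_trend(db: LinkageDatabase, level: int) -> float:
    """Rank correlation between genome read abundance and functional diversity."""
    if len(db.genomes) < 3:
        raise ValueError("trend requires at least 3 genomes")
    div = genome_function_diversity(db, level)
    ab = db.abundances.reindex(div.index)
    return _rank_correlation(ab.to_numpy(), div.to_numpy())


@dataclass(frozen=True)
class BreadthReport:
    per_category: pd.Series  # number of genomes contributing to each category
    abundance_breadth_correlation: float


def originating_genome_breadth(db: LinkageDatabase, level: int) -> BreadthReport:
    """How many genomes each category originates from, and whether
    higher-count categories are spread over more genomes."""
    M = db.matrix(level)
    breadth = (M > 0).sum(axis=0)
    totals = M.sum(axis=0)
    corr = _rank_correlation(totals.to_numpy(), breadth.to_numpy())
    return BreadthReport(breadth, corr)
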