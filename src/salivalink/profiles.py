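"""Hierarchical functional profiling of metagenome gene catalogs.

Genes annotated against a SEED-style four-level subsystem hierarchy
(hierarchy 1, hierarchy 2, hierarchy 3, function) are aggregated into
per-sample abundance profiles at any level.  On top of the profiles the
module computes the functional core and pan sets across samples,
pairwise enrichment/depletion signatures, pathway-level unique-protein
comparisons, PCA ordination and hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as scipy_hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

__all__ = [
    "FunctionHierarchy",
    "GeneRecord",
    "SampleFunctionProfile",
    "EnrichmentResult",
    "PathwayUniqueResult",
    "OrdinationResult",
    "ClusterResult",
    "build_profile",
    "hierarchy_from_records",
    "pool_records",
    "core_functions",
    "enrichment_signature",
    "pathway_unique_proteins",
    "ordinate_profiles",
    "cluster_profiles",
]

N_LEVELS = 4


@dataclass(frozen=True)
class FunctionHierarchy:
    """A four-level functional classification tree.

    ``levels[k]`` holds the node names of level ``k+1`` (k = 0..3); every
    level-4 node ("function") has exactly one ancestor at each higher
    level, recorded in ``paths``.
    """

    levels: tuple[tuple[str, ...], ...]
    parent: Mapping[str, str]  # child name -> parent name, for levels 2..4
    paths: Mapping[str, tuple[str, str, str, str]]  # function -> (h1,h2,h3,f)

    def __post_init__(self) -> None:
        if len(self.levels) != N_LEVELS:
            raise ValueError("hierarchy must have exactly 4 levels")

    @property
    def functions(self) -> tuple[str, ...]:
        return self.levels[3]

    def level_sizes(self) -> tuple[int, ...]:
        return tuple(len(lv) for lv in self.levels)

    def ancestor(self, function: str, level: int) -> str:
        """Ancestor of a level-4 function at ``level`` (1..4)."""
        _check_level(level)
        return self.paths[function][level - 1]

    def level_of(self, name: str) -> int:
        for k, names in enumerate(self.levels, start=1):
            if name in names:
                return k
        raise KeyError(f"unknown category: {name!r}")

    def descendant_functions(self, category: str) -> set[str]:
        """All level-4 functions below ``category`` (any level)."""
        level = self.level_of(category)
        return {f for f, path in self.paths.items() if path[level - 1] == category}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: its sample, function path, origin and hit count.

    ``path`` is the full (h1, h2, h3, function) assignment, or ``None``
    for genes whose function is unknown.  ``genome_id`` is the
    originating genome when one could be assigned.
    """

    gene_id: str
    sample_id: str
    path: tuple[str, str, str, str] | None
    genome_id: str | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"gene {self.gene_id}: count must be >= 1")
        if self.path is not None and len(self.path) != N_LEVELS:
            raise ValueError(f"gene {self.gene_id}: path must have 4 levels")

    @property
    def is_unknown(self) -> bool:
        return self.path is None


@dataclass(frozen=True)
class SampleFunctionProfile:
    """Per-sample functional abundance table at one hierarchy level.

    ``unknown_fraction`` is the fraction of gene-sequence counts carried
    by unknown-function genes; it is ``None`` when the sample has no
    records at all.  Relative abundances are over known-function
    categories only and sum to 1.
    """

    sample_id: str
    level: int
    counts: Mapping[str, int]
    relative_abundance: Mapping[str, float]
    unknown_fraction: float | None

    @property
    def categories(self) -> set[str]:
        return set(self.counts)

    def total_count(self) -> int:
        return sum(self.counts.values())


def _check_level(level: int) -> None:
    if not 1 <= level <= N_LEVELS:
        raise ValueError(f"level must be in 1..4, got {level}")


def hierarchy_from_records(records: Iterable[GeneRecord]) -> FunctionHierarchy:
    """Reconstruct the (observed part of the) hierarchy from gene records."""
    paths = {r.path[3]: r.path for r in records if r.path is not None}
    levels = tuple(
        tuple(sorted({p[k] for p in paths.values()})) for k in range(N_LEVELS)
    )
    parent: dict[str, str] = {}
    for p in paths.values():
        for k in range(1, N_LEVELS):
            parent[p[k]] = p[k - 1]
    return FunctionHierarchy(levels, parent, paths)


def build_profile(records: Sequence[GeneRecord], level: int) -> SampleFunctionProfile:
    """Aggregate gene records of one sample into a level profile.

    Counts sum each record's hit count into the record's ancestor
    category at ``level``.  Unknown-function records are excluded from
    counts and relative abundances but reported as ``unknown_fraction``.
    """
    _check_level(level)
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise ValueError(f"records mix sample ids: {sorted(sample_ids)}")
    sample_id = sample_ids.pop() if sample_ids else ""

    counts: dict[str, int] = {}
    known_total = 0
    unknown_total = 0
    for r in records:
        if r.is_unknown:
            unknown_total += r.count
            continue
        cat = r.path[level - 1]
        counts[cat] = counts.get(cat, 0) + r.count
        known_total += r.count

    grand_total = known_total + unknown_total
    rel = {c: n / known_total for c, n in counts.items()} if known_total else {}
    unknown_fraction = (unknown_total / grand_total) if grand_total else None
    return SampleFunctionProfile(sample_id, level, counts, rel, unknown_fraction)


def pool_records(records: Iterable[GeneRecord], pooled_id: str) -> list[GeneRecord]:
    """Relabel records from several samples as one pooled pseudo-sample."""
    return [
        GeneRecord(r.gene_id, pooled_id, r.path, r.genome_id, r.count) for r in records
    ]


@dataclass(frozen=True)
class CorePanResult:
    core: set[str]
    pan: set[str]
    core_gene_sequence_count: int
    pan_gene_sequence_count: int


def core_functions(profiles: Sequence[SampleFunctionProfile]) -> CorePanResult:
    """Core (shared by every sample) and pan (union) function sets.

    Operates on level-4 profiles.  The gene-sequence counts are the
    across-sample sums of hit counts of genes annotated to core (resp.
    any) functions.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if any(p.level != N_LEVELS for p in profiles):
        raise ValueError("core/pan analysis requires level-4 (function) profiles")
    sets = [p.categories for p in profiles]
    core = set.intersection(*sets)
    pan = set.union(*sets)
    core_count = sum(n for p in profiles for f, n in p.counts.items() if f in core)
    pan_count = sum(p.total_count() for p in profiles)
    return CorePanResult(core, pan, core_count, pan_count)


@dataclass(frozen=True)
class EnrichmentResult:
    """Signed percent enrichment of sample a relative to sample b.

    ``enrichment[c] = 100 * (RA_a(c) - RA_b(c)) / RA_b(c)``.  Categories
    observed in a but absent from b cannot be given a finite percent and
    are listed in ``exclusive_to_a`` instead.
    """

    enrichment: Mapping[str, float]
    exclusive_to_a: frozenset[str]


def enrichment_signature(
    profile_a: SampleFunctionProfile,
    profile_b: SampleFunctionProfile,
    min_abundance: float = 0.0,
) -> EnrichmentResult:
    """Per-category relative enrichment (+) / depletion (−) of a vs b.

    Categories whose relative abundance is below ``min_abundance`` in
    both samples are omitted.
    """
    if profile_a.level != profile_b.level:
        raise ValueError(
            f"level mismatch: {profile_a.level} vs {profile_b.level}"
        )
    ra, rb = profile_a.relative_abundance, profile_b.relative_abundance
    enrichment: dict[str, float] = {}
    exclusive: set[str] = set()
    for cat in set(ra) | set(rb):
        a, b = ra.get(cat, 0.0), rb.get(cat, 0.0)
        if a < min_abundance and b < min_abundance:
            continue
        if b == 0.0:
            exclusive.add(cat)
        else:
            enrichment[cat] = 100.0 * (a - b) / b
    return EnrichmentResult(enrichment, frozenset(exclusive))


@dataclass(frozen=True)
class PathwayUniqueResult:
    unique_to_a: int
    unique_to_b: int
    percent_excess: float | None
    status: str  # "ok" | "exclusive_to_a" | "undefined"


def pathway_unique_proteins(
    group_a_records: Sequence[GeneRecord],
    group_b_records: Sequence[GeneRecord],
    pathway: str,
    hierarchy: FunctionHierarchy,
) -> PathwayUniqueResult:
    """Count functions under ``pathway`` unique to each group.

    ``percent_excess = 100 * (unique_to_a - unique_to_b) / unique_to_b``
    when group b has unique functions; when b has none but a does, the
    ratio is undefined and flagged exclusive-to-a.
    """
    members = hierarchy.descendant_functions(pathway)  # raises on unknown pathway

    def observed(records: Sequence[GeneRecord]) -> set[str]:
        return {r.path[3] for r in records if r.path is not None and r.path[3] in members}

    fa, fb = observed(group_a_records), observed(group_b_records)
    ua, ub = len(fa - fb), len(fb - fa)
    if ub > 0:
        return PathwayUniqueResult(ua, ub, 100.0 * (ua - ub) / ub, "ok")
    if ua > 0:
        return PathwayUniqueResult(ua, ub, None, "exclusive_to_a")
    return PathwayUniqueResult(ua, ub, None, "undefined")


def profile_matrix(profiles: Sequence[SampleFunctionProfile]) -> pd.DataFrame:
    """Samples x categories matrix of relative abundances (zero-filled union)."""
    if len({p.level for p in profiles}) > 1:
        raise ValueError("profiles span multiple hierarchy levels")
    cats = sorted(set().union(*(set(p.relative_abundance) for p in profiles)))
    data = [[p.relative_abundance.get(c, 0.0) for c in cats] for p in profiles]
    return pd.DataFrame(data, index=[p.sample_id for p in profiles], columns=cats)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray


def ordinate_profiles(
    profiles: Sequence[SampleFunctionProfile], n_components: int = 2
) -> OrdinationResult:
    """PCA ordination of relative-abundance profiles (centered, unscaled)."""
    if len(profiles) < 2:
        raise ValueError("ordination needs at least 2 profiles")
    mat = profile_matrix(profiles)
    max_comp = min(mat.shape)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, categories)={max_comp}"
        )
    X = mat.to_numpy()
    if np.allclose(X, X.mean(axis=0), atol=1e-15):
        # degenerate: all profiles identical -> no variance to decompose
        coords = np.zeros((X.shape[0], n_components))
        evr = np.zeros(n_components)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        coords = pca.fit_transform(X)
        evr = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return OrdinationResult(pd.DataFrame(coords, index=mat.index, columns=cols), evr)


@dataclass(frozen=True)
class ClusterResult:
    labels: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy linkage encoding of the dendrogram

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def cluster_profiles(
    profiles: Sequence[SampleFunctionProfile], linkage_rule: str = "average"
) -> ClusterResult:
    """Hierarchical clustering of samples on Euclidean profile distances."""
    if len(profiles) < 2:
        raise ValueError("clustering needs at least 2 profiles")
    if linkage_rule not in {"single", "complete", "average", "ward"}:
        raise ValueError(f"unknown linkage rule: {linkage_rule!r}")
    mat = profile_matrix(profiles)
    dists = pdist(mat.to_numpy(), metric="euclidean")
    Z = scipy_hierarchy.linkage(dists, method=linkage_rule)
    return ClusterResult(tuple(mat.index), Z)
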