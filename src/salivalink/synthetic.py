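"""Synthetic whole-ecosystem data with known ground truth.

Everything the analysis consumes can be simulated here under explicit
generative models: a 4-level function catalog, a microbial community
with skewed genome abundances and abundance-linked functional
repertoires, paired-read alignment tables with a tunable host-DNA
fraction and a mapping-quality emission model, a toy host gene model
with reference sequence, and paired noisy variant call sets.  Every
generator is deterministic under its seed, and every emitted record is
traceable to a truth label, so recovery of the generative parameters by
the analysis modules can be tested exactly.

MAPQ emission is a two-point mixture: a host pair emits a high MAPQ
(default 150) on both mates with probability 1 - crossmap_rate and
otherwise two uniform MAPQs in [0, 100]; a microbial pair does the
reverse.  Under this model the strict ">threshold on both mates" rule
misclassifies a pair exactly when its crossmap coin comes up, so the
rule's error rate equals crossmap_rate analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .partition import HOST_LABEL, ReadPairAlignment
from .profiles import FunctionHierarchy, GeneRecord, N_LEVELS
from .variants import BASES, GeneModel, Transcript, VariantCall

__all__ = [
    "CommunityConfig",
    "EcosystemConfig",
    "MapqModel",
    "SyntheticTruth",
    "fold_for_relative_abundance_shift",
    "generate_function_catalog",
    "generate_community",
    "resample_catalog",
    "simulate_read_pairs",
    "generate_reference",
    "generate_gene_model",
    "simulate_variant_callsets",
]

_LEVEL_PREFIXES = ("H1", "H2", "H3", "FN")


class InvalidConfigError(ValueError):
    """A generator configuration violates its declared constraints."""


@dataclass
class SyntheticTruth:
    """Ground-truth labels attached to a simulation.

    ``read_origins`` maps read id -> 'host' or originating genome id;
    ``gene_functions``/``gene_genomes`` map gene id -> true assignment;
    ``variants`` holds the true variant records with per-site depth.
    """

    read_origins: dict[str, str] = field(default_factory=dict)
    gene_functions: dict[str, tuple[str, str, str, str] | None] = field(default_factory=dict)
    gene_genomes: dict[str, str] = field(default_factory=dict)
    variants: list[VariantCall] = field(default_factory=list)


def generate_function_catalog(
    level_sizes: Sequence[int], seed: int
) -> FunctionHierarchy:
    """Random 4-level function hierarchy with the given level sizes.

    Each node of level k >= 2 is attached to a uniformly drawn parent at
    level k-1; every level-4 function therefore has exactly one path to
    a level-1 category.
    """
    if len(level_sizes) != N_LEVELS:
        raise InvalidConfigError("level_sizes must have 4 entries")
    if any(int(s) < 1 for s in level_sizes):
        raise InvalidConfigError("every level size must be >= 1")
    rng = np.random.default_rng(seed)
    levels = tuple(
        tuple(f"{_LEVEL_PREFIXES[k]}_{i:04d}" for i in range(int(level_sizes[k])))
        for k in range(N_LEVELS)
    )
    parent: dict[str, str] = {}
    for k in range(1, N_LEVELS):
        idx = rng.integers(0, len(levels[k - 1]), size=len(levels[k]))
        for child, pi in zip(levels[k], idx):
            parent[child] = levels[k - 1][pi]
    paths: dict[str, tuple[str, str, str, str]] = {}
    for f in levels[3]:
        h3 = parent[f]
        h2 = parent[h3]
        h1 = parent[h2]
        paths[f] = (h1, h2, h3, f)
    return FunctionHierarchy(levels, parent, paths)


@dataclass
class CommunityConfig:
    """Generative parameters of a microbial community.

    ``abundance_law`` is one of 'lognormal' (sigma), 'dirichlet'
    (alpha), 'manual' (abundances); the resulting vector is normalised
    to sum to 1 and genomes are labelled G01, G02, ... in decreasing
    abundance.  ``repertoire_rule`` maps the abundance rank (1 = most
    abundant) to a target repertoire size; the realised size is
    floor(rule(rank)) plus Gaussian noise of sd ``repertoire_noise_sd``,
    clipped to [1, n_functions].  ``unknown_fraction`` of genes carry no
    functional assignment, emulating the large unknown-function
    component of real annotation.
    """

    n_genomes: int
    abundance_law: str = "lognormal"
    law_params: dict = field(default_factory=dict)
    repertoire_rule: Callable[[int], float] | None = None
    repertoire_noise_sd: float = 0.0
    unknown_fraction: float = 0.0
    mean_hits: float = 4.0  # mean extra hit count per gene record
    seed: int = 0


def _draw_abundances(cfg: CommunityConfig, rng: np.random.Generator) -> np.ndarray:
    law = cfg.abundance_law
    if law == "lognormal":
        sigma = float(cfg.law_params.get("sigma", 1.0))
        raw = rng.lognormal(mean=0.0, sigma=sigma, size=cfg.n_genomes)
    elif law == "dirichlet":
        alpha = float(cfg.law_params.get("alpha", 1.0))
        raw = rng.dirichlet(np.full(cfg.n_genomes, alpha))
    elif law == "manual":
        raw = np.asarray(cfg.law_params["abundances"], dtype=float)
        if len(raw) != cfg.n_genomes:
            raise InvalidConfigError("manual abundances length != n_genomes")
        if np.any(raw <= 0):
            raise InvalidConfigError("manual abundances must be strictly positive")
    else:
        raise InvalidConfigError(f"unknown abundance law: {law!r}")
    return raw / raw.sum()


def generate_community(
    cfg: CommunityConfig, catalog: FunctionHierarchy, sample_id: str = "S1"
) -> tuple[pd.Series, list[GeneRecord]]:
    """Draw genome abundances and a gene catalog over the function tree.

    Each genome's repertoire is a without-replacement draw of distinct
    functions from the catalog, of size given by the repertoire rule at
    the genome's abundance rank.  Each repertoire member becomes one
    gene record with a Poisson hit count (>= 1).
    """
    if cfg.n_genomes < 1:
        raise InvalidConfigError("n_genomes must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    raw = _draw_abundances(cfg, rng)
    order = np.argsort(-raw, kind="stable")
    abundances = raw[order]
    n_funcs = len(catalog.functions)
    width = max(2, len(str(cfg.n_genomes)))
    genomes = [f"G{i + 1:0{width}d}" for i in range(cfg.n_genomes)]
    series = pd.Series(abundances, index=genomes, name="abundance")

    rule = cfg.repertoire_rule or (lambda rank: 0.5 * n_funcs * rank ** -0.7)
    records: list[GeneRecord] = []
    funcs = np.asarray(catalog.functions)
    for rank, g in enumerate(genomes, start=1):
        size = int(np.floor(rule(rank)))
        if cfg.repertoire_noise_sd > 0:
            size += int(round(rng.normal(0.0, cfg.repertoire_noise_sd)))
        size = int(np.clip(size, 1, n_funcs))
        chosen = rng.choice(funcs, size=size, replace=False)
        for j, f in enumerate(chosen):
            unknown = rng.random() < cfg.unknown_fraction
            path = None if unknown else catalog.paths[str(f)]
            count = 1 + int(rng.poisson(cfg.mean_hits))
            records.append(
                GeneRecord(f"{g}_g{j:05d}", sample_id, path, genome_id=g, count=count)
            )
    return series, records


def resample_catalog(
    records: Sequence[GeneRecord],
    sample_id: str,
    seed: int,
    retain_prob: float = 1.0,
    category_fold: Mapping[str, float] | None = None,
    fold_level: int = 2,
) -> list[GeneRecord]:
    """Per-sample noisy copy of a community gene catalog.

    Each gene is retained with ``retain_prob`` and its hit count is
    redrawn as 1 + Poisson(original - 1).  ``category_fold`` multiplies
    the expected counts of genes whose ancestor at ``fold_level`` is in
    the map — the mechanism used to seed known enrichment shifts
    between sample groups.
    """
    rng = np.random.default_rng(seed)
    out: list[GeneRecord] = []
    folds = category_fold or {}
    for r in records:
        if rng.random() > retain_prob:
            continue
        fold = 1.0
        if r.path is not None and folds:
            fold = folds.get(r.path[fold_level - 1], 1.0)
        count = 1 + int(rng.poisson(max(r.count * fold - 1.0, 0.0)))
        out.append(GeneRecord(r.gene_id, sample_id, r.path, r.genome_id, count))
    return out


def fold_for_relative_abundance_shift(
    records: Sequence[GeneRecord],
    categories: Sequence[str],
    target_ratio: float,
    level: int,
) -> float:
    """Count multiplier that shifts the categories' relative abundance by
    ``target_ratio`` after renormalisation.

    Multiplying counts by r does not multiply relative abundances by r
    because the total grows too; the exact fold is
    ``F = r (T - S) / (T - r S)`` with T the total known-function count
    and S the categories' count.  Requires r S < T.
    """
    cats = set(categories)
    T = sum(r.count for r in records if r.path is not None)
    S = sum(r.count for r in records if r.path is not None and r.path[level - 1] in cats)
    if target_ratio * S >= T:
        raise InvalidConfigError("shifted categories too abundant for the requested ratio")
    return target_ratio * (T - S) / (T - target_ratio * S)


@dataclass
class MapqModel:
    """Two-point MAPQ mixture (see module docstring)."""

    host_mapq: int = 150
    crossmap_rate: float = 0.0
    low_max: int = 100  # inclusive upper bound of the low-MAPQ uniform


@dataclass
class EcosystemConfig:
    """Read-pair simulation parameters.

    ``host_fraction`` defaults mirror the study design: ~0.7 of total
    reads are host-derived in healthy-host (H) saliva and ~0.45 in
    caries-active (C) saliva, i.e. microbial fractions of ~30% and
    ~50-60%.
    """

    host_fraction: float
    n_read_pairs: int
    mapq_model: MapqModel = field(default_factory=MapqModel)
    seed: int = 0

    GROUP_HOST_FRACTION = {"H": 0.7, "C": 0.45}

    @classmethod
    def for_group(cls, group: str, n_read_pairs: int, **kw) -> "EcosystemConfig":
        try:
            hf = cls.GROUP_HOST_FRACTION[group]
        except KeyError:
            raise InvalidConfigError(f"unknown sample group {group!r}") from None
        return cls(host_fraction=hf, n_read_pairs=n_read_pairs, **kw)


def simulate_read_pairs(
    cfg: EcosystemConfig, abundances: pd.Series
) -> tuple[list[ReadPairAlignment], SyntheticTruth]:
    """Simulate paired-read alignment evidence against the host genome.

    Pair origins are multinomial over (host, genomes) with probabilities
    (host_fraction, (1 - host_fraction) * abundances); MAPQs follow the
    two-point mixture of ``cfg.mapq_model``.
    """
    if not 0.0 <= cfg.host_fraction <= 1.0:
        raise InvalidConfigError("host_fraction must be in [0, 1]")
    if cfg.n_read_pairs < 1:
        raise InvalidConfigError("n_read_pairs must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    m = cfg.mapq_model
    labels = np.array([HOST_LABEL] + list(abundances.index), dtype=object)
    probs = np.concatenate([[cfg.host_fraction], (1.0 - cfg.host_fraction) * abundances.to_numpy()])
    probs = probs / probs.sum()
    origin_idx = rng.choice(len(labels), size=cfg.n_read_pairs, p=probs)
    flips = rng.random(cfg.n_read_pairs) < m.crossmap_rate
    low = rng.integers(0, m.low_max + 1, size=(cfg.n_read_pairs, 2))

    pairs: list[ReadPairAlignment] = []
    truth = SyntheticTruth()
    width = len(str(cfg.n_read_pairs))
    for i in range(cfg.n_read_pairs):
        origin = str(labels[origin_idx[i]])
        is_host = origin == HOST_LABEL
        emit_high = is_host != flips[i]
        if emit_high:
            q1 = q2 = m.host_mapq
        else:
            q1, q2 = int(low[i, 0]), int(low[i, 1])
        rid = f"rp{i:0{width}d}"
        pairs.append(
            ReadPairAlignment(rid, q1, q2, target=None if is_host else origin)
        )
        truth.read_origins[rid] = origin
    return pairs, truth


def generate_reference(chrom_lengths: Mapping[str, int], seed: int) -> dict[str, str]:
    """Random nucleotide reference sequences, one per chromosome."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return {
        c: "".join(bases[rng.integers(0, 4, size=length)])
        for c, length in chrom_lengths.items()
    }


def generate_gene_model(
    n_genes: int, chrom_lengths: Mapping[str, int], seed: int
) -> GeneModel:
    """Random non-overlapping multi-exon gene model with framed CDS.

    Transcripts are placed by rejection sampling; each has 1-4 exons
    separated by introns of >= 60 bp, a CDS whose length is a multiple
    of 3, and a random strand.
    """
    if not chrom_lengths:
        raise InvalidConfigError("chrom_lengths must be non-empty")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    transcripts: list[Transcript] = []
    for gi in range(n_genes):
        n_exons = int(rng.integers(1, 5))
        exon_lens = rng.integers(120, 400, size=n_exons)
        intron_lens = rng.integers(60, 600, size=max(n_exons - 1, 0))
        tx_len = int(exon_lens.sum() + intron_lens.sum())
        if tx_len > max(chrom_lengths.values()):
            raise InvalidConfigError("gene longer than every chromosome")
        for attempt in range(200):
            chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
            if tx_len > chrom_lengths[chrom]:
                continue
            start = int(rng.integers(1, chrom_lengths[chrom] - tx_len + 2))
            end = start + tx_len - 1
            if all(end < s or start > e for s, e in placed[chrom]):
                break
        else:
            raise InvalidConfigError("could not place gene without overlap")
        placed[chrom].append((start, end))
        exons: list[tuple[int, int]] = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k]) - 1))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        exonic_total = int(exon_lens.sum())
        utr5 = int(rng.integers(0, min(60, exonic_total // 4) + 1))
        utr3 = int(rng.integers(0, min(60, exonic_total // 4) + 1))
        cds_len = exonic_total - utr5 - utr3
        cds_len -= cds_len % 3
        if cds_len < 6:
            utr5 = utr3 = 0
            cds_len = exonic_total - exonic_total % 3
        cds = _exonic_slice(exons, utr5, cds_len)
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            Transcript(f"tx{gi:04d}", chrom, start, end, strand, tuple(exons), tuple(cds))
        )
    transcripts.sort(key=lambda t: (t.chrom, t.start))
    return GeneModel(transcripts, dict(chrom_lengths))


def _exonic_slice(
    exons: Sequence[tuple[int, int]], offset: int, length: int
) -> list[tuple[int, int]]:
    """Genomic intervals of the exonic positions [offset, offset+length)."""
    out: list[tuple[int, int]] = []
    consumed = 0
    remaining = length
    for s, e in exons:
        exon_len = e - s + 1
        lo = max(offset - consumed, 0)
        if lo < exon_len and remaining > 0:
            take = min(exon_len - lo, remaining)
            out.append((s + lo, s + lo + take - 1))
            remaining -= take
        consumed += exon_len
    return out


def simulate_variant_callsets(
    truth_n: int,
    gene_model: GeneModel,
    depth_dist: Callable[[np.random.Generator, int], np.ndarray] | float,
    fp_rate_a: float,
    fn_rate_a: float,
    fp_rate_b: float,
    fn_rate_b: float,
    seed: int,
    n_candidates: int = 0,
    reference: Mapping[str, str] | None = None,
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall]]:
    """Truth SNVs plus two noisy caller outputs over the same genome.

    Each caller misses a truth variant independently with its fn rate
    and, over a universe of ``n_candidates`` non-truth error sites,
    reports a false positive independently with its fp rate.  Each error
    site carries a position-determined alt allele (a systematic miscall
    shared by both callers), so the expected number of false positives
    surviving the intersection is fp_a * fp_b * n_candidates.
    ``depth_dist`` is either a Poisson mean or a callable (rng, n) ->
    depths.
    """
    for r in (fp_rate_a, fn_rate_a, fp_rate_b, fn_rate_b):
        if not 0.0 <= r < 1.0:
            raise InvalidConfigError("fp/fn rates must be in [0, 1)")
    if truth_n < 0:
        raise InvalidConfigError("truth_n must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = sorted(gene_model.chrom_lengths)
    lengths = np.array([gene_model.chrom_lengths[c] for c in chroms], dtype=np.int64)
    total = int(lengths.sum())
    n_sites = truth_n + n_candidates
    if n_sites > total:
        raise InvalidConfigError("more sites requested than genome positions")
    offsets = rng.choice(total, size=n_sites, replace=False)
    bounds = np.cumsum(lengths)

    def locate(off: int) -> tuple[str, int]:
        ci = int(np.searchsorted(bounds, off, side="right"))
        prev = int(bounds[ci - 1]) if ci else 0
        return chroms[ci], int(off - prev + 1)

    def draw_depth(n: int) -> np.ndarray:
        if callable(depth_dist):
            return np.asarray(depth_dist(rng, n), dtype=int)
        return rng.poisson(float(depth_dist), size=n).astype(int)

    base_arr = sorted(BASES)

    def make_call(off: int, depth: int, caller: str) -> VariantCall:
        chrom, pos = locate(int(off))
        if reference is not None:
            ref = reference[chrom][pos - 1]
        else:
            ref = base_arr[int(off) % 4]
        alts = [b for b in base_arr if b != ref]
        alt = alts[(int(off) * 2654435761) % 3]  # position-determined alt
        return VariantCall(chrom, pos, ref, alt, depth=int(depth), caller=caller)

    truth_offsets = offsets[:truth_n]
    cand_offsets = offsets[truth_n:]
    truth_depths = draw_depth(truth_n)
    truth = [make_call(o, d, "truth") for o, d in zip(truth_offsets, truth_depths)]

    keep_a = rng.random(truth_n) >= fn_rate_a
    keep_b = rng.random(truth_n) >= fn_rate_b
    fp_a = rng.random(n_candidates) < fp_rate_a
    fp_b = rng.random(n_candidates) < fp_rate_b
    cand_depths = draw_depth(n_candidates)

    calls_a = [
        VariantCall(t.chrom, t.pos, t.ref, t.alt, t.depth, "caller_a")
        for t, k in zip(truth, keep_a)
        if k
    ] + [
        make_call(o, d, "caller_a")
        for o, d, k in zip(cand_offsets, cand_depths, fp_a)
        if k
    ]
    calls_b = [
        VariantCall(t.chrom, t.pos, t.ref, t.alt, t.depth, "caller_b")
        for t, k in zip(truth, keep_b)
        if k
    ] + [
        make_call(o, d, "caller_b")
        for o, d, k in zip(cand_offsets, cand_depths, fp_b)
        if k
    ]
    key = lambda v: (v.chrom, v.pos, v.alt)
    return sorted(truth, key=key), sorted(calls_a, key=key), sorted(calls_b, key=key)
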