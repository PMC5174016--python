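"""Consensus host-SNP derivation and genomic annotation.

Two independent caller outputs are intersected allele-exactly to form
the final (consensus) call set, filtered at a minimum read depth, then
classified by genomic region (exonic / splicing / UTR / intronic /
intergenic) and, for exonic SNVs, by coding effect via codon
translation.  Per-chromosome SNP density is summarised with a
chi-square uniformity statistic against a length-proportional
expectation.

Coordinate conventions: all positions here are 1-based inclusive (VCF
convention); BED conversion happens in the I/O layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "VariantCall",
    "ConsensusVariant",
    "Transcript",
    "GeneModel",
    "ConsensusResult",
    "intersect_call_sets",
    "filter_min_depth",
    "classify_region",
    "classify_coding_effect",
    "region_distribution",
    "chromosome_density",
    "genes_with_snps",
]

BASES = frozenset("ACGT")
REGION_CLASSES = ("exonic", "splicing", "UTR", "intronic", "intergenic")
SPLICE_WINDOW = 2  # intronic bases adjacent to an exon boundary


@dataclass(frozen=True)
class VariantCall:
    """One caller's SNV record (single-base ref and alt)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    caller: str = ""

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"{self.chrom}:{self.pos}: alleles must be A/C/G/T SNVs")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt")
        if self.depth < 0:
            raise ValueError(f"{self.chrom}:{self.pos}: negative depth")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ConsensusVariant:
    """A variant reported identically by both callers.

    ``depth`` is the minimum of the two callers' depths (conservative).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    region: str | None = None
    coding_effect: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Transcript:
    """A gene model entry: exons plus CDS intervals, 1-based inclusive."""

    tx_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]  # sorted by genomic start
    cds: tuple[tuple[int, int], ...]  # sorted by genomic start; may be empty

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.tx_id}: strand must be + or -")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"{self.tx_id}: exon outside transcript bounds")
        if self.cds and self.cds_length() % 3 != 0:
            raise ValueError(f"{self.tx_id}: CDS length not divisible by 3")

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_phases(self) -> tuple[int, ...]:
        """GFF3 phase of each CDS interval, in genomic order."""
        order = self.cds if self.strand == "+" else tuple(reversed(self.cds))
        phases, consumed = [], 0
        for s, e in order:
            phases.append((3 - consumed % 3) % 3)
            consumed += e - s + 1
        return tuple(phases if self.strand == "+" else reversed(phases))


@dataclass
class GeneModel:
    """Transcript annotation over a set of chromosomes."""

    transcripts: list[Transcript] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def by_chrom(self, chrom: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.chrom == chrom]


@dataclass(frozen=True)
class ConsensusResult:
    variants: tuple[ConsensusVariant, ...]
    ref_mismatches: int  # same (chrom,pos) with disagreeing ref alleles, excluded


def _index_calls(calls: Sequence[VariantCall], tag: str) -> dict:
    index: dict[tuple[str, int, str, str], VariantCall] = {}
    for c in calls:
        if c.key in index:
            raise ValueError(f"callset {tag}: duplicate call at {c.chrom}:{c.pos} {c.ref}>{c.alt}")
        index[c.key] = c
    return index


def intersect_call_sets(
    calls_a: Sequence[VariantCall], calls_b: Sequence[VariantCall]
) -> ConsensusResult:
    """Allele-exact intersection of two call sets.

    A consensus variant requires identical (chrom, pos, ref, alt) in
    both sets; its depth is the minimum of the two callers' depths.
    Positions where the callers disagree on the reference allele are
    excluded with a warning and counted in ``ref_mismatches``.
    """
    ia = _index_calls(calls_a, "a")
    ib = _index_calls(calls_b, "b")
    refs_b = {(c.chrom, c.pos): c.ref for c in calls_b}
    mismatches = sum(
        1 for c in calls_a if (c.chrom, c.pos) in refs_b and refs_b[(c.chrom, c.pos)] != c.ref
    )
    if mismatches:
        warnings.warn(
            f"{mismatches} position(s) with reference-allele disagreement excluded from consensus",
            stacklevel=2,
        )
    shared = sorted(set(ia) & set(ib), key=lambda k: (k[0], k[1], k[3]))
    variants = tuple(
        ConsensusVariant(*k, depth=min(ia[k].depth, ib[k].depth)) for k in shared
    )
    return ConsensusResult(variants, mismatches)


def filter_min_depth(
    calls: Sequence[ConsensusVariant], min_depth: int = 30
) -> list[ConsensusVariant]:
    """Keep variants with depth >= min_depth (a minimal depth of 30 retains 30)."""
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    for c in calls:
        if c.depth < 0:
            raise ValueError(f"negative depth at {c.chrom}:{c.pos}")
    return [c for c in calls if c.depth >= min_depth]


def _in_any(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def classify_region(v: ConsensusVariant, model: GeneModel) -> str:
    """Assign exactly one region class to a variant.

    Precedence when transcripts overlap: exonic > splicing > UTR >
    intronic > intergenic.  "Exonic" means inside a CDS interval; exon
    sequence outside the CDS is UTR; splicing is the 2 intronic bases
    flanking each internal exon boundary.
    """
    if v.chrom not in model.chrom_lengths:
        raise ValueError(f"unknown chromosome {v.chrom!r}")
    if not 1 <= v.pos <= model.chrom_lengths[v.chrom]:
        raise ValueError(f"{v.chrom}:{v.pos} outside chromosome length")
    best = "intergenic"
    rank = {c: i for i, c in enumerate(REGION_CLASSES)}
    for t in model.by_chrom(v.chrom):
        if not t.start <= v.pos <= t.end:
            continue
        if _in_any(v.pos, t.cds):
            cls = "exonic"
        elif _in_any(v.pos, t.exons):
            cls = "UTR"
        else:
            near_boundary = any(
                0 < v.pos - e <= SPLICE_WINDOW or 0 < s - v.pos <= SPLICE_WINDOW
                for s, e in t.exons
            )
            cls = "splicing" if near_boundary else "intronic"
        if rank[cls] < rank[best]:
            best = cls
    return best


def _cds_sequence(t: Transcript, reference: Mapping[str, str]) -> str:
    """Spliced CDS in translation order (revcomp for minus strand)."""
    seq = "".join(reference[t.chrom][s - 1 : e] for s, e in t.cds)
    return str(Seq(seq).reverse_complement()) if t.strand == "-" else seq


def _cds_offset(t: Transcript, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS."""
    off = 0
    forward = None
    for s, e in t.cds:
        if s <= pos <= e:
            forward = off + (pos - s)
            break
        off += e - s + 1
    if forward is None:
        return None
    return forward if t.strand == "+" else t.cds_length() - 1 - forward


def classify_coding_effect(
    v: ConsensusVariant, model: GeneModel, reference: Mapping[str, str]
) -> str:
    """Coding effect of an exonic SNV by codon translation.

    Translates the reference and alternate codon under the standard
    genetic code; minus-strand transcripts use reverse-complemented
    alleles.  Returns one of synonymous / nonsynonymous / stopgain /
    stoploss.
    """
    host = next(
        (t for t in model.by_chrom(v.chrom) if _in_any(v.pos, t.cds)), None
    )
    if host is None:
        raise ValueError(f"{v.chrom}:{v.pos} is not exonic; no CDS covers it")
    offset = _cds_offset(host, v.pos)
    cds_seq = _cds_sequence(host, reference)
    ref_allele, alt_allele = v.ref, v.alt
    if host.strand == "-":
        ref_allele = str(Seq(ref_allele).reverse_complement())
        alt_allele = str(Seq(alt_allele).reverse_complement())
    if cds_seq[offset] != ref_allele:
        raise ValueError(
            f"{v.chrom}:{v.pos}: reference allele {v.ref} does not match CDS sequence"
        )
    ci = 3 * (offset // 3)
    ref_codon = cds_seq[ci : ci + 3]
    alt_codon = ref_codon[: offset - ci] + alt_allele + ref_codon[offset - ci + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous"
    if alt_aa == "*":
        return "stopgain"
    if ref_aa == "*":
        return "stoploss"
    return "nonsynonymous"


def region_distribution(
    calls: Sequence[ConsensusVariant], model: GeneModel
) -> dict[str, float] | None:
    """Fraction of variants per region class; None for an empty call list."""
    if not calls:
        return None
    counts = dict.fromkeys(REGION_CLASSES, 0)
    for v in calls:
        counts[classify_region(v, model)] += 1
    n = len(calls)
    return {c: k / n for c, k in counts.items()}


@dataclass(frozen=True)
class DensityReport:
    density_per_mb: Mapping[str, float]
    chi_square: float | None  # None when df = 0
    degrees_of_freedom: int


def chromosome_density(
    calls: Sequence[ConsensusVariant], chrom_lengths: Mapping[str, int]
) -> DensityReport:
    """Per-chromosome SNP density and a uniformity chi-square.

    The statistic compares observed per-chromosome counts with a
    length-proportional expectation; df = #chromosomes - 1.
    """
    if any(l <= 0 for l in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    counts = dict.fromkeys(chrom_lengths, 0)
    for v in calls:
        if v.chrom not in counts:
            raise ValueError(f"variant on unknown chromosome {v.chrom!r}")
        counts[v.chrom] += 1
    density = {c: counts[c] / (chrom_lengths[c] / 1e6) for c in chrom_lengths}
    df = len(chrom_lengths) - 1
    n = sum(counts.values())
    if df == 0 or n == 0:
        return DensityReport(density, None, df)
    total_len = sum(chrom_lengths.values())
    chi2 = sum(
        (counts[c] - n * chrom_lengths[c] / total_len) ** 2
        / (n * chrom_lengths[c] / total_len)
        for c in chrom_lengths
    )
    return DensityReport(density, float(chi2), df)


def genes_with_snps(calls: Sequence[ConsensusVariant], model: GeneModel) -> int:
    """Number of transcripts containing at least one consensus SNP."""
    hit: set[str] = set()
    for t in model.transcripts:
        for v in calls:
            if v.chrom == t.chrom and t.start <= v.pos <= t.end:
                hit.add(t.tx_id)
                break
    return len(hit)
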