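"""Readers and writers for the pipeline's standard formats.

Alignment evidence travels as SAM (paired records matched by QNAME,
written/read with pysam) or as a 5-column TSV; gene catalogs and genome
read counts as TSV; gene models as GFF3 (read with gffutils) and BED12;
variants as VCF 4.2 (pysam); references as FASTA (Biopython); sample
dendrograms as Newick (scikit-bio); run configuration as a flat
key=value file.

Coordinate conventions are centralised here: VCF and GFF3 are 1-based
inclusive (the in-memory convention), BED12 is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio.tree import TreeNode

from .partition import ReadPairAlignment
from .profiles import ClusterResult, GeneRecord
from .variants import ConsensusVariant, GeneModel, Transcript, VariantCall

__all__ = [
    "write_alignment_tsv",
    "read_alignment_tsv",
    "write_sam",
    "read_sam",
    "write_gene_catalog",
    "read_gene_catalog",
    "write_genome_read_counts",
    "read_genome_read_counts",
    "write_gff3",
    "read_gff3",
    "write_bed12",
    "read_bed12",
    "write_vcf",
    "read_vcf",
    "write_consensus_vcf",
    "write_fasta",
    "read_fasta",
    "write_newick",
    "write_config",
    "read_config",
]

_MISSING = "-"


# --------------------------------------------------------------------------
# alignment tables

def write_alignment_tsv(
    path: str | Path,
    pairs: Sequence[ReadPairAlignment],
    truth: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmapq1\tmapq2\ttarget\ttruth_label\n")
        for p in pairs:
            label = truth.get(p.read_id, _MISSING) if truth else _MISSING
            fh.write(
                f"{p.read_id}\t{p.mapq1}\t{p.mapq2}\t{p.target or _MISSING}\t{label}\n"
            )


def read_alignment_tsv(
    path: str | Path,
) -> tuple[list[ReadPairAlignment], dict[str, str]]:
    """Returns (pairs, truth) where truth is empty if no labels present."""
    pairs: list[ReadPairAlignment] = []
    truth: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["read_id", "mapq1", "mapq2"]:
            raise ValueError(f"{path}: not an alignment TSV (header {header!r})")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            target = None if f[3] == _MISSING else f[3]
            pairs.append(ReadPairAlignment(f[0], int(f[1]), int(f[2]), target))
            if len(f) > 4 and f[4] != _MISSING:
                truth[f[0]] = f[4]
    return pairs, truth


def write_sam(path: str | Path, pairs: Sequence[ReadPairAlignment]) -> None:
    """Paired SAM records; the reference name encodes the mapping target."""
    targets = sorted({p.target for p in pairs if p.target is not None})
    refs = ["host"] + targets
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r, "LN": 1000000} for r in refs],
    }
    tid = {r: i for i, r in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in pairs:
            for mate, mapq in ((1, p.mapq1), (2, p.mapq2)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = p.read_id
                a.flag = 0x1 | (0x40 if mate == 1 else 0x80)
                a.reference_id = tid[p.target or "host"]
                a.reference_start = 0
                a.mapping_quality = mapq
                a.cigarstring = "100M"  # mapped records need a CIGAR; no bases stored
                out.write(a)


def read_sam(path: str | Path) -> list[ReadPairAlignment]:
    """Match paired records by QNAME; an unmapped mate contributes MAPQ 0."""
    mates: dict[str, dict] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            entry = mates.setdefault(rec.query_name, {"q1": 0, "q2": 0, "target": None})
            mapq = 0 if rec.is_unmapped else rec.mapping_quality
            if rec.is_read2:
                entry["q2"] = mapq
            else:
                entry["q1"] = mapq
            if not rec.is_unmapped and rec.reference_name != "host":
                entry["target"] = rec.reference_name
    return [
        ReadPairAlignment(rid, e["q1"], e["q2"], e["target"])
        for rid, e in mates.items()
    ]


# --------------------------------------------------------------------------
# gene catalogs

_CATALOG_COLS = ["gene_id", "sample_id", "genome_id", "h1", "h2", "h3", "function", "count"]


def write_gene_catalog(path: str | Path, records: Sequence[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CATALOG_COLS) + "\n")
        for r in records:
            path4 = r.path or (_MISSING,) * 4
            fh.write(
                "\t".join(
                    [r.gene_id, r.sample_id, r.genome_id or _MISSING, *path4, str(r.count)]
                )
                + "\n"
            )


def read_gene_catalog(path: str | Path) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CATALOG_COLS:
            raise ValueError(f"{path}: not a gene catalog TSV (header {header!r})")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_CATALOG_COLS):
                raise ValueError(f"{path}:{lineno}: expected {len(_CATALOG_COLS)} columns")
            fpath = None if f[3] == _MISSING else (f[3], f[4], f[5], f[6])
            genome = None if f[2] == _MISSING else f[2]
            records.append(GeneRecord(f[0], f[1], fpath, genome, int(f[7])))
    return records


def write_genome_read_counts(path: str | Path, counts: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tmapped_reads\n")
        for g in sorted(counts):
            fh.write(f"{g}\t{counts[g]}\n")


def read_genome_read_counts(path: str | Path) -> dict[str, int]:
    counts: dict[str, int] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            g, n = line.rstrip("\n").split("\t")
            counts[g] = int(n)
    return counts


# --------------------------------------------------------------------------
# gene models

def write_gff3(path: str | Path, model: GeneModel) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in sorted(model.chrom_lengths):
            fh.write(f"##sequence-region {c} 1 {model.chrom_lengths[c]}\n")
        for t in model.transcripts:
            base = f"{t.chrom}\tsalivalink\t"
            fh.write(
                base + f"mRNA\t{t.start}\t{t.end}\t.\t{t.strand}\t.\tID={t.tx_id}\n"
            )
            for i, (s, e) in enumerate(t.exons):
                fh.write(
                    base
                    + f"exon\t{s}\t{e}\t.\t{t.strand}\t.\tID={t.tx_id}.exon{i};Parent={t.tx_id}\n"
                )
            phases = t.cds_phases()
            for i, (s, e) in enumerate(t.cds):
                fh.write(
                    base
                    + f"CDS\t{s}\t{e}\t.\t{t.strand}\t{phases[i]}\tID={t.tx_id}.cds{i};Parent={t.tx_id}\n"
                )


def read_gff3(path: str | Path, chrom_lengths: Mapping[str, int] | None = None) -> GeneModel:
    text = Path(path).read_text()
    lengths: dict[str, int] = dict(chrom_lengths or {})
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            _, chrom, _, end = line.split()
            lengths.setdefault(chrom, int(end))
    db = gffutils.create_db(text, ":memory:", from_string=True, merge_strategy="create_unique")
    transcripts: list[Transcript] = []
    for mrna in db.features_of_type("mRNA"):
        exons = tuple(
            sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
        )
        cds = tuple(
            sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        )
        transcripts.append(
            Transcript(mrna.id, mrna.seqid, mrna.start, mrna.end, mrna.strand, exons, cds)
        )
    transcripts.sort(key=lambda t: (t.chrom, t.start))
    return GeneModel(transcripts, lengths)


def write_bed12(path: str | Path, model: GeneModel) -> None:
    with open(path, "w") as fh:
        for t in model.transcripts:
            thick_start = (t.cds[0][0] - 1) if t.cds else (t.start - 1)
            thick_end = t.cds[-1][1] if t.cds else t.start - 1
            sizes = ",".join(str(e - s + 1) for s, e in t.exons)
            starts = ",".join(str(s - t.start) for s, _ in t.exons)
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start - 1),
                        str(t.end),
                        t.tx_id,
                        "0",
                        t.strand,
                        str(thick_start),
                        str(thick_end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | Path, chrom_lengths: Mapping[str, int]) -> GeneModel:
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.rstrip("\n").split("\t")
            if len(f) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start0, end = f[0], int(f[1]), int(f[2])
            start = start0 + 1
            thick_start, thick_end = int(f[6]) + 1, int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + o, start + o + sz - 1) for o, sz in zip(offs, sizes)
            )
            cds = tuple(
                (max(s, thick_start), min(e, thick_end))
                for s, e in exons
                if s <= thick_end and e >= thick_start and thick_start <= thick_end
            )
            transcripts.append(
                Transcript(f[3], chrom, start, end, f[5], exons, cds)
            )
    transcripts.sort(key=lambda t: (t.chrom, t.start))
    return GeneModel(transcripts, dict(chrom_lengths))


# --------------------------------------------------------------------------
# variants

def _vcf_header(chrom_lengths: Mapping[str, int]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in sorted(chrom_lengths):
        h.contigs.add(c, length=chrom_lengths[c])
    h.info.add("DP", 1, "Integer", "Read depth")
    h.info.add("REGION", 1, "String", "Genomic region class")
    h.info.add("EFFECT", 1, "String", "Coding effect")
    return h


def write_vcf(
    path: str | Path,
    calls: Sequence[VariantCall],
    chrom_lengths: Mapping[str, int],
) -> None:
    header = _vcf_header(chrom_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(calls, key=lambda v: (v.chrom, v.pos, v.alt)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.info["DP"] = v.depth
            out.write(rec)


def read_vcf(path: str | Path, caller: str = "") -> list[VariantCall]:
    """Read SNV records; non-SNV alleles are skipped (the analysis is SNP-only)."""
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            ref = rec.ref
            depth = int(rec.info.get("DP", 0))
            for alt in rec.alts or ():
                if len(ref) == 1 and len(alt) == 1 and ref != alt and alt in "ACGT":
                    calls.append(VariantCall(rec.chrom, rec.pos, ref, alt, depth, caller))
    return calls


def write_consensus_vcf(
    path: str | Path,
    calls: Sequence[ConsensusVariant],
    chrom_lengths: Mapping[str, int],
) -> None:
    header = _vcf_header(chrom_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in calls:
            rec = out.new_record(contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt))
            rec.info["DP"] = v.depth
            if v.region:
                rec.info["REGION"] = v.region
            if v.coding_effect:
                rec.info["EFFECT"] = v.coding_effect
            out.write(rec)


# --------------------------------------------------------------------------
# sequences, trees, configs

def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_newick(path: str | Path, result: ClusterResult) -> None:
    tree = TreeNode.from_linkage_matrix(result.linkage_matrix, list(result.labels))
    with open(path, "w") as fh:
        fh.write(str(tree).strip() + "\n")


def write_config(path: str | Path, config: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        for k in config:
            fh.write(f"{k}={config[k]}\n")


def read_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out
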