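"""End-to-end orchestration: demo data, configuration, and the full run.

A run is driven by a flat key=value config file naming the sample
manifest (sample id, host group H or C, input paths) and the analysis
thresholds: the paired-MAPQ host threshold (default 100), the consensus
minimum read depth (default 30), the dominance top-k (default 5), and
the hierarchy levels for enrichment and linkage.  Stages execute in
order — read partition, functional profiles, core/pan, enrichment,
ordination/clustering, genome-function linkage, consensus variants —
skipping (and logging) any stage whose inputs a sample lacks.  The
report is fully regenerable from inputs + config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as slio
from .linkage import (
    build_linkage_db,
    diversity_abundance_trend,
    dominant_contribution,
    dominant_functions,
    dominant_genomes,
    originating_genome_breadth,
)
from .partition import partition_read_pairs
from .profiles import (
    build_profile,
    cluster_profiles,
    core_functions,
    enrichment_signature,
    ordinate_profiles,
    pool_records,
    profile_matrix,
)
from .synthetic import (
    CommunityConfig,
    EcosystemConfig,
    InvalidConfigError,
    MapqModel,
    generate_community,
    generate_function_catalog,
    generate_gene_model,
    generate_reference,
    resample_catalog,
    simulate_read_pairs,
    simulate_variant_callsets,
)
from .variants import (
    chromosome_density,
    classify_coding_effect,
    classify_region,
    filter_min_depth,
    genes_with_snps,
    intersect_call_sets,
    region_distribution,
)

__all__ = ["PipelineConfig", "make_demo_dataset", "run_pipeline", "DEMO_SAMPLES"]

log = logging.getLogger("salivalink")

DEMO_SAMPLES = (("H105", "H"), ("H114", "H"), ("C201", "C"), ("C218", "C"))

_SCALAR_KEYS = {
    "seed": int,
    "mapq_threshold": int,
    "min_depth": int,
    "top_k": int,
    "min_abundance": float,
    "enrich_level": int,
    "linkage_level": int,
    "model": str,
    "reference": str,
    "samples": str,
}
_SAMPLE_PREFIXES = ("alignments_", "catalog_", "calls_a_", "calls_b_")


@dataclass
class PipelineConfig:
    """Validated run configuration (see module docstring for the keys)."""

    samples: list[tuple[str, str]]  # (sample_id, group)
    alignments: dict[str, Path] = field(default_factory=dict)
    catalogs: dict[str, Path] = field(default_factory=dict)
    calls_a: dict[str, Path] = field(default_factory=dict)
    calls_b: dict[str, Path] = field(default_factory=dict)
    model: Path | None = None
    reference: Path | None = None
    mapq_threshold: int = 100
    min_depth: int = 30
    top_k: int = 5
    min_abundance: float = 0.0
    enrich_level: int = 2
    linkage_level: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        groups = {g for _, g in self.samples}
        unknown = groups - {"H", "C"}
        if unknown:
            raise InvalidConfigError(f"unknown sample group(s): {sorted(unknown)}")
        for thr in (self.mapq_threshold, self.min_depth, self.top_k):
            if thr < 0:
                raise InvalidConfigError("thresholds must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = slio.read_config(path)
        base = Path(path).parent
        if "samples" not in raw:
            raise InvalidConfigError(f"{path}: missing required key 'samples'")
        samples = []
        for item in raw["samples"].split(","):
            sid, _, grp = item.partition(":")
            samples.append((sid.strip(), grp.strip()))
        sample_ids = {s for s, _ in samples}
        kwargs: dict = {"samples": samples}
        path_maps = {"alignments_": {}, "catalog_": {}, "calls_a_": {}, "calls_b_": {}}
        for key, val in raw.items():
            if key == "samples":
                continue
            matched = False
            for prefix in _SAMPLE_PREFIXES:
                if key.startswith(prefix):
                    sid = key[len(prefix):]
                    if sid not in sample_ids:
                        raise InvalidConfigError(f"{path}: key {key!r} names unknown sample")
                    p = base / val
                    if not p.exists():
                        raise InvalidConfigError(f"{path}: input does not exist: {p}")
                    path_maps[prefix][sid] = p
                    matched = True
                    break
            if matched:
                continue
            if key not in _SCALAR_KEYS:
                raise InvalidConfigError(f"{path}: unknown config key {key!r}")
            if key in ("model", "reference"):
                p = base / val
                if not p.exists():
                    raise InvalidConfigError(f"{path}: input does not exist: {p}")
                kwargs[key] = p
            else:
                kwargs[key] = _SCALAR_KEYS[key](val)
        kwargs["alignments"] = path_maps["alignments_"]
        kwargs["catalogs"] = path_maps["catalog_"]
        kwargs["calls_a"] = path_maps["calls_a_"]
        kwargs["calls_b"] = path_maps["calls_b_"]
        return cls(**kwargs)


# --------------------------------------------------------------------------
# demo dataset

DEMO_LEVEL_SIZES = (8, 20, 60, 240)
DEMO_N_GENOMES = 20
DEMO_N_READ_PAIRS = 20000
DEMO_CROSSMAP_RATE = 0.02
DEMO_TRUTH_N = 1200
DEMO_N_CANDIDATES = 30000
DEMO_DEPTH_MEAN = 45.0
DEMO_FP, DEMO_FN = 0.03, 0.05
DEMO_FOLD = 2.0
DEMO_N_SHIFTED = 5
DEMO_CHROMS = {"chr1": 600_000, "chr2": 400_000, "chr3": 250_000}


def make_demo_dataset(outdir: str | Path, seed: int = 42) -> Path:
    """Write a 4-sample (2 H + 2 C) synthetic fixture set; returns config path.

    Host fractions follow the group defaults (0.7 for H, 0.45 for C);
    the two C samples carry a 2x count shift on 5 seeded hierarchy-2
    categories so that group structure is recoverable by enrichment and
    ordination.
    """
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / ".write_test").write_text("")
        (out / ".write_test").unlink()
    except OSError as exc:
        raise InvalidConfigError(f"output directory not writable: {out}") from exc

    rng = np.random.default_rng(seed)
    catalog = generate_function_catalog(DEMO_LEVEL_SIZES, seed=int(rng.integers(2**31)))
    community_cfg = CommunityConfig(
        n_genomes=DEMO_N_GENOMES,
        abundance_law="lognormal",
        law_params={"sigma": 1.2},
        unknown_fraction=0.3,
        seed=int(rng.integers(2**31)),
    )
    abundances, genes = generate_community(community_cfg, catalog, sample_id="community")
    shifted = sorted(rng.choice(catalog.levels[1], size=DEMO_N_SHIFTED, replace=False))
    model = generate_gene_model(40, DEMO_CHROMS, seed=int(rng.integers(2**31)))
    reference = generate_reference(DEMO_CHROMS, seed=int(rng.integers(2**31)))
    slio.write_gff3(out / "model.gff3", model)
    slio.write_bed12(out / "model.bed", model)
    slio.write_fasta(out / "reference.fa", reference)

    config: dict[str, object] = {
        "samples": ",".join(f"{s}:{g}" for s, g in DEMO_SAMPLES),
        "seed": seed,
        "mapq_threshold": 100,
        "min_depth": 30,
        "top_k": 5,
        "min_abundance": 0.0,
        "enrich_level": 2,
        "linkage_level": 1,
        "model": "model.gff3",
        "reference": "reference.fa",
    }
    for sample_id, group in DEMO_SAMPLES:
        eco = EcosystemConfig.for_group(
            group,
            DEMO_N_READ_PAIRS,
            mapq_model=MapqModel(crossmap_rate=DEMO_CROSSMAP_RATE),
            seed=int(rng.integers(2**31)),
        )
        pairs, truth = simulate_read_pairs(eco, abundances)
        slio.write_alignment_tsv(out / f"alignments_{sample_id}.tsv", pairs, truth.read_origins)

        fold = {c: DEMO_FOLD for c in shifted} if group == "C" else None
        records = resample_catalog(
            genes,
            sample_id,
            seed=int(rng.integers(2**31)),
            retain_prob=0.9,
            category_fold=fold,
            fold_level=2,
        )
        slio.write_gene_catalog(out / f"catalog_{sample_id}.tsv", records)

        truth_vars, calls_a, calls_b = simulate_variant_callsets(
            DEMO_TRUTH_N,
            model,
            DEMO_DEPTH_MEAN,
            DEMO_FP,
            DEMO_FN,
            DEMO_FP,
            DEMO_FN,
            seed=int(rng.integers(2**31)),
            n_candidates=DEMO_N_CANDIDATES,
            reference=reference,
        )
        slio.write_vcf(out / f"truth_{sample_id}.vcf", truth_vars, DEMO_CHROMS)
        slio.write_vcf(out / f"calls_a_{sample_id}.vcf", calls_a, DEMO_CHROMS)
        slio.write_vcf(out / f"calls_b_{sample_id}.vcf", calls_b, DEMO_CHROMS)
        config[f"alignments_{sample_id}"] = f"alignments_{sample_id}.tsv"
        config[f"catalog_{sample_id}"] = f"catalog_{sample_id}.tsv"
        config[f"calls_a_{sample_id}"] = f"calls_a_{sample_id}.vcf"
        config[f"calls_b_{sample_id}"] = f"calls_b_{sample_id}.vcf"

    cfg_path = out / "config.ini"
    slio.write_config(cfg_path, config)
    return cfg_path


# --------------------------------------------------------------------------
# the full run

def _round(x: float, nd: int = 10) -> float:
    return round(float(x), nd)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages and write report.json plus result tables.

    Returns the report dict.  Identical config + seed yields a
    byte-identical report body (no timestamps are recorded).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"samples": {s: {"group": g} for s, g in config.samples}, "skipped": []}

    # stage 1: read partition + per-genome read counts
    genome_reads: dict[str, dict[str, int]] = {}
    for sample_id, _ in config.samples:
        if sample_id not in config.alignments:
            report["skipped"].append(f"partition:{sample_id}")
            log.info("partition: no alignments for %s, skipped", sample_id)
            continue
        pairs, _truth = slio.read_alignment_tsv(config.alignments[sample_id])
        result = partition_read_pairs(pairs, threshold=config.mapq_threshold)
        log.info(
            "partition %s: %d pairs in, %d host / %d microbial",
            sample_id, result.n_pairs, len(result.host_ids), len(result.microbial_ids),
        )
        report["samples"][sample_id]["partition"] = {
            "n_pairs": result.n_pairs,
            "host_fraction": _round(result.host_fraction),
            "microbial_fraction": _round(result.microbial_fraction),
        }
        counts: dict[str, int] = {}
        microbial = result.microbial_ids
        for p in pairs:
            if p.read_id in microbial and p.target is not None:
                counts[p.target] = counts.get(p.target, 0) + 1
        genome_reads[sample_id] = counts

    # stage 2: functional profiles
    records_by_sample: dict[str, list] = {}
    profiles_by_level: dict[int, list] = {1: [], 2: [], 3: [], 4: []}
    for sample_id, _ in config.samples:
        if sample_id not in config.catalogs:
            report["skipped"].append(f"profiles:{sample_id}")
            log.info("profiles: no catalog for %s, skipped", sample_id)
            continue
        records = slio.read_gene_catalog(config.catalogs[sample_id])
        records_by_sample[sample_id] = records
        sample_entry = report["samples"][sample_id].setdefault("profiles", {})
        for level in range(1, 5):
            prof = build_profile(records, level)
            profiles_by_level[level].append(prof)
            sample_entry[f"level{level}_categories"] = len(prof.counts)
        sample_entry["unknown_fraction"] = _round(
            build_profile(records, 1).unknown_fraction or 0.0
        )
        log.info("profiles %s: %d gene records", sample_id, len(records))
    for level, profs in profiles_by_level.items():
        if profs:
            profile_matrix(profs).T.to_csv(out / f"profiles_level{level}.tsv", sep="\t")

    # stage 3: core / pan functions
    if profiles_by_level[4]:
        cp = core_functions(profiles_by_level[4])
        report["core_pan"] = {
            "core_functions": len(cp.core),
            "pan_functions": len(cp.pan),
            "core_gene_sequences": cp.core_gene_sequence_count,
            "pan_gene_sequences": cp.pan_gene_sequence_count,
        }
        log.info("core/pan: %d core of %d pan functions", len(cp.core), len(cp.pan))
    else:
        report["skipped"].append("core_pan")

    # stage 4: group enrichment (H vs C), pooled records per group
    groups: dict[str, list] = {"H": [], "C": []}
    for sample_id, group in config.samples:
        if sample_id in records_by_sample:
            groups[group].extend(records_by_sample[sample_id])
    if groups["H"] and groups["C"]:
        prof_h = build_profile(pool_records(groups["H"], "H"), config.enrich_level)
        prof_c = build_profile(pool_records(groups["C"], "C"), config.enrich_level)
        sig = enrichment_signature(prof_c, prof_h, min_abundance=config.min_abundance)
        table = sorted(sig.enrichment.items(), key=lambda kv: -kv[1])
        with open(out / "enrichment_C_vs_H.tsv", "w") as fh:
            fh.write("category\tenrichment_percent\n")
            for cat, pct in table:
                fh.write(f"{cat}\t{pct:.6f}\n")
            for cat in sorted(sig.exclusive_to_a):
                fh.write(f"{cat}\texclusive_to_C\n")
        report["enrichment_C_vs_H"] = {
            "n_categories": len(sig.enrichment),
            "max_enriched": table[0][0] if table else None,
            "max_enrichment_percent": _round(table[0][1]) if table else None,
            "exclusive_to_C": sorted(sig.exclusive_to_a),
        }
    else:
        report["skipped"].append("enrichment")

    # stage 5: ordination and clustering
    level_profiles = profiles_by_level[config.enrich_level]
    if len(level_profiles) >= 2:
        ord_res = ordinate_profiles(level_profiles, n_components=2)
        ord_res.coordinates.round(10).to_csv(out / "ordination.tsv", sep="\t")
        report["ordination"] = {
            "explained_variance_ratio": [_round(v) for v in ord_res.explained_variance_ratio],
            "pc1": {s: _round(v) for s, v in ord_res.coordinates["PC1"].items()},
        }
        clus = cluster_profiles(level_profiles, linkage_rule="average")
        slio.write_newick(out / "dendrogram.nwk", clus)
    else:
        report["skipped"].append("ordination")

    # stage 6: genome-function linkage and dominance
    for sample_id, _ in config.samples:
        if sample_id not in records_by_sample or sample_id not in genome_reads:
            report["skipped"].append(f"linkage:{sample_id}")
            continue
        reads = dict(genome_reads[sample_id])
        for r in records_by_sample[sample_id]:
            if r.genome_id is not None:
                reads.setdefault(r.genome_id, 0)  # genome seen in catalog, no mapped reads
        db = build_linkage_db(records_by_sample[sample_id], reads)
        level, k = config.linkage_level, config.top_k
        dom_g = dominant_genomes(db, k)
        contrib = dominant_contribution(db, level, k)
        breadth = originating_genome_breadth(db, level)
        db.matrix(level).to_csv(out / f"linkage_{sample_id}_level{level}.tsv", sep="\t")
        report["samples"][sample_id]["linkage"] = {
            "dominant_genomes": dom_g,
            "dominant_abundance_share": _round(db.abundances[dom_g].sum()),
            "dominant_functions": dominant_functions(db, level, k),
            "contribution_min": _round(contrib.minimum),
            "contribution_max": _round(contrib.maximum),
            "diversity_abundance_trend": _round(diversity_abundance_trend(db, level)),
            "abundance_breadth_correlation": _round(breadth.abundance_breadth_correlation),
            "unassigned_fraction": _round(db.unassigned_fraction),
        }

    # stage 7: consensus host variants
    model = slio.read_gff3(config.model) if config.model else None
    reference = slio.read_fasta(config.reference) if config.reference else None
    for sample_id, _ in config.samples:
        if (
            sample_id not in config.calls_a
            or sample_id not in config.calls_b
            or model is None
        ):
            report["skipped"].append(f"variants:{sample_id}")
            log.info("variants: inputs missing for %s, skipped", sample_id)
            continue
        a = slio.read_vcf(config.calls_a[sample_id], caller="a")
        b = slio.read_vcf(config.calls_b[sample_id], caller="b")
        consensus = intersect_call_sets(a, b)
        kept = filter_min_depth(consensus.variants, config.min_depth)
        dist = region_distribution(kept, model)
        effects: dict[str, int] = {}
        annotated = []
        for v in kept:
            region = classify_region(v, model)
            effect = None
            if region == "exonic" and reference is not None:
                effect = classify_coding_effect(v, model, reference)
                effects[effect] = effects.get(effect, 0) + 1
            annotated.append(
                type(v)(v.chrom, v.pos, v.ref, v.alt, v.depth, region, effect)
            )
        slio.write_consensus_vcf(
            out / f"consensus_{sample_id}.vcf", annotated, model.chrom_lengths
        )
        density = chromosome_density(kept, model.chrom_lengths)
        log.info(
            "variants %s: %d + %d calls in, %d consensus, %d pass depth>=%d",
            sample_id, len(a), len(b), len(consensus.variants), len(kept), config.min_depth,
        )
        report["samples"][sample_id]["variants"] = {
            "calls_a": len(a),
            "calls_b": len(b),
            "consensus": len(consensus.variants),
            "ref_mismatches": consensus.ref_mismatches,
            "pass_depth": len(kept),
            "region_fractions": {c: _round(f) for c, f in (dist or {}).items()},
            "coding_effects": effects,
            "genes_with_snps": genes_with_snps(kept, model),
            "density_chi_square": (
                _round(density.chi_square) if density.chi_square is not None else None
            ),
            "density_df": density.degrees_of_freedom,
        }

    report["fingerprint"] = {
        "config_sha256": _config_fingerprint(config),
        "seed": config.seed,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _config_fingerprint(config: PipelineConfig) -> str:
    payload = json.dumps(
        {
            "samples": config.samples,
            "mapq_threshold": config.mapq_threshold,
            "min_depth": config.min_depth,
            "top_k": config.top_k,
            "min_abundance": config.min_abundance,
            "enrich_level": config.enrich_level,
            "linkage_level": config.linkage_level,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()
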