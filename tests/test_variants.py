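"""Consensus SNPs, region and coding-effect classification, density."""

import pytest
from Bio.Seq import Seq

from salivalink.synthetic import generate_gene_model, generate_reference
from salivalink.variants import (
    REGION_CLASSES,
    ConsensusVariant,
    GeneModel,
    Transcript,
    VariantCall,
    chromosome_density,
    classify_coding_effect,
    classify_region,
    filter_min_depth,
    genes_with_snps,
    intersect_call_sets,
    region_distribution,
)


def vc(chrom, pos, ref, alt, depth=50, caller="a"):
    return VariantCall(chrom, pos, ref, alt, depth, caller)


def cons(chrom, pos, ref, alt, depth=50):
    return ConsensusVariant(chrom, pos, ref, alt, depth)


class TestIntersect:
    def test_simple_intersection(self):
        a = [vc("chr1", 100, "A", "G"), vc("chr2", 50, "C", "T")]
        b = [vc("chr1", 100, "A", "G", caller="b")]
        res = intersect_call_sets(a, b)
        assert [v.key for v in res.variants] == [("chr1", 100, "A", "G")]

    def test_allele_aware_matching(self):
        res = intersect_call_sets([vc("chr1", 10, "A", "G")], [vc("chr1", 10, "A", "T")])
        assert res.variants == ()

    def test_depth_is_minimum_of_callers(self):
        res = intersect_call_sets(
            [vc("chr1", 5, "A", "G", depth=80)], [vc("chr1", 5, "A", "G", depth=33)]
        )
        assert res.variants[0].depth == 33

    def test_ref_mismatch_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="disagreement"):
            res = intersect_call_sets([vc("chr1", 10, "A", "G")], [vc("chr1", 10, "C", "G")])
        assert res.variants == () and res.ref_mismatches == 1

    def test_matches_quadratic_oracle_on_random_sets(self, rng):
        def random_calls(n, tag):
            calls, seen = [], set()
            while len(calls) < n:
                pos = int(rng.integers(1, 400))
                ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
                if (pos, str(alt)) in seen:
                    continue
                seen.add((pos, str(alt)))
                calls.append(vc("chr1", pos, str(ref), str(alt), int(rng.integers(0, 99)), tag))
            return calls

        a, b = random_calls(500, "a"), random_calls(500, "b")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = intersect_call_sets(a, b)
        oracle = sorted(
            (x.chrom, x.pos, x.ref, x.alt, min(x.depth, y.depth))
            for x in a for y in b
            if (x.chrom, x.pos, x.ref, x.alt) == (y.chrom, y.pos, y.ref, y.alt)
        )
        got = sorted((v.chrom, v.pos, v.ref, v.alt, v.depth) for v in res.variants)
        assert got == oracle
        assert len(res.variants) <= min(len(a), len(b))


class TestDepthFilter:
    def test_threshold_inclusive_at_30(self):
        calls = [cons("chr1", i, "A", "G", depth=d) for i, d in enumerate((29, 30, 31), 1)]
        kept = filter_min_depth(calls, 30)
        assert [v.depth for v in kept] == [30, 31]

    def test_zero_threshold_identity(self):
        calls = [cons("chr1", 1, "A", "G", depth=0)]
        assert filter_min_depth(calls, 0) == calls

    def test_all_below_threshold_empty(self):
        calls = [cons("chr1", i, "A", "G", depth=5) for i in range(1, 4)]
        assert filter_min_depth(calls, 30) == []


@pytest.fixture(scope="module")
def toy_model():
    # one + strand transcript: exons 101-200 and 301-400, CDS 151-200 + 301-352
    tx = Transcript(
        "txA", "chr1", 101, 400, "+",
        exons=((101, 200), (301, 400)),
        cds=((151, 200), (301, 352)),
    )
    return GeneModel([tx], {"chr1": 1000})


class TestRegionClassification:
    def test_cds_position_is_exonic(self, toy_model):
        assert classify_region(cons("chr1", 160, "A", "G"), toy_model) == "exonic"

    def test_exon_outside_cds_is_utr(self, toy_model):
        assert classify_region(cons("chr1", 120, "A", "G"), toy_model) == "UTR"

    def test_deep_intron_is_intronic(self, toy_model):
        assert classify_region(cons("chr1", 250, "A", "G"), toy_model) == "intronic"

    def test_intron_edge_is_splicing(self, toy_model):
        assert classify_region(cons("chr1", 201, "A", "G"), toy_model) == "splicing"
        assert classify_region(cons("chr1", 299, "A", "G"), toy_model) == "splicing"

    def test_outside_transcripts_is_intergenic(self, toy_model):
        assert classify_region(cons("chr1", 900, "A", "G"), toy_model) == "intergenic"

    def test_empty_model_everything_intergenic(self):
        model = GeneModel([], {"chr1": 1000})
        assert classify_region(cons("chr1", 5, "A", "G"), model) == "intergenic"

    def test_position_beyond_chromosome_rejected(self, toy_model):
        with pytest.raises(ValueError, match="outside"):
            classify_region(cons("chr1", 5000, "A", "G"), toy_model)

    def test_classes_exhaustive_and_exclusive(self, rng):
        model = generate_gene_model(15, {"chr1": 100_000}, seed=8)
        for pos in rng.integers(1, 100_001, size=300):
            cls = classify_region(cons("chr1", int(pos), "A", "G"), model)
            assert cls in REGION_CLASSES


def effect_oracle(v, transcript, reference):
    """Independent oracle: translate the full CDS of the reference and of
    the mutated genome and compare protein sequences."""
    mutated = dict(reference)
    s = mutated[v.chrom]
    assert s[v.pos - 1] == v.ref
    mutated[v.chrom] = s[: v.pos - 1] + v.alt + s[v.pos :]

    def protein(ref):
        seq = "".join(ref[transcript.chrom][a - 1 : b] for a, b in transcript.cds)
        if transcript.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return str(Seq(seq).translate())

    p_ref, p_alt = protein(reference), protein(mutated)
    if p_ref == p_alt:
        return "synonymous"
    diff = next(i for i, (x, y) in enumerate(zip(p_ref, p_alt)) if x != y)
    if p_alt[diff] == "*":
        return "stopgain"
    if p_ref[diff] == "*":
        return "stoploss"
    return "nonsynonymous"


class TestCodingEffect:
    def _micro(self, cds_seq, strand="+"):
        # single-exon transcript whose CDS is exactly cds_seq on + coordinates
        genomic = cds_seq if strand == "+" else str(Seq(cds_seq).reverse_complement())
        ref = {"chr1": "TTTT" + genomic + "TTTT"}
        n = len(cds_seq)
        tx = Transcript("t", "chr1", 5, 4 + n, strand, ((5, 4 + n),), ((5, 4 + n),))
        return GeneModel([tx], {"chr1": len(ref["chr1"])}), ref

    def test_codon_table_examples(self):
        model, ref = self._micro("GGAATGTAC")
        # GGA->GGG Gly->Gly
        assert classify_coding_effect(cons("chr1", 7, "A", "G"), model, ref) == "synonymous"
        # ATG->ATA Met->Ile
        assert classify_coding_effect(cons("chr1", 10, "G", "A"), model, ref) == "nonsynonymous"
        # TAC->TAA stopgain
        assert classify_coding_effect(cons("chr1", 13, "C", "A"), model, ref) == "stopgain"

    def test_stoploss(self):
        model, ref = self._micro("ATGTAA")
        # TAA->CAA stop -> Gln
        assert classify_coding_effect(cons("chr1", 8, "T", "C"), model, ref) == "stoploss"

    def test_minus_strand_matches_full_cds_oracle(self):
        model, ref = self._micro("ATGGGCTAC", strand="-")
        tx = model.transcripts[0]
        # third codon base of the reverse-strand CDS is the genomic 5' end
        for pos in range(tx.start, tx.end + 1):
            base = ref["chr1"][pos - 1]
            for alt in "ACGT":
                if alt == base:
                    continue
                v = cons("chr1", pos, base, alt)
                assert classify_coding_effect(v, model, ref) == effect_oracle(v, tx, ref)

    def test_random_exonic_snvs_agree_with_oracle(self, rng):
        model = generate_gene_model(12, {"chr1": 150_000}, seed=21)
        reference = generate_reference(model.chrom_lengths, seed=22)
        strands = set()
        checked = 0
        while checked < 200:
            tx = model.transcripts[int(rng.integers(len(model.transcripts)))]
            s, e = tx.cds[int(rng.integers(len(tx.cds)))]
            pos = int(rng.integers(s, e + 1))
            base = reference["chr1"][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            v = cons("chr1", pos, base, alt)
            assert classify_coding_effect(v, model, reference) == effect_oracle(v, tx, reference)
            strands.add(tx.strand)
            checked += 1
        assert strands == {"+", "-"}

    def test_non_exonic_variant_rejected(self, toy_model):
        with pytest.raises(ValueError, match="not exonic"):
            classify_coding_effect(cons("chr1", 250, "A", "G"), toy_model, {"chr1": "A" * 1000})


class TestDistributions:
    def test_region_distribution_hand_placement(self, toy_model):
        calls = (
            [cons("chr1", p, "A", "G") for p in (160, 320)]  # exonic
            + [cons("chr1", p, "A", "G") for p in (240, 250, 260)]  # intronic
            + [cons("chr1", p, "A", "G") for p in (500, 600, 700, 800, 900)]  # intergenic
        )
        dist = region_distribution(calls, toy_model)
        assert dist["exonic"] == pytest.approx(0.2)
        assert dist["intronic"] == pytest.approx(0.3)
        assert dist["intergenic"] == pytest.approx(0.5)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_empty_model_all_intergenic(self):
        model = GeneModel([], {"chr1": 1000})
        dist = region_distribution([cons("chr1", 5, "A", "G")], model)
        assert dist["intergenic"] == 1.0

    def test_empty_calls_undefined(self, toy_model):
        assert region_distribution([], toy_model) is None


class TestChromosomeDensity:
    def test_proportional_counts_chi_square_zero(self):
        lengths = {"chr1": 2_000_000, "chr2": 1_000_000}
        calls = [cons("chr1", i, "A", "G") for i in range(1, 41)] + [
            cons("chr2", i, "A", "G") for i in range(1, 21)
        ]
        rep = chromosome_density(calls, lengths)
        assert rep.chi_square == pytest.approx(0.0)
        assert rep.density_per_mb == pytest.approx({"chr1": 20.0, "chr2": 20.0})

    def test_all_on_one_of_two_equal_chromosomes(self):
        lengths = {"chr1": 1_000_000, "chr2": 1_000_000}
        calls = [cons("chr1", i, "A", "G") for i in range(1, 101)]
        rep = chromosome_density(calls, lengths)
        assert rep.chi_square == pytest.approx(100.0)
        assert rep.degrees_of_freedom == 1

    def test_single_chromosome_undefined(self):
        rep = chromosome_density([cons("chr1", 1, "A", "G")], {"chr1": 1000})
        assert rep.chi_square is None and rep.degrees_of_freedom == 0

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            chromosome_density([cons("chrX", 1, "A", "G")], {"chr1": 1000})


class TestGenesWithSnps:
    def test_gene_counted_once(self, toy_model):
        calls = [cons("chr1", p, "A", "G") for p in (110, 160, 250, 320, 390)]
        assert genes_with_snps(calls, toy_model) == 1

    def test_no_snps_in_genes(self, toy_model):
        assert genes_with_snps([cons("chr1", 900, "A", "G")], toy_model) == 0

    def test_hand_placed_across_models(self):
        model = generate_gene_model(5, {"chr1": 100_000}, seed=2)
        targets = model.transcripts[:3]
        calls = [cons("chr1", t.start, "A", "G") for t in targets]
        assert genes_with_snps(calls, model) == 3
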