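"""Functional profiles: aggregation, core/pan algebra, enrichment, ordination."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from salivalink.profiles import (
    GeneRecord,
    SampleFunctionProfile,
    build_profile,
    cluster_profiles,
    core_functions,
    enrichment_signature,
    hierarchy_from_records,
    ordinate_profiles,
    pathway_unique_proteins,
)
from salivalink.synthetic import CommunityConfig, generate_community


def rec(gene, path, count, sample="S1", genome=None):
    return GeneRecord(gene, sample, path, genome, count)


P = lambda h1, h2, f: (h1, h2, f"{h2}.x", f)  # compact 4-level path builder


class TestBuildProfile:
    def test_level1_aggregation(self):
        records = [
            rec("a", P("cat", "p1", "f1"), 3),
            rec("b", P("cat", "p2", "f2"), 2),
        ]
        prof = build_profile(records, 1)
        assert prof.counts == {"cat": 5}
        assert prof.relative_abundance == {"cat": 1.0}

    def test_level2_hand_relative_abundances(self):
        # functions under 2 level-2 parents with counts (4, 1, 5) -> (0.4, 0.6)
        records = [
            rec("a", P("c", "p1", "f1"), 4),
            rec("b", P("c", "p1", "f2"), 1),
            rec("c", P("c", "p2", "f3"), 5),
        ]
        prof = build_profile(records, 2)
        assert prof.relative_abundance == pytest.approx({"p1": 0.5, "p2": 0.5})
        prof1 = build_profile(
            [rec("a", P("c", "p1", "f1"), 4), rec("c", P("c", "p2", "f3"), 6)], 2
        )
        assert prof1.relative_abundance == pytest.approx({"p1": 0.4, "p2": 0.6})

    def test_empty_records_flagged(self):
        prof = build_profile([], 1)
        assert prof.counts == {} and prof.unknown_fraction is None

    def test_unknown_functions_tracked_not_normalized(self):
        records = [rec("a", P("c", "p", "f"), 3), rec("u", None, 1)]
        prof = build_profile(records, 1)
        assert prof.relative_abundance == {"c": 1.0}
        assert prof.unknown_fraction == pytest.approx(0.25)

    def test_mixed_samples_rejected(self):
        records = [rec("a", P("c", "p", "f"), 1), rec("b", P("c", "p", "f"), 1, sample="S2")]
        with pytest.raises(ValueError, match="sample ids"):
            build_profile(records, 1)

    @pytest.mark.parametrize("level", [0, 5])
    def test_level_bounds(self, level):
        with pytest.raises(ValueError):
            build_profile([], level)


class TestProfileInvariants:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_normalization_and_hierarchical_conservation(self, catalog, seed):
        cfg = CommunityConfig(n_genomes=6, unknown_fraction=0.2, seed=seed)
        _, genes = generate_community(cfg, catalog)
        profs = {lv: build_profile(genes, lv) for lv in (1, 2, 3, 4)}
        for lv, prof in profs.items():
            if prof.relative_abundance:
                assert math.isclose(sum(prof.relative_abundance.values()), 1.0, abs_tol=1e-9)
        # level-k counts aggregate exactly to level-(k-1)
        paths = {r.path[3]: r.path for r in genes if r.path is not None}
        for lv in (2, 3, 4):
            rolled: dict[str, int] = {}
            for cat, n in profs[lv].counts.items():
                parent = next(p[lv - 2] for p in paths.values() if p[lv - 1] == cat)
                rolled[parent] = rolled.get(parent, 0) + n
            assert rolled == dict(profs[lv - 1].counts)


class TestCorePan:
    def _profiles(self, sets_with_counts):
        profs = []
        for i, counts in enumerate(sets_with_counts):
            path = lambda f: ("h1", "h2", "h3", f)
            records = [rec(f"g{i}{f}", path(f), n, sample=f"S{i}") for f, n in counts.items()]
            profs.append(build_profile(records, 4))
        return profs

    def test_set_algebra(self):
        profs = self._profiles([{"A": 1, "B": 1, "C": 1}, {"B": 1, "C": 1, "D": 1}, {"C": 1, "B": 1}])
        cp = core_functions(profs)
        assert cp.core == {"B", "C"} and cp.pan == {"A", "B", "C", "D"}

    def test_single_sample_core_equals_pan(self):
        profs = self._profiles([{"A": 2, "B": 3}])
        cp = core_functions(profs)
        assert cp.core == cp.pan == {"A", "B"}
        assert cp.core_gene_sequence_count == cp.pan_gene_sequence_count == 5

    def test_hand_gene_sequence_counts(self):
        # S1{B:2,C:1,A:4}, S2{B:1,C:3,D:2} -> core {B,C}, core count 2+1+1+3=7
        profs = self._profiles([{"B": 2, "C": 1, "A": 4}, {"B": 1, "C": 3, "D": 2}])
        cp = core_functions(profs)
        assert cp.core == {"B", "C"}
        assert cp.core_gene_sequence_count == 7
        assert cp.pan_gene_sequence_count == 13

    def test_adding_sample_monotone(self, rng):
        universe = [f"f{i}" for i in range(30)]
        collections = []
        for i in range(8):
            chosen = rng.choice(universe, size=rng.integers(5, 25), replace=False)
            collections.append({f: 1 for f in chosen})
        profs = self._profiles(collections)
        for k in range(2, len(profs) + 1):
            prev, cur = core_functions(profs[: k - 1]), core_functions(profs[:k])
            assert cur.core <= prev.core
            assert cur.pan >= prev.pan

    def test_requires_function_level(self):
        records = [rec("a", P("c", "p", "f"), 1)]
        with pytest.raises(ValueError, match="level-4"):
            core_functions([build_profile(records, 2)])


class TestEnrichment:
    def _prof(self, ra, sample="A"):
        counts = {c: int(v * 1000) for c, v in ra.items()}
        return SampleFunctionProfile(sample, 2, counts, ra, 0.0)

    def test_identical_profiles_zero(self):
        p = self._prof({"x": 0.4, "y": 0.6})
        sig = enrichment_signature(p, self._prof({"x": 0.4, "y": 0.6}, "B"))
        assert sig.enrichment == pytest.approx({"x": 0.0, "y": 0.0})

    def test_doubling_is_plus_100_percent(self):
        sig = enrichment_signature(
            self._prof({"x": 0.2, "y": 0.8}), self._prof({"x": 0.1, "y": 0.9}, "B")
        )
        assert sig.enrichment["x"] == pytest.approx(100.0)

    def test_exclusive_category_flagged_not_numeric(self):
        sig = enrichment_signature(
            self._prof({"x": 0.5, "y": 0.5}), self._prof({"y": 1.0}, "B")
        )
        assert "x" in sig.exclusive_to_a and "x" not in sig.enrichment

    def test_min_abundance_omits_rare_categories(self):
        sig = enrichment_signature(
            self._prof({"x": 0.001, "y": 0.999}),
            self._prof({"x": 0.002, "y": 0.998}, "B"),
            min_abundance=0.01,
        )
        assert "x" not in sig.enrichment and "x" not in sig.exclusive_to_a

    def test_level_mismatch_rejected(self):
        a = self._prof({"x": 1.0})
        b = SampleFunctionProfile("B", 3, {"x": 1}, {"x": 1.0}, 0.0)
        with pytest.raises(ValueError, match="level"):
            enrichment_signature(a, b)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    )
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetry(self, wa, wb):
        n = min(len(wa), len(wb))
        cats = [f"c{i}" for i in range(n)]
        ra = {c: w / sum(wa[:n]) for c, w in zip(cats, wa)}
        rb = {c: w / sum(wb[:n]) for c, w in zip(cats, wb)}
        ab = enrichment_signature(self._prof(ra), self._prof(rb, "B")).enrichment
        ba = enrichment_signature(self._prof(rb), self._prof(ra, "B")).enrichment
        for c in cats:
            assert (1 + ab[c] / 100) * (1 + ba[c] / 100) == pytest.approx(1.0)


class TestPathwayUniqueProteins:
    def _records(self, funcs, sample):
        path = lambda f: ("root", "pw" if f.startswith("p") else "other", "h3", f)
        return [rec(f"{sample}{f}", path(f), 1, sample=sample) for f in funcs]

    def _hierarchy(self):
        all_funcs = [f"p{i}" for i in range(12)] + ["q0"]
        return hierarchy_from_records(self._records(all_funcs, "X"))

    def test_disjoint_repertoires_hand_percent(self):
        h = self._hierarchy()
        a = self._records([f"p{i}" for i in range(7)], "A")
        b = self._records([f"p{i}" for i in range(7, 12)], "B")
        res = pathway_unique_proteins(a, b, "pw", h)
        assert (res.unique_to_a, res.unique_to_b) == (7, 5)
        assert res.percent_excess == pytest.approx(40.0)

    def test_identical_repertoires_undefined(self):
        h = self._hierarchy()
        a = self._records(["p1", "p2"], "A")
        b = self._records(["p1", "p2"], "B")
        res = pathway_unique_proteins(a, b, "pw", h)
        assert (res.unique_to_a, res.unique_to_b, res.status) == (0, 0, "undefined")

    def test_empty_b_is_exclusive(self):
        h = self._hierarchy()
        res = pathway_unique_proteins(self._records(["p1"], "A"), [], "pw", h)
        assert res.status == "exclusive_to_a" and res.unique_to_a == 1

    def test_unknown_pathway_rejected(self):
        with pytest.raises(KeyError):
            pathway_unique_proteins([], [], "nope", self._hierarchy())


class TestOrdination:
    def _prof(self, sample, ra):
        return SampleFunctionProfile(sample, 2, {}, ra, 0.0)

    def test_group_shift_separates_on_pc1(self):
        profs = [
            self._prof("a1", {"x": 0.8, "y": 0.1, "z": 0.1}),
            self._prof("a2", {"x": 0.78, "y": 0.12, "z": 0.1}),
            self._prof("b1", {"x": 0.2, "y": 0.7, "z": 0.1}),
            self._prof("b2", {"x": 0.22, "y": 0.68, "z": 0.1}),
        ]
        res = ordinate_profiles(profs)
        pc1 = res.coordinates["PC1"]
        assert np.sign(pc1["a1"]) == np.sign(pc1["a2"]) != np.sign(pc1["b1"]) == np.sign(pc1["b2"])
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-12

    def test_identical_profiles_collapse_to_origin(self):
        profs = [self._prof(s, {"x": 0.5, "y": 0.5}) for s in "abc"]
        res = ordinate_profiles(profs)
        assert np.allclose(res.coordinates.to_numpy(), 0.0)
        assert np.allclose(res.explained_variance_ratio, 0.0)

    def test_matches_brute_force_eigendecomposition(self):
        ras = [
            {"x": 0.5, "y": 0.3, "z": 0.2},
            {"x": 0.1, "y": 0.6, "z": 0.3},
            {"x": 0.3, "y": 0.3, "z": 0.4},
            {"x": 0.7, "y": 0.2, "z": 0.1},
        ]
        profs = [self._prof(f"s{i}", ra) for i, ra in enumerate(ras)]
        res = ordinate_profiles(profs, n_components=2)
        X = np.array([[ra[c] for c in sorted(ra)] for ra in ras])
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc / (len(ras) - 1))
        order = np.argsort(w)[::-1]
        expected = Xc @ V[:, order[:2]]
        got = res.coordinates.to_numpy()
        for j in range(2):  # compare up to sign
            assert np.allclose(got[:, j], expected[:, j], atol=1e-10) or np.allclose(
                got[:, j], -expected[:, j], atol=1e-10
            )

    def test_too_many_components_rejected(self):
        profs = [self._prof(s, {"x": 0.5, "y": 0.5}) for s in "ab"]
        with pytest.raises(ValueError, match="n_components"):
            ordinate_profiles(profs, n_components=3)


class TestClustering:
    def _prof(self, sample, p):
        return SampleFunctionProfile(sample, 1, {}, {"x": p, "y": 1 - p}, 0.0)

    def test_two_tight_groups_split_first_at_top(self):
        profs = [self._prof(s, p) for s, p in
                 [("a1", 0.1), ("a2", 0.12), ("b1", 0.9), ("b2", 0.88)]]
        res = cluster_profiles(profs, "single")
        from scipy.cluster.hierarchy import fcluster
        groups = fcluster(res.linkage_matrix, t=2, criterion="maxclust")
        assign = dict(zip(res.labels, groups))
        assert assign["a1"] == assign["a2"] != assign["b1"] == assign["b2"]

    def test_duplicate_profiles_merge_at_zero(self):
        profs = [self._prof("a", 0.3), self._prof("b", 0.3), self._prof("c", 0.9)]
        res = cluster_profiles(profs)
        assert res.merge_heights()[0] == pytest.approx(0.0)

    def test_single_linkage_merge_order_matches_hand_trace(self):
        # 1-D profiles at p = .1, .2, .4, .8; pairwise distance sqrt(2)|dp|
        profs = [self._prof(s, p) for s, p in
                 [("s0", 0.1), ("s1", 0.2), ("s2", 0.4), ("s3", 0.8)]]
        res = cluster_profiles(profs, "single")
        heights = res.merge_heights()
        expected = np.sqrt(2) * np.array([0.1, 0.2, 0.4])
        assert np.allclose(heights, expected, atol=1e-12)

    def test_one_profile_rejected(self):
        with pytest.raises(ValueError):
            cluster_profiles([self._prof("a", 0.5)])
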