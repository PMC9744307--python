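import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tadcoord.core import GenomicInterval, make_deg_record
from tadcoord.simulate import DEGSimSpec, GeneLocus, GenomeSimSpec, simulate_deg_table, simulate_genome
from tadcoord.tadstats import (
    CoordinationProfile,
    assign_to_tads,
    average_coordination,
    clustering_permutation_test,
    clustering_statistic,
    coordination_bin_comparison,
    coordination_permutation_test,
    coordination_score,
)
from conftest import exhaustive_clustering_p, exhaustive_coordination_p


def _assignment(tad_sizes, deg_per_tad, directions=None):
    """Build an assignment with given per-TAD gene and DEG counts."""
    tads, loci, degs = [], [], {}
    pos, gid = 0, 0
    dir_iter = iter(directions or [])
    for t, (size, nd) in enumerate(zip(tad_sizes, deg_per_tad)):
        tads.append(GenomicInterval("chr1", pos, pos + 1000))
        for k in range(size):
            gid += 1
            name = f"G{gid}"
            loci.append(GeneLocus(name, "chr1", pos + 10 * (k + 1)))
            if k < nd:
                d = next(dir_iter, "up")
                degs[name] = make_deg_record(name, 1.0 if d == "up" else -1.0, 1e-4, 0.01)
        pos += 1000
    return assign_to_tads(loci, tads, degs)


class TestAssignment:
    def test_tss_inside_tad_assigned(self):
        a = _assignment([2], [0])
        assert len(a.gene_ids) == 2 and a.n_tads == 1

    def test_right_boundary_is_exclusive(self):
        tads = [GenomicInterval("chr1", 100, 200)]
        inside = GeneLocus("G1", "chr1", 150)
        boundary = GeneLocus("G2", "chr1", 200)
        a = assign_to_tads([inside, boundary], tads)
        assert a.gene_ids == ["G1"]
        assert a.excluded_gene_ids == ["G2"]

    def test_excluded_count(self):
        tads = [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 2000, 3000)]
        loci = [GeneLocus(f"G{i}", "chr1", p) for i, p in enumerate(
            [10, 500, 999, 2500, 2999, 100, 200, 400, 1500, 1800]
        )]
        a = assign_to_tads(loci, tads)
        assert len(a.gene_ids) == 8 and a.n_excluded == 2

    def test_overlapping_tads_rejected(self):
        tads = [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 500, 1500)]
        with pytest.raises(ValueError, match="overlap"):
            assign_to_tads([GeneLocus("G1", "chr1", 10)], tads)

    def test_empty_tads_dropped(self):
        tads = [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 1000, 2000)]
        a = assign_to_tads([GeneLocus("G1", "chr1", 10)], tads)
        assert a.n_tads == 1


class TestClusteringStatistic:
    @pytest.mark.parametrize(
        "sizes,degs,expected",
        [
            ([2, 2], [1, 0], 25.0),        # 50% and 0% average to 25%
            ([3, 2], [3, 2], 100.0),        # all genes DEGs
            ([2, 4, 10], [1, 1, 1], pytest.approx(np.mean([50, 25, 10]), abs=1e-9)),
        ],
    )
    def test_worked_examples(self, sizes, degs, expected):
        assert clustering_statistic(_assignment(sizes, degs)) == expected

    def test_invariant_under_tad_and_gene_order(self):
        a = _assignment([2, 4, 10], [1, 1, 1])
        b = _assignment([10, 2, 4], [1, 1, 1])
        assert clustering_statistic(a) == clustering_statistic(b)


class TestClusteringPermutation:
    def test_all_degs_is_degenerate(self):
        a = _assignment([3, 2], [3, 2])
        with pytest.raises(ValueError, match="degenerate"):
            clustering_permutation_test(a, n_perm=10, seed=0)

    def test_degs_confined_to_small_tads_give_p_zero(self):
        # all DEGs packed into the gene-sparsest 10% of TADs
        sizes = [5] * 2 + [20] * 18
        degs = [5, 5] + [0] * 18
        a = _assignment(sizes, degs)
        res = clustering_permutation_test(a, n_perm=1000, seed=7)
        assert res.p == 0.0
        assert res.observed > res.null.max()

    def test_matches_exhaustive_enumeration_on_tiny_instance(self, two_tad_assignment):
        # 6 genes, 2 TADs, 2 DEGs: C(6,2)=15 labelings enumerable exactly
        obs, p_exact = exhaustive_clustering_p([4, 2], [0, 2], 2)
        res = clustering_permutation_test(two_tad_assignment, n_perm=4000, seed=1)
        assert res.observed == pytest.approx(obs)
        se = np.sqrt(p_exact * (1 - p_exact) / 4000)
        assert abs(res.p - p_exact) < 4 * se + 1e-9

    @pytest.mark.parametrize("sizes,degs,n_deg", [
        ([3, 3], [2, 0], 2),
        ([2, 2, 2], [1, 1, 1], 3),
        ([4, 2, 2], [0, 2, 1], 3),
    ])
    def test_enumeration_oracle_suite_small_instances(self, sizes, degs, n_deg):
        a = _assignment(sizes, degs)
        obs, p_exact = exhaustive_clustering_p(sizes, degs, n_deg)
        res = clustering_permutation_test(a, n_perm=3000, seed=5)
        assert res.observed == pytest.approx(obs)
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-4) / 3000)
        assert abs(res.p - p_exact) < 4 * se

    def test_null_mean_is_global_fraction_for_equal_tads(self):
        # hypergeometric expectation: with equal TAD sizes the statistic is
        # constant at the global DEG fraction for every labeling
        a = _assignment([5, 5, 5, 5], [3, 0, 2, 1])
        res = clustering_permutation_test(a, n_perm=200, seed=3)
        assert np.allclose(res.null, 100.0 * 6 / 20)
        assert res.observed == pytest.approx(100.0 * 6 / 20)

    def test_bitwise_reproducible(self, two_tad_assignment):
        r1 = clustering_permutation_test(two_tad_assignment, n_perm=100, seed=42)
        r2 = clustering_permutation_test(two_tad_assignment, n_perm=100, seed=42)
        assert r1.p == r2.p and np.array_equal(r1.null, r2.null)

    def test_add_one_estimator_never_zero(self, two_tad_assignment):
        res = clustering_permutation_test(
            two_tad_assignment, n_perm=100, seed=0, estimator="add_one"
        )
        assert 0 < res.p <= 1


class TestCoordinationScore:
    @pytest.mark.parametrize(
        "directions,expected",
        [
            (["down"] * 6, 100.0),
            (["up", "down"], 50.0),
            (["up", "up", "up", "down"], 75.0),
            (["up"] * 9, 100.0),
        ],
    )
    def test_majority_fraction(self, directions, expected):
        assert coordination_score(directions) == expected

    def test_needs_two_directions(self):
        with pytest.raises(ValueError):
            coordination_score(["up"])

    @given(st.lists(st.sampled_from(["up", "down"]), min_size=2, max_size=12))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_bounds_and_unanimity(self, directions):
        s = coordination_score(directions)
        assert 50.0 <= s <= 100.0
        assert (s == 100.0) == (len(set(directions)) == 1)


class TestAverageCoordination:
    def test_scores_average_and_bins(self):
        a = _assignment([3, 2], [3, 2], directions=["up", "up", "up", "up", "down"])
        prof = average_coordination(a)
        assert sorted(prof.scores) == [50.0, 100.0]
        assert prof.average == 75.0
        assert prof.bin_counts == {"50-60": 1, "60-70": 0, "70-80": 0, "80-90": 0, "90-100": 1}

    def test_single_deg_tads_excluded(self):
        a = _assignment([3, 2], [1, 2], directions=["up", "up", "down"])
        prof = average_coordination(a)
        assert len(prof.scores) == 1

    def test_no_eligible_tad_is_error(self):
        a = _assignment([3, 2], [1, 0], directions=["up"])
        with pytest.raises(ValueError, match="at least 2"):
            average_coordination(a)

    def test_full_coordination_generator_closure(self):
        tads, txs = simulate_genome(GenomeSimSpec(n_tads=20, genes_per_tad=5, seed=21))
        degs = simulate_deg_table(
            txs, tads, DEGSimSpec(deg_rate=0.5, coordination=1.0, seed=22)
        )
        a = assign_to_tads(
            [t for t in txs if t.transcript_id.endswith(".T1")], tads,
            {r.gene_id: r for r in degs},
        )
        assert average_coordination(a).average == 100.0


class TestCoordinationPermutation:
    def test_all_same_direction_p_one_with_warning(self, caplog):
        a = _assignment([3, 2], [3, 2], directions=["up"] * 5)
        with caplog.at_level("WARNING"):
            res = coordination_permutation_test(a, n_perm=50, seed=0)
        assert res.p == 1.0 and res.observed == 100.0
        assert "cannot vary" in caplog.text

    def test_matches_exhaustive_direction_enumeration(self):
        # two TADs of two DEGs each, directions (up,up) and (down,down):
        # 4!/(2!2!)=6 distinct arrangements, enumerable exactly
        a = _assignment([2, 2], [2, 2], directions=["up", "up", "down", "down"])
        obs, p_exact = exhaustive_coordination_p([0, 0, 1, 1], ["up", "up", "down", "down"])
        res = coordination_permutation_test(a, n_perm=3000, seed=9)
        assert res.observed == pytest.approx(obs) == 100.0
        se = np.sqrt(p_exact * (1 - p_exact) / 3000)
        assert abs(res.p - p_exact) < 4 * se

    def test_split_arrangement_oracle(self):
        a = _assignment([2, 2], [2, 2], directions=["up", "down", "up", "down"])
        obs, p_exact = exhaustive_coordination_p([0, 0, 1, 1], ["up", "down", "up", "down"])
        res = coordination_permutation_test(a, n_perm=3000, seed=10)
        assert res.observed == pytest.approx(obs) == 50.0
        assert p_exact == 1.0  # 50% is the floor: every arrangement >= it
        assert res.p == 1.0

    def test_strong_coordination_gives_p_zero(self):
        tads, txs = simulate_genome(GenomeSimSpec(n_tads=60, genes_per_tad=6, seed=31))
        degs = simulate_deg_table(
            txs, tads, DEGSimSpec(deg_rate=0.6, coordination=0.95, seed=32)
        )
        a = assign_to_tads(
            [t for t in txs if t.transcript_id.endswith(".T1")], tads,
            {r.gene_id: r for r in degs},
        )
        res = coordination_permutation_test(a, n_perm=1000, seed=33)
        assert res.p == 0.0


class TestBinComparison:
    def _profile(self, scores):
        from tadcoord.tadstats import _bin_scores

        arr = np.asarray(scores, dtype=float)
        return CoordinationProfile([], arr, float(arr.mean()), _bin_scores(arr))

    def test_extreme_enrichment(self):
        observed = self._profile([95.0, 92.0, 100.0])
        nulls = [self._profile([55.0, 52.0, 58.0]) for _ in range(20)]
        report = coordination_bin_comparison(observed, nulls)
        assert report["90-100"]["p_enrich"] == 0.0
        assert report["50-60"]["p_deplete"] == 0.0

    def test_observed_from_null_is_unremarkable(self):
        rng = np.random.default_rng(0)
        draws = [self._profile(rng.uniform(50, 100, size=30)) for _ in range(101)]
        report = coordination_bin_comparison(draws[0], draws[1:])
        for b in report.values():
            assert b["p_enrich"] > 0.05 and b["p_deplete"] > 0.05

    def test_degenerate_single_bin_null(self):
        observed = self._profile([55.0] * 3)
        nulls = [self._profile([55.0] * 3) for _ in range(10)]
        report = coordination_bin_comparison(observed, nulls)
        assert report["50-60"]["p_enrich"] == 1.0 and report["50-60"]["p_deplete"] == 1.0
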