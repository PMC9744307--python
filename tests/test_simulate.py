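import numpy as np
import pytest

from tadcoord.core import TranscriptRecord
from tadcoord.simulate import (
    DEGSimSpec,
    GenomeSimSpec,
    confined_deg_genome,
    simulate_deg_table,
    simulate_double_kd,
    simulate_fish_alleles,
    simulate_genome,
    simulate_proseq_track,
    _gene_loci,
)
from tadcoord.tadstats import assign_to_tads, average_coordination
from tadcoord.tss import call_genes


class TestSimulateGenome:
    def test_structure(self):
        tads, txs = simulate_genome(GenomeSimSpec(n_tads=2, genes_per_tad=3, seed=1))
        assert len(tads) == 2
        genes = _gene_loci(txs)
        assert 1 <= len(genes) <= 12
        # every gene TSS strictly inside exactly one TAD
        for g in genes:
            hits = [t for t in tads if t.start < g.tss < t.end - 1 or t.contains(g.tss)]
            assert len(hits) == 1
        # 1-3 transcripts per gene
        per_gene = {}
        for t in txs:
            per_gene.setdefault(t.gene_id, []).append(t)
        assert all(1 <= len(v) <= 3 for v in per_gene.values())

    def test_deterministic(self):
        spec = GenomeSimSpec(n_tads=4, genes_per_tad=3, seed=9)
        assert simulate_genome(spec) == simulate_genome(spec)

    def test_sparse_genome_exercises_empty_tads(self):
        tads, txs = simulate_genome(GenomeSimSpec(n_tads=30, genes_per_tad=1.0, seed=3))
        genes = _gene_loci(txs)
        a = assign_to_tads(genes, tads)
        # with Poisson(1) genes per TAD, some TADs hold fewer than 2 genes
        sizes = a.tad_sizes()
        assert (sizes < 2).any() or a.n_tads < 30

    def test_tads_are_a_partition_with_gap(self):
        tads, _ = simulate_genome(GenomeSimSpec(n_tads=5, genes_per_tad=2, inter_tad_gap_bp=5000, seed=2))
        for prev, nxt in zip(tads, tads[1:]):
            assert nxt.start - prev.end == 5000

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            GenomeSimSpec(n_tads=0)


class TestSimulateDegTable:
    def _genome(self, seed=5, n_tads=40, gpt=5):
        return simulate_genome(GenomeSimSpec(n_tads=n_tads, genes_per_tad=gpt, seed=seed))

    def test_marginal_deg_count_exact(self):
        tads, txs = self._genome()
        n_genes = len(_gene_loci(txs))
        degs = simulate_deg_table(txs, tads, DEGSimSpec(deg_rate=0.25, seed=6))
        assert sum(r.is_deg for r in degs) == round(0.25 * n_genes)
        assert len(degs) == n_genes

    def test_padj_straddles_threshold(self):
        tads, txs = self._genome()
        degs = simulate_deg_table(txs, tads, DEGSimSpec(deg_rate=0.3, seed=7), alpha=0.01)
        for r in degs:
            assert (r.padj <= 0.01) == r.is_deg

    def test_full_coordination_forces_unanimous_tads(self):
        tads, txs = self._genome()
        degs = simulate_deg_table(txs, tads, DEGSimSpec(deg_rate=0.5, coordination=1.0, seed=8))
        a = assign_to_tads(_gene_loci(txs), tads, {r.gene_id: r for r in degs})
        assert np.all(average_coordination(a).scores == 100.0)

    def test_deterministic(self):
        tads, txs = self._genome()
        spec = DEGSimSpec(deg_rate=0.2, seed=11)
        assert simulate_deg_table(txs, tads, spec) == simulate_deg_table(txs, tads, spec)

    def test_clustering_weight_concentrates_degs(self):
        tads, txs = self._genome(n_tads=50, gpt=6)
        flat = simulate_deg_table(txs, tads, DEGSimSpec(deg_rate=0.2, clustering_weight=1.0, seed=12))
        hot = simulate_deg_table(
            txs, tads, DEGSimSpec(deg_rate=0.2, clustering_weight=50.0, hot_tad_fraction=0.1, seed=12)
        )

        def tads_hit(degs):
            a = assign_to_tads(_gene_loci(txs), tads, {r.gene_id: r for r in degs})
            hits = {t for t, lab in zip(a.tad_index, a.labels) if lab}
            return len(hits)

        assert tads_hit(hot) < tads_hit(flat)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            DEGSimSpec(deg_rate=0.0)
        with pytest.raises(ValueError):
            DEGSimSpec(deg_rate=0.2, coordination=0.4)
        with pytest.raises(ValueError):
            DEGSimSpec(deg_rate=0.2, clustering_weight=0.5)


class TestSimulateDoubleKd:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            simulate_double_kd([], 0.7, 0.4)

    def test_partial_rescue_preserves_sign_and_shrinks(self):
        tads, txs = simulate_genome(GenomeSimSpec(n_tads=20, genes_per_tad=5, seed=13))
        single = simulate_deg_table(txs, tads, DEGSimSpec(deg_rate=0.5, seed=14))
        double = simulate_double_kd(single, 0.0, 1.0, seed=15)
        for s, d in zip(single, double):
            if s.is_deg:
                assert d.is_deg and d.direction == s.direction
                assert abs(d.log2fc) < abs(s.log2fc)


class TestSimulateProseq:
    def test_inactive_windows_stay_below_threshold(self):
        tads, txs = simulate_genome(GenomeSimSpec(n_tads=10, genes_per_tad=4, seed=16))
        track = simulate_proseq_track(txs, active_fraction=0.0, mean_count=50, seed=17)
        calls, inactive = call_genes(track, txs)
        assert calls == []

    def test_counts_land_in_the_promoter_window(self):
        txs = [TranscriptRecord("G1", "G1.T1", "chr1", 10_000, "+", 1000)]
        track = simulate_proseq_track(txs, active_fraction=1.0, mean_count=200, seed=18)
        inside = track.window_sum("+", "chr1", 10_000, 10_150)
        assert inside == track.total() and inside > 0

    def test_minus_strand_window_direction(self):
        txs = [TranscriptRecord("G1", "G1.T1", "chr1", 10_000, "-", 1000)]
        track = simulate_proseq_track(txs, active_fraction=1.0, mean_count=200, seed=19)
        assert track.window_sum("-", "chr1", 9_850, 10_000) == track.total()

    def test_deterministic(self):
        tads, txs = simulate_genome(GenomeSimSpec(n_tads=5, genes_per_tad=3, seed=20))
        t1 = simulate_proseq_track(txs, 0.5, 100, seed=21)
        t2 = simulate_proseq_track(txs, 0.5, 100, seed=21)
        assert t1 == t2


class TestConfinedDegGenome:
    def test_deg_placement(self):
        tads, loci, degs = confined_deg_genome(n_tads=20, seed=22)
        a = assign_to_tads(loci, tads, degs)
        deg_tads = {t for t, lab in zip(a.tad_index, a.labels) if lab}
        assert len(deg_tads) == 2  # 10% of 20
        sizes = a.tad_sizes()
        # the DEG-designated TADs are the gene-sparse ones
        assert all(sizes[t] == min(sizes) for t in deg_tads)

    def test_every_confined_gene_is_deg(self):
        tads, loci, degs = confined_deg_genome(n_tads=20, seed=23)
        a = assign_to_tads(loci, tads, degs)
        deg_tads = {t for t, lab in zip(a.tad_index, a.labels) if lab}
        for t, lab in zip(a.tad_index, a.labels):
            assert lab == (t in deg_tads)


class TestSimulateLoops:
    def test_anchors_land_near_the_designated_tss_fraction(self):
        from tadcoord.enrich import nearest_anchor_distance, proximity_enrichment
        from tadcoord.simulate import simulate_loops

        tads, txs = simulate_genome(GenomeSimSpec(n_tads=60, genes_per_tad=6, seed=40))
        degs = simulate_deg_table(txs, tads, DEGSimSpec(deg_rate=0.3, seed=41))
        by_gene = {r.gene_id: r for r in degs}
        loci = _gene_loci(txs)
        loops = simulate_loops(loci, by_gene, frac_deg_near=0.6, frac_nondeg_near=0.05, seed=42)
        deg_d = [nearest_anchor_distance(g.chrom, g.tss, loops)
                 for g in loci if by_gene[g.gene_id].is_deg]
        non_d = [nearest_anchor_distance(g.chrom, g.tss, loops)
                 for g in loci if not by_gene[g.gene_id].is_deg]
        res = proximity_enrichment(deg_d, non_d, threshold=5000)
        assert res.odds_ratio > 1 and res.p < 0.01

    def test_deterministic(self):
        from tadcoord.simulate import simulate_loops

        tads, txs = simulate_genome(GenomeSimSpec(n_tads=10, genes_per_tad=4, seed=43))
        degs = {r.gene_id: r for r in simulate_deg_table(txs, tads, DEGSimSpec(deg_rate=0.3, seed=44))}
        assert simulate_loops(txs, degs, seed=45) == simulate_loops(txs, degs, seed=45)


def test_fish_generator_determinism():
    a = simulate_fish_alleles(100, 0.5, seed=30)
    b = simulate_fish_alleles(100, 0.5, seed=30)
    assert a == b
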