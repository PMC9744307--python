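#!/usr/bin/env python
"""Generate every input the downstream analyses consume.

Emulates, at desk scale, a two-knockdown nascent-transcription study:
a TAD partition with a gene annotation, per-condition differential-
expression tables with within-TAD clustering and directional
coordination, strand-separated 3'-end signal, chromatin loops enriched
near DEG TSSs, a co-depletion (double-knockdown) table, and per-allele
FISH sphere geometries for control and knockdown conditions.
Everything is written as plain text under results/inputs/.
"""

from pathlib import Path

from tadcoord.io import write_deg_table, write_intervals, write_signal, write_transcript_table
from tadcoord.simulate import (
    DEGSimSpec,
    GenomeSimSpec,
    simulate_deg_table,
    simulate_double_kd,
    simulate_fish_alleles,
    simulate_genome,
    simulate_loops,
    simulate_proseq_track,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 20260918


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    tads, transcripts = simulate_genome(
        GenomeSimSpec(n_tads=100, genes_per_tad=6, seed=SEED)
    )
    n_genes = len({t.gene_id for t in transcripts})
    print(f"genome: {len(tads)} TADs, {n_genes} genes, {len(transcripts)} transcripts")
    write_intervals(OUT / "tads.bed", tads)
    write_transcript_table(OUT / "transcripts.tsv", transcripts)

    # the two single knockdowns: clustered, coordinated misexpression
    deg_a = simulate_deg_table(
        transcripts, tads,
        DEGSimSpec(deg_rate=0.25, clustering_weight=8.0, coordination=0.85, seed=SEED + 1),
    )
    deg_b = simulate_deg_table(
        transcripts, tads,
        DEGSimSpec(deg_rate=0.25, clustering_weight=8.0, coordination=0.85, seed=SEED + 2),
    )
    write_deg_table(OUT / "degs_kd_a.tsv", deg_a)
    write_deg_table(OUT / "degs_kd_b.tsv", deg_b)
    print(f"knockdown A: {sum(r.is_deg for r in deg_a)} DEGs; "
          f"knockdown B: {sum(r.is_deg for r in deg_b)} DEGs")

    # co-depletion rescues most of knockdown A's DEGs
    double = simulate_double_kd(deg_a, frac_full=0.625, frac_partial=0.22, seed=SEED + 3)
    write_deg_table(OUT / "degs_double_kd.tsv", double)

    # 3'-end signal: most genes transcriptionally active
    track = simulate_proseq_track(transcripts, active_fraction=0.9, mean_count=80, seed=SEED + 4)
    write_signal(track, OUT / "proseq_plus.bedgraph", OUT / "proseq_minus.bedgraph")
    print(f"signal track: {track.total()} 3'-end counts")

    # loops enriched near DEG promoters
    loops = simulate_loops(
        transcripts, {r.gene_id: r for r in deg_a},
        frac_deg_near=0.35, frac_nondeg_near=0.15, seed=SEED + 5,
    )
    write_intervals(OUT / "loops.bedpe", loops)
    print(f"loops: {len(loops)}")

    # FISH alleles: knockdown of the loader lowers cross-boundary contact
    with open(OUT / "fish_alleles.tsv", "w") as fh:
        fh.write("allele_id\tcondition\tax\tay\taz\tra\tbx\tby\tbz\trb\n")
        for cond, prob, seed in (("control", 0.55, SEED + 6), ("kd_a", 0.35, SEED + 7)):
            for m in simulate_fish_alleles(1200, prob, seed=seed, condition=cond):
                fh.write(
                    f"{m.allele_id}\t{m.condition}\t"
                    + "\t".join(f"{v:.1f}" for v in (*m.center_a, m.radius_a, *m.center_b, m.radius_b))
                    + "\n"
                )
    print(f"wrote inputs under {OUT}")


if __name__ == "__main__":
    main()
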