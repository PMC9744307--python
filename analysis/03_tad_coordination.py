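#!/usr/bin/env python
"""Are DEGs clustered within TADs, and do TAD-mates change together?

For each knockdown: assign active genes to TADs, measure the average
per-TAD DEG percentage against 1,000 label shuffles, then the average
coordination score (majority direction fraction over TADs with >= 2
DEGs) against 1,000 direction shuffles, and compare binned coordination
scores to the null.  Writes results/tad_statistics.json.
"""

import json
from pathlib import Path

import numpy as np

from tadcoord.io import read_deg_table, read_intervals
from tadcoord.simulate import GeneLocus
from tadcoord.tadstats import (
    TADAssignment,
    assign_to_tads,
    average_coordination,
    clustering_permutation_test,
    coordination_bin_comparison,
    coordination_permutation_test,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
N_PERM = 1000
SEED = 7


def active_gene_loci():
    loci = []
    with open(ROOT / "tss_calls.tsv") as fh:
        next(fh)
        for line in fh:
            gid, _tid, chrom, tss, _strand, _count = line.rstrip("\n").split("\t")
            loci.append(GeneLocus(gid, chrom, int(tss)))
    return loci


def analyse(label: str, deg_path: Path, tads, loci) -> dict:
    degs = {r.gene_id: r for r in read_deg_table(deg_path, alpha=0.01)}
    a = assign_to_tads(loci, tads, degs)
    n_deg = int(a.labels.sum())
    clust = clustering_permutation_test(a, n_perm=N_PERM, seed=SEED)
    coord = coordination_permutation_test(a, n_perm=N_PERM, seed=SEED + 1)
    profile = average_coordination(a)

    # binned comparison against direction-shuffle null profiles
    rng = np.random.default_rng(SEED + 2)
    codes = np.array([1 if d == "up" else 0 for lab, d in zip(a.labels, a.directions) if lab])
    nulls = []
    for _ in range(200):
        it = iter(rng.permutation(codes))
        b_dirs = [("up" if next(it) else "down") if lab else None for lab in a.labels]
        b = TADAssignment(a.gene_ids, a.tad_index, a.labels, b_dirs, a.tad_ids)
        nulls.append(average_coordination(b))
    bins = coordination_bin_comparison(profile, nulls)

    frac_unanimous = float(np.mean(profile.scores == 100.0))
    print(f"[{label}] {n_deg} DEGs in {a.n_tads} TADs; "
          f"clustering {clust.observed:.2f}% vs null mean {clust.null.mean():.2f}% (p={clust.p}); "
          f"coordination {coord.observed:.1f}% vs null mean {coord.null.mean():.1f}% (p={coord.p}); "
          f"{100 * frac_unanimous:.0f}% of eligible TADs fully coordinated")
    return {
        "n_deg": n_deg,
        "clustering": {"observed": clust.observed, "null_mean": float(clust.null.mean()), "p": clust.p},
        "coordination": {"observed": coord.observed, "null_mean": float(coord.null.mean()), "p": coord.p},
        "bin_comparison": bins,
        "fraction_fully_coordinated_tads": frac_unanimous,
    }


def main() -> None:
    tads = read_intervals(ROOT / "inputs" / "tads.bed", "BED")
    loci = active_gene_loci()
    report = {
        "kd_a": analyse("kd_a", ROOT / "inputs" / "degs_kd_a.tsv", tads, loci),
        "kd_b": analyse("kd_b", ROOT / "inputs" / "degs_kd_b.tsv", tads, loci),
    }
    out = ROOT / "tad_statistics.json"
    out.write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
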