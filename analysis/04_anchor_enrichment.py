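#!/usr/bin/env python
"""Are DEG promoters preferentially near loop anchors, and do the two
knockdowns hit overlapping gene sets?

Computes TSS-to-nearest-anchor distances, Fisher tests of the <=5 kb and
<=200 kb proximity fractions (DEGs vs non-DEGs), the Spearman
correlation of anchor distance with |log2 fold change| among DEGs, the
fixed-universe overlap test between the two DEG sets, and their
direction concordance.  Writes results/enrichment.json.
"""

import json
from pathlib import Path

from tadcoord.core import AnalysisConfig
from tadcoord.enrich import (
    distance_fc_correlation,
    fisher_overlap,
    nearest_anchor_distance,
    proximity_enrichment,
    shared_direction,
)
from tadcoord.io import read_deg_table, read_intervals
from tadcoord.simulate import GeneLocus

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = AnalysisConfig()
    loops = read_intervals(ROOT / "inputs" / "loops.bedpe", "BEDPE")
    degs_a = {r.gene_id: r for r in read_deg_table(ROOT / "inputs" / "degs_kd_a.tsv")}
    degs_b = {r.gene_id: r for r in read_deg_table(ROOT / "inputs" / "degs_kd_b.tsv")}

    loci = []
    with open(ROOT / "tss_calls.tsv") as fh:
        next(fh)
        for line in fh:
            gid, _tid, chrom, tss, *_ = line.rstrip("\n").split("\t")
            loci.append(GeneLocus(gid, chrom, int(tss)))

    dist = {g.gene_id: nearest_anchor_distance(g.chrom, g.tss, loops) for g in loci}
    deg_d = [dist[g] for g in dist if degs_a[g].is_deg]
    non_d = [dist[g] for g in dist if not degs_a[g].is_deg]

    report = {}
    for label, kb in (("near", cfg.anchor_near_kb), ("far", cfg.anchor_far_kb)):
        res = proximity_enrichment(deg_d, non_d, threshold=kb * 1000)
        frac_deg = 100.0 * res.table.a / (res.table.a + res.table.b)
        frac_non = 100.0 * res.table.c / (res.table.c + res.table.d)
        report[f"proximity_{label}"] = {
            "threshold_kb": kb, "deg_pct": frac_deg, "nondeg_pct": frac_non,
            "odds_ratio": res.odds_ratio, "p_one_greater": res.p,
        }
        print(f"<= {kb:g} kb of an anchor: {frac_deg:.1f}% of DEGs vs "
              f"{frac_non:.1f}% of non-DEGs (OR {res.odds_ratio:.2f}, one-tailed p {res.p:.3g})")

    pairs = [(dist[g], degs_a[g].log2fc) for g in dist
             if degs_a[g].is_deg and dist[g] is not None]
    rho, p = distance_fc_correlation(*zip(*pairs))
    report["distance_fc_spearman"] = {"rho": rho, "p": p, "n": len(pairs)}
    print(f"anchor distance vs |log2FC| among DEGs: Spearman rho {rho:.3f}, p {p:.3g} (n={len(pairs)})")

    set_a = {g for g, r in degs_a.items() if r.is_deg}
    set_b = {g for g, r in degs_b.items() if r.is_deg}
    ov = fisher_overlap(len(set_a), len(set_b), len(set_a & set_b), cfg.universe_size)
    n_shared, n_same, frac = shared_direction(degs_a, degs_b)
    report["set_overlap"] = {
        "n_a": len(set_a), "n_b": len(set_b), "n_overlap": len(set_a & set_b),
        "universe": cfg.universe_size, "p_one_tailed": ov.p,
    }
    report["shared_direction"] = {"n_shared": n_shared, "n_same": n_same, "fraction": frac}
    print(f"DEG set overlap: {len(set_a & set_b)} of {len(set_a)}/{len(set_b)} "
          f"(universe {cfg.universe_size}), one-tailed p {ov.p:.3g}")
    print(f"shared DEGs changed in the same direction: {n_same}/{n_shared} "
          f"({100 * frac:.0f}%)" if frac is not None else "no shared DEGs")

    out = ROOT / "enrichment.json"
    out.write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
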