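import pytest

from tadcoord.core import GenomicInterval, make_deg_record
from tadcoord.simulate import GeneLocus
from tadcoord.tadstats import assign_to_tads


@pytest.fixture
def two_tad_assignment():
    """6 genes in 2 TADs (sizes 4 and 2), 2 DEGs both in the small TAD."""
    tads = [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 1000, 2000)]
    loci = [GeneLocus(f"G{i}", "chr1", p) for i, p in enumerate([100, 300, 500, 700, 1100, 1500])]
    degs = {
        "G4": make_deg_record("G4", 1.0, 0.001, 0.01),
        "G5": make_deg_record("G5", -1.0, 0.001, 0.01),
    }
    return assign_to_tads(loci, tads, degs)


def exhaustive_clustering_p(tad_sizes, deg_counts_observed, n_deg):
    """Exact percentile-rank p for the clustering statistic by enumerating
    every placement of n_deg labels over the genes (independent oracle:
    plain-Python statistic, full enumeration)."""
    import itertools

    genes = []
    for t, size in enumerate(tad_sizes):
        genes.extend([t] * size)
    n = len(genes)

    def stat(deg_positions):
        per_tad = [0] * len(tad_sizes)
        for i in deg_positions:
            per_tad[genes[i]] += 1
        fracs = [100.0 * d / s for d, s in zip(per_tad, tad_sizes)]
        return sum(fracs) / len(fracs)

    observed_positions = []
    i = 0
    for t, (size, d) in enumerate(zip(tad_sizes, deg_counts_observed)):
        observed_positions.extend(range(i, i + d))
        i += size
    obs = stat(observed_positions)
    values = [stat(c) for c in itertools.combinations(range(n), n_deg)]
    return obs, sum(v >= obs - 1e-9 for v in values) / len(values)


def exhaustive_coordination_p(tad_of_deg, directions):
    """Exact p for average coordination by enumerating every arrangement
    of the direction multiset over the DEG slots."""
    import itertools

    n_tads = max(tad_of_deg) + 1

    def avg(dirs):
        scores = []
        for t in range(n_tads):
            ds = [d for td, d in zip(tad_of_deg, dirs) if td == t]
            if len(ds) >= 2:
                up = sum(d == "up" for d in ds)
                scores.append(100.0 * max(up, len(ds) - up) / len(ds))
        return sum(scores) / len(scores)

    obs = avg(directions)
    # every arrangement (permutation) of the slots is equally likely, so
    # enumerate all of them rather than only distinct multiset orders
    values = [avg(p) for p in itertools.permutations(directions)]
    return obs, sum(v >= obs - 1e-9 for v in values) / len(values)


def hypergeom_tail_enumeration(n_a, n_b, overlap, universe):
    """Upper-tail overlap probability by direct hypergeometric summation."""
    from math import comb

    total = comb(universe, n_b)
    return sum(
        comb(n_a, k) * comb(universe - n_a, n_b - k)
        for k in range(overlap, min(n_a, n_b) + 1)
    ) / total
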