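"""Loop-anchor proximity enrichment, distance-fold-change correlation,
and fixed-universe gene-set overlap tests.

Anchor distance is measured TSS-to-interval-edge with inside = 0, the
strictest reading of "within N kb of a loop anchor".  Set overlaps use a
one-tailed (enrichment) Fisher exact test against a fixed background
universe of genes that could appear on either list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import DEGRecord, Loop

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "nearest_anchor_distance",
    "proximity_enrichment",
    "distance_fc_correlation",
    "fisher_overlap",
    "shared_direction",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable2x2
    odds_ratio: float
    p: float
    tail: str  # one_greater / two_sided
    p_two_sided: float | None = None


def nearest_anchor_distance(chrom: str, tss: int, loops: Sequence[Loop]) -> float | None:
    """bp distance from a TSS to the nearest loop-anchor interval.

    Zero when the TSS lies inside an anchor, else the gap to the nearer
    edge (last base for downstream anchors, since intervals are
    half-open).  None when the chromosome carries no loop.
    """
    best: float | None = None
    for loop in loops:
        if loop.anchor_a.chrom != chrom:
            continue
        for anchor in loop.anchors:
            if anchor.contains(tss):
                return 0.0
            gap = float(anchor.start - tss) if tss < anchor.start else float(tss - (anchor.end - 1))
            if best is None or gap < best:
                best = gap
    return best


def proximity_enrichment(
    group_a_distances: Sequence[float],
    group_b_distances: Sequence[float],
    threshold: float,
) -> EnrichmentResult:
    """Fisher exact test on near/far counts at ``threshold`` bp.

    Each group is dichotomized at distance <= threshold; missing
    distances (no loop on the chromosome) count as far.
    """
    if len(group_a_distances) == 0 or len(group_b_distances) == 0:
        raise ValueError("both groups must be non-empty")

    def _near(ds):
        return sum(1 for d in ds if d is not None and not math.isnan(d) and d <= threshold)

    a_near = _near(group_a_distances)
    b_near = _near(group_b_distances)
    table = ContingencyTable2x2(
        a_near, len(group_a_distances) - a_near, b_near, len(group_b_distances) - b_near
    )
    odds, p_greater = stats.fisher_exact(table.as_array(), alternative="greater")
    _, p_two = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return EnrichmentResult(table, float(odds), float(p_greater), "one_greater", float(p_two))


def distance_fc_correlation(
    distances: Sequence[float], log2fcs: Sequence[float], signed: bool = False
) -> tuple[float, float]:
    """Spearman correlation of anchor distance against fold change.

    By default the magnitude |log2fc| is used (the monotone notion behind
    "genes closer to anchors tend to have a greater fold change"); pass
    signed=True for the raw values.  Returns (rho, two-sided p).
    """
    d = np.asarray(distances, dtype=float)
    f = np.asarray(log2fcs, dtype=float)
    if d.size != f.size:
        raise ValueError("distances and fold changes differ in length")
    if d.size < 4:
        raise ValueError("need at least 4 pairs")
    if not signed:
        f = np.abs(f)
    if np.all(d == d[0]) or np.all(f == f[0]):
        raise ValueError("constant input: rank correlation undefined")
    res = stats.spearmanr(d, f)
    return float(res.statistic), float(res.pvalue)


def fisher_overlap(n_a: int, n_b: int, n_overlap: int, universe: int = 20000) -> EnrichmentResult:
    """One-tailed Fisher exact test for the overlap of two gene sets.

    The 2x2 table is (shared, A-only, B-only, neither) over a fixed
    background universe; p is the upper hypergeometric tail (enrichment).
    """
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap exceeds a set size")
    if min(n_a, n_b, n_overlap) < 0:
        raise ValueError("set sizes must be non-negative")
    if n_a + n_b - n_overlap > universe:
        raise ValueError("sets do not fit in the universe")
    table = ContingencyTable2x2(
        n_overlap, n_a - n_overlap, n_b - n_overlap, universe - n_a - n_b + n_overlap
    )
    p = float(stats.hypergeom.sf(n_overlap - 1, universe, n_a, n_b))
    arr = table.as_array()
    odds = math.inf
    if arr[0, 1] * arr[1, 0] > 0:
        odds = float(arr[0, 0] * arr[1, 1] / (arr[0, 1] * arr[1, 0]))
    return EnrichmentResult(table, odds, p, "one_greater")


def shared_direction(
    degs_a: dict[str, DEGRecord], degs_b: dict[str, DEGRecord]
) -> tuple[int, int, float | None]:
    """Concordance of shared DEGs between two conditions.

    Returns (#shared DEGs, #changed in the same direction, fraction);
    the fraction is None when the intersection is empty.
    """
    shared = [
        g for g, r in degs_a.items()
        if r.is_deg and g in degs_b and degs_b[g].is_deg
    ]
    same = sum(1 for g in shared if degs_a[g].direction == degs_b[g].direction)
    frac = same / len(shared) if shared else None
    return len(shared), same, frac
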