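"""TAD-level clustering and coordination statistics with label-shuffle nulls.

The clustering statistic is the unweighted mean, over TADs, of the
percentage of each TAD's genes carrying the positive label (DEG among
active genes, or active among all genes).  The coordination score of a
TAD is the majority fraction of its DEG directions: 100 x max(#up,
#down) / #DEGs, so 50% is an even split and 100% is unanimous.

Both observed statistics are compared against nulls built by uniformly
shuffling labels (or directions) across the gene universe while keeping
category counts constant; the p-value is the percentile rank of the
observed value, reported as the raw proportion of null draws at or above
it (it can be exactly 0).

A degeneracy worth knowing about: when every TAD contains the same
number of genes, the mean of per-TAD percentages equals the global
positive fraction for *every* labeling, so the clustering test has no
power there.  Sensitivity comes entirely from covariance between label
placement and per-TAD gene counts (e.g. DEGs concentrating in gene-
sparse TADs); see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import DEGRecord, GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "TADAssignment",
    "PermutationResult",
    "CoordinationProfile",
    "COORDINATION_BINS",
    "assign_to_tads",
    "clustering_statistic",
    "clustering_permutation_test",
    "coordination_score",
    "average_coordination",
    "coordination_permutation_test",
    "coordination_bin_comparison",
]

_DIR_CODE = {"down": 0, "up": 1}


@dataclass
class TADAssignment:
    """Genes partitioned into non-overlapping TADs, with binary labels.

    ``tad_index[i]`` is the retained-TAD index of assigned gene i;
    ``labels[i]`` its positive-label status; ``directions[i]`` its DEG
    direction ("up"/"down") or None.  Genes falling outside every TAD are
    excluded from the statistic but their labels/directions still join
    the shuffle universe (the study shuffles across all genes).
    """

    gene_ids: list[str]
    tad_index: np.ndarray
    labels: np.ndarray
    directions: list[str | None]
    tad_ids: list[str]
    excluded_gene_ids: list[str] = field(default_factory=list)
    excluded_labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    excluded_directions: list[str | None] = field(default_factory=list)

    @property
    def n_tads(self) -> int:
        return len(self.tad_ids)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_gene_ids)

    def tad_sizes(self) -> np.ndarray:
        return np.bincount(self.tad_index, minlength=self.n_tads)


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    n_perm: int
    seed: int


@dataclass
class CoordinationProfile:
    """Per-TAD coordination scores over TADs with enough DEGs."""

    tad_ids: list[str]
    scores: np.ndarray  # percent, each in [50, 100]
    average: float
    bin_counts: dict[str, int]


COORDINATION_BINS = ("50-60", "60-70", "70-80", "80-90", "90-100")
_BIN_UPPER = (60.0, 70.0, 80.0, 90.0, 100.0)


def _bin_scores(scores: np.ndarray) -> dict[str, int]:
    # five 10-point bins, upper-inclusive; 50 falls in the first bin
    counts = dict.fromkeys(COORDINATION_BINS, 0)
    for s in scores:
        for name, upper in zip(COORDINATION_BINS, _BIN_UPPER):
            if s <= upper + 1e-9:
                counts[name] += 1
                break
    return counts


def _check_non_overlapping(tads: Sequence[GenomicInterval]) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for i, t in enumerate(tads):
        by_chrom.setdefault(t.chrom, []).append((i, t))
    index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, items in by_chrom.items():
        items.sort(key=lambda it: it[1].start)
        prev = None
        for _, t in items:
            if prev is not None and t.start < prev.end:
                raise ValueError(
                    f"overlapping TADs on {chrom}: [{prev.start},{prev.end}) and "
                    f"[{t.start},{t.end})"
                )
            prev = t
        starts = np.array([t.start for _, t in items])
        ends = np.array([t.end for _, t in items])
        idx = np.array([i for i, _ in items])
        index[chrom] = (starts, ends, idx)
    return index


def assign_to_tads(
    genes: Sequence,
    tads: Sequence[GenomicInterval],
    degs: dict[str, DEGRecord] | None = None,
    label_of: Callable | None = None,
) -> TADAssignment:
    """Assign genes (anything with gene_id/chrom/tss attributes, e.g. a
    dominant-TSS call) to the TAD containing the TSS.

    The positive label defaults to DEG status from ``degs``; pass
    ``label_of`` to label by something else (e.g. transcriptional
    activity over all genes).  TADs with no assigned gene are dropped;
    genes outside every TAD are excluded but remembered for shuffling.
    """
    index = _check_non_overlapping(tads)

    def _label(g) -> bool:
        if label_of is not None:
            return bool(label_of(g))
        if degs is None:
            return False
        rec = degs.get(g.gene_id)
        return bool(rec is not None and rec.is_deg)

    def _direction(g) -> str | None:
        if degs is None:
            return None
        rec = degs.get(g.gene_id)
        if rec is not None and rec.is_deg:
            return rec.direction
        return None

    raw_tad: list[int] = []
    kept: list = []
    excluded: list = []
    for g in genes:
        tad = -1
        if g.chrom in index:
            starts, ends, idx = index[g.chrom]
            j = int(np.searchsorted(starts, g.tss, side="right")) - 1
            if j >= 0 and g.tss < ends[j]:
                tad = int(idx[j])
        if tad >= 0:
            kept.append(g)
            raw_tad.append(tad)
        else:
            excluded.append(g)

    used = sorted(set(raw_tad))
    remap = {orig: new for new, orig in enumerate(used)}
    tad_ids = [f"{tads[i].chrom}:{tads[i].start}-{tads[i].end}" for i in used]
    return TADAssignment(
        gene_ids=[g.gene_id for g in kept],
        tad_index=np.array([remap[t] for t in raw_tad], dtype=int),
        labels=np.array([_label(g) for g in kept], dtype=bool),
        directions=[_direction(g) for g in kept],
        tad_ids=tad_ids,
        excluded_gene_ids=[g.gene_id for g in excluded],
        excluded_labels=np.array([_label(g) for g in excluded], dtype=bool),
        excluded_directions=[_direction(g) for g in excluded],
    )


def _statistic(tad_index: np.ndarray, labels: np.ndarray, n_tads: int, sizes: np.ndarray) -> float:
    pos = np.bincount(tad_index, weights=labels.astype(float), minlength=n_tads)
    frac = 100.0 * pos / sizes
    return float(frac.mean())


def clustering_statistic(a: TADAssignment) -> float:
    """Unweighted mean over TADs of 100 x (#positive genes / #genes)."""
    if a.n_tads == 0:
        raise ValueError("no TAD with at least one assigned gene")
    return _statistic(a.tad_index, a.labels, a.n_tads, a.tad_sizes())


def clustering_permutation_test(
    a: TADAssignment,
    n_perm: int = 1000,
    seed: int = 0,
    include_unassigned: bool = True,
    estimator: str = "raw",
) -> PermutationResult:
    """Label-shuffle null for the clustering statistic.

    Labels are permuted uniformly over the gene universe (assigned genes
    plus, by default, genes outside every TAD) keeping category counts
    constant; the statistic is recomputed per permutation and p is the
    fraction of null values at or above the observed one (ties count
    toward the tail).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if a.n_tads == 0:
        raise ValueError("no TAD with at least one assigned gene")
    universe = a.labels
    if include_unassigned and a.n_excluded:
        universe = np.concatenate([a.labels, a.excluded_labels])
    if universe.all() or not universe.any():
        raise ValueError("degenerate label set: all genes share one label")
    sizes = a.tad_sizes()
    n_assigned = len(a.labels)
    observed = _statistic(a.tad_index, a.labels, a.n_tads, sizes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(universe)
        null[i] = _statistic(a.tad_index, perm[:n_assigned], a.n_tads, sizes)
    p = _percentile_rank_p(observed, null, estimator)
    return PermutationResult(observed, null, p, n_perm, seed)


def _percentile_rank_p(observed: float, null: np.ndarray, estimator: str) -> float:
    r = int(np.sum(null >= observed - 1e-9))
    if estimator == "raw":
        return r / len(null)
    if estimator == "add_one":
        return (r + 1) / (len(null) + 1)
    raise ValueError(f"unknown estimator {estimator!r}")


def coordination_score(directions: Sequence[str]) -> float:
    """Majority fraction of up/down directions, as a percent in [50, 100]."""
    if len(directions) < 2:
        raise ValueError("coordination needs at least two DEG directions")
    codes = [_DIR_CODE[d] for d in directions]
    n_up = sum(codes)
    return 100.0 * max(n_up, len(codes) - n_up) / len(codes)


def _deg_slots(a: TADAssignment) -> tuple[np.ndarray, np.ndarray]:
    """(tad index, up-code) for each assigned DEG with a direction."""
    tad_idx, codes = [], []
    for t, lab, d in zip(a.tad_index, a.labels, a.directions):
        if lab and d in _DIR_CODE:
            tad_idx.append(t)
            codes.append(_DIR_CODE[d])
    return np.array(tad_idx, dtype=int), np.array(codes, dtype=int)


def _coordination_average(
    tad_idx: np.ndarray, codes: np.ndarray, n_tads: int, min_degs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-eligible-TAD scores and the eligible TAD indices."""
    n_deg = np.bincount(tad_idx, minlength=n_tads)
    eligible = np.flatnonzero(n_deg >= min_degs)
    if eligible.size == 0:
        raise ValueError(f"no TAD with at least {min_degs} DEGs")
    n_up = np.bincount(tad_idx, weights=codes.astype(float), minlength=n_tads)
    maj = np.maximum(n_up, n_deg - n_up)
    scores = 100.0 * maj[eligible] / n_deg[eligible]
    return scores, eligible


def average_coordination(a: TADAssignment, min_degs: int = 2) -> CoordinationProfile:
    """Coordination profile over TADs containing >= ``min_degs`` DEGs.

    The average is the unweighted mean of per-TAD scores; bin counts use
    five upper-inclusive 10-point bins from 50-60 to 90-100.
    """
    tad_idx, codes = _deg_slots(a)
    if tad_idx.size == 0:
        raise ValueError("assignment contains no DEGs with directions")
    scores, eligible = _coordination_average(tad_idx, codes, a.n_tads, min_degs)
    return CoordinationProfile(
        tad_ids=[a.tad_ids[i] for i in eligible],
        scores=scores,
        average=float(scores.mean()),
        bin_counts=_bin_scores(scores),
    )


def coordination_permutation_test(
    a: TADAssignment,
    n_perm: int = 1000,
    seed: int = 0,
    min_degs: int = 2,
    include_unassigned: bool = True,
    estimator: str = "raw",
) -> PermutationResult:
    """Direction-shuffle null for the average coordination.

    Directions (i.e. fold-change signs) are permuted among DEG slots only
    — TAD membership and per-TAD DEG counts stay fixed — and the average
    coordination is recomputed each time.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    tad_idx, codes = _deg_slots(a)
    if tad_idx.size == 0:
        raise ValueError("assignment contains no DEGs with directions")
    pool = codes
    if include_unassigned:
        extra = np.array(
            [_DIR_CODE[d] for lab, d in zip(a.excluded_labels, a.excluded_directions)
             if lab and d in _DIR_CODE],
            dtype=int,
        )
        if extra.size:
            pool = np.concatenate([codes, extra])
    scores, _ = _coordination_average(tad_idx, codes, a.n_tads, min_degs)
    observed = float(scores.mean())
    if pool.sum() in (0, pool.size):
        logger.warning("all DEGs share one direction; permutation cannot vary, p = 1")
        null = np.full(n_perm, observed)
        return PermutationResult(observed, null, 1.0, n_perm, seed)
    rng = np.random.default_rng(seed)
    n_slots = tad_idx.size
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pool)[:n_slots]
        s, _ = _coordination_average(tad_idx, perm, a.n_tads, min_degs)
        null[i] = s.mean()
    p = _percentile_rank_p(observed, null, estimator)
    return PermutationResult(observed, null, p, n_perm, seed)


def coordination_bin_comparison(
    observed: CoordinationProfile, null_profiles: Sequence[CoordinationProfile]
) -> dict[str, dict[str, float]]:
    """Observed vs expected TAD counts per coordination bin.

    For each 10-point bin: the observed TAD count, the null mean, and
    percentile-rank p in each direction (enrichment: null >= observed;
    depletion: null <= observed).
    """
    if not null_profiles:
        raise ValueError("need at least one null profile")
    for p in null_profiles:
        if tuple(p.bin_counts) != tuple(observed.bin_counts):
            raise ValueError("bin mismatch between observed and null profiles")
    report: dict[str, dict[str, float]] = {}
    n = len(null_profiles)
    for name in observed.bin_counts:
        obs = observed.bin_counts[name]
        null_counts = np.array([p.bin_counts[name] for p in null_profiles])
        report[name] = {
            "observed": float(obs),
            "null_mean": float(null_counts.mean()),
            "p_enrich": float(np.sum(null_counts >= obs) / n),
            "p_deplete": float(np.sum(null_counts <= obs) / n),
        }
    return report
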