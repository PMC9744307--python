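"""Oligopaint FISH contact and configuration statistics.

Per-allele measurements arrive as post-segmentation summaries: each
labeled domain is a sphere (centroid in nm, radius in nm) or a
precomputed volume.  Contact between two domains means their
surface-to-surface gap is at most the cutoff (250 nm by default, set by
the imaging resolution); overlapping signals always count as contact.
Overlap fractions normalize the sphere-intersection (lens) volume by the
smaller domain's volume unless told otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleMeasurement",
    "ConfigurationCall",
    "sphere_volume",
    "sphere_overlap_volume",
    "overlap_fraction",
    "call_contact",
    "contact_frequency",
    "contact_delta",
    "compare_overlap_distributions",
    "classify_configuration",
    "configuration_from_fraction",
]


def sphere_volume(radius: float) -> float:
    return 4.0 / 3.0 * math.pi * radius**3


def sphere_overlap_volume(r1: float, r2: float, d: float) -> float:
    """Closed-form volume of the intersection of two spheres (nm^3).

    d is the center-to-center distance.  Disjoint spheres give 0; one
    sphere inside the other gives the smaller sphere's volume; otherwise
    the standard lens formula.
    """
    if r1 < 0 or r2 < 0 or d < 0:
        raise ValueError("radii and distance must be non-negative")
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return sphere_volume(min(r1, r2))
    return (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


@dataclass
class AlleleMeasurement:
    """One allele's pair of labeled domains.

    Either give sphere geometry (centers + radii) and let volumes, the
    boundary gap and the overlap volume be derived, or supply the
    summaries directly.
    """

    allele_id: str
    condition: str
    center_a: tuple[float, float, float] | None = None
    radius_a: float | None = None
    center_b: tuple[float, float, float] | None = None
    radius_b: float | None = None
    volume_a: float | None = None
    volume_b: float | None = None
    overlap_volume: float | None = None
    boundary_gap_nm: float | None = None

    def __post_init__(self) -> None:
        if self.radius_a is not None and self.radius_a < 0:
            raise ValueError("radius_a must be >= 0")
        if self.radius_b is not None and self.radius_b < 0:
            raise ValueError("radius_b must be >= 0")
        have_geometry = (
            self.center_a is not None
            and self.center_b is not None
            and self.radius_a is not None
            and self.radius_b is not None
        )
        if have_geometry:
            d = math.dist(self.center_a, self.center_b)
            if self.volume_a is None:
                self.volume_a = sphere_volume(self.radius_a)
            if self.volume_b is None:
                self.volume_b = sphere_volume(self.radius_b)
            if self.boundary_gap_nm is None:
                self.boundary_gap_nm = d - self.radius_a - self.radius_b
            if self.overlap_volume is None:
                self.overlap_volume = sphere_overlap_volume(self.radius_a, self.radius_b, d)
        if self.overlap_volume is not None and self.volume_a and self.volume_b:
            if self.overlap_volume > min(self.volume_a, self.volume_b) * (1 + 1e-9):
                raise ValueError("overlap_volume exceeds the smaller domain volume")

    @classmethod
    def from_spheres(
        cls,
        allele_id: str,
        condition: str,
        center_a: Sequence[float],
        radius_a: float,
        center_b: Sequence[float],
        radius_b: float,
    ) -> "AlleleMeasurement":
        return cls(
            allele_id,
            condition,
            center_a=tuple(center_a),
            radius_a=float(radius_a),
            center_b=tuple(center_b),
            radius_b=float(radius_b),
        )


def overlap_fraction(m: AlleleMeasurement, denominator: str = "smaller") -> float:
    """Spatial-overlap fraction of an allele's two domains, in [0, 1].

    denominator: "smaller" (default), "union", "a" or "b".
    """
    if m.volume_a is None or m.volume_b is None or m.overlap_volume is None:
        raise ValueError("measurement lacks volumes")
    if m.volume_a <= 0 or m.volume_b <= 0:
        raise ValueError("zero domain volume")
    if denominator == "smaller":
        denom = min(m.volume_a, m.volume_b)
    elif denominator == "union":
        denom = m.volume_a + m.volume_b - m.overlap_volume
    elif denominator == "a":
        denom = m.volume_a
    elif denominator == "b":
        denom = m.volume_b
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return min(1.0, m.overlap_volume / denom)


def call_contact(m: AlleleMeasurement, cutoff_nm: float = 250.0) -> bool:
    """Contact call: boundary gap <= cutoff (overlapping signals always contact)."""
    if m.boundary_gap_nm is None:
        raise ValueError("measurement lacks a boundary gap")
    return m.boundary_gap_nm <= cutoff_nm


def contact_frequency(alleles: Sequence[AlleleMeasurement], cutoff_nm: float = 250.0) -> float:
    """Percent of alleles whose domains are in contact."""
    if not alleles:
        raise ValueError("no alleles")
    n = sum(call_contact(m, cutoff_nm) for m in alleles)
    return 100.0 * n / len(alleles)


def contact_delta(
    condition: Sequence[AlleleMeasurement],
    control: Sequence[AlleleMeasurement],
    cutoff_nm: float = 250.0,
) -> float:
    """Change in contact frequency, condition minus control, in percentage points."""
    return contact_frequency(condition, cutoff_nm) - contact_frequency(control, cutoff_nm)


def compare_overlap_distributions(
    a: Sequence[float], b: Sequence[float], grid_points: int = 101
) -> tuple[float, dict[str, np.ndarray]]:
    """Two-sided Mann-Whitney test plus cumulative frequency curves.

    Returns (p, curves) where curves holds a shared grid and the two
    empirical CDFs evaluated on it.  An all-equal pooled sample is
    degenerate: p = 1 with a warning.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("both samples need at least 2 values")
    pooled = np.concatenate([xa, xb])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        logger.warning("degenerate comparison: all pooled values equal; p = 1")
        grid = np.full(grid_points, lo)
        ones = np.ones(grid_points)
        return 1.0, {"grid": grid, "cdf_a": ones, "cdf_b": ones}
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="auto")
    grid = np.linspace(lo, hi, grid_points)
    curves = {
        "grid": grid,
        "cdf_a": np.searchsorted(np.sort(xa), grid, side="right") / xa.size,
        "cdf_b": np.searchsorted(np.sort(xb), grid, side="right") / xb.size,
    }
    return float(res.pvalue), curves


@dataclass(frozen=True)
class ConfigurationCall:
    allele_id: str
    category: str  # interacting / exclusion
    fraction_in_domains: float


def configuration_from_fraction(allele_id: str, fraction: float) -> ConfigurationCall:
    """Category from the fraction of gene signal inside the two domains.

    Interacting requires a strict majority (> 0.5); exactly half is
    exclusion.
    """
    category = "interacting" if fraction > 0.5 else "exclusion"
    return ConfigurationCall(allele_id, category, float(fraction))


def _fraction_in_union(
    gene: tuple[Sequence[float], float],
    up: tuple[Sequence[float], float],
    down: tuple[Sequence[float], float],
    grid: int,
) -> float:
    (gc, gr), (uc, ur), (dc, dr) = gene, up, down
    gc, uc, dc = (np.asarray(c, dtype=float) for c in (gc, uc, dc))
    d_ud = float(np.linalg.norm(uc - dc))
    v_gu = sphere_overlap_volume(gr, ur, float(np.linalg.norm(gc - uc)))
    v_gd = sphere_overlap_volume(gr, dr, float(np.linalg.norm(gc - dc)))
    vg = sphere_volume(gr)
    if d_ud >= ur + dr or v_gu == 0.0 or v_gd == 0.0:
        # the domains (or their overlaps with the gene) are disjoint:
        # inclusion-exclusion has no triple term and stays closed-form
        return (v_gu + v_gd) / vg
    # triple sphere overlap has no tidy closed form; integrate the gene
    # sphere on a deterministic midpoint grid
    ax = np.linspace(-gr, gr, grid + 1)
    mid = (ax[:-1] + ax[1:]) / 2
    X, Y, Z = np.meshgrid(mid, mid, mid, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1) + gc
    inside_gene = (X**2 + Y**2 + Z**2) <= gr**2
    in_up = np.sum((pts - uc) ** 2, axis=-1) <= ur**2
    in_down = np.sum((pts - dc) ** 2, axis=-1) <= dr**2
    n_gene = int(inside_gene.sum())
    if n_gene == 0:
        return 0.0
    return float(np.sum(inside_gene & (in_up | in_down)) / n_gene)


def classify_configuration(
    gene: tuple[Sequence[float], float],
    upstream: tuple[Sequence[float], float],
    downstream: tuple[Sequence[float], float],
    allele_id: str = "allele",
    grid: int = 48,
) -> ConfigurationCall:
    """Interacting vs exclusion call for a gene probe between two domains.

    Each argument is (center xyz in nm, radius in nm).  The call is
    "interacting" when the majority (> 0.5) of the gene sphere's volume
    lies inside the union of the upstream and downstream domains.
    """
    if gene[1] <= 0:
        raise ValueError("gene probe volume must be positive")
    frac = _fraction_in_union(gene, upstream, downstream, grid)
    return configuration_from_fraction(allele_id, frac)
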