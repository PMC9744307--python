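"""Synthetic inputs with the statistical structure each stage assumes.

The generators emulate, at desk scale, the structure of the study's
data: genes grouped into a non-overlapping TAD partition, DEG labels
with tunable within-TAD clustering and directional coordination,
adjusted-p/log2-fold-change pairs that only matter through threshold
crossings, negative-binomial promoter-window counts at single-base
resolution, knockdown-rescue structure for paired tables, and per-allele
sphere geometries with condition-dependent separation.  Everything is
reproducible from (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DEGRecord, GenomicInterval, Loop, SignalTrack, TranscriptRecord, make_deg_record
from .fish import AlleleMeasurement
from .tadstats import assign_to_tads

__all__ = [
    "GenomeSimSpec",
    "DEGSimSpec",
    "GeneLocus",
    "simulate_genome",
    "simulate_deg_table",
    "simulate_double_kd",
    "simulate_proseq_track",
    "simulate_fish_alleles",
    "simulate_loops",
    "confined_deg_genome",
]

# gene TSS slots are laid on a 1 kb grid inside each TAD so that promoter
# windows (151 nt) of different genes can never overlap
_SLOT_BP = 1000


@dataclass(frozen=True)
class GeneLocus:
    """Minimal gene handle for TAD assignment (one locus per gene)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"


@dataclass
class GenomeSimSpec:
    n_tads: int = 50
    genes_per_tad: float = 5.0  # Poisson mean
    tad_length_bp: int = 1_000_000
    inter_tad_gap_bp: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tads <= 0 or self.genes_per_tad <= 0 or self.tad_length_bp <= 0:
            raise ValueError("GenomeSimSpec fields must be positive")
        if self.inter_tad_gap_bp < 0:
            raise ValueError("inter_tad_gap_bp must be >= 0")
        if self.tad_length_bp < 4 * _SLOT_BP:
            raise ValueError("tad_length_bp too small to place genes")


@dataclass
class DEGSimSpec:
    deg_rate: float = 0.2
    clustering_weight: float = 1.0  # >= 1; concentrates DEGs in designated TADs
    coordination: float = 0.5  # P(DEG matches its TAD's majority direction)
    lfc_scale: float = 0.5
    hot_tad_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.deg_rate < 1.0):
            raise ValueError("deg_rate must lie in (0,1)")
        if not (0.5 <= self.coordination <= 1.0):
            raise ValueError("coordination must lie in [0.5, 1]")
        if self.clustering_weight < 1.0:
            raise ValueError("clustering_weight must be >= 1")
        if not (0.0 < self.hot_tad_fraction <= 1.0):
            raise ValueError("hot_tad_fraction must lie in (0, 1]")


def simulate_genome(spec: GenomeSimSpec) -> tuple[list[GenomicInterval], list[TranscriptRecord]]:
    """A non-overlapping TAD partition and a transcript annotation.

    Every gene's TSS lies strictly inside exactly one TAD; each gene has
    1-3 transcripts sharing its gene id, some at identical TSS positions
    to exercise dominant-TSS tie-breaking.  Per gene, the first listed
    transcript sits at the gene's base TSS.
    """
    rng = np.random.default_rng(spec.seed)
    chrom = "chrS"
    tads: list[GenomicInterval] = []
    transcripts: list[TranscriptRecord] = []
    gene_counter = 0
    stride = spec.tad_length_bp + spec.inter_tad_gap_bp
    for i in range(spec.n_tads):
        start = i * stride
        end = start + spec.tad_length_bp
        tads.append(GenomicInterval(chrom, start, end))
        slots = np.arange(start + _SLOT_BP, end - _SLOT_BP, _SLOT_BP)
        n_genes = min(int(rng.poisson(spec.genes_per_tad)), slots.size)
        tss_positions = np.sort(rng.choice(slots, size=n_genes, replace=False))
        for tss in tss_positions:
            gene_counter += 1
            gid = f"G{gene_counter:06d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_tx = int(rng.integers(1, 4))
            offsets = [0]
            for _ in range(n_tx - 1):
                # ~40% of extra transcripts share the base TSS exactly
                offsets.append(0 if rng.random() < 0.4 else int(rng.integers(1, 400)))
            for k, off in enumerate(offsets, start=1):
                pos = int(tss) + off if strand == "+" else int(tss) - off
                transcripts.append(
                    TranscriptRecord(
                        gid, f"{gid}.T{k}", chrom, pos, strand,
                        int(rng.integers(500, 50_001)),
                    )
                )
    return tads, transcripts


def _gene_loci(transcripts: list[TranscriptRecord]) -> list[GeneLocus]:
    """One locus per gene: the first listed transcript (the base TSS)."""
    seen: dict[str, GeneLocus] = {}
    for t in transcripts:
        if t.gene_id not in seen:
            seen[t.gene_id] = GeneLocus(t.gene_id, t.chrom, t.tss, t.strand)
    return list(seen.values())


def simulate_deg_table(
    genes: list[TranscriptRecord] | list[GeneLocus],
    tads: list[GenomicInterval],
    spec: DEGSimSpec,
    alpha: float = 0.01,
) -> list[DEGRecord]:
    """A differential-expression table with tunable TAD structure.

    Exactly round(deg_rate x n_genes) genes become DEGs, drawn with
    probability proportional to ``clustering_weight`` in a designated
    subset of TADs.  Each TAD carries a latent majority direction; every
    DEG matches it with probability ``coordination``.  padj for DEGs is
    log-uniform on (0, alpha], for non-DEGs uniform on (alpha, 1]: only
    the threshold crossing matters downstream.
    """
    loci = _gene_loci(genes) if genes and isinstance(genes[0], TranscriptRecord) else list(genes)
    n = len(loci)
    if n == 0:
        raise ValueError("no genes to label")
    rng = np.random.default_rng(spec.seed)
    assignment = assign_to_tads(loci, tads)
    gene_tad = dict(zip(assignment.gene_ids, (int(t) for t in assignment.tad_index)))

    n_hot = max(1, round(spec.hot_tad_fraction * assignment.n_tads))
    hot = set(rng.choice(assignment.n_tads, size=min(n_hot, assignment.n_tads), replace=False).tolist())
    weights = np.array(
        [spec.clustering_weight if gene_tad.get(g.gene_id) in hot else 1.0 for g in loci]
    )
    n_deg = round(spec.deg_rate * n)
    deg_idx = set(
        rng.choice(n, size=n_deg, replace=False, p=weights / weights.sum()).tolist()
    )
    majority = rng.random(max(assignment.n_tads, 1)) < 0.5  # True = up

    records: list[DEGRecord] = []
    for i, g in enumerate(loci):
        if i in deg_idx:
            tad = gene_tad.get(g.gene_id)
            maj_up = bool(majority[tad]) if tad is not None else bool(rng.random() < 0.5)
            up = maj_up if rng.random() < spec.coordination else not maj_up
            magnitude = abs(rng.normal(0.0, spec.lfc_scale)) + 0.05
            lfc = magnitude if up else -magnitude
            padj = float(10 ** rng.uniform(-12, math.log10(alpha)))
            padj = min(padj, alpha)
        else:
            lfc = float(rng.normal(0.0, spec.lfc_scale / 5))
            padj = float(alpha + (1.0 - alpha) * rng.uniform(1e-9, 1.0))
        records.append(make_deg_record(g.gene_id, lfc, padj, alpha))
    return records


def simulate_double_kd(
    single: list[DEGRecord],
    frac_full: float,
    frac_partial: float,
    seed: int = 0,
    alpha: float = 0.01,
) -> list[DEGRecord]:
    """A co-depletion table rescuing designated fractions of the DEGs.

    Of the single-knockdown DEGs (in seeded random order), round(frac_full
    x n) lose significance, round(frac_partial x n) stay significant with
    the same sign and strictly diminished |log2fc|, and the rest are
    unchanged.  Non-DEGs pass through untouched.
    """
    if frac_full < 0 or frac_partial < 0 or frac_full + frac_partial > 1.0:
        raise ValueError("need frac_full, frac_partial >= 0 with sum <= 1")
    rng = np.random.default_rng(seed)
    deg_positions = [i for i, r in enumerate(single) if r.is_deg]
    order = rng.permutation(len(deg_positions))
    n_full = round(frac_full * len(deg_positions))
    n_partial = round(frac_partial * len(deg_positions))
    full = {deg_positions[j] for j in order[:n_full]}
    partial = {deg_positions[j] for j in order[n_full : n_full + n_partial]}

    out: list[DEGRecord] = []
    for i, r in enumerate(single):
        if i in full:
            padj = float(alpha + (1.0 - alpha) * rng.uniform(0.01, 1.0))
            lfc = r.log2fc * rng.uniform(0.0, 0.3)
            out.append(make_deg_record(r.gene_id, lfc, padj, alpha))
        elif i in partial:
            lfc = r.log2fc * rng.uniform(0.2, 0.8)
            out.append(make_deg_record(r.gene_id, lfc, r.padj, alpha))
        else:
            out.append(r)
    return out


def simulate_proseq_track(
    transcripts: list[TranscriptRecord],
    active_fraction: float,
    mean_count: float,
    seed: int = 0,
    window: int = 150,
    nb_dispersion: float = 10.0,
) -> SignalTrack:
    """A 3'-end signal track with a designated fraction of active genes.

    Active genes place a negative-binomial window count (mean
    ``mean_count``, shape ``nb_dispersion``) at single-base resolution in
    the promoter window of their base transcript; inactive genes place
    at most 9 counts there, so the activity caller's threshold separates
    the classes up to NB tail mass.
    """
    if mean_count <= 0:
        raise ValueError("mean_count must be positive")
    if not (0.0 <= active_fraction <= 1.0):
        raise ValueError("active_fraction must lie in [0,1]")
    rng = np.random.default_rng(seed)
    loci = _gene_loci(transcripts)
    n_active = round(active_fraction * len(loci))
    active = set(rng.choice(len(loci), size=n_active, replace=False).tolist())
    track = SignalTrack()
    p_nb = nb_dispersion / (nb_dispersion + mean_count)
    for i, g in enumerate(loci):
        if i in active:
            count = int(rng.negative_binomial(nb_dispersion, p_nb))
        else:
            count = int(rng.integers(0, 10))
        if count == 0:
            continue
        if g.strand == "+":
            positions = np.arange(g.tss, g.tss + window + 1)
        else:
            positions = np.arange(max(0, g.tss - window), g.tss + 1)
        placed = rng.multinomial(count, np.full(positions.size, 1.0 / positions.size))
        for pos, c in zip(positions, placed):
            if c:
                track.add(g.strand, g.chrom, int(pos), int(c))
    return track


def simulate_fish_alleles(
    n_alleles: int,
    contact_prob: float,
    sep_mean_nm: float = 500.0,
    radius_nm: float = 400.0,
    seed: int = 0,
    cutoff_nm: float = 250.0,
    condition: str = "sim",
    radius_jitter: float = 0.1,
) -> list[AlleleMeasurement]:
    """Per-allele two-sphere geometries with a set contact probability.

    With probability ``contact_prob`` the boundary gap is drawn at or
    below the contact cutoff (possibly negative, i.e. overlapping);
    otherwise the gap is cutoff plus an exponential excess with mean
    ``sep_mean_nm``.  Overlap volumes follow from the sphere geometry.
    """
    if not (0.0 <= contact_prob <= 1.0):
        raise ValueError("contact_prob must lie in [0,1]")
    if radius_nm < 0:
        raise ValueError("radius_nm must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[AlleleMeasurement] = []
    for i in range(n_alleles):
        r1 = radius_nm * (1.0 + radius_jitter * rng.uniform(-1, 1))
        r2 = radius_nm * (1.0 + radius_jitter * rng.uniform(-1, 1))
        if rng.random() < contact_prob:
            gap = rng.uniform(-min(r1, r2), cutoff_nm) if min(r1, r2) > 0 else rng.uniform(0, cutoff_nm)
        else:
            gap = cutoff_nm + 1e-6 + rng.exponential(sep_mean_nm)
        d = max(0.0, r1 + r2 + gap)
        out.append(
            AlleleMeasurement.from_spheres(
                f"{condition}_{i:05d}", condition, (0.0, 0.0, 0.0), r1, (d, 0.0, 0.0), r2
            )
        )
    return out


def simulate_loops(
    genes: list[GeneLocus] | list[TranscriptRecord],
    degs: dict[str, DEGRecord],
    frac_deg_near: float = 0.3,
    frac_nondeg_near: float = 0.1,
    near_bp: int = 2000,
    anchor_width: int = 500,
    span_bp: int = 200_000,
    seed: int = 0,
) -> list[Loop]:
    """Chromatin loops whose upstream anchors sit near a tunable fraction
    of DEG (and non-DEG) TSSs, so anchor-proximity enrichment is real by
    construction.  The partner anchor lies ``span_bp`` downstream.
    """
    for frac in (frac_deg_near, frac_nondeg_near):
        if not (0.0 <= frac <= 1.0):
            raise ValueError("near fractions must lie in [0,1]")
    loci = _gene_loci(genes) if genes and isinstance(genes[0], TranscriptRecord) else list(genes)
    rng = np.random.default_rng(seed)
    loops: list[Loop] = []
    for g in loci:
        rec = degs.get(g.gene_id)
        frac = frac_deg_near if (rec is not None and rec.is_deg) else frac_nondeg_near
        if rng.random() >= frac:
            continue
        offset = int(rng.integers(0, near_bp + 1))
        a_start = max(0, g.tss - offset)
        a = GenomicInterval(g.chrom, a_start, a_start + anchor_width)
        b = GenomicInterval(g.chrom, a_start + span_bp, a_start + span_bp + anchor_width)
        loops.append(Loop(a, b))
    return loops


def confined_deg_genome(
    n_tads: int = 100,
    deg_tad_fraction: float = 0.1,
    genes_per_deg_tad: int = 20,
    genes_per_other_tad: int = 40,
    seed: int = 0,
    alpha: float = 0.01,
) -> tuple[list[GenomicInterval], list[GeneLocus], dict[str, DEGRecord]]:
    """The strong-clustering regime: every DEG confined to the gene-
    sparsest ``deg_tad_fraction`` of TADs, which are saturated with DEGs.

    With equal per-TAD gene counts the mean-of-percentages clustering
    statistic is blind to label placement (see tadstats docstring), so
    the confined TADs are made gene-sparse relative to the rest; the
    observed statistic then exceeds every label shuffle and the
    permutation p is 0.
    """
    rng = np.random.default_rng(seed)
    chrom = "chrS"
    tad_len = max((max(genes_per_deg_tad, genes_per_other_tad) + 2) * _SLOT_BP, 10 * _SLOT_BP)
    n_deg_tads = max(1, round(deg_tad_fraction * n_tads))
    tads, loci = [], []
    degs: dict[str, DEGRecord] = {}
    counter = 0
    for i in range(n_tads):
        start = i * tad_len
        tads.append(GenomicInterval(chrom, start, start + tad_len))
        is_deg_tad = i < n_deg_tads
        n_genes = genes_per_deg_tad if is_deg_tad else genes_per_other_tad
        for k in range(n_genes):
            counter += 1
            gid = f"G{counter:06d}"
            loci.append(GeneLocus(gid, chrom, start + (k + 1) * _SLOT_BP))
            if is_deg_tad:
                lfc = float(rng.normal(0.0, 0.8))
                lfc = lfc if abs(lfc) > 0.05 else 0.05
                degs[gid] = make_deg_record(gid, lfc, float(10 ** rng.uniform(-8, math.log10(alpha))), alpha)
            else:
                degs[gid] = make_deg_record(
                    gid, float(rng.normal(0.0, 0.1)), float(alpha + 0.98 * rng.uniform(1e-6, 1.0)), alpha
                )
    return tads, loci, degs
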