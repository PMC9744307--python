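"""Domain types and configuration shared by every analysis stage.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``.  Annotation tables carry 0-based TSS positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields

__all__ = [
    "GenomicInterval",
    "TranscriptRecord",
    "SignalTrack",
    "DEGRecord",
    "Loop",
    "AnalysisConfig",
    "make_deg_record",
    "gene_id_numeric",
]

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptRecord:
    """One annotated transcript: identity, TSS, strand and length.

    ``gene_id`` must contain a numeric portion (Ensembl-style); it is the
    final tie-break when collapsing transcripts to one dominant TSS.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    tss: int
    strand: str
    transcript_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        if self.transcript_length <= 0:
            raise ValueError("transcript_length must be positive")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        gene_id_numeric(self.gene_id)  # raises if no numeric portion


def gene_id_numeric(gene_id: str) -> int:
    """Numeric portion of an identifier (``ENSG000002`` -> 2)."""
    m = re.search(r"(\d+)", gene_id)
    if m is None:
        raise ValueError(f"gene id {gene_id!r} has no numeric portion")
    return int(m.group(1))


class SignalTrack:
    """Strand-separated single-base counts of RNA 3' ends.

    Internally a mapping ``(strand, chrom) -> {position: count}``.  Counts
    are non-negative integers; absent positions are zero.
    """

    def __init__(self) -> None:
        self._data: dict[tuple[str, str], dict[int, int]] = {}

    def add(self, strand: str, chrom: str, pos: int, count: int) -> None:
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {strand!r}")
        if count < 0:
            raise ValueError(f"negative count {count} at {chrom}:{pos}")
        if pos < 0:
            raise ValueError(f"negative position {pos}")
        self._data.setdefault((strand, chrom), {})[pos] = (
            self._data.get((strand, chrom), {}).get(pos, 0) + count
        )

    def get(self, strand: str, chrom: str, pos: int) -> int:
        return self._data.get((strand, chrom), {}).get(pos, 0)

    def has_chrom(self, strand: str, chrom: str) -> bool:
        return (strand, chrom) in self._data

    def positions(self, strand: str, chrom: str) -> dict[int, int]:
        return dict(self._data.get((strand, chrom), {}))

    def window_sum(self, strand: str, chrom: str, lo: int, hi: int) -> int:
        """Sum of counts over the closed interval [lo, hi]."""
        bucket = self._data.get((strand, chrom))
        if not bucket:
            return 0
        if hi - lo + 1 < len(bucket):
            return sum(bucket.get(p, 0) for p in range(lo, hi + 1))
        return sum(c for p, c in bucket.items() if lo <= p <= hi)

    def total(self) -> int:
        return sum(sum(b.values()) for b in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        a = {k: {p: c for p, c in v.items() if c} for k, v in self._data.items()}
        b = {k: {p: c for p, c in v.items() if c} for k, v in other._data.items()}
        return {k: v for k, v in a.items() if v} == {k: v for k, v in b.items() if v}

    @staticmethod
    def sum_tracks(tracks: list["SignalTrack"]) -> "SignalTrack":
        """Pool composite counts across samples (done before TSS calling)."""
        out = SignalTrack()
        for t in tracks:
            for (strand, chrom), bucket in t._data.items():
                for pos, count in bucket.items():
                    out.add(strand, chrom, pos, count)
        return out


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene differential-expression call.

    ``is_deg`` and ``direction`` are derived from ``padj`` and ``log2fc``
    via :func:`make_deg_record`; the invariants are re-checked here so a
    hand-built record cannot be inconsistent.
    """

    gene_id: str
    log2fc: float
    padj: float | None
    is_deg: bool
    direction: str  # up / down / none

    def __post_init__(self) -> None:
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj must lie in [0,1], got {self.padj}")
        if self.is_deg and self.padj is None:
            raise ValueError("a DEG must have an adjusted p-value")
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not self.is_deg and self.direction != "none":
            raise ValueError("non-DEGs carry direction 'none'")
        if self.is_deg:
            want = "up" if self.log2fc > 0 else "down"
            if self.direction != want:
                raise ValueError(
                    f"direction {self.direction!r} inconsistent with log2fc {self.log2fc}"
                )


def make_deg_record(gene_id: str, log2fc: float, padj: float | None, alpha: float) -> DEGRecord:
    """Build a DEGRecord, deriving significance at threshold ``alpha``.

    The threshold is inclusive (padj <= alpha).  A missing padj never
    counts as a DEG but the record is retained for downstream joins.
    """
    is_deg = padj is not None and padj <= alpha
    if is_deg and log2fc == 0:
        # a significant gene with exactly zero fold change is not orientable
        is_deg = False
    direction = "none"
    if is_deg:
        direction = "up" if log2fc > 0 else "down"
    return DEGRecord(gene_id, float(log2fc), padj, is_deg, direction)


@dataclass(frozen=True)
class Loop:
    """An intra-chromosomal chromatin loop: two anchor intervals."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError(
                "loop anchors must share a chromosome "
                f"({self.anchor_a.chrom} vs {self.anchor_b.chrom})"
            )

    @property
    def anchors(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (self.anchor_a, self.anchor_b)


@dataclass
class AnalysisConfig:
    """Every fixed constant of the pipeline, with study defaults.

    alpha            DEG significance threshold on adjusted p (inclusive).
    n_perm           permutation count for the label-shuffle nulls.
    tss_window       nt downstream of the TSS counted (window is TSS..TSS+150
                     inclusive on the plus strand, mirrored on minus).
    active_min_count minimum promoter-window count for an active TSS
                     (<=9 counts is inactive, hence 10).
    anchor_near_kb   loop-anchor proximity threshold, kb.
    anchor_far_kb    secondary proximity threshold, kb.
    universe_size    gene universe backing set-overlap Fisher tests.
    contact_cutoff_nm FISH boundary-gap cutoff defining contact.
    """

    alpha: float = 0.01
    n_perm: int = 1000
    tss_window: int = 150
    active_min_count: int = 10
    anchor_near_kb: float = 5.0
    anchor_far_kb: float = 200.0
    universe_size: int = 20000
    contact_cutoff_nm: float = 250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0,1)")
        for f in fields(self):
            if f.name in ("alpha", "seed"):
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
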