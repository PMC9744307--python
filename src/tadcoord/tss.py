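"""Dominant-TSS calling from nascent-transcription 3'-end signal.

Per gene, each annotated transcript gets a promoter-window count (TSS to
+150 nt downstream, strand-aware, both endpoints inclusive: 151 bases at
the default window).  Transcripts with <= 9 counts are inactive; among a
gene's active transcripts exactly one dominant TSS is chosen by a
deterministic cascade:

1. highest window count;
2. among ties, the TSS furthest upstream (smallest coordinate on the plus
   strand, largest on the minus strand);
3. among equal start positions, the longest annotated transcript;
4. finally the lowest numeric portion of the gene identifier.

The cascade is a total order, so the call never depends on input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import AnalysisConfig, SignalTrack, TranscriptRecord, gene_id_numeric

logger = logging.getLogger(__name__)

__all__ = ["TSSCall", "tss_window_count", "call_active", "select_dominant", "call_genes"]


@dataclass(frozen=True)
class TSSCall:
    gene_id: str
    dominant_transcript_id: str
    chrom: str
    tss: int
    strand: str
    window_count: int
    active: bool


def tss_window_count(track: SignalTrack, t: TranscriptRecord, window: int = 150) -> int:
    """3'-end counts in the strand-aware promoter window of transcript ``t``.

    Plus strand: positions TSS .. TSS+window inclusive; minus strand the
    window extends toward lower coordinates (TSS-window .. TSS).  An
    absent chromosome yields 0 with a logged warning.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not track.has_chrom(t.strand, t.chrom):
        logger.warning(
            "chromosome %s (%s strand) absent from signal track; count 0 for %s",
            t.chrom, t.strand, t.transcript_id,
        )
        return 0
    if t.strand == "+":
        lo, hi = t.tss, t.tss + window
    else:
        lo, hi = max(0, t.tss - window), t.tss
    return track.window_sum(t.strand, t.chrom, lo, hi)


def call_active(counts: list[tuple[TranscriptRecord, int]], min_count: int = 10) -> list[bool]:
    """Activity flags: a TSS is active iff its window count >= min_count."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [c >= min_count for _, c in counts]


def _dominance_key(item: tuple[TranscriptRecord, int]):
    t, count = item
    upstream = t.tss if t.strand == "+" else -t.tss
    return (-count, upstream, -t.transcript_length, gene_id_numeric(t.gene_id))


def select_dominant(transcripts_with_counts: list[tuple[TranscriptRecord, int]]) -> TSSCall:
    """Collapse one gene's active TSSs to its single dominant TSS."""
    if not transcripts_with_counts:
        raise ValueError("no active TSS: cannot select a dominant one")
    t, count = min(transcripts_with_counts, key=_dominance_key)
    return TSSCall(t.gene_id, t.transcript_id, t.chrom, t.tss, t.strand, count, True)


def call_genes(
    track: SignalTrack,
    transcripts: list[TranscriptRecord],
    config: AnalysisConfig | None = None,
) -> tuple[list[TSSCall], list[str]]:
    """Run the full caller over an annotation.

    Returns one TSSCall per gene with at least one active transcript, plus
    the ids of genes with none.  Dominant TSSs of different genes sharing
    a start position are kept (one call per gene) but flagged in the log.
    """
    cfg = config or AnalysisConfig()
    by_gene: dict[str, list[tuple[TranscriptRecord, int]]] = {}
    order: list[str] = []
    for t in transcripts:
        if t.gene_id not in by_gene:
            order.append(t.gene_id)
        by_gene.setdefault(t.gene_id, []).append((t, tss_window_count(track, t, cfg.tss_window)))
    calls: list[TSSCall] = []
    inactive: list[str] = []
    for gid in order:
        items = by_gene[gid]
        flags = call_active(items, cfg.active_min_count)
        active_items = [it for it, ok in zip(items, flags) if ok]
        if not active_items:
            inactive.append(gid)
            continue
        calls.append(select_dominant(active_items))
    starts: dict[tuple[str, int], list[str]] = {}
    for c in calls:
        starts.setdefault((c.chrom, c.tss), []).append(c.gene_id)
    for (chrom, tss), gids in starts.items():
        if len(gids) > 1:
            logger.warning(
                "dominant TSSs of genes %s share start %s:%d", gids, chrom, tss
            )
    return calls, inactive
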