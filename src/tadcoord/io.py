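"""Readers and writers for the plain-text formats every stage touches.

BED (>=3 columns), BEDPE (>=6 columns), 4-column bedGraph, and headered
TSV tables.  Parsers are deliberately strict: a malformed line fails with
its line number rather than being skipped.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

from .core import (
    DEGRecord,
    GenomicInterval,
    Loop,
    SignalTrack,
    TranscriptRecord,
    make_deg_record,
)

__all__ = [
    "ParseError",
    "read_intervals",
    "write_intervals",
    "read_signal",
    "write_signal",
    "read_deg_table",
    "write_deg_table",
    "read_transcript_table",
    "write_transcript_table",
]


class ParseError(ValueError):
    """Raised for a malformed line; message names the file and line number."""


def _lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _int_field(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what} {value!r}") from None


def read_intervals(path: str | Path, format: str = "BED") -> list[GenomicInterval] | list[Loop]:
    """Read a BED file into intervals, or a BEDPE file into loops.

    Input order is preserved.  Validation failures report the offending
    line number.
    """
    fmt = format.upper()
    if fmt not in ("BED", "BEDPE"):
        raise ValueError(f"format must be BED or BEDPE, got {format!r}")
    out: list = []
    need = 3 if fmt == "BED" else 6
    for lineno, cols in _lines(path):
        if len(cols) < need:
            raise ParseError(f"{path}:{lineno}: expected >= {need} columns, got {len(cols)}")
        try:
            if fmt == "BED":
                strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
                out.append(
                    GenomicInterval(
                        cols[0],
                        _int_field(cols[1], path, lineno, "start"),
                        _int_field(cols[2], path, lineno, "end"),
                        strand,
                    )
                )
            else:
                a = GenomicInterval(
                    cols[0],
                    _int_field(cols[1], path, lineno, "start"),
                    _int_field(cols[2], path, lineno, "end"),
                )
                b = GenomicInterval(
                    cols[3],
                    _int_field(cols[4], path, lineno, "start"),
                    _int_field(cols[5], path, lineno, "end"),
                )
                out.append(Loop(a, b))
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(path: str | Path, items: list[GenomicInterval] | list[Loop]) -> None:
    with open(path, "w") as fh:
        for it in items:
            if isinstance(it, Loop):
                a, b = it.anchors
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")
            else:
                fh.write(f"{it.chrom}\t{it.start}\t{it.end}\tregion\t0\t{it.strand}\n")


def _read_bedgraph_into(track: SignalTrack, path: str | Path, strand: str) -> None:
    seen: dict[str, set[int]] = {}
    for lineno, cols in _lines(path):
        if len(cols) < 4:
            raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns, got {len(cols)}")
        chrom = cols[0]
        start = _int_field(cols[1], path, lineno, "start")
        end = _int_field(cols[2], path, lineno, "end")
        try:
            value = float(cols[3])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric value {cols[3]!r}") from None
        if value < 0:
            raise ParseError(f"{path}:{lineno}: negative count {value}")
        if value != int(value):
            raise ParseError(f"{path}:{lineno}: count {value} is not integer-valued")
        if end <= start or start < 0:
            raise ParseError(f"{path}:{lineno}: bad run [{start}, {end})")
        occupied = seen.setdefault(chrom, set())
        run = range(start, end)
        if any(p in occupied for p in run):
            raise ParseError(f"{path}:{lineno}: overlapping runs on {strand} strand of {chrom}")
        occupied.update(run)
        count = int(value)
        if count == 0:
            continue
        for pos in run:
            track.add(strand, chrom, pos, count)


def read_signal(path_plus: str | Path, path_minus: str | Path) -> SignalTrack:
    """Read strand-separated 3'-end bedGraphs into a per-base SignalTrack."""
    track = SignalTrack()
    _read_bedgraph_into(track, path_plus, "+")
    _read_bedgraph_into(track, path_minus, "-")
    return track


def write_signal(track: SignalTrack, path_plus: str | Path, path_minus: str | Path) -> None:
    """Write a track back to two bedGraphs, merging equal-count adjacent runs."""
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as fh:
            chroms = sorted({c for s, c in track._data if s == strand})
            for chrom in chroms:
                bucket = track.positions(strand, chrom)
                run_start = None
                prev_pos = prev_count = None
                for pos in sorted(bucket):
                    count = bucket[pos]
                    if count == 0:
                        continue
                    if run_start is not None and pos == prev_pos + 1 and count == prev_count:
                        prev_pos = pos
                        continue
                    if run_start is not None:
                        fh.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_count}\n")
                    run_start, prev_pos, prev_count = pos, pos, count
                if run_start is not None:
                    fh.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_count}\n")


_DEG_COLS = ["gene_id", "log2fc", "padj"]


def read_deg_table(path: str | Path, alpha: float = 0.01) -> list[DEGRecord]:
    """Read a differential-expression TSV (gene_id, log2fc, padj).

    Records with missing padj are retained (the rescue classifier needs
    them) but are never DEGs.  Duplicate gene ids are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    missing = [c for c in _DEG_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ParseError(f"{path}: duplicate gene ids {dups[:5]}")
    lfc = pd.to_numeric(df["log2fc"], errors="raise")
    if lfc.isna().any():
        raise ParseError(f"{path}: missing log2fc values")
    padj = pd.to_numeric(df["padj"], errors="raise")
    out = []
    for gid, fc, p in zip(df["gene_id"], lfc, padj):
        out.append(make_deg_record(gid, float(fc), None if math.isnan(p) else float(p), alpha))
    return out


def write_deg_table(path: str | Path, records: list[DEGRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tpadj\n")
        for r in records:
            p = "" if r.padj is None else repr(r.padj)
            fh.write(f"{r.gene_id}\t{r.log2fc!r}\t{p}\n")


_TX_COLS = ["gene_id", "transcript_id", "chrom", "tss", "strand", "transcript_length"]


def read_transcript_table(path: str | Path) -> list[TranscriptRecord]:
    """Read a TSS annotation TSV (0-based TSS positions)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str, "chrom": str})
    missing = [c for c in _TX_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return [
        TranscriptRecord(
            row.gene_id, row.transcript_id, row.chrom, int(row.tss), row.strand,
            int(row.transcript_length),
        )
        for row in df.itertuples()
    ]


def write_transcript_table(path: str | Path, records: list[TranscriptRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TX_COLS) + "\n")
        for t in records:
            fh.write(
                f"{t.gene_id}\t{t.transcript_id}\t{t.chrom}\t{t.tss}\t{t.strand}\t{t.transcript_length}\n"
            )
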