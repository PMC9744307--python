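"""Classify single-knockdown DEGs as fully, partially, or not rescued
in a co-depletion condition.

A DEG is fully rescued when it is no longer significant in the double
knockdown (padj > alpha, or missing — it passed no significance call);
partially rescued when it stays significant in the same direction with a
strictly diminished |log2fc|; anything else — including significant sign
flips, which are flagged rather than silently merged — is not rescued.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .core import DEGRecord

logger = logging.getLogger(__name__)

__all__ = ["RescueCall", "RescueSummary", "classify_rescue"]

CATEGORIES = ("fully", "partially", "not_rescued")


@dataclass(frozen=True)
class RescueCall:
    gene_id: str
    category: str
    sign_flip: bool
    lfc_single: float
    lfc_double: float | None
    padj_double: float | None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")
        if self.sign_flip and self.category != "not_rescued":
            raise ValueError("sign_flip only applies to not_rescued genes")


@dataclass(frozen=True)
class RescueSummary:
    n_deg: int
    counts: dict[str, int]
    percentages: dict[str, float]


def classify_rescue(
    single: Sequence[DEGRecord],
    double: Sequence[DEGRecord],
    alpha: float = 0.01,
    missing_policy: str = "fully",
) -> tuple[list[RescueCall], RescueSummary]:
    """Per-gene rescue calls for every DEG of the single knockdown.

    ``missing_policy`` governs single-KD DEGs absent from the double
    table: "fully" (default; they passed no significance call, mirroring
    the missing-padj rule) or "error".
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0,1)")
    if missing_policy not in ("fully", "error"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    double_by_gene = {r.gene_id: r for r in double}
    calls: list[RescueCall] = []
    for s in single:
        if not s.is_deg:
            continue
        d = double_by_gene.get(s.gene_id)
        if d is None:
            if missing_policy == "error":
                raise ValueError(f"DEG {s.gene_id} absent from double-knockdown table")
            logger.warning("DEG %s absent from double-knockdown table; fully rescued", s.gene_id)
            calls.append(RescueCall(s.gene_id, "fully", False, s.log2fc, None, None))
            continue
        if d.padj is None or d.padj > alpha:
            calls.append(RescueCall(s.gene_id, "fully", False, s.log2fc, d.log2fc, d.padj))
            continue
        same_sign = (s.log2fc > 0) == (d.log2fc > 0) and d.log2fc != 0
        if same_sign and abs(d.log2fc) < abs(s.log2fc):
            calls.append(RescueCall(s.gene_id, "partially", False, s.log2fc, d.log2fc, d.padj))
        else:
            calls.append(
                RescueCall(s.gene_id, "not_rescued", not same_sign, s.log2fc, d.log2fc, d.padj)
            )
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    n = len(calls)
    pct = {c: (100.0 * counts[c] / n if n else 0.0) for c in CATEGORIES}
    return calls, RescueSummary(n, counts, pct)
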