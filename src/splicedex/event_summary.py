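"""Tallies of filtered alternative-splicing events by type."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .as_classifier import EVENT_TYPES
from .splicing_quant import SplicingResult

__all__ = ["EventTally", "tally_events", "tally_from_counts"]


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * ndigits), ROUND_HALF_UP))


@dataclass
class EventTally:
    counts: dict[str, int]  # per event type
    total: int
    percentages: dict[str, float]  # 100*count/total, half-up to 1 decimal
    n_up: int | None = None
    n_down: int | None = None
    n_genes: int | None = None
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Alternative Event Type": list(self.counts),
                "N. of AS Regulated Events": list(self.counts.values()),
                "Percentage": [self.percentages[t] for t in self.counts],
            }
        )


def tally_from_counts(
    counts: dict[str, int],
    n_up: int | None = None,
    n_down: int | None = None,
    n_genes: int | None = None,
) -> EventTally:
    """Tally from per-type event counts (e.g. a published summary table)."""
    for t in counts:
        if t not in EVENT_TYPES:
            raise ValueError(f"unknown event type {t!r}")
    full = {t: int(counts.get(t, 0)) for t in EVENT_TYPES}
    total = sum(full.values())
    if total == 0:
        pct = {t: 0.0 for t in EVENT_TYPES}
        return EventTally(full, 0, pct, n_up, n_down, n_genes, empty=True)
    pct = {t: _round_half_up(100.0 * c / total) for t, c in full.items()}
    return EventTally(full, total, pct, n_up, n_down, n_genes)


def tally_events(results: list[SplicingResult]) -> EventTally:
    """Tally classified, filtered results: per-type counts, one-decimal
    percentages, up/down split, and the number of distinct genes."""
    counts: dict[str, int] = {t: 0 for t in EVENT_TYPES}
    n_up = n_down = 0
    genes = set()
    for r in results:
        counts[r.event.event_type] += 1
        if r.regulation == "up":
            n_up += 1
        else:
            n_down += 1
        genes.add(r.gene_id)
    tally = tally_from_counts(counts, n_up=n_up, n_down=n_down, n_genes=len(genes))
    return tally
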