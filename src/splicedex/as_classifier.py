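"""Alternative-splicing event classification on gene models.

Each transcript exon is compared against its corresponding reference
("genomic") exon. Six rules are applied:

* **alternative first exon** — a transcript's first exon, at a genomic exon
  that also hosts internal exons of other transcripts, starting at least
  ``min_terminal_offset`` nt upstream (transcription direction) of the
  internal-exon boundary evidence;
* **alternative terminal exon** — the mirror rule for a transcript's last
  exon, extending at least the offset downstream;
* **alternative acceptor (3') site** — an internal exon whose first position
  (transcription direction) differs from the reference first position;
* **alternative donor (5') site** — an internal exon whose last position
  differs from the reference last position;
* **intron retention** — a whole reference intron contained in one
  transcript exon;
* **exon cassette (skipping)** — a genomic exon absent from a transcript
  that has exons flanking it on both sides.

First/last exons are evaluated only against the terminal rules; internal
exons route to the acceptor/donor rules; transcript exons that retain an
intron are excluded from boundary comparisons (their outer boundaries belong
to the retention event). Boundary evidence for a genomic exon is taken from
internal, non-retaining transcript exons: the reference first position is
the 5'-most such first position, the reference last position the 3'-most
such last position.

A seventh category, ``unknown``, is reserved for differentially used
regions (supplied by the quantification stage) that match none of the six
rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from . import intervals as iv
from .gene_model import GeneModel, GenomicExon, TranscriptExon, corresponding_genomic_exon

EVENT_TYPES = (
    "alternative_first_exon",
    "alternative_terminal_exon",
    "exon_cassette",
    "alternative_acceptor_site",
    "alternative_donor_site",
    "intron_retention",
    "unknown",
)


class LabelingError(ValueError):
    """Event feature label does not resolve to a feature of the gene."""


@dataclass(frozen=True)
class SpliceEvent:
    gene_id: str
    event_type: str
    feature_label: str  # "e<k>", "i<k>" or "ae<k>"
    chrom: str
    start: int
    end: int
    supporting_transcripts: tuple[str, ...] = ()
    excluded_transcripts: tuple[str, ...] = ()

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.start > self.end:
            raise ValueError("start > end")
        if set(self.supporting_transcripts) & set(self.excluded_transcripts):
            raise ValueError("supporting and excluded transcripts overlap")


def _first_pos(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end

def _last_pos(start: int, end: int, strand: str) -> int:
    return end if strand == "+" else start


def _upstream_extent(te_first: int, ref_first: int, strand: str) -> int:
    """How far te's first position lies upstream (transcription dir) of ref."""
    return ref_first - te_first if strand == "+" else te_first - ref_first

def _downstream_extent(te_last: int, ref_last: int, strand: str) -> int:
    return te_last - ref_last if strand == "+" else ref_last - te_last


def classify_gene(model: GeneModel, min_terminal_offset: int = 10) -> list[SpliceEvent]:
    """Classify all alternative-splicing events of one gene model.

    Pure function of ``(model, min_terminal_offset)``; events are
    deduplicated on ``(gene_id, event_type, feature_label)`` (transcript
    sets and coordinate spans merged) and returned in transcription order.
    """
    if min_terminal_offset < 0:
        raise ValueError("min_terminal_offset must be >= 0")
    strand = model.strand
    introns = model.introns()

    # transcript exons retaining a whole reference intron
    retaining: dict[tuple[str, int], list[str]] = {}  # te key -> intron labels
    for tid, tes in model.transcripts.items():
        for te in tes:
            labels = [
                lab for lab, lo, hi in introns if iv.contains((te.start, te.end), (lo, hi))
            ]
            if labels:
                retaining[(tid, te.ordinal)] = labels

    # per genomic exon: which transcripts correspond, and boundary evidence
    corr: dict[str, list[TranscriptExon]] = {g.exon_label: [] for g in model.genomic_exons}
    for tid, tes in model.transcripts.items():
        for te in tes:
            g = corresponding_genomic_exon(te, model)
            if g is not None:
                corr[g.exon_label].append(te)

    def internal_evidence(label: str, exclude_tid: str | None = None):
        """Internal non-retaining exons at this genomic exon."""
        return [
            te for te in corr[label]
            if te.role == "internal"
            and (te.transcript_id, te.ordinal) not in retaining
            and te.transcript_id != exclude_tid
        ]

    raw: list[SpliceEvent] = []

    # --- terminal and splice-site rules, per transcript exon ------------
    for tid, tes in model.transcripts.items():
        for te in tes:
            g = corresponding_genomic_exon(te, model)
            if g is None:
                continue
            te_first = _first_pos(te.start, te.end, strand)
            te_last = _last_pos(te.start, te.end, strand)
            retains = (tid, te.ordinal) in retaining

            if te.role in ("first", "last"):
                others = internal_evidence(g.exon_label, exclude_tid=tid)
                if not others:
                    continue
                firsts = [_first_pos(o.start, o.end, strand) for o in others]
                lasts = [_last_pos(o.start, o.end, strand) for o in others]
                ref_first = min(firsts) if strand == "+" else max(firsts)
                ref_last = max(lasts) if strand == "+" else min(lasts)
                if te.role == "first" and _upstream_extent(te_first, ref_first, strand) >= min_terminal_offset:
                    raw.append(SpliceEvent(
                        model.gene_id, "alternative_first_exon", g.exon_label,
                        model.chrom, te.start, te.end,
                        (tid,), tuple(sorted({o.transcript_id for o in others})),
                    ))
                if te.role == "last" and _downstream_extent(te_last, ref_last, strand) >= min_terminal_offset:
                    raw.append(SpliceEvent(
                        model.gene_id, "alternative_terminal_exon",
                        "a" + g.exon_label, model.chrom, te.start, te.end,
                        (tid,), tuple(sorted({o.transcript_id for o in others})),
                    ))
            elif te.role == "internal" and not retains:
                peers = internal_evidence(g.exon_label)
                firsts = [_first_pos(o.start, o.end, strand) for o in peers]
                lasts = [_last_pos(o.start, o.end, strand) for o in peers]
                ref_first = min(firsts) if strand == "+" else max(firsts)
                ref_last = max(lasts) if strand == "+" else min(lasts)
                agree_first = sorted(
                    {o.transcript_id for o in peers
                     if _first_pos(o.start, o.end, strand) == ref_first} - {tid}
                )
                agree_last = sorted(
                    {o.transcript_id for o in peers
                     if _last_pos(o.start, o.end, strand) == ref_last} - {tid}
                )
                if te_first != ref_first:
                    raw.append(SpliceEvent(
                        model.gene_id, "alternative_acceptor_site", g.exon_label,
                        model.chrom, g.start, g.end, (tid,), tuple(agree_first),
                    ))
                if te_last != ref_last:
                    raw.append(SpliceEvent(
                        model.gene_id, "alternative_donor_site", g.exon_label,
                        model.chrom, g.start, g.end, (tid,), tuple(agree_last),
                    ))

    # --- exon cassette ---------------------------------------------------
    for g in model.genomic_exons:
        supporting = sorted({te.transcript_id for te in corr[g.exon_label]})
        excluded = []
        for tid, tes in model.transcripts.items():
            if tid in supporting:
                continue
            if any(iv.overlap_len((te.start, te.end), (g.start, g.end)) > 0 for te in tes):
                continue
            has_up = any(te.end < g.start for te in tes)
            has_down = any(te.start > g.end for te in tes)
            if has_up and has_down:
                excluded.append(tid)
        if supporting and excluded:
            raw.append(SpliceEvent(
                model.gene_id, "exon_cassette", g.exon_label,
                model.chrom, g.start, g.end,
                tuple(supporting), tuple(sorted(excluded)),
            ))

    # --- intron retention -------------------------------------------------
    for lab, lo, hi in introns:
        supporting = sorted({
            te.transcript_id
            for tes in model.transcripts.values() for te in tes
            if iv.contains((te.start, te.end), (lo, hi))
        })
        if not supporting:
            continue
        excluded = []
        for tid, tes in model.transcripts.items():
            if tid in supporting:
                continue
            splices = any(te.end == lo - 1 for te in tes) and any(
                te.start == hi + 1 for te in tes
            )
            if splices:
                excluded.append(tid)
        raw.append(SpliceEvent(
            model.gene_id, "intron_retention", lab, model.chrom, lo, hi,
            tuple(supporting), tuple(sorted(excluded)),
        ))

    return _dedup(raw)


def _dedup(events: list[SpliceEvent]) -> list[SpliceEvent]:
    merged: dict[tuple[str, str, str], SpliceEvent] = {}
    for ev in events:
        key = (ev.gene_id, ev.event_type, ev.feature_label)
        if key in merged:
            prev = merged[key]
            sup = tuple(sorted(set(prev.supporting_transcripts) | set(ev.supporting_transcripts)))
            exc = tuple(sorted(
                (set(prev.excluded_transcripts) | set(ev.excluded_transcripts)) - set(sup)
            ))
            merged[key] = replace(
                prev,
                start=min(prev.start, ev.start),
                end=max(prev.end, ev.end),
                supporting_transcripts=sup,
                excluded_transcripts=exc,
            )
        else:
            merged[key] = ev

    def feat_index(label: str) -> tuple[int, int]:
        m = re.fullmatch(r"(a?)([ei])(\d+)", label)
        return (int(m.group(3)), "ei".index(m.group(2))) if m else (10**9, 9)

    return sorted(
        merged.values(),
        key=lambda e: (feat_index(e.feature_label), EVENT_TYPES.index(e.event_type)),
    )


def resolve_feature(model: GeneModel, feature_label: str) -> tuple[int, int]:
    """Genomic coordinates of an ``e<k>``/``ae<k>``/``i<k>`` feature label."""
    m = re.fullmatch(r"(a?)(e|i)(\d+)", feature_label)
    if not m:
        raise LabelingError(f"malformed feature label {feature_label!r}")
    k = int(m.group(3))
    if m.group(2) == "e":
        try:
            g = model.exon_by_label(f"e{k}")
        except KeyError:
            raise LabelingError(f"{model.gene_id} has no exon e{k}") from None
        return g.start, g.end
    for lab, lo, hi in model.introns():
        if lab == f"i{k}":
            return lo, hi
    raise LabelingError(f"{model.gene_id} has no intron i{k}")


def label_feature(event: SpliceEvent, model: GeneModel) -> str:
    """Validate and return the event's feature label (``e18``/``i31``/``ae5``)."""
    if event.gene_id != model.gene_id:
        raise LabelingError("event does not belong to this model")
    lo, hi = resolve_feature(model, event.feature_label)
    if iv.overlap_len((lo, hi), (event.start, event.end)) == 0:
        raise LabelingError(
            f"label {event.feature_label} does not overlap event coordinates"
        )
    return event.feature_label


def coordinates_string(event: SpliceEvent) -> str:
    """Genomic-coordinate string, e.g. ``chr9:36118754-36118964``."""
    return f"{event.chrom}:{event.start}-{event.end}"


def unknown_event(model: GeneModel, feature_label: str) -> SpliceEvent:
    """Build an ``unknown`` event for a regulated region matching no rule."""
    lo, hi = resolve_feature(model, feature_label)
    return SpliceEvent(model.gene_id, "unknown", feature_label, model.chrom, lo, hi)


def events_for_regulated_features(
    model: GeneModel,
    regulated_labels: list[str],
    events: list[SpliceEvent] | None = None,
    min_terminal_offset: int = 10,
) -> list[SpliceEvent]:
    """Assign one event per regulated feature; rule misses become ``unknown``.

    The quantification stage supplies the differentially used exon/intron
    labels; any label with no classified event of the six defined types gets
    an ``unknown`` event (e.g. a regulated intron with no retention evidence
    or a regulated exon present in all transcripts).
    """
    if events is None:
        events = classify_gene(model, min_terminal_offset)
    by_label: dict[str, list[SpliceEvent]] = {}
    for ev in events:
        by_label.setdefault(ev.feature_label, []).append(ev)
    out = []
    for lab in regulated_labels:
        cands = by_label.get(lab, [])
        # terminal-exon events carry an "ae" label; a regulated exon label
        # "e<k>" also matches an "ae<k>" event on the same exon
        if not cands and lab.startswith("e"):
            cands = by_label.get("a" + lab, [])
        out.append(cands[0] if cands else unknown_event(model, lab))
    return out
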