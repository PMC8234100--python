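"""Published summary values from the motivating coronary-artery-disease
PBMC splicing screen, bundled as worked-example inputs.

These are printed results of the original study (not outputs of this
package): the per-type tally of the 113 differentially regulated events
found in the 2-vs-2 CAD-vs-control RNA-seq comparison, and the ten events
surviving the |SI-FC| >= 2 filter. They feed the tally and filter stages
as known inputs with known expected behaviour.
"""

from __future__ import annotations

import pandas as pd

# Per-type counts of the 113 regulated events (|SI-FC| >= 1.5, p <= 0.05).
PUBLISHED_EVENT_COUNTS: dict[str, int] = {
    "alternative_first_exon": 14,
    "alternative_terminal_exon": 10,
    "exon_cassette": 14,
    "alternative_acceptor_site": 5,
    "alternative_donor_site": 6,
    "intron_retention": 6,
    "unknown": 58,
}

PUBLISHED_N_UP = 24
PUBLISHED_N_DOWN = 89
PUBLISHED_N_GENES = 86

# The ten events retained at |SI-FC| >= 2 (hg19 coordinates).
_TOP_EVENT_ROWS = [
    # gene, event_type, feature, regulation, si_fc, p, chrom, start, end
    ("CFAP44", "unknown", "e25", "up", 3.51, 4.87e-2, "chr3", 113052252, 113052429),
    ("PLCB2", "unknown", "i31", "down", 3.23, 9.14e-4, "chr15", 40581119, 40581471),
    ("RECK", "unknown", "e18", "down", 2.64, 2.17e-2, "chr9", 36118754, 36118964),
    ("VTI1A", "unknown", "i1", "up", 2.63, 6.80e-3, "chr10", 114208248, 114208639),
    ("CD58", "alternative_terminal_exon", "ae5", "down", 2.45, 3.91e-2, "chr1", 117061321, 117061851),
    ("MIR4469 // RNF170", "alternative_terminal_exon", "ae6", "down", 2.29, 2.93e-2, "chr8", 42716503, 42716886),
    ("PTER", "exon_cassette", "e2", "down", 2.21, 2.41e-2, "chr10", 16479356, 16479489),
    ("GPATCH2L", "alternative_terminal_exon", "ae9", "down", 2.19, 4.61e-2, "chr14", 76662316, 76662739),
    ("CLEC12A", "unknown", "i1", "down", 2.13, 1.23e-2, "chr12", 10124287, 10131564),
    ("BLNK", "exon_cassette", "e16", "down", 2.13, 3.31e-2, "chr10", 97956663, 97956735),
]

PUBLISHED_TOP_EVENTS = pd.DataFrame(
    _TOP_EVENT_ROWS,
    columns=[
        "gene_id", "event_type", "feature_label", "regulation",
        "si_fc_magnitude", "p_value", "chrom", "start", "end",
    ],
)


def published_top_events_as_results():
    """The |SI-FC| >= 2 table as SplicingResult objects, usable as input to
    the filter and tally stages."""
    from .as_classifier import SpliceEvent
    from .splicing_quant import SplicingResult

    out = []
    for row in PUBLISHED_TOP_EVENTS.itertuples(index=False):
        ev = SpliceEvent(
            row.gene_id, row.event_type, row.feature_label,
            row.chrom, row.start, row.end,
        )
        out.append(
            SplicingResult(row.gene_id, ev, row.si_fc_magnitude, row.regulation, row.p_value)
        )
    return out
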