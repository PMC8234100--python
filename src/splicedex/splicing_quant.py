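"""Splicing-index quantification of exon-level differential usage.

Counts on exonic/intronic features and on each gene's constitutive regions
are normalized by median-of-ratios size factors. Genes pass an expression
filter when their RPKM exceeds the 97.5th percentile of intergenic
background RPKM in at least one group. Per sample, the splicing index of a
feature is the pseudocounted ratio of its normalized count to the gene's
normalized constitutive count; the splicing-index fold-change (SI-FC) is
the ratio of group mean indices, reported as a magnitude >= 1 plus an
up/down direction (and equivalently as a +/- signed value). Significance is
a two-sided Welch t-test on log2 splicing indices; events are retained at
|SI-FC| >= 1.5 and uncorrected p <= 0.05 by default.

The splicing-index formula is a reconstruction: exon-array/RNA-seq splicing
index pipelines report a magnitude and a direction but the exact statistic
is proprietary in the commercial implementations. The per-sample
exon/constitutive ratio with pseudocount 1 and a ratio of group means is
the simplest statistic consistent with that reporting style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .as_classifier import SpliceEvent

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "ExpressionSummary",
    "SplicingResult",
    "NormalizationError",
    "size_factors",
    "rpkm",
    "rpkm_frame",
    "expressed_filter",
    "splicing_index",
    "splicing_index_fc",
    "test_event",
    "filter_significant",
]


class NormalizationError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Integer read counts per (feature, sample) with feature lengths."""

    counts: pd.DataFrame  # features x samples, integer
    lengths: pd.Series  # nt per feature

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("missing feature lengths")
        if (self.lengths < 1).any():
            raise ValueError("feature lengths must be >= 1")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, path: str) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.drop(columns=["length"]).astype(int), df["length"])

    def to_tsv(self, path: str) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="feature_id")


@dataclass
class SampleDesign:
    groups: dict[str, str]  # sample_id -> group label
    reference_group: str

    def __post_init__(self):
        labels = set(self.groups.values())
        if self.reference_group not in labels:
            raise ValueError(f"reference group {self.reference_group!r} absent")
        if len(labels) != 2:
            raise ValueError("differential contrasts require exactly 2 groups")

    @property
    def case_group(self) -> str:
        return next(g for g in self.groups.values() if g != self.reference_group)

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @classmethod
    def from_csv(cls, path: str, reference_group: str) -> "SampleDesign":
        df = pd.read_csv(path)
        return cls(dict(zip(df["sample_id"], df["group"])), reference_group)


@dataclass
class ExpressionSummary:
    gene_id: str
    rpkm: pd.Series  # per sample
    expressed: dict[str, bool]  # per group

    @property
    def retained(self) -> bool:
        return any(self.expressed.values())


@dataclass
class SplicingResult:
    gene_id: str
    event: SpliceEvent
    si_fc_magnitude: float
    regulation: str  # up | down
    p_value: float = float("nan")

    def __post_init__(self):
        if self.si_fc_magnitude < 1:
            raise ValueError("si_fc_magnitude must be >= 1")
        if self.regulation not in ("up", "down"):
            raise ValueError("regulation must be 'up' or 'down'")

    @property
    def signed_fc(self) -> float:
        return self.si_fc_magnitude if self.regulation == "up" else -self.si_fc_magnitude


# ----------------------------------------------------------------------
def size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    factor_s = median over all-positive features f of
    counts[f, s] / geometric_mean_over_samples(counts[f, .]).
    """
    counts = matrix.counts.to_numpy(dtype=float)
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        raise NormalizationError("no feature with nonzero counts in every sample")
    logc = np.log(counts[pos])
    log_gm = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_gm, axis=0))
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def rpkm(count: float, length_nt: int, mapped_reads: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if length_nt < 1 or mapped_reads < 1:
        raise ValueError("length and mapped reads must be >= 1")
    return count / ((length_nt / 1_000) * (mapped_reads / 1_000_000))


def rpkm_frame(matrix: CountMatrix, mapped_reads: pd.Series | None = None) -> pd.DataFrame:
    """RPKM per (feature, sample); library sizes default to column sums."""
    if mapped_reads is None:
        mapped_reads = matrix.counts.sum(axis=0)
    denom = matrix.lengths.to_numpy()[:, None] / 1e3 * mapped_reads.to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        matrix.counts.to_numpy() / denom, index=matrix.counts.index, columns=matrix.counts.columns
    )


def background_threshold(intergenic_rpkm: np.ndarray) -> float:
    """97.5th percentile (linear interpolation) of intergenic background RPKM."""
    bg = np.asarray(intergenic_rpkm, dtype=float).ravel()
    if bg.size == 0:
        raise NormalizationError("empty intergenic background")
    if bg.size < 20:
        raise NormalizationError(
            f"need >= 20 intergenic background values, got {bg.size}"
        )
    return float(np.percentile(bg, 97.5))


def expressed_filter(
    gene_rpkm: pd.Series, design: SampleDesign, intergenic_rpkm: np.ndarray,
    gene_id: str = "",
) -> ExpressionSummary:
    """A gene is expressed in a group if its mean RPKM exceeds the
    intergenic background threshold; it is retained if expressed in >= 1
    of the two compared conditions."""
    thr = background_threshold(intergenic_rpkm)
    expressed = {}
    for grp in {design.reference_group, design.case_group}:
        vals = gene_rpkm[design.samples(grp)]
        expressed[grp] = bool(vals.mean() > thr)
    return ExpressionSummary(gene_id, gene_rpkm, expressed)


# ----------------------------------------------------------------------
def splicing_index(
    exon_counts: pd.Series,
    constitutive_counts: pd.Series,
    factors: pd.Series,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sample splicing index: pseudocounted ratio of normalized exon to
    normalized constitutive counts."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    e = exon_counts / factors + pseudocount
    c = constitutive_counts / factors + pseudocount
    return e / c


def splicing_index_fc(
    exon_counts: pd.Series,
    constitutive_counts: pd.Series,
    factors: pd.Series,
    design: SampleDesign,
    pseudocount: float = 1.0,
) -> tuple[float, str, float]:
    """(magnitude, regulation, signed_fc) of the case/reference ratio of
    group mean splicing indices. A ratio of exactly 1 reports 'up', +1."""
    if pseudocount == 0:
        case_c = constitutive_counts[design.samples(design.case_group)]
        ref_c = constitutive_counts[design.samples(design.reference_group)]
        if (case_c == 0).all() or (ref_c == 0).all():
            raise NormalizationError("all-zero constitutive counts in a group")
    si = splicing_index(exon_counts, constitutive_counts, factors, pseudocount)
    case = si[design.samples(design.case_group)].mean()
    ref = si[design.samples(design.reference_group)].mean()
    ratio = case / ref
    magnitude = max(ratio, 1.0 / ratio)
    regulation = "up" if ratio >= 1 else "down"
    signed = magnitude if regulation == "up" else -magnitude
    return magnitude, regulation, signed


def test_event(si_values: pd.Series, design: SampleDesign) -> float:
    """Two-sided Welch t-test on log2 splicing indices."""
    a = np.log2(si_values[design.samples(design.case_group)].to_numpy(float))
    b = np.log2(si_values[design.samples(design.reference_group)].to_numpy(float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def filter_significant(
    results: list[SplicingResult], min_fc: float = 1.5, max_p: float = 0.05
) -> list[SplicingResult]:
    """Keep results with |SI-FC| >= min_fc and p <= max_p, input order kept."""
    if min_fc < 1:
        raise ValueError("min_fc must be >= 1")
    return [
        r for r in results
        if r.si_fc_magnitude >= min_fc and r.p_value <= max_p
    ]


# ----------------------------------------------------------------------
def quantify(
    exon_cm: CountMatrix,
    constitutive_cm: CountMatrix,
    intergenic_cm: CountMatrix,
    design: SampleDesign,
    events_by_feature: dict[str, SpliceEvent],
    pseudocount: float = 1.0,
) -> list[SplicingResult]:
    """End-to-end quantification over an exon-feature count matrix.

    Exon feature ids follow the ``<gene_id>:<feature_label>`` convention;
    constitutive feature ids are gene ids. Genes failing the intergenic
    background filter are skipped. ``events_by_feature`` maps an exon
    feature id to its classified event (``unknown`` where no rule matched).
    """
    factors = size_factors(constitutive_cm)
    mapped = constitutive_cm.counts.sum(axis=0) + intergenic_cm.counts.sum(axis=0)
    gene_rpkm = rpkm_frame(constitutive_cm, mapped)
    bg_rpkm = rpkm_frame(intergenic_cm, mapped).to_numpy().ravel()

    results: list[SplicingResult] = []
    for feat in exon_cm.feature_ids:
        gene_id = feat.split(":", 1)[0]
        if gene_id not in constitutive_cm.counts.index:
            continue
        summary = expressed_filter(gene_rpkm.loc[gene_id], design, bg_rpkm, gene_id)
        if not summary.retained:
            continue
        exon_counts = exon_cm.counts.loc[feat]
        const_counts = constitutive_cm.counts.loc[gene_id]
        magnitude, regulation, _ = splicing_index_fc(
            exon_counts, const_counts, factors, design, pseudocount
        )
        si = splicing_index(exon_counts, const_counts, factors, pseudocount)
        p = test_event(si, design)
        event = events_by_feature[feat]
        results.append(SplicingResult(gene_id, event, magnitude, regulation, p))
    return results


def results_table(results: list[SplicingResult]) -> pd.DataFrame:
    """Results as a table with study-style column names."""
    from .as_classifier import coordinates_string

    rows = [
        {
            "Gene Symbol": r.gene_id,
            "Alternative Event Type": r.event.event_type,
            "Involved Exon": r.event.feature_label,
            "Regulation Splicing Index": r.regulation,
            "Splicing-Index Fold-Change": r.si_fc_magnitude,
            "Splicing-Index p-Value": r.p_value,
            "Event Coordinates": coordinates_string(r.event),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
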