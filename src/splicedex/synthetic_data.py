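"""Seeded generators for every input the pipeline consumes.

Three generators stand in for the study's data:

* :func:`make_toy_annotation` — a deterministic toy annotation with at
  least one gene per splicing-event rule plus negative controls
  (a 9-nt sub-threshold first exon; a single-transcript gene), together
  with the hand-derived truth table of expected events;
* :func:`simulate_counts` — negative-binomial read counts on exon/intron
  features, constitutive regions, and low-coverage intergenic background,
  with splicing-index fold-changes planted by scaling case-group exon
  means against an unchanged constitutive baseline;
* :func:`simulate_cohort` — a three-group qPCR cohort (24 control, 72
  stable-disease, 32 infarction subjects by default) with planted group
  fold-changes for the two splice-variant targets, planted long/short
  correlations, and clinical covariates built with planted Pearson
  correlations to log expression.

All outputs are pure functions of the spec (seed included); regenerating
with the same spec is byte-identical.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .gene_model import GeneModel, write_gtf
from .qpcr_expression import CtRecord
from .splicing_quant import CountMatrix, SampleDesign

__all__ = [
    "CohortSpec",
    "CountSpec",
    "SimulationSpec",
    "make_toy_annotation",
    "simulate_counts",
    "simulate_cohort",
    "write_cohort",
]

GROUPS = ("CTR", "CAD", "AMI")


@dataclass
class CohortSpec:
    """Cohort sizes and planted effects for the qPCR stage.

    Group sizes and the planted fold-changes/ratio mirror the study design
    this generator emulates: 24/72/32 subjects, long-variant AMI-vs-CTR
    fold-change -3.3, short-variant AMI-vs-CTR -4.5 and AMI-vs-CAD -4.2,
    and an elevated long/short ratio (9.7) in the infarction group. The
    fold-changes and the AMI ratio over-determine the remaining group
    ratios, so those follow from the constraint rather than being set
    independently.
    """

    n_ctr: int = 24
    n_cad: int = 72
    n_ami: int = 32
    fc_long_ami_vs_ctr: float = -3.3
    fc_short_ami_vs_ctr: float = -4.5
    fc_short_ami_vs_cad: float = -4.2
    ratio_long_short_ami: float = 9.7
    ratio_long_short_cad: float = 5.7
    base_short_ami_expr: float = 0.004  # geometric-mean 2^(-dCt), ~dCt 8
    ct_noise_sd: float = 0.25  # cycles, per-subject biological+technical
    ref_ct_mean: float = 24.0
    ref_ct_sd: float = 0.3
    n_replicates: int = 2
    replicate_sd: float = 0.05  # cycles, within-plate technical
    # within-group correlation of long vs short log expression
    long_short_corr: dict = field(
        default_factory=lambda: {"CTR": 0.601, "CAD": 0.890, "AMI": 0.528}
    )
    # planted Pearson r of covariates vs long log2 expression, per group
    covariate_corr: dict = field(
        default_factory=lambda: {
            ("CTR", "hdl"): 0.545,
            ("CTR", "tg"): -0.460,
            ("AMI", "tg"): 0.461,
        }
    )
    # subjects per group with missing lipid covariates (listwise-drop rule)
    n_missing_lipids: dict = field(
        default_factory=lambda: {"CTR": 5, "CAD": 0, "AMI": 4}
    )
    hdl_mean: float = 50.0  # mg/dl
    hdl_sd: float = 12.0
    tg_mean: float = 150.0  # mg/dl
    tg_sd: float = 60.0

    def __post_init__(self):
        for n in (self.n_ctr, self.n_cad, self.n_ami):
            if n < 3:
                raise ValueError("group sizes must be >= 3")
        for fc in (self.fc_long_ami_vs_ctr, self.fc_short_ami_vs_ctr, self.fc_short_ami_vs_cad):
            if -1 < fc < 1:
                raise ValueError("planted fold-changes must have magnitude >= 1")
        for r in list(self.long_short_corr.values()) + list(self.covariate_corr.values()):
            if not -1 < r < 1:
                raise ValueError("planted correlations must satisfy |r| < 1")

    def group_sizes(self) -> dict[str, int]:
        return {"CTR": self.n_ctr, "CAD": self.n_cad, "AMI": self.n_ami}

    def group_means(self) -> dict[str, dict[str, float]]:
        """Planted geometric-mean expression per (group, target)."""
        s_ami = self.base_short_ami_expr
        l_ami = self.ratio_long_short_ami * s_ami
        means = {
            "AMI": {"long": l_ami, "short": s_ami},
            "CTR": {
                "long": abs(self.fc_long_ami_vs_ctr) * l_ami,
                "short": abs(self.fc_short_ami_vs_ctr) * s_ami,
            },
            "CAD": {
                "short": abs(self.fc_short_ami_vs_cad) * s_ami,
            },
        }
        means["CAD"]["long"] = self.ratio_long_short_cad * means["CAD"]["short"]
        return means

    def analytic_auc_cad_vs_ami(self) -> float:
        """AUC of the optimal linear combination of the two log2 levels for
        CAD vs AMI, under the generator's Gaussian model with a pooled
        covariance: Phi(sqrt(delta' Sigma^-1 delta / 2))."""
        m = self.group_means()
        delta = np.array([
            math.log2(m["CAD"]["long"] / m["AMI"]["long"]),
            math.log2(m["CAD"]["short"] / m["AMI"]["short"]),
        ])
        def cov(group):
            r = self.long_short_corr[group]
            return self.ct_noise_sd**2 * np.array([[1.0, r], [r, 1.0]])
        if self.ct_noise_sd == 0:  # noise-free limit: perfect separation
            return 1.0 if np.any(delta != 0) else 0.5
        w_cad, w_ami = self.n_cad - 1, self.n_ami - 1
        sigma = (w_cad * cov("CAD") + w_ami * cov("AMI")) / (w_cad + w_ami)
        maha2 = float(delta @ np.linalg.solve(sigma, delta))
        return float(stats.norm.cdf(math.sqrt(maha2 / 2.0)))


@dataclass
class CountSpec:
    """RNA-seq stage: a 2-vs-2 design by default, matching the sequencing
    arm this generator emulates; parameter-recovery suites raise n."""

    n_per_group: int = 2
    dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2
    constitutive_mean: float = 500.0
    exon_mean: float = 200.0
    intron_mean: float = 5.0
    intergenic_mean: float = 1.0
    n_intergenic: int = 40
    intergenic_length: int = 1000
    # feature id ("<gene>:<label>") -> planted signed splicing-index FC
    planted_si_fc: dict = field(default_factory=lambda: {"g_cassette:e2": -2.64})

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for fc in self.planted_si_fc.values():
            if -1 < fc < 1:
                raise ValueError("planted fold-changes must have magnitude >= 1")


@dataclass
class SimulationSpec:
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    counts: CountSpec = field(default_factory=CountSpec)


# ----------------------------------------------------------------------
# toy annotation
# ----------------------------------------------------------------------
_CHROM = "chrS"
_CHROM_SIZE = 100_000

# (gene, strand, {transcript: exons}) with gene-relative coordinates; the
# truth table below is the hand-application of the six rules.
_TOY_GENES: list[tuple[str, str, dict[str, list[tuple[int, int]]]]] = [
    ("g_cassette", "+", {"tA": [(101, 200), (301, 400), (501, 600)],
                         "tB": [(101, 200), (501, 600)]}),
    ("g_mcassette", "-", {"tA": [(101, 200), (301, 400), (501, 600)],
                          "tB": [(101, 200), (501, 600)]}),
    ("g_retention", "+", {"tA": [(101, 200), (301, 400)],
                          "tB": [(101, 400)]}),
    ("g_acceptor", "+", {"tA": [(101, 200), (301, 400), (501, 600)],
                         "tB": [(101, 200), (305, 400), (501, 600)]}),
    ("g_donor", "+", {"tA": [(101, 200), (301, 400), (501, 600)],
                      "tB": [(101, 200), (301, 396), (501, 600)]}),
    ("g_macceptor", "-", {"tA": [(101, 200), (301, 400), (501, 600)],
                          "tB": [(101, 200), (301, 396), (501, 600)]}),
    ("g_first", "+", {"tA": [(101, 200), (301, 400), (501, 600)],
                      "tC": [(286, 400), (501, 600)]}),
    ("g_negfirst", "+", {"tA": [(101, 200), (301, 400), (501, 600)],
                         "tC": [(292, 400), (501, 600)]}),  # 9 nt: below threshold
    ("g_terminal", "+", {"tA": [(101, 200), (301, 400), (501, 600)],
                         "tD": [(101, 200), (301, 415)]}),
    ("g_single", "+", {"tA": [(101, 200), (301, 400), (501, 600)]}),
]

# expected (gene_id, event_type, feature_label); genes absent here must
# yield no events
TOY_TRUTH_TABLE: list[tuple[str, str, str]] = [
    ("g_cassette", "exon_cassette", "e2"),
    ("g_mcassette", "exon_cassette", "e2"),
    ("g_retention", "intron_retention", "i1"),
    ("g_acceptor", "alternative_acceptor_site", "e2"),
    ("g_donor", "alternative_donor_site", "e2"),
    ("g_macceptor", "alternative_acceptor_site", "e2"),
    ("g_first", "alternative_first_exon", "e2"),
    ("g_terminal", "alternative_terminal_exon", "ae2"),
]


def make_toy_annotation(
    spec: SimulationSpec | None = None, gtf_path: str | None = None
) -> tuple[dict[str, GeneModel], list[tuple[str, str, str]]]:
    """Build the toy gene-model set and its expected-event truth table.

    The construction is deterministic (gene placement is fixed), so the
    serialized GTF is byte-identical across calls.
    """
    models: dict[str, GeneModel] = {}
    for i, (gid, strand, txs) in enumerate(_TOY_GENES):
        offset = 1000 + i * 2000
        shifted = {
            tid: [(s + offset, e + offset) for s, e in exons]
            for tid, exons in txs.items()
        }
        models[gid] = GeneModel.from_transcript_exons(gid, _CHROM, strand, shifted)
    if gtf_path is not None:
        write_gtf(models, gtf_path)
    return models, list(TOY_TRUTH_TABLE)


def toy_chrom_sizes() -> dict[str, int]:
    return {_CHROM: _CHROM_SIZE}


# ----------------------------------------------------------------------
# RNA-seq counts
# ----------------------------------------------------------------------
def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, float)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _gene_factors(rng: np.random.Generator, n: int, dispersion: float) -> np.ndarray:
    """Per-sample gene-level biological expression factors.

    Gamma with mean 1 and variance ``dispersion``: counts drawn
    Poisson(mu * factor) are marginally negative binomial with
    var = mu + dispersion * mu^2, and the factor is shared by all features
    of the gene in that sample, as biological expression variation is —
    the splicing index cancels it by construction.
    """
    shape = 1.0 / dispersion
    return rng.gamma(shape, dispersion, size=n)


def simulate_counts(
    models: dict[str, GeneModel], spec: SimulationSpec
) -> tuple[CountMatrix, CountMatrix, CountMatrix, SampleDesign, dict]:
    """NB counts for exon/intron features, constitutive regions, and
    intergenic background in a CTR-vs-CAD two-group design.

    Case-group (CAD) means of planted features are scaled by the planted
    splicing-index fold-change while the constitutive baseline is left
    unchanged; every sample gets its own library-depth factor so that
    median-of-ratios normalization is exercised. Biological overdispersion
    enters as a per-(sample, gene) expression factor shared by the gene's
    exon, intron and constitutive features, with Poisson counting noise on
    top — marginally negative binomial, but (as for real reads, which all
    come from the same RNA) cancelling in the splicing index.
    """
    from .splicing_quant import CountMatrix  # local to avoid cycle confusion

    cs = spec.counts
    for feat in cs.planted_si_fc:
        gid = feat.split(":", 1)[0]
        if gid not in models:
            raise ValueError(f"planted feature {feat!r} has no gene model")
    rng = np.random.default_rng([spec.seed, 1])
    n = cs.n_per_group
    samples = [f"CTR_{i+1}" for i in range(n)] + [f"CAD_{i+1}" for i in range(n)]
    design = SampleDesign(
        {s: ("CTR" if s.startswith("CTR") else "CAD") for s in samples},
        reference_group="CTR",
    )
    depth = rng.uniform(0.8, 1.2, size=2 * n)

    exon_rows, exon_lengths, exon_ids = [], [], []
    const_rows, const_lengths, const_ids = [], [], []
    for gid in sorted(models):
        m = models[gid]
        gene_factor = _gene_factors(rng, 2 * n, cs.dispersion)
        feats = [(g.exon_label, g.start, g.end, cs.exon_mean) for g in m.genomic_exons]
        feats += [(lab, lo, hi, cs.intron_mean) for lab, lo, hi in m.introns()]
        for lab, lo, hi, base in feats:
            fid = f"{gid}:{lab}"
            fc = cs.planted_si_fc.get(fid)
            case_scale = 1.0 if fc is None else (fc if fc >= 1 else 1.0 / abs(fc))
            mean = np.array(
                [base] * n + [base * case_scale] * n
            ) * depth * gene_factor
            exon_rows.append(rng.poisson(mean))
            exon_lengths.append(hi - lo + 1)
            exon_ids.append(fid)
        const_rows.append(rng.poisson(cs.constitutive_mean * depth * gene_factor))
        from .gene_model import constitutive_regions
        const_lengths.append(
            sum(r.end - r.start + 1 for r in constitutive_regions(m)) or 1
        )
        const_ids.append(gid)

    inter_rows = [
        _nb(rng, cs.intergenic_mean * depth, cs.dispersion)
        for _ in range(cs.n_intergenic)
    ]
    inter_ids = [f"intergenic_{k+1}" for k in range(cs.n_intergenic)]

    def cm(rows, ids, lengths):
        return CountMatrix(
            pd.DataFrame(np.array(rows), index=ids, columns=samples),
            pd.Series(lengths, index=ids),
        )

    exon_cm = cm(exon_rows, exon_ids, exon_lengths)
    const_cm = cm(const_rows, const_ids, const_lengths)
    inter_cm = cm(
        inter_rows, inter_ids, [cs.intergenic_length] * cs.n_intergenic
    )
    truth = {"planted_si_fc": dict(cs.planted_si_fc), "depth": depth.tolist()}
    return exon_cm, const_cm, inter_cm, design, truth


# ----------------------------------------------------------------------
# qPCR cohort
# ----------------------------------------------------------------------
def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[list[CtRecord], pd.DataFrame, dict]:
    """Generate Ct records, clinical covariates, and the truth record.

    Reference-gene Ct ~ Normal(24, 0.3); target Ct = reference Ct -
    log2(planted expression) + noise, with (long, short) noise drawn
    bivariate-normal at the planted within-group correlation. Covariates
    get their planted Pearson correlation to long log2 expression through
    the usual Cholesky/orthogonal-mixture construction; a fixed number of
    subjects per group have missing lipid values.
    """
    co = spec.cohort
    rng = np.random.default_rng([spec.seed, 2])
    means = co.group_means()

    records: list[CtRecord] = []
    cov_rows = []
    truth_expr: dict[str, dict[str, list[float]]] = {}
    for group in GROUPS:
        n = co.group_sizes()[group]
        r = co.long_short_corr[group]
        L = np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]]))
        z = rng.standard_normal((n, 2)) @ L.T * co.ct_noise_sd
        ref_ct = rng.normal(co.ref_ct_mean, co.ref_ct_sd, size=n)
        log2_long = math.log2(means[group]["long"]) - z[:, 0]
        log2_short = math.log2(means[group]["short"]) - z[:, 1]
        truth_expr[group] = {
            "log2_long": log2_long.tolist(),
            "log2_short": log2_short.tolist(),
        }

        # covariates correlated with the long-variant log expression
        if co.ct_noise_sd > 0:
            t_long = -z[:, 0] / co.ct_noise_sd  # standardized
        else:
            t_long = np.zeros(n)  # noise-free limit: nothing to correlate with
        missing_idx = set(
            rng.choice(n, size=co.n_missing_lipids.get(group, 0), replace=False)
        )
        for name, mu, sd in (("hdl", co.hdl_mean, co.hdl_sd), ("tg", co.tg_mean, co.tg_sd)):
            rr = co.covariate_corr.get((group, name), 0.0)
            eta = rng.standard_normal(n)
            vals = mu + sd * (rr * t_long + math.sqrt(1 - rr**2) * eta)
            np.clip(vals, 1.0, None, out=vals)
            if name == "hdl":
                hdl = vals
            else:
                tg = vals

        for i in range(n):
            sid = f"{group}_{i+1:03d}"
            ct_ref = ref_ct[i]
            ct_long = ct_ref - log2_long[i]
            ct_short = ct_ref - log2_short[i]
            for target, ct in (("long", ct_long), ("short", ct_short), ("reference", ct_ref)):
                reps = ct + rng.normal(0.0, co.replicate_sd, size=co.n_replicates)
                records.append(CtRecord(sid, group, target, tuple(np.round(reps, 4))))
            miss = i in missing_idx
            cov_rows.append(
                {
                    "sample_id": sid,
                    "group": group,
                    "hdl": np.nan if miss else round(float(hdl[i]), 1),
                    "tg": np.nan if miss else round(float(tg[i]), 1),
                }
            )

    covariates = pd.DataFrame(cov_rows)
    truth = {
        "seed": spec.seed,
        "group_sizes": co.group_sizes(),
        "planted_fc": {
            "long_ami_vs_ctr": co.fc_long_ami_vs_ctr,
            "short_ami_vs_ctr": co.fc_short_ami_vs_ctr,
            "short_ami_vs_cad": co.fc_short_ami_vs_cad,
        },
        "planted_ratio_long_short": {
            "AMI": co.ratio_long_short_ami,
            "CAD": co.ratio_long_short_cad,
        },
        "planted_long_short_corr": dict(co.long_short_corr),
        "planted_covariate_corr": {
            f"{g}:{c}": v for (g, c), v in co.covariate_corr.items()
        },
        "group_geometric_means": means,
        "analytic_auc_cad_vs_ami": co.analytic_auc_cad_vs_ami(),
    }
    return records, covariates, truth


def write_cohort(
    records: list[CtRecord], covariates: pd.DataFrame, truth: dict, out_dir: str
) -> None:
    """Write ct.csv (long format), clinical.csv and truth.json."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in records:
        row = {"sample_id": rec.sample_id, "group": rec.group, "target": rec.target}
        for k, c in enumerate(rec.ct_replicates, 1):
            row[f"ct_rep{k}"] = c
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "ct.csv"), index=False)
    covariates.to_csv(os.path.join(out_dir, "clinical.csv"), index=False)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
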