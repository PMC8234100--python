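"""Gene models: reference ("genomic") exons, transcript exon chains, and the
derived constitutive and intergenic regions.

A gene model carries two views of a locus. *Transcript exons* are the exons
exactly as each annotated transcript uses them. *Genomic exons* are the
reference exon units of the locus, reconstructed as the merged union of all
transcript exons after removing introns that another transcript splices out
(so a retained intron stays an intron in the reference structure rather than
being absorbed into a merged exon). Genomic exons are labelled ``e1..eN`` in
transcription order; the gap after exon *k* (again in transcription order) is
intron ``i<k>``.

Coordinates are 1-based inclusive throughout; BED output converts to 0-based
half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils

from . import intervals as iv

__all__ = [
    "GenomicExon",
    "TranscriptExon",
    "GeneModel",
    "Region",
    "AnnotationParseError",
    "GeneModelError",
    "CoordinateError",
    "parse_annotation",
    "corresponding_genomic_exon",
    "constitutive_regions",
    "intergenic_regions",
    "write_gtf",
    "write_bed6",
]


class AnnotationParseError(ValueError):
    """A record in the annotation file could not be parsed."""


class GeneModelError(ValueError):
    """Transcript structure violates gene-model invariants."""


class CoordinateError(ValueError):
    """Coordinates fall outside the stated chromosome."""


@dataclass(frozen=True)
class GenomicExon:
    gene_id: str
    exon_label: str  # "e<k>", k in transcription order
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise GeneModelError(f"{self.gene_id} {self.exon_label}: start > end")


@dataclass(frozen=True)
class TranscriptExon:
    transcript_id: str
    ordinal: int  # 1-based, transcription order
    chrom: str
    start: int
    end: int
    strand: str
    role: str  # first | internal | last | only


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    kind: str  # constitutive | intergenic | exon | intron
    name: str = ""


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    genomic_exons: list[GenomicExon] = field(default_factory=list)
    transcripts: dict[str, list[TranscriptExon]] = field(default_factory=dict)

    # ------------------------------------------------------------------
    @classmethod
    def from_transcript_exons(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        transcript_exons: dict[str, list[tuple[int, int]]],
    ) -> "GeneModel":
        """Build a model from raw per-transcript exon intervals.

        Reference exons are the merged union of transcript exons, computed
        after subtracting from each transcript exon any intron of another
        transcript that it fully contains (intron retention must not merge
        the flanking reference exons).
        """
        if not transcript_exons:
            raise GeneModelError(f"{gene_id}: no transcripts")
        if strand not in "+-":
            raise GeneModelError(f"{gene_id}: bad strand {strand!r}")

        # All introns implied by any transcript's splicing.
        tx_introns: list[tuple[int, int]] = []
        per_tx_sorted: dict[str, list[tuple[int, int]]] = {}
        for tid, exons in transcript_exons.items():
            if not exons:
                raise GeneModelError(f"{gene_id}/{tid}: transcript without exons")
            exs = sorted(exons)
            for (s1, e1), (s2, e2) in zip(exs, exs[1:]):
                if s2 <= e1:
                    raise GeneModelError(f"{gene_id}/{tid}: overlapping exons")
                tx_introns.append((e1 + 1, s2 - 1))
            per_tx_sorted[tid] = exs

        pieces: list[tuple[int, int]] = []
        for tid, exs in per_tx_sorted.items():
            own = {(e1 + 1, s2 - 1) for (s1, e1), (s2, e2) in zip(exs, exs[1:])}
            retained = [i for i in tx_introns if i not in own]
            for ex in exs:
                inner = [i for i in retained if iv.contains(ex, i)]
                pieces.extend(iv.subtract([ex], inner))

        union = iv.merge(pieces)
        ordered = union if strand == "+" else list(reversed(union))
        gexons = [
            GenomicExon(gene_id, f"e{k}", chrom, s, e, strand)
            for k, (s, e) in enumerate(ordered, start=1)
        ]

        transcripts: dict[str, list[TranscriptExon]] = {}
        for tid, exs in per_tx_sorted.items():
            chain = exs if strand == "+" else list(reversed(exs))
            n = len(chain)
            out = []
            for k, (s, e) in enumerate(chain, start=1):
                role = (
                    "only" if n == 1 else
                    "first" if k == 1 else
                    "last" if k == n else "internal"
                )
                out.append(TranscriptExon(tid, k, chrom, s, e, strand, role))
            transcripts[tid] = out

        return cls(gene_id, chrom, strand, gexons, transcripts)

    # ------------------------------------------------------------------
    @property
    def span(self) -> tuple[int, int]:
        starts = [te.start for tes in self.transcripts.values() for te in tes]
        ends = [te.end for tes in self.transcripts.values() for te in tes]
        return min(starts), max(ends)

    def introns(self) -> list[tuple[str, int, int]]:
        """``(label, start, end)`` for gaps between adjacent genomic exons;
        ``i<k>`` follows exon ``e<k>`` in transcription order."""
        out = []
        ex = self.genomic_exons
        for k in range(len(ex) - 1):
            a, b = ex[k], ex[k + 1]
            lo, hi = (a.end + 1, b.start - 1) if self.strand == "+" else (b.end + 1, a.start - 1)
            if lo <= hi:
                out.append((f"i{k + 1}", lo, hi))
        return out

    def exon_by_label(self, label: str) -> GenomicExon:
        for g in self.genomic_exons:
            if g.exon_label == label:
                return g
        raise KeyError(label)


# ----------------------------------------------------------------------
def parse_annotation(path: str, dialect: str = "gtf") -> dict[str, GeneModel]:
    """Parse a GTF/GFF3 file into gene models keyed by gene_id.

    Exon features must carry ``gene_id`` and ``transcript_id`` attributes
    (both GTF 2.2 and the GFF3 flavour written by this package do).
    """
    if dialect not in {"gtf", "gff3"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise AnnotationParseError(f"cannot parse {path}: {exc}") from exc

    per_gene: dict[str, dict[str, list[tuple[int, int]]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    tx_meta: dict[str, tuple[str, str]] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            gid = feat.attributes["gene_id"][0]
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationParseError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks {exc} attribute"
            ) from exc
        tkey = (gid, tid)
        if tkey in tx_meta and tx_meta[tkey] != (feat.seqid, feat.strand):
            raise GeneModelError(
                f"transcript {tid} spans multiple chromosomes/strands"
            )
        tx_meta[tkey] = (feat.seqid, feat.strand)
        if gid in meta and meta[gid] != (feat.seqid, feat.strand):
            raise GeneModelError(f"gene {gid} spans multiple chromosomes/strands")
        meta[gid] = (feat.seqid, feat.strand)
        per_gene.setdefault(gid, {}).setdefault(tid, []).append((feat.start, feat.end))

    models = {}
    for gid, txs in per_gene.items():
        chrom, strand = meta[gid]
        models[gid] = GeneModel.from_transcript_exons(gid, chrom, strand, txs)
    return models


def corresponding_genomic_exon(t_exon: TranscriptExon, model: GeneModel) -> GenomicExon | None:
    """Genomic exon with maximal overlap; ties go to the 5'-most exon in
    transcription direction; ``None`` if nothing overlaps."""
    best: GenomicExon | None = None
    best_ov = 0
    for g in model.genomic_exons:  # already in transcription order
        ov = iv.overlap_len((t_exon.start, t_exon.end), (g.start, g.end))
        if ov > best_ov:
            best, best_ov = g, ov
    return best


def constitutive_regions(model: GeneModel) -> list[Region]:
    """Maximal intervals covered by every transcript's exons."""
    lists = [
        [(te.start, te.end) for te in tes] for tes in model.transcripts.values()
    ]
    common = iv.intersect_many(lists)
    return [Region(model.chrom, s, e, "constitutive", model.gene_id) for s, e in common]


def intergenic_regions(
    models: dict[str, GeneModel] | list[GeneModel], chrom_sizes: dict[str, int]
) -> list[Region]:
    """Complement of merged gene spans per chromosome, clipped to [1, size]."""
    if isinstance(models, dict):
        models = list(models.values())
    spans: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        if m.chrom not in chrom_sizes:
            raise CoordinateError(f"no size for chromosome {m.chrom}")
        s, e = m.span
        if e > chrom_sizes[m.chrom] or s < 1:
            raise CoordinateError(
                f"gene {m.gene_id} span {s}-{e} exceeds {m.chrom} size "
                f"{chrom_sizes[m.chrom]}"
            )
        spans.setdefault(m.chrom, []).append((s, e))
    out = []
    for chrom in sorted(spans):
        for s, e in iv.complement(spans[chrom], 1, chrom_sizes[chrom]):
            out.append(Region(chrom, s, e, "intergenic", "intergenic"))
    return out


# ----------------------------------------------------------------------
def write_gtf(models: dict[str, GeneModel] | list[GeneModel], path: str) -> None:
    """Serialize gene models as GTF 2.2 exon features (round-trip safe)."""
    if isinstance(models, dict):
        models = list(models.values())
    with open(path, "w") as fh:
        for m in sorted(models, key=lambda m: (m.chrom, m.span[0], m.gene_id)):
            for tid in sorted(m.transcripts):
                for te in sorted(m.transcripts[tid], key=lambda t: t.start):
                    attrs = f'gene_id "{m.gene_id}"; transcript_id "{tid}";'
                    fh.write(
                        f"{m.chrom}\tsplicedex\texon\t{te.start}\t{te.end}\t.\t"
                        f"{m.strand}\t.\t{attrs}\n"
                    )


def write_bed6(regions: list[Region], path: str) -> None:
    """BED6 output: 0-based half-open, score 0, strand '.'"""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name or r.kind}\t0\t.\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise AnnotationParseError(f"{path}:{ln}: expected 'chrom<TAB>size'")
            sizes[parts[0]] = int(parts[1])
    return sizes
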