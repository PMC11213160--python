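"""Transcript models and SV gene-impact classification.

Each retained SV is classified per candidate gene into exactly one
category of the gene-overlap taxonomy: pLoF, CG (copy gain), IED
(intragenic exon duplication), partial_gene_DUP, partial_exon_DUP,
whole_gene_INV, UTR, promoter, intronic, enhancer or intergenic.

Conventions: the affected base span of an intra-chromosomal event with
breakpoints (p1, p2) is the half-open-converted interval [p1+1, p2]
(VCF semantics: POS is the base before the event); breakpoint containment
uses the reported positions directly.  Promoters are the 1 kb window
immediately upstream of the TSS on the transcribed strand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sv_io import GenomicBreakpoint, SVRecord, canonicalize

log = logging.getLogger(__name__)

GENE_DISRUPTIVE = frozenset({"pLoF", "CG", "IED"})

CATEGORIES = (
    "pLoF",
    "CG",
    "IED",
    "partial_gene_DUP",
    "partial_exon_DUP",
    "whole_gene_INV",
    "UTR",
    "promoter",
    "intronic",
    "enhancer",
    "intergenic",
)

DEFAULT_MAX_SPAN = 1_000_000
DEFAULT_PROMOTER_SIZE = 1_000
DEFAULT_FLANK = 10_000

Interval = tuple[int, int]  # 1-based inclusive


@dataclass
class TranscriptModel:
    """Canonical transcript of one gene (1-based inclusive intervals)."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval]
    cds_segments: list[Interval]

    def __post_init__(self) -> None:
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds_segments = sorted(tuple(c) for c in self.cds_segments)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def utr_segments(self) -> list[Interval]:
        """Exonic bases not covered by CDS."""
        out: list[Interval] = []
        for ex in self.exons:
            pieces = [ex]
            for cds in self.cds_segments:
                nxt = []
                for s, e in pieces:
                    if cds[1] < s or cds[0] > e:
                        nxt.append((s, e))
                        continue
                    if s < cds[0]:
                        nxt.append((s, cds[0] - 1))
                    if e > cds[1]:
                        nxt.append((cds[1] + 1, e))
                pieces = nxt
            out.extend(pieces)
        return sorted(out)

    @property
    def introns(self) -> list[Interval]:
        return [
            (e1 + 1, s2 - 1)
            for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
            if s2 - e1 > 1
        ]

    def promoter_window(self, size: int = DEFAULT_PROMOTER_SIZE) -> Interval:
        """1 kb window immediately upstream of the TSS (strand-aware)."""
        if self.strand == "+":
            return (max(1, self.tss - size), self.tss - 1)
        return (self.tss + 1, self.tss + size)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class RegulatoryElement:
    chrom: str
    start: int
    end: int
    element_type: str  # promoter | enhancer
    target_gene: str

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class ImpactAnnotation:
    sv_id: str
    gene_id: str | None
    category: str
    fusion_partner: str | None = None
    evidence: str = ""


# ---------------------------------------------------------------------------
# readers


def read_gene_models(gtf_path: str | Path) -> list[TranscriptModel]:
    """Load canonical transcript models from a GTF/GFF3 file.

    When a gene has several transcripts, the one tagged
    ``Ensembl_canonical`` wins; otherwise the first by coordinate.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[TranscriptModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="transcript"))
        if not transcripts:
            continue
        canonical = None
        for t in transcripts:
            tags = t.attributes.get("tag", [])
            if any("Ensembl_canonical" in tag for tag in tags):
                canonical = t
                break
        if canonical is None:
            canonical = transcripts[0]
        exons = [(e.start, e.end) for e in db.children(canonical, featuretype="exon")]
        cds = [(c.start, c.end) for c in db.children(canonical, featuretype="CDS")]
        name = gene.attributes.get("gene_name", [gene.id])[0]
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                gene_name=name,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons,
                cds_segments=cds,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start))
    return models


def read_enhancers(bed_path: str | Path) -> list[RegulatoryElement]:
    """BED4 enhancer file (name column = target gene id); converts the
    0-based half-open BED coordinates to 1-based inclusive."""
    out: list[RegulatoryElement] = []
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            out.append(
                RegulatoryElement(
                    chrom=chrom,
                    start=int(start) + 1,
                    end=int(end),
                    element_type="enhancer",
                    target_gene=name,
                )
            )
    return out


# ---------------------------------------------------------------------------
# classification


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _affected_interval(sv: SVRecord) -> Interval | None:
    if sv.svtype == "TRA":
        return None
    sv = canonicalize(sv)
    if sv.svtype == "INS":
        return (sv.bp1.pos, sv.bp1.pos)
    return (sv.bp1.pos + 1, sv.bp2.pos)


def candidate_genes(
    sv: SVRecord,
    models: Sequence[TranscriptModel],
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[TranscriptModel]:
    """Genes to classify this SV against.

    Events with a defined span <= ``max_span`` take every gene their
    interval intersects; larger events and translocations only genes
    containing a breakpoint (short-read large-SV interiors are not
    trusted).
    """
    sv = canonicalize(sv)
    span = _affected_interval(sv)
    if span is not None and sv.svtype != "TRA" and (span[1] - span[0] + 1) <= max_span:
        return [
            m
            for m in models
            if m.chrom == sv.bp1.chrom and _overlaps(span, (m.start, m.end))
        ]
    return [
        m
        for m in models
        if m.contains(sv.bp1.chrom, sv.bp1.pos) or m.contains(sv.bp2.chrom, sv.bp2.pos)
    ]


def classify_impact(
    sv: SVRecord,
    gene: TranscriptModel,
    regulatory: Sequence[RegulatoryElement] = (),
    promoter_size: int = DEFAULT_PROMOTER_SIZE,
) -> ImpactAnnotation:
    """Assign exactly one impact category for this (SV, gene) pair.

    Gene-body rules fire first (per-type decision table), then promoter,
    then enhancer, else intergenic.
    """
    sv = canonicalize(sv)
    span = _affected_interval(sv)
    bp1_in = gene.contains(sv.bp1.chrom, sv.bp1.pos)
    bp2_in = gene.contains(sv.bp2.chrom, sv.bp2.pos)

    def hits(segments: Iterable[Interval]) -> bool:
        return span is not None and any(_overlaps(span, seg) for seg in segments)

    def bp_in(segments: Iterable[Interval], bp: GenomicBreakpoint) -> bool:
        return bp.chrom == gene.chrom and any(
            s <= bp.pos <= e for s, e in segments
        )

    category = evidence = None
    if sv.svtype == "DEL":
        if hits(gene.cds_segments):
            category, evidence = "pLoF", "removes CDS bases"
        elif hits(gene.utr_segments):
            category, evidence = "UTR", "removes UTR exon bases only"
        elif span is not None and any(
            i[0] <= span[0] and span[1] <= i[1] for i in gene.introns
        ):
            category, evidence = "intronic", "fully within one intron"
    elif sv.svtype == "DUP":
        gene_inside = (
            span is not None
            and gene.chrom == sv.bp1.chrom
            and span[0] <= gene.start
            and gene.end <= span[1]
        )
        if not bp1_in and not bp2_in and gene_inside:
            category, evidence = "CG", "gene fully duplicated"
        elif bp1_in and bp2_in:
            if bp_in(gene.exons, sv.bp1) and bp_in(gene.exons, sv.bp2):
                category, evidence = "pLoF", "both breakpoints in exons"
            elif span is not None and any(
                span[0] <= s and e <= span[1] for s, e in gene.exons
            ):
                category, evidence = "IED", ">=1 exon fully duplicated in-gene"
            else:
                category, evidence = "partial_exon_DUP", "intragenic, no whole exon"
        elif bp1_in != bp2_in:
            category, evidence = "partial_gene_DUP", "one breakpoint in gene"
    elif sv.svtype == "INV":
        gene_inside = (
            span is not None
            and gene.chrom == sv.bp1.chrom
            and span[0] <= gene.start
            and gene.end <= span[1]
        )
        if gene_inside and not bp1_in and not bp2_in:
            category, evidence = "whole_gene_INV", "gene fully inverted"
        elif bp1_in or bp2_in:
            category, evidence = "pLoF", "breakpoint in gene body"
    elif sv.svtype == "TRA":
        if bp1_in or bp2_in:
            category, evidence = "pLoF", "breakpoint in gene body"
    elif sv.svtype == "INS":
        if bp_in(gene.cds_segments, sv.bp1):
            category, evidence = "pLoF", "insertion in CDS"
        elif bp_in(gene.utr_segments, sv.bp1):
            category, evidence = "UTR", "insertion in UTR exon"
        elif bp_in(gene.introns, sv.bp1):
            category, evidence = "intronic", "insertion in intron"

    if category is None:
        promoter = gene.promoter_window(promoter_size)
        if bp_in([promoter], sv.bp1) or bp_in([promoter], sv.bp2):
            category, evidence = "promoter", "breakpoint in promoter window"
        else:
            enh = [
                e
                for e in regulatory
                if e.element_type == "enhancer" and e.target_gene == gene.gene_id
            ]
            if any(e.contains(bp.chrom, bp.pos) for e in enh for bp in (sv.bp1, sv.bp2)):
                category, evidence = "enhancer", "breakpoint in target enhancer"
            else:
                category, evidence = "intergenic", "no rule fired"
    return ImpactAnnotation(sv.id, gene.gene_id, category, evidence=evidence)


def annotate_fusion(
    tra: SVRecord, models: Sequence[TranscriptModel]
) -> str | None:
    """``GENE1-GENE2`` label when both breakpoints land in distinct genes,
    in reported breakpoint order; ``None`` otherwise."""
    if tra.svtype != "TRA":
        return None
    g1 = next(
        (m for m in models if m.contains(tra.bp1.chrom, tra.bp1.pos)), None
    )
    g2 = next(
        (m for m in models if m.contains(tra.bp2.chrom, tra.bp2.pos)), None
    )
    if g1 is None or g2 is None or g1.gene_id == g2.gene_id:
        return None
    return f"{g1.gene_name}-{g2.gene_name}"


def annotate_sv(
    sv: SVRecord,
    models: Sequence[TranscriptModel],
    regulatory: Sequence[RegulatoryElement] = (),
    max_span: int = DEFAULT_MAX_SPAN,
    promoter_size: int = DEFAULT_PROMOTER_SIZE,
) -> list[ImpactAnnotation]:
    """All per-gene annotations for one SV (plus fusion labelling for TRA).

    SVs hitting no gene at all get a single gene-less ``intergenic`` (or
    ``promoter``/``enhancer``) annotation.
    """
    sv = canonicalize(sv)
    genes = candidate_genes(sv, models, max_span=max_span)
    nearby = genes or _regulatory_neighbours(sv, models, regulatory, promoter_size)
    annotations = [
        classify_impact(sv, g, regulatory, promoter_size) for g in nearby
    ]
    if not annotations:
        annotations = [ImpactAnnotation(sv.id, None, "intergenic", evidence="no gene nearby")]
    fusion = annotate_fusion(sv, models)
    if fusion is not None:
        for ann in annotations:
            if ann.category == "pLoF":
                ann.fusion_partner = fusion
    return annotations


def _regulatory_neighbours(
    sv: SVRecord,
    models: Sequence[TranscriptModel],
    regulatory: Sequence[RegulatoryElement],
    promoter_size: int,
) -> list[TranscriptModel]:
    """Genes whose promoter or linked enhancer contains an SV breakpoint."""
    out = []
    by_id = {m.gene_id: m for m in models}
    for m in models:
        w = m.promoter_window(promoter_size)
        if any(
            bp.chrom == m.chrom and w[0] <= bp.pos <= w[1]
            for bp in (sv.bp1, sv.bp2)
        ):
            out.append(m)
    for e in regulatory:
        if e.element_type != "enhancer" or e.target_gene not in by_id:
            continue
        if any(e.contains(bp.chrom, bp.pos) for bp in (sv.bp1, sv.bp2)):
            m = by_id[e.target_gene]
            if m not in out:
                out.append(m)
    return out


def write_impact_table(
    annotations: Sequence[ImpactAnnotation], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sv_id\tgene_id\tcategory\tfusion\tevidence\n")
        for a in annotations:
            fh.write(
                f"{a.sv_id}\t{a.gene_id or 'NA'}\t{a.category}\t"
                f"{a.fusion_partner or 'NA'}\t{a.evidence}\n"
            )
    return path


# ---------------------------------------------------------------------------
# read-depth sanity check


def depth_ratio(
    sv: SVRecord,
    depth: Mapping[str, np.ndarray],
    flank: int = DEFAULT_FLANK,
) -> float:
    """Mean depth inside a DEL/DUP divided by the mean of its +-flank.

    ``depth`` maps chromosome -> per-base coverage (index 0 = position 1).
    Flanks extending beyond the contig are truncated with a warning.
    """
    if sv.svtype not in ("DEL", "DUP"):
        raise ValueError("depth_ratio applies to DEL/DUP only")
    sv = canonicalize(sv)
    track = np.asarray(depth[sv.bp1.chrom], dtype=float)
    lo, hi = sv.bp1.pos, sv.bp2.pos  # affected bases lo+1..hi -> idx lo..hi-1
    inside = track[lo : hi]
    left_start = lo - flank
    right_end = hi + flank
    if left_start < 0 or right_end > len(track):
        warnings.warn("flank truncated at contig boundary")
        left_start = max(0, left_start)
        right_end = min(len(track), right_end)
    flanks = np.concatenate([track[left_start:lo], track[hi:right_end]])
    return float(inside.mean() / flanks.mean())
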