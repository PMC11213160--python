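"""SV record model and VCF I/O in the supported caller dialects.

Three dialects are supported:

``manta``
    Symbolic ALT records (``<DEL>``, ``<DUP:TANDEM>``, ``<INS>``, ``<INV>``)
    with ``END``/``SVLEN`` INFO fields; inter-chromosomal junctions are
    emitted as paired BND lines.
``gridss``
    Every junction as paired bracket-notation BND lines (plus symbolic
    ``<INS>`` for fully assembled insertions).
``genotyped``
    Multi-sample aggregate VCF with per-site ``PASS_ratio`` INFO and
    ``GT:FT:GQ`` FORMAT fields; INV/TRA sites are BND pairs (no FT there,
    genotype quality gates those instead).

Coordinates are 1-based VCF-style throughout.  The length of an
intra-chromosomal event is ``bp2.pos - bp1.pos`` (end minus start, no +1),
insertions use the inserted sequence length, and translocations have no
defined length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

log = logging.getLogger(__name__)

SIMPLE_TYPES = ("DEL", "DUP", "INS", "INV", "TRA")

#: junction orientation of (bp1, bp2) implied by each intra-chromosomal type
_TYPE_ORIENTS = {
    "DEL": ("+", "-"),
    "DUP": ("-", "+"),
    "INV": ("+", "+"),
    "INS": ("+", "-"),
}

_ORIENTS_TO_TYPE = {
    ("+", "-"): "DEL",
    ("-", "+"): "DUP",
    ("+", "+"): "INV",
    ("-", "-"): "INV",
}

_BND_RE = re.compile(
    r"^([A-Za-z.]*)([\[\]])([^\[\]:]+):(\d+)([\[\]])([A-Za-z.]*)$"
)


class SVParseError(ValueError):
    """Malformed SV record (carries the offending data-line number)."""


@dataclass(frozen=True)
class GenomicBreakpoint:
    """One side of a junction: 1-based position plus orientation.

    ``orient`` is ``"+"`` when the joined segment extends to the left of the
    breakpoint (the breakend is at a segment's right edge) and ``"-"`` when
    it extends to the right.
    """

    chrom: str
    pos: int
    orient: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"breakpoint position must be >= 1, got {self.pos}")
        if not self.chrom:
            raise ValueError("breakpoint chromosome must be non-empty")
        if self.orient not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orient!r}")


@dataclass
class SVRecord:
    """One structural variant with two breakpoints and caller provenance."""

    id: str
    bp1: GenomicBreakpoint
    bp2: GenomicBreakpoint
    svtype: str
    caller: str = ""
    filter_pass: bool = True
    mate_id: str | None = None
    insertion_seq: str | None = None
    #: True when the record was resolved from paired BND lines; the
    #: genotype-QC stage gates these on GQ instead of FT.
    bnd_derived: bool = False

    def __post_init__(self) -> None:
        if self.svtype not in SIMPLE_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        inter = self.bp1.chrom != self.bp2.chrom
        if inter != (self.svtype == "TRA"):
            raise ValueError(
                f"{self.id}: TRA iff breakpoints on different chromosomes "
                f"(got {self.svtype} on {self.bp1.chrom}/{self.bp2.chrom})"
            )

    @property
    def is_intra(self) -> bool:
        return self.bp1.chrom == self.bp2.chrom

    def key(self) -> tuple:
        """Equality key ignoring orientation bookkeeping and mate ids."""
        return (
            self.id,
            self.bp1.chrom,
            self.bp1.pos,
            self.bp2.chrom,
            self.bp2.pos,
            self.svtype,
            self.filter_pass,
            self.insertion_seq,
        )


def make_record(
    id: str,
    chrom1: str,
    pos1: int,
    chrom2: str,
    pos2: int,
    svtype: str,
    **kwargs,
) -> SVRecord:
    """Convenience constructor assigning type-conventional orientations."""
    if svtype == "TRA":
        o1, o2 = "+", "-"
    elif svtype in _TYPE_ORIENTS:
        o1, o2 = _TYPE_ORIENTS[svtype]
    else:
        raise ValueError(f"unknown SV type {svtype!r}")
    rec = SVRecord(
        id=id,
        bp1=GenomicBreakpoint(chrom1, pos1, o1),
        bp2=GenomicBreakpoint(chrom2, pos2, o2),
        svtype=svtype,
        **kwargs,
    )
    return canonicalize(rec)


def canonicalize(record: SVRecord) -> SVRecord:
    """Order intra-chromosomal breakpoints by position (idempotent).

    Inter-chromosomal breakpoints keep their reported order so that fusion
    naming follows the caller.
    """
    if record.is_intra and record.bp1.pos > record.bp2.pos:
        return replace(record, bp1=record.bp2, bp2=record.bp1)
    return record


def sv_length(record: SVRecord) -> int | None:
    """Base count of the event, or ``None`` where undefined (TRA).

    DEL/DUP/INV use end minus start; INS uses the inserted sequence length
    when available.
    """
    if record.svtype == "TRA":
        return None
    if record.svtype == "INS":
        return len(record.insertion_seq) if record.insertion_seq else None
    rec = canonicalize(record)
    return rec.bp2.pos - rec.bp1.pos


# ---------------------------------------------------------------------------
# BND bracket notation


def parse_bnd_alt(alt: str) -> tuple[str, int, str, str]:
    """Decompose a bracket-notation ALT.

    Returns ``(mate_chrom, mate_pos, self_orient, mate_orient)``.  A leading
    ref/inserted piece means this breakend keeps sequence to its left
    (``+``); ``]`` brackets mean the mate keeps sequence to its left.
    """
    m = _BND_RE.match(alt)
    if not m or m.group(2) != m.group(5):
        raise ValueError(f"malformed BND ALT {alt!r}")
    prefix, bracket, chrom, pos, _, suffix = m.groups()
    if bool(prefix) == bool(suffix):
        raise ValueError(f"malformed BND ALT {alt!r}")
    self_orient = "+" if prefix else "-"
    mate_orient = "+" if bracket == "]" else "-"
    return chrom, int(pos), self_orient, mate_orient


def format_bnd_alt(self_orient: str, mate: GenomicBreakpoint, ref: str = "N") -> str:
    bracket = "]" if mate.orient == "+" else "["
    piece = f"{bracket}{mate.chrom}:{mate.pos}{bracket}"
    return f"{ref}{piece}" if self_orient == "+" else f"{piece}{ref}"


@dataclass
class BndLine:
    """One raw BND data line, prior to mate pairing."""

    id: str
    chrom: str
    pos: int
    mate_chrom: str
    mate_pos: int
    self_orient: str
    mate_orient: str
    mate_id: str | None
    filter_pass: bool = True
    caller: str = ""
    line_no: int | None = None


def _pair_svtype(bp1: GenomicBreakpoint, bp2: GenomicBreakpoint) -> str:
    if bp1.chrom != bp2.chrom:
        return "TRA"
    lo, hi = (bp1, bp2) if bp1.pos <= bp2.pos else (bp2, bp1)
    return _ORIENTS_TO_TYPE[(lo.orient, hi.orient)]


def resolve_bnd_pairs(lines: Sequence[BndLine], caller: str = "") -> list[SVRecord]:
    """Deduplicate mate-paired BND lines into simple SV records.

    Same-chromosome pairs map to DEL/DUP/INV from their junction
    orientations, different chromosomes to TRA.  Orphans (missing mate) are
    retained as single-junction records built from their own ALT, with a
    warning.  Mates whose coordinates disagree raise :class:`SVParseError`.
    """
    by_id = {ln.id: ln for ln in lines}
    seen: set[str] = set()
    out: list[SVRecord] = []
    for ln in lines:
        if ln.id in seen:
            continue
        mate = by_id.get(ln.mate_id) if ln.mate_id else None
        if mate is None:
            # fall back to MATEID symmetry: another line naming us as mate
            for cand in lines:
                if cand.id not in seen and cand.id != ln.id and cand.mate_id == ln.id:
                    mate = cand
                    break
        seen.add(ln.id)
        bp1 = GenomicBreakpoint(ln.chrom, ln.pos, ln.self_orient)
        bp2 = GenomicBreakpoint(ln.mate_chrom, ln.mate_pos, ln.mate_orient)
        if mate is not None:
            seen.add(mate.id)
            if (mate.chrom, mate.pos) != (ln.mate_chrom, ln.mate_pos) or (
                mate.mate_chrom,
                mate.mate_pos,
            ) != (ln.chrom, ln.pos):
                raise SVParseError(
                    f"inconsistent mate coordinates for BND pair {ln.id}/{mate.id}"
                )
            filter_pass = ln.filter_pass or mate.filter_pass
        else:
            log.warning("orphan BND %s retained as single-junction record", ln.id)
            filter_pass = ln.filter_pass
        rec = SVRecord(
            id=ln.id,
            bp1=bp1,
            bp2=bp2,
            svtype=_pair_svtype(bp1, bp2),
            caller=caller or ln.caller,
            filter_pass=filter_pass,
            mate_id=mate.id if mate else ln.mate_id,
            bnd_derived=True,
        )
        out.append(canonicalize(rec))
    return out


# ---------------------------------------------------------------------------
# VCF reading


@dataclass
class GenotypePayload:
    """Raw per-sample genotype data from a genotyped-dialect VCF."""

    samples: list[str]
    #: site id -> (pass_ratio, site FILTER pass flag)
    site_info: dict[str, tuple[float | None, bool]] = field(default_factory=dict)
    #: site id -> list aligned with samples of (alt allele count or None, FT, GQ)
    calls: dict[str, list[tuple[int | None, str | None, int | None]]] = field(
        default_factory=dict
    )


def _filter_pass(rec: pysam.VariantRecord) -> bool:
    keys = list(rec.filter.keys())
    return not keys or keys == ["PASS"] or keys == ["."]


def _alt_count(gt: tuple) -> int | None:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return None
    return sum(1 for a in alleles if a > 0)


def read_sv_vcf(
    path: str | Path, dialect: str
) -> list[SVRecord] | tuple[list[SVRecord], GenotypePayload]:
    """Read a VCF in one of the supported dialects.

    Returns the canonicalized record list; for ``dialect="genotyped"`` a
    ``(records, payload)`` tuple where the payload carries the raw genotype
    matrix inputs.
    """
    if dialect not in ("manta", "gridss", "genotyped"):
        raise ValueError(f"unknown dialect {dialect!r}")
    vcf = pysam.VariantFile(str(path))
    caller = dialect if dialect != "genotyped" else ""
    records: list[SVRecord] = []
    bnd_lines: list[BndLine] = []
    bnd_payload: dict[str, tuple] = {}
    payload = GenotypePayload(samples=list(vcf.header.samples))

    for line_no, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
        alt = rec.alts[0] if rec.alts else ""
        svtype = rec.info.get("SVTYPE")
        fpass = _filter_pass(rec)
        try:
            if alt.startswith("<") or (svtype and svtype != "BND" and "[" not in alt and "]" not in alt):
                if svtype is None:
                    raise SVParseError(f"line {line_no}: symbolic ALT without SVTYPE")
                if svtype == "INS":
                    seq = rec.info.get("SVINSSEQ")
                    end = rec.pos
                    sv = make_record(
                        rec.id, rec.chrom, rec.pos, rec.chrom, end, "INS",
                        caller=caller, filter_pass=fpass, insertion_seq=seq,
                    )
                else:
                    end = rec.info.get("END") or rec.stop
                    sv = make_record(
                        rec.id, rec.chrom, rec.pos, rec.chrom, int(end),
                        svtype, caller=caller, filter_pass=fpass,
                    )
                records.append(sv)
                if dialect == "genotyped":
                    _collect_genotypes(payload, rec, sv.id)
            else:
                mate_chrom, mate_pos, so, mo = parse_bnd_alt(alt)
                mate_id = rec.info.get("MATEID")
                if isinstance(mate_id, tuple):
                    mate_id = mate_id[0]
                bnd_lines.append(
                    BndLine(
                        id=rec.id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        mate_chrom=mate_chrom,
                        mate_pos=mate_pos,
                        self_orient=so,
                        mate_orient=mo,
                        mate_id=mate_id,
                        filter_pass=fpass,
                        caller=caller,
                        line_no=line_no,
                    )
                )
                if dialect == "genotyped":
                    bnd_payload[rec.id] = rec
        except SVParseError:
            raise
        except ValueError as exc:
            raise SVParseError(f"line {line_no}: {exc}") from exc

    resolved = resolve_bnd_pairs(bnd_lines, caller=caller)
    for sv in resolved:
        records.append(sv)
        if dialect == "genotyped" and sv.id in bnd_payload:
            _collect_genotypes(payload, bnd_payload[sv.id], sv.id)
    vcf.close()
    records = [canonicalize(r) for r in records]
    if dialect == "genotyped":
        return records, payload
    return records


def _collect_genotypes(payload: GenotypePayload, rec: pysam.VariantRecord, site_id: str) -> None:
    ratio = rec.info.get("PASS_ratio")
    payload.site_info[site_id] = (
        float(ratio) if ratio is not None else None,
        _filter_pass(rec),
    )
    calls = []
    for sample in payload.samples:
        fmt = rec.samples[sample]
        gt = _alt_count(fmt.get("GT", (None,)))
        ft = fmt.get("FT")
        gq = fmt.get("GQ")
        calls.append((gt, ft, int(gq) if gq is not None else None))
    payload.calls[site_id] = calls


# ---------------------------------------------------------------------------
# VCF writing


def _build_header(
    records: Iterable[SVRecord],
    samples: Sequence[str] = (),
    contigs: Mapping[str, int] | None = None,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">')
    header.add_line('##INFO=<ID=SVINSSEQ,Number=1,Type=String,Description="Inserted sequence">')
    header.add_line('##INFO=<ID=PASS_ratio,Number=1,Type=Float,Description="Fraction of PASS genotype calls">')
    header.add_line('##FILTER=<ID=LowQual,Description="Low quality call">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=FT,Number=1,Type=String,Description="Per-genotype filter">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_line('##ALT=<ID=DEL,Description="Deletion">')
    header.add_line('##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">')
    header.add_line('##ALT=<ID=INS,Description="Insertion">')
    header.add_line('##ALT=<ID=INV,Description="Inversion">')
    if contigs is None:
        contigs = {}
        for r in records:
            for bp in (r.bp1, r.bp2):
                contigs[bp.chrom] = max(contigs.get(bp.chrom, 0), bp.pos + 100_000)

    def _chrom_key(name: str):
        m = re.match(r"chr(\d+)$", name)
        return (0, int(m.group(1))) if m else (1, name)

    for chrom in sorted(contigs, key=_chrom_key):
        header.contigs.add(chrom, length=contigs[chrom])
    for s in samples:
        header.add_sample(s)
    return header


_SYMBOLIC_ALT = {"DEL": "<DEL>", "DUP": "<DUP:TANDEM>", "INS": "<INS>", "INV": "<INV>"}


def write_sv_vcf(
    records: Sequence[SVRecord],
    path: str | Path,
    dialect: str,
    genotypes: GenotypePayload | None = None,
    contigs: Mapping[str, int] | None = None,
) -> Path:
    """Write records as a VCF 4.2 file in the requested dialect.

    ``manta``/``genotyped`` write symbolic ALT lines for intra-chromosomal
    DEL/DUP/INS and paired BND lines for TRA (and, for ``genotyped``, INV —
    Graphtyper-style, so the FT-vs-GQ masking rule is exercised);
    ``gridss`` writes BND pairs for everything except symbolic INS.
    """
    path = Path(path)
    samples = genotypes.samples if genotypes is not None else ()
    header = _build_header(records, samples=samples, contigs=contigs)
    out = pysam.VariantFile(str(path), "w", header=header)
    for sv in records:
        sv = canonicalize(sv)
        if dialect == "gridss":
            as_bnd = sv.svtype != "INS"
        elif dialect == "genotyped":
            as_bnd = sv.svtype in ("TRA", "INV")
        else:
            as_bnd = sv.svtype == "TRA"
        if as_bnd:
            _write_bnd_pair(out, sv, genotypes)
        else:
            _write_symbolic(out, sv, genotypes)
    out.close()
    return path


def _new_rec(
    out: pysam.VariantFile, chrom: str, pos: int, id: str, alt: str,
    fpass: bool, stop: int | None = None,
):
    rec = out.new_record(
        contig=chrom, start=pos - 1, stop=stop if stop is not None else pos,
        alleles=("N", alt), id=id,
    )
    rec.filter.add("PASS" if fpass else "LowQual")
    return rec


def _fill_genotypes(rec, site_id: str, genotypes: GenotypePayload | None, bnd: bool) -> None:
    if genotypes is None or site_id not in genotypes.calls:
        return
    ratio, _ = genotypes.site_info.get(site_id, (None, True))
    if ratio is not None:
        rec.info["PASS_ratio"] = ratio
    for sample, (gt, ft, gq) in zip(genotypes.samples, genotypes.calls[site_id]):
        fmt = rec.samples[sample]
        if gt is None:
            fmt["GT"] = (None, None)
        elif gt == 0:
            fmt["GT"] = (0, 0)
        elif gt == 1:
            fmt["GT"] = (0, 1)
        else:
            fmt["GT"] = (1, 1)
        if not bnd and ft is not None:
            fmt["FT"] = ft
        if gq is not None:
            fmt["GQ"] = gq


def _site_pass(sv: SVRecord, genotypes: GenotypePayload | None) -> bool:
    if genotypes is not None and sv.id in genotypes.site_info:
        return genotypes.site_info[sv.id][1]
    return sv.filter_pass


def _write_symbolic(out, sv: SVRecord, genotypes: GenotypePayload | None) -> None:
    fpass = _site_pass(sv, genotypes)
    stop = sv.bp1.pos if sv.svtype == "INS" else sv.bp2.pos
    rec = _new_rec(
        out, sv.bp1.chrom, sv.bp1.pos, sv.id, _SYMBOLIC_ALT[sv.svtype], fpass,
        stop=stop,
    )
    rec.info["SVTYPE"] = sv.svtype
    if sv.svtype == "INS":
        if sv.insertion_seq:
            rec.info["SVINSSEQ"] = sv.insertion_seq
            rec.info["SVLEN"] = len(sv.insertion_seq)
    else:
        rec.info["SVLEN"] = (
            -(sv.bp2.pos - sv.bp1.pos) if sv.svtype == "DEL" else sv.bp2.pos - sv.bp1.pos
        )
    _fill_genotypes(rec, sv.id, genotypes, bnd=False)
    out.write(rec)


def _write_bnd_pair(out, sv: SVRecord, genotypes: GenotypePayload | None) -> None:
    fpass = _site_pass(sv, genotypes)
    id1, id2 = sv.id, f"{sv.id}_mate"
    alt1 = format_bnd_alt(sv.bp1.orient, sv.bp2)
    alt2 = format_bnd_alt(sv.bp2.orient, sv.bp1)
    for id_, chrom, pos, alt, mate in (
        (id1, sv.bp1.chrom, sv.bp1.pos, alt1, id2),
        (id2, sv.bp2.chrom, sv.bp2.pos, alt2, id1),
    ):
        rec = _new_rec(out, chrom, pos, id_, alt, fpass)
        rec.info["SVTYPE"] = "BND"
        rec.info["MATEID"] = mate
        _fill_genotypes(rec, sv.id, genotypes, bnd=True)
        out.write(rec)
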