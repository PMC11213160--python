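"""Known-SV catalog concordance, novelty flags and clinical significance.

A cohort SV matches a catalog entry when the types agree, the chromosome
pair agrees, and both breakpoints lie within the window (default 200 bp)
of the catalog breakpoints.  Unmatched SVs are novel.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .sv_io import SVRecord, canonicalize

DEFAULT_WINDOW = 200
DEFAULT_MAX_AF = 0.01

SEVERITY_ORDER = [
    "pathogenic",
    "likely_pathogenic",
    "uncertain",
    "likely_benign",
    "benign",
]
_SEVERITY_RANK = {s: i for i, s in enumerate(SEVERITY_ORDER)}


@dataclass
class CatalogEntry:
    id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    svtype: str
    significance: str = "none"  # pathogenic/likely_pathogenic/uncertain/likely_benign/benign/none
    population_afs: dict[str, float] = field(default_factory=dict)


@dataclass
class CatalogAnnotation:
    """Per-SV catalog summary consumed by the pathogenicity cascade."""

    sv_id: str
    matched_ids: list[str] = field(default_factory=list)
    significance: str | None = None
    max_reported_af: float | None = None

    @property
    def novel(self) -> bool:
        return not self.matched_ids


def read_catalog(path: str | Path) -> list[CatalogEntry]:
    """TSV catalog: id, chrom1, pos1, chrom2, pos2, svtype, significance,
    population_afs (``pop:af`` pairs, comma-separated, or ``.``)."""
    out: list[CatalogEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            afs: dict[str, float] = {}
            raw = f[idx["population_afs"]]
            if raw and raw != ".":
                for pair in raw.split(","):
                    pop, af = pair.split(":")
                    afs[pop] = float(af)
            out.append(
                CatalogEntry(
                    id=f[idx["id"]],
                    chrom1=f[idx["chrom1"]],
                    pos1=int(f[idx["pos1"]]),
                    chrom2=f[idx["chrom2"]],
                    pos2=int(f[idx["pos2"]]),
                    svtype=f[idx["svtype"]],
                    significance=f[idx["significance"]],
                    population_afs=afs,
                )
            )
    return out


def write_catalog(entries: Sequence[CatalogEntry], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\tchrom1\tpos1\tchrom2\tpos2\tsvtype\tsignificance\tpopulation_afs\n")
        for e in entries:
            afs = ",".join(f"{p}:{v:g}" for p, v in e.population_afs.items()) or "."
            fh.write(
                f"{e.id}\t{e.chrom1}\t{e.pos1}\t{e.chrom2}\t{e.pos2}\t"
                f"{e.svtype}\t{e.significance}\t{afs}\n"
            )
    return path


def match_catalog(
    sv: SVRecord,
    catalog: Sequence[CatalogEntry],
    window: int = DEFAULT_WINDOW,
) -> list[CatalogEntry]:
    """All catalog entries concordant with ``sv`` (type + both breakpoints
    within the window; reciprocal breakpoint order accepted)."""
    sv = canonicalize(sv)
    out = []
    for e in catalog:
        if e.svtype != sv.svtype:
            continue
        pairs = [((sv.bp1.chrom, sv.bp1.pos), (sv.bp2.chrom, sv.bp2.pos))]
        if sv.svtype == "TRA":
            pairs.append(((sv.bp2.chrom, sv.bp2.pos), (sv.bp1.chrom, sv.bp1.pos)))
        for (c1, p1), (c2, p2) in pairs:
            if (
                c1 == e.chrom1
                and c2 == e.chrom2
                and abs(p1 - e.pos1) <= window
                and abs(p2 - e.pos2) <= window
            ):
                out.append(e)
                break
    return out


def clinvar_tier(matches: Sequence[CatalogEntry]) -> str | None:
    """Most severe significance among the matches; ``None`` if unmatched or
    none of the matches carries an interpretation."""
    sigs = [m.significance for m in matches if m.significance in _SEVERITY_RANK]
    if not sigs:
        return None
    return min(sigs, key=_SEVERITY_RANK.__getitem__)


def catalog_frequency_exclusion(
    matches: Sequence[CatalogEntry], max_af: float = DEFAULT_MAX_AF
) -> bool:
    """True when any reported population AF reaches ``max_af`` (the SV is
    too frequent in reference populations to remain a candidate)."""
    return any(
        af >= max_af for m in matches for af in m.population_afs.values()
    )


def annotate_against_catalog(
    svs: Sequence[SVRecord],
    catalog: Sequence[CatalogEntry],
    window: int = DEFAULT_WINDOW,
) -> dict[str, CatalogAnnotation]:
    index: dict[tuple, list[CatalogEntry]] = defaultdict(list)
    for e in catalog:
        index[e.svtype].append(e)
    out: dict[str, CatalogAnnotation] = {}
    for sv in svs:
        matches = match_catalog(sv, index.get(sv.svtype, ()), window)
        afs = [af for m in matches for af in m.population_afs.values()]
        out[sv.id] = CatalogAnnotation(
            sv_id=sv.id,
            matched_ids=[m.id for m in matches],
            significance=clinvar_tier(matches),
            max_reported_af=max(afs) if afs else None,
        )
    return out


def write_catalog_annotation(
    annotations: dict[str, CatalogAnnotation], path: str | Path
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sv_id\tmatched_ids\tsignificance\tmax_reported_af\tnovel\n")
        for ann in annotations.values():
            fh.write(
                f"{ann.sv_id}\t{','.join(ann.matched_ids) or '.'}\t"
                f"{ann.significance or 'NA'}\t"
                f"{'NA' if ann.max_reported_af is None else f'{ann.max_reported_af:g}'}\t"
                f"{ann.novel}\n"
            )
    return path
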