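"""Dual-caller concordance: produce the per-sample high-confidence SV set.

Two calls are concordant when they share an SV type and chromosome pair,
both breakpoints lie within the matching window (default 200 bp) of each
other, and at least one of the two is PASS.  Matching is one-to-one and
greedy by total breakpoint distance; the concordant set carries the
Manta-side representation forward (the genotyping input contract).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .sv_io import SVRecord, write_sv_vcf

DEFAULT_WINDOW = 200


@dataclass
class ConcordantCall:
    manta_record: SVRecord
    gridss_record: SVRecord
    bp1_dist: int
    bp2_dist: int


@dataclass
class MatchSummary:
    matched: int
    manta_only: int
    gridss_only: int

    @property
    def matched_fraction(self) -> float:
        total = self.matched + self.manta_only
        return self.matched / total if total else 0.0


def _pair_distances(a: SVRecord, b: SVRecord, window: int) -> tuple[int, int] | None:
    """Distances if the pair satisfies the concordance rule, else ``None``."""
    if a.svtype != b.svtype:
        return None
    if not (a.filter_pass or b.filter_pass):
        return None
    if a.svtype == "INS":
        if a.bp1.chrom != b.bp1.chrom:
            return None
        d = abs(a.bp1.pos - b.bp1.pos)
        return (d, d) if d <= window else None
    orientations = [(a.bp1, a.bp2)]
    if a.svtype == "TRA":
        # reciprocal mate order must still match (unordered fallback)
        orientations.append((a.bp2, a.bp1))
    best = None
    for x1, x2 in orientations:
        if (x1.chrom, x2.chrom) != (b.bp1.chrom, b.bp2.chrom):
            continue
        d1, d2 = abs(x1.pos - b.bp1.pos), abs(x2.pos - b.bp2.pos)
        if d1 <= window and d2 <= window and (best is None or d1 + d2 < sum(best)):
            best = (d1, d2)
    return best


def match_callsets(
    manta: Sequence[SVRecord],
    gridss: Sequence[SVRecord],
    window: int = DEFAULT_WINDOW,
) -> list[ConcordantCall]:
    """One-to-one greedy matching of two canonicalized callsets.

    Candidate pairs are bucketed by (svtype, chromosome) for scale, then
    assigned in order of total breakpoint distance; ties break on the
    (order-independent) sorted id pair so the result is symmetric under
    caller-role swap.
    """
    buckets: dict[tuple, list[int]] = defaultdict(list)
    for j, g in enumerate(gridss):
        buckets[(g.svtype, g.bp1.chrom)].append(j)
        if g.svtype == "TRA":
            buckets[(g.svtype, g.bp2.chrom)].append(j)

    candidates = []
    for i, m in enumerate(manta):
        seen_j: set[int] = set()
        for chrom in {m.bp1.chrom, m.bp2.chrom}:
            for j in buckets.get((m.svtype, chrom), ()):
                if j in seen_j:
                    continue
                seen_j.add(j)
                dists = _pair_distances(m, gridss[j], window)
                if dists is not None:
                    candidates.append((dists[0] + dists[1], *dists, i, j))

    candidates.sort(
        key=lambda c: (c[0], tuple(sorted((manta[c[3]].id, gridss[c[4]].id))))
    )
    used_m: set[int] = set()
    used_g: set[int] = set()
    matches: list[ConcordantCall] = []
    for total, d1, d2, i, j in candidates:
        if i in used_m or j in used_g:
            continue
        used_m.add(i)
        used_g.add(j)
        matches.append(ConcordantCall(manta[i], gridss[j], d1, d2))
    return matches


def concordant_fraction(
    manta: Sequence[SVRecord],
    gridss: Sequence[SVRecord],
    window: int = DEFAULT_WINDOW,
) -> MatchSummary:
    matched = len(match_callsets(manta, gridss, window))
    return MatchSummary(
        matched=matched,
        manta_only=len(manta) - matched,
        gridss_only=len(gridss) - matched,
    )


def write_concordant_set(
    matches: Sequence[ConcordantCall],
    vcf_path: str | Path,
    tsv_path: str | Path | None = None,
) -> Path:
    """Emit the concordant set as a Manta-dialect VCF plus provenance TSV."""
    records = [m.manta_record for m in matches]
    write_sv_vcf(records, vcf_path, dialect="manta")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write(
                "manta_id\tgridss_id\tsvtype\tbp1_dist\tbp2_dist\t"
                "manta_pass\tgridss_pass\n"
            )
            for m in matches:
                fh.write(
                    f"{m.manta_record.id}\t{m.gridss_record.id}\t"
                    f"{m.manta_record.svtype}\t{m.bp1_dist}\t{m.bp2_dist}\t"
                    f"{m.manta_record.filter_pass}\t{m.gridss_record.filter_pass}\n"
                )
    return Path(vcf_path)
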