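"""Population genotype QC and ancestry-stratified allele frequencies.

The QC order is fixed: site filters (FILTER + PASS_ratio), genotype
masking (FT for simple sites, GQ for BND-derived sites), per-group
missingness, fixed-site removal, then frequency computation on the
surviving high-quality calls only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .sv_io import GenotypePayload, SVRecord, read_sv_vcf

log = logging.getLogger(__name__)

MISSING = -1

DEFAULT_MIN_PASS_RATIO = 0.5
DEFAULT_MIN_GQ = 20
DEFAULT_MAX_MISSING = 0.2

RARE_MAX = 0.01     # MAF < 1% -> rare
COMMON_MIN = 0.05   # MAF > 5% -> common


@dataclass
class SVGenotypeMatrix:
    """SV sites x samples alternate-allele counts with QC side-channels.

    ``genotypes`` holds 0/1/2 alt-allele counts with -1 for missing; ``ft``
    the per-call filter tags (or None); ``gq`` genotype qualities (NaN when
    absent).  ``pass_ratio`` and ``site_pass`` are per-site arrays.
    """

    sites: list[SVRecord]
    samples: list[str]
    groups: dict[str, str]
    genotypes: np.ndarray          # (n_sites, n_samples) int8
    ft: np.ndarray                 # (n_sites, n_samples) object
    gq: np.ndarray                 # (n_sites, n_samples) float
    pass_ratio: np.ndarray         # (n_sites,) float, NaN if absent
    site_pass: np.ndarray          # (n_sites,) bool

    def __post_init__(self) -> None:
        missing_groups = [s for s in self.samples if s not in self.groups]
        if missing_groups:
            raise ValueError(f"samples without group label: {missing_groups[:5]}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def group_names(self) -> list[str]:
        return sorted(set(self.groups[s] for s in self.samples))

    def group_mask(self, group: str) -> np.ndarray:
        return np.array([self.groups[s] == group for s in self.samples])

    def subset(self, keep: np.ndarray) -> "SVGenotypeMatrix":
        idx = np.flatnonzero(keep)
        return SVGenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            samples=self.samples,
            groups=self.groups,
            genotypes=self.genotypes[idx],
            ft=self.ft[idx],
            gq=self.gq[idx],
            pass_ratio=self.pass_ratio[idx],
            site_pass=self.site_pass[idx],
        )

    @classmethod
    def from_vcf(
        cls, path: str | Path, groups: Mapping[str, str]
    ) -> "SVGenotypeMatrix":
        records, payload = read_sv_vcf(path, dialect="genotyped")
        return cls.from_payload(records, payload, groups)

    @classmethod
    def from_payload(
        cls,
        records: Sequence[SVRecord],
        payload: GenotypePayload,
        groups: Mapping[str, str],
    ) -> "SVGenotypeMatrix":
        n_sites, n_samples = len(records), len(payload.samples)
        gts = np.full((n_sites, n_samples), MISSING, dtype=np.int8)
        fts = np.full((n_sites, n_samples), None, dtype=object)
        gqs = np.full((n_sites, n_samples), np.nan)
        ratio = np.full(n_sites, np.nan)
        spass = np.zeros(n_sites, dtype=bool)
        for i, rec in enumerate(records):
            r, fp = payload.site_info.get(rec.id, (None, rec.filter_pass))
            ratio[i] = np.nan if r is None else r
            spass[i] = fp
            for j, (gt, ft, gq) in enumerate(payload.calls.get(rec.id, [])):
                gts[i, j] = MISSING if gt is None else gt
                fts[i, j] = ft
                gqs[i, j] = np.nan if gq is None else gq
        return cls(
            sites=list(records),
            samples=list(payload.samples),
            groups=dict(groups),
            genotypes=gts,
            ft=fts,
            gq=gqs,
            pass_ratio=ratio,
            site_pass=spass,
        )


# ---------------------------------------------------------------------------
# QC steps (fixed order)


def apply_site_filters(
    matrix: SVGenotypeMatrix, min_pass_ratio: float = DEFAULT_MIN_PASS_RATIO
) -> SVGenotypeMatrix:
    """Keep sites with FILTER PASS and PASS_ratio >= threshold.

    Sites without a PASS_ratio are dropped with a warning.
    """
    no_ratio = np.isnan(matrix.pass_ratio)
    if no_ratio.any():
        for i in np.flatnonzero(no_ratio):
            log.warning("site %s has no PASS_ratio; dropped", matrix.sites[i].id)
    keep = matrix.site_pass & ~no_ratio & (matrix.pass_ratio >= min_pass_ratio)
    return matrix.subset(keep)


def mask_low_quality_genotypes(
    matrix: SVGenotypeMatrix, min_gq: int = DEFAULT_MIN_GQ
) -> SVGenotypeMatrix:
    """Set low-quality calls to missing.

    Simple (non-BND-derived) sites: FT != PASS -> missing.  BND-derived
    sites (INV/TRA resolved from breakend pairs, which carry no FT):
    GQ < ``min_gq`` -> missing.
    """
    gts = matrix.genotypes.copy()
    bnd = np.array([s.bnd_derived for s in matrix.sites])
    ft_fail = np.frompyfunc(lambda t: t is not None and t != "PASS", 1, 1)(
        matrix.ft
    ).astype(bool)
    ft_missing = np.frompyfunc(lambda t: t is None, 1, 1)(matrix.ft).astype(bool)
    simple_fail = ~bnd[:, None] & (ft_fail | ft_missing)
    with np.errstate(invalid="ignore"):
        gq_fail = np.isnan(matrix.gq) | (matrix.gq < min_gq)
    bnd_fail = bnd[:, None] & gq_fail
    gts[simple_fail | bnd_fail] = MISSING
    out = matrix.subset(np.ones(matrix.n_sites, dtype=bool))
    out.genotypes = gts
    return out


def filter_missingness(
    matrix: SVGenotypeMatrix, max_missing: float = DEFAULT_MAX_MISSING
) -> SVGenotypeMatrix:
    """Drop sites whose missingness exceeds the cap in ANY ancestry group."""
    keep = np.ones(matrix.n_sites, dtype=bool)
    for group in matrix.group_names:
        gmask = matrix.group_mask(group)
        if not gmask.any():
            continue
        miss = (matrix.genotypes[:, gmask] == MISSING).mean(axis=1)
        keep &= miss <= max_missing
    return matrix.subset(keep)


def drop_fixed_sites(matrix: SVGenotypeMatrix) -> SVGenotypeMatrix:
    """Remove sites fixed for the alternate allele (overall AF = 1)."""
    called = matrix.genotypes != MISSING
    an = 2 * called.sum(axis=1)
    ac = np.where(called, matrix.genotypes, 0).sum(axis=1)
    fixed = (an > 0) & (ac == an)
    return matrix.subset(~fixed)


def run_qc(
    matrix: SVGenotypeMatrix,
    min_pass_ratio: float = DEFAULT_MIN_PASS_RATIO,
    min_gq: int = DEFAULT_MIN_GQ,
    max_missing: float = DEFAULT_MAX_MISSING,
) -> SVGenotypeMatrix:
    """All QC steps in the fixed order."""
    matrix = apply_site_filters(matrix, min_pass_ratio)
    matrix = mask_low_quality_genotypes(matrix, min_gq)
    matrix = filter_missingness(matrix, max_missing)
    return drop_fixed_sites(matrix)


# ---------------------------------------------------------------------------
# Frequencies


@dataclass
class GroupFrequency:
    ac: int
    an: int

    @property
    def af(self) -> float | None:
        return self.ac / self.an if self.an else None

    @property
    def maf(self) -> float | None:
        return None if self.af is None else min(self.af, 1.0 - self.af)

    @property
    def tier(self) -> str | None:
        return None if self.maf is None else frequency_tier(self.maf)


@dataclass
class FrequencyRecord:
    site_id: str
    groups: dict[str, GroupFrequency] = field(default_factory=dict)
    overall: GroupFrequency | None = None

    def maf(self, group: str) -> float | None:
        gf = self.groups.get(group)
        return gf.maf if gf else None

    def max_group_maf(self) -> float | None:
        mafs = [gf.maf for gf in self.groups.values() if gf.maf is not None]
        return max(mafs) if mafs else None


def frequency_tier(maf: float) -> str:
    """rare (<1%), low_frequency (1-5% closed), common (>5%)."""
    if not 0.0 <= maf <= 0.5 + 1e-12:
        raise ValueError(f"MAF must be in [0, 0.5], got {maf}")
    if maf < RARE_MAX:
        return "rare"
    if maf <= COMMON_MIN:
        return "low_frequency"
    return "common"


def compute_frequencies(matrix: SVGenotypeMatrix) -> list[FrequencyRecord]:
    """Per-group and overall AC/AN/AF/MAF from non-missing calls."""
    out: list[FrequencyRecord] = []
    gmasks = {g: matrix.group_mask(g) for g in matrix.group_names}
    for i, site in enumerate(matrix.sites):
        row = matrix.genotypes[i]
        called = row != MISSING
        rec = FrequencyRecord(site_id=site.id)
        for g, gmask in gmasks.items():
            sel = gmask & called
            an = 2 * int(sel.sum())
            ac = int(row[sel].sum())
            rec.groups[g] = GroupFrequency(ac=ac, an=an)
            if an == 0:
                log.warning("site %s: no called genotypes in group %s", site.id, g)
        rec.overall = GroupFrequency(
            ac=int(row[called].sum()), an=2 * int(called.sum())
        )
        out.append(rec)
    return out


def write_frequency_table(
    freqs: Sequence[FrequencyRecord], path: str | Path, groups: Sequence[str]
) -> Path:
    """TSV with per-group AC/AN/AF/MAF/tier columns (AF/MAF shown to 3 dp)."""
    path = Path(path)
    cols = ["site_id"]
    for g in groups:
        cols += [f"{g}_ac", f"{g}_an", f"{g}_af", f"{g}_maf", f"{g}_tier"]
    cols += ["overall_af", "overall_tier"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in freqs:
            row = [rec.site_id]
            for g in groups:
                gf = rec.groups.get(g, GroupFrequency(0, 0))
                row += [
                    str(gf.ac),
                    str(gf.an),
                    _fmt(gf.af),
                    _fmt(gf.maf),
                    gf.tier or "NA",
                ]
            row += [_fmt(rec.overall.af), rec.overall.tier or "NA"]
            fh.write("\t".join(row) + "\n")
    return path


def _fmt(x: float | None) -> str:
    return "NA" if x is None else f"{x:.3f}"
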