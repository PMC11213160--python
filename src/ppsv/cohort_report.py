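"""Carrier summaries, clinical correlation and report rendering.

Percentages use half-up rounding so printed values always recompute from
their own counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

from .pathogenicity import PPSV_TIERS, PathogenicityCall
from .population_genotypes import SVGenotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_GG_CUT = 3

#: reporting tier groups: label -> set of cascade tiers it aggregates
REPORT_TIERS = {
    "clinvar": {"clinvar_pathogenic", "clinvar_likely_pathogenic"},
    "predicted": {"pp_sv"},
    "pp_sv_any": set(PPSV_TIERS),
    "cautionary": {"cautionary_pp_sv"},
}

NCCN_RULES = {"standard": 4, "extended": 3}


@dataclass
class PatientRecord:
    patient_id: str
    group: str
    age: float | None = None
    psa: float | None = None
    isup_gg: int | None = None  # None = unknown
    family_history: str = ""


@dataclass
class TierGroupStat:
    carriers: int
    cohort: int

    @property
    def pct(self) -> float:
        return round_pct(self.carriers, self.cohort, 1)


@dataclass
class AggressiveStat:
    aggressive: int
    known: int
    unknown: int

    @property
    def pct(self) -> float:
        return round_pct(self.aggressive, self.known, 1)

    @property
    def pct_unknown_as_carrier(self) -> float:
        """Alternative convention: unknown-pathology carriers kept in the
        denominator."""
        return round_pct(self.aggressive, self.known + self.unknown, 1)


@dataclass
class CohortSummary:
    group_sizes: dict[str, int]
    #: (tier label, group) -> stat; group "all" aggregates
    tier_stats: dict[tuple[str, str], TierGroupStat] = field(default_factory=dict)
    aggressive: dict[str, AggressiveStat] = field(default_factory=dict)
    eligibility: dict[tuple[str, str], TierGroupStat] = field(default_factory=dict)


def round_pct(num: int, denom: int, ndigits: int = 1) -> float:
    """Half-up percentage rounding (``12.35 -> 12.4``, ``81/113 -> 72``)."""
    if denom == 0:
        return 0.0
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(100) * Decimal(num) / Decimal(denom)).quantize(q, ROUND_HALF_UP)
    )


def carriers_from_matrix(matrix: SVGenotypeMatrix) -> dict[str, set[str]]:
    """site id -> set of samples with >=1 alternate allele."""
    out: dict[str, set[str]] = {}
    for i, site in enumerate(matrix.sites):
        row = matrix.genotypes[i]
        out[site.id] = {
            s for s, gt in zip(matrix.samples, row) if gt > 0
        }
    return out


def _tier_carrier_patients(
    calls: Sequence[PathogenicityCall],
    carriers: Mapping[str, set[str]],
    tiers: set[str],
) -> set[str]:
    out: set[str] = set()
    for c in calls:
        if c.tier in tiers:
            out |= carriers.get(c.sv_id, set())
    return out


def carrier_summary(
    calls: Sequence[PathogenicityCall],
    carriers: Mapping[str, set[str]],
    patients: Sequence[PatientRecord],
    gg_cut: int = DEFAULT_GG_CUT,
) -> CohortSummary:
    """Distinct-patient carrier counts and percentages per reporting tier
    and ancestry group, plus aggressive-disease fractions per tier."""
    by_id = {p.patient_id: p for p in patients}
    groups = sorted({p.group for p in patients})
    sizes = {g: sum(1 for p in patients if p.group == g) for g in groups}
    summary = CohortSummary(group_sizes=sizes)

    for label, tier_set in REPORT_TIERS.items():
        tier_patients = _tier_carrier_patients(calls, carriers, tier_set)
        unknown_patients = tier_patients - by_id.keys()
        for pid in unknown_patients:
            log.warning("carrier %s not in clinical table", pid)
        for g in groups:
            n = sum(1 for pid in tier_patients if pid in by_id and by_id[pid].group == g)
            summary.tier_stats[(label, g)] = TierGroupStat(n, sizes[g])
        summary.tier_stats[(label, "all")] = TierGroupStat(
            len(tier_patients), sum(sizes.values())
        )
        summary.aggressive[label] = aggressive_fraction(
            tier_patients, patients, gg_cut=gg_cut
        )

    for rule, cut in NCCN_RULES.items():
        for g, stat in nccn_eligibility(patients, cut).items():
            summary.eligibility[(rule, g)] = stat
    return summary


def aggressive_fraction(
    carrier_ids: set[str],
    patients: Sequence[PatientRecord],
    gg_cut: int = DEFAULT_GG_CUT,
) -> AggressiveStat:
    """Fraction of carriers with ISUP GG >= cut among those with known
    grade; unknown-grade carriers counted separately."""
    by_id = {p.patient_id: p for p in patients}
    known = [by_id[pid] for pid in carrier_ids if pid in by_id and by_id[pid].isup_gg is not None]
    unknown = sum(
        1 for pid in carrier_ids if pid in by_id and by_id[pid].isup_gg is None
    )
    aggressive = sum(1 for p in known if p.isup_gg >= gg_cut)
    return AggressiveStat(aggressive=aggressive, known=len(known), unknown=unknown)


def nccn_eligibility(
    patients: Sequence[PatientRecord], gg_cut: int
) -> dict[str, TierGroupStat]:
    """Per-group counts of patients meeting a grade-based testing rule."""
    groups = sorted({p.group for p in patients})
    out = {}
    for g in groups:
        members = [p for p in patients if p.group == g]
        eligible = sum(1 for p in members if p.isup_gg is not None and p.isup_gg >= gg_cut)
        out[g] = TierGroupStat(eligible, len(members))
    return out


# ---------------------------------------------------------------------------
# rendering


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    out: list[PatientRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")

            def get(col, cast=str):
                raw = f[idx[col]] if col in idx and len(f) > idx[col] else ""
                if raw in ("", "unknown", "NA", "."):
                    return None
                return cast(raw)

            out.append(
                PatientRecord(
                    patient_id=f[idx["patient_id"]],
                    group=f[idx["group"]],
                    age=get("age", float),
                    psa=get("psa", float),
                    isup_gg=get("isup_gg", int),
                    family_history=get("family_history") or "",
                )
            )
    return out


def render_tables(
    calls: Sequence[PathogenicityCall],
    carriers: Mapping[str, set[str]],
    patients: Sequence[PatientRecord],
    frequencies: Mapping[str, "object"],
    impacts: Mapping[str, list],
    sites: Mapping[str, "object"],
    outdir: str | Path,
    gg_cut: int = DEFAULT_GG_CUT,
) -> dict[str, Path]:
    """Write the candidate-SV table, the per-carrier clinical table and a
    machine-readable JSON summary.  Deterministic row order."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {p.patient_id: p for p in patients}
    reported = [
        c for c in calls if c.tier in PPSV_TIERS | {"cautionary_pp_sv"}
    ]
    reported.sort(key=lambda c: (c.tier, c.sv_id))

    t1 = outdir / "candidates.tsv"
    with open(t1, "w") as fh:
        fh.write(
            "sv_id\tgenes\tcategory\ttier\tchrom1\tpos1\tchrom2\tpos2\tsvtype\t"
            + "\t".join(
                f"maf_{g}" for g in sorted({p.group for p in patients})
            )
            + "\tcatalog_max_af\n"
        )
        for c in reported:
            sv = sites.get(c.sv_id)
            freq = frequencies.get(c.sv_id)
            anns = [a for a in impacts.get(c.sv_id, []) if a.gene_id]
            genes = ",".join(dict.fromkeys(a.gene_id for a in anns)) or "."
            cats = ",".join(dict.fromkeys(a.category for a in anns)) or "."
            mafs = []
            for g in sorted({p.group for p in patients}):
                maf = freq.maf(g) if freq is not None else None
                mafs.append("NA" if maf is None else f"{maf:.3f}")
            cat_af = c.evidence.get("catalog_max_af")
            fh.write(
                f"{c.sv_id}\t{genes}\t{cats}\t{c.tier}\t"
                f"{sv.bp1.chrom}\t{sv.bp1.pos}\t{sv.bp2.chrom}\t{sv.bp2.pos}\t"
                f"{sv.svtype}\t" + "\t".join(mafs) + "\t"
                f"{'NA' if cat_af is None else f'{cat_af:g}'}\n"
            )

    t2 = outdir / "carriers.tsv"
    with open(t2, "w") as fh:
        fh.write("sv_id\ttier\tsvtype\tpatient_id\tgroup\tage\tpsa\tisup_gg\n")
        for c in reported:
            sv = sites.get(c.sv_id)
            for pid in sorted(carriers.get(c.sv_id, ())):
                p = by_id.get(pid)
                age = "" if p is None or p.age is None else f"{p.age:g}"
                psa = "" if p is None or p.psa is None else f"{p.psa:g}"
                gg = "unknown" if p is None or p.isup_gg is None else str(p.isup_gg)
                fh.write(
                    f"{c.sv_id}\t{c.tier}\t{sv.svtype}\t{pid}\t"
                    f"{p.group if p else 'NA'}\t{age}\t{psa}\t{gg}\n"
                )

    summary = carrier_summary(calls, carriers, patients, gg_cut=gg_cut)
    js = outdir / "summary.json"
    payload = {
        "group_sizes": summary.group_sizes,
        "tiers": {
            f"{label}/{group}": {
                "carriers": st.carriers,
                "cohort": st.cohort,
                "pct": st.pct,
            }
            for (label, group), st in sorted(summary.tier_stats.items())
        },
        "aggressive": {
            label: {
                "aggressive": st.aggressive,
                "known": st.known,
                "unknown": st.unknown,
                "pct": st.pct,
            }
            for label, st in sorted(summary.aggressive.items())
        },
        "eligibility": {
            f"{rule}/{group}": {
                "eligible": st.carriers,
                "cohort": st.cohort,
                "pct": round_pct(st.carriers, st.cohort, 0),
            }
            for (rule, group), st in sorted(summary.eligibility.items())
        },
    }
    js.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return {"candidates": t1, "carriers": t2, "summary": js}
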