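"""Consensus pathogenicity cascade.

An SV must be gene-disruptive (pLoF/CG/IED), rare in both ancestry
groups, pass the pathogenicity-score consensus (>=2 of 4 tools over their
thresholds), hit >=2 of 3 cancer gene sets, survive catalog-frequency
exclusion, and finally clear a curated gene-role gate that decides
between PP-SV, cautionary PP-SV and unlikely-pathogenic.  Catalog
pathogenic/likely-pathogenic (or benign) interpretations short-circuit
the score consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .catalog_match import CatalogAnnotation, catalog_frequency_exclusion
from .gene_impact import GENE_DISRUPTIVE, ImpactAnnotation
from .population_genotypes import COMMON_MIN, RARE_MAX, FrequencyRecord

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "strvctvre": 0.37,
    "cadd_sv": 10.0,
    "postre": 0.8,
    "phenosv": 0.5,
}

#: which SV types each scoring tool covers (absence elsewhere is legal)
TOOL_COVERAGE = {
    "strvctvre": {"DEL", "DUP"},       # exonic DEL/DUP only
    "cadd_sv": {"DEL", "DUP", "INS"},
    "postre": {"DEL", "DUP", "INV", "TRA"},
    "phenosv": {"DEL", "DUP", "INS", "INV", "TRA"},
}

DEFAULT_MIN_TOOLS = 2
DEFAULT_MIN_GENESETS = 2

TIERS = (
    "clinvar_pathogenic",
    "clinvar_likely_pathogenic",
    "pp_sv",
    "cautionary_pp_sv",
    "unlikely",
    "excluded_benign",
    "excluded_common",
    "excluded_catalog_af",
    "excluded_no_consensus",
    "excluded_no_cancer_support",
    "not_gene_disruptive",
)

PPSV_TIERS = frozenset(
    {"clinvar_pathogenic", "clinvar_likely_pathogenic", "pp_sv"}
)

ROLES = ("tumour_suppressor", "oncogene", "conflicting", "unclear")


@dataclass
class ScorePanel:
    sv_id: str
    strvctvre: float | None = None
    cadd_sv: float | None = None
    postre: float | None = None
    phenosv: float | None = None

    def score(self, tool: str) -> float | None:
        return getattr(self, tool)


@dataclass
class GeneCuration:
    gene_id: str
    role: str  # tumour_suppressor | oncogene | conflicting | unclear
    note: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown curated role {self.role!r}")


@dataclass
class PathogenicityCall:
    sv_id: str
    tier: str
    evidence: dict = field(default_factory=dict)


def tools_passed(
    panel: ScorePanel,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
) -> set[str]:
    """Tools whose score is present and at or above threshold.

    Absent scores never pass (no imputation), so e.g. a TRA needs both of
    the two tools able to score it.
    """
    out = set()
    for tool, cut in thresholds.items():
        score = panel.score(tool)
        if score is not None and score >= cut:
            out.add(tool)
    return out


def is_candidate(
    panel: ScorePanel,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    min_tools: int = DEFAULT_MIN_TOOLS,
) -> bool:
    return len(tools_passed(panel, thresholds)) >= min_tools


def cancer_gene_support(
    genes: Sequence[str],
    genesets: Mapping[str, set[str]],
    min_sets: int = DEFAULT_MIN_GENESETS,
) -> tuple[int, bool]:
    """(number of gene sets hit by ANY of the genes, hit >= ``min_sets``)."""
    hit = sum(1 for members in genesets.values() if any(g in members for g in genes))
    return hit, hit >= min_sets


def _curation_gate(
    disruptive: Sequence[ImpactAnnotation],
    roles: Mapping[str, str],
) -> tuple[str, dict]:
    role_set = {roles[a.gene_id] for a in disruptive}
    info = {"roles": {a.gene_id: roles[a.gene_id] for a in disruptive}}
    if "tumour_suppressor" in role_set and "oncogene" in role_set:
        return "cautionary_pp_sv", info
    if "unclear" in role_set or "conflicting" in role_set:
        return "cautionary_pp_sv", info
    supported = False
    for ann in disruptive:
        role = roles[ann.gene_id]
        if ann.category == "pLoF" and role == "tumour_suppressor":
            supported = True
        elif ann.category in ("CG", "IED") and role == "oncogene":
            supported = True
    return ("pp_sv" if supported else "unlikely"), info


def classify(
    sv_id: str,
    impacts: Sequence[ImpactAnnotation],
    frequency: FrequencyRecord,
    catalog: CatalogAnnotation | None,
    panel: ScorePanel,
    curation: Mapping[str, GeneCuration],
    genesets: Mapping[str, set[str]],
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    min_tools: int = DEFAULT_MIN_TOOLS,
    min_genesets: int = DEFAULT_MIN_GENESETS,
    rare_max: float = RARE_MAX,
    common_min: float = COMMON_MIN,
    catalog_max_af: float = 0.01,
) -> PathogenicityCall:
    """Run the full cascade for one SV; first rule wins.

    1. not gene-disruptive -> ``not_gene_disruptive``
    2. common (group MAF > 5%) -> ``excluded_common``
    3. catalog pathogenic/likely-pathogenic/benign short-circuit
    4. score consensus (>=2 tools) -> ``excluded_no_consensus``
    5. cancer gene-set support (>=2 sets) -> ``excluded_no_cancer_support``
    6. low-frequency (MAF >= 1% in a group) -> ``excluded_common``;
       catalog population AF >= cutoff -> ``excluded_catalog_af``
    7. curated gene-role gate -> pp_sv / cautionary_pp_sv / unlikely
    """
    disruptive = [a for a in impacts if a.category in GENE_DISRUPTIVE]
    evidence: dict = {
        "disruptive_genes": [a.gene_id for a in disruptive],
        "categories": {a.gene_id: a.category for a in disruptive},
    }

    def call(tier: str) -> PathogenicityCall:
        return PathogenicityCall(sv_id=sv_id, tier=tier, evidence=evidence)

    if not disruptive:
        return call("not_gene_disruptive")

    mafs = {g: gf.maf for g, gf in frequency.groups.items() if gf.maf is not None}
    evidence["group_maf"] = mafs
    if any(maf > common_min for maf in mafs.values()):
        return call("excluded_common")

    if catalog is not None and catalog.significance is not None:
        evidence["catalog"] = {
            "matched_ids": catalog.matched_ids,
            "significance": catalog.significance,
        }
        if catalog.significance == "pathogenic":
            return call("clinvar_pathogenic")
        if catalog.significance == "likely_pathogenic":
            return call("clinvar_likely_pathogenic")
        if catalog.significance in ("benign", "likely_benign"):
            return call("excluded_benign")
        # uncertain falls through to the score consensus

    passed = tools_passed(panel, thresholds)
    evidence["tools_passed"] = sorted(passed)
    if len(passed) < min_tools:
        return call("excluded_no_consensus")

    genes = list(dict.fromkeys(a.gene_id for a in disruptive))
    for a in impacts:
        if a.fusion_partner:
            for part in a.fusion_partner.split("-"):
                if part not in genes:
                    genes.append(part)
    n_sets, supported = cancer_gene_support(genes, genesets, min_genesets)
    evidence["genesets_hit"] = n_sets
    if not supported:
        return call("excluded_no_cancer_support")

    if any(maf >= rare_max for maf in mafs.values()):
        return call("excluded_common")
    if catalog is not None:
        evidence["catalog_max_af"] = catalog.max_reported_af
        if catalog.max_reported_af is not None and catalog.max_reported_af >= catalog_max_af:
            return call("excluded_catalog_af")

    role_lookup = {}
    for a in disruptive:
        cur = curation.get(a.gene_id)
        if cur is None:
            log.warning("gene %s absent from curation table; treated as unclear", a.gene_id)
            role_lookup[a.gene_id] = "unclear"
        else:
            role_lookup[a.gene_id] = cur.role
    tier, info = _curation_gate(disruptive, role_lookup)
    evidence.update(info)
    return call(tier)


# ---------------------------------------------------------------------------
# table I/O


def read_score_tables(paths: Mapping[str, str | Path]) -> dict[str, ScorePanel]:
    """Merge per-tool two-column (sv_id, score) TSVs into panels."""
    panels: dict[str, ScorePanel] = {}
    for tool, path in paths.items():
        if tool not in DEFAULT_THRESHOLDS:
            raise ValueError(f"unknown scoring tool {tool!r}")
        with open(path) as fh:
            fh.readline()
            for line in fh:
                sv_id, raw = line.rstrip("\n").split("\t")[:2]
                if raw in (".", "NA", ""):
                    continue
                panel = panels.setdefault(sv_id, ScorePanel(sv_id=sv_id))
                setattr(panel, tool, float(raw))
    return panels


def read_geneset(path: str | Path) -> set[str]:
    """One gene per line, or GMT (name, description, members...)."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or not fields[0]:
                continue
            if len(fields) >= 3:  # GMT row
                genes.update(g for g in fields[2:] if g)
            else:
                genes.add(fields[0])
    return genes


def read_curation_table(path: str | Path) -> dict[str, GeneCuration]:
    out: dict[str, GeneCuration] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            cur = GeneCuration(
                gene_id=f[idx["gene_id"]],
                role=f[idx["role"]],
                note=f[idx["note"]] if "note" in idx and len(f) > idx["note"] else "",
            )
            out[cur.gene_id] = cur
    return out


def write_calls(calls: Sequence[PathogenicityCall], path: str | Path) -> Path:
    import json

    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sv_id\ttier\tevidence\n")
        for c in calls:
            fh.write(f"{c.sv_id}\t{c.tier}\t{json.dumps(c.evidence, sort_keys=True)}\n")
    return path
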