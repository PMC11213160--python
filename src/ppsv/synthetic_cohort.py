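"""Synthetic cohort generator with a planted-truth table.

Produces a complete, internally consistent input bundle for the whole
pipeline — gene annotation (GTF), enhancers (BED), per-sample caller VCF
pairs, a multi-sample genotyped VCF, four pathogenicity score tables, a
known-SV catalog, cancer gene sets, a gene-role curation table and a
clinical table — together with a truth table recording, per planted SV,
its coordinates, impact category, group allele frequencies, carriers and
the tier the pipeline is expected to assign.

Layout: each gene lives in its own fixed-size slot (no overlap), every
chromosome ends in a gene desert where background and intergenic events
are placed.  All randomness flows from a single seed.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .gene_impact import GENE_DISRUPTIVE, RegulatoryElement, TranscriptModel
from .sv_io import (
    GenotypePayload,
    SVRecord,
    make_record,
    read_sv_vcf,
    write_sv_vcf,
)

SLOT = 60_000
GENE_MARGIN = 15_000
DESERT_GAP = 50_000
DESERT_LEN = 400_000
UTR_LEN = 100

_PASS_SCORES = {"strvctvre": 0.80, "cadd_sv": 22.0, "postre": 0.92, "phenosv": 0.88}
_FAIL_SCORES = {"strvctvre": 0.10, "cadd_sv": 4.0, "postre": 0.35, "phenosv": 0.21}
_TOOL_ORDER = ["phenosv", "postre", "cadd_sv", "strvctvre"]
_TOOL_TYPES = {
    "strvctvre": {"DEL", "DUP"},
    "cadd_sv": {"DEL", "DUP", "INS"},
    "postre": {"DEL", "DUP", "INV", "TRA"},
    "phenosv": {"DEL", "DUP", "INS", "INV", "TRA"},
}
_EXONIC_CATEGORIES = {"pLoF", "CG", "IED", "partial_exon_DUP", "UTR"}
_PASS_K = {"pass0": 0, "pass1": 1, "pass2": 2, "pass_all": 99}


@dataclass
class PlantedSVSpec:
    """One planted SV: what it does to its gene and how the evidence is
    arranged (scores, frequency, catalog presence, curation roles)."""

    label: str
    category: str
    svtype: str
    gene_role: str = "tumour_suppressor"
    partner_role: str | None = None  # second gene of a TRA fusion
    score_pattern: str = "pass2"     # pass0 | pass1 | pass2 | pass_all
    carriers_african: int = 0
    carriers_european: int = 0
    clinvar: str | None = None       # pathogenic/likely_pathogenic/benign/uncertain
    in_catalog: bool = False
    catalog_af: float | None = None
    cancer_sets: int = 2             # gene sets the target gene(s) appear in


@dataclass
class PerturbSpec:
    """Targeted degradation applied by :func:`perturb`."""

    site_fail_count: int = 0     # force PASS_ratio below threshold
    missing_site_count: int = 0  # give sites per-group missingness = missing_rate
    missing_rate: float = 0.25
    ft_fail_rate: float = 0.0
    gq_drop_rate: float = 0.0
    orphan_bnd_count: int = 0
    jitter_site_count: int = 0   # shift GRIDSS breakpoints of shared sites
    jitter_shift: int = 300


def default_planted_specs() -> list[PlantedSVSpec]:
    S = PlantedSVSpec
    return [
        # catalog-interpreted tiers
        S("clinvar_path_del", "pLoF", "DEL", clinvar="pathogenic", in_catalog=True,
          carriers_african=1),
        S("clinvar_lp_ied", "IED", "DUP", clinvar="likely_pathogenic", in_catalog=True,
          carriers_african=2),
        S("clinvar_lp_del", "pLoF", "DEL", clinvar="likely_pathogenic", in_catalog=True,
          carriers_african=1),
        S("clinvar_benign_del", "pLoF", "DEL", clinvar="benign", in_catalog=True,
          score_pattern="pass0", carriers_african=3),
        S("clinvar_uncertain_del", "pLoF", "DEL", clinvar="uncertain", in_catalog=True,
          score_pattern="pass2", carriers_african=1),
        # predicted PP-SVs
        S("ppsv_del_ts", "pLoF", "DEL", carriers_african=1),
        S("ppsv_del_ts_eur", "pLoF", "DEL", score_pattern="pass_all", carriers_european=1),
        S("ppsv_del_known", "pLoF", "DEL", in_catalog=True, catalog_af=1e-4,
          carriers_african=2),
        S("ppsv_inv_ts", "pLoF", "INV", carriers_african=1),
        S("ppsv_inv_ts2", "pLoF", "INV", carriers_african=2),
        S("ppsv_cg_onc", "CG", "DUP", gene_role="oncogene", in_catalog=True,
          catalog_af=1.3e-4, carriers_african=1),
        S("ppsv_ied_onc", "IED", "DUP", gene_role="oncogene", carriers_european=1),
        S("ppsv_tra_ts", "pLoF", "TRA", carriers_european=1),
        S("ppsv_fusion_ts_ts", "pLoF", "TRA", partner_role="tumour_suppressor",
          carriers_european=1),
        S("ppsv_ins_cds", "pLoF", "INS", carriers_african=1),
        # cautionary
        S("caut_fusion_ts_onc", "pLoF", "TRA", partner_role="oncogene",
          carriers_african=1),
        S("caut_fusion_ts_unclear", "pLoF", "TRA", partner_role="unclear",
          carriers_african=2),
        S("caut_del_conflicting", "pLoF", "DEL", gene_role="conflicting",
          carriers_african=1),
        # unlikely pathogenic
        S("unlikely_inv_onc", "pLoF", "INV", gene_role="oncogene", carriers_african=1),
        S("unlikely_del_onc", "pLoF", "DEL", gene_role="oncogene", carriers_african=1),
        S("unlikely_cg_ts", "CG", "DUP", gene_role="tumour_suppressor",
          carriers_african=1),
        # exclusions
        S("excl_common_del", "pLoF", "DEL", carriers_african=14),
        S("excl_lowfreq_del", "pLoF", "DEL", carriers_african=6),
        S("excl_noconsensus_del", "pLoF", "DEL", score_pattern="pass1",
          carriers_african=1),
        S("excl_noconsensus_tra", "pLoF", "TRA", score_pattern="pass1",
          carriers_african=1),
        S("excl_nocancer_del", "pLoF", "DEL", cancer_sets=1, carriers_african=1),
        S("excl_catalogaf_del", "pLoF", "DEL", in_catalog=True, catalog_af=0.03,
          carriers_african=1),
        S("excl_catalogaf_tra", "pLoF", "TRA", in_catalog=True, catalog_af=0.01,
          carriers_african=1),
        # non-gene-disruptive categories
        S("nd_partial_gene_dup", "partial_gene_DUP", "DUP", score_pattern="pass0",
          carriers_african=1),
        S("nd_partial_exon_dup", "partial_exon_DUP", "DUP", score_pattern="pass0",
          carriers_african=1),
        S("nd_whole_gene_inv", "whole_gene_INV", "INV", score_pattern="pass0",
          carriers_african=1),
        S("nd_utr_del", "UTR", "DEL", score_pattern="pass0", carriers_african=1),
        S("nd_promoter_del", "promoter", "DEL", score_pattern="pass0",
          carriers_african=1),
        S("nd_intronic_del", "intronic", "DEL", score_pattern="pass0",
          carriers_european=1),
        S("nd_enhancer_del", "enhancer", "DEL", score_pattern="pass0",
          carriers_african=1),
        S("nd_intergenic_del", "intergenic", "DEL", score_pattern="pass0",
          carriers_african=1),
    ]


@dataclass
class SimulationPlan:
    seed: int = 1
    n_african: int = 113
    n_european: int = 57
    n_genes: int = 45
    n_chroms: int = 4
    background_sv_counts: dict = field(
        default_factory=lambda: {"DEL": 18, "DUP": 8, "INS": 4, "INV": 4, "TRA": 4}
    )
    shared_caller_fraction: float = 0.8
    breakpoint_jitter: int = 0
    genotype_error_rate: float = 0.0
    missingness_rate: float = 0.0
    planted: list[PlantedSVSpec] = field(default_factory=default_planted_specs)
    perturb: PerturbSpec = field(default_factory=PerturbSpec)

    def __post_init__(self) -> None:
        for name in ("shared_caller_fraction", "genotype_error_rate", "missingness_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        needs_tra = any(s.svtype == "TRA" for s in self.planted) or (
            self.background_sv_counts.get("TRA", 0) > 0
        )
        if needs_tra and self.n_chroms < 2:
            raise ValueError("TRA events require at least two chromosomes")

    # -- YAML round-trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationPlan":
        d = yaml.safe_load(Path(path).read_text())
        d["planted"] = [PlantedSVSpec(**p) for p in d.get("planted", [])]
        if "perturb" in d:
            d["perturb"] = PerturbSpec(**d["perturb"])
        return cls(**d)


@dataclass
class Bundle:
    """Paths of a generated input bundle."""

    root: Path

    @property
    def gtf(self) -> Path: return self.root / "annotation.gtf"
    @property
    def enhancers(self) -> Path: return self.root / "enhancers.bed"
    @property
    def samples_tsv(self) -> Path: return self.root / "samples.tsv"
    @property
    def clinical(self) -> Path: return self.root / "clinical.tsv"
    @property
    def genotyped_vcf(self) -> Path: return self.root / "genotyped.vcf"
    @property
    def catalog(self) -> Path: return self.root / "catalog.tsv"
    @property
    def curation(self) -> Path: return self.root / "curation.tsv"
    @property
    def truth(self) -> Path: return self.root / "truth.tsv"
    @property
    def calls_dir(self) -> Path: return self.root / "calls"
    @property
    def genesets_dir(self) -> Path: return self.root / "genesets"

    def caller_vcf(self, sample: str, caller: str) -> Path:
        return self.calls_dir / f"{sample}.{caller}.vcf"

    def score_table(self, tool: str) -> Path:
        return self.root / f"scores.{tool}.tsv"

    @property
    def geneset_paths(self) -> dict[str, Path]:
        return {
            name: self.genesets_dir / f"{name}.txt"
            for name in ("hallmark", "oncogenic_signatures", "cosmic_cgc")
        }

    def read_groups(self) -> dict[str, str]:
        groups = {}
        with open(self.samples_tsv) as fh:
            fh.readline()
            for line in fh:
                sample, group = line.rstrip("\n").split("\t")
                groups[sample] = group
        return groups


# ---------------------------------------------------------------------------
# annotation


def _build_gene(rng: np.random.Generator, chrom: str, slot_start: int,
                idx: int) -> TranscriptModel:
    n_exons = int(rng.integers(4, 10))
    strand = "+" if idx % 2 == 0 else "-"
    pos = slot_start + GENE_MARGIN
    exons: list[tuple[int, int]] = []
    for k in range(n_exons):
        terminal = k in (0, n_exons - 1)
        elen = int(rng.integers(300, 450)) if terminal else int(rng.integers(150, 300))
        exons.append((pos, pos + elen - 1))
        pos = pos + elen + int(rng.integers(800, 1800))
    start, end = exons[0][0], exons[-1][1]
    if end - slot_start > SLOT - GENE_MARGIN:
        raise ValueError("infeasible gene packing: gene exceeds its slot")
    cds = []
    for k, (s, e) in enumerate(exons):
        if k == 0:
            cds.append((s + UTR_LEN, e))
        elif k == n_exons - 1:
            cds.append((s, e - UTR_LEN))
        else:
            cds.append((s, e))
    gid = f"G{idx:03d}"
    return TranscriptModel(
        gene_id=gid, gene_name=gid, chrom=chrom, strand=strand,
        start=start, end=end, exons=exons, cds_segments=cds,
    )


def _chrom_layout(plan: SimulationPlan) -> tuple[dict[str, int], int]:
    slots_per_chrom = max(1, -(-plan.n_genes // plan.n_chroms))
    desert_start = slots_per_chrom * SLOT + DESERT_GAP
    contigs = {
        f"chr{i + 1}": desert_start + DESERT_LEN for i in range(plan.n_chroms)
    }
    return contigs, desert_start


def simulate_annotation(
    plan: SimulationPlan, out_dir: str | Path
) -> tuple[list[TranscriptModel], list[RegulatoryElement]]:
    """Write ``annotation.gtf`` and ``enhancers.bed``; return the models.

    Genes are packed one per 60 kb slot, round-robin over chromosomes,
    with alternating strands; each gene gets an intergenic enhancer near
    its slot start.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 1]))
    models: list[TranscriptModel] = []
    enhancers: list[RegulatoryElement] = []
    for idx in range(plan.n_genes):
        chrom = f"chr{idx % plan.n_chroms + 1}"
        slot_start = (idx // plan.n_chroms) * SLOT
        gene = _build_gene(rng, chrom, slot_start, idx)
        models.append(gene)
        # one intergenic enhancer per gene, near the slot start
        enhancers.append(
            RegulatoryElement(
                chrom=chrom,
                start=slot_start + 2_000,
                end=slot_start + 2_800,
                element_type="enhancer",
                target_gene=gene.gene_id,
            )
        )
    _write_gtf(models, out_dir / "annotation.gtf")
    with open(out_dir / "enhancers.bed", "w") as fh:
        for e in enhancers:
            fh.write(f"{e.chrom}\t{e.start - 1}\t{e.end}\t{e.target_gene}\n")
    return models, enhancers


def _write_gtf(models: Sequence[TranscriptModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#!genome synthetic\n")
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; gene_name "{m.gene_name}";'
            tattrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1"; '
                f'gene_name "{m.gene_name}"; tag "Ensembl_canonical";'
            )
            fh.write(
                f"{m.chrom}\tsynthetic\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.chrom}\tsynthetic\ttranscript\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{tattrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tsynthetic\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{tattrs}\n"
                )
            for s, e in m.cds_segments:
                fh.write(
                    f"{m.chrom}\tsynthetic\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t{tattrs}\n"
                )


# ---------------------------------------------------------------------------
# SV placement


def _mid(iv: tuple[int, int]) -> int:
    return (iv[0] + iv[1]) // 2


class _DesertAllocator:
    def __init__(self, desert_start: int):
        self.desert_start = desert_start
        self.cursor: dict[str, int] = {}

    def take(self, chrom: str, length: int = 0) -> int:
        pos = self.cursor.get(chrom, self.desert_start)
        self.cursor[chrom] = pos + length + 3_000
        return pos


def _place_planted(
    spec: PlantedSVSpec,
    sv_id: str,
    gene: TranscriptModel,
    partner: TranscriptModel | None,
    desert: _DesertAllocator,
    rng: np.random.Generator,
    enhancer: RegulatoryElement | None,
) -> SVRecord:
    g = gene
    introns = g.introns
    cat, st = spec.category, spec.svtype
    compatible = {
        "pLoF": {"DEL", "DUP", "INV", "INS", "TRA"},
        "CG": {"DUP"},
        "IED": {"DUP"},
        "partial_exon_DUP": {"DUP"},
        "partial_gene_DUP": {"DUP"},
        "whole_gene_INV": {"INV"},
        "UTR": {"DEL"},
        "promoter": {"DEL"},
        "intronic": {"DEL"},
        "enhancer": {"DEL"},
        "intergenic": {"DEL"},
    }
    if st not in compatible.get(cat, set()):
        raise ValueError(
            f"{spec.label}: cannot place category {cat!r} as SV type {st!r}"
        )
    ins_seq = None
    if st == "TRA":
        p1 = _mid(introns[0])
        if partner is not None:
            c2, p2 = partner.chrom, _mid(partner.introns[0])
        else:
            c2 = "chr1" if g.chrom != "chr1" else "chr2"
            p2 = desert.take(c2, 0)
        return make_record(sv_id, g.chrom, p1, c2, p2, "TRA")
    if cat == "pLoF" and st == "DEL":
        p1, p2 = _mid(introns[0]), _mid(introns[1])
    elif cat == "pLoF" and st == "DUP":
        p1, p2 = _mid(g.exons[1]), _mid(g.exons[2])
    elif cat == "pLoF" and st == "INV":
        p1, p2 = _mid(introns[0]), g.end + 5_000
    elif cat == "pLoF" and st == "INS":
        p1 = p2 = _mid(g.exons[1])
        ins_seq = "".join(rng.choice(list("ACGT"), size=120))
    elif cat == "CG":
        p1, p2 = g.start - 3_000, g.end + 3_000
    elif cat == "IED":
        p1, p2 = _mid(introns[0]), _mid(introns[1])
    elif cat == "partial_exon_DUP":
        p1, p2 = _mid(introns[0]), _mid(g.exons[1])
    elif cat == "partial_gene_DUP":
        p1, p2 = g.start - 3_000, _mid(introns[1])
    elif cat == "whole_gene_INV":
        p1, p2 = g.start - 3_000, g.end + 3_000
    elif cat == "UTR":
        first = g.exons[0]
        p1, p2 = first[0] + 10, first[0] + 80
    elif cat == "intronic":
        p1, p2 = introns[0][0] + 50, introns[0][0] + 250
    elif cat == "promoter":
        w = g.promoter_window()
        p1, p2 = w[0] + 200, w[0] + 700
    elif cat == "enhancer":
        if enhancer is None:
            raise ValueError(f"{spec.label}: gene {g.gene_id} has no enhancer")
        p1, p2 = enhancer.start + 100, enhancer.start + 300
    elif cat == "intergenic":
        p1 = desert.take(g.chrom, 200)
        p2 = p1 + 200
    else:
        raise ValueError(
            f"{spec.label}: cannot place category {cat!r} as {st}"
        )
    return make_record(sv_id, g.chrom, p1, g.chrom, p2, st, insertion_seq=ins_seq)


def _expected_tier(spec: PlantedSVSpec, maf_afr: float, maf_eur: float) -> str:
    """Tier the pipeline must assign — derived from the plan, not by
    running the classifier."""
    if spec.category not in GENE_DISRUPTIVE:
        return "not_gene_disruptive"
    if max(maf_afr, maf_eur) > 0.05:
        return "excluded_common"
    if spec.clinvar == "pathogenic":
        return "clinvar_pathogenic"
    if spec.clinvar == "likely_pathogenic":
        return "clinvar_likely_pathogenic"
    if spec.clinvar in ("benign", "likely_benign"):
        return "excluded_benign"
    covered = _covered_tools(spec.svtype, spec.category in _EXONIC_CATEGORIES)
    n_pass = min(_PASS_K[spec.score_pattern], len(covered))
    if n_pass < 2:
        return "excluded_no_consensus"
    if spec.cancer_sets < 2:
        return "excluded_no_cancer_support"
    if maf_afr >= 0.01 or maf_eur >= 0.01:
        return "excluded_common"
    if spec.in_catalog and spec.catalog_af is not None and spec.catalog_af >= 0.01:
        return "excluded_catalog_af"
    roles = {spec.gene_role}
    if spec.partner_role is not None:
        roles.add(spec.partner_role)
    if "tumour_suppressor" in roles and "oncogene" in roles:
        return "cautionary_pp_sv"
    if "unclear" in roles or "conflicting" in roles:
        return "cautionary_pp_sv"
    if spec.category == "pLoF" and "tumour_suppressor" in roles:
        return "pp_sv"
    if spec.category in ("CG", "IED") and "oncogene" in roles:
        return "pp_sv"
    return "unlikely"


def _covered_tools(svtype: str, exonic: bool) -> list[str]:
    tools = [t for t in _TOOL_ORDER if svtype in _TOOL_TYPES[t]]
    if not exonic and "strvctvre" in tools:
        tools.remove("strvctvre")
    return tools


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class _Site:
    record: SVRecord
    caller: str              # both | manta_only | gridss_only
    carriers: list[int]      # sample indices (het)
    spec: PlantedSVSpec | None = None
    gene: TranscriptModel | None = None
    partner: TranscriptModel | None = None


def simulate_cohort(
    plan: SimulationPlan, out_dir: str | Path
) -> tuple[Bundle, pd.DataFrame]:
    """Generate the full bundle and its truth table (also written to
    ``truth.tsv``).  Deterministic per seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = Bundle(root=out_dir)
    models, enhancers = simulate_annotation(plan, out_dir)
    contigs, desert_start = _chrom_layout(plan)
    desert = _DesertAllocator(desert_start)
    enh_by_gene = {e.target_gene: e for e in enhancers}

    samples = [f"AFR{i + 1:03d}" for i in range(plan.n_african)] + [
        f"EUR{i + 1:03d}" for i in range(plan.n_european)
    ]
    groups = {s: ("African" if s.startswith("AFR") else "European") for s in samples}
    afr_idx = np.arange(plan.n_african)
    eur_idx = np.arange(plan.n_african, plan.n_african + plan.n_european)

    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 2]))

    # -- planted sites ---------------------------------------------------
    if len(plan.planted) > plan.n_genes:
        raise ValueError("more planted SVs than genes available")
    sites: list[_Site] = []
    gene_cursor = 0
    for i, spec in enumerate(plan.planted):
        if gene_cursor >= plan.n_genes:
            raise ValueError("not enough genes for the planted specs")
        gene = models[gene_cursor]
        gene_cursor += 1
        partner = None
        if spec.svtype == "TRA" and spec.partner_role is not None:
            if gene_cursor >= plan.n_genes:
                raise ValueError("not enough genes for fusion partners")
            partner = models[gene_cursor]
            gene_cursor += 1
        if spec.category == "IED" and len(gene.exons) < 3:
            raise ValueError(f"{spec.label}: IED requires >=3 exons")
        sv_id = f"SV{i + 1:04d}"
        rec = _place_planted(
            spec, sv_id, gene, partner, desert, rng, enh_by_gene.get(gene.gene_id)
        )
        carriers = list(
            rng.choice(afr_idx, size=spec.carriers_african, replace=False)
        ) + list(rng.choice(eur_idx, size=spec.carriers_european, replace=False))
        sites.append(_Site(rec, "both", carriers, spec, gene, partner))

    # -- background sites ------------------------------------------------
    n_planted = len(sites)
    counter = n_planted
    for svtype, count in sorted(plan.background_sv_counts.items()):
        for _ in range(count):
            counter += 1
            sv_id = f"SV{counter:04d}"
            chrom = f"chr{int(rng.integers(1, plan.n_chroms + 1))}"
            if svtype == "TRA":
                p1 = desert.take(chrom)
                c2 = f"chr{(int(chrom[3:]) % plan.n_chroms) + 1}"
                rec = make_record(sv_id, chrom, p1, c2, desert.take(c2), "TRA")
            elif svtype == "INS":
                p1 = desert.take(chrom)
                seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(60, 200))))
                rec = make_record(sv_id, chrom, p1, chrom, p1, "INS", insertion_seq=seq)
            else:
                length = int(rng.integers(80, 2_000))
                p1 = desert.take(chrom, length)
                rec = make_record(sv_id, chrom, p1, chrom, p1 + length, svtype)
            u = rng.random()
            caller = (
                "both"
                if u < plan.shared_caller_fraction
                else ("manta_only" if rng.random() < 0.5 else "gridss_only")
            )
            k_afr = min(int(rng.integers(3, 20)), plan.n_african)
            k_eur = min(int(rng.integers(1, 8)), plan.n_european)
            carriers = list(rng.choice(afr_idx, size=k_afr, replace=False)) + list(
                rng.choice(eur_idx, size=k_eur, replace=False)
            )
            sites.append(_Site(rec, caller, carriers))

    # -- per-sample caller VCFs -----------------------------------------
    bundle.calls_dir.mkdir(exist_ok=True)
    jitter = {}
    for s in sites:
        if plan.breakpoint_jitter > 0:
            j = plan.breakpoint_jitter
            jitter[s.record.id] = (
                int(rng.integers(-j, j + 1)),
                int(rng.integers(-j, j + 1)),
            )
        else:
            jitter[s.record.id] = (0, 0)
    carried: dict[int, list[_Site]] = {i: [] for i in range(len(samples))}
    for s in sites:
        for ci in s.carriers:
            carried[ci].append(s)
    for si, sample in enumerate(samples):
        manta_recs = [
            s.record for s in carried[si] if s.caller in ("both", "manta_only")
        ]
        gridss_recs = []
        for s in carried[si]:
            if s.caller not in ("both", "gridss_only"):
                continue
            j1, j2 = jitter[s.record.id]
            r = s.record
            gridss_recs.append(
                make_record(
                    f"{r.id}_g", r.bp1.chrom, max(1, r.bp1.pos + j1),
                    r.bp2.chrom, max(1, r.bp2.pos + j2), r.svtype,
                    caller="gridss", insertion_seq=r.insertion_seq,
                )
            )
        write_sv_vcf(manta_recs, bundle.caller_vcf(sample, "manta"), "manta",
                     contigs=contigs)
        write_sv_vcf(gridss_recs, bundle.caller_vcf(sample, "gridss"), "gridss",
                     contigs=contigs)

    # -- genotyped multi-sample VCF -------------------------------------
    geno_sites = [s for s in sites if s.caller == "both"]
    payload = GenotypePayload(samples=samples)
    for s in geno_sites:
        bnd = s.record.svtype in ("TRA", "INV")
        calls = []
        n_pass = 0
        for i in range(len(samples)):
            gt: int | None = 1 if i in set(s.carriers) else 0
            if plan.missingness_rate > 0 and rng.random() < plan.missingness_rate:
                gt = None
            ft = None
            gq = 99
            if bnd:
                if plan.genotype_error_rate > 0 and rng.random() < plan.genotype_error_rate:
                    gq = 10
                ok = gq >= 20
            else:
                ft = "PASS"
                if plan.genotype_error_rate > 0 and rng.random() < plan.genotype_error_rate:
                    ft = "FAIL"
                ok = ft == "PASS"
            n_pass += ok
            calls.append((gt, ft, gq))
        payload.calls[s.record.id] = calls
        payload.site_info[s.record.id] = (n_pass / len(samples), True)
    write_sv_vcf(
        [s.record for s in geno_sites], bundle.genotyped_vcf, "genotyped",
        genotypes=payload, contigs=contigs,
    )

    # -- samples / clinical ---------------------------------------------
    with open(bundle.samples_tsv, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in samples:
            fh.write(f"{s}\t{groups[s]}\n")
    with open(bundle.clinical, "w") as fh:
        fh.write("patient_id\tgroup\tage\tpsa\tisup_gg\tfamily_history\n")
        for s in samples:
            age = int(rng.integers(48, 86))
            psa = round(float(rng.lognormal(2.5, 1.0)), 1)
            gg = int(rng.choice([1, 2, 3, 4, 5], p=[0.1, 0.1, 0.2, 0.3, 0.3]))
            fh.write(f"{s}\t{groups[s]}\t{age}\t{psa}\t{gg}\t\n")

    # -- score tables ----------------------------------------------------
    score_rows: dict[str, list[tuple[str, float]]] = {t: [] for t in _TOOL_ORDER}
    for s in sites:
        if s.caller != "both":
            continue
        exonic = s.spec is not None and s.spec.category in _EXONIC_CATEGORIES
        covered = _covered_tools(s.record.svtype, exonic)
        pattern = s.spec.score_pattern if s.spec is not None else "pass0"
        k = _PASS_K[pattern]
        for rank, tool in enumerate(covered):
            val = _PASS_SCORES[tool] if rank < k else _FAIL_SCORES[tool]
            score_rows[tool].append((s.record.id, val))
    for tool in _TOOL_ORDER:
        with open(bundle.score_table(tool), "w") as fh:
            fh.write("sv_id\tscore\n")
            for sv_id, val in score_rows[tool]:
                fh.write(f"{sv_id}\t{val:g}\n")

    # -- catalog ---------------------------------------------------------
    catalog_lines = ["id\tchrom1\tpos1\tchrom2\tpos2\tsvtype\tsignificance\tpopulation_afs"]
    for s in sites:
        if s.spec is None or not (s.spec.in_catalog or s.spec.clinvar):
            continue
        r = s.record
        off1, off2 = int(rng.integers(-100, 101)), int(rng.integers(-100, 101))
        sig = s.spec.clinvar or "none"
        af = s.spec.catalog_af if s.spec.catalog_af is not None else 1e-4
        catalog_lines.append(
            f"CAT_{r.id}\t{r.bp1.chrom}\t{r.bp1.pos + off1}\t{r.bp2.chrom}\t"
            f"{r.bp2.pos + off2}\t{r.svtype}\t{sig}\tAFR:{af:g},EUR:6.3e-06"
        )
    # decoys far from everything
    for i in range(5):
        catalog_lines.append(
            f"CAT_DECOY{i}\tchr1\t{10_000_000 + i * 5_000}\tchr1\t"
            f"{10_001_000 + i * 5_000}\tDEL\tnone\tAFR:0.2,EUR:0.3"
        )
    bundle.catalog.write_text("\n".join(catalog_lines) + "\n")

    # -- gene sets & curation -------------------------------------------
    bundle.genesets_dir.mkdir(exist_ok=True)
    geneset_members: dict[str, list[str]] = {
        "hallmark": [f"FILLER_H{i}" for i in range(5)],
        "oncogenic_signatures": [f"FILLER_O{i}" for i in range(5)],
        "cosmic_cgc": [f"FILLER_C{i}" for i in range(5)],
    }
    set_order = list(geneset_members)
    roles: dict[str, str] = {m.gene_id: "unclear" for m in models}
    for s in sites:
        if s.spec is None:
            continue
        roles[s.gene.gene_id] = s.spec.gene_role
        if s.partner is not None:
            roles[s.partner.gene_id] = s.spec.partner_role
            if s.spec.cancer_sets >= 2:
                geneset_members["hallmark"].append(s.gene.gene_id)
                geneset_members["cosmic_cgc"].append(s.partner.gene_id)
            elif s.spec.cancer_sets == 1:
                geneset_members["hallmark"].append(s.gene.gene_id)
        else:
            for name in set_order[: s.spec.cancer_sets]:
                geneset_members[name].append(s.gene.gene_id)
    for name, path in bundle.geneset_paths.items():
        path.write_text("\n".join(geneset_members[name]) + "\n")
    with open(bundle.curation, "w") as fh:
        fh.write("gene_id\trole\tnote\n")
        for gid in sorted(roles):
            fh.write(f"{gid}\t{roles[gid]}\t\n")

    # -- truth table -----------------------------------------------------
    rows = []
    for s in sites:
        r = s.record
        maf_afr = len([c for c in s.carriers if c < plan.n_african]) / (2 * plan.n_african)
        maf_eur = len([c for c in s.carriers if c >= plan.n_african]) / (2 * plan.n_european)
        if s.spec is not None:
            tier = _expected_tier(s.spec, maf_afr, maf_eur)
            category = s.spec.category
            label = s.spec.label
            novel = not (s.spec.in_catalog or s.spec.clinvar)
            fusion = (
                f"{s.gene.gene_name}-{s.partner.gene_name}" if s.partner else ""
            )
        else:
            tier, category, label, novel, fusion = (
                "not_gene_disruptive", "intergenic", "background", True, ""
            )
        rows.append(
            {
                "sv_id": r.id,
                "label": label,
                "chrom1": r.bp1.chrom,
                "pos1": r.bp1.pos,
                "chrom2": r.bp2.chrom,
                "pos2": r.bp2.pos,
                "svtype": r.svtype,
                "gene": s.gene.gene_id if s.gene else "",
                "partner": s.partner.gene_id if s.partner else "",
                "category": category,
                "caller": s.caller,
                "af_african": maf_afr,
                "af_european": maf_eur,
                "expected_tier": tier,
                "novel": novel,
                "fusion": fusion,
                "carriers": ";".join(samples[c] for c in sorted(s.carriers)),
            }
        )
    truth = pd.DataFrame(rows)
    truth.to_csv(bundle.truth, sep="\t", index=False)
    return bundle, truth


# ---------------------------------------------------------------------------
# perturbation


@dataclass
class PerturbReport:
    site_filter_casualties: list[str] = field(default_factory=list)
    missingness_casualties: list[str] = field(default_factory=list)
    jittered_sites: list[str] = field(default_factory=list)
    orphan_ids: list[str] = field(default_factory=list)


def perturb(plan: SimulationPlan, bundle: Bundle, out_dir: str | Path | None = None) -> tuple[Bundle, PerturbReport]:
    """Degrade a generated bundle per ``plan.perturb``.

    Site failures and missingness are applied with exact counts so the
    expected casualties are deterministic; a zero spec leaves the bundle
    byte-identical.
    """
    spec = plan.perturb
    if out_dir is not None:
        out_dir = Path(out_dir)
        if out_dir.resolve() != bundle.root.resolve():
            if out_dir.exists():
                shutil.rmtree(out_dir)
            shutil.copytree(bundle.root, out_dir)
        bundle = Bundle(root=out_dir)
    report = PerturbReport()
    if all(
        getattr(spec, f) == 0
        for f in (
            "site_fail_count", "missing_site_count", "ft_fail_rate",
            "gq_drop_rate", "orphan_bnd_count", "jitter_site_count",
        )
    ):
        return bundle, report

    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 3]))
    groups = bundle.read_groups()
    records, payload = read_sv_vcf(bundle.genotyped_vcf, dialect="genotyped")
    site_ids = [r.id for r in records]
    n_samples = len(payload.samples)

    fail_ids = list(rng.choice(site_ids, size=min(spec.site_fail_count, len(site_ids)), replace=False))
    for sid in fail_ids:
        payload.site_info[sid] = (0.3, payload.site_info[sid][1])
    report.site_filter_casualties = sorted(fail_ids)

    remaining = [s for s in site_ids if s not in set(fail_ids)]
    miss_ids = list(
        rng.choice(remaining, size=min(spec.missing_site_count, len(remaining)), replace=False)
    )
    group_members: dict[str, list[int]] = {}
    for i, s in enumerate(payload.samples):
        group_members.setdefault(groups[s], []).append(i)
    for sid in miss_ids:
        calls = payload.calls[sid]
        casualty = False
        for g, members in group_members.items():
            k = round(spec.missing_rate * len(members))
            hit = rng.choice(members, size=k, replace=False)
            for i in hit:
                gt, ft, gq = calls[i]
                calls[i] = (None, ft, gq)
            if k / len(members) > 0.2:
                casualty = True
        if casualty:
            report.missingness_casualties.append(sid)
    report.missingness_casualties.sort()

    if spec.ft_fail_rate > 0 or spec.gq_drop_rate > 0:
        for rec in records:
            bnd = rec.svtype in ("TRA", "INV")
            calls = payload.calls[rec.id]
            for i in range(n_samples):
                gt, ft, gq = calls[i]
                if bnd and spec.gq_drop_rate > 0 and rng.random() < spec.gq_drop_rate:
                    calls[i] = (gt, ft, 10)
                elif not bnd and spec.ft_fail_rate > 0 and rng.random() < spec.ft_fail_rate:
                    calls[i] = (gt, "FAIL", gq)

    # recompute PASS_ratio from degraded calls (except forced failures)
    for rec in records:
        if rec.id in set(fail_ids):
            continue
        bnd = rec.svtype in ("TRA", "INV")
        ok = 0
        for gt, ft, gq in payload.calls[rec.id]:
            ok += (gq is not None and gq >= 20) if bnd else (ft == "PASS")
        payload.site_info[rec.id] = (ok / n_samples, payload.site_info[rec.id][1])

    contigs = {c: length for c, length in _contigs_from_vcf(bundle.genotyped_vcf).items()}
    write_sv_vcf(records, bundle.genotyped_vcf, "genotyped", genotypes=payload,
                 contigs=contigs)

    # jitter shared sites out of the concordance window in the GRIDSS VCFs
    if spec.jitter_site_count > 0:
        truth = pd.read_csv(bundle.truth, sep="\t", keep_default_na=False)
        shared = truth[truth["caller"] == "both"]
        chosen = list(shared["sv_id"].iloc[: spec.jitter_site_count])
        report.jittered_sites = chosen
        carrier_map = {
            row["sv_id"]: [c for c in str(row["carriers"]).split(";") if c]
            for _, row in shared.iterrows()
        }
        affected_samples = sorted({s for sid in chosen for s in carrier_map[sid]})
        for sample in affected_samples:
            path = bundle.caller_vcf(sample, "gridss")
            recs = read_sv_vcf(path, dialect="gridss")
            out = []
            for r in recs:
                base = r.id[:-2] if r.id.endswith("_g") else r.id
                if base in chosen:
                    r = make_record(
                        r.id, r.bp1.chrom, r.bp1.pos + spec.jitter_shift,
                        r.bp2.chrom, r.bp2.pos + spec.jitter_shift, r.svtype,
                        insertion_seq=r.insertion_seq,
                    )
                out.append(r)
            write_sv_vcf(out, path, "gridss", contigs=contigs)

    # orphan breakends appended to the first sample's GRIDSS VCF
    if spec.orphan_bnd_count > 0:
        sample = sorted(groups)[0]
        path = bundle.caller_vcf(sample, "gridss")
        with open(path, "a") as fh:
            for i in range(spec.orphan_bnd_count):
                oid = f"ORPHAN{i + 1}"
                chrom = next(iter(contigs))
                pos = 5_000 + i * 100
                fh.write(
                    f"{chrom}\t{pos}\t{oid}\tN\tN[{chrom}:{pos + 10_000}[\t.\tPASS\tSVTYPE=BND\n"
                )
                report.orphan_ids.append(oid)
    return bundle, report


def _contigs_from_vcf(path: Path) -> dict[str, int]:
    import pysam

    vcf = pysam.VariantFile(str(path))
    out = {name: c.length for name, c in vcf.header.contigs.items()}
    vcf.close()
    return out
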