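"""End-to-end orchestration over a generated (or equivalent) input bundle.

Stages run in a fixed order — integrate, genotype-qc, annotate,
match-catalog, classify, report — writing intermediate artifacts and a
funnel log of per-stage input/output counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import (
    callset_integration,
    catalog_match,
    cohort_report,
    gene_impact,
    pathogenicity,
    population_genotypes,
    sv_io,
)
from .config import PipelineConfig
from .synthetic_cohort import Bundle

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, funnel: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed after {funnel}: {cause}")
        self.stage = stage
        self.funnel = funnel


@dataclass
class PipelineResult:
    outdir: Path
    funnel: dict = field(default_factory=dict)
    calls: list = field(default_factory=list)
    frequencies: dict = field(default_factory=dict)
    impacts: dict = field(default_factory=dict)
    catalog_annotations: dict = field(default_factory=dict)
    matrix: "population_genotypes.SVGenotypeMatrix | None" = None


def run_pipeline(
    config: PipelineConfig, bundle: Bundle, outdir: str | Path
) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(outdir=outdir)
    funnel = result.funnel
    stage = "integrate"
    try:
        funnel["integrate"] = _stage_integrate(config, bundle, outdir)

        stage = "genotype-qc"
        matrix, freqs = _stage_genotype_qc(config, bundle, outdir)
        result.matrix = matrix
        result.frequencies = {f.site_id: f for f in freqs}
        funnel["genotype_qc"] = {
            "sites_out": matrix.n_sites,
        }

        stage = "annotate"
        models = gene_impact.read_gene_models(bundle.gtf)
        enhancers = gene_impact.read_enhancers(bundle.enhancers)
        impacts: dict[str, list] = {}
        for site in matrix.sites:
            impacts[site.id] = gene_impact.annotate_sv(
                site, models, enhancers,
                max_span=config.max_span, promoter_size=config.promoter_size,
            )
        result.impacts = impacts
        gene_impact.write_impact_table(
            [a for anns in impacts.values() for a in anns], outdir / "impacts.tsv"
        )
        funnel["annotate"] = {
            "gene_disruptive": sum(
                any(a.category in gene_impact.GENE_DISRUPTIVE for a in anns)
                for anns in impacts.values()
            )
        }

        stage = "match-catalog"
        catalog = catalog_match.read_catalog(bundle.catalog)
        cat_ann = catalog_match.annotate_against_catalog(
            matrix.sites, catalog, window=config.catalog_window
        )
        result.catalog_annotations = cat_ann
        catalog_match.write_catalog_annotation(cat_ann, outdir / "catalog_annotation.tsv")
        funnel["match_catalog"] = {
            "known": sum(not a.novel for a in cat_ann.values()),
            "novel": sum(a.novel for a in cat_ann.values()),
        }

        stage = "classify"
        panels = pathogenicity.read_score_tables(
            {t: bundle.score_table(t) for t in config.score_thresholds}
        )
        genesets = {
            name: pathogenicity.read_geneset(path)
            for name, path in bundle.geneset_paths.items()
        }
        curation = pathogenicity.read_curation_table(bundle.curation)
        calls = []
        for site in matrix.sites:
            calls.append(
                pathogenicity.classify(
                    site.id,
                    impacts[site.id],
                    result.frequencies[site.id],
                    cat_ann.get(site.id),
                    panels.get(site.id, pathogenicity.ScorePanel(sv_id=site.id)),
                    curation,
                    genesets,
                    thresholds=config.score_thresholds,
                    min_tools=config.min_tools,
                    min_genesets=config.min_genesets,
                    rare_max=config.rare_max_maf,
                    common_min=config.common_min_maf,
                    catalog_max_af=config.catalog_max_af,
                )
            )
        result.calls = calls
        pathogenicity.write_calls(calls, outdir / "calls.tsv")
        tier_counts: dict[str, int] = {}
        for c in calls:
            tier_counts[c.tier] = tier_counts.get(c.tier, 0) + 1
        funnel["classify"] = tier_counts

        stage = "report"
        patients = cohort_report.read_clinical_table(bundle.clinical)
        carriers = cohort_report.carriers_from_matrix(matrix)
        sites_by_id = {s.id: s for s in matrix.sites}
        cohort_report.render_tables(
            calls, carriers, patients, result.frequencies, impacts,
            sites_by_id, outdir, gg_cut=config.gg_cut,
        )
    except Exception as exc:  # pragma: no cover - error path
        raise StageError(stage, funnel, exc) from exc

    (outdir / "funnel.json").write_text(json.dumps(funnel, indent=2, sort_keys=True))
    return result


def _stage_integrate(config: PipelineConfig, bundle: Bundle, outdir: Path) -> dict:
    conc_dir = outdir / "concordant"
    conc_dir.mkdir(exist_ok=True)
    groups = bundle.read_groups()
    totals = {"matched": 0, "manta_only": 0, "gridss_only": 0}
    for sample in sorted(groups):
        manta = sv_io.read_sv_vcf(bundle.caller_vcf(sample, "manta"), "manta")
        gridss = sv_io.read_sv_vcf(bundle.caller_vcf(sample, "gridss"), "gridss")
        matches = callset_integration.match_callsets(
            manta, gridss, window=config.concordance_window
        )
        callset_integration.write_concordant_set(
            matches,
            conc_dir / f"{sample}.concordant.vcf",
            conc_dir / f"{sample}.concordant.tsv",
        )
        totals["matched"] += len(matches)
        totals["manta_only"] += len(manta) - len(matches)
        totals["gridss_only"] += len(gridss) - len(matches)
    return totals


def _stage_genotype_qc(config: PipelineConfig, bundle: Bundle, outdir: Path):
    groups = bundle.read_groups()
    matrix = population_genotypes.SVGenotypeMatrix.from_vcf(
        bundle.genotyped_vcf, groups
    )
    matrix = population_genotypes.run_qc(
        matrix,
        min_pass_ratio=config.min_pass_ratio,
        min_gq=config.min_gq,
        max_missing=config.max_missing,
    )
    freqs = population_genotypes.compute_frequencies(matrix)
    population_genotypes.write_frequency_table(
        freqs, outdir / "frequencies.tsv", matrix.group_names
    )
    return matrix, freqs
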