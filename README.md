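# ppsv

Germline structural-variant (SV) pathogenicity discovery toolkit: an
end-to-end, testable implementation of a consensus "potentially
pathogenic SV" (PP-SV) classification workflow for ancestry-stratified
patient cohorts.

The pipeline stages are:

1. **Callset integration** (`ppsv.callset_integration`) — match
   Manta-style and GRIDSS-style per-sample callsets into a
   high-confidence concordant set (same SV type, both breakpoints within
   200 bp, at least one caller PASS).
2. **Population genotype QC** (`ppsv.population_genotypes`) — site
   filters (FILTER + `PASS_ratio >= 0.5`), genotype masking (`FT != PASS`
   for simple sites, `GQ < 20` for breakend-derived INV/TRA sites),
   per-ancestry missingness (`<= 20%` in both groups), fixed-site
   removal, then ancestry-stratified AC/AN/AF/MAF and frequency tiers
   (rare < 1%, low-frequency 1–5%, common > 5%).
3. **Gene impact annotation** (`ppsv.gene_impact`) — classify each SV
   against canonical transcript models into pLoF / CG / IED /
   partial-gene DUP / partial-exon DUP / whole-gene INV / UTR / promoter
   / intronic / enhancer / intergenic; name TRA gene fusions; restrict
   events > 1 Mbp to breakpoint-hit genes; read-depth-ratio sanity check
   for DEL/DUP.
4. **Catalog matching** (`ppsv.catalog_match`) — dbVar/ClinVar-style
   catalog concordance (both breakpoints within 200 bp, same type),
   novelty flags, clinical-significance tiers and reported population
   AFs.
5. **Pathogenicity cascade** (`ppsv.pathogenicity`) — gene-disruptive
   gate, rarity gates, ClinVar short-circuit, score consensus (>= 2 of
   StrVCTVRE >= 0.37 / CADD-SV >= 10 / POSTRE >= 0.8 / PhenoSV >= 0.5,
   honouring each tool's SV-type coverage), >= 2-of-3 cancer gene-set
   support, catalog-frequency exclusion, and a curated gene-role gate
   deciding PP-SV vs cautionary PP-SV vs unlikely.
6. **Cohort reporting** (`ppsv.cohort_report`) — distinct-carrier
   summaries per tier and ancestry group, aggressive-disease fractions
   (ISUP GG >= 3), germline-testing eligibility arithmetic, and
   candidate/carrier tables plus a JSON summary.

A first-class synthetic cohort generator (`ppsv.synthetic_cohort`)
produces complete input bundles — GTF annotation, enhancer BED,
per-sample caller VCF pairs, a multi-sample genotyped VCF, four score
tables, a catalog, cancer gene sets, a curation table and a clinical
table — with a planted truth table, so every stage is testable offline.
A `perturb` step injects orphan breakends, failing sites, genotype
noise and out-of-window breakpoint jitter with deterministic expected
casualties.

## CLI

```bash
# generate a synthetic bundle (default plan: 113 + 57 samples, 36 planted SVs)
ppsv simulate --seed 1 --out bundle/

# run the whole pipeline over it
ppsv run --bundle bundle/ --out out/

# or stage by stage
ppsv integrate --manta s1.manta.vcf --gridss s1.gridss.vcf --out s1.concordant
ppsv genotype-qc --vcf bundle/genotyped.vcf --samples bundle/samples.tsv --out freqs.tsv
ppsv annotate --vcf s1.concordant.vcf --gtf bundle/annotation.gtf \
    --enhancers bundle/enhancers.bed --out impacts.tsv
ppsv match-catalog --vcf s1.concordant.vcf --catalog bundle/catalog.tsv --out cat.tsv
ppsv classify --bundle bundle/ --out out/
ppsv report --calls out/calls.tsv --vcf bundle/genotyped.vcf \
    --samples bundle/samples.tsv --clinical bundle/clinical.tsv --gg-cut 3 --out report/
```

All thresholds (concordance window, QC cutoffs, MAF tiers, score
thresholds, consensus counts, grade-group cut) live in
`ppsv.config.PipelineConfig`, override them with a YAML file via
`--config` or with the per-command flags.

`out/` contains per-stage artifacts: concordant per-sample VCFs,
`frequencies.tsv`, `impacts.tsv`, `catalog_annotation.tsv`, `calls.tsv`
(tier + JSON evidence trail per SV), `candidates.tsv`, `carriers.tsv`,
`summary.json` and a `funnel.json` of per-stage counts.

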