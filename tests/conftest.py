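import pytest

from ppsv.config import PipelineConfig
from ppsv.gene_impact import TranscriptModel
from ppsv.pipeline import run_pipeline
from ppsv.synthetic_cohort import SimulationPlan, simulate_cohort


def toy_gene(
    gene_id: str = "GX",
    chrom: str = "chr1",
    strand: str = "+",
    start: int = 100_000,
    n_exons: int = 5,
    exon_len: int = 200,
    intron_len: int = 1_000,
    utr: int = 50,
    gene_name: str | None = None,
) -> TranscriptModel:
    """Regular toy transcript: equal exons/introns, terminal UTR pieces."""
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    cds = []
    for k, (s, e) in enumerate(exons):
        if k == 0:
            cds.append((s + utr, e))
        elif k == n_exons - 1:
            cds.append((s, e - utr))
        else:
            cds.append((s, e))
    return TranscriptModel(
        gene_id=gene_id,
        gene_name=gene_name or gene_id,
        chrom=chrom,
        strand=strand,
        start=exons[0][0],
        end=exons[-1][1],
        exons=exons,
        cds_segments=cds,
    )


@pytest.fixture(scope="session")
def default_plan() -> SimulationPlan:
    return SimulationPlan(seed=7)


@pytest.fixture(scope="session")
def default_bundle(default_plan, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    bundle, truth = simulate_cohort(default_plan, out)
    return bundle, truth


@pytest.fixture(scope="session")
def pipeline_result(default_bundle, tmp_path_factory):
    bundle, _ = default_bundle
    out = tmp_path_factory.mktemp("pipeline_out")
    return run_pipeline(PipelineConfig(), bundle, out)


@pytest.fixture()
def small_plan() -> SimulationPlan:
    from ppsv.synthetic_cohort import PlantedSVSpec

    return SimulationPlan(
        seed=11,
        n_african=12,
        n_european=8,
        n_genes=10,
        n_chroms=2,
        background_sv_counts={"DEL": 4, "DUP": 2, "INS": 1, "INV": 1, "TRA": 1},
        planted=[
            PlantedSVSpec("p1", "pLoF", "DEL", carriers_african=1),
            PlantedSVSpec("p2", "IED", "DUP", gene_role="oncogene",
                          carriers_european=1),
            PlantedSVSpec("p3", "pLoF", "TRA",
                          partner_role="tumour_suppressor", carriers_african=2),
        ],
    )
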