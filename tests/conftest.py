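import pytest

from varcohort.genome_io import GenomeIndex
from varcohort.pipeline import PipelineConfig, run_pipeline
from varcohort.synthetic_data import (
    SimConfig,
    simulate_cohort,
    simulate_gene_models,
)


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default-scale simulated five-line cohort (seeded, exact truth)."""
    return simulate_cohort(SimConfig(seed=1), tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def pipeline_result(cohort, tmp_path_factory):
    return run_pipeline(
        PipelineConfig(
            manifest=cohort.manifest_path,
            out_dir=tmp_path_factory.mktemp("reports"),
        )
    )


@pytest.fixture(scope="session")
def toy_genes(tmp_path_factory):
    """Toy genome + gene models with planted variants for all 23 effects."""
    return simulate_gene_models(tmp_path_factory.mktemp("genes"), seed=0)


@pytest.fixture
def toy_genome():
    return GenomeIndex(chromosomes=(("chr1", 1000), ("chr2", 500)))
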