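import pytest

from ttrcensus import (
    PipelineConfig,
    generate_worked_genome,
    resources,
    run_pipeline,
)


@pytest.fixture(scope="session")
def registry():
    return resources.default_registry()


@pytest.fixture(scope="session")
def area_table():
    return resources.default_area_table()


@pytest.fixture(scope="session")
def worked_genome(tmp_path_factory):
    """The fixed 10-protein toy genome (2 TTRs, 1 hybrid, 3 ST, cds 10)."""
    outdir = tmp_path_factory.mktemp("worked_genome")
    return generate_worked_genome(outdir)


@pytest.fixture(scope="session")
def worked_result(worked_genome, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("worked_bundle")
    config = PipelineConfig(
        proteome=worked_genome.proteome_fasta,
        hits=worked_genome.hits_tsv,
        genome_meta=worked_genome.genome_meta_tsv,
        tm_segments=worked_genome.tm_tsv,
        outdir=str(outdir),
        min_genomes=1,
    )
    return run_pipeline(config)
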