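import pytest

from tecurate import CascadeInputs, SimulationRecipe, generate_dataset
from tecurate.config import PipelineConfig


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_dataset():
    """One fully generated synthetic dataset (seed 42), shared read-only."""
    return generate_dataset(SimulationRecipe(rng_seed=42))


def cascade_inputs(dataset) -> CascadeInputs:
    return CascadeInputs(
        model_hits=dataset.self_hits,
        genome_hits=dataset.genome_hits,
        exon_hits=dataset.exon_hits,
        exon_products=dataset.exon_products,
        tandem_records=dataset.tandem_records,
        trna_rows=dataset.trna_rows,
    )
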