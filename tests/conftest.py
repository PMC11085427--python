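import pytest
from hypothesis import settings

from flavogwas.datasets import load_curated
from flavogwas.synthetic import SyntheticParams

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def curated():
    """The bundled curated evidence (pathways, UR lists, recurrence, counts)."""
    return load_curated()


@pytest.fixture(scope="session")
def small_params():
    """Downscaled generator parameters for fast per-test synthetic runs."""
    return SyntheticParams(
        universe_size=500,
        study_sizes=(60, 50, 40),
        shared_core_size=5,
        n_planted_priority=4,
        trait_set_sizes={
            "hypertension": 40,
            "atherosclerosis": 15,
            "arterial_stiffness": 10,
        },
        n_decoy_associations=5,
        n_background_sets=8,
        n_planted_pathways=1,
        pathway_size_range=(10, 20),
        enrichment_factor=8.0,
        n_background_regulators=10,
        n_planted_regulators=2,
        regulator_targets_range=(20, 60),
        bias_factor=8.0,
        n_lit_background=30,
    )
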