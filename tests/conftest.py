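import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

warnings.filterwarnings(
    "ignore", message="Precision loss occurred in moment calculation")


@pytest.fixture(scope="session")
def references():
    from tesurvey.references import build_reference_set
    return build_reference_set()


@pytest.fixture(scope="session")
def planted_scenario():
    """Two 250 kb genomes with maT/mariner/Tigger copies at divergence
    0.05, half frameshift-defective; shared by mining/element tests."""
    from tesurvey import synthetic as syn
    tree = syn.simulate_host_tree(2, 100, seed=11)
    genomes = syn.synthesize_genomes(tree, 250_000, 0.35, seed=12)
    truth = None
    for i, fam in enumerate(["maT", "mariner", "Tigger"]):
        genomes, truth = syn.plant_elements(
            genomes, syn.default_spec(fam), 2, 0.05,
            defective_fraction=0.5, defective_mode="frameshift",
            seed=13 + i, truth=truth)
    return tree, genomes, truth


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """The packaged five-species demonstration, run once per session."""
    from tesurvey.pipeline import run_pipeline
    from tesurvey.scenarios import demo_config
    out = tmp_path_factory.mktemp("demo")
    return run_pipeline(demo_config(seed=1, output_dir=str(out)))
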