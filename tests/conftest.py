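import pytest
from hypothesis import settings

from mircascade.pipeline import PipelineConfig, run_pipeline
from mircascade.simulate import SimulationConfig, simulate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default synthetic study fixture (seed 1), written to disk."""
    out = tmp_path_factory.mktemp("bundle")
    bundle = simulate_dataset(SimulationConfig(seed=1), out_dir=out)
    return bundle, out


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A scaled-down bundle for fast structural pipeline tests."""
    out = tmp_path_factory.mktemp("small_bundle")
    cfg = SimulationConfig(
        seed=7, n_hairpins=2, n_hairpins_with_star=1, n_decoys=2,
        myb_family_size=3, myb_divergent_cycles=6, tas_cycles=6,
        n_secondary_targets=1, n_decoy_targets=1,
        library_total_reads=5_000, degradome_tags_per_transcript=100,
    )
    bundle = simulate_dataset(cfg, out_dir=out)
    return bundle, out


@pytest.fixture(scope="session")
def pipeline_run(default_bundle, tmp_path_factory):
    """One end-to-end run on the default fixture, shared across tests."""
    _, bundle_dir = default_bundle
    out = tmp_path_factory.mktemp("pipeline_out")
    run = run_pipeline(bundle_dir, out, PipelineConfig(seed=1))
    assert run.exit_status == 0, run.summary
    return run, out
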