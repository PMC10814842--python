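import pytest

from resrisk.io import RunConfig, run_pipeline, write_example_inputs


@pytest.fixture(scope="session")
def example_run(tmp_path_factory):
    """A full synthetic-fixture pipeline run (shared across tests)."""
    root = tmp_path_factory.mktemp("example")
    config_path = write_example_inputs(root, seed=11, n_iter=400)
    config = RunConfig.load(config_path)
    outputs = run_pipeline(config)
    return {"root": root, "config_path": config_path, "config": config, "outputs": outputs}
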