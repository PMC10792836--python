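import json
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory) -> tuple[Path, dict]:
    """One full pipeline run at the study conditions (default config,
    seed 1); shared across tests that only read its outputs."""
    from admodnet.pipeline import run_pipeline

    out = run_pipeline(seed=1, out_dir=tmp_path_factory.mktemp("run") / "r1")
    with open(out / "results.json") as fh:
        results = json.load(fh)
    truth = json.loads((out / "truth.json").read_text())
    return out, {"results": results, "truth": truth}
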