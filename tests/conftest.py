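import time

import pytest

from asrna.model import AnalysisConfig
from asrna.pipeline import run_pipeline
from asrna.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Down-scaled synthetic study bundle (seed 1) shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle_small") / "bundle"
    config = SyntheticConfig.small(seed=1)
    truth = generate_dataset(config, str(outdir))
    return {"dir": str(outdir), "truth": truth, "config": config}


@pytest.fixture(scope="session")
def small_run(small_bundle):
    result = run_pipeline(small_bundle["dir"], AnalysisConfig(seed=1))
    return {**small_bundle, "result": result}


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """The default-scale synthetic study (seed 1) through the whole pipeline."""
    outdir = tmp_path_factory.mktemp("bundle_full") / "bundle"
    config = SyntheticConfig(seed=1)
    truth = generate_dataset(config, str(outdir))
    t0 = time.monotonic()
    result = run_pipeline(str(outdir), AnalysisConfig(seed=1))
    elapsed = time.monotonic() - t0
    return {"dir": str(outdir), "truth": truth, "config": config,
            "result": result, "elapsed": elapsed}
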