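import json

import pytest

from stratomics import pipeline, synthetic

#: signature-stage parameters for the CI-scale end-to-end run: candidate k
#: capped at 5 and 8 replicates keep the orchestrated run in seconds while
#: leaving two above-truth candidates for the selection rule to reject
CI_SIGNATURE_PARAMS = {"k_max": 5, "n_replicates": 8}


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """A complete synthetic two-cohort study at CI scale (17 vs 60)."""
    cfg = synthetic.default_config(scale="test", seed=11)
    out = tmp_path_factory.mktemp("study")
    paths, ledger = synthetic.simulate_study(cfg, out)
    return {"config": cfg, "paths": paths, "ledger": ledger, "dir": out}


@pytest.fixture(scope="session")
def bundle(study, tmp_path_factory):
    """A full pipeline run over the session study."""
    out = tmp_path_factory.mktemp("bundle")
    config = pipeline.default_run_config(study["paths"], out, seed=11)
    config["signatures"].update(CI_SIGNATURE_PARAMS)
    bundle_dir = pipeline.run_all(config)
    return {"config": config, "dir": bundle_dir}


@pytest.fixture(scope="session")
def recovery_report(study, bundle):
    return synthetic.evaluate_recovery(study["ledger"], bundle["dir"])
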