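import numpy as np
import pytest
from dataclasses import replace

from tizmap.phantom import PhantomSpec, build_labels, assign_sources, simulate_gre


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    return replace(PhantomSpec(), noise_sigma=0.0, dsc_noise_sigma=0.0,
                   dce_noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    labels = build_labels(noiseless_spec)
    return assign_sources(labels, noiseless_spec)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    labels = build_labels(default_spec)
    return assign_sources(labels, default_spec)


@pytest.fixture(scope="session")
def noiseless_gre(noiseless_phantom, noiseless_spec):
    return simulate_gre(noiseless_phantom, noiseless_spec)


@pytest.fixture(scope="session")
def qsm_loop(noiseless_phantom, noiseless_gre):
    """Full noiseless QSM chain: unwrap -> field -> V-SHARP -> both inversions."""
    from tizmap import qsm

    gt = noiseless_phantom
    brain = gt.labels.data > 0
    tumor = gt.labels.mask("ed", "ncr", "et", "tiz")
    fields, chis = qsm.reconstruct_chi(noiseless_gre, brain, tumor)
    return gt, fields, chis


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One end-to-end run on the default noisy phantom, shared across tests."""
    from tizmap.pipeline import RunConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = RunConfig(out_dir=str(out), seed=1234)
    return run_pipeline(cfg)
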