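import numpy as np
import pytest

from scaffoldquant.pipeline import FIXTURE_CONFIGS, make_fixtures
from scaffoldquant.simulate import (
    AssaySimConfig,
    ScaffoldSimConfig,
    generate_assay_tables,
    generate_scaffold_stack,
)


def tiny_config(**overrides) -> ScaffoldSimConfig:
    return ScaffoldSimConfig(**{**FIXTURE_CONFIGS["tiny"], **overrides})


@pytest.fixture(scope="session")
def tiny_sim():
    """One deterministic tiny stack: (config, stack, labels, truth)."""
    cfg = tiny_config(seed=0)
    stack, labels, truth = generate_scaffold_stack(cfg)
    return cfg, stack, labels, truth


@pytest.fixture(scope="session")
def small_sim():
    """The small (~300-cell) fixture used for segmentation scoring."""
    cfg = ScaffoldSimConfig(**FIXTURE_CONFIGS["small"], seed=0)
    stack, labels, truth = generate_scaffold_stack(cfg)
    return cfg, stack, labels, truth


@pytest.fixture(scope="session")
def assay_series():
    return generate_assay_tables(AssaySimConfig(), seed=0)


@pytest.fixture(scope="session")
def tiny_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures") / "tiny"
    hashes = make_fixtures("tiny", outdir, seed=0)
    return outdir, hashes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
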