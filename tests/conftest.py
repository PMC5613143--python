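import numpy as np
import pandas as pd
import pytest

from matdosage.config import SyntheticConfig
from matdosage.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort for structural tests."""
    cfg = SyntheticConfig(n_genes=120, seed=3)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full default pipeline run (6000 genes, seed 42), shared."""
    from matdosage.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("demo") / "run_a"
    report = run_pipeline({"seed": 42}, out_dir=out)
    return out, report


@pytest.fixture(scope="session")
def demo_cohort():
    """The cohort underlying the default demo run (seed 42)."""
    cfg = SyntheticConfig(seed=42)
    return cfg, simulate_cohort(cfg)


def two_group_frame(rng, n_genes, n_a=3, n_b=3, mean=8.0, sd=0.3, shift=None):
    """Null (or shifted) two-group log2 matrix pair for calibration tests."""
    idx = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    a = pd.DataFrame(rng.normal(mean, sd, size=(n_genes, n_a)), index=idx)
    b = pd.DataFrame(rng.normal(mean, sd, size=(n_genes, n_b)), index=idx)
    if shift is not None:
        b = b.add(shift, axis=0)
    return a, b
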