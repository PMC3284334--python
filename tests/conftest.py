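import pytest

import ydelmap as y
from ydelmap import pipeline as pl


@pytest.fixture(scope="session")
def small_genome() -> y.GenomeModel:
    """A compact male genome shared by read-only tests."""
    cfg = y.GenomeConfig(
        autosome_lengths={"chr1": 20_000}, x_length=30_000, y_length=50_000
    )
    return y.simulate_genome(cfg, seed=11)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One demo pipeline run shared by pipeline/screen tests."""
    out = tmp_path_factory.mktemp("demo") / "run"
    cfg = pl.demo_config(seed=42, outdir=str(out))
    report = pl.run_pipeline(cfg)
    return cfg, report, out
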