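import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_sites(rows):
    """Rows of (chrom, pos, strand, meth, cov) -> site DataFrame."""
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "cov"])
    df["pos"] = df["pos"].astype(np.int64)
    df["cov"] = df["cov"].astype(np.int64)
    df["meth"] = df["meth"].astype(np.float64)
    df.loc[df["cov"] == 0, "meth"] = np.nan
    return df.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_crisp_dataset(tmp_path_factory):
    """One 300-kb crisp synthetic dataset shared across pipeline tests."""
    from methtiles import synth

    params = synth.crisp(
        seed=7,
        chrom_sizes={"chr1": 300_000},
        n_background_loci=300,
        n_depleted_loci=40,
    )
    outdir = tmp_path_factory.mktemp("crisp_data")
    paths = synth.write_synthetic_dataset(params, outdir)
    return params, paths
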