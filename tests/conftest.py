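import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methlink import MethylationMatrix, SimConfig, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_metadata(samples, size_classes, feeds=None, has_rna=None):
    n = len(samples)
    return pd.DataFrame(
        {
            "size_class": size_classes,
            "feed": feeds if feeds is not None else ["Feed1"] * n,
            "has_rna": has_rna if has_rna is not None else [True] * n,
        },
        index=pd.Index(samples, name="sample_id"),
    )


def make_matrix(loci, meth, total, size_classes=None, feeds=None):
    """Small MethylationMatrix from explicit (contig, position) loci and
    loci x samples count arrays."""
    meth = np.asarray(meth)
    total = np.asarray(total)
    samples = [f"s{j}" for j in range(meth.shape[1])]
    if size_classes is None:
        half = len(samples) // 2
        size_classes = ["large"] * half + ["small"] * (len(samples) - half)
    md = make_metadata(samples, size_classes, feeds)
    return MethylationMatrix(
        pd.DataFrame(loci, columns=["contig", "position"]), samples, meth, total, md
    )


@pytest.fixture(scope="session")
def sim():
    """Default-condition synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_filtered(sim):
    from methlink import filter_complete_coverage

    return filter_complete_coverage(sim.matrix)
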