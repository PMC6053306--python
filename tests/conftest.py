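import numpy as np
import pandas as pd
import pytest

from pchic.genome import GenomeLayout, TssCatalog, build_fragment_map
from pchic.records import Interaction
from pchic.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def bundle():
    """Default-condition synthetic dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle") / "input"
    bundle.write(d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_fragment_map():
    layout = GenomeLayout({"chr1": 100_000, "chr2": 50_000})
    cuts = {
        "chr1": list(range(500, 100_000, 500)),
        "chr2": list(range(400, 50_000, 400)),
    }
    return build_fragment_map(layout, cuts)


def make_interaction(
    gene="G1",
    chrom="chr1",
    bait=(1_000, 2_000),
    other=(50_000, 50_500),
    score=7.5,
    replicate="rep1",
    other_chrom=None,
):
    return Interaction(
        gene=gene,
        chrom=chrom,
        bait_start=bait[0],
        bait_end=bait[1],
        other_chrom=other_chrom or chrom,
        other_start=other[0],
        other_end=other[1],
        score=score,
        replicate=replicate,
    )


@pytest.fixture()
def tss_catalog():
    frame = pd.DataFrame(
        {
            "gene": ["GA", "GB", "GC"],
            "chrom": ["chr1", "chr1", "chr2"],
            "pos": [10_000, 60_000, 20_000],
            "strand": ["+", "-", "+"],
        }
    )
    return TssCatalog(frame)
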