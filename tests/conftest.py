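import numpy as np
import pandas as pd
import pytest

from atacqc.model import FragmentLibrary, GenomeLayout
from atacqc.synthetic import (
    GeneratorConfig,
    generate_annotation,
    generate_library,
)


@pytest.fixture
def tiny_layout():
    return GenomeLayout(
        lengths={"chr1": 100_000, "chr2": 50_000, "chrM": 16_500}
    )


def make_library(layout, frags, read_length=75, **kwargs):
    """Build a FragmentLibrary from (chrom, start, end) tuples."""
    records = pd.DataFrame(frags, columns=["chrom", "start", "end"])
    records["chrom"] = records["chrom"].astype(object)
    records["start"] = records["start"].astype(np.int64)
    records["end"] = records["end"].astype(np.int64)
    return FragmentLibrary(
        records=records, layout=layout, read_length=read_length, **kwargs
    )


@pytest.fixture
def lib_builder():
    return make_library


@pytest.fixture(scope="session")
def default_cfg():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_annotation(default_cfg):
    return generate_annotation(default_cfg)


@pytest.fixture(scope="session")
def default_library(default_cfg, default_annotation):
    return generate_library(default_cfg, default_annotation)


@pytest.fixture(scope="session")
def small_cfg():
    """Down-scaled generator config for fast structural tests."""
    return GeneratorConfig(
        seed=7,
        nuclear_chrom_length=400_000,
        n_peaks=40,
        n_fragments=30_000,
        complexity=300_000,
        chip_decoys_per_factor=8,
    )


@pytest.fixture(scope="session")
def small_annotation(small_cfg):
    return generate_annotation(small_cfg)


@pytest.fixture(scope="session")
def small_library(small_cfg, small_annotation):
    return generate_library(small_cfg, small_annotation)
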