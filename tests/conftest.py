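import numpy as np
import pandas as pd
import pytest

from trajectome.io import CountMatrix


@pytest.fixture
def toy_cm() -> CountMatrix:
    """3 genes x 4 samples, 2 per (condition, timepoint) cell at day1 only... kept
    minimal: day1 has 2 injury + 2 sham; day14 has 2 injury + 2 sham."""
    genes = ["gA", "gB", "gC"]
    samples = [
        ("s1", "injury", "day1", "b1"),
        ("s2", "injury", "day1", "b1"),
        ("s3", "sham", "day1", "b1"),
        ("s4", "sham", "day1", "b1"),
        ("s5", "injury", "day14", "b2"),
        ("s6", "injury", "day14", "b2"),
        ("s7", "sham", "day14", "b2"),
        ("s8", "sham", "day14", "b2"),
    ]
    sample_meta = pd.DataFrame(
        samples, columns=["sample", "condition", "timepoint", "batch"]
    ).set_index("sample")
    counts = pd.DataFrame(
        np.arange(24).reshape(3, 8) + 1,
        index=pd.Index(genes, name="gene"),
        columns=sample_meta.index,
    )
    gene_meta = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "tss": [1000, 9000, 500],
            "strand": ["+", "-", "+"],
            "length": [2000, 1500, 800],
        },
        index=pd.Index(genes, name="gene"),
    )
    return CountMatrix(counts=counts, sample_meta=sample_meta, gene_meta=gene_meta)


@pytest.fixture
def sim_kwargs():
    """Moderate-size simulation settings shared by recovery tests."""
    return dict(
        module_fractions={
            "i": 0.02, "ii": 0.03, "iii": 0.03, "iv": 0.15,
            "v": 0.12, "vi": 0.02, "vii": 0.02, "viii": 0.01,
        },
        effect_scale=2.0,
        base_mean_range=(100.0, 2000.0),
    )
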