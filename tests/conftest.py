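import dataclasses

import numpy as np
import pytest

from devtraj import core, simulate


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, linear scale."""
    samples = [
        core.SampleMeta(f"s{i}", "human", "V1C", age)
        for i, age in enumerate([56.0, 100.0, 200.0, 400.0])
    ]
    values = np.array(
        [
            [1.0, 3.0, 7.0, 15.0],
            [2.0, 2.0, 2.0, 2.0],
            [0.0, 5.0, 0.0, 9.0],
        ]
    )
    return core.ExpressionDataset(values=values, gene_ids=["gA", "gB", "gC"], samples=samples)


@pytest.fixture
def small_config():
    """A reduced simulation for fast unit tests."""
    return dataclasses.replace(
        simulate.SimConfig(seed=0),
        n_genes=120,
        n_switch=40,
        n_dnb=10,
        n_neoteny=5,
        n_acceleration=5,
        n_modules=1,
        module_size=20,
        n_celltypes=3,
        markers_per_type=5,
    )


def write_tsv_pair(tmp_path, ds: core.ExpressionDataset):
    matrix = tmp_path / "matrix.tsv"
    meta = tmp_path / "meta.tsv"
    core.write_expression(ds, matrix, meta)
    return matrix, meta
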