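"""Shared fixtures: all array data are generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spma import SimDesign, simulate_arrayset

ATF_FIXTURE = (
    "ATF\t1.0\n"
    "2\t8\n"
    '"Type=GenePix Results 3"\n'
    '"Wavelengths=635"\n'
    '"Block"\t"Row"\t"Column"\t"ID"\t"Name"\t"Flags"\t"F635 Median"\t"B635 Median"\n'
    '1\t1\t1\t"P1"\t"ProteinA"\t0\t500\t100\n'
    '1\t1\t2\t"P1"\t"ProteinA"\t0\t520\t110\n'
    '1\t1\t3\t"P2"\t"ProteinB"\t0\t230\t95\n'
    '1\t2\t1\t"P2"\t"ProteinB"\t0\t250\t105\n'
    '1\t2\t2\t"C1"\t"empty"\t0\t90\t100\n'
    '1\t2\t3\t"C2"\t""\t0\t85\t98\n'
)


@pytest.fixture
def atf_file(tmp_path):
    path = tmp_path / "array1.gpr"
    path.write_text(ATF_FIXTURE)
    return path


@pytest.fixture
def small_arrayset():
    """Default-shaped simulated set: 130 features x 3 spots, 8 arrays."""
    design = SimDesign(seed=11)
    aset, truth = simulate_arrayset(design)
    return aset, truth


@pytest.fixture(scope="session")
def de_arrayset():
    """Set with 2 bad arrays (v=4, both in one condition) and 10% truly
    differential proteins."""
    design = SimDesign(
        seed=7,
        de_fraction=0.1,
        de_log2fc=1.5,
        array_variance_factors=[1, 1, 4, 4, 1, 1, 1, 1],
    )
    return simulate_arrayset(design)


def two_group_design(n_per_group: int = 4) -> np.ndarray:
    return np.column_stack(
        [
            np.repeat([1.0, 0.0], [n_per_group, n_per_group]),
            np.repeat([0.0, 1.0], [n_per_group, n_per_group]),
        ]
    )


@pytest.fixture
def gaussian_matrix():
    """5000 x 8 homoscedastic Gaussian log2-like matrix."""
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.normal(8.0, 0.5, size=(5000, 8)),
        columns=[f"S{j + 1}" for j in range(8)],
    )
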