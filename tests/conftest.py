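"""Shared fixtures and small test utilities."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from polarsurf import IntensityMatrix, SampleDesign
from polarsurf.io import Side


def make_design(n_pairs: int) -> SampleDesign:
    """A{i}/B{i} sample pairs for bioreplicates R1..Rn."""
    samples, reps, sides = [], [], []
    for i in range(1, n_pairs + 1):
        samples += [f"A{i}", f"B{i}"]
        reps += [f"R{i}", f"R{i}"]
        sides += [Side.APICAL, Side.BASOLATERAL]
    return SampleDesign(tuple(samples), tuple(reps), tuple(sides))


def make_matrix(values, n_pairs: int, feature_ids=None, level: str = "protein") -> IntensityMatrix:
    """Matrix with columns A1,B1,...,An,Bn from a 2-D array-like (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    cols = [c for i in range(1, n_pairs + 1) for c in (f"A{i}", f"B{i}")]
    if feature_ids is None:
        feature_ids = [f"P{j + 1}" for j in range(arr.shape[0])]
    return IntensityMatrix(pd.DataFrame(arr, index=feature_ids, columns=cols), level)


def adjusted_rand_index(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index from the pair-counting contingency formula."""
    assert len(labels_a) == len(labels_b)
    a_vals = sorted(set(labels_a))
    b_vals = sorted(set(labels_b))
    table = np.zeros((len(a_vals), len(b_vals)), dtype=np.int64)
    ai = {v: i for i, v in enumerate(a_vals)}
    bi = {v: i for i, v in enumerate(b_vals)}
    for x, y in zip(labels_a, labels_b):
        table[ai[x], bi[y]] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    n = len(labels_a)
    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@pytest.fixture
def design4() -> SampleDesign:
    return make_design(4)


@pytest.fixture
def design7() -> SampleDesign:
    return make_design(7)
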