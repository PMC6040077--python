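"""Shared fixtures: synthetic studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from stratiprof.recruitment import classify_all, recruitment_matrix
from stratiprof.synthetic import default_study_config, make_study


@pytest.fixture(scope="session")
def small_study():
    """A light default study (3k reads/sample) for unit-level checks."""
    return make_study(default_study_config(n_reads_per_sample=3_000), seed=7)


@pytest.fixture(scope="session")
def small_study_recruited(small_study):
    mat, assignments = recruitment_matrix(
        small_study.samples, small_study.genomes, return_assignments=True
    )
    classes = classify_all(mat, small_study.samples)
    return small_study, mat, assignments, classes


def mutate_at(seq: str, positions: list[int]) -> str:
    """Deterministically substitute the base at each given position."""
    nxt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = nxt[out[p]]
    return "".join(out)


@pytest.fixture
def mutator():
    return mutate_at
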