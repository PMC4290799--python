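"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from privgwas import GenotypeMatrix, HaplotypeMatrix
from privgwas.preprocess import compute_allele_counts
from privgwas.synth import task1_fixture, task2_fixture


@pytest.fixture(scope="session")
def task1():
    """Dataset-1-like cohorts: 311 SNVs, 14 blocks, 200/174/174, pinned seed."""
    return task1_fixture(0)


@pytest.fixture(scope="session")
def task1_counts(task1):
    return compute_allele_counts(task1.case), compute_allele_counts(task1.control)


@pytest.fixture(scope="session")
def task2():
    """Task-2-like cohorts: 5000 independent SNVs, 201/174/174, pinned seed."""
    return task2_fixture(0)


@pytest.fixture(scope="session")
def task2_counts(task2):
    return compute_allele_counts(task2.case), compute_allele_counts(task2.control)


def random_genotypes(
    n_snvs: int, n_individuals: int, seed: int, missing_rate: float = 0.0
) -> GenotypeMatrix:
    rng = np.random.default_rng(seed)
    dosages = rng.integers(0, 3, size=(n_snvs, n_individuals)).astype(np.int8)
    if missing_rate:
        from privgwas import MISSING

        dosages[rng.random(dosages.shape) < missing_rate] = MISSING
    return GenotypeMatrix(
        individual_ids=[f"I{j}" for j in range(n_individuals)],
        snv_ids=[f"rs{i}" for i in range(n_snvs)],
        dosages=dosages,
    )


def random_haplotypes(n_snvs: int, n_individuals: int, seed: int) -> HaplotypeMatrix:
    rng = np.random.default_rng(seed)
    return HaplotypeMatrix(
        individual_ids=[f"I{j}" for j in range(n_individuals)],
        snv_ids=[f"rs{i}" for i in range(n_snvs)],
        alleles=rng.integers(0, 2, size=(2 * n_individuals, n_snvs)).astype(np.int8),
    )
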