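"""Shared fixtures and independent oracles for the test suite."""

from itertools import product

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from pwaskit import CohortSpec, simulate_cohort

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


def enumerate_hit_distribution(scores, genotypes):
    """Brute-force distribution of the number of damaged gene copies.

    Independent-allele model (mu = 0): a sample carries ``genotypes[i]``
    copies of variant i, and each copy independently damages its gene
    copy with probability ``1 - scores[i]``.  Enumerates all 2^(total
    copies) damage outcomes; returns {n_damaged: probability}.

    This is the independent oracle for the aggregation formulas at
    mu = 0, p = q = 1: D = P(0 damaged), R = P(<= 1 damaged).
    """
    copy_damage = []
    for s, g in zip(scores, genotypes):
        copy_damage.extend([1.0 - s] * int(g))
    dist: dict[int, float] = {}
    for outcome in product((0, 1), repeat=len(copy_damage)):
        p = 1.0
        for damaged, d in zip(outcome, copy_damage):
            p *= d if damaged else (1.0 - d)
        dist[sum(outcome)] = dist.get(sum(outcome), 0.0) + p
    return dist


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 400-sample, 25-gene synthetic cohort."""
    return simulate_cohort(CohortSpec(n_samples=400, n_genes=25, seed=11))


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    return small_cohort.build_scores()
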