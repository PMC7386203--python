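"""Statistical power simulation for gene-level association testing.

Each simulation iteration considers a single gene whose effect on a
continuous phenotype follows the generative model::

    y = beta * x + e,     e ~ N(0, 1)

where ``x`` is the gene's standardized functional effect (the dominant
score column, the recessive one, or their additive composition), and
``beta`` is the effect size.  Binary phenotypes are produced from the
same liability ``y`` by thresholding at a prevalence quantile.  Variant
effect scores can be distorted with additive Gaussian noise of standard
deviation ``epsilon`` before aggregation, emulating an imperfect
damage predictor.

Power at a given cohort size is the fraction of replicates in which the
matching association test rejects, with a Wilson 95% confidence
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.proportion import proportion_confint

from .aggregation import AggregationParams, build_gene_score_matrices
from .association import PhenotypeVector, test_gene
from .variants import perturb_scores

__all__ = [
    "SimulationSpec",
    "simulate_gene_effect",
    "simulate_phenotype",
    "estimate_power",
]

_INHERITANCE = ("dominant", "recessive", "additive")


@dataclass
class SimulationSpec:
    """Generative description of a simulated phenotype study.

    Attributes
    ----------
    inheritance : {"dominant", "recessive", "additive"}
        How the causal gene's effect is composed from its score columns.
    beta : float
        Effect size on the standardized gene effect.
    epsilon : float
        Standard deviation of the Gaussian noise added to variant effect
        scores before aggregation (0 = perfect scores).
    cohort_sizes : list of int
        Cohort sizes at which power is estimated.
    n_replicates : int
        Monte-Carlo replicates per cohort size (>= 20 for a usable CI).
    phenotype_kind : {"continuous", "binary"}
    prevalence : float
        Case fraction for binary phenotypes (liability threshold).
    seed : int
    """

    inheritance: str = "dominant"
    beta: float = 0.05
    epsilon: float = 0.0
    cohort_sizes: list[int] = field(default_factory=lambda: [1000, 10000, 50000])
    n_replicates: int = 100
    phenotype_kind: str = "continuous"
    prevalence: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inheritance not in _INHERITANCE:
            raise ValueError(f"unknown inheritance mode: {self.inheritance}")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.phenotype_kind not in ("continuous", "binary"):
            raise ValueError(f"unknown phenotype kind: {self.phenotype_kind}")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if any(n <= 0 for n in self.cohort_sizes):
            raise ValueError("cohort sizes must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("score column is constant; cannot standardize")
    return (v - v.mean()) / sd


def simulate_gene_effect(
    dom_col: Sequence[float], rec_col: Sequence[float], inheritance: str
) -> np.ndarray:
    """Compose and standardize a gene's effect on the phenotype.

    Dominant and recessive modes standardize the corresponding score
    column to mean 0, sd 1.  The additive mode is the standardized sum
    of the two standardized columns — the symmetric composition of the
    two inheritance patterns.
    """
    if inheritance not in _INHERITANCE:
        raise ValueError(f"unknown inheritance mode: {inheritance}")
    dom = np.asarray(dom_col, dtype=float)
    rec = np.asarray(rec_col, dtype=float)
    if dom.shape != rec.shape:
        raise ValueError("dominant and recessive columns must have equal length")
    if inheritance == "dominant":
        return _standardize(dom)
    if inheritance == "recessive":
        return _standardize(rec)
    return _standardize(_standardize(dom) + _standardize(rec))


def simulate_phenotype(
    x: np.ndarray,
    beta: float,
    phenotype_kind: str = "continuous",
    seed: int | np.random.Generator = 0,
    prevalence: float = 0.1,
    sample_ids: Optional[Sequence[str]] = None,
) -> PhenotypeVector:
    """Draw a phenotype y = beta * x + N(0, 1) from a standardized effect.

    Binary phenotypes threshold the continuous liability at its
    theoretical ``1 - prevalence`` quantile (y is N(0, 1 + beta^2) under
    the generative model), so the expected case fraction equals
    ``prevalence``.  Deterministic given the seed.
    """
    x = np.asarray(x, dtype=float)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    y = beta * x + rng.normal(0.0, 1.0, size=x.size)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(x.size)]
    if phenotype_kind == "continuous":
        return PhenotypeVector(list(sample_ids), y, kind="continuous")
    if phenotype_kind == "binary":
        liability_sd = float(np.sqrt(1.0 + beta * beta))
        threshold = liability_sd * scipy.stats.norm.ppf(1.0 - prevalence)
        return PhenotypeVector(
            list(sample_ids), (y > threshold).astype(float), kind="binary"
        )
    raise ValueError(f"unknown phenotype kind: {phenotype_kind}")


_MATCHING_TEST = {"dominant": "dominant", "recessive": "recessive", "additive": "generalized"}


def _rebuild_gene_scores(cohort, gene_id, params, epsilon, rng, sample_index):
    """Recompute one gene's D and R columns on a subcohort, with score noise."""
    idx = cohort.variant_indices(gene_id)
    gene_variants = [cohort.variants[i] for i in idx]
    if epsilon > 0:
        gene_variants = perturb_scores(
            gene_variants, epsilon, seed=int(rng.integers(2**31))
        )
    store = cohort.genotypes.subset_samples(sample_index)
    probs = store.probs(idx)
    dom, rec = build_gene_score_matrices(
        gene_variants, probs, store.sample_ids, params, gene_ids=[gene_id]
    )
    return dom.values[:, 0], rec.values[:, 0]


def estimate_power(
    spec: SimulationSpec,
    cohort,
    params: AggregationParams = AggregationParams(),
    alpha: float = 0.05,
    test_model: Optional[str] = None,
) -> pd.DataFrame:
    """Estimate power as a function of cohort size by Monte-Carlo.

    For each cohort size, each replicate picks a gene (with a
    non-constant effect column in the subsampled cohort), perturbs its
    variant scores by ``spec.epsilon``, rebuilds the gene's dominant and
    recessive scores, simulates the phenotype under ``spec``, and runs
    the association test matching the simulated inheritance (additive
    effects use the generalized test; pass ``test_model`` to force a
    mismatched test).  Power is the rejection fraction at level
    ``alpha``, with a Wilson 95% CI.

    ``cohort`` is any object exposing ``sample_ids``, ``gene_ids``,
    ``variants``, ``variant_indices(gene_id)``, ``genotypes`` (a
    probability store) and ``covariates`` — e.g.
    :class:`pwaskit.fixtures.Cohort`.

    Returns a data frame with columns
    ``cohort_size, power, ci_low, ci_high, n_replicates``.
    """
    n_available = len(cohort.sample_ids)
    for n in spec.cohort_sizes:
        if n > n_available:
            raise ValueError(
                f"cohort size {n} exceeds available samples ({n_available})"
            )
    rng = np.random.default_rng(spec.seed)
    if test_model is None:
        test_model = _MATCHING_TEST[spec.inheritance]
    records = []
    for n in spec.cohort_sizes:
        hits = 0
        for _ in range(spec.n_replicates):
            sample_index = rng.choice(n_available, size=n, replace=False)
            sub_cov = cohort.covariates.subset(sample_index)
            # retry gene choice until the effect column varies in the subcohort
            for _attempt in range(50):
                gene_id = cohort.gene_ids[int(rng.integers(len(cohort.gene_ids)))]
                D_col, R_col = _rebuild_gene_scores(
                    cohort, gene_id, params, spec.epsilon, rng, sample_index
                )
                try:
                    x = simulate_gene_effect(D_col, R_col, spec.inheritance)
                except ValueError:
                    continue
                break
            else:
                raise RuntimeError(
                    "could not find a gene with a variable effect column"
                )
            pheno = simulate_phenotype(
                x,
                spec.beta,
                spec.phenotype_kind,
                seed=rng,
                prevalence=spec.prevalence,
                sample_ids=[cohort.sample_ids[i] for i in sample_index],
            )
            res = test_gene(D_col, R_col, pheno, sub_cov, test_model)
            hits += res.p_value < alpha
        low, high = proportion_confint(hits, spec.n_replicates, method="wilson")
        records.append(
            {
                "cohort_size": n,
                "power": hits / spec.n_replicates,
                "ci_low": float(low),
                "ci_high": float(high),
                "n_replicates": spec.n_replicates,
            }
        )
    return pd.DataFrame.from_records(records)
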