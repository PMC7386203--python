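"""Synthetic cohort generation.

Builds fully synthetic inputs — gene architectures, variant effect
scores, Hardy-Weinberg genotypes, Gaussian covariates and (optionally)
phenotypes with a planted causal gene — so the whole pipeline can be
exercised and validated without any external data.

What the generator emulates: exome-like gene architectures where each
gene carries a few dozen protein-affecting variants (log-normal count,
mean about 36), mostly missense with a minority of loss-of-function
classes; rare-to-low-frequency alternate alleles sampled log-uniformly;
genotypes in Hardy-Weinberg proportions with variants independent of
each other (no linkage disequilibrium); covariates independent of the
genotypes.  Population structure, relatedness and imputation noise are
deliberately absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as _io
from .aggregation import AggregationParams, GeneScoreMatrix, build_gene_score_matrices
from .association import CovariateMatrix, PhenotypeVector
from .simulation import simulate_gene_effect, simulate_phenotype
from .variants import Consequence, VariantRecord, score_variant

__all__ = ["CohortSpec", "Cohort", "simulate_cohort", "generate_cohort", "plant_association"]

_BASES = np.array(list("ACGT"))

#: Default consequence-class proportions: missense dominates exome
#: protein-affecting variation, with small loss-of-function and indel
#: minorities.
DEFAULT_CONSEQUENCE_MIX = {
    "missense": 0.85,
    "nonsense": 0.05,
    "frameshift": 0.04,
    "canonical_splice": 0.03,
    "inframe_indel": 0.03,
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``variants_per_gene`` follows a log-normal with the given mean
    (sigma on the log scale fixed at 0.75), truncated below at 1.
    Alternate allele frequencies are log-uniform on
    ``allele_freq_range``.  Missense effect scores are Beta(a, b).
    """

    n_samples: int = 1000
    n_genes: int = 50
    mean_variants_per_gene: float = 36.0
    allele_freq_range: tuple[float, float] = (0.001, 0.05)
    consequence_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_MIX)
    )
    missense_score_dist: tuple[float, float] = (2.0, 2.0)
    n_covariates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise ValueError("n_samples and n_genes must be positive")
        if self.mean_variants_per_gene < 1:
            raise ValueError("mean_variants_per_gene must be >= 1")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("allele frequencies must lie in (0, 0.5]")
        total = sum(self.consequence_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"consequence proportions sum to {total}, expected 1")
        if self.n_covariates < 0:
            raise ValueError("n_covariates must be >= 0")


@dataclass
class Cohort:
    """An in-memory cohort: scored variants, genotypes, covariates.

    ``spec`` and ``allele_freqs`` are populated for simulated cohorts
    and ``None`` for cohorts loaded from files.
    """

    spec: Optional[CohortSpec]
    variants: list[VariantRecord]
    allele_freqs: Optional[np.ndarray]
    genotypes: "_io.GenotypeStore"
    covariates: CovariateMatrix

    def __post_init__(self) -> None:
        self.gene_ids = sorted({v.gene_id for v in self.variants})
        self._gene_index: dict[str, list[int]] = {g: [] for g in self.gene_ids}
        for i, v in enumerate(self.variants):
            self._gene_index[v.gene_id].append(i)

    @property
    def sample_ids(self) -> list[str]:
        return self.genotypes.sample_ids

    def variant_indices(self, gene_id: str) -> list[int]:
        return self._gene_index[gene_id]

    def n_variants_per_gene(self) -> dict[str, int]:
        return {g: len(idx) for g, idx in self._gene_index.items()}

    def build_scores(
        self, params: AggregationParams = AggregationParams()
    ) -> tuple[GeneScoreMatrix, GeneScoreMatrix]:
        """Dominant and recessive score matrices for the whole cohort."""
        return build_gene_score_matrices(
            self.variants,
            self.genotypes,
            self.sample_ids,
            params,
            gene_ids=self.gene_ids,
        )


def _draw_variants(spec: CohortSpec, rng: np.random.Generator):
    sigma = 0.75
    mu = np.log(spec.mean_variants_per_gene) - sigma**2 / 2.0
    counts = np.maximum(1, np.round(rng.lognormal(mu, sigma, spec.n_genes))).astype(int)

    classes = list(spec.consequence_mix)
    probs = np.array([spec.consequence_mix[c] for c in classes])
    a, b = spec.missense_score_dist
    lo, hi = spec.allele_freq_range

    variants: list[VariantRecord] = []
    freqs: list[float] = []
    pos = 0
    for g in range(spec.n_genes):
        gene_id = f"GENE{g:04d}"
        for _ in range(counts[g]):
            pos += rng.integers(1, 100)
            ref, alt = rng.choice(4, size=2, replace=False)
            consequence = Consequence(classes[rng.choice(len(classes), p=probs)])
            kwargs = {}
            if consequence is Consequence.MISSENSE:
                kwargs["score"] = float(rng.beta(a, b))
            elif consequence is Consequence.INFRAME_INDEL:
                kwargs.update(
                    n_sub=int(rng.poisson(1.0)),
                    n_ins=int(rng.poisson(0.5)),
                    n_del=int(rng.poisson(0.5)),
                )
            v = VariantRecord(
                variant_key=f"1:{pos}:{_BASES[ref]}:{_BASES[alt]}",
                gene_id=gene_id,
                consequence=consequence,
                **kwargs,
            )
            v.score = score_variant(v)
            variants.append(v)
            freqs.append(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
    return variants, np.asarray(freqs)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full synthetic cohort, deterministic given ``spec.seed``.

    Genotypes are sampled per variant as Binomial(2, f) alternate-allele
    counts (Hardy-Weinberg proportions at the variant's drawn frequency
    f), independently across variants and samples.
    """
    rng = np.random.default_rng(spec.seed)
    variants, freqs = _draw_variants(spec, rng)
    if not variants:
        raise ValueError("infeasible cohort spec: no variants generated")
    n, m = spec.n_samples, len(variants)
    hard = rng.binomial(2, freqs[None, :], size=(n, m)).astype(np.int8)
    sample_ids = [f"S{i:06d}" for i in range(n)]
    store = _io.GenotypeStore(
        sample_ids, [v.variant_key for v in variants], hard=hard
    )
    cov = pd.DataFrame(
        rng.normal(size=(n, spec.n_covariates)),
        columns=[f"cov{i + 1}" for i in range(spec.n_covariates)],
    )
    covariates = CovariateMatrix(sample_ids, cov)
    return Cohort(spec, variants, freqs, store, covariates)


def generate_cohort(spec: CohortSpec, out_dir) -> Cohort:
    """Simulate a cohort and write its inputs to ``out_dir``.

    Emits ``variants.tsv`` (variant-effects table), ``genotypes.vcf``
    (VCF v4.2 hard calls) and ``covariates.tsv``.  Byte-identical across
    runs with the same spec.
    """
    cohort = simulate_cohort(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_variant_table(cohort.variants, out / "variants.tsv")
    _io.write_vcf(out / "genotypes.vcf", cohort.genotypes)
    frame = cohort.covariates.data.drop(columns=["const"]).copy()
    frame.insert(0, "sample_id", cohort.sample_ids)
    frame.to_csv(out / "covariates.tsv", sep="\t", index=False, float_format="%.10g")
    return cohort


def load_cohort(path, dialect: str = "vcf_gt") -> Cohort:
    """Load a cohort written by :func:`generate_cohort` (or equivalent files).

    Expects ``variants.tsv``, ``genotypes.vcf`` and ``covariates.tsv``
    under ``path``; variants with unset scores get rule-based ones.
    """
    base = Path(path)
    variants = _io.read_variant_table(base / "variants.tsv")
    variants = [
        v if v.score is not None else _scored_copy(v) for v in variants
    ]
    store = _io.read_genotypes(base / "genotypes.vcf", dialect)
    order = {k: i for i, k in enumerate(store.variant_keys)}
    missing = [v.variant_key for v in variants if v.variant_key not in order]
    if missing:
        raise ValueError(f"variants absent from genotype file: {missing[:5]}")
    variants = sorted(variants, key=lambda v: order[v.variant_key])
    covariates = _io.read_covariates(base / "covariates.tsv")
    if covariates.sample_ids != store.sample_ids:
        raise ValueError("covariates and genotypes disagree on sample order")
    return Cohort(None, variants, None, store, covariates)


def _scored_copy(v: VariantRecord) -> VariantRecord:
    v.score = score_variant(v)
    return v


def plant_association(
    cohort: Cohort,
    gene_id: str,
    inheritance: str,
    beta: float,
    phenotype_kind: str = "continuous",
    seed: int = 0,
    params: AggregationParams = AggregationParams(),
    prevalence: float = 0.1,
    out_dir=None,
) -> tuple[PhenotypeVector, dict]:
    """Simulate a phenotype causally driven by one gene of the cohort.

    The gene's standardized effect column (per ``inheritance``) feeds
    ``y = beta * x + N(0, 1)``.  Returns the phenotype and a
    ground-truth record ``{gene_id, inheritance, beta, phenotype_kind,
    seed}``; if ``out_dir`` is given, writes ``phenotype.tsv`` and
    ``truth.json`` there.

    Raises if the gene's effect column is constant (e.g. a recessive
    column when the gene has only heterozygous carriers).
    """
    if gene_id not in cohort.gene_ids:
        raise ValueError(f"unknown gene: {gene_id}")
    dom, rec = build_gene_score_matrices(
        [cohort.variants[i] for i in cohort.variant_indices(gene_id)],
        cohort.genotypes.probs(cohort.variant_indices(gene_id)),
        cohort.sample_ids,
        params,
        gene_ids=[gene_id],
    )
    x = simulate_gene_effect(dom.values[:, 0], rec.values[:, 0], inheritance)
    pheno = simulate_phenotype(
        x,
        beta,
        phenotype_kind,
        seed=seed,
        prevalence=prevalence,
        sample_ids=cohort.sample_ids,
    )
    truth = {
        "gene_id": gene_id,
        "inheritance": inheritance,
        "beta": beta,
        "phenotype_kind": phenotype_kind,
        "seed": seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_phenotype(pheno, out / "phenotype.tsv")
        (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return pheno, truth
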