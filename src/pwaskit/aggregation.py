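"""Aggregation of variant effect scores into per-sample gene scores.

This is the mathematical core of the method.  For a gene carrying
variants with effect scores ``s_1..s_k`` and per-sample genotype
probabilities ``(p0, p1, p2)`` per variant, two quantities are computed
per variant:

* ``x_i`` — the probability that the gene retains its function
  considering variant i alone::

      x_i = p0 + p1 * s_i + p2 * (mu * s_i + (1 - mu) * s_i**2)

  where ``mu`` in [0, 1] interpolates between treating the two allele
  copies of a homozygous genotype as fully dependent (mu = 1, effect
  s_i) and fully independent (mu = 0, effect s_i**2);

* ``y_i`` — the probability that variant i damages exactly one of the
  two gene copies::

      y_i = p1 * (1 - s_i) + p2 * (1 - mu) * 2 * s_i * (1 - s_i)

  (a fully dependent homozygous variant cannot hit exactly one copy,
  hence the ``1 - mu`` factor on the homozygous term).

The dominant gene score is a p-norm softening of the independence
product ``x_1 * ... * x_k``::

    D = exp(-|| (log 1/x_1, ..., log 1/x_k) ||_p)

with ``p = 1`` giving the product (full independence between variants)
and ``p = inf`` giving ``min(x_i)`` (full dependence).  The recessive
score expresses the probability of at most one damaging hit,
``(1 + zeta_q) * D_p`` with ``zeta_q = ||(y_i / x_i)||_q``, extended by
continuity to a four-case piecewise rule when some ``x_i = 0``.

Unphased genotypes are assumed: distinct variants are taken to hit
distinct gene copies, which is what makes compound heterozygosity
(two heterozygous loss-of-function variants in one gene) register as a
recessive-damage event.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Protocol, Sequence, Union, runtime_checkable

import numpy as np
import pandas as pd

from .variants import VariantRecord

__all__ = [
    "AggregationParams",
    "GenotypeProbabilities",
    "GeneScoreMatrix",
    "retention_prob",
    "single_hit_prob",
    "dominant_score",
    "recessive_score",
    "build_gene_score_matrices",
]

logger = logging.getLogger(__name__)

_PROB_TOL = 1e-6


def _check_norm_order(name: str, value: float) -> float:
    value = float(value)
    if not (value >= 1.0):  # also rejects NaN
        raise ValueError(f"{name} must be in [1, inf], got {value}")
    return value


@dataclass(frozen=True)
class AggregationParams:
    """The five parameters of the dominant/recessive aggregation scheme.

    Defaults are the published values fitted on known gene-disease
    associations: ``mu_D=1, p_D=1.25, mu_R=0.5, p_R=inf, q_R=3``.
    ``inf`` is admissible for the norm orders ``p_D``, ``p_R``, ``q_R``.
    """

    mu_D: float = 1.0
    p_D: float = 1.25
    mu_R: float = 0.5
    p_R: float = math.inf
    q_R: float = 3.0

    def __post_init__(self) -> None:
        for name in ("mu_D", "mu_R"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("p_D", "p_R", "q_R"):
            _check_norm_order(name, getattr(self, name))


@dataclass(frozen=True)
class GenotypeProbabilities:
    """Probabilities that the alternate allele occurs 0, 1 or 2 times.

    Renormalized on construction; a triplet whose sum deviates from 1 by
    more than 1e-6 before renormalization is rejected.
    """

    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        for name, v in (("p0", self.p0), ("p1", self.p1), ("p2", self.p2)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.p0 + self.p1 + self.p2
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(
                f"genotype probabilities sum to {total}, expected 1 +/- {_PROB_TOL}"
            )
        if total != 1.0:
            object.__setattr__(self, "p0", self.p0 / total)
            object.__setattr__(self, "p1", self.p1 / total)
            object.__setattr__(self, "p2", self.p2 / total)

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2])


@dataclass
class GeneScoreMatrix:
    """n samples x m genes matrix of functional effect scores in [0, 1]."""

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    model: str  # "dominant" or "recessive"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"score matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if self.model not in ("dominant", "recessive"):
            raise ValueError(f"model must be dominant or recessive, got {self.model}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_ids.index(gene_id)]


GenotypeLike = Union[GenotypeProbabilities, Sequence[float]]


def _geno_array(g: GenotypeLike) -> np.ndarray:
    if isinstance(g, GenotypeProbabilities):
        return g.as_array()
    return GenotypeProbabilities(*g).as_array()


def retention_prob(s: float, g: GenotypeLike, mu: float) -> float:
    """Probability x_i that the gene retains function considering one variant."""
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"effect score must be in [0, 1], got {s}")
    if not (0.0 <= mu <= 1.0):
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    p0, p1, p2 = _geno_array(g)
    return float(p0 + p1 * s + p2 * (mu * s + (1.0 - mu) * s * s))


def single_hit_prob(s: float, g: GenotypeLike, mu: float) -> float:
    """Probability y_i that one variant damages exactly one gene copy."""
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"effect score must be in [0, 1], got {s}")
    if not (0.0 <= mu <= 1.0):
        raise ValueError(f"mu must be in [0, 1], got {mu}")
    _, p1, p2 = _geno_array(g)
    return float(p1 * (1.0 - s) + p2 * (1.0 - mu) * 2.0 * s * (1.0 - s))


def _pnorm_rows(v: np.ndarray, p: float) -> np.ndarray:
    """Row-wise p-norm of a non-negative 2-d array, overflow/underflow safe.

    Factors out the row maximum so that v_i**p never under- or
    overflows for large p.
    """
    if math.isinf(p):
        return v.max(axis=1)
    if p == 1.0:
        return v.sum(axis=1)
    m = v.max(axis=1)
    safe_m = np.where(m > 0, m, 1.0)
    scaled = v / safe_m[:, None]
    return m * (scaled**p).sum(axis=1) ** (1.0 / p)


def _dominant_rows(x: np.ndarray, p: float) -> np.ndarray:
    """Vectorized D over the rows of a 2-d array ``x`` (samples x variants)."""
    if math.isinf(p):
        return x.min(axis=1)
    # x_i = 0 short-circuits to D = 0 before any log is taken
    zero = (x == 0).any(axis=1)
    safe = np.where(x > 0, x, 1.0)
    out = np.exp(-_pnorm_rows(-np.log(safe), p))
    out[zero] = 0.0
    return out


def dominant_score(x: Sequence[float], p: float) -> float:
    """Dominant gene score D = exp(-||(log 1/x_i)||_p) over one gene's variants.

    ``p = 1`` yields the product of the x_i (independent variants);
    ``p = inf`` yields min(x_i) (fully dependent); any x_i = 0 forces
    D = 0.  Callers must emit 1 for variant-free genes before reaching
    here — an empty vector is rejected.
    """
    x_arr = np.asarray(x, dtype=float)
    if x_arr.ndim != 1 or x_arr.size == 0:
        raise ValueError("x must be a non-empty 1-d vector")
    if (x_arr < 0).any() or (x_arr > 1).any():
        raise ValueError("retention probabilities must lie in [0, 1]")
    p = _check_norm_order("p", p)
    return float(_dominant_rows(x_arr[None, :], p)[0])


def _recessive_rows(
    x: np.ndarray, y: np.ndarray, p: float, q: float
) -> tuple[np.ndarray, int]:
    """Vectorized piecewise R over rows; returns (scores, n_clipped)."""
    n, k = x.shape
    out = np.empty(n)
    zeros = x == 0
    n_zero = zeros.sum(axis=1)

    # (a) two or more x_i = 0: a second hit is certain
    out[n_zero >= 2] = 0.0

    # (b)/(c) exactly one x_i = 0
    one = n_zero == 1
    if one.any():
        idx = np.argmax(zeros[one], axis=1)
        rows = np.flatnonzero(one)
        y_i = y[rows, idx]
        if p == 1.0:
            rest = np.where(zeros[one], 1.0, x[one]).prod(axis=1)
            out[rows] = y_i * rest
        else:
            out[rows] = y_i

    # (d) all x_i != 0: (1 + zeta_q) * D_p
    full = n_zero == 0
    if full.any():
        xf = x[full]
        zeta = _pnorm_rows(y[full] / xf, q)
        out[full] = (1.0 + zeta) * _dominant_rows(xf, p)

    n_clipped = int((out > 1.0).sum())
    np.clip(out, 0.0, 1.0, out=out)
    return out, n_clipped


def recessive_score(
    x: Sequence[float], y: Sequence[float], p: float, q: float
) -> float:
    """Recessive gene score R: probability of at most one damaging hit.

    Piecewise by the number of zero x_i: two or more zeros give 0;
    exactly one zero gives y_i (p > 1) or y_i times the product of the
    remaining x_j (p = 1); no zeros give ``(1 + zeta_q) * D_p``.  The
    result is clipped to [0, 1] (with finite q the correction factor can
    push the product form slightly above 1); clipping is logged.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.ndim != 1 or x_arr.size == 0:
        raise ValueError("x must be a non-empty 1-d vector")
    if x_arr.shape != y_arr.shape:
        raise ValueError(
            f"x and y must have the same length, got {x_arr.size} and {y_arr.size}"
        )
    if (y_arr > 1).any() or (y_arr < 0).any():
        raise ValueError("single-hit probabilities must lie in [0, 1]")
    p = _check_norm_order("p", p)
    q = _check_norm_order("q", q)
    scores, n_clipped = _recessive_rows(x_arr[None, :], y_arr[None, :], p, q)
    if n_clipped:
        logger.debug("recessive score exceeded 1 and was clipped")
    return float(scores[0])


@runtime_checkable
class SupportsProbs(Protocol):
    """Anything that can serve genotype probability triplets per variant.

    ``probs(indices)`` must return an (n_samples, len(indices), 3) array
    of (p0, p1, p2); ``n_samples`` and ``n_variants`` describe the store.
    """

    n_samples: int
    n_variants: int

    def probs(self, indices: Sequence[int]) -> np.ndarray: ...


def _group_variants(
    variants: Sequence[VariantRecord], gene_ids: Sequence[str]
) -> dict[str, list[int]]:
    known = set(gene_ids)
    groups: dict[str, list[int]] = {g: [] for g in gene_ids}
    for j, v in enumerate(variants):
        if v.gene_id not in known:
            raise ValueError(
                f"variant {v.variant_key} references unknown gene {v.gene_id}"
            )
        groups[v.gene_id].append(j)
    return groups


def build_gene_score_matrices(
    variants: Sequence[VariantRecord],
    genotype_probs: Union[np.ndarray, "SupportsProbs"],
    sample_ids: Sequence[str],
    params: AggregationParams = AggregationParams(),
    gene_ids: Sequence[str] | None = None,
) -> tuple[GeneScoreMatrix, GeneScoreMatrix]:
    """Compute the dominant and recessive score matrices for a cohort.

    Parameters
    ----------
    variants : sequence of VariantRecord
        All scored variants; their order defines the variant axis of
        ``genotype_probs``.
    genotype_probs : ndarray of shape (n_samples, n_variants, 3), or store
        Per sample x variant probability triplets (p0, p1, p2), either a
        dense array or any object satisfying :class:`SupportsProbs`
        (e.g. an on-demand store over hard genotype calls).  A missing
        call is encoded as (1, 0, 0) — the variant is assumed absent,
        which can only hide damage, never invent it.
    sample_ids : sequence of str
    params : AggregationParams
        ``x`` is computed with ``mu_D`` for the dominant matrix and
        recomputed with ``mu_R`` for the recessive matrix; ``y`` always
        uses ``mu_R``.
    gene_ids : sequence of str, optional
        Gene universe (and column order).  Defaults to the genes seen in
        ``variants``, sorted.  Genes with zero variants score exactly 1
        in both matrices.

    Returns
    -------
    (GeneScoreMatrix, GeneScoreMatrix)
        The dominant and recessive matrices, row-aligned on samples.
    """
    n = len(sample_ids)
    if isinstance(genotype_probs, SupportsProbs) and not isinstance(
        genotype_probs, np.ndarray
    ):
        store = genotype_probs
        if (store.n_samples, store.n_variants) != (n, len(variants)):
            raise ValueError(
                f"genotype store is {store.n_samples} x {store.n_variants}, "
                f"expected {n} samples x {len(variants)} variants"
            )
        fetch = store.probs
    else:
        probs = np.asarray(genotype_probs, dtype=float)
        if probs.shape != (n, len(variants), 3):
            raise ValueError(
                f"genotype_probs shape {probs.shape} does not match "
                f"({n} samples, {len(variants)} variants, 3)"
            )

        def fetch(indices):
            return probs[:, indices, :]
    if gene_ids is None:
        gene_ids = sorted({v.gene_id for v in variants})
    groups = _group_variants(variants, gene_ids)

    scores = np.asarray(
        [v.score if v.score is not None else np.nan for v in variants], dtype=float
    )
    if np.isnan(scores).any():
        missing = [v.variant_key for v in variants if v.score is None]
        raise ValueError(f"variants without scores: {missing[:5]}")

    dom = np.ones((n, len(gene_ids)))
    rec = np.ones((n, len(gene_ids)))
    n_clipped = 0
    for col, gid in enumerate(gene_ids):
        idx = groups[gid]
        if not idx:
            continue
        s = scores[idx]  # (k,)
        gene_probs = fetch(idx)
        p0 = gene_probs[..., 0]
        p1 = gene_probs[..., 1]
        p2 = gene_probs[..., 2]
        hom_D = params.mu_D * s + (1.0 - params.mu_D) * s * s
        hom_R = params.mu_R * s + (1.0 - params.mu_R) * s * s
        x_D = p0 + p1 * s + p2 * hom_D
        x_R = p0 + p1 * s + p2 * hom_R
        y_R = p1 * (1.0 - s) + p2 * (1.0 - params.mu_R) * 2.0 * s * (1.0 - s)
        dom[:, col] = _dominant_rows(x_D, params.p_D)
        rec_col, clipped = _recessive_rows(x_R, y_R, params.p_R, params.q_R)
        rec[:, col] = rec_col
        n_clipped += clipped
    if n_clipped:
        logger.info(
            "recessive scores clipped to 1 in %d sample x gene cells", n_clipped
        )

    sample_ids = list(sample_ids)
    gene_ids = list(gene_ids)
    return (
        GeneScoreMatrix(sample_ids, gene_ids, dom, "dominant"),
        GeneScoreMatrix(sample_ids, gene_ids, rec, "recessive"),
    )
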