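"""Per-variant functional effect scores.

Every protein-affecting variant receives an effect score ``s`` in [0, 1],
interpreted as the probability that the gene product retains its function
given the variant (0 = complete loss of function, 1 = no effect).  Scores
come from three sources:

* loss-of-function classes (nonsense, frameshift, canonical splice site)
  are fixed at 0 by rule;
* missense variants carry a score from an external predictor, supplied
  either pre-computed in the variant table or through a pluggable scorer
  callable;
* in-frame indels get a rule-based score from the numbers of substituted,
  inserted and deleted amino acids.

The module also provides the two score manipulations used in robustness
analyses: a global permutation of scores across variants (a negative
control that destroys the score-variant correspondence while preserving
the score distribution) and additive Gaussian perturbation (emulating
predictor noise).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Consequence",
    "VariantRecord",
    "IndelWeights",
    "score_variant",
    "score_variants",
    "shuffle_scores",
    "perturb_scores",
]


class Consequence(str, enum.Enum):
    """Protein-affecting consequence classes supported by the model."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    INFRAME_INDEL = "inframe_indel"


#: Classes assumed to abolish protein function entirely (score 0).
LOSS_OF_FUNCTION = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE}
)


@dataclass(frozen=True)
class IndelWeights:
    """Per-residue damage weights for the in-frame indel rule.

    The score of an in-frame indel is
    ``max(0, 1 - (n_sub*w_sub + n_ins*w_ins + n_del*w_del))``:
    monotone decreasing in each residue count, exactly 1 when no residue
    is affected, saturating at 0.
    """

    w_sub: float = 0.05
    w_ins: float = 0.05
    w_del: float = 0.05


@dataclass
class VariantRecord:
    """One protein-affecting variant.

    Parameters
    ----------
    variant_key : str
        ``chrom:pos:ref:alt`` with a 1-based position, as in VCF.
    gene_id : str
        Identifier of the affected protein-coding gene.
    consequence : Consequence
        One of the five supported protein-level consequence classes.
    score : float or None
        Effect score in [0, 1]; may be unset before scoring.
    n_sub, n_ins, n_del : int or None
        Numbers of substituted / inserted / deleted amino acids.
        Present iff the consequence is an in-frame indel.
    """

    variant_key: str
    gene_id: str
    consequence: Consequence
    score: Optional[float] = None
    n_sub: Optional[int] = None
    n_ins: Optional[int] = None
    n_del: Optional[int] = None

    def __post_init__(self) -> None:
        self.consequence = Consequence(self.consequence)
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(
                f"variant {self.variant_key}: score {self.score} outside [0, 1]"
            )
        is_indel = self.consequence is Consequence.INFRAME_INDEL
        counts = (self.n_sub, self.n_ins, self.n_del)
        if is_indel:
            if any(c is None for c in counts):
                raise ValueError(
                    f"variant {self.variant_key}: in-frame indel requires "
                    "n_sub, n_ins and n_del"
                )
            if any(c < 0 for c in counts):  # type: ignore[operator]
                raise ValueError(
                    f"variant {self.variant_key}: negative amino-acid count"
                )
        elif any(c is not None for c in counts):
            raise ValueError(
                f"variant {self.variant_key}: amino-acid counts are only "
                "meaningful for in-frame indels"
            )


MissenseScorer = Callable[[VariantRecord], float]


def _indel_score(v: VariantRecord, weights: IndelWeights) -> float:
    damage = (
        v.n_sub * weights.w_sub + v.n_ins * weights.w_ins + v.n_del * weights.w_del
    )
    return max(0.0, 1.0 - damage)


def score_variant(
    v: VariantRecord,
    missense_scorer: Optional[MissenseScorer] = None,
    indel_weights: IndelWeights = IndelWeights(),
) -> float:
    """Assign the effect score of a single variant by consequence class.

    Loss-of-function classes map to exactly 0.  Missense variants use the
    pluggable ``missense_scorer`` if given, otherwise the pre-set
    ``v.score``; the result is clipped to [0, 1].  In-frame indels use the
    residue-count rule parameterized by ``indel_weights``.

    Raises
    ------
    ValueError
        For an unknown consequence class, or a missense variant with
        neither a scorer nor a pre-set score.
    """
    try:
        consequence = Consequence(v.consequence)
    except ValueError:
        raise ValueError(f"unknown consequence class: {v.consequence!r}") from None

    if consequence in LOSS_OF_FUNCTION:
        return 0.0
    if consequence is Consequence.INFRAME_INDEL:
        return _indel_score(v, indel_weights)
    # missense
    if missense_scorer is not None:
        raw = float(missense_scorer(v))
    elif v.score is not None:
        raw = float(v.score)
    else:
        raise ValueError(
            f"missense variant {v.variant_key} has no pre-set score and no "
            "missense scorer was provided"
        )
    return float(min(1.0, max(0.0, raw)))


def score_variants(
    variants: Sequence[VariantRecord],
    missense_scorer: Optional[MissenseScorer] = None,
    indel_weights: IndelWeights = IndelWeights(),
) -> list[VariantRecord]:
    """Return copies of ``variants`` with their scores filled in."""
    return [
        replace(v, score=score_variant(v, missense_scorer, indel_weights))
        for v in variants
    ]


def _require_scores(variants: Sequence[VariantRecord]) -> np.ndarray:
    scores = []
    for v in variants:
        if v.score is None:
            raise ValueError(f"variant {v.variant_key} has no score set")
        scores.append(v.score)
    return np.asarray(scores, dtype=float)


def shuffle_scores(
    variants: Sequence[VariantRecord], seed: int
) -> list[VariantRecord]:
    """Permute effect scores uniformly at random across all variants.

    The permutation is global (not within gene): it severs the
    correspondence between each variant and its predicted damage while
    conserving the score multiset and the variant-to-gene mapping, which
    is exactly the negative control needed to show that association
    signal depends on score-variant assignment.

    Deterministic given ``seed``.
    """
    scores = _require_scores(variants)
    rng = np.random.default_rng(seed)
    permuted = scores[rng.permutation(len(scores))]
    return [replace(v, score=float(s)) for v, s in zip(variants, permuted)]


def perturb_scores(
    variants: Sequence[VariantRecord], epsilon: float, seed: int
) -> list[VariantRecord]:
    """Add Gaussian noise N(0, epsilon^2) to every score, clipping to [0, 1].

    ``epsilon = 0`` is the identity.  Clipping keeps the perturbed scores
    interpretable as retention probabilities, which the aggregation
    formulas require.  Deterministic given ``seed``.
    """
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    scores = _require_scores(variants)
    if epsilon == 0:
        return list(variants)
    rng = np.random.default_rng(seed)
    noisy = np.clip(scores + rng.normal(0.0, epsilon, size=len(scores)), 0.0, 1.0)
    return [replace(v, score=float(s)) for v, s in zip(variants, noisy)]
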