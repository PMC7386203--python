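"""Covariate-adjusted gene-phenotype association testing.

For every gene the phenotype is regressed on covariates plus the gene's
functional effect score(s): ordinary least squares for continuous
phenotypes, logistic regression for binary ones.  Three nested
hypotheses are tested per gene:

* dominant — H0: beta_D = 0, with the dominant score D in the model;
* recessive — H0: beta_R = 0, with the recessive score R;
* generalized — H0: beta_D = beta_R = 0, with both scores, tested by an
  F-test (linear) or likelihood-ratio chi2 with 2 df (logistic).

Multiple testing is controlled per model column by Benjamini-Hochberg
q-values.  Effect sizes are Cohen's d between cases and controls for
binary phenotypes and the covariate-partial Pearson correlation for
continuous ones.

The model/results split follows the statsmodels convention: build a
:class:`PWAS` model from the score matrices, phenotype and covariates,
call :meth:`PWAS.fit`, and read estimates off the returned
:class:`PWASResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .aggregation import GeneScoreMatrix

__all__ = [
    "PhenotypeVector",
    "CovariateMatrix",
    "AssociationResult",
    "GeneTestResult",
    "PWAS",
    "PWASResults",
    "test_gene",
    "run_pwas",
    "split_categorical",
    "fdr_adjust",
    "cohens_d",
]

_MODELS = ("dominant", "recessive", "generalized")


@dataclass
class PhenotypeVector:
    """A phenotype aligned to sample ids.

    ``kind`` is one of ``continuous``, ``binary`` or ``categorical``.
    Binary values must be coded {0, 1}.  Samples with missing values are
    dropped on construction (association runs on the remaining samples).
    """

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "continuous"
    name: str = "phenotype"
    categories: Optional[list] = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown phenotype kind: {self.kind}")
        values = np.asarray(self.values)
        if self.kind != "categorical":
            values = values.astype(float)
            keep = ~np.isnan(values)
            if not keep.all():
                self.sample_ids = [s for s, k in zip(self.sample_ids, keep) if k]
                values = values[keep]
        if len(self.sample_ids) != len(values):
            raise ValueError("sample_ids and values must have equal length")
        if self.kind == "binary":
            uniq = np.unique(values)
            if not np.isin(uniq, [0.0, 1.0]).all():
                raise ValueError(f"binary phenotype must be coded 0/1, found {uniq}")
        if self.kind == "categorical" and self.categories is None:
            self.categories = sorted(pd.unique(values).tolist())
        self.values = values


@dataclass
class CovariateMatrix:
    """Named covariate columns, including a constant intercept column.

    Collinear columns are dropped (QR-based rank reduction) with a
    warning so that every downstream design matrix has full column rank.
    """

    sample_ids: list[str]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.data):
            raise ValueError("sample_ids and covariate rows must align")
        self.data = self.data.astype(float).reset_index(drop=True)
        if "const" not in self.data.columns:
            self.data.insert(0, "const", 1.0)
        kept = _full_rank_columns(self.data.to_numpy())
        if len(kept) < self.data.shape[1]:
            dropped = [c for i, c in enumerate(self.data.columns) if i not in kept]
            warnings.warn(
                f"dropping collinear covariate columns: {dropped}", stacklevel=2
            )
            self.data = self.data.iloc[:, list(kept)]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample_col: str = "sample_id"):
        frame = frame.copy()
        ids = frame.pop(sample_col).astype(str).tolist()
        return cls(ids, frame)

    def subset(self, index: np.ndarray) -> "CovariateMatrix":
        return CovariateMatrix(
            [self.sample_ids[i] for i in index], self.data.iloc[index]
        )


def _full_rank_columns(a: np.ndarray, tol: float = 1e-10) -> list[int]:
    """Indices of a maximal left-to-right independent column subset."""
    kept: list[int] = []
    basis = np.empty((a.shape[0], 0))
    for j in range(a.shape[1]):
        candidate = np.column_stack([basis, a[:, j]])
        if np.linalg.matrix_rank(candidate, tol=tol) > basis.shape[1]:
            kept.append(j)
            basis = candidate
    return kept


@dataclass
class GeneTestResult:
    """Outcome of one regression test on one gene."""

    p_value: float
    coefficients: dict[str, float]
    flag: Optional[str] = None  # "degenerate", "separation", "nonconvergence", ...


@dataclass
class AssociationResult:
    """Per-gene association summary across the three inheritance tests."""

    gene_id: str
    p_dominant: float
    p_recessive: float
    p_generalized: float
    beta_D: float
    beta_R: float
    effect_size: float
    n_samples: int
    n_variants: int
    q_dominant: float = np.nan
    q_recessive: float = np.nan
    q_generalized: float = np.nan
    flags: str = ""


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement.

    Each q is at least its p, and the q-values are invariant to the
    input ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Standardized mean difference of scores between cases and controls.

    ``(mean_cases - mean_controls) / pooled_sd``; negative d means cases
    carry lower (more damaged) gene scores.  Returns NaN when a class is
    empty or the pooled standard deviation is zero.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    if cases.size == 0 or controls.size == 0:
        return float("nan")
    n1, n2 = cases.size, controls.size
    if n1 + n2 < 3:
        return float("nan")
    v1 = cases.var(ddof=1) if n1 > 1 else 0.0
    v2 = controls.var(ddof=1) if n2 > 1 else 0.0
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    if pooled == 0:
        return float("nan")
    return float((cases.mean() - controls.mean()) / pooled)


def partial_pearson_r(
    scores: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> float:
    """Pearson correlation of score and phenotype after removing covariates."""
    resid_y = y - covariates @ np.linalg.lstsq(covariates, y, rcond=None)[0]
    resid_s = scores - covariates @ np.linalg.lstsq(covariates, scores, rcond=None)[0]
    if resid_s.std() == 0 or resid_y.std() == 0:
        return float("nan")
    return float(scipy.stats.pearsonr(resid_s, resid_y)[0])


def split_categorical(y: PhenotypeVector) -> list[PhenotypeVector]:
    """Split a categorical phenotype into one-vs-rest binary phenotypes."""
    if y.kind != "categorical":
        raise ValueError("split_categorical requires a categorical phenotype")
    categories = y.categories or sorted(pd.unique(y.values).tolist())
    if len(categories) < 2:
        raise ValueError("categorical phenotype needs at least 2 categories")
    out = []
    values = np.asarray(y.values)
    for cat in categories:
        mask = values == cat
        if not mask.any():
            raise ValueError(f"category {cat!r} has zero members")
        out.append(
            PhenotypeVector(
                sample_ids=list(y.sample_ids),
                values=mask.astype(float),
                kind="binary",
                name=f"{y.name}:{cat}",
            )
        )
    return out


def _score_design(
    D: Optional[np.ndarray],
    R: Optional[np.ndarray],
    C: np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    cols = [C]
    names: list[str] = []
    if D is not None:
        cols.append(D[:, None])
        names.append("D")
    if R is not None:
        cols.append(R[:, None])
        names.append("R")
    return np.column_stack(cols), names


def test_gene(
    D: Optional[np.ndarray],
    R: Optional[np.ndarray],
    y: PhenotypeVector,
    C: CovariateMatrix,
    model: str,
) -> GeneTestResult:
    """Run one inheritance-model regression test for a single gene.

    ``model`` selects which score columns enter the regression: dominant
    uses D only, recessive uses R only, generalized uses both and tests
    the joint null beta_D = beta_R = 0.  Degenerate score columns
    (constant across samples) and unstable logistic fits (perfect
    separation, non-convergence) are flagged and reported with p = 1 —
    a conservative fallback that protects the false-discovery guarantee.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model: {model}")
    if model == "dominant":
        use_D, use_R = D, None
    elif model == "recessive":
        use_D, use_R = None, R
    else:
        use_D, use_R = D, R

    cov = C.data.to_numpy()
    n = cov.shape[0]
    for vec, label in ((use_D, "D"), (use_R, "R")):
        if vec is not None and len(vec) != n:
            raise ValueError(f"score column {label} has length {len(vec)}, expected {n}")
    if len(y.values) != n:
        raise ValueError("phenotype and covariates are not row-aligned")

    # degenerate: no variability in any requested score column
    active = [(v, label) for v, label in ((use_D, "D"), (use_R, "R")) if v is not None]
    if any(np.ptp(v) == 0 for v, _ in active):
        return GeneTestResult(
            1.0, {label: 0.0 for _, label in active}, flag="degenerate"
        )

    # collinearity of the two score columns (generalized only): degrade to 1 df
    degraded = False
    if model == "generalized" and use_D is not None and use_R is not None:
        aug = np.column_stack([cov, use_D, use_R])
        if np.linalg.matrix_rank(aug) < aug.shape[1]:
            use_R = None
            degraded = True

    X, score_names = _score_design(use_D, use_R, cov)
    k_score = len(score_names)

    try:
        if y.kind == "continuous":
            res = sm.OLS(y.values, X).fit()
            if k_score == 1:
                p = float(res.pvalues[-1])
            else:
                contrast = np.zeros((k_score, X.shape[1]))
                contrast[:, -k_score:] = np.eye(k_score)
                p = float(res.f_test(contrast).pvalue)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y.values, X).fit(disp=0, maxiter=100)
            if not res.mle_retvals.get("converged", True):
                return GeneTestResult(
                    1.0, {name: 0.0 for name in score_names}, flag="nonconvergence"
                )
            if k_score == 1:
                p = float(res.pvalues[-1])
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    reduced = sm.Logit(y.values, cov).fit(disp=0, maxiter=100)
                lr = 2.0 * (res.llf - reduced.llf)
                p = float(scipy.stats.chi2.sf(max(lr, 0.0), df=k_score))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return GeneTestResult(
            1.0, {name: 0.0 for name in score_names}, flag="separation"
        )
    if not np.isfinite(p):
        return GeneTestResult(1.0, {name: 0.0 for name in score_names}, flag="unstable")

    coefs = {
        name: float(res.params[X.shape[1] - k_score + i])
        for i, name in enumerate(score_names)
    }
    flag = "collinear_scores" if degraded else None
    return GeneTestResult(p, coefs, flag=flag)


class PWAS:
    """Gene-level association model of a phenotype on effect scores.

    Parameters
    ----------
    dominant, recessive : GeneScoreMatrix
        Per-sample gene score matrices sharing sample and gene orderings.
    phenotype : PhenotypeVector
        Continuous or binary (split categorical phenotypes first with
        :func:`split_categorical`).
    covariates : CovariateMatrix
        Always includes a constant intercept column.
    n_variants : dict, optional
        Per-gene variant counts for reporting.

    Samples are intersected across the three inputs by sample id; a
    phenotype or covariate sample absent from the score matrices raises.
    """

    def __init__(
        self,
        dominant: GeneScoreMatrix,
        recessive: GeneScoreMatrix,
        phenotype: PhenotypeVector,
        covariates: CovariateMatrix,
        n_variants: Optional[dict[str, int]] = None,
    ):
        if dominant.gene_ids != recessive.gene_ids:
            raise ValueError("dominant and recessive matrices differ in gene order")
        if dominant.sample_ids != recessive.sample_ids:
            raise ValueError("dominant and recessive matrices differ in sample order")
        if phenotype.kind == "categorical":
            raise ValueError(
                "categorical phenotypes must be split (split_categorical) first"
            )
        score_pos = {s: i for i, s in enumerate(dominant.sample_ids)}
        cov_pos = {s: i for i, s in enumerate(covariates.sample_ids)}
        missing = [
            s for s in phenotype.sample_ids if s not in score_pos or s not in cov_pos
        ]
        if missing:
            raise ValueError(
                f"samples missing from scores or covariates: {missing[:5]}"
            )
        self.sample_ids = list(phenotype.sample_ids)
        rows = np.asarray([score_pos[s] for s in self.sample_ids])
        cov_rows = np.asarray([cov_pos[s] for s in self.sample_ids])
        self.gene_ids = list(dominant.gene_ids)
        self.D = dominant.values[rows]
        self.R = recessive.values[rows]
        self.phenotype = phenotype
        self.covariates = covariates.subset(cov_rows)
        self.n_variants = n_variants or {}

    @classmethod
    def from_files(
        cls,
        dominant_path,
        recessive_path,
        phenotype_path,
        covariates_path,
        phenotype_kind: str = "continuous",
    ) -> "PWAS":
        from . import io as _io

        dom = _io.read_score_matrix(dominant_path, "dominant")
        rec = _io.read_score_matrix(recessive_path, "recessive")
        pheno = _io.read_phenotype(phenotype_path, phenotype_kind)
        cov = _io.read_covariates(covariates_path)
        return cls(dom, rec, pheno, cov)

    def fit(self, fdr: float = 0.05) -> "PWASResults":
        """Test every gene under all three inheritance models.

        Returns a :class:`PWASResults` carrying per-gene p-values,
        Benjamini-Hochberg q-values per model column, score coefficients
        and effect sizes.
        """
        rows = []
        y = self.phenotype
        binary = y.kind == "binary"
        cov_arr = self.covariates.data.to_numpy()
        for j, gid in enumerate(self.gene_ids):
            D_col = self.D[:, j]
            R_col = self.R[:, j]
            res_d = test_gene(D_col, None, y, self.covariates, "dominant")
            res_r = test_gene(None, R_col, y, self.covariates, "recessive")
            res_g = test_gene(D_col, R_col, y, self.covariates, "generalized")
            # effect size on the score column of the better-supported
            # single-inheritance model
            eff_col = D_col if res_d.p_value <= res_r.p_value else R_col
            if binary:
                eff = cohens_d(eff_col, y.values.astype(int))
            else:
                eff = partial_pearson_r(eff_col, y.values, cov_arr)
            flags = ";".join(
                f"{m}:{r.flag}"
                for m, r in (
                    ("dominant", res_d),
                    ("recessive", res_r),
                    ("generalized", res_g),
                )
                if r.flag
            )
            rows.append(
                AssociationResult(
                    gene_id=gid,
                    p_dominant=res_d.p_value,
                    p_recessive=res_r.p_value,
                    p_generalized=res_g.p_value,
                    beta_D=res_g.coefficients.get("D", np.nan),
                    beta_R=res_g.coefficients.get("R", np.nan),
                    effect_size=eff,
                    n_samples=len(self.sample_ids),
                    n_variants=self.n_variants.get(gid, -1),
                    flags=flags,
                )
            )
        if rows:
            for attr in _MODELS:
                q = fdr_adjust([getattr(r, f"p_{attr}") for r in rows])
                for r, qv in zip(rows, q):
                    setattr(r, f"q_{attr}", float(qv))
        return PWASResults(self, rows, fdr=fdr)


class PWASResults:
    """Fitted per-gene association results.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per gene, sorted by the generalized-model p-value.
    """

    _columns = [
        "gene_id",
        "p_dominant",
        "p_recessive",
        "p_generalized",
        "q_dominant",
        "q_recessive",
        "q_generalized",
        "beta_D",
        "beta_R",
        "effect_size",
        "n_samples",
        "n_variants",
        "flags",
    ]

    def __init__(self, model: PWAS, results: list[AssociationResult], fdr: float = 0.05):
        self.model = model
        self.results = results
        self.fdr = fdr
        frame = pd.DataFrame(
            [{c: getattr(r, c) for c in self._columns} for r in results],
            columns=self._columns,
        )
        if len(frame):
            frame = frame.sort_values(
                ["p_generalized", "gene_id"], kind="mergesort"
            ).reset_index(drop=True)
            for m in _MODELS:
                frame[f"significant_{m}"] = frame[f"q_{m}"] < fdr
        self.table = frame

    def significant(self, model: str = "generalized") -> pd.DataFrame:
        if model not in _MODELS:
            raise ValueError(f"unknown model: {model}")
        if not len(self.table):
            return self.table
        return self.table[self.table[f"q_{model}"] < self.fdr]

    def summary(self, top: int = 10) -> str:
        """Human-readable summary of the strongest associations."""
        lines = [
            "PWAS association results",
            "=" * 64,
            f"phenotype: {self.model.phenotype.name} ({self.model.phenotype.kind})",
            f"samples:   {len(self.model.sample_ids)}",
            f"genes:     {len(self.model.gene_ids)}",
            f"FDR:       q < {self.fdr:g} -> "
            + ", ".join(
                f"{m}: {int((self.table[f'q_{m}'] < self.fdr).sum()) if len(self.table) else 0}"
                for m in _MODELS
            ),
            "-" * 64,
        ]
        cols = ["gene_id", "p_dominant", "p_recessive", "p_generalized",
                "q_generalized", "effect_size"]
        if len(self.table):
            lines.append(self.table[cols].head(top).to_string(index=False))
        else:
            lines.append("(no genes tested)")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        from . import io as _io

        _io.write_results(self, path)


def run_pwas(
    dom: GeneScoreMatrix,
    rec: GeneScoreMatrix,
    y: PhenotypeVector,
    C: CovariateMatrix,
    fdr: float = 0.05,
    n_variants: Optional[dict[str, int]] = None,
) -> PWASResults:
    """Convenience wrapper: build a :class:`PWAS` model and fit it."""
    return PWAS(dom, rec, y, C, n_variants=n_variants).fit(fdr=fdr)
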