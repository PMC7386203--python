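"""File formats, configuration and serialization.

Supported inputs:

* genotypes — VCF v4.2 (GT hard calls or GP probability triplets, read
  through cyvcf2) or a long-format TSV ``sample_id  variant_key  p0 p1 p2``;
* variant effects — TSV with columns
  ``variant_key  gene_id  consequence  score  n_sub  n_ins  n_del``;
* phenotypes — TSV ``sample_id  value``;
* covariates — TSV ``sample_id  cov1  cov2 ...``;
* run configuration — TOML (``[aggregation]`` section carries the five
  aggregation parameters; the norm orders accept the string ``"inf"``).

All coordinates are VCF 1-based; variant keys are
``CHROM:POS:REF:ALT`` on the reference strand.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .aggregation import AggregationParams, GeneScoreMatrix
from .association import CovariateMatrix, PhenotypeVector
from .variants import Consequence, VariantRecord

__all__ = [
    "GenotypeStore",
    "RunConfig",
    "read_genotypes",
    "read_variant_table",
    "write_variant_table",
    "read_phenotype",
    "write_phenotype",
    "read_covariates",
    "read_score_matrix",
    "write_score_matrix",
    "write_results",
    "write_vcf",
]

_GP_SUM_RANGE = (0.99, 1.01)
MISSING_TRIPLET = (1.0, 0.0, 0.0)


@dataclass
class GenotypeStore:
    """Per sample x variant genotype probabilities.

    Holds either hard allele counts (``hard``: int8 matrix, -1 for a
    missing call) or dense probability triplets (``dense``), expanding
    hard calls to triplets on demand.  Missing calls become (1, 0, 0):
    an ungenotyped variant is treated as absent.
    """

    sample_ids: list[str]
    variant_keys: list[str]
    hard: Optional[np.ndarray] = None
    dense: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if (self.hard is None) == (self.dense is None):
            raise ValueError("exactly one of hard / dense must be provided")
        n, m = len(self.sample_ids), len(self.variant_keys)
        if self.hard is not None and self.hard.shape != (n, m):
            raise ValueError(f"hard-call matrix shape {self.hard.shape} != ({n},{m})")
        if self.dense is not None and self.dense.shape != (n, m, 3):
            raise ValueError(f"probability array shape {self.dense.shape} != ({n},{m},3)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def probs(self, indices: Sequence[int]) -> np.ndarray:
        """(n_samples, len(indices), 3) probability triplets."""
        idx = np.asarray(indices, dtype=int)
        if self.dense is not None:
            return self.dense[:, idx, :]
        g = self.hard[:, idx]
        out = np.zeros((self.n_samples, idx.size, 3))
        out[..., 0] = (g == 0) | (g < 0)  # missing -> homozygous reference
        out[..., 1] = g == 1
        out[..., 2] = g == 2
        return out

    def dense_probs(self) -> np.ndarray:
        return self.probs(range(self.n_variants))

    def subset_samples(self, index: np.ndarray) -> "GenotypeStore":
        ids = [self.sample_ids[i] for i in index]
        if self.hard is not None:
            return GenotypeStore(ids, list(self.variant_keys), hard=self.hard[index])
        return GenotypeStore(ids, list(self.variant_keys), dense=self.dense[index])


def _parse_norm_order(value) -> float:
    if isinstance(value, str):
        if value.lower() in ("inf", "infinity"):
            return math.inf
        return float(value)
    return float(value)


@dataclass
class RunConfig:
    """Top-level run configuration (TOML-backed; CLI flags override)."""

    aggregation: AggregationParams = field(default_factory=AggregationParams)
    fdr_threshold: float = 0.05
    indel_weights: tuple[float, float, float] = (0.05, 0.05, 0.05)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError(f"fdr_threshold must be in (0, 1), got {self.fdr_threshold}")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        agg_raw = raw.get("aggregation", {})
        agg = AggregationParams(
            mu_D=float(agg_raw.get("mu_D", 1.0)),
            p_D=_parse_norm_order(agg_raw.get("p_D", 1.25)),
            mu_R=float(agg_raw.get("mu_R", 0.5)),
            p_R=_parse_norm_order(agg_raw.get("p_R", "inf")),
            q_R=_parse_norm_order(agg_raw.get("q_R", 3.0)),
        )
        weights = raw.get("indel_weights", {})
        return cls(
            aggregation=agg,
            fdr_threshold=float(raw.get("fdr_threshold", 0.05)),
            indel_weights=(
                float(weights.get("w_sub", 0.05)),
                float(weights.get("w_ins", 0.05)),
                float(weights.get("w_del", 0.05)),
            ),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )


# ---------------------------------------------------------------------------
# genotypes


def _hard_call_from_gt(gt_types_row):
    # cyvcf2 gt_types under gts012=True: 0=HOM_REF, 1=HET, 2=HOM_ALT, 3=UNKNOWN
    mapping = np.array([0, 1, 2, -1], dtype=np.int8)
    return mapping[gt_types_row]


def read_genotypes(path, dialect: str) -> GenotypeStore:
    """Read genotypes as probability triplets under a named dialect.

    ``vcf_gt`` maps hard GT calls 0/0, 0/1, 1/1 to (1,0,0), (0,1,0),
    (0,0,1) and ``./.`` to (1,0,0).  ``vcf_gp`` takes the FORMAT/GP
    triplet as (p0, p1, p2), rejecting triplets whose sum falls outside
    [0.99, 1.01] and renormalizing the rest.  ``tsv_probs`` reads a
    long-format table ``sample_id  variant_key  p0  p1  p2``.
    """
    path = Path(path)
    if dialect in ("vcf_gt", "vcf_gp"):
        return _read_vcf(path, use_gp=(dialect == "vcf_gp"))
    if dialect == "tsv_probs":
        return _read_tsv_probs(path)
    raise ValueError(f"unknown genotype dialect: {dialect}")


def _read_vcf(path: Path, use_gp: bool) -> GenotypeStore:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    keys: list[str] = []
    rows = []
    for i, record in enumerate(vcf):
        if len(record.ALT) != 1:
            raise ValueError(
                f"{path}: record {i + 1} ({record.CHROM}:{record.POS}) is not "
                "bi-allelic; decompose multi-allelic sites first"
            )
        keys.append(f"{record.CHROM}:{record.POS}:{record.REF}:{record.ALT[0]}")
        if use_gp:
            gp = record.format("GP")
            if gp is None:
                raise ValueError(
                    f"{path}: record {i + 1} has no GP field under dialect vcf_gp"
                )
            gp = np.asarray(gp, dtype=float)
            sums = gp.sum(axis=1)
            bad = (sums < _GP_SUM_RANGE[0]) | (sums > _GP_SUM_RANGE[1])
            if bad.any():
                j = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{path}: record {i + 1}, sample {samples[j]}: GP sums to "
                    f"{sums[j]:.4f}, outside [0.99, 1.01]"
                )
            rows.append(gp / sums[:, None])
        else:
            rows.append(_hard_call_from_gt(vcf_gt_types(record)))
    if use_gp:
        dense = np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0, 3))
        return GenotypeStore(samples, keys, dense=dense)
    hard = (
        np.stack(rows, axis=1).astype(np.int8)
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeStore(samples, keys, hard=hard)


def vcf_gt_types(record) -> np.ndarray:
    return np.asarray(record.gt_types)


def _read_tsv_probs(path: Path) -> GenotypeStore:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "variant_key": str})
    required = {"sample_id", "variant_key", "p0", "p1", "p2"}
    if not required.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    sums = frame[["p0", "p1", "p2"]].sum(axis=1)
    bad = (sums < _GP_SUM_RANGE[0]) | (sums > _GP_SUM_RANGE[1])
    if bad.any():
        line = int(frame.index[bad][0]) + 2  # header + 1-based
        raise ValueError(
            f"{path}: line {line}: probability triplet sums to "
            f"{sums[bad].iloc[0]:.4f}, outside [0.99, 1.01]"
        )
    samples = list(pd.unique(frame["sample_id"]))
    keys = list(pd.unique(frame["variant_key"]))
    sidx = {s: i for i, s in enumerate(samples)}
    vidx = {v: i for i, v in enumerate(keys)}
    dense = np.zeros((len(samples), len(keys), 3))
    dense[..., 0] = 1.0  # unlisted pairs are treated as missing calls
    rows = frame["sample_id"].map(sidx).to_numpy()
    cols = frame["variant_key"].map(vidx).to_numpy()
    triplets = frame[["p0", "p1", "p2"]].to_numpy(dtype=float)
    triplets /= triplets.sum(axis=1, keepdims=True)
    dense[rows, cols] = triplets
    return GenotypeStore(samples, keys, dense=dense)


def write_vcf(
    path,
    store: GenotypeStore,
    contigs: Optional[Sequence[str]] = None,
) -> None:
    """Write hard calls or GP triplets as an uncompressed VCF v4.2."""
    keys_parts = [k.split(":") for k in store.variant_keys]
    if contigs is None:
        contigs = sorted({p[0] for p in keys_parts}, key=str)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    if store.hard is not None:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        fmt = "GT"
    else:
        lines.append(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
        )
        lines.append(
            '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities">'
        )
        fmt = "GT:GP"
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
    lines.append("\t".join(header[:-1] + ["INFO", "FORMAT"] + store.sample_ids))
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    for j, (chrom, pos, ref, alt) in enumerate(keys_parts):
        fields = [chrom, pos, store.variant_keys[j], ref, alt, ".", "PASS", ".", fmt]
        if store.hard is not None:
            fields += [gt_strings[int(g)] for g in store.hard[:, j]]
        else:
            for trip in store.dense[:, j]:
                gt = gt_strings[int(np.argmax(trip))]
                fields.append(gt + ":" + ",".join(f"{p:.4f}" for p in trip))
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# variant effects table

_VARIANT_COLUMNS = ["variant_key", "gene_id", "consequence", "score", "n_sub", "n_ins", "n_del"]


def read_variant_table(path) -> list[VariantRecord]:
    """Read the variant-effects TSV into VariantRecord objects."""
    frame = pd.read_csv(path, sep="\t", dtype={"variant_key": str, "gene_id": str})
    missing = set(_VARIANT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        consequence = Consequence(row.consequence)
        is_indel = consequence is Consequence.INFRAME_INDEL

        def _int(v):
            return None if pd.isna(v) else int(v)

        records.append(
            VariantRecord(
                variant_key=row.variant_key,
                gene_id=row.gene_id,
                consequence=consequence,
                score=None if pd.isna(row.score) else float(row.score),
                n_sub=_int(row.n_sub) if is_indel else None,
                n_ins=_int(row.n_ins) if is_indel else None,
                n_del=_int(row.n_del) if is_indel else None,
            )
        )
    return records


def write_variant_table(variants: Sequence[VariantRecord], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "variant_key": v.variant_key,
                "gene_id": v.gene_id,
                "consequence": v.consequence.value,
                "score": v.score,
                "n_sub": v.n_sub,
                "n_ins": v.n_ins,
                "n_del": v.n_del,
            }
            for v in variants
        ],
        columns=_VARIANT_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# phenotypes / covariates / score matrices


def read_phenotype(path, kind: str = "continuous") -> PhenotypeVector:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "value"}.issubset(frame.columns):
        raise ValueError(f"{path}: expected columns sample_id, value")
    values = (
        frame["value"].to_numpy()
        if kind == "categorical"
        else frame["value"].to_numpy(dtype=float)
    )
    return PhenotypeVector(frame["sample_id"].tolist(), values, kind=kind)


def write_phenotype(pheno: PhenotypeVector, path) -> None:
    pd.DataFrame({"sample_id": pheno.sample_ids, "value": pheno.values}).to_csv(
        path, sep="\t", index=False
    )


def read_covariates(path) -> CovariateMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns:
        raise ValueError(f"{path}: expected a sample_id column")
    return CovariateMatrix.from_frame(frame)


def read_score_matrix(path, model: str) -> GeneScoreMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return GeneScoreMatrix(
        sample_ids=[str(s) for s in frame.index],
        gene_ids=[str(g) for g in frame.columns],
        values=frame.to_numpy(dtype=float),
        model=model,
    )


def write_score_matrix(matrix: GeneScoreMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# association results

_FLOAT_COLUMNS = [
    "p_dominant",
    "p_recessive",
    "p_generalized",
    "q_dominant",
    "q_recessive",
    "q_generalized",
    "beta_D",
    "beta_R",
    "effect_size",
]


def write_results(results, path, allow_empty: bool = True) -> None:
    """Write per-gene association results as a TSV.

    Rows are sorted by the generalized-model p-value; floats are printed
    in scientific notation with 6 significant digits.
    """
    table = results.table if hasattr(results, "table") else results
    if not len(table) and not allow_empty:
        raise ValueError("no results to write (pass allow_empty=True for a header-only file)")
    table = table.copy()
    for col in _FLOAT_COLUMNS:
        if col in table.columns:
            table[col] = table[col].map(lambda v: f"{v:.5E}")
    table.to_csv(path, sep="\t", index=False)
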