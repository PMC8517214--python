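"""Normalization, negative-binomial differential testing, and ranking.

The test is a documented stand-in for heavier differential machinery:
median-of-ratios normalization, moment dispersion with a fitted
mean-dispersion trend floor, and a Wald test on a pseudocount-shrunk log2
fold change, with Benjamini-Hochberg adjustment. It is validated by
calibration and power simulations, not by matching any external tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .regions import CountMatrix

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # p-values of exactly 0 are clamped here
PSEUDOCOUNT = 0.5
LFC_CLAMP = 50.0


@dataclass(frozen=True)
class DifferentialRecord:
    feature_id: str
    log2fc: float
    pvalue: float
    padj: float
    mean_norm: float

    def __post_init__(self) -> None:
        if not (0 < self.pvalue <= 1):
            raise ValueError("pvalue must lie in (0, 1]")
        if self.padj < self.pvalue - 1e-12:
            raise ValueError("padj must be >= pvalue")
        if not np.isfinite(self.log2fc):
            raise ValueError("log2fc must be finite")


@dataclass
class RankedTable:
    """Differential records in rank order (rank 1 = strongest upregulation)."""

    records: list[DifferentialRecord]

    @property
    def feature_ids(self) -> list[str]:
        return [r.feature_id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def size_factors(matrix: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, centered to geometric mean 1.

    Falls back to total-count scaling (with a warning) when no feature is
    nonzero in every sample.
    """
    counts = matrix.counts.astype(float)
    if counts.size == 0 or not np.any(counts):
        raise ValueError("cannot compute size factors for an all-zero matrix")
    all_nonzero = np.all(counts > 0, axis=1)
    if np.any(all_nonzero):
        sub = counts[all_nonzero]
        log_ref = np.mean(np.log(sub), axis=1)
        factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    else:
        logger.warning(
            "no feature with nonzero counts in all samples; "
            "falling back to total-count scaling"
        )
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("a sample has zero total counts")
        factors = totals
    return factors / np.exp(np.mean(np.log(factors)))


def _fit_dispersion_trend(mean_norm: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu over features with positive estimates."""
    mask = (alpha_mom > 0) & (mean_norm > 0)
    if mask.sum() < 3:
        fallback = float(np.mean(alpha_mom[alpha_mom > 0])) if np.any(alpha_mom > 0) else 0.01
        return max(fallback, 1e-8), 0.0
    x = 1.0 / mean_norm[mask]
    y = alpha_mom[mask]
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    a0, a1 = float(max(coef[0], 0.0)), float(max(coef[1], 0.0))
    if a0 == 0.0 and a1 == 0.0:
        a0 = max(float(np.median(y)), 1e-8)
    return a0, a1


def nb_differential(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    allow_pooled_dispersion: bool = False,
    factors: np.ndarray | None = None,
) -> list[DifferentialRecord]:
    """Per-feature NB Wald test of group B over group A.

    Returns one record per feature in input order. log2fc is computed on
    normalized group means with a 0.5 pseudocount; p-values of exactly 0 are
    clamped to 1e-300; BH adjustment is applied across all features.
    """
    if (len(group_a) < 2 or len(group_b) < 2) and not allow_pooled_dispersion:
        raise ValueError(
            "each group needs >= 2 samples for dispersion estimation; "
            "pass allow_pooled_dispersion=True to opt into pooled mode"
        )
    cols_a = matrix.columns_for(group_a)
    cols_b = matrix.columns_for(group_b)
    if factors is None:
        factors = size_factors(matrix)
    factors = np.asarray(factors, dtype=float)
    norm = matrix.counts.astype(float) / factors[None, :]
    ka = norm[:, cols_a]
    kb = norm[:, cols_b]
    na, nb = len(cols_a), len(cols_b)

    mu_a = ka.mean(axis=1)
    mu_b = kb.mean(axis=1)
    mean_norm = norm.mean(axis=1)

    # moment dispersion, pooled over the two groups (or over all samples
    # when a group has a single replicate)
    if na >= 2 and nb >= 2:
        var_a = ka.var(axis=1, ddof=1)
        var_b = kb.var(axis=1, ddof=1)
        wa, wb = na - 1, nb - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            da = np.where(mu_a > 0, (var_a - mu_a) / mu_a**2, 0.0)
            db = np.where(mu_b > 0, (var_b - mu_b) / mu_b**2, 0.0)
        alpha_mom = (wa * da + wb * db) / (wa + wb)
    else:
        pooled = norm[:, cols_a + cols_b]
        mu_p = pooled.mean(axis=1)
        var_p = pooled.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_mom = np.where(mu_p > 0, (var_p - mu_p) / mu_p**2, 0.0)
    alpha_mom = np.clip(alpha_mom, 0.0, None)

    a0, a1 = _fit_dispersion_trend(mean_norm, alpha_mom)
    with np.errstate(divide="ignore"):
        trend = a0 + a1 / np.clip(mean_norm, 1e-8, None)
    # moment estimate shrunk toward the trend, floored at 80% of the trend;
    # both constants were chosen so the Wald test is calibrated (type-I
    # fraction ~0.05) on null NB simulations at 3 vs 3 replicates, where the
    # raw moment estimator is far too noisy to use directly
    alpha = np.maximum(0.8 * trend, 0.3 * alpha_mom + 0.7 * trend)
    alpha = np.clip(alpha, 1e-8, 100.0)

    ln2sq = np.log(2.0) ** 2
    mu_a_s = mu_a + PSEUDOCOUNT
    mu_b_s = mu_b + PSEUDOCOUNT
    log2fc = np.log2(mu_b_s / mu_a_s)
    log2fc = np.clip(log2fc, -LFC_CLAMP, LFC_CLAMP)
    var_a_log = (mu_a_s + alpha * mu_a_s**2) / (na * mu_a_s**2 * ln2sq)
    var_b_log = (mu_b_s + alpha * mu_b_s**2) / (nb * mu_b_s**2 * ln2sq)
    se = np.sqrt(var_a_log + var_b_log)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    pvalues = 2.0 * stats.norm.sf(np.abs(wald))
    pvalues = np.clip(pvalues, P_FLOOR, 1.0)
    _rej, padj, *_ = multipletests(pvalues, method="fdr_bh")
    padj = np.maximum(np.clip(padj, P_FLOOR, 1.0), pvalues)

    return [
        DifferentialRecord(
            feature_id=f,
            log2fc=float(lfc),
            pvalue=float(p),
            padj=float(q),
            mean_norm=float(m),
        )
        for f, lfc, p, q, m in zip(matrix.features, log2fc, pvalues, padj, mean_norm)
    ]


def select_representative_isoform(
    isoforms_by_gene: Mapping[str, Sequence[tuple[str, int, int]]],
) -> dict[str, str]:
    """Keep, per gene, the isoform with the most reads per annotated length.

    ``isoforms_by_gene`` maps gene -> sequence of (isoform_id, length, count).
    Ties on read density prefer the longer annotation, then the
    lexicographically smallest id.
    """
    chosen: dict[str, str] = {}
    for gene, isoforms in isoforms_by_gene.items():
        if not isoforms:
            continue
        for _iso, length, _count in isoforms:
            if length <= 0:
                raise ValueError(f"gene {gene}: isoform length must be > 0")
        best = max(
            isoforms,
            key=lambda item: (item[2] / item[1], item[1], _ReverseStr(item[0])),
        )
        chosen[gene] = best[0]
    return chosen


class _ReverseStr(str):
    """Orders strings in reverse so max() picks the lexicographically smallest."""

    def __lt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other: str) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def rank_regions(records: Sequence[DifferentialRecord]) -> RankedTable:
    """Rank by signed significance.

    Upregulated records (log2fc > 0) come first by ascending p, then
    log2fc == 0 by descending p, then downregulated by descending p; ties
    break by |log2fc| descending, then feature id.
    """

    def key(record: DifferentialRecord):
        if record.log2fc > 0:
            return (0, record.pvalue, -abs(record.log2fc), record.feature_id)
        if record.log2fc == 0:
            return (1, -record.pvalue, -abs(record.log2fc), record.feature_id)
        return (2, -record.pvalue, -abs(record.log2fc), record.feature_id)

    return RankedTable(records=sorted(records, key=key))


DIFF_COLUMNS = ("feature_id", "log2fc", "pvalue", "padj", "mean_norm")


def write_differential_table(
    records: Sequence[DifferentialRecord], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("# " + "\t".join(DIFF_COLUMNS) + "\n")
        for r in records:
            handle.write(
                f"{r.feature_id}\t{r.log2fc:.6g}\t{r.pvalue:.6g}\t"
                f"{r.padj:.6g}\t{r.mean_norm:.6g}\n"
            )


def read_differential_table(path: str | Path) -> list[DifferentialRecord]:
    records: list[DifferentialRecord] = []
    with open(path) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fid, lfc, p, q, m = line.rstrip("\n").split("\t")
            records.append(
                DifferentialRecord(
                    feature_id=fid,
                    log2fc=float(lfc),
                    pvalue=float(p),
                    padj=float(q),
                    mean_norm=float(m),
                )
            )
    return records
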