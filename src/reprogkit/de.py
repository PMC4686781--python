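"""Negative-binomial differential expression between two sample groups.

The model is the standard overdispersed count model for bulk RNA-seq: the
count of gene *g* in sample *j* is NB-distributed with mean
``mu_gj = s_j * q_g(line)`` and variance ``mu + alpha_g * mu**2``, where
``s_j`` is a per-sample size factor, ``q_g`` a normalized per-group
abundance and ``alpha_g`` the per-gene dispersion.  The pipeline runs

1. median-of-ratios size factors,
2. per-gene method-of-moments dispersion, pooled within cell lines,
3. per-contrast Wald tests on the log2 fold change between the group
   abundance MLEs, with Benjamini-Hochberg adjustment.

No empirical-Bayes shrinkage of dispersions or fold changes is applied;
every estimator here is a transparent closed form or a one-dimensional
MLE, which keeps each stage testable against brute-force oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from .io import CountMatrix, SampleSheet

logger = logging.getLogger(__name__)

#: floor and ceiling for the NB dispersion (variance = mu + alpha * mu^2)
ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0

LN2 = np.log(2.0)

DE_COLUMNS = (
    "base_mean_a", "base_mean_b", "log2fc", "se", "wald_z", "pvalue", "qvalue", "flag",
)


@dataclass(frozen=True)
class ContrastSpec:
    """Two disjoint sample groups to compare; fold change is b over a."""

    group_a: tuple[str, ...]
    group_b: tuple[str, ...]
    label: str

    def __post_init__(self) -> None:
        a, b = set(self.group_a), set(self.group_b)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{self.label}: each group needs >= 2 samples")
        if a & b:
            raise ValueError(f"{self.label}: groups overlap: {sorted(a & b)}")


@dataclass(frozen=True)
class DEResult:
    """Per-gene Wald test results for one contrast.

    ``table`` is indexed by gene and carries normalized group means,
    log2 fold change (b vs a), its standard error, the Wald z statistic,
    two-sided p, BH-adjusted q and a flag (``ok``, ``extreme`` for a
    group with no counts, ``untestable`` for genes with no counts at all).
    """

    label: str
    table: pd.DataFrame


def estimate_size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, take the median over reference genes (those with
    positive counts in every sample) of the ratio of the gene's count to
    its across-sample geometric mean.  If no gene is positive everywhere,
    fall back to total-count ratios (scaled to geometric mean one) with a
    warning.
    """
    counts = matrix.data.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        ref = counts[positive]
        log_geomean = np.log(ref).mean(axis=1, keepdims=True)
        ratios = np.exp(np.log(ref) - log_geomean)
        s = np.median(ratios, axis=0)
    else:
        logger.warning("no gene positive in all samples; using total-count size factors")
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot normalize: a sample has zero total counts")
        s = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(s, index=matrix.data.columns, name="size_factor")


def estimate_dispersions(
    matrix: CountMatrix,
    size_factors: pd.Series,
    sheet: SampleSheet,
    alpha_min: float = ALPHA_MIN,
    alpha_max: float = ALPHA_MAX,
    stabilize: bool = True,
) -> pd.Series:
    """Per-gene method-of-moments dispersion on normalized counts.

    The sample variance is pooled within cell lines (residuals from each
    line's own mean, divided by n_samples - n_lines), so genuine between-
    line expression differences do not inflate the dispersion, and the
    moment estimate is ``(s2 - mean) / mean**2``.

    With three replicates per line the per-gene estimate has very few
    degrees of freedom; genes whose variance is underestimated by chance
    would otherwise get wildly inflated Wald statistics.  ``stabilize``
    therefore fits a mean-dispersion trend ``a0 + a1/mean`` (non-negative
    least squares) across genes and floors each per-gene estimate at its
    trend value — the conservative maximum rule.  Pass ``stabilize=False``
    for the raw per-gene moment estimates.  Results are clipped to
    [alpha_min, alpha_max]; all-zero genes get alpha_min.
    """
    samples = sheet.sample_ids
    y = matrix.data.loc[:, samples].to_numpy(dtype=float) / size_factors.loc[samples].to_numpy()
    lines = sheet.table.set_index("sample_id").loc[samples, "line_id"].to_numpy()
    n = y.shape[1]
    uniq = pd.unique(lines)
    if n - len(uniq) < 1:
        raise ValueError("dispersion estimation needs replication within lines")
    ss = np.zeros(y.shape[0])
    for line in uniq:
        cols = lines == line
        resid = y[:, cols] - y[:, cols].mean(axis=1, keepdims=True)
        ss += (resid ** 2).sum(axis=1)
    s2 = ss / (n - len(uniq))
    grand = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (s2 - grand) / grand ** 2
    expressed = grand > 0
    alpha = np.where(expressed, raw, alpha_min)
    if stabilize and expressed.any():
        design = np.column_stack([np.ones(int(expressed.sum())), 1.0 / grand[expressed]])
        coef, _ = nnls(design, np.clip(raw[expressed], 0.0, None))
        trend = np.zeros_like(grand)
        trend[expressed] = coef[0] + coef[1] / grand[expressed]
        alpha = np.maximum(alpha, trend)
    alpha = np.clip(alpha, alpha_min, alpha_max)
    return pd.Series(alpha, index=matrix.data.index, name="dispersion")


def _fit_group_abundance(
    counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray,
    max_iter: int = 200, tol: float = 1e-12,
) -> np.ndarray:
    """MLE of the common normalized abundance q with mu_j = s_j * q.

    Solves the NB score equation sum_j (k_j - s_j q) / (1 + alpha s_j q) = 0
    by the fixed-point iteration q <- sum(k_j w_j) / sum(s_j w_j) with
    w_j = 1 / (1 + alpha s_j q), vectorized over genes.  With equal size
    factors within the group this reduces in one step to the mean of
    normalized counts.  Genes with no counts converge to q = 0.
    """
    q = (counts / sf).mean(axis=1)
    for _ in range(max_iter):
        w = 1.0 / (1.0 + alpha[:, None] * sf * q[:, None])
        q_new = (counts * w).sum(axis=1) / (sf * w).sum(axis=1)
        if np.all(np.abs(q_new - q) <= tol * (q + 1.0)):
            q = q_new
            break
        q = q_new
    return q


def _wald_information(q: np.ndarray, sf: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fisher information for log q: sum_j mu_j / (1 + alpha * mu_j)."""
    mu = sf * q[:, None]
    return (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)


def nb_wald_test(
    matrix: CountMatrix,
    size_factors: pd.Series,
    dispersions: pd.Series,
    contrast: ContrastSpec,
) -> DEResult:
    """Two-group NB Wald test at fixed per-gene dispersion.

    Fits the group abundances by maximum likelihood, tests
    ``log2(q_b / q_a) = 0`` with the standard error from the Fisher
    information at the fit, and BH-adjusts p-values within the contrast.
    A group with no counts at all has its abundance floored at half a
    normalized count spread over the group's total depth (flag
    ``extreme``) so silencing remains detectable; genes with no counts in
    either group are reported with p = 1 and excluded from the BH
    denominator (flag ``untestable``).
    """
    missing = [s for s in contrast.group_a + contrast.group_b
               if s not in matrix.data.columns]
    if missing:
        raise ValueError(f"{contrast.label}: samples not in matrix: {missing}")
    genes = matrix.data.index
    alpha = dispersions.reindex(genes).to_numpy(dtype=float)
    if np.isnan(alpha).any():
        raise ValueError("dispersions missing for some genes")

    results = {}
    for tag, group in (("a", contrast.group_a), ("b", contrast.group_b)):
        k = matrix.data.loc[:, list(group)].to_numpy(dtype=float)
        sf = size_factors.loc[list(group)].to_numpy(dtype=float)
        q = _fit_group_abundance(k, sf, alpha)
        results[tag] = (q, sf)
    q_a, sf_a = results["a"]
    q_b, sf_b = results["b"]

    zero_a, zero_b = q_a == 0, q_b == 0
    untestable = zero_a & zero_b
    extreme = (zero_a | zero_b) & ~untestable
    # half a pseudo-count over the group's depth keeps the information finite
    floor_a = 0.5 / sf_a.sum()
    floor_b = 0.5 / sf_b.sum()
    qf_a = np.where(zero_a, floor_a, q_a)
    qf_b = np.where(zero_b, floor_b, q_b)

    log2fc = np.where(untestable, 0.0, np.log2(qf_b) - np.log2(qf_a))
    info_a = _wald_information(qf_a, sf_a, alpha)
    info_b = _wald_information(qf_b, sf_b, alpha)
    with np.errstate(divide="ignore"):
        se = np.sqrt(1.0 / info_a + 1.0 / info_b) / LN2
    z = np.where(untestable, 0.0, log2fc / se)
    p = np.where(untestable, 1.0, 2.0 * stats.norm.sf(np.abs(z)))

    qval = np.ones(len(genes))
    testable = ~untestable
    if testable.any():
        qval[testable] = bh_adjust(p[testable])

    flag = np.where(untestable, "untestable", np.where(extreme, "extreme", "ok"))
    table = pd.DataFrame(
        {
            "base_mean_a": q_a,
            "base_mean_b": q_b,
            "log2fc": log2fc,
            "se": se,
            "wald_z": z,
            "pvalue": p,
            "qvalue": qval,
            "flag": flag,
        },
        index=genes,
    )
    return DEResult(label=contrast.label, table=table)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1; invariant to the
    input order of ties and always >= the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def write_de_table(result: DEResult, path) -> None:
    result.table.rename_axis("gene_id").to_csv(path, sep="\t")


def read_de_table(path, label: str) -> DEResult:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE columns {missing}")
    return DEResult(label=label, table=df)
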