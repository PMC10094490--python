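"""Self-contained negative-binomial differential expression.

The model is the standard RNA-seq NB parameterization
``var = mu + alpha * mu**2``: median-of-ratios size factors, per-gene
method-of-moments dispersion pooled across groups, a Wald test on the log2
ratio of normalized group means with a delta-method standard error, and
Benjamini-Hochberg FDR control. Genes with adjusted p <= 0.05 (configurable)
are flagged as differentially expressed (DEGs); expression levels can also
be reported as FPKM.

Two groups only (the queen-vs-worker contrast); multi-factor designs are out
of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-8
LN2 = np.log(2.0)


class DiffExprError(ValueError):
    pass


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    ``factor_j = median_g(count_gj / geomean_g)`` over genes expressed in
    every sample. With ``pseudo_reference=True`` the geometric mean is
    computed on counts+1 and all genes participate — a fallback for sparse
    matrices where no gene is positive everywhere.
    """
    x = counts.to_numpy(dtype=float)
    if x.size == 0:
        raise DiffExprError("empty count matrix")
    if pseudo_reference:
        logs = np.log(x + 1.0)
        log_geomean = logs.mean(axis=1)
        usable = np.ones(x.shape[0], dtype=bool)
    else:
        usable = (x > 0).all(axis=1)
        if not usable.any():
            raise DiffExprError(
                "no gene has nonzero counts in every sample; "
                "retry with pseudo_reference=True"
            )
        with np.errstate(divide="ignore"):
            logs = np.log(x)
        log_geomean = np.where(usable, logs.mean(axis=1), np.nan)
    ratios = np.exp(
        logs[usable] - log_geomean[usable, None]
    )
    factors = np.median(ratios, axis=0)
    if (factors <= 0).any():
        raise DiffExprError("non-positive size factor; data too sparse")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_masks(
    samples: pd.Index, groups: pd.Series, numerator: str | None = None
) -> tuple[np.ndarray, np.ndarray, str, str]:
    g = groups.reindex(samples)
    if g.isna().any():
        missing = list(samples[g.isna()])
        raise DiffExprError(f"samples without group label: {missing}")
    labels = list(dict.fromkeys(g))
    if len(labels) != 2:
        raise DiffExprError(f"need exactly 2 groups, got {labels}")
    if numerator is not None:
        if numerator not in labels:
            raise DiffExprError(f"numerator {numerator!r} not among {labels}")
        labels = [numerator] + [x for x in labels if x != numerator]
    a, b = labels
    return (g == a).to_numpy(), (g == b).to_numpy(), a, b


def _moment_dispersion_raw(
    counts: pd.DataFrame, factors: pd.Series, groups: pd.Series
) -> pd.Series:
    """Unclipped per-gene method-of-moments dispersion (may be negative)."""
    norm = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    mask_a, mask_b, _, _ = _group_masks(counts.columns, groups)
    num = np.zeros(norm.shape[0])
    den = 0.0
    for mask in (mask_a, mask_b):
        n_k = int(mask.sum())
        if n_k < 2:
            raise DiffExprError("each group needs >= 2 samples for dispersion")
        sub = norm[:, mask]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_k = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
        num += alpha_k * (n_k - 1)
        den += n_k - 1
    return pd.Series(num / den, index=counts.index, name="dispersion")


def moment_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion, pooled across groups.

    Within each group, ``alpha_k = (s2_k - mean_k) / mean_k**2`` on
    normalized counts; the gene estimate is the df-weighted (n_k - 1) mean
    of the group estimates, floored at `floor`.
    """
    raw = _moment_dispersion_raw(counts, factors, groups)
    return pd.Series(
        np.maximum(raw.to_numpy(), floor), index=counts.index, name="dispersion"
    )


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series,
    floor: float = DISPERSION_FLOOR,
    method: str = "common",
) -> pd.Series:
    """NB dispersion for the Wald test.

    ``method="common"`` (default) assigns every gene the across-gene mean of
    the unclipped per-gene moment estimates. With only ``n - 2`` residual
    degrees of freedom per gene in a two-group design, per-gene estimates
    are far too noisy to plug into a normal-reference Wald test (the z
    statistic then behaves like a t with ~4 df and the test runs well above
    its nominal level), so pooling across genes is what keeps the test
    calibrated at small n — the same reason NB differential-expression tools
    moderate their dispersions. Because the moments are taken within groups,
    genuine expression differences between groups do not inflate the pooled
    value. ``method="per-gene"`` returns the raw clipped moment estimates
    for data whose dispersions genuinely vary from gene to gene.
    """
    if method == "per-gene":
        return moment_dispersion(counts, factors, groups, floor=floor)
    if method != "common":
        raise DiffExprError(f"unknown dispersion method {method!r}")
    raw = _moment_dispersion_raw(counts, factors, groups)
    common = max(float(raw.mean()), floor)
    return pd.Series(
        np.full(len(counts), common), index=counts.index, name="dispersion"
    )


def nb_wald_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    dispersions: pd.Series,
    groups: pd.Series,
    deg_threshold: float = 0.05,
    numerator: str | None = None,
) -> pd.DataFrame:
    """Wald test on log2(mean_A / mean_B) of normalized counts.

    The SE of each group's log2 mean comes from the delta method under the
    NB variance ``mu + alpha mu**2``:
    ``SE_k = sqrt((m_k + alpha m_k^2) / (n_k m_k^2)) / ln 2``. When a group
    mean is zero, 0.5 is added to both group means (a per-sample pseudo-count
    on the normalized scale) to keep the fold change finite; those genes are
    flagged in the ``zero_inflated`` column. p-values are BH-adjusted and
    genes with ``padj <= deg_threshold`` are flagged as DEGs.

    The numerator group (A) defaults to the first label encountered in
    `groups`; pass ``numerator`` to fix the contrast orientation explicitly.
    """
    mask_a, mask_b, label_a, label_b = _group_masks(counts.columns, groups, numerator)
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise DiffExprError("each group needs >= 2 samples")
    norm = counts.to_numpy(dtype=float) / factors.reindex(counts.columns).to_numpy()
    m_a = norm[:, mask_a].mean(axis=1)
    m_b = norm[:, mask_b].mean(axis=1)
    base_mean = norm.mean(axis=1)
    alpha = dispersions.reindex(counts.index).to_numpy()

    zero = (m_a == 0) | (m_b == 0)
    m_a_adj = np.where(zero, m_a + 0.5, m_a)
    m_b_adj = np.where(zero, m_b + 0.5, m_b)
    # difference of logs (not log of ratio) so a group swap negates exactly
    log2fc = np.log2(m_a_adj) - np.log2(m_b_adj)
    se_a = np.sqrt((m_a_adj + alpha * m_a_adj**2) / (n_a * m_a_adj**2)) / LN2
    se_b = np.sqrt((m_b_adj + alpha * m_b_adj**2) / (n_b * m_b_adj**2)) / LN2
    se = np.sqrt(se_a**2 + se_b**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.maximum(se, 1e-300), 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(pvalue)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2_fold_change": log2fc,
            "lfcSE": se,
            "stat": z,
            "p_value": pvalue,
            "p_adj": padj,
            "is_deg": padj <= deg_threshold,
            "zero_inflated": zero,
        },
        index=counts.index,
    ).rename_axis("gene_id")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DiffExprError("p_values must be 1-D")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    totals: pd.Series | None = None,
) -> pd.DataFrame:
    """``FPKM_gj = count_gj * 1e9 / (length_g * total_j)``.

    `totals` defaults to per-sample column sums.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])
        raise DiffExprError(f"genes without length: {missing[:5]}")
    if (lengths <= 0).any():
        raise DiffExprError("gene lengths must be positive")
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        raise DiffExprError("per-sample totals must be positive")
    return counts * 1e9 / np.outer(lengths.to_numpy(), totals.to_numpy())


def run_differential(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    group_col: str = "caste",
    sample_col: str = "sample",
    deg_threshold: float = 0.05,
    gene_lengths: pd.Series | None = None,
    numerator: str | None = None,
) -> pd.DataFrame:
    """Full pipeline: size factors -> dispersion -> Wald -> BH (-> FPKM means)."""
    groups = samples.set_index(sample_col)[group_col]
    factors = size_factors(counts)
    disp = estimate_dispersion(counts, factors, groups)
    result = nb_wald_test(counts, factors, disp, groups,
                          deg_threshold=deg_threshold, numerator=numerator)
    result["dispersion"] = disp
    if gene_lengths is not None:
        result["mean_fpkm"] = fpkm(counts, gene_lengths).mean(axis=1)
    return result
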