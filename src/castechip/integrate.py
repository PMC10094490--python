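"""Peak-gene-expression integration.

Connects classified H3K4me1 consensus peaks with the gene annotation and the
differential-expression results: assigns peaks to genes (promoter window or
gene body, nearest-TSS tie-break), summarizes DEG / differential-peak-gene
(DPG) overlaps, correlates peak fold changes with expression fold changes
(Spearman), runs a generic hypergeometric over-representation analysis
against user-supplied gene sets, and computes a strand-aware TSS coverage
metaprofile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .genome_io import FeatureIndex, GenomeAnnotation

DIFFERENTIAL_CLASSES_PREFIX = "differential_up_"


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_value: float

    def to_dict(self) -> dict:
        return {"rho": self.rho, "n": self.n, "p_value": self.p_value}


@dataclass
class OverlapSummary:
    n1: int
    n2: int
    intersection: int
    jaccard: float

    def to_dict(self) -> dict:
        return {
            "n1": self.n1, "n2": self.n2,
            "intersection": self.intersection, "jaccard": self.jaccard,
        }


@dataclass
class MetaProfile:
    """Mean coverage in uniform bins around the TSS (negative = upstream)."""

    offsets: np.ndarray  # bin centers relative to the TSS
    mean_signal: np.ndarray
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_signal": self.mean_signal}
        )

    @property
    def argmax_offset(self) -> float:
        return float(self.offsets[int(np.nanargmax(self.mean_signal))])


def link_peaks_to_genes(
    peaks: pd.DataFrame,
    genome: GenomeAnnotation,
    upstream: int = 2000,
    downstream: int = 200,
    index: FeatureIndex | None = None,
) -> pd.DataFrame:
    """Assign each peak to at most one gene by midpoint containment.

    A peak whose midpoint lies in a promoter window links to that gene
    (type ``promoter``); otherwise a midpoint inside a gene span links as
    ``gene_body``. Several candidates resolve by smallest absolute TSS
    distance, then gene id. Intergenic midpoints yield no link.
    """
    if index is None:
        index = FeatureIndex(genome, upstream, downstream)
    genes = {g.gene_id: g for g in genome.genes}
    rows = []
    for row in peaks.itertuples(index=False):
        mid = (int(row.start) + int(row.end)) // 2
        cat, gid = index.classify(row.chrom, mid)
        if gid is None:
            continue
        link_type = "promoter" if cat == "promoter" else "gene_body"
        rows.append(
            {
                "peak_id": row.peak_id,
                "gene_id": gid,
                "link_type": link_type,
                "tss_distance": genes[gid].tss_distance(mid),
            }
        )
    return pd.DataFrame(rows, columns=["peak_id", "gene_id", "link_type", "tss_distance"])


def differential_peak_genes(
    classified_peaks: pd.DataFrame, links: pd.DataFrame
) -> set[str]:
    """Genes linked to at least one differential peak (the DPG set)."""
    diff_ids = set(
        classified_peaks.loc[
            classified_peaks["peak_class"].str.startswith(DIFFERENTIAL_CLASSES_PREFIX),
            "peak_id",
        ]
    )
    return set(links.loc[links["peak_id"].isin(diff_ids), "gene_id"])


def overlap_sets(genes1: Iterable[str], genes2: Iterable[str]) -> OverlapSummary:
    s1, s2 = set(genes1), set(genes2)
    inter = len(s1 & s2)
    union = len(s1 | s2)
    return OverlapSummary(
        n1=len(s1), n2=len(s2), intersection=inter,
        jaccard=inter / union if union else 0.0,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with the large-sample t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    res = stats.spearmanr(x, y)
    return CorrelationResult(
        rho=float(res.statistic), n=int(x.size), p_value=float(res.pvalue)
    )


def signal_expression_correlation(
    classified_peaks: pd.DataFrame,
    links: pd.DataFrame,
    de_results: pd.DataFrame,
    deg_only: bool = False,
) -> CorrelationResult:
    """Spearman correlation of per-gene peak log2FC with expression log2FC.

    For each gene linked to at least one differential peak, the peak side is
    the mean log2 fold change of its differential peaks (caste A over B, the
    same orientation as the expression fold change, so positive rho means
    co-directional chromatin and expression change). ``deg_only=True``
    restricts the pairs to flagged DEGs.
    """
    diff = classified_peaks[
        classified_peaks["peak_class"].str.startswith(DIFFERENTIAL_CLASSES_PREFIX)
    ][["peak_id", "fold_change"]]
    merged = links.merge(diff, on="peak_id")
    if merged.empty:
        raise ValueError("no linked pairs: no differential peak maps to a gene")
    per_gene = merged.groupby("gene_id")["fold_change"].apply(
        lambda v: float(np.mean(np.log2(v)))
    )
    expr = de_results["log2_fold_change"]
    if deg_only:
        expr = expr[de_results["is_deg"]]
    pairs = pd.DataFrame({"peak_lfc": per_gene}).join(
        expr.rename("expr_lfc"), how="inner"
    ).dropna()
    if len(pairs) < 3:
        raise ValueError("no linked pairs: fewer than 3 genes with both values")
    return spearman(pairs["peak_lfc"], pairs["expr_lfc"])


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: malformed GMT line {lineno}")
        sets[fields[0]] = set(fields[2:])
    return sets


def hypergeometric_enrichment(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test, BH across sets.

    ``p = P(X >= k)`` with X hypergeometric(N=len(universe), K=len(set),
    n=len(query)); genes outside the universe are ignored. The universe
    choice dominates ORA results — pass it explicitly.
    """
    uni = set(universe)
    q = set(query) & uni
    rows = []
    for name, members in gene_sets.items():
        k_set = set(members) & uni
        k = len(q & k_set)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(k_set), len(q)))
        rows.append(
            {"gene_set": name, "overlap": k, "set_size": len(k_set),
             "query_size": len(q), "universe_size": len(uni), "p_value": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["p_adj"] = []
    return out


def tss_metaprofile(
    coverage: Mapping[str, np.ndarray],
    genome: GenomeAnnotation,
    flank: int = 2000,
    bin_size: int = 50,
) -> MetaProfile:
    """Strand-aware mean coverage in `bin_size` bins within ±`flank` of TSSs.

    Bins are averaged per gene, then across genes; genes truncated at a
    chromosome edge contribute only their covered bins. Bin centers are
    reported so offset 0 lies between the two central bins.
    """
    if len(genome.genes) == 0:
        raise ValueError("annotation has no genes")
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for g in genome.genes:
        arr = coverage.get(g.chrom)
        if arr is None:
            continue
        t = g.tss
        lo, hi = t - flank, t + flank
        clip_lo, clip_hi = max(lo, 0), min(hi, len(arr))
        if clip_lo >= clip_hi:
            continue
        window = np.full(2 * flank, np.nan)
        window[clip_lo - lo: clip_hi - lo] = arr[clip_lo:clip_hi]
        if g.strand == "-":
            window = window[::-1]
        binned = window.reshape(n_bins, bin_size)
        valid = np.isfinite(binned)
        bin_ok = valid.all(axis=1)
        sums[bin_ok] += binned[bin_ok].mean(axis=1)
        counts[bin_ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    offsets = np.arange(n_bins) * bin_size - flank + bin_size / 2
    return MetaProfile(offsets=offsets, mean_signal=mean, n_genes=len(genome.genes))
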