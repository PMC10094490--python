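"""Consensus peaks across castes/replicates and their classification.

The comparison follows the two-caste ChIP-seq design: per-replicate peak
calls are merged (>=1 bp overlap) into consensus intervals; a consensus peak
is a *caste-unique* peak when it is present in every replicate of one caste
and in no replicate of the other, and a *differential* peak when it passes
``p < alpha`` (Welch t on log2 normalized signal) and ``fold change >
fc_threshold`` between castes. Unique classification takes precedence:
peaks absent from one caste are never tested as differential. Remaining
peaks are ``shared`` when testable and ``unresolved`` when fewer than two
replicates per caste carry signal.

Peak positions are annotated by the feature category of the midpoint
(promoter > exon > intron > intergenic), and the caste-wise distribution of
categories is compared with a Pearson chi-squared test over
{promoter, intron, exon} (intergenic excluded), as in the underlying
two-instar queen/worker comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import FeatureIndex, GenomeAnnotation, read_bed
from .synth import ReplicatePeakSet

PEAK_CLASSES = (
    "unique_A", "unique_B", "differential_up_A", "differential_up_B",
    "shared", "unresolved",
)


@dataclass
class ConsensusPeaks:
    """Merged consensus intervals with per-(caste, replicate) signal.

    ``presence`` and ``signal`` are (n_peaks x n_samples) arrays; column
    ``j`` corresponds to ``samples[j] = (caste, replicate)``.
    """

    intervals: pd.DataFrame  # chrom, start, end, peak_id
    samples: list[tuple[str, int]]
    presence: np.ndarray
    signal: np.ndarray

    @property
    def castes(self) -> list[str]:
        seen: list[str] = []
        for caste, _ in self.samples:
            if caste not in seen:
                seen.append(caste)
        return seen

    def caste_columns(self, caste: str) -> list[int]:
        return [j for j, (c, _) in enumerate(self.samples) if c == caste]


@dataclass
class DistributionTestResult:
    """2 x k contingency table and its Pearson chi-squared test."""

    table: pd.DataFrame
    chi_squared: float
    dof: int
    p_value: float

    def to_dict(self) -> dict:
        return {
            "table": {str(k): [int(x) for x in v]
                      for k, v in self.table.to_dict(orient="list").items()},
            "rows": [str(r) for r in self.table.index],
            "chi_squared": self.chi_squared,
            "dof": self.dof,
            "p_value": self.p_value,
        }


def merge_within_replicate(peaks: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping intervals within one replicate (scores length-weighted)."""
    if peaks.empty:
        return peaks
    out = []
    for chrom, sub in peaks.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur = None
        for row in sub.itertuples(index=False):
            if cur is None or row.start >= cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = dict(chrom=chrom, start=row.start, end=row.end,
                           name=row.name, score=row.score, strand=".",
                           _w=row.end - row.start)
            else:
                w = row.end - row.start
                cur["score"] = (cur["score"] * cur["_w"] + row.score * w) / (cur["_w"] + w)
                cur["end"] = max(cur["end"], row.end)
                cur["_w"] += w
        if cur is not None:
            out.append(cur)
    df = pd.DataFrame(out).drop(columns="_w")
    return df


def build_consensus(peaksets: Sequence[ReplicatePeakSet]) -> ConsensusPeaks:
    """Union-merge all replicate intervals (>=1 bp overlap) into consensus peaks.

    A replicate is *present* on a consensus peak when at least one of its
    intervals overlaps it by >=1 bp; its signal is then the overlap-weighted
    mean score of its overlapping intervals, and 0 when absent.
    """
    samples = [(ps.caste, ps.replicate) for ps in peaksets]
    rows = []
    for j, ps in enumerate(peaksets):
        merged = merge_within_replicate(ps.peaks)
        for r in merged.itertuples(index=False):
            rows.append((r.chrom, int(r.start), int(r.end), j, float(r.score)))
    if not rows:
        return ConsensusPeaks(
            intervals=pd.DataFrame(columns=["chrom", "start", "end", "peak_id"]),
            samples=samples,
            presence=np.zeros((0, len(samples)), dtype=bool),
            signal=np.zeros((0, len(samples))),
        )
    all_peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "rep", "score"])
    all_peaks = all_peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    consensus_rows = []
    presence_rows = []
    signal_rows = []
    n_samples = len(samples)
    for chrom, sub in all_peaks.groupby("chrom", sort=True):
        members: list[tuple] = []
        cur_start = cur_end = None
        for row in sub.itertuples(index=False):
            if cur_end is None or row.start < cur_end:
                cur_start = row.start if cur_start is None else cur_start
                cur_end = row.end if cur_end is None else max(cur_end, row.end)
                members.append(row)
            else:
                consensus_rows.append((chrom, cur_start, cur_end))
                presence_rows.append(_member_presence(members, n_samples))
                signal_rows.append(_member_signal(members, cur_start, cur_end, n_samples))
                cur_start, cur_end, members = row.start, row.end, [row]
        if members:
            consensus_rows.append((chrom, cur_start, cur_end))
            presence_rows.append(_member_presence(members, n_samples))
            signal_rows.append(_member_signal(members, cur_start, cur_end, n_samples))

    intervals = pd.DataFrame(consensus_rows, columns=["chrom", "start", "end"])
    intervals["peak_id"] = [f"consensus{i + 1:05d}" for i in range(len(intervals))]
    return ConsensusPeaks(
        intervals=intervals,
        samples=samples,
        presence=np.array(presence_rows, dtype=bool),
        signal=np.array(signal_rows, dtype=float),
    )


def _member_presence(members, n_samples: int) -> np.ndarray:
    out = np.zeros(n_samples, dtype=bool)
    for m in members:
        out[m.rep] = True
    return out


def _member_signal(members, start: int, end: int, n_samples: int) -> np.ndarray:
    num = np.zeros(n_samples)
    den = np.zeros(n_samples)
    for m in members:
        ov = min(m.end, end) - max(m.start, start)
        num[m.rep] += m.score * ov
        den[m.rep] += ov
    with np.errstate(invalid="ignore"):
        sig = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return sig


def classify_unique(
    presence_a: Sequence[bool], presence_b: Sequence[bool]
) -> str | None:
    """All-replicates-in-one-caste, none-in-the-other uniqueness rule.

    Returns ``"A"`` / ``"B"`` for the caste holding the peak, else None.
    """
    a = np.asarray(presence_a, dtype=bool)
    b = np.asarray(presence_b, dtype=bool)
    if a.all() and not b.any():
        return "A"
    if b.all() and not a.any():
        return "B"
    return None


def normalize_signals(consensus: ConsensusPeaks) -> np.ndarray:
    """Library-size normalization: each replicate's total peak signal scaled
    to the median library. Zero-total replicates keep factor 1."""
    totals = consensus.signal.sum(axis=0)
    positive = totals[totals > 0]
    if positive.size == 0:
        return consensus.signal.copy()
    med = np.median(positive)
    factors = np.where(totals > 0, totals / med, 1.0)
    return consensus.signal / factors


def test_differential(
    signals_a: Sequence[float],
    signals_b: Sequence[float],
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> tuple[float, float, str | None]:
    """Welch two-sided t on log2(signal + pseudocount) between castes.

    Fold change is ``(mean_A + c) / (mean_B + c)`` on the normalized scale.
    Returns ``(fold_change, p_value, direction)`` with direction ``"A"`` /
    ``"B"`` when ``p < alpha`` and ``max(fc, 1/fc) > fc_threshold``, else
    None. Degenerate zero-variance inputs give p=1 when the means agree.
    """
    a = np.asarray(signals_a, dtype=float)
    b = np.asarray(signals_b, dtype=float)
    fc = (a.mean() + pseudocount) / (b.mean() + pseudocount)
    la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    if la.std() == 0 and lb.std() == 0:
        p = 1.0 if la.mean() == lb.mean() else 0.0
    else:
        p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
    direction = None
    if p < alpha and max(fc, 1.0 / fc) > fc_threshold:
        direction = "A" if fc > 1.0 else "B"
    return float(fc), p, direction


def classify_consensus(
    consensus: ConsensusPeaks,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Assign exactly one class per consensus peak.

    Order of evaluation: caste-unique first (all-replicates rule), then the
    differential test when both castes carry >=2 nonzero-signal replicates,
    ``shared`` when the test does not reject, ``unresolved`` otherwise.
    Fold changes are reported caste A over caste B.
    """
    castes = consensus.castes
    if len(castes) != 2:
        raise ValueError(f"need exactly 2 castes, got {castes}")
    caste_a, caste_b = castes
    cols_a = consensus.caste_columns(caste_a)
    cols_b = consensus.caste_columns(caste_b)
    signal = normalize_signals(consensus) if normalize else consensus.signal

    out = consensus.intervals.copy()
    classes, fcs, pvals = [], [], []
    for i in range(len(out)):
        pa = consensus.presence[i, cols_a]
        pb = consensus.presence[i, cols_b]
        sa = signal[i, cols_a]
        sb = signal[i, cols_b]
        unique = classify_unique(pa, pb)
        if unique is not None:
            caste = caste_a if unique == "A" else caste_b
            classes.append(f"unique_{caste}")
            fc = (sa.mean() + pseudocount) / (sb.mean() + pseudocount)
            fcs.append(float(fc))
            pvals.append(np.nan)
            continue
        if (sa > 0).sum() < 2 or (sb > 0).sum() < 2:
            fc = (sa.mean() + pseudocount) / (sb.mean() + pseudocount)
            classes.append("unresolved")
            fcs.append(float(fc))
            pvals.append(np.nan)
            continue
        fc, p, direction = test_differential(
            sa, sb, fc_threshold=fc_threshold, alpha=alpha, pseudocount=pseudocount
        )
        if direction is None:
            classes.append("shared")
        else:
            caste = caste_a if direction == "A" else caste_b
            classes.append(f"differential_up_{caste}")
        fcs.append(fc)
        pvals.append(p)
    out["peak_class"] = classes
    out["fold_change"] = fcs
    out["p_value"] = pvals
    out["n_present_A"] = consensus.presence[:, cols_a].sum(axis=1) if len(out) else []
    out["n_present_B"] = consensus.presence[:, cols_b].sum(axis=1) if len(out) else []
    return out


def annotate_peaks(
    peaks: pd.DataFrame,
    genome: GenomeAnnotation,
    upstream: int = 2000,
    downstream: int = 200,
    index: FeatureIndex | None = None,
) -> pd.DataFrame:
    """Add the feature category of each peak midpoint (floor of (start+end)/2)."""
    if index is None:
        index = FeatureIndex(genome, upstream, downstream)
    out = peaks.copy()
    cats = []
    for chrom, start, end in zip(out["chrom"], out["start"], out["end"]):
        mid = (int(start) + int(end)) // 2
        cats.append(index.classify(chrom, mid)[0])
    out["feature"] = cats
    return out


def distribution_test(
    categories_a: Iterable[str],
    categories_b: Iterable[str],
    categories: Sequence[str] = ("promoter", "intron", "exon"),
    labels: tuple[str, str] = ("A", "B"),
) -> DistributionTestResult:
    """Pearson chi-squared (no continuity correction) on the 2 x k table of
    peak feature categories per caste; intergenic peaks are excluded before
    tabulation."""
    counts = {}
    for label, cats in zip(labels, (categories_a, categories_b)):
        s = pd.Series([c for c in cats if c in categories], dtype=object)
        counts[label] = [int((s == c).sum()) for c in categories]
    table = pd.DataFrame(counts, index=list(categories)).T
    row_margins = table.sum(axis=1)
    col_margins = table.sum(axis=0)
    for name, margin in row_margins.items():
        if margin == 0:
            raise ValueError(f"zero row margin for caste {name!r}")
    for name, margin in col_margins.items():
        if margin == 0:
            raise ValueError(f"zero column margin for category {name!r}")
    chi2, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return DistributionTestResult(
        table=table, chi_squared=float(chi2), dof=int(dof), p_value=float(p)
    )


def classify_peaks(
    peaksets: Sequence[ReplicatePeakSet],
    genome: GenomeAnnotation | None = None,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    upstream: int = 2000,
    downstream: int = 200,
) -> pd.DataFrame:
    """Consensus + classification (+ annotation when a genome is given)."""
    consensus = build_consensus(peaksets)
    classified = classify_consensus(consensus, fc_threshold=fc_threshold, alpha=alpha)
    if genome is not None:
        classified = annotate_peaks(classified, genome, upstream, downstream)
    return classified


def read_peak_manifest(manifest_path: str | Path) -> list[ReplicatePeakSet]:
    """Read a TSV manifest (caste, replicate, path) of per-replicate BED files."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    base = Path(manifest_path).parent
    peaksets = []
    for row in manifest.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        peaksets.append(
            ReplicatePeakSet(
                caste=str(row.caste),
                replicate=int(row.replicate) - 1,
                peaks=read_bed(path),
            )
        )
    return peaksets
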