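"""Synthetic data generator with a planted ground truth.

Emulates the structure of a two-caste (queen ``Q`` vs worker ``W``), 3-replicate
H3K4me1 ChIP-seq + RNA-seq larval experiment on a single synthetic chromosome:

* a gene annotation (non-overlapping genes, 2-6 exons each);
* per-replicate peak calls containing planted *caste-unique* peaks (present in
  every replicate of one caste, absent from the other), planted *differential*
  peaks (present in both castes with group means differing by a planted log2
  fold change), and background peaks (equal means);
* a gene x sample negative-binomial count matrix with planted differentially
  expressed genes and with expression fold changes rank-correlated, at a
  configurable target Spearman rho, with the planted peak fold changes of the
  genes hosting differential peaks;
* qPCR Ct tables for selected genes with a constant reference gene.

Every planted quantity is recorded in a :class:`TruthManifest`, so downstream
classification, differential testing and integration can be scored against
known truth. All randomness flows from ``SimulationConfig.seed``; identical
configs produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    FeatureIndex,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    promoter_window,
    write_bed,
    write_bedgraph,
    write_counts,
    write_gff3,
    write_table,
)

PEAK_WIDTH = 1000  # typical H3K4me1 domain scale; see docs/methods.md
PEAK_JITTER = 50  # max per-replicate boundary shift, bases
_MIN_PEAK_SEPARATION = 200  # keeps planted peaks unmergeable after jitter
_REFERENCE_GENE = "GAPDH"


class SimulationError(ValueError):
    """Configuration that cannot be realized (e.g. genome too dense)."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults define the study conditions.

    ``nb_dispersion`` is the NB alpha in ``var = mu + alpha * mu**2``.
    ``dropout_prob`` is the probability that a planted caste-unique peak is
    missed in one replicate of its own caste; it exists only to exercise the
    strictness of the all-replicates uniqueness rule.
    """

    seed: int = 0
    chrom_length: int = 5_000_000
    n_genes: int = 500
    n_background_peaks: int = 400
    n_unique_peaks_per_caste: int = 60
    n_differential_peaks: int = 80
    planted_log2fc: float = 2.0
    peak_mean_count: float = 100.0
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    frac_unique_in_promoter_casteB: float = 0.6
    frac_unique_in_intron_casteA: float = 0.6
    n_de_genes: int = 100
    de_log2fc: float = 1.5
    rna_mean_count: float = 200.0
    signal_expression_rho: float = 0.3
    dropout_prob: float = 0.0
    caste_a: str = "Q"
    caste_b: str = "W"
    promoter_upstream: int = 2000
    promoter_downstream: int = 200
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_background_peaks": self.n_background_peaks,
            "n_unique_peaks_per_caste": self.n_unique_peaks_per_caste,
            "n_differential_peaks": self.n_differential_peaks,
            "n_de_genes": self.n_de_genes,
            "n_replicates": self.n_replicates,
            "chrom_length": self.chrom_length,
        }
        for name, value in counts.items():
            if value < 0:
                raise SimulationError(f"{name} must be >= 0, got {value}")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        for name in (
            "frac_unique_in_promoter_casteB",
            "frac_unique_in_intron_casteA",
            "dropout_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise SimulationError("nb_dispersion must be >= 0")
        if not -1.0 <= self.signal_expression_rho <= 1.0:
            raise SimulationError("signal_expression_rho must be in [-1, 1]")
        if self.caste_a == self.caste_b:
            raise SimulationError("caste labels must differ")

    @property
    def castes(self) -> tuple[str, str]:
        return (self.caste_a, self.caste_b)

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{caste}_rep{r + 1}"
            for caste in self.castes
            for r in range(self.n_replicates)
        ]


@dataclass
class ReplicatePeakSet:
    """Peak calls of one (caste, replicate): a BED-like DataFrame."""

    caste: str
    replicate: int
    peaks: pd.DataFrame  # chrom, start, end, name, score, strand

    @property
    def label(self) -> str:
        return f"{self.caste}_rep{self.replicate + 1}"


@dataclass
class TruthManifest:
    """Planted ground truth: per-peak and per-gene records plus the config."""

    peaks: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "params": self.params,
            "peaks": self.peaks.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            peaks=pd.DataFrame(payload["peaks"]),
            genes=pd.DataFrame(payload["genes"]),
            params=payload["params"],
        )


def _nb_draw(rng: np.random.Generator, mean, alpha: float, size=None) -> np.ndarray:
    """NB draws with var = mu + alpha mu^2; alpha=0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes with random exon structure on one chromosome.

    Gene lengths are uniform on [2000, 10000]; intergenic gaps get a fixed
    minimum (room for promoter windows and intergenic peaks) plus a random
    share of the remaining space, so placement never needs rejection sampling
    and the output is deterministic in the seed.
    """
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_genes
    if n == 0:
        return GenomeAnnotation(
            chromosomes={config.chrom_name: config.chrom_length}, genes=[]
        )
    lengths = rng.integers(2000, 10001, size=n)
    min_gap = max(2200, config.promoter_upstream + 200)
    required = int(lengths.sum()) + min_gap * (n + 1)
    if required > config.chrom_length:
        raise SimulationError(
            f"genome too dense: {n} genes need >= {required} bases "
            f"but chrom_length is {config.chrom_length}"
        )
    spare = config.chrom_length - required
    extra = rng.multinomial(spare, np.full(n + 1, 1.0 / (n + 1)))
    gaps = min_gap + extra
    starts = np.cumsum(gaps[:n]) + np.concatenate([[0], np.cumsum(lengths)[:-1]])
    strands = rng.choice(["+", "-"], size=n)
    genes = []
    for i in range(n):
        start, length = int(starts[i]), int(lengths[i])
        n_exons = int(rng.integers(2, 7))
        n_segments = 2 * n_exons - 1  # exon/intron alternation, >=50 bp each
        seg = rng.multinomial(
            length - 50 * n_segments, np.full(n_segments, 1.0 / n_segments)
        ) + 50
        bounds = start + np.concatenate([[0], np.cumsum(seg)])
        exons = [
            (int(bounds[j]), int(bounds[j + 1])) for j in range(0, n_segments, 2)
        ]
        genes.append(
            Gene(
                gene_id=f"gene{i + 1:04d}",
                chrom=config.chrom_name,
                start=start,
                end=start + length,
                strand=str(strands[i]),
                exons=exons,
            )
        )
    return GenomeAnnotation(
        chromosomes={config.chrom_name: config.chrom_length}, genes=genes
    )


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------


def _split_counts(total: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of `total` into len(fractions) bins."""
    raw = np.asarray(fractions, dtype=float) * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


class _Placer:
    """Places planted peak midpoints in requested feature categories without
    letting any two planted peaks come close enough to merge after jitter."""

    def __init__(self, config: SimulationConfig, genome: GenomeAnnotation,
                 rng: np.random.Generator) -> None:
        self.config = config
        self.genome = genome
        self.rng = rng
        self.index = FeatureIndex(
            genome, config.promoter_upstream, config.promoter_downstream
        )
        self.occupied: list[tuple[int, int]] = []  # padded intervals, sorted later
        self.free_genes = list(genome.genes)
        rng.shuffle(self.free_genes)

    def _collides(self, start: int, end: int) -> bool:
        pad = PEAK_JITTER * 2 + _MIN_PEAK_SEPARATION
        return any(start - pad < e and s < end + pad for s, e in self.occupied)

    def _try_midpoint(self, mid: int, category: str | None) -> bool:
        half = PEAK_WIDTH // 2
        start, end = mid - half, mid + half
        if start < PEAK_JITTER or end > self.config.chrom_length - PEAK_JITTER:
            return False
        if self._collides(start, end):
            return False
        if category is not None:
            cat, _ = self.index.classify(self.config.chrom_name, mid)
            if cat != category:
                return False
        self.occupied.append((start, end))
        return True

    def place_in_feature(self, category: str, near_tss: bool = False,
                         max_tries: int = 200) -> tuple[int, Gene]:
        """Pick an unused host gene and a midpoint classifying as `category`.

        Promoter placements with ``near_tss`` centre on the TSS (jitter
        ±100 bp) so aggregate coverage peaks at the TSS, as H3K4me1 does.
        """
        for _ in range(max_tries):
            if not self.free_genes:
                break
            gene = self.free_genes[-1]
            mid = self._candidate_midpoint(gene, category, near_tss)
            if mid is not None and self._try_midpoint(mid, category):
                self.free_genes.pop()
                return mid, gene
            # rotate: try another gene
            self.free_genes.insert(0, self.free_genes.pop())
        raise SimulationError(
            f"insufficient {category} space to place planted peaks"
        )

    def _candidate_midpoint(self, gene: Gene, category: str,
                            near_tss: bool) -> int | None:
        rng = self.rng
        if category == "promoter":
            if near_tss:
                jitter = int(rng.integers(-100, 101))
                return gene.tss + jitter if gene.strand == "+" else gene.tss - jitter
            w = promoter_window(
                gene, self.config.promoter_upstream,
                self.config.promoter_downstream, self.config.chrom_length,
            )
            return int(rng.integers(w.start, w.end))
        pool = gene.introns if category == "intron" else gene.exons
        pool = [(s, e) for s, e in pool if e - s >= 60]
        if not pool:
            return None
        s, e = pool[int(rng.integers(len(pool)))]
        return int(rng.integers(s + 25, e - 25))

    def place_intergenic(self, max_tries: int = 500) -> int:
        gene_starts = np.array([g.start for g in self.genome.genes])
        gene_ends = np.array([g.end for g in self.genome.genes])
        for _ in range(max_tries):
            mid = int(self.rng.integers(
                PEAK_WIDTH, self.config.chrom_length - PEAK_WIDTH
            ))
            inside = np.any((gene_starts <= mid) & (mid < gene_ends))
            if not inside and self._try_midpoint(mid, None):
                return mid
        raise SimulationError("insufficient intergenic space for background peaks")


def simulate_peaks(
    config: SimulationConfig, genome: GenomeAnnotation
) -> tuple[list[ReplicatePeakSet], TruthManifest]:
    """Plant caste-unique, differential, and background peaks.

    Unique peaks appear (with ±50 bp boundary jitter) in every replicate of
    their caste and in no replicate of the other caste, unless
    ``dropout_prob`` removes them from one own-caste replicate. Differential
    peaks appear in all replicates of both castes with NB counts whose group
    means differ by the planted log2 fold change (sign random per peak, with
    a lognormal spread so fold changes vary between peaks). Background peaks
    have equal means in both castes.

    Placement: caste-B unique peaks go to promoters (fraction
    ``frac_unique_in_promoter_casteB``, remainder split intron/exon);
    caste-A unique peaks go to introns (``frac_unique_in_intron_casteA``,
    remainder split promoter/exon); differential peaks go 60% promoter /
    20% intron / 20% exon, each hosted by a distinct gene; background peaks
    are intergenic.
    """
    rng = np.random.default_rng([config.seed, 202])
    placer = _Placer(config, genome, rng)
    records: list[dict] = []

    nu = config.n_unique_peaks_per_caste
    fb = config.frac_unique_in_promoter_casteB
    fa = config.frac_unique_in_intron_casteA
    plans: list[tuple[str, str, bool]] = []  # (class, category, near_tss)
    for cat, k in zip(
        ("promoter", "intron", "exon"),
        _split_counts(nu, [fb, (1 - fb) / 2, (1 - fb) / 2]),
    ):
        plans += [(f"unique_{config.caste_b}", cat, cat == "promoter")] * k
    for cat, k in zip(
        ("intron", "promoter", "exon"),
        _split_counts(nu, [fa, (1 - fa) / 2, (1 - fa) / 2]),
    ):
        plans += [(f"unique_{config.caste_a}", cat, cat == "promoter")] * k
    for cat, k in zip(
        ("promoter", "intron", "exon"),
        _split_counts(config.n_differential_peaks, [0.6, 0.2, 0.2]),
    ):
        plans += [("differential", cat, cat == "promoter")] * k

    for cls, cat, near in plans:
        mid, gene = placer.place_in_feature(cat, near_tss=near)
        records.append(
            dict(true_class=cls, feature=cat, midpoint=mid, gene_id=gene.gene_id)
        )
    for _ in range(config.n_background_peaks):
        mid = placer.place_intergenic()
        records.append(
            dict(true_class="background", feature="intergenic", midpoint=mid,
                 gene_id=None)
        )

    truth = pd.DataFrame(
        records, columns=["true_class", "feature", "midpoint", "gene_id"]
    )
    truth["peak_id"] = [f"pk{i + 1:05d}" for i in range(len(truth))]
    truth["chrom"] = config.chrom_name
    half = PEAK_WIDTH // 2
    truth["start"] = truth["midpoint"] - half
    truth["end"] = truth["midpoint"] + half

    # planted fold changes (caste A over caste B, log2 scale)
    log2fc = np.zeros(len(truth))
    is_diff = (truth["true_class"] == "differential").to_numpy()
    n_diff = int(is_diff.sum())
    signs = rng.choice([-1.0, 1.0], size=n_diff)
    # lognormal spread gives continuous, rankable fold changes while keeping
    # essentially all planted peaks above the 2-fold detection threshold
    spread = np.exp(rng.normal(0.0, 0.15, size=n_diff))
    log2fc[is_diff] = signs * config.planted_log2fc * spread
    log2fc[truth["true_class"] == f"unique_{config.caste_a}"] = np.inf
    log2fc[truth["true_class"] == f"unique_{config.caste_b}"] = -np.inf
    truth["log2fc"] = log2fc

    # per-replicate NB signals and jittered intervals
    peaksets: list[ReplicatePeakSet] = []
    dropout_rep = rng.integers(0, config.n_replicates, size=len(truth))
    dropout_fire = rng.random(len(truth)) < config.dropout_prob
    jitter = rng.integers(
        -PEAK_JITTER, PEAK_JITTER + 1,
        size=(len(truth), 2, config.n_replicates),
    )
    lfc = truth["log2fc"].to_numpy()
    finite = np.where(np.isfinite(lfc), lfc, 0.0)
    mean_a = np.where(
        np.isposinf(lfc), config.peak_mean_count,
        np.where(np.isneginf(lfc), 0.0,
                 config.peak_mean_count * np.exp2(finite / 2)),
    )
    mean_b = np.where(
        np.isneginf(lfc), config.peak_mean_count,
        np.where(np.isposinf(lfc), 0.0,
                 config.peak_mean_count * np.exp2(-finite / 2)),
    )
    for ci, caste in enumerate(config.castes):
        means = mean_a if ci == 0 else mean_b
        for r in range(config.n_replicates):
            scores = np.maximum(
                _nb_draw(rng, np.maximum(means, 1e-9), config.nb_dispersion), 1
            )
            present = means > 0
            own = truth["true_class"] == f"unique_{caste}"
            drop = own.to_numpy() & dropout_fire & (dropout_rep == r)
            present = present & ~drop
            shift = jitter[:, ci, r]
            sub = pd.DataFrame(
                {
                    "chrom": truth["chrom"],
                    "start": truth["start"] + shift,
                    "end": truth["end"] + shift,
                    "name": truth["peak_id"],
                    "score": scores.astype(float),
                    "strand": ".",
                }
            )[present]
            sub = sub.sort_values(["start", "end"]).reset_index(drop=True)
            peaksets.append(ReplicatePeakSet(caste=caste, replicate=r, peaks=sub))

    cols = ["peak_id", "chrom", "start", "end", "true_class", "feature",
            "gene_id", "log2fc"]
    manifest = TruthManifest(
        peaks=truth[cols].copy(),
        params={k: v for k, v in asdict(config).items()},
    )
    return peaksets, manifest


def peak_coverage(
    peaksets: Iterable[ReplicatePeakSet], chrom_length: int
) -> dict[str, np.ndarray]:
    """Mean per-base peak signal per caste (averaged over replicates).

    Each peak contributes a triangular profile rising from its edges to a
    summit at its midpoint — the shape of a fragment pileup — scaled so the
    summit equals the peak score. A flat box would leave the TSS metaprofile
    with a plateau whose argmax is arbitrary; a summit makes it identifiable.
    """
    by_caste: dict[str, list[np.ndarray]] = {}
    for ps in peaksets:
        arr = np.zeros(chrom_length)
        for s, e, v in zip(ps.peaks["start"], ps.peaks["end"], ps.peaks["score"]):
            s, e = max(int(s), 0), min(int(e), chrom_length)
            if s >= e:
                continue
            mid = (s + e) / 2.0
            half = (e - s) / 2.0
            pos = np.arange(s, e)
            arr[s:e] += v * (1.0 - np.abs(pos + 0.5 - mid) / half)
        by_caste.setdefault(ps.caste, []).append(arr)
    return {caste: np.mean(arrs, axis=0) for caste, arrs in by_caste.items()}


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig, genome: GenomeAnnotation, truth: TruthManifest
) -> tuple[pd.DataFrame, pd.DataFrame, TruthManifest]:
    """NB count matrix with planted DE genes and peak-correlated effects.

    Genes hosting planted differential peaks receive expression log2 fold
    changes generated from a Gaussian copula on the ranks of their peak
    log2 fold changes, with Pearson parameter ``r = 2 sin(pi * rho / 6)`` so
    the planted Spearman correlation matches ``signal_expression_rho``.
    ``n_de_genes`` further genes (disjoint from the peak hosts) receive a
    ±``de_log2fc`` shift. All other genes are exact nulls.

    Returns ``(counts, samples, truth)`` where ``samples`` maps sample id to
    caste and ``truth.genes`` records the planted per-gene effects.
    """
    rng = np.random.default_rng([config.seed, 303])
    gene_ids = genome.gene_ids
    n = len(gene_ids)
    expr_lfc = pd.Series(np.zeros(n), index=gene_ids)
    chrom_lfc = pd.Series(np.full(n, np.nan), index=gene_ids)

    diff = truth.peaks[truth.peaks["true_class"] == "differential"]
    host = diff.dropna(subset=["gene_id"]).groupby("gene_id")["log2fc"].mean()
    host = host[[g in set(gene_ids) for g in host.index]]
    if len(host):
        chrom_lfc[host.index] = host.to_numpy()
        ranks = stats.rankdata(host.to_numpy())
        # Blom normal scores of the peak-log2FC ranks
        a = stats.norm.ppf((ranks - 0.375) / (len(ranks) + 0.25))
        r = 2.0 * np.sin(np.pi * config.signal_expression_rho / 6.0)
        b = r * a + np.sqrt(max(1.0 - r * r, 0.0)) * rng.normal(size=len(ranks))
        expr_lfc[host.index] = 0.5 * b

    if config.n_de_genes > n:
        raise SimulationError(
            f"n_de_genes={config.n_de_genes} exceeds n_genes={n}"
        )
    candidates = [g for g in gene_ids if g not in set(host.index)]
    if config.n_de_genes > len(candidates):
        raise SimulationError(
            "n_de_genes exceeds the number of genes without planted peaks"
        )
    de_genes = list(rng.choice(candidates, size=config.n_de_genes, replace=False))
    de_signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    expr_lfc[de_genes] = de_signs * config.de_log2fc

    samples = pd.DataFrame(
        {
            "sample": config.sample_names,
            "caste": [s.split("_")[0] for s in config.sample_names],
        }
    )
    depth = np.exp(rng.normal(0.0, 0.15, size=len(samples)))
    mu_a = config.rna_mean_count * np.exp2(expr_lfc.to_numpy() / 2)
    mu_b = config.rna_mean_count * np.exp2(-expr_lfc.to_numpy() / 2)
    cols = {}
    for j, (name, caste) in enumerate(zip(samples["sample"], samples["caste"])):
        mu = mu_a if caste == config.caste_a else mu_b
        cols[name] = _nb_draw(rng, mu * depth[j], config.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))

    lengths = pd.Series(
        {g.gene_id: g.transcript_length for g in genome.genes}, name="length"
    )
    truth.genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_de": [g in set(de_genes) for g in gene_ids],
            "expr_log2fc": expr_lfc.to_numpy(),
            "chrom_log2fc": chrom_lfc.to_numpy(),
            "length": lengths[gene_ids].to_numpy(),
        }
    )
    return counts, samples, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    truth: TruthManifest,
    genes: Sequence[str],
    config: SimulationConfig,
    sigma: float = 0.2,
    reference_gene: str = _REFERENCE_GENE,
) -> pd.DataFrame:
    """Ct table for target `genes` plus a constant-expectation reference gene.

    ``Ct = baseline - log2(relative expression) + Normal(0, sigma)``; the
    relative expression of a target in caste A is ``2^(expr_log2fc/2)`` and
    in caste B ``2^(-expr_log2fc/2)``, so the fold change A vs B recovered by
    the ddCt method equals ``2^expr_log2fc`` at sigma=0.
    """
    rng = np.random.default_rng([config.seed, 404])
    if truth.genes.empty:
        raise SimulationError("truth manifest has no gene records yet")
    lfc = truth.genes.set_index("gene_id")["expr_log2fc"]
    unknown = [g for g in genes if g not in lfc.index]
    if unknown:
        raise SimulationError(f"unknown gene id(s): {unknown}")
    rows = []
    for caste in config.castes:
        sign = 1.0 if caste == config.caste_a else -1.0
        for r in range(config.n_replicates):
            sample = f"{caste}_rep{r + 1}"
            rows.append(
                (sample, caste, reference_gene,
                 15.0 + rng.normal(0.0, sigma) if sigma > 0 else 15.0)
            )
            for g in genes:
                rel = np.exp2(sign * lfc[g] / 2)
                noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                rows.append((sample, caste, g, 20.0 - np.log2(rel) + noise))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


# ---------------------------------------------------------------------------
# writing a full simulated dataset
# ---------------------------------------------------------------------------


def write_simulation(
    config: SimulationConfig,
    outdir: str | Path,
    qpcr_genes: Sequence[str] | None = None,
) -> dict[str, Path]:
    """Run the full simulator and write all artifacts; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    peaksets, truth = simulate_peaks(config, genome)
    counts, samples, truth = simulate_expression(config, genome, truth)
    if qpcr_genes is None:
        de = truth.genes[truth.genes["is_de"]]
        qpcr_genes = list(de["gene_id"].head(5))
    paths: dict[str, Path] = {}
    paths["gff3"] = outdir / "genome.gff3"
    write_gff3(genome, paths["gff3"])
    for ps in peaksets:
        p = outdir / f"{ps.label}.bed"
        write_bed(ps.peaks, p)
        paths[f"bed_{ps.label}"] = p
    coverage = peak_coverage(peaksets, config.chrom_length)
    for caste, arr in coverage.items():
        p = outdir / f"{caste}_coverage.bedgraph"
        write_bedgraph({config.chrom_name: arr}, p)
        paths[f"bedgraph_{caste}"] = p
    paths["counts"] = outdir / "counts.tsv"
    write_counts(counts, paths["counts"])
    paths["samples"] = outdir / "samples.tsv"
    write_table(samples, paths["samples"])
    if qpcr_genes:
        ct = simulate_qpcr(truth, qpcr_genes, config)
        paths["qpcr"] = outdir / "qpcr_ct.tsv"
        write_table(ct, paths["qpcr"])
    paths["truth"] = outdir / "truth.json"
    truth.to_json(paths["truth"])
    return paths
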