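"""Genome annotation, interval geometry, and file I/O.

Canonical coordinate convention throughout the package: 0-based, half-open
intervals (BED-like). GFF3 uses 1-based closed coordinates on disk; the
conversion happens in :func:`read_gff3` / :func:`write_gff3` and nowhere
else — no internal function accepts 1-based input.

Feature categories form a closed vocabulary (``promoter``, ``exon``,
``intron``, ``intergenic``) with precedence promoter > exon > intron >
intergenic when a position falls in several features at once.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from intervaltree import IntervalTree

#: Default promoter window around the TSS, in bases. The window runs
#: ``upstream`` bases 5' of the TSS to ``downstream`` bases 3' of it,
#: strand-aware. 2 kb / 200 bp is a conventional promoter definition;
#: it is configurable everywhere it is used.
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 200

FEATURE_CATEGORIES = ("promoter", "exon", "intron", "intergenic")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class GenomeIOError(ValueError):
    """Malformed annotation or interval input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise GenomeIOError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class Gene:
    """A gene model: span, strand, and sorted non-overlapping exons.

    Coordinates are canonical (0-based half-open). The TSS coordinate is
    ``start`` for + genes and ``end`` for − genes; as a half-open boundary
    it sits immediately 5' of the first transcribed base on either strand,
    so window arithmetic is symmetric between strands.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise GenomeIOError(f"gene {self.gene_id}: invalid span")
        self.exons = sorted(self.exons)
        prev_end = self.start
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise GenomeIOError(f"gene {self.gene_id}: exon outside gene")
            if s < prev_end:
                raise GenomeIOError(f"gene {self.gene_id}: overlapping exons")
            if s >= e:
                raise GenomeIOError(f"gene {self.gene_id}: empty exon")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i][1] < self.exons[i + 1][0]
        ]

    @property
    def transcript_length(self) -> int:
        """Summed exon length, used as the FPKM length denominator."""
        return sum(e - s for s, e in self.exons) if self.exons else self.end - self.start

    def tss_distance(self, position: int) -> int:
        """Signed distance from the TSS; negative values are upstream."""
        return position - self.tss if self.strand == "+" else self.tss - position


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus a list of gene models."""

    chromosomes: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise GenomeIOError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
            length = self.chromosomes.get(g.chrom)
            if length is not None and g.end > length:
                raise GenomeIOError(
                    f"gene {g.gene_id} extends past end of {g.chrom}"
                )
        self.genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def promoter_window(
    gene: Gene,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    For a + gene the window is ``[TSS-upstream, TSS+downstream)``; for a −
    gene it is ``[TSS-downstream, TSS+upstream)``. A zero-width request
    degenerates to a 1-base window at the TSS so parameter sweeps over
    window sizes stay total.
    """
    if upstream < 0 or downstream < 0:
        raise GenomeIOError("promoter window sizes must be >= 0")
    t = gene.tss
    if gene.strand == "+":
        start, end = t - upstream, t + downstream
    else:
        start, end = t - downstream, t + upstream
    if start == end:  # degenerate: pin to the first transcribed base
        start, end = (t, t + 1) if gene.strand == "+" else (t - 1, t)
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end, gene.strand)


class FeatureIndex:
    """Interval-tree index of promoters, exons and introns for position lookup.

    Built once per annotation; :meth:`classify` applies the category
    precedence promoter > exon > intron > intergenic, breaking ties among
    genes within a category by absolute TSS distance, then gene id.
    """

    def __init__(
        self,
        genome: GenomeAnnotation,
        upstream: int = PROMOTER_UPSTREAM,
        downstream: int = PROMOTER_DOWNSTREAM,
    ) -> None:
        self.genome = genome
        self.upstream = upstream
        self.downstream = downstream
        self._trees: dict[str, dict[str, IntervalTree]] = {
            cat: {} for cat in ("promoter", "exon", "intron")
        }
        self._genes = {g.gene_id: g for g in genome.genes}
        for g in genome.genes:
            chrom_len = genome.chromosomes.get(g.chrom)
            w = promoter_window(g, upstream, downstream, chrom_len)
            self._add("promoter", g.chrom, w.start, w.end, g.gene_id)
            for s, e in g.exons:
                self._add("exon", g.chrom, s, e, g.gene_id)
            for s, e in g.introns:
                self._add("intron", g.chrom, s, e, g.gene_id)

    def _add(self, cat: str, chrom: str, start: int, end: int, gid: str) -> None:
        if start < end:
            self._trees[cat].setdefault(chrom, IntervalTree()).addi(start, end, gid)

    def hits(self, chrom: str, position: int, category: str) -> list[str]:
        tree = self._trees[category].get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(position))

    def classify(self, chrom: str, position: int) -> tuple[str, str | None]:
        """Return ``(category, gene_id)`` for a single base position."""
        for cat in ("promoter", "exon", "intron"):
            gids = self.hits(chrom, position, cat)
            if gids:
                best = min(
                    gids,
                    key=lambda gid: (abs(self._genes[gid].tss_distance(position)), gid),
                )
                return cat, best
        return "intergenic", None


def classify_position(
    position: int,
    genome: GenomeAnnotation,
    chrom: str | None = None,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
    index: FeatureIndex | None = None,
) -> str:
    """Feature category of one genomic base (see :class:`FeatureIndex`)."""
    if index is None:
        index = FeatureIndex(genome, upstream, downstream)
    if chrom is None:
        chrom = next(iter(genome.chromosomes))
    return index.classify(chrom, position)[0]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read gene/exon models from GFF3 (1-based closed) into canonical coords.

    Chromosome lengths are taken from ``##sequence-region`` directives when
    present. Raises :class:`GenomeIOError` with a line number on malformed
    lines and on exons lying outside their parent gene.
    """
    with _open_text(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise GenomeIOError(f"{path}: malformed GFF3 line {lineno}: {line!r}")
    chromosomes: dict[str, int] = {}
    if not text.strip() or all(
        ln.startswith("#") or not ln.strip() for ln in text.splitlines()
    ):
        for ln in text.splitlines():
            if ln.startswith("##sequence-region"):
                _, name, _one, length = ln.split()
                chromosomes[name] = int(length)
        return GenomeAnnotation(chromosomes=chromosomes, genes=[])
    db = gffutils.create_db(
        text, ":memory:", from_string=True, keep_order=True, merge_strategy="error"
    )
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            _, name, _one, length = directive.split()
            chromosomes[name] = int(length)
    genes: list[Gene] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [
            (e.start - 1, e.end)  # GFF3 1-based closed -> 0-based half-open
            for e in db.children(feat, featuretype="exon", order_by="start")
        ]
        gene = Gene(
            gene_id=feat.id,
            chrom=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand,
            exons=exons,
        )
        genes.append(gene)
        if gene.chrom not in chromosomes:
            chromosomes.setdefault(gene.chrom, 0)
            chromosomes[gene.chrom] = max(chromosomes[gene.chrom], gene.end)
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes)


def write_gff3(genome: GenomeAnnotation, path: str | Path) -> None:
    """Write the annotation as GFF3; inverse of :func:`read_gff3`."""
    lines = ["##gff-version 3"]
    for name, length in genome.chromosomes.items():
        lines.append(f"##sequence-region {name} 1 {length}")
    for g in genome.genes:
        lines.append(
            "\t".join(
                [g.chrom, "castechip", "gene", str(g.start + 1), str(g.end), ".",
                 g.strand, ".", f"ID={g.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(g.exons, start=1):
            lines.append(
                "\t".join(
                    [g.chrom, "castechip", "exon", str(s + 1), str(e), ".",
                     g.strand, ".", f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED / bedGraph / TSV tables
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, chromosomes: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Read a BED3-6 file into a DataFrame with canonical columns.

    Unknown chromosomes only warn (peak files may precede the annotation);
    ``start >= end`` is an error.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=BED_COLUMNS, usecols=range(6), dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS)
    except ValueError:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        df.columns = BED_COLUMNS[: df.shape[1]]
        for col in BED_COLUMNS[df.shape[1]:]:
            df[col] = "." if col in ("name", "strand") else 0.0
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise GenomeIOError(f"{path}: start >= end at data line {bad[0] + 1}")
    if (df["start"] < 0).any():
        raise GenomeIOError(f"{path}: negative start coordinate")
    if chromosomes is not None:
        unknown = set(df["chrom"]) - set(chromosomes)
        if unknown:
            import warnings

            warnings.warn(f"{path}: unknown chromosomes {sorted(unknown)}")
    df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0.0)
    return df.reset_index(drop=True)


def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    df = peaks.copy()
    for col in BED_COLUMNS:
        if col not in df:
            df[col] = "." if col in ("name", "strand") else 0.0
    df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"], dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    if (df["start"] >= df["end"]).any():
        raise GenomeIOError(f"{path}: start >= end in bedGraph")
    return df


def write_bedgraph(coverage: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Run-length encode per-base coverage arrays into 4-column bedGraph."""
    rows = []
    for chrom in coverage:
        values = np.asarray(coverage[chrom], dtype=float)
        if values.size == 0:
            continue
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [values.size]])
        for s, e in zip(starts, ends):
            if values[s] != 0:
                rows.append((chrom, int(s), int(e), float(values[s])))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def bedgraph_to_array(df: pd.DataFrame, chrom: str, length: int) -> np.ndarray:
    arr = np.zeros(length, dtype=float)
    sub = df[df["chrom"] == chrom]
    for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
        arr[int(s): min(int(e), length)] += v
    return arr


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x sample count table: first column gene ids, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise GenomeIOError(f"{path}: duplicate gene ids")
    if (df.values < 0).any():
        raise GenomeIOError(f"{path}: negative counts")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
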