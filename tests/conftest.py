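"""Shared fixtures: a tiny hand-built genome and small simulation configs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from castechip.genome_io import Gene, GenomeAnnotation
from castechip.synth import SimulationConfig


@pytest.fixture()
def tiny_genome() -> GenomeAnnotation:
    """Three genes (two +, one −) on a 10 kb chromosome, small enough for
    exhaustive per-base oracles. Gene g2's promoter window overlaps g1's tail
    so precedence rules are exercised."""
    return GenomeAnnotation(
        chromosomes={"chr1": 10_000},
        genes=[
            Gene("g1", "chr1", 1_000, 3_000, "+",
                 exons=[(1_000, 1_400), (1_800, 2_200), (2_600, 3_000)]),
            Gene("g2", "chr1", 4_000, 6_000, "+",
                 exons=[(4_000, 4_500), (5_500, 6_000)]),
            Gene("g3", "chr1", 7_000, 9_500, "-",
                 exons=[(7_000, 7_600), (8_400, 9_500)]),
        ],
    )


@pytest.fixture()
def small_config() -> SimulationConfig:
    """Simulation small enough for per-test use but structurally complete."""
    return SimulationConfig(
        seed=7,
        chrom_length=1_500_000,
        n_genes=120,
        n_background_peaks=80,
        n_unique_peaks_per_caste=20,
        n_differential_peaks=24,
        n_de_genes=30,
    )


def brute_force_category(
    genome: GenomeAnnotation, position: int, upstream: int = 2000,
    downstream: int = 200,
) -> tuple[str, str | None]:
    """Independent per-base classifier: explicit loops, no interval trees.

    Precedence promoter > exon > intron > intergenic; ties within a category
    resolve by absolute TSS distance then gene id.
    """
    hits: dict[str, list[str]] = {"promoter": [], "exon": [], "intron": []}
    for g in genome.genes:
        t = g.start if g.strand == "+" else g.end
        if g.strand == "+":
            lo, hi = t - upstream, t + downstream
        else:
            lo, hi = t - downstream, t + upstream
        if lo == hi:
            lo, hi = (t, t + 1) if g.strand == "+" else (t - 1, t)
        lo = max(lo, 0)
        hi = min(hi, genome.chromosomes[g.chrom])
        if lo <= position < hi:
            hits["promoter"].append(g.gene_id)
        for s, e in g.exons:
            if s <= position < e:
                hits["exon"].append(g.gene_id)
        for i in range(len(g.exons) - 1):
            if g.exons[i][1] <= position < g.exons[i + 1][0]:
                hits["intron"].append(g.gene_id)
    for cat in ("promoter", "exon", "intron"):
        if hits[cat]:
            def key(gid: str):
                g = next(x for x in genome.genes if x.gene_id == gid)
                t = g.start if g.strand == "+" else g.end
                d = position - t if g.strand == "+" else t - position
                return (abs(d), gid)
            return cat, min(hits[cat], key=key)
    return "intergenic", None
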