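"""Consensus merging, unique/differential classification, distribution test."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from castechip import peaks as pk
from castechip.synth import (
    ReplicatePeakSet,
    SimulationConfig,
    simulate_genome,
    simulate_peaks,
)


def _peakset(caste, rep, intervals, scores=None):
    scores = scores if scores is not None else [10.0] * len(intervals)
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [s for s, _ in intervals],
            "end": [e for _, e in intervals],
            "name": [f"{caste}{rep}_{i}" for i in range(len(intervals))],
            "score": scores,
            "strand": ".",
        }
    )
    return ReplicatePeakSet(caste=caste, replicate=rep, peaks=df)


class TestClassifyUnique:
    def test_all_in_one_none_in_other(self):
        assert pk.classify_unique([1, 1, 1], [0, 0, 0]) == "A"
        assert pk.classify_unique([0, 0, 0], [1, 1, 1]) == "B"

    def test_partial_presence_is_not_unique(self):
        assert pk.classify_unique([1, 1, 0], [0, 0, 0]) is None

    def test_exhaustive_truth_table_n3(self):
        # all 2^6 presence patterns against an independently written rule
        for pattern in itertools.product([False, True], repeat=6):
            a, b = pattern[:3], pattern[3:]
            expected = None
            if all(a) and not any(b):
                expected = "A"
            elif all(b) and not any(a):
                expected = "B"
            assert pk.classify_unique(a, b) == expected, pattern


class TestBuildConsensus:
    def test_identical_intervals_in_six_replicates(self):
        sets = [
            _peakset(c, r, [(100, 1100)])
            for c in ("Q", "W") for r in range(3)
        ]
        cons = pk.build_consensus(sets)
        assert len(cons.intervals) == 1
        assert cons.presence.all()

    def test_two_disjoint_intervals(self):
        sets = [_peakset("Q", 0, [(0, 100), (200, 300)]),
                _peakset("W", 0, [(0, 100)])]
        cons = pk.build_consensus(sets)
        assert len(cons.intervals) == 2

    def test_touching_intervals_do_not_merge(self):
        sets = [_peakset("Q", 0, [(0, 100)]), _peakset("W", 0, [(100, 200)])]
        cons = pk.build_consensus(sets)
        assert len(cons.intervals) == 2

    def test_empty_input_gives_empty_output(self):
        cons = pk.build_consensus(
            [_peakset("Q", 0, []), _peakset("W", 0, [])]
        )
        assert len(cons.intervals) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_interval_graph_components(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        intervals = []
        for _ in range(n):
            s = int(rng.integers(0, 5_000))
            intervals.append((s, s + int(rng.integers(50, 400))))
        # split intervals arbitrarily over 6 replicates
        assignment = rng.integers(0, 6, size=n)
        sets = []
        for j, (c, r) in enumerate([(c, r) for c in "QW" for r in range(3)]):
            ivs = [iv for iv, a in zip(intervals, assignment) if a == j]
            sets.append(_peakset(c, r, ivs))
        cons = pk.build_consensus(sets)

        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                a, b = intervals[i], intervals[j]
                if a[0] < b[1] and b[0] < a[1]:
                    g.add_edge(i, j)
        expected = sorted(
            (min(intervals[i][0] for i in comp), max(intervals[i][1] for i in comp))
            for comp in nx.connected_components(g)
        )
        got = sorted(zip(cons.intervals["start"], cons.intervals["end"]))
        assert got == expected


class TestDifferentialTest:
    def test_identical_signals_not_differential(self):
        fc, p, direction = pk.test_differential([100, 100, 100], [100, 100, 100])
        assert fc == 1.0
        assert direction is None

    def test_welch_matches_textbook_computation(self):
        a, b, c = np.array([400.0, 410.0, 390.0]), np.array([100.0, 95.0, 105.0]), 1.0
        fc, p, direction = pk.test_differential(a, b, pseudocount=c)
        # independent textbook Welch on log2(x + 1)
        la, lb = np.log2(a + c), np.log2(b + c)
        va, vb = la.var(ddof=1) / 3, lb.var(ddof=1) / 3
        t = (la.mean() - lb.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy.stats import t as tdist

        p_expected = 2 * tdist.sf(abs(t), df)
        assert fc == pytest.approx((a.mean() + c) / (b.mean() + c), abs=1e-12)
        assert p == pytest.approx(p_expected, abs=1e-10)
        assert direction == "A"

    def test_fold_change_gate(self):
        # clearly significant but below 2-fold: must not classify
        fc, p, direction = pk.test_differential(
            [150.0, 150.1, 149.9], [100.0, 100.1, 99.9]
        )
        assert p < 0.05 and max(fc, 1 / fc) < 2
        assert direction is None

    def test_alpha_gate(self):
        # above 2-fold but noisy: must not classify
        fc, p, direction = pk.test_differential(
            [300.0, 40.0, 500.0], [100.0, 90.0, 110.0]
        )
        assert max(fc, 1 / fc) > 2 and p > 0.05
        assert direction is None

    def test_direction_b(self):
        fc, p, direction = pk.test_differential(
            [100.0, 95.0, 105.0], [400.0, 410.0, 390.0]
        )
        assert direction == "B"
        assert fc < 1


def _simulated_classification(seed=4, **overrides):
    fields = dict(
        chrom_length=1_500_000, n_genes=120, n_background_peaks=60,
        n_unique_peaks_per_caste=15, n_differential_peaks=20,
    )
    fields.update(overrides)
    cfg = SimulationConfig(seed=seed, **fields)
    genome = simulate_genome(cfg)
    peaksets, truth = simulate_peaks(cfg, genome)
    return cfg, genome, peaksets, truth


class TestClassifyConsensus:
    def test_every_peak_gets_exactly_one_class(self):
        _, _, peaksets, _ = _simulated_classification()
        cons = pk.build_consensus(peaksets)
        classified = pk.classify_consensus(cons)
        valid = {"unique_Q", "unique_W", "differential_up_Q",
                 "differential_up_W", "shared", "unresolved"}
        assert classified["peak_class"].notna().all()
        assert set(classified["peak_class"]) <= valid
        assert len(classified) >= 1

    def test_threshold_monotonicity(self):
        _, _, peaksets, _ = _simulated_classification()
        cons = pk.build_consensus(peaksets)

        def n_diff(fc, alpha):
            cl = pk.classify_consensus(cons, fc_threshold=fc, alpha=alpha)
            return cl["peak_class"].str.startswith("differential").sum()

        assert n_diff(2.0, 0.05) >= n_diff(3.0, 0.05) >= n_diff(4.0, 0.05)
        assert n_diff(2.0, 0.05) >= n_diff(2.0, 0.01) >= n_diff(2.0, 0.001)

    def test_caste_swap_symmetry(self):
        _, _, peaksets, _ = _simulated_classification()
        fwd = pk.classify_consensus(pk.build_consensus(peaksets))
        swapped = pk.classify_consensus(
            pk.build_consensus(
                [ps for ps in peaksets if ps.caste == "W"]
                + [ps for ps in peaksets if ps.caste == "Q"]
            )
        )
        assert (fwd["peak_class"] == "unique_Q").sum() == (
            swapped["peak_class"] == "unique_Q"
        ).sum()  # labels are caste names, so counts are preserved
        merged = fwd.merge(swapped, on=["chrom", "start", "end"],
                           suffixes=("_f", "_s"))
        np.testing.assert_allclose(
            merged["fold_change_f"], 1.0 / merged["fold_change_s"], rtol=1e-12
        )

    def test_planted_uniques_recovered_strictly(self):
        cfg, _, peaksets, truth = _simulated_classification(seed=9)
        classified = pk.classify_consensus(pk.build_consensus(peaksets))
        planted = truth.peaks[truth.peaks["true_class"].str.startswith("unique")]
        hits = 0
        for row in planted.itertuples(index=False):
            overlap = classified[
                (classified["start"] < row.end) & (row.start < classified["end"])
            ]
            assert len(overlap) == 1
            if overlap.iloc[0]["peak_class"] == row.true_class:
                hits += 1
        assert hits == len(planted)

    def test_dropout_breaks_uniqueness(self):
        cfg, _, peaksets, truth = _simulated_classification(
            seed=13, dropout_prob=1.0, n_background_peaks=0,
            n_differential_peaks=0,
        )
        classified = pk.classify_consensus(pk.build_consensus(peaksets))
        assert not classified["peak_class"].str.startswith("unique").any()


class TestAnnotatePeaks:
    def test_midpoint_rule_straddling_boundary(self, tiny_genome):
        # peak straddles g1 promoter/first-exon boundary at 1000 with the
        # midpoint in the exon (promoter downstream window ends at 1200)
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [900], "end": [1700], "peak_id": ["p1"]}
        )
        annotated = pk.annotate_peaks(peaks, tiny_genome)
        assert annotated.loc[0, "feature"] == "exon"

    def test_agrees_with_per_base_oracle(self, tiny_genome):
        from conftest import brute_force_category

        rng = np.random.default_rng(1)
        starts = rng.integers(0, 9_000, size=500)
        peaks = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 800,
             "peak_id": [f"p{i}" for i in range(500)]}
        )
        annotated = pk.annotate_peaks(peaks, tiny_genome)
        for row in annotated.itertuples(index=False):
            mid = (row.start + row.end) // 2
            assert row.feature == brute_force_category(tiny_genome, mid)[0]


class TestDistributionTest:
    def test_identical_distributions_give_zero(self):
        res = pk.distribution_test(
            ["promoter"] * 10 + ["intron"] * 10 + ["exon"] * 10,
            ["promoter"] * 10 + ["intron"] * 10 + ["exon"] * 10,
        )
        assert res.chi_squared == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_by_two(self):
        res = pk.distribution_test(
            ["promoter"] * 20 + ["intron"] * 10,
            ["promoter"] * 10 + ["intron"] * 20,
            categories=("promoter", "intron"),
        )
        assert res.chi_squared == pytest.approx(20 / 3, abs=1e-9)
        assert res.dof == 1
        assert res.p_value == pytest.approx(0.009823274507519235, abs=1e-9)

    def test_intergenic_excluded(self):
        res = pk.distribution_test(
            ["promoter", "intron", "exon", "intergenic", "intergenic"],
            ["promoter", "intron", "exon"],
        )
        assert res.table.to_numpy().sum() == 6

    def test_zero_margin_is_named(self):
        with pytest.raises(ValueError, match="exon"):
            pk.distribution_test(
                ["promoter", "intron"], ["promoter", "intron"],
            )
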