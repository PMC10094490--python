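"""Simulator correctness: determinism, planted structure, noise models."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from castechip import genome_io as gio
from castechip.synth import (
    SimulationConfig,
    SimulationError,
    _nb_draw,
    simulate_expression,
    simulate_genome,
    simulate_peaks,
    simulate_qpcr,
    write_simulation,
)
from castechip.qpcr import delta_delta_ct


class TestSimulateGenome:
    def test_zero_genes_is_valid_and_writable(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_genes=0)
        genome = simulate_genome(cfg)
        assert len(genome) == 0
        p = tmp_path / "empty.gff3"
        gio.write_gff3(genome, p)
        assert len(gio.read_gff3(p)) == 0

    def test_byte_identical_given_seed(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_genes=40, chrom_length=600_000)
        for name in ("a", "b"):
            gio.write_gff3(simulate_genome(cfg), tmp_path / f"{name}.gff3")
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_genes_pairwise_disjoint_by_quadratic_scan(self):
        genome = simulate_genome(SimulationConfig(seed=5, n_genes=500))
        spans = [(g.start, g.end) for g in genome.genes]
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                a, b = spans[i], spans[j]
                assert a[1] <= b[0] or b[1] <= a[0]
            assert 0 <= spans[i][0] < spans[i][1] <= genome.chromosomes["chr1"]

    def test_too_dense_raises(self):
        with pytest.raises(SimulationError, match="genome too dense"):
            simulate_genome(SimulationConfig(seed=1, n_genes=500,
                                             chrom_length=2_000_000))

    def test_exon_counts_in_range(self):
        genome = simulate_genome(SimulationConfig(seed=2, n_genes=50,
                                                  chrom_length=800_000))
        for g in genome.genes:
            assert 2 <= len(g.exons) <= 6
            assert 2_000 <= g.end - g.start <= 10_000


def _presence_by_scan(truth_row, peakset) -> bool:
    """Brute-force: does any replicate interval overlap this planted peak?"""
    for s, e in zip(peakset.peaks["start"], peakset.peaks["end"]):
        if truth_row.start < e and s < truth_row.end:
            return True
    return False


class TestSimulatePeaks:
    def test_unique_peaks_present_exactly_in_own_caste(self, small_config):
        genome = simulate_genome(small_config)
        peaksets, truth = simulate_peaks(small_config, genome)
        uw = truth.peaks[truth.peaks["true_class"] == "unique_W"]
        assert len(uw) == small_config.n_unique_peaks_per_caste
        for row in uw.itertuples(index=False):
            for ps in peaksets:
                present = _presence_by_scan(row, ps)
                assert present == (ps.caste == "W"), (row.peak_id, ps.label)

    def test_dropout_removes_one_own_replicate(self):
        cfg = SimulationConfig(seed=11, chrom_length=1_500_000, n_genes=120,
                               n_background_peaks=0, n_differential_peaks=0,
                               n_unique_peaks_per_caste=15, dropout_prob=1.0)
        genome = simulate_genome(cfg)
        peaksets, truth = simulate_peaks(cfg, genome)
        for row in truth.peaks.itertuples(index=False):
            own = row.true_class.split("_")[1]
            n_present = sum(
                _presence_by_scan(row, ps) for ps in peaksets if ps.caste == own
            )
            n_other = sum(
                _presence_by_scan(row, ps) for ps in peaksets if ps.caste != own
            )
            assert n_present == cfg.n_replicates - 1
            assert n_other == 0

    def test_forced_promoter_placement(self):
        cfg = SimulationConfig(seed=3, chrom_length=1_500_000, n_genes=120,
                               n_background_peaks=0, n_differential_peaks=0,
                               n_unique_peaks_per_caste=20,
                               frac_unique_in_promoter_casteB=1.0)
        genome = simulate_genome(cfg)
        _, truth = simulate_peaks(cfg, genome)
        index = gio.FeatureIndex(genome)
        uw = truth.peaks[truth.peaks["true_class"] == "unique_W"]
        for row in uw.itertuples(index=False):
            mid = (row.start + row.end) // 2
            assert index.classify("chr1", mid)[0] == "promoter"

    def test_planted_classes_exclusive_and_counted(self, small_config):
        genome = simulate_genome(small_config)
        _, truth = simulate_peaks(small_config, genome)
        assert truth.peaks["peak_id"].is_unique
        counts = truth.peaks["true_class"].value_counts()
        assert counts["unique_Q"] == small_config.n_unique_peaks_per_caste
        assert counts["unique_W"] == small_config.n_unique_peaks_per_caste
        assert counts["differential"] == small_config.n_differential_peaks
        assert counts["background"] == small_config.n_background_peaks
        # planted intervals never overlap each other (class exclusivity
        # survives consensus merging)
        iv = truth.peaks.sort_values("start")
        assert (iv["start"].to_numpy()[1:] >= iv["end"].to_numpy()[:-1]).all()

    def test_within_chromosome_bounds(self, small_config):
        genome = simulate_genome(small_config)
        peaksets, truth = simulate_peaks(small_config, genome)
        assert (truth.peaks["start"] >= 0).all()
        assert (truth.peaks["end"] <= small_config.chrom_length).all()
        for ps in peaksets:
            assert (ps.peaks["start"] >= 0).all()
            assert (ps.peaks["end"] <= small_config.chrom_length).all()


class TestNBNoise:
    def test_moments_match_mean_plus_quadratic(self):
        rng = np.random.default_rng(0)
        mu, alpha = 100.0, 0.05
        draws = _nb_draw(rng, np.full(5_000, mu), alpha)
        expected_var = mu + alpha * mu * mu
        assert abs(draws.var() - expected_var) / expected_var < 0.15

    def test_zero_dispersion_is_poisson(self):
        rng = np.random.default_rng(0)
        draws = _nb_draw(rng, np.full(5_000, 50.0), 0.0)
        assert abs(draws.var() - 50.0) / 50.0 < 0.15


class TestSimulateExpression:
    def test_null_de_effect_indistinguishable(self):
        # with de_log2fc=0 the planted-DE genes' measured |log2FC| must match
        # the null genes' distribution
        lfc_de, lfc_null = [], []
        for seed in range(3):
            cfg = SimulationConfig(seed=seed, chrom_length=1_500_000, n_genes=120,
                                   n_background_peaks=0, n_differential_peaks=0,
                                   n_unique_peaks_per_caste=0,
                                   n_de_genes=40, de_log2fc=0.0)
            genome = simulate_genome(cfg)
            _, truth = simulate_peaks(cfg, genome)
            counts, samples, truth = simulate_expression(cfg, genome, truth)
            caste = samples.set_index("sample")["caste"]
            mean_q = counts.loc[:, caste == "Q"].mean(axis=1)
            mean_w = counts.loc[:, caste == "W"].mean(axis=1)
            lfc = np.log2((mean_q + 0.5) / (mean_w + 0.5))
            de = truth.genes.set_index("gene_id")["is_de"]
            lfc_de.extend(np.abs(lfc[de[lfc.index]]))
            lfc_null.extend(np.abs(lfc[~de[lfc.index]]))
        assert stats.ks_2samp(lfc_de, lfc_null).pvalue > 0.01

    def test_too_many_de_genes_rejected(self, small_config):
        genome = simulate_genome(small_config)
        _, truth = simulate_peaks(small_config, genome)
        cfg = SimulationConfig(**{**small_config.__dict__, "n_de_genes": 1_000})
        with pytest.raises(SimulationError, match="n_de_genes"):
            simulate_expression(cfg, genome, truth)

    def test_counts_shape_and_truth_records(self, small_config):
        genome = simulate_genome(small_config)
        _, truth = simulate_peaks(small_config, genome)
        counts, samples, truth = simulate_expression(small_config, genome, truth)
        assert counts.shape == (small_config.n_genes, 2 * small_config.n_replicates)
        assert (counts.to_numpy() >= 0).all()
        assert truth.genes["is_de"].sum() == small_config.n_de_genes
        hosts = truth.genes["chrom_log2fc"].notna().sum()
        assert hosts == truth.peaks.query("true_class == 'differential'")[
            "gene_id"
        ].nunique()


class TestSimulateQpcr:
    def _truth(self, cfg):
        genome = simulate_genome(cfg)
        _, truth = simulate_peaks(cfg, genome)
        _, _, truth = simulate_expression(cfg, genome, truth)
        return truth

    def test_noiseless_inversion_recovers_fold(self, small_config):
        truth = self._truth(small_config)
        de = truth.genes[truth.genes["is_de"]].iloc[0]
        ct = simulate_qpcr(truth, [de["gene_id"]], small_config, sigma=0.0)
        res = delta_delta_ct(ct, de["gene_id"], "GAPDH", control_group="W")
        mean_rq = res.group_summary.set_index("group")["mean_rq"]
        assert mean_rq["Q"] == pytest.approx(2 ** de["expr_log2fc"], abs=1e-12)
        assert mean_rq["W"] == pytest.approx(1.0, abs=1e-12)

    def test_reference_gene_rq_is_one(self, small_config):
        truth = self._truth(small_config)
        ct = simulate_qpcr(truth, [], small_config, sigma=0.0)
        res = delta_delta_ct(ct, "GAPDH", "GAPDH", control_group="W")
        assert np.allclose(res.per_sample["rq"], 1.0)

    def test_unknown_gene_rejected(self, small_config):
        truth = self._truth(small_config)
        with pytest.raises(SimulationError, match="unknown gene"):
            simulate_qpcr(truth, ["nope"], small_config)

    def test_noisy_recovery_monte_carlo(self):
        # planted fold 4 (log2fc = 2), sigma 0.2, n=3: the mean recovered
        # fold stays in [3, 5.3] across seeds
        folds = []
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, chrom_length=400_000, n_genes=20,
                                   n_background_peaks=0, n_differential_peaks=0,
                                   n_unique_peaks_per_caste=0, n_de_genes=1,
                                   de_log2fc=2.0)
            genome = simulate_genome(cfg)
            _, truth = simulate_peaks(cfg, genome)
            _, _, truth = simulate_expression(cfg, genome, truth)
            gene = truth.genes.loc[truth.genes["is_de"], "gene_id"].iloc[0]
            sign = truth.genes.set_index("gene_id").loc[gene, "expr_log2fc"]
            ct = simulate_qpcr(truth, [gene], cfg, sigma=0.2)
            control = "W" if sign > 0 else "Q"
            res = delta_delta_ct(ct, gene, "GAPDH", control_group=control)
            treat = "Q" if control == "W" else "W"
            folds.append(
                res.group_summary.set_index("group").loc[treat, "mean_rq"]
            )
        assert 3.0 <= np.mean(folds) <= 5.3


class TestWriteSimulation:
    def test_full_dataset_deterministic(self, tmp_path, small_config):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        p1 = write_simulation(small_config, d1)
        write_simulation(small_config, d2)
        match, mismatch, errors = filecmp.cmpfiles(
            d1, d2, [p.name for p in d1.iterdir()], shallow=False
        )
        assert not mismatch and not errors
        assert (d1 / "truth.json").exists()
        assert len(p1) > 10
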