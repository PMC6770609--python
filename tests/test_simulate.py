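"""Synthetic cohort generator: event rendering, dosage model, gene sets."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bcngdose as b
from bcngdose.simulate import GroundTruth, make_gene_sets


def _overlap_fraction(segments, region, min_cn=3):
    """Fraction of a region covered by segments at or above min_cn."""
    sub = segments[(segments["chromosome"] == region.chromosome)
                   & (segments["copy_number"] >= min_cn)]
    starts = np.maximum(sub["start"].to_numpy(), region.start)
    ends = np.minimum(sub["end"].to_numpy(), region.end)
    return np.maximum(ends - starts, 0).sum() / region.length


class TestCnaProfiles:
    def test_forced_gain_covers_majority_of_the_region(self):
        cfg = b.SimulationConfig(
            seed=0, n_tumour=5, n_normal=0, n_cin=5, n_msi=0,
            n_transcripts_per_region=1,
            per_region_gain_freq={"8q": 1.0}, background_gain_freq=0.0,
            background_loss_freq=0.0,
        )
        catalog = b.RegionCatalog.from_layout(cfg.region_layout)
        rng = np.random.default_rng(cfg.seed)
        segments, events, metadata = b.simulate_cna_profiles(cfg, catalog, rng)
        region = catalog.region("8q")
        for sample in metadata.index:
            frac = _overlap_fraction(segments[segments["sample"] == sample], region)
            assert frac > 0.5

    def test_no_events_means_flat_disomic_profiles(self):
        cfg = b.SimulationConfig(
            seed=1, n_tumour=6, n_normal=3, n_cin=6, n_msi=0,
            n_transcripts_per_region=1,
            background_gain_freq=0.0, background_loss_freq=0.0,
        )
        catalog = b.RegionCatalog.from_layout(cfg.region_layout)
        segments, events, _ = b.simulate_cna_profiles(cfg, catalog, np.random.default_rng(1))
        assert (segments["copy_number"] == 2).all()
        assert events.empty

    def test_recovered_gain_frequency_within_binomial_interval(self):
        # gain probability 0.5 on chromosome 13 over 400 tumours; the arm
        # caller must recover a frequency inside the 99% binomial interval
        cfg = b.SimulationConfig(
            seed=4, n_tumour=400, n_normal=0, n_cin=400, n_msi=0,
            n_transcripts_per_region=1,
            per_region_gain_freq={"13": 0.5}, background_gain_freq=0.0,
            background_loss_freq=0.0,
        )
        catalog = b.RegionCatalog.from_layout(cfg.region_layout)
        segments, _, meta = b.simulate_cna_profiles(cfg, catalog, np.random.default_rng(4))
        calls = b.build_arm_call_matrix(segments, catalog)
        freq = b.cna_frequencies(calls, list(meta.index))
        half_width = stats.norm.ppf(0.995) * np.sqrt(0.25 / 400) * 100
        assert abs(freq.loc["13", "gain_pct"] - 50.0) < half_width

    def test_isochromosome_renders_p_loss_q_gain(self):
        cfg = b.SimulationConfig(
            seed=7, n_tumour=20, n_normal=0, n_cin=20, n_msi=0,
            n_transcripts_per_region=1,
            iso_freq={"8": 1.0}, background_gain_freq=0.0, background_loss_freq=0.0,
        )
        catalog = b.RegionCatalog.from_layout(cfg.region_layout)
        segments, _, meta = b.simulate_cna_profiles(cfg, catalog, np.random.default_rng(7))
        calls = b.build_arm_call_matrix(segments, catalog)
        flags = calls.iso_flags()
        assert flags["i(8q)"].all()


class TestDosageModel:
    @pytest.mark.parametrize(
        "exponent, expected_ratio",
        [
            (1.0, 1.5),
            (0.0, 1.0),
            (np.log(1.25) / np.log(1.5), 1.25),  # trisomy in the 1.2-1.3 band
        ],
    )
    def test_trisomic_mean_ratio(self, exponent, expected_ratio):
        # Monte-Carlo oracle: >= 10^4 draws per condition; every tumour
        # gains the single toy region, normals stay disomic.
        cfg = b.SimulationConfig(
            seed=11, n_tumour=150, n_normal=150, n_cin=150, n_msi=0,
            region_layout="toy-1", n_transcripts_per_region=70,
            per_region_gain_freq={"c1": 1.0}, background_gain_freq=0.0,
            background_loss_freq=0.0,
            frac_upregulated=0.0, frac_downregulated=0.0, tumour_effect_fc=1.0,
            dosage_exponent_null=exponent,
            library_size_sd=0.0, sd_log_expression=0.5,
        )
        cohort = b.simulate_cohort(cfg)
        tum = cohort.counts[cohort.tumour_samples].to_numpy().mean()
        nrm = cohort.counts[cohort.normal_samples].to_numpy().mean()
        assert tum / nrm == pytest.approx(expected_ratio, rel=0.03)


class TestGeneSets:
    def _truth(self, n, frac_up, seed=0):
        rng = np.random.default_rng(seed)
        reg = rng.choice(["up", "down", "null"], size=n,
                         p=[frac_up, frac_up, 1 - 2 * frac_up])
        return pd.DataFrame(
            {"regulation": reg, "dosage_exponent": 0.5, "baseline_mean": 100.0},
            index=pd.Index([f"T{i:05d}" for i in range(n)], name="transcript"),
        )

    def test_factor_one_membership_independent_of_truth(self):
        truth = self._truth(4000, frac_up=0.2, seed=1)
        cfg = b.SimulationConfig(geneset_enrichment_factor=1.0, geneset_size=400)
        sets = make_gene_sets(cfg, truth, np.random.default_rng(3))
        up = truth["regulation"] == "up"
        frac_in_set = up.loc[sets["fitness_t"]].mean()
        # binomial 99.9% interval around the pool fraction
        half = stats.norm.ppf(0.9995) * np.sqrt(up.mean() * (1 - up.mean()) / 400)
        assert abs(frac_in_set - up.mean()) < half

    def test_factor_three_is_recovered_by_measured_enrichment(self):
        truth = self._truth(20000, frac_up=0.02, seed=2)
        cfg = b.SimulationConfig(geneset_enrichment_factor=3.0, geneset_size=800)
        sets = make_gene_sets(cfg, truth, np.random.default_rng(5))
        up = truth["regulation"] == "up"
        fold = up.loc[sets["gained_vel_t"]].mean() / up.mean()
        assert fold == pytest.approx(3.0, abs=1.0)
        assert fold > 1.5

    def test_empty_pool_warns_and_returns_empty_sets(self):
        truth = self._truth(0, frac_up=0.0)
        cfg = b.SimulationConfig(geneset_size=10)
        with pytest.warns(UserWarning):
            sets = make_gene_sets(cfg, truth, np.random.default_rng(0))
        assert all(len(v) == 0 for v in sets.values())

    def test_factor_below_one_rejected(self):
        cfg = b.SimulationConfig()
        cfg.geneset_enrichment_factor = 0.5
        with pytest.raises(b.ConfigurationError):
            make_gene_sets(cfg, self._truth(10, 0.2), np.random.default_rng(0))


class TestCohortContracts:
    def test_same_config_reproduces_bit_identical_outputs(self):
        cfg = b.SimulationConfig(seed=13, region_layout="toy-4",
                                 n_transcripts_per_region=12,
                                 n_tumour=10, n_normal=4, n_cin=10, n_msi=0)
        c1 = b.simulate_cohort(cfg)
        c2 = b.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(c1.counts, c2.counts)
        pd.testing.assert_frame_equal(c1.segments, c2.segments)
        assert c1.truth.gene_sets == c2.truth.gene_sets

    def test_conservation_of_transcripts_and_samples(self):
        cfg = b.SimulationConfig(seed=14, region_layout="toy-4",
                                 n_transcripts_per_region=12,
                                 n_tumour=8, n_normal=4, n_cin=8, n_msi=0)
        cohort = b.simulate_cohort(cfg)
        assert cohort.counts.index.equals(cohort.annotation.index)
        assert set(cohort.counts.columns) == set(cohort.metadata.index)
        assert set(cohort.segments["sample"]) == set(cohort.metadata.index)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(b.ConfigurationError):
            b.SimulationConfig(frac_upregulated=0.7, frac_downregulated=0.5).validate()


class TestNullFidelity:
    def test_null_cohort_yields_uniform_pvalues(self):
        # with every effect switched off, the tumour-vs-normal contrast on
        # >= 2000 transcripts must give uniform p-values (KS at alpha=0.01)
        cfg = b.SimulationConfig(
            seed=21, n_tumour=10, n_normal=10, n_cin=10, n_msi=0,
            region_layout="toy-2", n_transcripts_per_region=1020,
            background_gain_freq=0.0, background_loss_freq=0.0,
            frac_upregulated=0.0, frac_downregulated=0.0, tumour_effect_fc=1.0,
        )
        cohort = b.simulate_cohort(cfg)
        res = b.de_test(cohort.counts, cohort.tumour_samples, cohort.normal_samples)
        assert len(res.table) >= 2000
        ks = stats.kstest(res.table["pvalue"], "uniform")
        assert ks.pvalue > 0.01
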