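"""Synthetic droplet generator: partitioning statistics, series, cohorts."""

import math

import numpy as np
import pytest
from scipy import stats

from ddscreen import (
    AssayConfig,
    CohortModel,
    SampleTruth,
    blank_truth,
    blood_to_copies_per_well,
    simulate_cohort,
    simulate_dilution_series,
    simulate_replicates,
    simulate_well,
)
from ddscreen.errors import ConfigError, SaturationError


class TestAssayConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"droplet_volume_nl": 0.0},
            {"droplets_per_well": 0},
            {"rain_fraction": 0.5},
            {"false_positive_rate": 1.0},
            {"positive_amplitude_mean": (500.0,) * 4},
            {"channel_map": {"SMN1": 1, "RPP30": 1, "SMN2": 3, "TREC": 4}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            AssayConfig(**kwargs)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigError):
            AssayConfig.from_dict({"droplet_volume": 0.85})

    def test_dict_round_trip(self, cfg):
        assert AssayConfig.from_dict(cfg.to_dict()) == cfg


class TestSimulateWell:
    def test_blank_well_has_no_positive_labels(self, clean_cfg, rng):
        well = simulate_well(blank_truth(), clean_cfg, rng=rng)
        assert well.truth_labels.sum() == 0
        assert well.accepted_events == clean_cfg.droplets_per_well

    def test_positive_fraction_matches_poisson_occupancy(self, clean_cfg, rng):
        """At lambda = ln 2 copies/droplet, P(positive) = 1 - e^-lambda = 1/2."""
        lam = math.log(2.0)
        conc_reaction = lam / (clean_cfg.droplet_volume_nl * 1e-3)  # copies/µL
        copies_per_well = conc_reaction * clean_cfg.well_volume_ul
        rpp30_blood = copies_per_well * clean_cfg.blood_factor
        truth = SampleTruth(smn1_cn=0, smn2_cn=0, trec_blood=0.0, rpp30_blood=rpp30_blood)
        well = simulate_well(truth, clean_cfg, rng=rng)
        frac = well.truth_labels[:, 1].mean()  # RPP30 = channel 2
        n = clean_cfg.droplets_per_well
        assert abs(frac - 0.5) < 3.0 * math.sqrt(0.25 / n)

    @pytest.mark.parametrize("lam", [0.05, 0.3, 1.0, 2.0])
    def test_occupancy_converges_to_poisson_formula(self, clean_cfg, lam):
        """Positive fraction tracks 1 - exp(-lambda) across loads."""
        conc_reaction = lam / (clean_cfg.droplet_volume_nl * 1e-3)
        rpp30_blood = conc_reaction * clean_cfg.well_volume_ul * clean_cfg.blood_factor
        truth = SampleTruth(smn1_cn=0, smn2_cn=0, trec_blood=0.0, rpp30_blood=rpp30_blood)
        well = simulate_well(truth, clean_cfg, rng=np.random.default_rng(17))
        frac = well.truth_labels[:, 1].mean()
        expected = 1.0 - math.exp(-lam)
        se = math.sqrt(expected * (1 - expected) / clean_cfg.droplets_per_well)
        assert abs(frac - expected) < 4.0 * se

    def test_same_seed_gives_identical_wells(self, cfg, typical_truth):
        w1 = simulate_well(typical_truth, cfg, rng=np.random.default_rng(5))
        w2 = simulate_well(typical_truth, cfg, rng=np.random.default_rng(5))
        assert np.array_equal(w1.amplitudes, w2.amplitudes)
        assert np.array_equal(w1.truth_labels, w2.truth_labels)

    def test_different_seeds_differ(self, cfg, typical_truth):
        w1 = simulate_well(typical_truth, cfg, rng=np.random.default_rng(5))
        w2 = simulate_well(typical_truth, cfg, rng=np.random.default_rng(6))
        assert not np.array_equal(w1.amplitudes, w2.amplitudes)

    def test_saturating_load_raises(self, cfg):
        n_copies = 11 * cfg.droplets_per_well  # > 10 copies/droplet equivalent
        rpp30_blood = n_copies * cfg.blood_factor
        truth = SampleTruth(rpp30_blood=rpp30_blood)
        with pytest.raises(SaturationError):
            simulate_well(truth, cfg, rng=np.random.default_rng(0))

    def test_blank_truth_requires_zero_targets(self):
        from ddscreen import Role

        with pytest.raises(ConfigError):
            SampleTruth(smn1_cn=1, smn2_cn=0, trec_blood=0, rpp30_blood=0, role=Role.BLANK)


class TestReplicates:
    @pytest.mark.parametrize("n_within,n_runs", [(20, 1), (5, 5)])
    def test_counts_and_run_ids(self, cfg, typical_truth, rng, n_within, n_runs):
        wells = simulate_replicates(typical_truth, cfg, n_within, n_runs, rng=rng)
        assert len(wells) == n_within * n_runs
        assert len({w.run_id for w in wells}) == n_runs

    def test_degenerate_series_equals_single_well(self, cfg, typical_truth):
        wells = simulate_replicates(
            typical_truth, cfg, 1, 1, rng=np.random.default_rng(3)
        )
        single = simulate_well(
            typical_truth,
            cfg,
            rng=np.random.default_rng(3),
            well_id=wells[0].well_id,
        )
        assert np.array_equal(wells[0].amplitudes, single.amplitudes)


class TestDilutionSeries:
    def test_expected_levels_are_two_fold(self, cfg, rng):
        series = simulate_dilution_series(100.0, 2, 1, cfg, rng=rng)
        assert [c for c, _ in series] == [100.0, 50.0]

    def test_design_shape_and_lowest_level(self, cfg, rng):
        series = simulate_dilution_series(2500.0, 8, 5, cfg, rng=rng)
        assert len(series) == 40
        lowest = min(c for c, _ in series)
        assert lowest == pytest.approx(2500.0 / 2**7)  # ~19.5 copies/µL blood

    def test_reproducible_with_fixed_seed(self, cfg):
        s1 = simulate_dilution_series(200.0, 3, 2, cfg, rng=np.random.default_rng(2))
        s2 = simulate_dilution_series(200.0, 3, 2, cfg, rng=np.random.default_rng(2))
        for (c1, w1), (c2, w2) in zip(s1, s2):
            assert c1 == c2 and np.array_equal(w1.amplitudes, w2.amplitudes)


class TestCohort:
    def test_empty_cohort(self, cfg, rng):
        assert simulate_cohort(0, cfg, rng=rng) == []

    def test_single_copy_smn1_count_in_binomial_interval(self, cfg, rng):
        n = 1867
        cohort = simulate_cohort(n, cfg, rng=rng, make_wells=False)
        count = sum(1 for truth, _ in cohort if truth.smn1_cn == 1)
        p = CohortModel().smn1_frequencies[1]
        lo, hi = stats.binom.ppf([0.025, 0.975], n, p)
        assert lo <= count <= hi  # expectation ~43

    def test_smn2_frequencies_chi_square(self, cfg):
        n = 100_000
        cohort = simulate_cohort(
            n, cfg, rng=np.random.default_rng(99), make_wells=False
        )
        freqs = CohortModel().smn2_frequencies
        observed = np.array(
            [sum(1 for t, _ in cohort if t.smn2_cn == cn) for cn in sorted(freqs)]
        )
        expected = np.array([freqs[cn] * n for cn in sorted(freqs)])
        _, p = stats.chisquare(observed, expected)
        assert p > 0.001

    def test_preterm_fraction_and_gestational_split(self, cfg, rng):
        cohort = simulate_cohort(2000, cfg, rng=rng, make_wells=False)
        preterm = sum(1 for t, _ in cohort if t.gestational_age_weeks < 34)
        assert 0 < preterm < 2000 * 0.1

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ConfigError):
            CohortModel(smn1_frequencies={1: 0.5, 2: 0.4})


def test_blood_to_well_round_trip(cfg):
    """Copies-per-well inversion is the exact inverse of the blood conversion."""
    from ddscreen import to_blood_concentration

    for conc in (0.0, 57.0, 4200.0, 208_333.0):
        assert to_blood_concentration(
            blood_to_copies_per_well(conc, cfg), cfg
        ) == pytest.approx(conc)
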