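"""Synthetic cohort generator: subjects, hypnograms, true EE, gas inversion."""

import numpy as np
import pytest

from somnocal import (
    CohortConfig,
    EESeries,
    GroupSpec,
    generate_cohort,
    gas_from_ee,
    score_architecture,
    simulate_hypnogram,
    simulate_true_ee,
    sliding_smr,
    weir_ee,
)
from somnocal.io import subjects_to_frame


def single_group_config(n, ffm_mean=55.3, ffm_sd=5.6, seed=0, **kw):
    base = CohortConfig(seed=seed).groups["male_runner"]
    groups = {"male_runner": GroupSpec(**{**base.__dict__, "n": n,
                                          "ffm_mean": ffm_mean, "ffm_sd": ffm_sd})}
    return CohortConfig(groups=groups, seed=seed, **kw)


class TestGenerateCohort:
    def test_default_group_counts(self, cohort):
        counts = {}
        for s in cohort:
            counts[s.group] = counts.get(s.group, 0) + 1
        assert counts == {"male_runner": 9, "amenorrheic_runner": 8,
                          "menstruating_runner": 9, "female_control": 10,
                          "male_control": 10}

    def test_same_seed_identical_tables(self, default_config):
        a = subjects_to_frame(generate_cohort(default_config))
        b = subjects_to_frame(generate_cohort(default_config))
        assert a.to_csv() == b.to_csv()

    def test_different_seed_differs(self, default_config, cohort):
        other = generate_cohort(CohortConfig(seed=99))
        assert other[0].ffm_kg != cohort[0].ffm_kg

    def test_large_sample_ffm_mean_converges(self):
        """Law of large numbers: 1000 subjects at target 55.3 +- 5.6 kg land
        within 0.5 kg of the target mean."""
        subjects = generate_cohort(single_group_config(1000))
        ffm = np.array([s.ffm_kg for s in subjects])
        assert abs(ffm.mean() - 55.3) < 0.5
        assert abs(ffm.std(ddof=1) - 5.6) < 0.6

    def test_group_means_within_two_sd(self, cohort, default_config):
        for label, g in default_config.groups.items():
            members = [s for s in cohort if s.group == label]
            ffm = np.mean([s.ffm_kg for s in members])
            fm = np.mean([s.fm_kg for s in members])
            assert abs(ffm - g.ffm_mean) < 2 * g.ffm_sd
            assert abs(fm - g.fm_mean) < 2 * g.fm_sd

    def test_body_mass_closure_and_tissue_sum(self, cohort):
        for s in cohort:
            assert s.body_mass_kg == pytest.approx(s.ffm_kg + s.fm_kg)
            assert s.tissues.total == pytest.approx(s.body_mass_kg, rel=1e-9)

    def test_sex_and_menstrual_consistency(self, cohort):
        for s in cohort:
            assert s.sex_code in (1, 2)
            if s.sex_code == 1:
                assert s.menstrual_status == "not_applicable"
            else:
                assert s.menstrual_status in ("amenorrhea", "menstruating")

    def test_invalid_targets_rejected(self):
        with pytest.raises(ValueError, match="size"):
            single_group_config(0)
        with pytest.raises(ValueError, match="sd"):
            single_group_config(5, ffm_sd=-1.0)

    def test_composition_variant_shifts_estimates_not_truth(self, male_runner):
        from somnocal import composition_variant, estimate_smr
        alt = composition_variant(male_runner, ffm_offset_kg=-1.5,
                                  fm_offset_kg=0.8)
        assert alt.ffm_kg == pytest.approx(male_runner.ffm_kg - 1.5)
        assert alt.tissues.total == pytest.approx(alt.body_mass_kg)
        assert alt.true_smr_kj_day == male_runner.true_smr_kj_day
        assert estimate_smr(alt.ffm_kg) < estimate_smr(male_runner.ffm_kg)


class TestSimulateHypnogram:
    def test_exactly_960_epochs(self, male_runner, default_config):
        h = simulate_hypnogram(male_runner, 0, default_config)
        assert len(h) == 960
        assert h.duration_min == 480.0

    def test_stage_epochs_conserve_night(self, male_runner, default_config):
        h = simulate_hypnogram(male_runner, 5, default_config)
        assert sum(h.stage_epoch_counts().values()) == 960

    def test_seed_required(self, male_runner, default_config):
        with pytest.raises(ValueError, match="seed"):
            simulate_hypnogram(male_runner, None, default_config)

    def test_determinism(self, male_runner, default_config):
        a = simulate_hypnogram(male_runner, 7, default_config)
        b = simulate_hypnogram(male_runner, 7, default_config)
        assert np.array_equal(a.epochs, b.epochs)

    def test_male_runner_mean_tst_near_target(self, default_config, rng):
        """200 nights: mean total sleep time within [445, 485] min against
        the 465.9-min group target."""
        subjects = [s for s in generate_cohort(default_config)
                    if s.group == "male_runner"]
        tst = []
        for i in range(200):
            h = simulate_hypnogram(subjects[i % len(subjects)],
                                   int(rng.integers(2**31)), default_config)
            tst.append(score_architecture(h).tst_min)
        assert 445 <= np.mean(tst) <= 485

    def test_cohort_mean_stage_minutes_within_10pct(self, default_config, rng):
        subjects = [s for s in generate_cohort(default_config)
                    if s.group == "female_control"]
        totals = []
        for i in range(150):
            h = simulate_hypnogram(subjects[i % len(subjects)],
                                   int(rng.integers(2**31)), default_config)
            sm = h.stage_minutes()
            totals.append([sm[k] for k in ("N1", "N2", "N3", "R")])
        mean = np.array(totals).mean(axis=0)
        target = default_config.groups["female_control"].stage_minutes
        for got, want in zip(mean, (target[k] for k in ("N1", "N2", "N3", "R"))):
            assert abs(got - want) <= 0.10 * want

    def test_zero_wake_probability_gives_full_efficiency(self, male_runner):
        config = CohortConfig(seed=0, wake_probability=0.0)
        h = simulate_hypnogram(male_runner, 11, config)
        arch = score_architecture(h)
        assert arch.waso_min == 0.0
        assert arch.sleep_efficiency_pct == pytest.approx(100.0)


class TestSimulateTrueEE:
    def test_flat_when_everything_off(self, male_runner):
        config = CohortConfig(seed=0, ee_noise_cv=0.0, night_cv=0.0,
                              drift_amplitude=0.0,
                              stage_multipliers={s: 1.0 for s in "W N1 N2 N3 R".split()})
        h = simulate_hypnogram(male_runner, 1, config)
        ee = simulate_true_ee(male_runner, h, config, 2)
        assert np.allclose(ee.ee_kj_min, male_runner.basal_kj_min)

    def test_luteal_multiplier_exact_without_noise(self, male_runner, cohort):
        subject = next(s for s in cohort if s.menstrual_status == "menstruating")
        config = CohortConfig(seed=0, ee_noise_cv=0.0, night_cv=0.0)
        h = simulate_hypnogram(subject, 3, config)
        fol = simulate_true_ee(subject, h, config, 4, phase="follicular")
        lut = simulate_true_ee(subject, h, config, 5, phase="luteal")
        r_f = sliding_smr(fol)[0]
        r_l = sliding_smr(lut)[0]
        assert r_l / r_f == pytest.approx(1.027, rel=1e-12)

    def test_n3_below_rem_on_true_series(self, male_runner, default_config):
        """Default multipliers put slow-wave sleep below REM in mean EE."""
        h = simulate_hypnogram(male_runner, 6, default_config)
        ee = simulate_true_ee(male_runner, h, default_config, 7)
        minute_stage = h.minute_stages()
        n3 = ee.ee_kj_min[minute_stage == "N3"].mean()
        rem = ee.ee_kj_min[minute_stage == "R"].mean()
        assert n3 < rem

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(stage_multipliers={"W": 1.0, "N1": 1.0, "N2": 1.0,
                                            "N3": -0.5, "R": 1.0})

    def test_seed_required(self, male_runner, default_config):
        h = simulate_hypnogram(male_runner, 1, default_config)
        with pytest.raises(ValueError, match="seed"):
            simulate_true_ee(male_runner, h, default_config, None)


class TestGasFromEE:
    def _series(self, values):
        return EESeries(np.asarray(values, dtype=float),
                        segments={"sleep": (0, len(values))})

    def test_round_trip_through_weir(self, rng):
        ee = self._series(rng.gamma(8, 0.6, 480))
        gas = gas_from_ee(ee, rer_target=0.85, urinary_nitrogen_g_day=12.0)
        back = weir_ee(gas)
        assert np.allclose(back.ee_kj_min, ee.ee_kj_min, rtol=1e-12)

    def test_rer_exact_each_minute(self, rng):
        gas = gas_from_ee(self._series(rng.gamma(8, 0.6, 100)), rer_target=0.85)
        assert np.allclose(gas.vco2 / gas.vo2, 0.85)

    def test_zero_ee_zero_gas(self):
        gas = gas_from_ee(self._series(np.zeros(10)), rer_target=0.8)
        assert np.all(gas.vo2 == 0) and np.all(gas.vco2 == 0)

    @pytest.mark.parametrize("rer", [0.5, 1.4])
    def test_out_of_range_rer_rejected(self, rer):
        with pytest.raises(ValueError):
            gas_from_ee(self._series(np.ones(10)), rer_target=rer)

    def test_negative_ee_rejected(self):
        with pytest.raises(ValueError):
            gas_from_ee(EESeries(np.array([-1.0])), rer_target=0.8)
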