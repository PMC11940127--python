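import numpy as np
import pytest

from hoinet import hoi
from hoinet.behavior import filter_trials
from hoinet.cohort import (
    CohortConfig,
    PlantSpec,
    collider_amplitude,
    common_driver_amplitude,
    generate_behavior,
    generate_cohort,
    generate_epochs,
    implied_correlation,
    participant_table,
    plant_structure,
)
from hoinet.preprocessing import bandpass_trial, representative_trial
from tests.conftest import BETA, DELTA, small_config


class TestConfigValidation:
    def test_default_matches_study_design(self):
        cfg = CohortConfig()
        table = participant_table(cfg)
        assert len(table) == 17 + 15
        assert sum(g == "treatment" for _, g in table) == 17
        assert cfg.n_samples == 800
        assert cfg.n_trials == 576

    def test_non_integer_sample_count_rejected(self):
        with pytest.raises(ValueError, match="integer sample count"):
            CohortConfig(epoch_ms=800.3)

    def test_unbalanced_trial_count_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            CohortConfig(n_trials=100)

    def test_planted_channel_out_of_range_rejected(self):
        plant = PlantSpec((1, 2, 70), DELTA, "collider", 1.0)
        with pytest.raises(ValueError, match="out of range"):
            CohortConfig(planted_effects=(plant,))

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_control=1)


class TestPlantSpec:
    def test_collider_needs_three_channels(self):
        with pytest.raises(ValueError):
            PlantSpec((1, 2), DELTA, "collider", 1.0)

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError, match="unknown structure"):
            PlantSpec((1, 2, 3), DELTA, "fan_in", 1.0)

    def test_empty_target_set_rejected(self):
        with pytest.raises(ValueError):
            PlantSpec((), DELTA, "common_driver", 1.0)


class TestDeterminismAndNullEffects:
    def test_same_seed_bit_identical(self):
        cfg = small_config(n_channels=4, n_trials=16, n_treatment=2, n_control=2, seed=7)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for key in a.epochs:
            assert np.array_equal(a.epochs[key].data, b.epochs[key].data)
            assert a.behavior[key].equals(b.behavior[key])

    def test_zero_amplitude_plant_is_exact_null(self):
        base = small_config(n_channels=4, n_trials=16, n_treatment=2, n_control=2, seed=3)
        planted = small_config(
            n_channels=4, n_trials=16, n_treatment=2, n_control=2, seed=3,
            planted_effects=(PlantSpec((0, 1, 2), DELTA, "collider", 0.0),),
        )
        for p, g in participant_table(base):
            a = generate_epochs(base, p, g, "follow_up")
            b = generate_epochs(planted, p, g, "follow_up")
            assert np.array_equal(a.data, b.data)

    def test_plant_amplitude_zero_returns_input(self):
        cfg = small_config(n_channels=4, n_trials=16, n_treatment=2, n_control=2)
        es = generate_epochs(cfg, "T00", "treatment", "baseline")
        out = plant_structure(es, PlantSpec((0, 1, 2), BETA, "common_driver", 0.0))
        assert out is es

    def test_plant_touches_only_target_channels(self, rng):
        cfg = small_config(n_channels=6, n_trials=16, n_treatment=2, n_control=2)
        es = generate_epochs(cfg, "T00", "treatment", "follow_up")
        out = plant_structure(es, PlantSpec((1, 3, 4), BETA, "common_driver", 2.0), rng)
        changed = [
            ch for ch in range(6) if not np.array_equal(out.data[ch], es.data[ch])
        ]
        assert changed == [1, 3, 4]

    def test_plant_applied_only_to_specified_group_session(self):
        plant = PlantSpec((0, 1, 2), BETA, "common_driver", 2.0,
                          group="treatment", session="follow_up")
        cfg = small_config(n_channels=4, n_trials=16, n_treatment=2, n_control=2,
                           planted_effects=(plant,))
        null_cfg = small_config(n_channels=4, n_trials=16, n_treatment=2, n_control=2)
        # control follow-up and treatment baseline are untouched
        for p, g, s in [("C00", "control", "follow_up"), ("T00", "treatment", "baseline")]:
            assert np.array_equal(
                generate_epochs(cfg, p, g, s).data,
                generate_epochs(null_cfg, p, g, s).data,
            )
        assert not np.array_equal(
            generate_epochs(cfg, "T00", "treatment", "follow_up").data,
            generate_epochs(null_cfg, "T00", "treatment", "follow_up").data,
        )


class TestPlantGeometry:
    """Planted structures must realize their implied correlation matrices."""

    def test_implied_matrices_give_spec_o_information(self):
        # the canonical geometries reproduce the closed-form O-information
        common = implied_correlation(
            PlantSpec((0, 1, 2), BETA, "common_driver", common_driver_amplitude(0.5))
        )
        assert np.allclose(common, np.full((3, 3), 0.5) + 0.5 * np.eye(3))
        assert hoi.o_from_corr(common) == pytest.approx(0.1226, abs=1e-3)
        assert hoi.tc_from_corr(common) == pytest.approx(0.5, abs=1e-9)

        coll = implied_correlation(
            PlantSpec((0, 1, 2), BETA, "collider",
                      collider_amplitude(1 / np.sqrt(3), 3))
        )
        assert coll[0, 1] == pytest.approx(1 / np.sqrt(3), abs=1e-12)
        assert coll[1, 2] == 0.0
        assert hoi.o_from_corr(coll) == pytest.approx(-0.2075, abs=1e-3)

    @pytest.mark.parametrize("structure,rho", [("common_driver", 0.5),
                                               ("collider", 1 / np.sqrt(3))])
    def test_measured_correlations_match_implied(self, structure, rho):
        """Band-filtered, trial-averaged planted subsets show the designed
        pairwise correlations to within 0.05, averaged over the cohort."""
        amp = (common_driver_amplitude(rho) if structure == "common_driver"
               else collider_amplitude(rho, 3))
        plant = PlantSpec((1, 2, 3), BETA, structure, amp)
        implied = implied_correlation(plant)
        acc = np.zeros((3, 3))
        n = 0
        for seed in range(3):  # average out per-epoch correlation noise
            cfg = small_config(n_channels=16, planted_effects=(plant,), seed=seed)
            for p, g in participant_table(cfg):
                if g != "treatment":
                    continue
                es = generate_epochs(cfg, p, g, "follow_up")
                rep = bandpass_trial(representative_trial(es.data), BETA, cfg.fs)
                acc += np.corrcoef(rep[[1, 2, 3]])
                n += 1
        assert np.abs(acc / n - implied).max() < 0.05


class TestBehaviorTables:
    def test_session_totals_and_block_balance(self):
        cfg = CohortConfig()
        table = generate_behavior(cfg, "treatment", "baseline",
                                  np.random.default_rng(0))
        assert len(table) == 576
        for _, block in table.groupby("block"):
            assert len(block) == 144
            assert (block["imType"] == "face").sum() == 72
            assert (block["imType"] == "car").sum() == 72
            assert (block["imCoh"] == 37.5).sum() == 72

    def test_timeouts_have_no_rt(self):
        cfg = CohortConfig()
        rng = np.random.default_rng(5)
        table = generate_behavior(cfg, "control", "follow_up", rng)
        timeouts = table["outcome"] == "timeout"
        assert table.loc[timeouts, "rt_ms"].isna().all()
        assert table.loc[~timeouts, "rt_ms"].notna().all()

    def test_default_rts_pass_validity_filter(self):
        cfg = CohortConfig()
        table = generate_behavior(cfg, "treatment", "baseline",
                                  np.random.default_rng(2))
        assert filter_trials(table).mean() > 0.9
        correct = (table["outcome"] == "correct").mean()
        assert correct > 0.8  # both groups should score highly

    def test_fast_rt_model_mostly_discarded(self):
        cfg = CohortConfig(rt_median_ms=200.0, rt_sigma=0.1)
        table = generate_behavior(cfg, "treatment", "baseline",
                                  np.random.default_rng(2))
        assert filter_trials(table).mean() < 0.2


def test_null_cohort_groups_statistically_indistinguishable():
    """With no planted effects, treatment and control follow-up TC values on
    a fixed triplet are drawn from the same distribution."""
    from hoinet.behavior import mann_whitney_u
    from tests.conftest import raw_band_trials

    tvals, cvals = [], []
    for seed in range(20):
        cfg = CohortConfig(n_channels=4, n_trials=16, bands=(BETA,), seed=seed)
        trials, groups = raw_band_trials(cfg, BETA, "follow_up")
        for p, bt in trials.items():
            v = hoi.total_correlation(bt.data[[0, 1, 2]])
            (tvals if groups[p] == "treatment" else cvals).append(v)
    _, p = mann_whitney_u(tvals, cvals)
    assert p > 0.01
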