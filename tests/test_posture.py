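"""COP derivation, preprocessing, sway metrics and group effect sizes."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from bbs_workbench.posture import (
    SwayMetrics,
    SwayTrial,
    aggregate_participant,
    cohens_d,
    cop_from_forces,
    compare_groups,
    lowpass_zero_phase,
    preprocess,
    sway_metrics,
)


def force_trial(fz, mx, my, n=6000, rate=200.0, pid="P1"):
    return SwayTrial(
        participant_id=pid,
        sample_rate=rate,
        forces=pd.DataFrame(
            {
                "Fx": np.zeros(n), "Fy": np.zeros(n), "Fz": np.full(n, fz, dtype=float),
                "Mx": np.broadcast_to(mx, n).astype(float).copy(),
                "My": np.broadcast_to(my, n).astype(float).copy(),
                "Mz": np.zeros(n),
            }
        ),
    )


def cop_trial(ml, ap, rate=100.0, pid="P1"):
    return SwayTrial(
        participant_id=pid,
        sample_rate=rate,
        cop=pd.DataFrame({"cop_ml": np.asarray(ml, float), "cop_ap": np.asarray(ap, float)}),
    )


class TestCopFromForces:
    def test_direct_ratio(self):
        trial = cop_from_forces(force_trial(fz=700.0, mx=0.0, my=-7.0))
        assert trial.cop["cop_ml"].iloc[0] == pytest.approx(1.0)  # -(-7)/700 m -> +1 cm
        assert trial.cop["cop_ap"].iloc[0] == pytest.approx(0.0)

    def test_constant_forces_give_constant_cop(self):
        trial = cop_from_forces(force_trial(fz=650.0, mx=3.25, my=1.3))
        assert trial.cop["cop_ml"].std() < 1e-12
        assert trial.cop["cop_ap"].std() < 1e-12

    def test_zero_load_marks_unusable(self):
        trial = force_trial(fz=700.0, mx=0.0, my=0.0)
        trial.forces.loc[100, "Fz"] = 0.0
        assert not cop_from_forces(trial).usable

    def test_inverse_mapping_round_trip(self):
        """COP -> forces -> COP recovers the path to 1e-9 cm."""
        rng = np.random.default_rng(5)
        ml = rng.normal(0, 0.5, size=2000)
        ap = rng.normal(0, 0.7, size=2000)
        fz = np.full(2000, 612.0)
        trial = SwayTrial(
            participant_id="P1",
            sample_rate=100.0,
            forces=pd.DataFrame(
                {
                    "Fx": np.zeros(2000), "Fy": np.zeros(2000), "Fz": fz,
                    "Mx": ap / 100.0 * fz, "My": -ml / 100.0 * fz, "Mz": np.zeros(2000),
                }
            ),
        )
        trial = cop_from_forces(trial)
        np.testing.assert_allclose(trial.cop["cop_ml"], ml, atol=1e-9)
        np.testing.assert_allclose(trial.cop["cop_ap"], ap, atol=1e-9)


class TestPreprocess:
    def test_30s_200hz_yields_2000_samples(self):
        t = np.arange(6000) / 200.0
        trial = preprocess(cop_trial(np.sin(t), np.cos(t), rate=200.0))
        assert trial.usable
        assert len(trial.cop) == 2000
        assert trial.sample_rate == 100.0

    def test_dc_series_unchanged(self):
        trial = preprocess(cop_trial(np.full(3000, 2.5), np.full(3000, -1.0)))
        np.testing.assert_allclose(trial.cop["cop_ml"], 2.5, atol=1e-9)
        np.testing.assert_allclose(trial.cop["cop_ap"], -1.0, atol=1e-9)

    def test_cutoff_sinusoid_half_amplitude(self):
        """A 6 Hz sinusoid leaves the double-pass filter at ~0.5 amplitude."""
        t = np.arange(3000) / 100.0
        x = np.sin(2 * np.pi * 6.0 * t)
        trial = preprocess(cop_trial(x, x))
        out = trial.cop["cop_ml"].to_numpy()[200:-200]  # exclude edge transients
        ratio = out.max()
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_short_trial_unusable(self):
        trial = preprocess(cop_trial(np.zeros(2000), np.zeros(2000)))  # 20 s @100 Hz
        assert not trial.usable
        assert "short" in trial.reason

    def test_zero_phase_preserves_peak_location(self):
        t = np.arange(2000) / 100.0
        bump = np.exp(-0.5 * ((t - 10.0) / 1.0) ** 2)
        filtered = lowpass_zero_phase(bump, 100.0)
        assert abs(int(np.argmax(filtered)) - int(np.argmax(bump))) <= 1


class TestSwayMetrics:
    def test_single_step_path_length(self):
        ml = np.array([0.0, 3.0] + [3.0] * 100)
        ap = np.array([0.0, 4.0] + [4.0] * 100)
        # add tiny jitter on a copy to keep SDs finite without moving the path
        m = sway_metrics(cop_trial(ml + 1e-12 * np.arange(102), ap))
        assert m.cop_length == pytest.approx(5.0, abs=1e-6)

    def test_stationary_cop_flagged(self):
        trial = cop_trial(np.zeros(100), np.zeros(100))
        assert sway_metrics(trial) is None
        assert not trial.usable

    def test_scaling_law(self):
        rng = np.random.default_rng(9)
        ml, ap = rng.normal(0, 1, 500), rng.normal(0, 1, 500)
        m1 = sway_metrics(cop_trial(ml, ap))
        m2 = sway_metrics(cop_trial(2 * ml, 2 * ap))
        assert m2.cop_length == pytest.approx(2 * m1.cop_length)
        assert m2.ml_sd_log == pytest.approx(m1.ml_sd_log + math.log(2))
        assert m2.ap_sd_log == pytest.approx(m1.ap_sd_log + math.log(2))

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(10)
        ml, ap = rng.normal(0, 1, 500), rng.normal(0, 1, 500)
        fwd = sway_metrics(cop_trial(ml, ap))
        rev = sway_metrics(cop_trial(ml[::-1], ap[::-1]))
        assert rev.cop_length == pytest.approx(fwd.cop_length)

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        ml, ap = rng.normal(0, 1, 500), rng.normal(0, 1, 500)
        base = sway_metrics(cop_trial(ml, ap))
        shifted = sway_metrics(cop_trial(ml + 7.0, ap - 3.0))
        assert shifted.cop_length == pytest.approx(base.cop_length)
        assert shifted.ml_sd_log == pytest.approx(base.ml_sd_log)
        assert shifted.ap_sd_log == pytest.approx(base.ap_sd_log)


class TestAggregation:
    def _usable(self, seed):
        rng = np.random.default_rng(seed)
        return cop_trial(rng.normal(0, 1, 500), rng.normal(0, 1, 500))

    def test_fewer_than_two_usable_excluded(self):
        assert aggregate_participant([self._usable(1)]) is None
        assert aggregate_participant([]) is None

    def test_mean_of_three_trials(self):
        trials = [self._usable(s) for s in (1, 2, 3)]
        expected = np.vstack(
            [sway_metrics(self._usable(s)).as_array() for s in (1, 2, 3)]
        ).mean(axis=0)
        agg = aggregate_participant(trials)
        np.testing.assert_allclose(agg.as_array(), expected)

    def test_unusable_trials_ignored(self):
        short = cop_trial(np.zeros(10), np.zeros(10))
        short.mark_unusable("lost balance")
        assert aggregate_participant([short, self._usable(1)]) is None


class TestCohensD:
    def test_children_cop_length_cell(self):
        assert cohens_d(35.74, 21.37, 6, 23.81, 15.36, 6) == pytest.approx(-0.641, abs=5e-4)

    def test_adults_cop_length_cell(self):
        assert cohens_d(19.45, 11.15, 5, 11.95, 1.36, 4) == pytest.approx(-0.944, abs=5e-4)

    def test_equal_means_give_zero(self):
        assert cohens_d(5.0, 1.0, 6, 5.0, 3.0, 6) == 0.0

    def test_antisymmetry(self):
        d1 = cohens_d(10.0, 2.0, 5, 12.0, 3.0, 7)
        d2 = cohens_d(12.0, 3.0, 7, 10.0, 2.0, 5)
        assert d1 == pytest.approx(-d2)

    def test_both_sds_zero_undefined(self):
        with pytest.raises(ValueError):
            cohens_d(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_unweighted_rms_discriminates_from_pooled_sd(self):
        """The n-weighted pooled-SD denominator cannot reproduce the
        unequal-n adult COP-length cell; the unweighted RMS does."""
        mean_a, sd_a, n_a = 19.45, 11.15, 5
        mean_c, sd_c, n_c = 11.95, 1.36, 4
        pooled = math.sqrt(
            ((n_a - 1) * sd_a**2 + (n_c - 1) * sd_c**2) / (n_a + n_c - 2)
        )
        d_pooled = (mean_c - mean_a) / pooled
        assert abs(d_pooled - (-0.944)) > 0.03
        assert cohens_d(mean_a, sd_a, n_a, mean_c, sd_c, n_c) == pytest.approx(
            -0.944, abs=5e-4
        )


def test_compare_groups_builds_study_style_table():
    rng = np.random.default_rng(21)
    affected = [SwayMetrics(*(rng.normal([30, -0.5, -0.3], 1.0))) for _ in range(6)]
    control = [SwayMetrics(*(rng.normal([24, -0.8, -0.4], 1.0))) for _ in range(6)]
    cmp = compare_groups(affected, control)
    assert list(cmp.table.index) == ["cop_length", "ml_sd_log", "ap_sd_log"]
    row = cmp.table.loc["cop_length"]
    expected = cohens_d(
        row["affected_mean"], row["affected_sd"], 6,
        row["control_mean"], row["control_sd"], 6,
    )
    assert row["cohen_d"] == pytest.approx(expected)
    assert cmp.n_affected == 6 and cmp.n_control == 6
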