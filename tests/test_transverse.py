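"""Strand-length import, differencing, ADF stationarity, fluctuation variance."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from forktrace import simkit
from forktrace.transverse import (
    adf_test,
    analyze_fluctuations,
    calibrate_bp_per_px,
    difference_series,
    fluctuation_variance,
    import_masks,
    skeleton_length,
    transverse_kinetics,
)


class TestImportMasks:
    def test_straight_line_length(self):
        lab = np.zeros((1, 30, 60), dtype=np.uint8)
        lab[0, 15, 5:55] = 1  # 50-px straight line
        df = import_masks(lab, {1: "leading"}, bp_per_px=300.0)
        assert df["leading_px"].iloc[0] == pytest.approx(50.0)
        assert df["leading_bp"].iloc[0] == pytest.approx(15_000.0)

    def test_diagonal_line_uses_sqrt2_steps(self):
        lab = np.zeros((1, 40, 40), dtype=np.uint8)
        for i in range(20):
            lab[0, 5 + i, 5 + i] = 1
        df = import_masks(lab, {1: "leading"}, bp_per_px=1.0)
        assert df["leading_px"].iloc[0] == pytest.approx(1 + 19 * np.sqrt(2), rel=0.01)

    def test_missing_class_is_nan_not_zero(self):
        lab = np.zeros((2, 20, 20), dtype=np.uint8)
        lab[0, 10, 2:12] = 1
        lab[1, 10, 2:12] = 1
        df = import_masks(lab, {1: "leading", 2: "lagging"}, bp_per_px=1.0)
        assert df["lagging_px"].isna().all()
        assert df["leading_px"].notna().all()

    def test_per_molecule_calibration_from_final_leading(self):
        assert calibrate_bp_per_px(np.array([10.0, 50.0, 90.0]), 27_000) == pytest.approx(300.0)

    def test_simulated_masks_recovered_within_2px(self):
        # rasterize known strand lengths as straight lines and re-measure
        rng = np.random.default_rng(0)
        true_px = rng.integers(10, 50, size=6)
        lab = np.zeros((6, 64, 64), dtype=np.uint8)
        for f, L in enumerate(true_px):
            lab[f, 20, 4 : 4 + L] = 1
        df = import_masks(lab, {1: "leading"}, bp_per_px=1.0)
        assert np.all(np.abs(df["leading_px"].to_numpy() - true_px) <= 2)


class TestDifferencing:
    def test_basic_example(self):
        np.testing.assert_allclose(difference_series([10.0, 12.0, 15.0]), [2.0, 3.0])

    def test_constant_gives_zeros(self):
        np.testing.assert_allclose(difference_series(np.full(8, 3.0)), np.zeros(7))

    def test_length_and_missing_policy(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        d = difference_series(x)
        # both pairs spanning the NaN are dropped
        np.testing.assert_allclose(d, [1.0, 1.0])
        assert len(difference_series(np.arange(10.0))) == 9

    def test_cumsum_roundtrip(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30).cumsum()
        d = difference_series(x)
        np.testing.assert_allclose(x[0] + np.concatenate([[0], np.cumsum(d)]), x)


class TestAdf:
    def test_random_walk_keeps_unit_root(self):
        kept = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            walk = np.cumsum(rng.normal(size=500))
            kept += not adf_test(walk).stationary
        assert kept >= 27  # >= 90 %

    def test_white_noise_rejects_unit_root(self):
        rej = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            rej += adf_test(rng.normal(size=500)).stationary
        assert rej >= 27

    def test_differencing_flips_random_walk_decision(self):
        flipped = 0
        for seed in range(30):
            rng = np.random.default_rng(2000 + seed)
            walk = np.cumsum(rng.normal(size=500))
            if not adf_test(walk).stationary and adf_test(np.diff(walk)).stationary:
                flipped += 1
        assert flipped >= 27

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            adf_test(np.arange(10.0))


class TestFluctuationVariance:
    def test_noiseless_linear_growth_zero(self):
        assert fluctuation_variance(np.linspace(0, 27, 60)) == pytest.approx(0.0, abs=1e-20)

    def test_iid_noise_gives_2_sigma_squared(self):
        rng = np.random.default_rng(3)
        sigma = 0.95
        vals = [
            fluctuation_variance(np.linspace(0, 27, 400) + rng.normal(0, sigma, 400))
            for _ in range(50)
        ]
        assert np.mean(vals) == pytest.approx(2 * sigma**2, rel=0.05)

    def test_invariant_under_offset_and_linear_trend(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 20, 100) + rng.normal(0, 1, 100)
        t = np.arange(100.0)
        base = fluctuation_variance(x)
        assert fluctuation_variance(x + 7.3) == pytest.approx(base)
        # a linear trend shifts the mean of the differences, not their variance
        assert fluctuation_variance(x + 0.05 * t) == pytest.approx(base)

    def test_constrained_exceeds_unconstrained_in_paired_cohorts(self):
        wins = 0
        n_pairs = 20
        for s in range(n_pairs):
            a, _ = simkit.simulate_transverse_traces(
                simkit.KINETIC_PRESETS["unconstrained"],
                simkit.ROTATION_PRESETS["unconstrained"],
                8,
                seed=100 + s,
            )
            b, _ = simkit.simulate_transverse_traces(
                simkit.KINETIC_PRESETS["constrained"],
                simkit.ROTATION_PRESETS["constrained"],
                8,
                seed=300 + s,
            )
            va = np.mean(
                [fluctuation_variance(g["lagging_bp"] / 1000) for _, g in a.groupby("molecule_id")]
            )
            vb = np.mean(
                [fluctuation_variance(g["lagging_bp"] / 1000) for _, g in b.groupby("molecule_id")]
            )
            wins += vb > va
        assert wins >= int(0.95 * n_pairs)

    def test_analyze_fluctuations_summary(self):
        traces, _ = simkit.simulate_transverse_traces(
            simkit.KINETIC_PRESETS["unconstrained"],
            simkit.ROTATION_PRESETS["unconstrained"],
            2,
            seed=5,
        )
        g = traces[traces["molecule_id"] == 0]
        fl = analyze_fluctuations(g)
        assert fl.stationary_after_diff
        assert fl.diff_variance_kb2 > 0


class TestTransverseKinetics:
    def test_noiseless_leading_growth_rate(self):
        t = np.arange(80) * 5.0
        df = pd.DataFrame(
            {
                "molecule_id": 0,
                "t_s": t,
                "leading_bp": np.minimum(100.0 * t, 27_000.0),
                "parental_bp": 27_000.0 - np.minimum(100.0 * t, 27_000.0),
                "lagging_bp": np.minimum(100.0 * t, 27_000.0),
            }
        )
        out = transverse_kinetics(df)
        assert out["leading"]["rate_bp_s"] == pytest.approx(100.0, rel=1e-6)
        assert out["parental"]["rate_bp_s"] == pytest.approx(-100.0, rel=1e-6)

    def test_parental_mirrors_leading_on_simulated_traces(self):
        kin = dataclasses.replace(
            simkit.KINETIC_PRESETS["unconstrained"],
            pause_prob_once=0.0,
            pause_prob_twice=0.0,
            completion_prob=1.0,
            duration=900.0,
        )
        rot = dataclasses.replace(
            simkit.ROTATION_PRESETS["unconstrained"],
            base_length_noise_kb=0.1,
            strand_noise_kb=0.1,
        )
        traces, _ = simkit.simulate_transverse_traces(kin, rot, 5, seed=6)
        rates = []
        for _, g in traces.groupby("molecule_id"):
            out = transverse_kinetics(g)
            rates.append((out["leading"]["rate_bp_s"], out["parental"]["rate_bp_s"]))
        for lead, par in rates:
            assert par == pytest.approx(-lead, rel=0.1)

    def test_lagging_rate_scales_with_compaction_factor(self):
        kin = dataclasses.replace(
            simkit.KINETIC_PRESETS["unconstrained"],
            pause_prob_once=0.0,
            pause_prob_twice=0.0,
            completion_prob=1.0,
            duration=900.0,
        )
        rot = dataclasses.replace(
            simkit.ROTATION_PRESETS["unconstrained"],
            base_length_noise_kb=0.1,
            strand_noise_kb=0.1,
            lagging_scale=0.8,
        )
        traces, _ = simkit.simulate_transverse_traces(kin, rot, 5, seed=7)
        for _, g in traces.groupby("molecule_id"):
            out = transverse_kinetics(g)
            assert out["lagging"]["rate_bp_s"] == pytest.approx(
                0.8 * out["leading"]["rate_bp_s"], rel=0.1
            )

    def test_skeleton_length_empty_mask_nan(self):
        assert np.isnan(skeleton_length(np.zeros((5, 5), dtype=bool)))


class TestProperties:
    """Hypothesis-driven invariants of the differencing statistics."""

    from hypothesis import given, settings, strategies as st

    @staticmethod
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=2,
            max_size=200,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_difference_cumsum_roundtrip(xs):
        x = np.asarray(xs)
        d = difference_series(x)
        np.testing.assert_allclose(
            x[0] + np.concatenate([[0], np.cumsum(d)]), x, atol=1e-6
        )

    @staticmethod
    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=12,
            max_size=100,
        ),
        st.floats(min_value=-100, max_value=100, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_variance_invariant_under_offset(xs, c):
        x = np.asarray(xs)
        assert fluctuation_variance(x + c) == pytest.approx(
            fluctuation_variance(x), rel=1e-6, abs=1e-9
        )
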