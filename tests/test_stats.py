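import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import delayrep as dr
from delayrep.stats import (
    exclude_outlier_participants,
    indifference_point,
    log_transform,
    normalize_reproductions,
)
from conftest import make_veridical


def cell(samples, reproductions, participant="P1", retention=2.0):
    return pd.DataFrame(
        {
            "participant": participant,
            "retention_s": retention,
            "sample_ms": np.asarray(samples, float),
            "reproduced_ms": np.asarray(reproductions, float),
        }
    )


class TestLogTransform:
    def test_known_values(self):
        d = cell([640, 1000], [640, 1000])
        out = log_transform(d)
        assert out["log10_sample"].iloc[0] == pytest.approx(2.80618, abs=1e-5)
        assert out["log10_sample"].iloc[1] == pytest.approx(3.0)

    @given(st.lists(st.floats(1.0, 1e5), min_size=1, max_size=30))
    def test_round_trip_identity(self, values):
        d = cell(values, values)
        out = log_transform(d)
        back = 10 ** out["log10_reproduced"].to_numpy()
        assert np.allclose(back, values, rtol=1e-12)

    def test_non_positive_duration_names_row(self):
        d = cell([640, 640], [500, -1])
        with pytest.raises(ValueError, match="reproduced_ms"):
            log_transform(d)


class TestExclusion:
    def test_veridical_data_keeps_everyone(self):
        data = make_veridical(3)
        kept, report = exclude_outlier_participants(data)
        assert report.removed == []
        assert set(report.flag_counts.values()) == {0}
        assert len(kept) == len(data)

    @pytest.mark.parametrize("n_bad,removed", [(31, True), (30, False)])
    def test_trial_count_boundary_is_strict(self, n_bad, removed):
        """Removal requires strictly more than 30 flagged trials."""
        data = make_veridical(2)
        target = data["participant"].iloc[0]
        idx = data.index[data["participant"] == target][:n_bad]
        data.loc[idx, "reproduced_ms"] = data.loc[idx, "sample_ms"] * 6.0
        kept, report = exclude_outlier_participants(data)
        assert (target in report.removed) is removed
        assert report.flag_counts[target] == n_bad

    def test_flags_both_directions(self):
        data = cell([640] * 4, [640 * 6, 640 / 6, 640 * 4, 640])
        _, report = exclude_outlier_participants(data, trial_threshold=1)
        assert report.flag_counts["P1"] == 2

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            exclude_outlier_participants(make_veridical(1), ratio_threshold=0)


class TestBlockRegression:
    def test_veridical_gives_unit_slope(self):
        d = cell([453, 640, 904], [453, 640, 904])
        a, b = dr.fit_block_regression(d)
        assert a == pytest.approx(1.0)
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_constant_reproduction_gives_flat_line(self):
        d = cell([453, 640, 904], [500, 500, 500])
        a, b = dr.fit_block_regression(d)
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(np.log10(500))

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(0)
        s = np.array([227, 321, 453, 640, 904, 1277, 1804], float)
        r = s * np.exp(rng.normal(0, 0.1, 7))
        a, b = dr.fit_block_regression(cell(s, r))
        x, y = np.log10(s), np.log10(r)
        X = np.column_stack([x, np.ones(7)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert a == pytest.approx(beta[0], abs=1e-10)
        assert b == pytest.approx(beta[1], abs=1e-10)

    def test_single_interval_degenerate(self):
        with pytest.raises(ValueError):
            dr.fit_block_regression(cell([640, 640], [600, 700]))


class TestIndifferencePoint:
    def test_flat_line_crosses_unity_at_its_level(self):
        assert indifference_point(0.0, np.log10(640)) == pytest.approx(640)

    @given(st.floats(-2, 0.9))
    def test_any_line_through_the_center_fixed_point(self, a):
        """Lines through (log 640, log 640) cross unity at 640 ms."""
        b = (1 - a) * np.log10(640)
        assert indifference_point(a, b) == pytest.approx(640, rel=1e-9)

    def test_half_slope_arithmetic(self):
        assert indifference_point(0.5, 1.4031) == pytest.approx(10**2.8062, rel=1e-4)

    def test_unit_slope_is_undefined_flag(self):
        assert np.isnan(indifference_point(1.0, 0.3))
        assert np.isnan(indifference_point(1.0 + 1e-12, 0.3))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            indifference_point(np.inf, 0.0)

    @given(st.floats(0.1, 0.9), st.floats(0.1, 2.0), st.floats(0.5, 5.0))
    def test_scale_equivariance(self, a, b, k):
        """Multiplying all durations by k multiplies the crossing point by k.

        Rescaling durations by k leaves the log-log slope and shifts the
        intercept by (1-a) log k.
        """
        i1 = indifference_point(a, b)
        i2 = indifference_point(a, b + (1 - a) * np.log10(k))
        assert i2 == pytest.approx(k * i1, rel=1e-9)


class TestNormalization:
    def test_veridical_cell_recovers_samples(self):
        d = cell([453, 640, 904] * 2, [453, 640, 904] * 2)
        assert np.allclose(normalize_reproductions(d), d["sample_ms"])

    def test_constant_reproduction_maps_to_mean_sample(self):
        d = cell([453, 640, 904], [777, 777, 777])
        assert np.allclose(normalize_reproductions(d), d["sample_ms"].mean())

    @given(st.integers(0, 1000))
    def test_mean_conservation(self, seed):
        """The mean recentered reproduction equals the mean sample exactly."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 40)
        d = cell(rng.uniform(100, 2000, n), rng.uniform(100, 2000, n))
        r_prime = normalize_reproductions(d)
        assert np.mean(r_prime) == pytest.approx(d["sample_ms"].mean(), rel=1e-12)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            normalize_reproductions(cell([], []))


class TestErrorStats:
    def test_perfect_reproduction_zero_errors(self):
        data = make_veridical(2)
        es = dr.error_stats(data)
        assert np.allclose(es["ve"], 0.0)
        assert np.allclose(es["cv"], 0.0)
        assert (es["n_reps"] == 10).all()

    def test_unit_ve_construction(self):
        """R' values sitting one mean-interval above S_i give VE exactly 1."""
        s_bar = 600.0
        for s_i in (400.0, 800.0):
            rp = np.full(5, s_i + s_bar)
            assert dr.vertical_error(rp, s_i, s_bar) == pytest.approx(1.0)

    def test_unit_cv_construction(self):
        """Two repetitions straddling the mean by +/- Sbar give CV exactly 1."""
        d = cell([600.0, 600.0], [600 - 600, 600 + 600])
        # reproduced must be positive; shift both by the same amount instead
        d["reproduced_ms"] = [1.0, 1201.0]
        es = dr.error_stats(d)
        assert es["cv"].iloc[0] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        """Direct loop evaluation of the decomposition on a random cell."""
        rng = np.random.default_rng(42)
        s = np.repeat([300.0, 600.0, 1200.0], 8)
        r = rng.uniform(200, 2000, len(s))
        d = cell(s, r)
        es = dr.error_stats(d).set_index("sample_ms")
        r_bar, s_bar = r.mean(), s.mean()
        for s_i in (300.0, 600.0, 1200.0):
            rp = r[s == s_i] - r_bar + s_bar
            ve = abs(rp.mean() - s_i) / s_bar
            cv = np.sqrt(((rp - rp.mean()) ** 2).mean()) / s_bar
            assert es.loc[s_i, "ve"] == pytest.approx(ve, abs=1e-12)
            assert es.loc[s_i, "cv"] == pytest.approx(cv, abs=1e-12)

    def test_log_scale_option(self):
        data = make_veridical(1)
        es = dr.error_stats(data, scale="log10")
        assert (es["scale"] == "log10").all()
        assert np.allclose(es["ve"], 0.0)

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError):
            dr.error_stats(make_veridical(1), scale="seconds")


def test_block_fits_table_shape(small_exp2_dataset):
    data, _ = small_exp2_dataset
    fits = dr.block_fits(data)
    assert len(fits) == 20 * 3
    assert (fits["n_trials"] == 70).all()
    assert fits["slope"].between(0, 1.2).all()
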