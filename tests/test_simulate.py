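"""Synthetic cohort generator: calibration, determinism, injections, I/O."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tegma.errors import ConfigurationError, ParseError
from tegma.reference import ACT_TO_CRT_R_LINE, CFF_MA_DECAY
from tegma.simulate import (CSV_COLUMNS, CohortConfig, PairedDataset,
                            default_channels, default_cohort_config,
                            generate_dataset, inject_missingness,
                            inject_outliers, lognormal_params_from_quartiles,
                            read_fixture, sample_crt_r, simulate_cohort,
                            write_fixture)


class TestCrtRMarginal:
    def test_quartile_inversion_closed_form(self):
        # median 0.7, IQR 0.5-0.9 -> mu = ln 0.7, sigma = ln(1.8)/(2 z_.75)
        mu, sigma = lognormal_params_from_quartiles(0.7, 0.5, 0.9)
        assert mu == pytest.approx(-0.3567, abs=1e-4)
        assert sigma == pytest.approx(0.4357, abs=1e-4)

    def test_zero_spread_degenerates_to_constant(self):
        cfg = default_cohort_config(n_records=20, crt_r_log_sigma=0.0)
        vals = sample_crt_r(cfg)
        assert np.all(vals == math.exp(cfg.crt_r_log_mu))

    def test_monte_carlo_matches_truncated_lognormal_quantiles(self):
        # Oracle: closed-form quantile function of the log-normal restricted
        # to [0.3, 5.5]. The truncated distribution's own quartiles (not the
        # untruncated 0.5/0.9 targets, which a two-parameter log-normal
        # cannot reproduce jointly with the median) are the reference.
        cfg = default_cohort_config(seed=42, n_records=50_000)
        dist = stats.lognorm(s=cfg.crt_r_log_sigma,
                             scale=math.exp(cfg.crt_r_log_mu))
        f_lo, f_hi = dist.cdf(cfg.crt_r_lo), dist.cdf(cfg.crt_r_hi)
        q1, med, q3 = dist.ppf(f_lo + np.array([0.25, 0.5, 0.75])
                               * (f_hi - f_lo))
        vals = sample_crt_r(cfg)
        emp_q1, emp_med, emp_q3 = np.percentile(vals, [25, 50, 75])
        assert emp_med == pytest.approx(med, abs=0.01)
        assert emp_q1 == pytest.approx(q1, abs=0.01)
        assert emp_q3 == pytest.approx(q3, abs=0.01)
        # headline calibration: median ~ 0.7 min, quartile ratio ~ 1.8
        assert emp_med == pytest.approx(0.7, abs=0.02)
        assert emp_q3 / emp_q1 == pytest.approx(1.8, abs=0.05)
        assert vals.min() >= cfg.crt_r_lo and vals.max() <= cfg.crt_r_hi


class TestGenerateDataset:
    def test_noiseless_points_lie_on_model_curves(self):
        cfg = default_cohort_config(
            n_records=200, channels=default_channels(noiseless=True))
        ds = generate_dataset(cfg)
        x = ds.df["crt_r_min"].to_numpy()
        np.testing.assert_allclose(
            ds.df["cff_ma_mm"].to_numpy(), CFF_MA_DECAY.predict(x),
            rtol=1e-12)

    def test_teg_act_is_exact_inverse_of_linear_map(self):
        ds = generate_dataset(default_cohort_config(n_records=300, seed=5))
        crt_r = ds.df["crt_r_min"].to_numpy()
        act = ds.df["teg_act_s"].to_numpy()
        line = ACT_TO_CRT_R_LINE
        np.testing.assert_array_equal(act, (crt_r - line.intercept)
                                      / line.slope)
        # forward map returns CRT-R to float round-off
        np.testing.assert_allclose(line.predict(act), crt_r, rtol=1e-12)

    def test_noisy_correlation_matches_variance_decomposition(self):
        # Population |r| follows r^2 = Var(mean curve)/(Var + noise_sd^2)
        # under the calibrated marginal: 0.596 before clipping, 0.58 once
        # amplitudes are clipped at zero (large-n Monte-Carlo oracle).
        cfg = default_cohort_config(seed=11, n_records=2349,
                                    missing_rate=0.0, outlier_rate=0.0)
        ds = generate_dataset(cfg)
        r = np.corrcoef(ds.df["crt_r_min"], ds.df["cff_ma_mm"])[0, 1]
        assert abs(r) == pytest.approx(0.58, abs=0.05)

    def test_values_respect_clip_bounds(self):
        ds = simulate_cohort(default_cohort_config(seed=2, n_records=2000))
        for ch in default_channels():
            vals = ds.df[ch.column].dropna().to_numpy()
            assert vals.min() >= ch.clip_lo and vals.max() <= ch.clip_hi

    def test_seed_determinism_is_bitwise(self):
        a = simulate_cohort(default_cohort_config(seed=9, n_records=500))
        b = simulate_cohort(default_cohort_config(seed=9, n_records=500))
        pd.testing.assert_frame_equal(a.df, b.df)
        c = simulate_cohort(default_cohort_config(seed=10, n_records=500))
        assert not a.df.equals(c.df)


class TestInjections:
    def test_zero_rates_leave_dataset_unchanged(self):
        ds = generate_dataset(default_cohort_config(n_records=50, seed=1))
        assert inject_missingness(ds, 0.0, seed=3).df.equals(ds.df)
        assert inject_outliers(ds, 0.0, 5.6, 9.0, seed=3).df.equals(ds.df)

    def test_missingness_count_within_binomial_band(self):
        rate = 80 / 2453
        ds = generate_dataset(default_cohort_config(n_records=2453, seed=4))
        out = inject_missingness(ds, rate, seed=4)
        k = out.provenance["n_missing_injected"]
        lo, hi = stats.binom.interval(0.95, 2453, rate)
        assert lo <= k <= hi
        assert int(out.df[list(CSV_COLUMNS[1:])].isna().any(axis=1).sum()) == k

    def test_missingness_blanks_one_field_per_affected_record(self):
        ds = generate_dataset(default_cohort_config(n_records=10, seed=8))
        out = inject_missingness(ds, 0.5, seed=8)
        per_row = out.df[list(CSV_COLUMNS[1:])].isna().sum(axis=1)
        assert set(per_row.unique()) <= {0, 1}
        rerun = inject_missingness(ds, 0.5, seed=8)
        pd.testing.assert_frame_equal(out.df, rerun.df)

    def test_outlier_count_within_binomial_band_and_all_excluded(self):
        from tegma.preprocess import apply_exclusions
        rate = 24 / 2453
        ds = generate_dataset(default_cohort_config(n_records=2453, seed=6))
        out = inject_outliers(ds, rate, 5.6, 15.0, seed=6)
        k = out.provenance["n_outliers_injected"]
        lo, hi = stats.binom.interval(0.95, 2453, rate)
        assert lo <= k <= hi
        assert int((out.df["crt_r_min"] > 5.5).sum()) == k
        filtered, report = apply_exclusions(out)
        assert report.n_outlier_excluded == k
        assert (filtered.df["crt_r_min"] <= 5.5).all()

    def test_outlier_bound_at_or_below_exclusion_threshold_rejected(self):
        ds = generate_dataset(default_cohort_config(n_records=5))
        with pytest.raises(ConfigurationError):
            inject_outliers(ds, 0.1, 5.5, 9.0)

    @pytest.mark.parametrize("field,value", [
        ("missing_rate", 1.0), ("outlier_rate", -0.1), ("n_records", 0),
        ("crt_r_lo", 0.0), ("outlier_lo", 5.0),
    ])
    def test_invalid_config_rejected(self, field, value):
        with pytest.raises(ConfigurationError):
            CohortConfig(**{field: value})


class TestFixtureIO:
    def test_round_trip_is_lossless(self, tmp_path):
        ds = simulate_cohort(default_cohort_config(seed=3, n_records=80))
        path = tmp_path / "cohort.csv"
        write_fixture(ds, path)
        back = read_fixture(path)
        pd.testing.assert_frame_equal(ds.df, back.df)

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("record_id,crt_r_min,crt_ma_mm\n0,0.7,54.2\n")
        with pytest.raises(ParseError, match="ckh_r_min") as exc:
            read_fixture(path)
        assert exc.value.column == "ckh_r_min"

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        ds = generate_dataset(default_cohort_config(n_records=3, seed=0))
        path = tmp_path / "cohort.csv"
        write_fixture(ds, path)
        lines = path.read_text().splitlines()
        cells = lines[2].split(",")
        cells[4] = "not-a-number"  # ckh_ma_mm of the second record
        lines[2] = ",".join(cells)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="ckh_ma_mm"):
            read_fixture(path)

    def test_empty_record_set_round_trips(self, tmp_path):
        empty = PairedDataset(
            pd.DataFrame({c: pd.Series(dtype=float) for c in CSV_COLUMNS}))
        path = tmp_path / "empty.csv"
        write_fixture(empty, path)
        assert path.read_text() == ",".join(CSV_COLUMNS) + "\n"
        assert read_fixture(path).n_records == 0
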