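import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gslsrm.quant import (
    ND,
    PeakAreaTable,
    SRMChromatogram,
    area_ratio_table,
    detection_summary,
    integrate_peak,
    linearity,
    matrix_factor,
    read_area_table,
    recovery,
    round_sigfig,
    write_area_table,
)


def gaussian_trace(rt=10.0, sd=0.1, amplitude=1000.0, baseline=None, t=None):
    if t is None:
        t = np.arange(5.0, 15.0, 0.01)
    y = amplitude * np.exp(-0.5 * ((t - rt) / sd) ** 2)
    if baseline is not None:
        y = y + baseline(t)
    return SRMChromatogram("t1", t, np.clip(y, 0, None))


class TestSRMChromatogram:
    def test_rejects_unsorted_time(self):
        with pytest.raises(ValueError, match="increasing"):
            SRMChromatogram("x", np.array([1.0, 0.5, 2.0]), np.zeros(3))

    def test_rejects_negative_intensity(self):
        with pytest.raises(ValueError, match="negative"):
            SRMChromatogram("x", np.array([0.0, 1.0]), np.array([1.0, -1.0]))


class TestIntegratePeak:
    def test_gaussian_closed_form(self):
        chrom = gaussian_trace(amplitude=1000.0, sd=0.1)
        peak = integrate_peak(chrom, (9.0, 11.0))
        expected = 1000.0 * 0.1 * math.sqrt(2 * math.pi)
        assert peak.detected
        assert peak.area == pytest.approx(expected, rel=0.01)
        assert peak.rt == pytest.approx(10.0, abs=0.02)
        assert peak.height == pytest.approx(1000.0, rel=0.01)

    def test_flat_zero_not_detected(self):
        t = np.arange(0.0, 20.0, 0.01)
        peak = integrate_peak(SRMChromatogram("x", t, np.zeros_like(t)), (9.0, 11.0))
        assert not peak.detected
        assert peak.area == 0.0

    def test_sloped_baseline(self):
        chrom = gaussian_trace(amplitude=1000.0, sd=0.1, baseline=lambda t: 50.0 + 20.0 * t)
        peak = integrate_peak(chrom, (9.0, 11.0))
        expected = 1000.0 * 0.1 * math.sqrt(2 * math.pi)
        assert peak.area == pytest.approx(expected, rel=0.02)

    def test_empty_window_raises(self):
        chrom = gaussian_trace()
        with pytest.raises(ValueError):
            integrate_peak(chrom, (11.0, 9.0))
        with pytest.raises(ValueError):
            integrate_peak(chrom, (40.0, 41.0))

    def test_linearity_in_scale(self):
        chrom = gaussian_trace(amplitude=500.0)
        scaled = SRMChromatogram("t1", chrom.time, chrom.intensity * 3.0)
        a1 = integrate_peak(chrom, (9.0, 11.0)).area
        a3 = integrate_peak(scaled, (9.0, 11.0)).area
        assert a3 == pytest.approx(3.0 * a1, rel=1e-9)

    def test_small_peak_below_noise_floor(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 20.0, 0.01)
        noise = np.clip(rng.normal(100.0, 30.0, t.size), 0, None)
        y = noise + 5.0 * np.exp(-0.5 * ((t - 10.0) / 0.1) ** 2)
        peak = integrate_peak(SRMChromatogram("x", t, y), (9.5, 10.5))
        assert not peak.detected


class TestAreaRatioTable:
    def _table(self, values):
        return PeakAreaTable(pd.DataFrame({"medium": values}, index=["DSGb5", "GD1a"]))

    def test_table1_dsgb5(self):
        num = self._table([4577916.0, 4343382.0])
        den = self._table([997593.0, 4503695.0])
        out = area_ratio_table(num, den)
        assert out.loc["DSGb5", "medium"] == 459
        assert out.loc["GD1a", "medium"] == 96.4

    def test_identity_is_100(self):
        t = self._table([123.0, 456.0])
        assert (area_ratio_table(t, t)["medium"] == 100.0).all()

    def test_nd_denominator_undefined(self):
        num = self._table([10.0, 10.0])
        den = self._table([np.nan, 0.0])
        out = area_ratio_table(num, den)
        assert out["medium"].isna().all()

    def test_no_shared_analytes(self):
        a = PeakAreaTable(pd.DataFrame({"s": [1.0]}, index=["x"]))
        b = PeakAreaTable(pd.DataFrame({"s": [1.0]}, index=["y"]))
        with pytest.raises(ValueError):
            area_ratio_table(a, b)


class TestRoundSigfig:
    @pytest.mark.parametrize(
        "value,expected",
        [(458.896, 459.0), (117.398, 117.0), (96.4404, 96.4), (89.5883, 89.6), (0.0, 0.0)],
    )
    def test_three_sigfig(self, value, expected):
        assert round_sigfig(value, 3) == expected


class TestMatrixFactor:
    def test_additive_spiking_is_100(self):
        assert matrix_factor(1000.0, 500.0, 1500.0) == pytest.approx(100.0)

    def test_mirrors_published_value(self):
        assert matrix_factor(1000.0, 500.0, 1560.0) == pytest.approx(106.0)

    def test_full_suppression_is_0(self):
        assert matrix_factor(1000.0, 500.0, 500.0) == pytest.approx(0.0)

    def test_alternate_convention(self):
        assert matrix_factor(1000.0, 500.0, 1500.0, convention="alternate") == pytest.approx(100.0)

    def test_zero_divisor_named(self):
        with pytest.raises(ZeroDivisionError, match="area_std"):
            matrix_factor(0.0, 500.0, 1500.0)
        with pytest.raises(ZeroDivisionError, match="area_matrix"):
            matrix_factor(1000.0, 0.0, 1500.0, convention="alternate")

    @given(
        st.floats(min_value=1.0, max_value=1e6),
        st.floats(min_value=0.0, max_value=1e6),
        st.floats(min_value=0.0, max_value=1e6),
        st.floats(min_value=0.1, max_value=100.0),
    )
    def test_scale_invariance(self, std, matrix, spiked, k):
        base = matrix_factor(std, matrix, spiked)
        scaled = matrix_factor(k * std, k * matrix, k * spiked)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestRecovery:
    def test_identity(self):
        assert recovery(1000.0, 1000.0) == 100.00

    def test_two_decimal(self):
        assert recovery(957.7, 1000.0) == 95.77

    def test_zero_processed(self):
        assert recovery(0.0, 1000.0) == 0.00

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            recovery(10.0, 0.0)


class TestLinearity:
    def test_collinear(self):
        slope, intercept, r = linearity([(1, 2), (2, 4), (3, 6)])
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(42)
        x = np.array([0.1, 0.3, 1.0, 3.0, 10.0])
        y = 2.0 * x + 0.5 + rng.normal(0, 0.1, x.size)
        slope, intercept, r = linearity(list(zip(x, y)))
        # independent oracle: explicit normal equations + covariance formula
        A = np.vstack([x, np.ones_like(x)]).T
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        r_oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert slope == pytest.approx(beta[0], abs=1e-10)
        assert intercept == pytest.approx(beta[1], abs=1e-10)
        assert r == pytest.approx(r_oracle, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            linearity([(1, 2), (2, 4)])
        with pytest.raises(ValueError):
            linearity([(1, 2), (1, 3), (1, 4)])

    @settings(max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_r_squared_matches_covariance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, size=8)
        if np.unique(x).size < 2:
            x[0] += 1.0
        y = rng.uniform(0, 1e6, size=8)
        _, _, r = linearity(list(zip(x, y)))
        cov = ((x - x.mean()) * (y - y.mean())).sum()
        denom = math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r**2 == pytest.approx((cov / denom) ** 2, abs=1e-10)


class TestDetectionSummary:
    def test_counts(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(1, 100, size=240)
        nd_idx = rng.choice(240, size=52, replace=False)
        values[nd_idx] = np.nan
        table = PeakAreaTable(
            pd.DataFrame({"HK-2": values}, index=[f"a{i}" for i in range(240)])
        )
        out = detection_summary(table)
        assert out.loc["HK-2", "detected"] == 188
        assert out.loc["HK-2", "not_detected"] == 52

    def test_all_detected(self):
        table = PeakAreaTable(pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"]))
        assert detection_summary(table).loc["s", "not_detected"] == 0

    def test_empty(self):
        table = PeakAreaTable(pd.DataFrame({"s": []}))
        out = detection_summary(table)
        assert out.loc["s", "detected"] == 0
        assert out.loc["s", "not_detected"] == 0


class TestAreaTableIO:
    def test_round_trip_with_nd(self, tmp_path):
        df = pd.DataFrame(
            {"HK-2": [997593.0, np.nan], "ACHN": [4577916.0, 12.0]},
            index=["DSGb5 (d18:1/16:0)", "GM2 (d18:1/24:1)"],
        )
        path = tmp_path / "areas.csv"
        write_area_table(PeakAreaTable(df), path)
        assert ND in path.read_text()
        back = read_area_table(path)
        pd.testing.assert_frame_equal(back.data, df, check_names=False)
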