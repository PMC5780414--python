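"""Trapezoidal depth integration with bottom extension and sd propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from darkcarbon import (
    DHAL_FLAG,
    DepthSample,
    InvalidInputError,
    StationProfile,
    integrate_profile,
    propagate_integral_sd,
)
from darkcarbon.integration import trapezoid_weights


def make_profile(depths, rates, bottom, sds=None, station="T", flags=None):
    sds = sds if sds is not None else [None] * len(depths)
    flags = flags if flags is not None else [frozenset()] * len(depths)
    samples = [
        DepthSample(station, z, abd=r, abd_sd=s, flags=f)
        for z, r, s, f in zip(depths, rates, sds, flags)
    ]
    return StationProfile(station, bottom, samples)


def riemann_oracle(depths, rates, bottom):
    """Dense numerical integral of the piecewise-linear interpolant.

    Independent of the closed-form weight bookkeeping: evaluates the
    interpolant (with constant extension beyond the deepest sample, the
    bottom-extension convention) on a dense sub-metre grid and sums.
    """
    z = np.union1d(np.linspace(depths[0], bottom, 8192), np.asarray(depths, dtype=float))
    z = z[(z >= depths[0]) & (z <= bottom)]
    r = np.interp(z, depths, rates)
    return float(np.trapezoid(r, z)) / 1e3


class TestIntegrateProfile:
    def test_tyrrhenian_station_profile(self):
        """114/231/59/48 µg C/m³/d at 200-3500 m over a 3571 m column → 396."""
        p = make_profile([200, 400, 2500, 3500], [114, 231, 59, 48], 3571)
        assert integrate_profile(p, "abd").value == pytest.approx(396.0, rel=6e-3)

    def test_alboran_station_profile(self):
        p = make_profile([200, 400, 1500, 2633], [268, 198, 204, 142], 2640)
        assert integrate_profile(p, "abd").value == pytest.approx(465.0, rel=6e-3)

    def test_uniform_rate_is_a_rectangle(self):
        p = make_profile([200, 700, 1200], [100, 100, 100], 1200)
        assert integrate_profile(p, "abd").value == pytest.approx(100.0)

    def test_flagged_sample_excluded_and_recorded(self):
        depths = [200, 500, 1000, 2000, 3000, 3400]
        rates = [140, 370, 290, 245, 207, 730]
        flags = [frozenset()] * 5 + [frozenset({DHAL_FLAG})]
        p = make_profile(depths, rates, 3625, flags=flags)
        res = integrate_profile(p, "abd")
        assert res.excluded == [3400.0]
        assert res.n_points == 5
        assert res.value == pytest.approx(864.4, abs=0.1)
        # including the interface sample inflates the column far beyond it
        res_all = integrate_profile(p, "abd", exclusions=())
        assert res_all.value > 1000.0

    def test_no_usable_samples_rejected(self):
        p = make_profile([200, 400], [None, None], 500)
        with pytest.raises(InvalidInputError):
            integrate_profile(p, "abd")

    def test_no_upward_extrapolation(self, caplog):
        p = make_profile([500, 1000], [100, 100], 1000)
        with caplog.at_level("WARNING"):
            res = integrate_profile(p, "abd", z_top=200.0)
        assert res.value == pytest.approx(50.0)  # 500-1000 m only
        assert res.z_top == 500.0

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_matches_dense_riemann_oracle(self, data):
        n = data.draw(st.integers(2, 7))
        depths = sorted(data.draw(st.lists(
            st.integers(200, 3000), min_size=n, max_size=n, unique=True)))
        depths = [float(z) for z in depths]
        rates = data.draw(st.lists(st.floats(0.0, 500.0), min_size=n, max_size=n))
        bottom = max(depths) + data.draw(st.floats(1.0, 500.0))
        p = make_profile(depths, rates, bottom)
        value = integrate_profile(p, "abd").value
        oracle = riemann_oracle(depths, rates, bottom)
        assert value == pytest.approx(oracle, rel=1e-3, abs=1e-6)

    def test_additive_over_a_split_column(self):
        depths = [200, 400, 1500, 2633]
        rates = [268, 198, 204, 142]
        full = integrate_profile(make_profile(depths, rates, 2640), "abd").value
        upper = make_profile(depths[:3], rates[:3], 1500)
        lower = make_profile(depths[2:], rates[2:], 2640)
        split = integrate_profile(upper, "abd").value + integrate_profile(
            lower, "abd", z_top=1500.0).value
        assert split == pytest.approx(full, rel=1e-12)

    def test_pointwise_monotonicity(self):
        depths = [200, 1000, 2000]
        small = make_profile(depths, [50, 60, 70], 2500)
        large = make_profile(depths, [55, 80, 71], 2500)
        assert integrate_profile(large, "abd").value > integrate_profile(small, "abd").value


class TestSDPropagation:
    def test_zero_point_sds_give_zero(self):
        p = make_profile([200, 1000], [100, 100], 1500, sds=[0.0, 0.0])
        assert propagate_integral_sd(p, "abd") == 0.0

    def test_single_point_closed_form(self):
        # one sample: sd × column thickness / 10³
        p = make_profile([200], [100], 1200, sds=[7.0])
        assert propagate_integral_sd(p, "abd") == pytest.approx(7.0 * 1000 / 1e3)

    def test_delta_method_quadrature(self):
        """Weights 100/1150/1550/571 m for the 200-3500 m grid over 3571 m.

        Hand quadrature: sqrt((100·14)² + (1150·21)² + (1550·9)² + (571·6)²)/10³.
        """
        p = make_profile([200, 400, 2500, 3500], [114, 231, 59, 48], 3571, sds=[14, 21, 9, 6])
        expected = np.sqrt((100 * 14) ** 2 + (1150 * 21) ** 2 + (1550 * 9) ** 2 + (571 * 6) ** 2) / 1e3
        assert propagate_integral_sd(p, "abd") == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(28.1, abs=0.05)

    def test_missing_sds_yield_absent(self):
        p = make_profile([200, 1000], [100, 100], 1500, sds=[1.0, None])
        assert propagate_integral_sd(p, "abd") is None


def test_trapezoid_weights_sum_to_column_thickness():
    depths = [200.0, 400.0, 2500.0, 3500.0]
    w = trapezoid_weights(depths, 3571.0)
    assert w.sum() == pytest.approx(3571.0 - 200.0)
    assert w.tolist() == pytest.approx([100.0, 1150.0, 1550.0, 571.0])
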