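"""Band integration, proportion normalisation, repeat aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmidrbe.errors import EmptyLaneError
from plasmidrbe.gel_quant import (
    BandWindow,
    FormProportions,
    LaneProfile,
    aggregate_repeats,
    integrate_bands,
    proportions_from_intensities,
)


def _gaussian_lane(areas, centres=(20.0, 50.0, 80.0), sigma=2.0, baseline=0.0, n=2001):
    x = np.linspace(0.0, 100.0, n)
    sig = np.full_like(x, baseline)
    for a, c in zip(areas, centres):
        sig += a * np.exp(-0.5 * ((x - c) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    windows = [BandWindow(s, c - 6, c + 6) for s, c in zip(("SC", "OC", "L"), centres)]
    return LaneProfile(x, sig), windows


def test_gaussian_bands_integrate_in_area_ratio():
    """Unit-area Gaussians scaled 6:3:1 integrate in ratio 6:3:1 within 1%."""
    profile, windows = _gaussian_lane((6.0, 3.0, 1.0))
    ints = integrate_bands(profile, windows)
    assert ints["SC"] / ints["L"] == pytest.approx(6.0, rel=0.01)
    assert ints["OC"] / ints["L"] == pytest.approx(3.0, rel=0.01)


def test_constant_signal_is_all_baseline():
    x = np.linspace(0.0, 100.0, 500)
    profile = LaneProfile(x, np.full_like(x, 3.7))
    windows = [BandWindow(s, c - 6, c + 6) for s, c in zip(("SC", "OC", "L"), (20, 50, 80))]
    with pytest.raises(EmptyLaneError):
        integrate_bands(profile, windows)


def test_overhanging_band_integrates_window_portion_only():
    """A band centred on a window edge: integral equals the brute trapezoid
    over the in-window samples alone."""
    x = np.linspace(0.0, 100.0, 4001)
    sigma, c = 2.0, 26.0  # centre sits on the SC window's upper edge
    sig = np.exp(-0.5 * ((x - c) / sigma) ** 2)
    profile = LaneProfile(x, sig)
    windows = [BandWindow(s, w0, w1) for s, (w0, w1) in zip(("SC", "OC", "L"), ((14, 26), (44, 56), (74, 86)))]
    ints = integrate_bands(profile, windows)
    mask = (x >= 14) & (x <= 26)
    oracle = np.trapezoid(sig[mask], x[mask])  # baseline is ~0 here
    assert ints["SC"] == pytest.approx(oracle, rel=1e-6)


def test_dense_grid_oracle_agreement():
    """Band integrals agree with an independent dense-grid integration within 0.5%."""
    profile, windows = _gaussian_lane((4.0, 2.0, 1.5), baseline=0.2, n=1501)
    ints = integrate_bands(profile, windows)
    dense_x = np.linspace(0.0, 100.0, 200001)
    for w, area in zip(windows, (4.0, 2.0, 1.5)):
        mask = (dense_x >= w.start) & (dense_x <= w.end)
        dense = np.interp(dense_x, profile.positions, np.clip(profile.signal - 0.2, 0, None))
        oracle = np.trapezoid(dense[mask], dense_x[mask])
        assert ints[w.species] == pytest.approx(oracle, rel=0.005)


def test_window_validation():
    profile, windows = _gaussian_lane((1.0, 1.0, 1.0))
    with pytest.raises(ValueError, match="overlap"):
        integrate_bands(profile, [BandWindow("SC", 10, 52), windows[1], windows[2]])
    with pytest.raises(ValueError, match="outside"):
        integrate_bands(profile, [BandWindow("SC", -5, 26), windows[1], windows[2]])


@pytest.mark.parametrize(
    "intensities, expected",
    [
        ((0.867, 0.100, 0.033), (0.867, 0.100, 0.033)),  # unirradiated dry control
        ((5.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
        ((2.0, 2.0, 2.0), (1 / 3, 1 / 3, 1 / 3)),
    ],
)
def test_proportions_from_intensities(intensities, expected):
    p = proportions_from_intensities(*intensities)
    assert p.as_tuple() == pytest.approx(expected, abs=1e-12)


def test_empty_lane_and_negative_intensities():
    with pytest.raises(EmptyLaneError):
        proportions_from_intensities(0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        proportions_from_intensities(-1.0, 1.0, 1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    a=st.floats(0.0, 1e3),
    b=st.floats(0.0, 1e3),
    c=st.floats(1e-6, 1e3),
    k=st.floats(1e-6, 1e6),
)
def test_proportions_scale_invariant_and_sum_to_one(a, b, c, k):
    p = proportions_from_intensities(a, b, c)
    q = proportions_from_intensities(a * k, b * k, c * k)
    assert sum(p.as_tuple()) == pytest.approx(1.0, abs=1e-9)
    assert p.as_tuple() == pytest.approx(q.as_tuple(), rel=1e-9, abs=1e-12)


class TestAggregateRepeats:
    def _props(self, sc):
        return FormProportions(sc, (1 - sc) * 0.6, (1 - sc) * 0.4)

    def test_two_point_formula(self):
        mean, sem = aggregate_repeats([self._props(0.8), self._props(0.9)])
        assert mean.p_sc == pytest.approx(0.85)
        assert sem["SC"] == pytest.approx(0.05)

    def test_identical_repeats_sem_zero(self):
        mean, sem = aggregate_repeats([self._props(0.7)] * 3)
        assert all(v == pytest.approx(0.0, abs=1e-15) for v in sem.values())

    def test_three_point_sem(self):
        mean, sem = aggregate_repeats([self._props(v) for v in (0.86, 0.87, 0.88)])
        assert mean.p_sc == pytest.approx(0.87)
        assert sem["SC"] == pytest.approx(0.01 / math.sqrt(3), abs=1e-5)  # 0.00577

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError, match="2 gel repeats"):
            aggregate_repeats([self._props(0.8)])


def test_form_proportions_validation():
    with pytest.raises(ValueError):
        FormProportions(0.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        FormProportions(1.2, -0.1, -0.1)
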