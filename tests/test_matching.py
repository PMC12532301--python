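import numpy as np
import pytest

import rayleighsim as rs
from rayleighsim.errors import GridMismatchError, NoMatchInRangeError


def _scaled_mixture(instrument, k):
    """Scale both mixture channels' radiometric output by a common factor."""
    from dataclasses import replace
    red = replace(instrument.red, spd=k * instrument.red.spd)
    green = replace(instrument.green, spd=k * instrument.green.spd)
    return replace(instrument, red=red, green=green)


class TestConeExcitation:
    def test_zero_spd_gives_zero(self, grid, normal_set):
        z = rs.Spectrum(grid, np.zeros(len(grid)))
        assert rs.cone_excitation(z, normal_set["L"]) == 0.0

    def test_linearity_in_spd(self, grid, normal_set):
        spd = rs.synthesize_led_spd(592, 16, grid)
        e1 = rs.cone_excitation(spd, normal_set["L"])
        e2 = rs.cone_excitation(2.0 * spd, normal_set["L"])
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_impulse_excitation_is_a_direct_lookup(self, grid, normal_set):
        v = np.zeros(len(grid))
        i = int(round(560 - grid.start_nm))
        v[i] = 3.7
        e = rs.cone_excitation(rs.Spectrum(grid, v), normal_set["M"])
        assert e == pytest.approx(3.7 * normal_set["M"].values[i] * grid.step_nm,
                                  rel=1e-12)

    def test_grid_mismatch_rejected(self, normal_set):
        other = rs.make_grid(400, 700, 1)
        spd = rs.synthesize_led_spd(592, 16, other)
        with pytest.raises(GridMismatchError):
            rs.cone_excitation(spd, normal_set["L"])


class TestRatioCurve:
    def test_identical_cones_give_unit_ratio_everywhere(self, penn, normal_set):
        twin = rs.Observer("normal", normal_set["M"], normal_set["M"])
        curve = rs.excitation_ratio_curve(penn, twin, 51)
        np.testing.assert_allclose(curve.ratio, 1.0, atol=1e-12)
        assert rs.reference_ratio(penn, twin) == pytest.approx(1.0, abs=1e-12)

    def test_normal_ratio_strictly_increasing_toward_red(self, penn, normal_observer):
        curve = rs.excitation_ratio_curve(penn, normal_observer, 101)
        assert np.all(np.diff(curve.ratio) > 0)

    def test_common_channel_rescaling_leaves_ratio_unchanged(self, penn, normal_observer):
        a = rs.excitation_ratio_curve(penn, normal_observer, 31).ratio
        b = rs.excitation_ratio_curve(_scaled_mixture(penn, 3.0), normal_observer, 31).ratio
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestReferenceRatio:
    def test_invariant_to_amber_intensity(self, penn, normal_observer):
        r1 = rs.reference_ratio(penn, normal_observer, 1.0)
        r10 = rs.reference_ratio(penn, normal_observer, 10.0)
        assert r10 == pytest.approx(r1, rel=1e-12)

    def test_zero_intensity_rejected(self, penn, normal_observer):
        with pytest.raises(ValueError):
            rs.reference_ratio(penn, normal_observer, 0.0)

    def test_amber_equal_to_mixture_reproduces_its_ratio(self, penn, normal_observer):
        lam0 = 0.35
        mix = rs.mixture_spd(penn, lam0)
        inst = rs.with_amber_spd(penn, mix)
        ea = rs.cone_excitation(mix, normal_observer.cone_a)
        eb = rs.cone_excitation(mix, normal_observer.cone_b)
        assert rs.reference_ratio(inst, normal_observer) == pytest.approx(ea / eb,
                                                                          rel=1e-12)


class TestPredictMatch:
    def test_physical_identity_match_is_observer_independent(
            self, penn, normal_set, pre, normal_observer):
        inst = rs.with_amber_spd(penn, rs.mixture_spd(penn, 0.5))
        for obs in (normal_observer,
                    rs.make_anomalous_observer(normal_set, "protanomalous", -300, pre),
                    rs.make_anomalous_observer(normal_set, "deuteranomalous", 300, pre)):
            assert rs.predict_match(inst, obs).lambda_star == pytest.approx(0.5,
                                                                            abs=1e-6)

    def test_invariant_to_amber_intensity_rescaling(self, penn, normal_observer):
        lam1 = rs.predict_match(penn, normal_observer).lambda_star
        lam10 = rs.predict_match(
            rs.with_amber_spd(penn, 10.0 * penn.amber.spd), normal_observer
        ).lambda_star
        assert abs(lam1 - lam10) < 1e-9

    def test_invariant_to_common_mixture_rescaling(self, penn, normal_observer):
        lam1 = rs.predict_match(penn, normal_observer).lambda_star
        lam3 = rs.predict_match(_scaled_mixture(penn, 3.0), normal_observer).lambda_star
        assert abs(lam1 - lam3) < 1e-9

    def test_prediction_satisfies_its_own_invariant(self, penn, normal_observer):
        pred = rs.predict_match(penn, normal_observer)
        rel = abs(pred.mixture_ratio_at_match - pred.amber_ratio) / pred.amber_ratio
        assert rel <= 1e-6
        lo, hi = penn.control_range
        assert lo <= pred.lambda_star <= hi

    def test_agrees_with_brute_force_oracle(self, penn, normal_set, pre):
        rng = np.random.default_rng(42)
        for _ in range(10):
            kind = ["protanomalous", "deuteranomalous"][rng.integers(2)]
            s = float(rng.uniform(-1500, 1500))
            if abs(s) < 5:
                continue
            obs = rs.make_anomalous_observer(normal_set, kind, s, pre)
            lam = rs.predict_match(penn, obs).lambda_star
            oracle = rs.brute_force_match(penn, obs, 1e-4)
            assert abs(lam - oracle) <= 1e-4

    def test_no_match_error_reports_end_point_signs(self, oculus, normal_set, pre):
        """A sufficiently extreme variant pushes the crossing off the scale."""
        obs = rs.make_anomalous_observer(normal_set, "protanomalous", 2950.0, pre)
        try:
            pred = rs.predict_match(oculus, obs)
        except NoMatchInRangeError as err:
            assert np.sign(err.f_low) == np.sign(err.f_high)
        else:
            # if still on-scale, its matching range must reach the scale end
            assert rs.matching_range(oculus, obs, 0.01).touches_end
            del pred

    def test_monotone_in_shift_on_each_branch(self, penn, normal_set, pre):
        for kind, sign in (("protanomalous", 1), ("deuteranomalous", 1)):
            lams = [rs.predict_match(
                penn, rs.make_anomalous_observer(normal_set, kind, s, pre)
            ).lambda_star for s in np.linspace(-1000, 1000, 11) if s != 0]
            assert np.all(np.diff(lams) * sign > 0)


class TestBruteForce:
    def test_physical_identity(self, penn, normal_observer):
        inst = rs.with_amber_spd(penn, rs.mixture_spd(penn, 0.25))
        assert abs(rs.brute_force_match(inst, normal_observer, 1e-3) - 0.25) <= 1e-3

    def test_coarser_resolution_bounded_change(self, penn, normal_observer):
        fine = rs.brute_force_match(penn, normal_observer, 1e-3)
        coarse = rs.brute_force_match(penn, normal_observer, 1e-2)
        assert abs(fine - coarse) <= 1e-2


class TestMatchingRange:
    def test_zero_delta_degenerates_to_the_match(self, penn, normal_observer):
        lam = rs.predict_match(penn, normal_observer).lambda_star
        mr = rs.matching_range(penn, normal_observer, 0.0)
        assert mr.lambda_lo == mr.lambda_hi == lam

    def test_width_non_decreasing_in_delta(self, penn, normal_set, pre):
        obs = rs.make_anomalous_observer(normal_set, "deuteranomalous", 300, pre)
        widths = [rs.matching_range(penn, obs, d).width
                  for d in (0.001, 0.01, 0.1)]
        assert widths[0] <= widths[1] <= widths[2]

    def test_huge_delta_reaches_scale_ends(self, penn, normal_observer):
        mr = rs.matching_range(penn, normal_observer, 1e6)
        assert mr.touches_end
        lo, hi = penn.control_range
        assert (mr.lambda_lo, mr.lambda_hi) == (lo, hi)


class TestBrightnessMatch:
    def test_intensity_equates_summed_excitations(self, penn, normal_observer):
        lam = 0.9
        intensity = rs.brightness_match_intensity(penn, normal_observer, lam)
        mix = rs.mixture_spd(penn, lam)
        target = (rs.cone_excitation(mix, normal_observer.cone_a)
                  + rs.cone_excitation(mix, normal_observer.cone_b))
        amber = rs.reference_spd(penn, 1.0)
        per_unit = (rs.cone_excitation(amber, normal_observer.cone_a)
                    + rs.cone_excitation(amber, normal_observer.cone_b))
        assert intensity * per_unit == pytest.approx(target, rel=1e-9)

    def test_doubling_mixture_doubles_intensity(self, penn, normal_observer):
        i1 = rs.brightness_match_intensity(penn, normal_observer, 0.9)
        i2 = rs.brightness_match_intensity(_scaled_mixture(penn, 2.0),
                                           normal_observer, 0.9)
        assert i2 == pytest.approx(2 * i1, rel=1e-12)
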