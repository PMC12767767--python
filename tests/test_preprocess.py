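"""Cropping, wall localization, normalization, zeroing and centering."""

import numpy as np
import pytest

from diffsizer import (
    ProfilePair,
    crop_profile,
    locate_walls,
    normalize_brightfield,
    normalize_fluorescent_set,
    zero_and_center,
)
from diffsizer.errors import DegenerateProfileError, NoSignalError, WallNotFoundError


def make_pair(x, bf, fl, label="P00"):
    return ProfilePair(label, 0.0, np.asarray(x, float), np.asarray(bf, float), np.asarray(fl, float))


def synthetic_pair(dx=2.0, wall=400.0, peak_x=0.0, pad=20, amp=800.0):
    """Flat 200 baseline, wall spikes at x = +-160, Gaussian analyte band."""
    x = np.arange(-320.0, 321.0, dx)
    bf = np.full_like(x, 200.0)
    for wc in (-160.0, 160.0):
        bf += (wall - 200.0) * np.exp(-(((x - wc) / 5.0) ** 2))
    fl = 200.0 + amp * np.exp(-(((x - peak_x) / 20.0) ** 2))
    bf[:pad] = 0.0
    bf[-pad:] = 0.0
    fl[:pad] = 0.0
    fl[-pad:] = 0.0
    return ProfilePair("P00", 0.0, x, bf, fl)


class TestCrop:
    def test_hand_computed_band(self):
        # brightfield [0,0,120,150,160,158,0]: mean 84.0, population std 73.75,
        # lower limit 10.25 -> indices 2..5 survive
        pair = make_pair(range(7), [0, 0, 120, 150, 160, 158, 0], [1] * 7)
        out = crop_profile(pair)
        np.testing.assert_array_equal(out.brightfield, [120, 150, 160, 158])
        np.testing.assert_array_equal(out.x, [2, 3, 4, 5])

    def test_no_zero_ends_unchanged(self):
        pair = make_pair(range(5), [200, 210, 190, 205, 200], [1] * 5)
        out = crop_profile(pair)
        np.testing.assert_array_equal(out.brightfield, pair.brightfield)

    def test_crop_is_idempotent(self):
        pair = synthetic_pair()
        once = crop_profile(pair)
        twice = crop_profile(once)
        np.testing.assert_array_equal(once.x, twice.x)
        np.testing.assert_array_equal(once.brightfield, twice.brightfield)

    def test_fluorescent_cropped_identically(self):
        pair = synthetic_pair()
        out = crop_profile(pair)
        assert len(out.fluorescent) == len(out.brightfield) == len(out.x)
        assert out.fluorescent[0] > 0  # padded zeros removed

    def test_all_below_band_rejected(self):
        pair = make_pair(range(3), [5.0, 5.0, 5.0], [1] * 3)
        # constant trace: std 0, lower limit = mean; nothing exceeds it
        with pytest.raises(DegenerateProfileError):
            crop_profile(pair)


class TestLocateWalls:
    def test_bright_spikes_recovered(self):
        sp = locate_walls(crop_profile(synthetic_pair()), wall_thickness=20.0)
        assert sp.wall_centers[0] == pytest.approx(-160.0, abs=2.0)
        assert sp.wall_centers[1] == pytest.approx(160.0, abs=2.0)

    def test_dark_spikes_recovered(self):
        sp = locate_walls(crop_profile(synthetic_pair(wall=20.0)), wall_thickness=20.0)
        assert sp.wall_centers[0] == pytest.approx(-160.0, abs=2.0)
        assert sp.wall_centers[1] == pytest.approx(160.0, abs=2.0)

    def test_excluded_region_width(self):
        sp = locate_walls(crop_profile(synthetic_pair()), wall_thickness=20.0)
        x = sp.pair.x
        # inside starts after left wall + thickness, ends before right wall - thickness
        assert x[sp.inside[0]] > sp.wall_centers[0] + 20.0 - 1e-9
        assert x[sp.inside[1] - 1] < sp.wall_centers[1] - 20.0 + 1e-9
        # outside sections stop/start a full doubled-thickness away
        assert x[sp.outside_left[1] - 1] < sp.wall_centers[0] - 20.0 + 1e-9
        assert x[sp.outside_right[0]] > sp.wall_centers[1] + 20.0 - 1e-9

    def test_sections_disjoint_and_ordered(self):
        sp = locate_walls(crop_profile(synthetic_pair()), wall_thickness=20.0)
        assert sp.outside_left[1] <= sp.inside[0] < sp.inside[1] <= sp.outside_right[0]

    def test_wall_at_trace_end_rejected(self):
        x = np.arange(0.0, 200.0, 2.0)
        bf = np.full_like(x, 200.0)
        bf[2] = 400.0  # spike too close to the end
        bf[60] = 400.0
        fl = 200.0 + 100.0 * np.exp(-(((x - 70.0) / 10.0) ** 2))
        with pytest.raises(WallNotFoundError):
            locate_walls(make_pair(x, bf, fl), wall_thickness=20.0)

    def test_sectioning_invariant_under_shift(self):
        sp0 = locate_walls(crop_profile(synthetic_pair()), 20.0)
        shifted = crop_profile(synthetic_pair()).shifted(37.0)
        sp1 = locate_walls(shifted, 20.0)
        assert sp0.inside == sp1.inside
        assert sp0.outside_left == sp1.outside_left
        assert sp1.wall_centers[0] == pytest.approx(sp0.wall_centers[0] + 37.0)


class TestNormalize:
    def _sectioned(self, **kw):
        return locate_walls(crop_profile(synthetic_pair(**kw)), 20.0)

    def test_brightfield_inside_mean_hits_standard(self):
        sp = normalize_brightfield(self._sectioned(), standard=200.0)
        assert sp.bright_inside.mean() == pytest.approx(200.0, abs=1e-9)

    def test_brightfield_scale_invariance(self):
        sp = self._sectioned()
        doubled = sp.__class__(
            pair=ProfilePair(
                sp.pair.label, sp.pair.position, sp.pair.x,
                sp.pair.brightfield * 2.0, sp.pair.fluorescent,
            ),
            wall_centers=sp.wall_centers, wall_thickness=sp.wall_thickness,
            inside=sp.inside, outside_left=sp.outside_left, outside_right=sp.outside_right,
        )
        a = normalize_brightfield(sp).pair.brightfield
        b = normalize_brightfield(doubled).pair.brightfield
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_fluorescent_two_step(self):
        sps = [self._sectioned(amp=a) for a in (400.0, 800.0)]
        out = normalize_fluorescent_set(sps, standard=200.0)
        integrals = [sp.inside_integral() for sp in out]
        assert integrals[0] == pytest.approx(integrals[1], rel=1e-9)

    def test_single_profile_step2_factor_one(self):
        sp = self._sectioned()
        (out,) = normalize_fluorescent_set([sp], standard=200.0)
        # baseline moved to 200; with it already at 200 the profile is unchanged
        np.testing.assert_allclose(out.pair.fluorescent, sp.pair.fluorescent, rtol=1e-12)

    def test_normalization_preserves_shape(self):
        sps = [self._sectioned(amp=a) for a in (300.0, 900.0)]
        out = normalize_fluorescent_set(sps)
        for before, after in zip(sps, out):
            r = np.corrcoef(before.fluor_inside, after.fluor_inside)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)


class TestZeroAndCenter:
    def _prepared(self, peak_x=12.0):
        sps = [locate_walls(crop_profile(synthetic_pair(peak_x=peak_x)), 20.0)]
        return normalize_fluorescent_set(sps)[0]

    def test_peak_moved_to_origin(self):
        out = zero_and_center(self._prepared(peak_x=12.0))
        peak = out.pair.x[np.argmax(out.pair.fluorescent)]
        assert peak == pytest.approx(0.0, abs=1e-9)

    def test_outside_mean_zero(self):
        out = zero_and_center(self._prepared())
        assert out.fluor_outside.mean() == pytest.approx(0.0, abs=1e-9)

    def test_wall_centers_shift_rigidly(self):
        sp = self._prepared(peak_x=12.0)
        out = zero_and_center(sp)
        shift = out.pair.x[0] - sp.pair.x[0]
        assert out.wall_centers[0] == pytest.approx(sp.wall_centers[0] + shift, abs=1e-9)
        assert shift == pytest.approx(-12.0, abs=1e-9)

    def test_flat_trace_raises_no_signal(self):
        sp = self._prepared()
        flat_pair = ProfilePair(
            sp.pair.label, sp.pair.position, sp.pair.x,
            sp.pair.brightfield, np.full_like(sp.pair.fluorescent, 200.0),
        )
        flat = sp.__class__(
            pair=flat_pair, wall_centers=sp.wall_centers,
            wall_thickness=sp.wall_thickness, inside=sp.inside,
            outside_left=sp.outside_left, outside_right=sp.outside_right,
        )
        with pytest.raises(NoSignalError):
            zero_and_center(flat)


class TestOnSimulatorOutput:
    def test_wall_recovery_within_one_sample(self, noiseless_2nm):
        dx = noiseless_2nm.provenance["dx_um"]
        truth = noiseless_2nm.provenance["wall_centers_x"]
        for pair in noiseless_2nm.profiles:
            sp = locate_walls(crop_profile(pair), 20.0)
            assert sp.wall_centers[0] == pytest.approx(truth[0], abs=dx)
            assert sp.wall_centers[1] == pytest.approx(truth[1], abs=dx)
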