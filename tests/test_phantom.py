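"""Synthetic phantom generator: geometry, HU classes, spillover, noise."""

import numpy as np
import pytest

from remnantvol import (
    GeometryError,
    PhantomSpec,
    SphereSpec,
    generate_ct,
    generate_pair,
    generate_spect,
    sphere_diameter_cm,
    sphere_radius_mm,
)
from remnantvol.phantom import sphere_fractions
from conftest import single_sphere_spec, two_sphere_spec


class TestGeometry:
    def test_radius_and_diameter(self):
        # V = 4/3 pi r^3; a 10 mL sphere is 2.7 cm across
        assert sphere_radius_mm(10.0) == pytest.approx(13.365, abs=1e-3)
        assert round(sphere_diameter_cm(10.0), 1) == 2.7
        assert round(sphere_diameter_cm(0.5), 1) == 1.0

    def test_sphere_outside_cylinder(self):
        with pytest.raises(GeometryError):
            PhantomSpec(
                spheres=[SphereSpec((5.0, 5.0, 30.0), 3.0)],
                ct_shape=(64, 64, 16),
                neck_radius_mm=25.0,
            )

    def test_overlapping_spheres(self):
        spec_kwargs = dict(ct_shape=(128, 128, 16), neck_radius_mm=55.0)
        c = (127 / 2 * 1.1, 127 / 2 * 1.1, 33.0)
        with pytest.raises(GeometryError):
            PhantomSpec(
                spheres=[SphereSpec(c, 3.0), SphereSpec((c[0] + 5, c[1], c[2]), 3.0)],
                **spec_kwargs,
            )

    def test_surface_separation_recorded(self):
        spec = two_sphere_spec((1.5, 3.0), separation_mm=10.0)
        assert spec.surface_separations_mm() == [pytest.approx(10.0)]


class TestGenerateCT:
    def test_voxelized_volume_within_half_percent(self):
        """Fraction-weighted voxelization of a 10 mL sphere recovers its
        volume to 0.5% at 1.1 x 1.1 x 4.4 mm resolution."""
        spec = single_sphere_spec(10.0)
        _, frac = sphere_fractions(
            spec.ct_origin, spec.ct_spacing, spec.ct_shape, spec.spheres[0], 3
        )
        v = frac.sum() * 5.324e-3
        assert abs(v - 10.0) / 10.0 < 0.005

    def test_hu_classes_present(self):
        spec = single_sphere_spec(3.0)
        ct = generate_ct(spec)
        s = spec.spheres[0]
        # cavity center reads volume-class HU, far corner reads water
        ix = tuple(int(round(c / d)) for c, d in zip(s.center_mm, spec.ct_spacing))
        assert 1050 - 20 <= ct.values[ix] <= 1090 + 20
        assert abs(ct.values[0, 0, 0] - 1000) < 20
        # inside the cylinder but away from the sphere: background class
        bg = ct.values[ix[0], ix[1] + 30, ix[2]]
        assert 1115 - 20 <= bg <= 1130 + 20

    def test_constant_ranges_give_two_values_plus_mixtures(self):
        spec = single_sphere_spec(3.0)
        spec.hu_volume_range = (1070.0, 1070.0)
        spec.hu_background_range = (1120.0, 1120.0)
        spec.hu_noise_sd = 0.0
        spec.hu_integer = False
        ct = generate_ct(spec)
        inside = ct.values[ct.values != 1000.0]
        pure = np.isin(inside, (1070.0, 1120.0))
        mixtures = inside[~pure]
        assert pure.sum() > 0.9 * inside.size  # bulk is pure tissue classes
        assert np.all((mixtures > 1000.0) & (mixtures < 1120.0))

    def test_integer_hu_and_determinism(self):
        spec = single_sphere_spec(1.5, seed=9)
        a = generate_ct(spec)
        b = generate_ct(single_sphere_spec(1.5, seed=9))
        assert np.array_equal(a.values, b.values)
        assert np.all(a.values == np.round(a.values))
        c = generate_ct(single_sphere_spec(1.5, seed=10))
        assert not np.array_equal(a.values, c.values)


class TestGenerateSPECT:
    def test_counts_confined_without_blur(self):
        spec = single_sphere_spec(1.5, fwhm=0.0, noise=False)
        sp = generate_spect(spec)
        _, frac = sphere_fractions(
            spec.spect_origin, spec.spect_spacing, spec.spect_shape,
            spec.spheres[0], 3,
        )
        full = np.zeros(spec.spect_shape)
        s = spec.spheres[0]
        box, fr = sphere_fractions(
            spec.spect_origin, spec.spect_spacing, spec.spect_shape, s, 3
        )
        full[box] = fr
        assert sp.values[full == 0].sum() == 0.0
        assert sp.values[full > 0].sum() > 0

    def test_total_counts_match_activity(self):
        """Blur conserves counts: total expected counts equal administered
        activity times the counts-per-MBq scale."""
        spec = single_sphere_spec(1.5, fwhm=14.0, noise=False)
        sp = generate_spect(spec)
        conc = spec.spheres[0].activity_conc
        expected_total = conc * 1.5 * spec.counts_per_mbq
        # voxelization of the sphere is itself ~0.5% accurate
        assert sp.values.sum() == pytest.approx(expected_total, rel=0.01)

    def test_linearity_in_activity(self):
        spec = single_sphere_spec(3.0, fwhm=9.0, noise=False)
        low = generate_spect(spec)
        spec2 = single_sphere_spec(3.0, fwhm=9.0, noise=False)
        spec2.spheres[0].activity_conc = spec.spheres[0].activity_conc * 2
        high = generate_spect(spec2)
        assert np.allclose(high.values, 2 * low.values)

    def test_poisson_noise_seeded(self):
        a = generate_spect(single_sphere_spec(1.5, seed=4))
        b = generate_spect(single_sphere_spec(1.5, seed=4))
        c = generate_spect(single_sphere_spec(1.5, seed=5))
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)
        assert np.all(a.values == np.round(a.values))  # integer counts

    def test_background_activity_ratio(self):
        spec = single_sphere_spec(1.5, fwhm=0.0, noise=False, pct_bkg=10.0)
        sp = generate_spect(spec)
        # a background voxel far from the sphere carries ~10% of the cavity
        # concentration (per voxel counts scale with concentration)
        s = spec.spheres[0]
        ix = tuple(
            int(round((c - o) / d))
            for c, o, d in zip(s.center_mm, spec.spect_origin, spec.spect_spacing)
        )
        cavity = sp.values[ix]
        bg = sp.values[ix[0], ix[1] + 8, ix[2]]
        assert bg / cavity == pytest.approx(
            0.10 * spec.activity_conc_volume / s.activity_conc, rel=0.05
        )


class TestGeneratePair:
    def test_pair_and_truth(self):
        pair, truth = generate_pair(two_sphere_spec((1.5, 3.0), seed=3))
        assert pair.spect.shape == pair.ct.shape
        assert truth.surface_separations_mm == [pytest.approx(10.0)]
        assert len(truth.rois_single) == 2
        assert [s.volume_ml for s in truth.spheres] == [1.5, 3.0]
        # combined ROI at least twice the area of the largest single ROI
        def area(roi):
            xs, ys = roi.polygon[:, 0], roi.polygon[:, 1]
            return (xs.max() - xs.min()) * (ys.max() - ys.min())

        assert area(truth.roi_combined) >= 2 * max(area(r) for r in truth.rois_single)

    def test_fig4d_style_pair_valid(self):
        pair, truth = generate_pair(two_sphere_spec((10.0, 0.5), seed=2))
        assert truth.voxelized_volumes_ml[0] == pytest.approx(10.0, rel=0.005)
        assert truth.voxelized_volumes_ml[1] == pytest.approx(0.5, rel=0.05)

    def test_single_rois_exclude_neighbor(self):
        spec = two_sphere_spec((1.5, 3.0), seed=3)
        _, truth = generate_pair(spec)
        for roi, own in zip(truth.rois_single, spec.spheres):
            other = [s for s in spec.spheres if s is not own][0]
            xs = roi.polygon[:, 0] * spec.ct_spacing[0]
            assert not (
                xs.min() < other.center_mm[0] - other.radius_mm
                and xs.max() > other.center_mm[0] + other.radius_mm
            )
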