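"""Ring templates: printed design counts, partition properties, NAC model."""

import math

import numpy as np
import pytest

import acrpet
from acrpet.sampling_templates import (
    effective_radius,
    make_registration_templates,
    transaxial_attenuation_factor,
)


class TestInsertTemplates:
    def test_ring_counts_ten_hot_eleven_cold(self, insert_templates):
        for name, t in insert_templates.items():
            expected = 10 if name.startswith("hot") else 11
            assert t.n_rings == expected, name

    def test_central_circle_diameter_4mm(self, insert_templates):
        for t in insert_templates.values():
            assert t.ring_bounds[0] == (0.0, 2.0)

    def test_ring_boundary_aligned_with_insert_wall(self, insert_templates):
        """One ring boundary coincides with each fillable insert's inner wall."""
        for name in ("hot_25mm", "hot_16mm", "hot_12mm", "hot_8mm",
                     "cold_air", "cold_water"):
            t = insert_templates[name]
            edges = {b for bounds in t.ring_bounds for b in bounds}
            assert any(math.isclose(e, t.true_boundary_radius) for e in edges), name

    def test_rings_disjoint_and_contiguous(self, insert_templates):
        t = insert_templates["hot_25mm"]
        pts = t.ring_points()
        seen = set()
        for p in pts:
            keys = {(round(x, 3), round(y, 3)) for x, y in p}
            assert not (keys & seen)        # pairwise disjoint masks
            seen |= keys
        for (a, b), (c, _d) in zip(t.ring_bounds[:-1], t.ring_bounds[1:]):
            assert math.isclose(b, c)

    def test_effective_radii_strictly_increasing_and_match_masks(self, insert_templates):
        for t in insert_templates.values():
            r = t.effective_radii
            assert np.all(np.diff(r) > 0)
            cx, cy = t.center
            for p, r_eff in zip(t.ring_points(), r):
                mc = np.hypot(p[:, 0] - cx, p[:, 1] - cy).mean()
                assert abs(mc - r_eff) / r_eff < 0.02


class TestRodTemplates:
    def test_ring_counts_per_set(self, rod_templates):
        counts = tuple(rod_templates[f"rods_{i}"].n_rings for i in range(1, 7))
        assert counts == (11, 10, 9, 7, 6, 4)

    def test_central_circle_diameter(self, rod_templates):
        for t in rod_templates.values():
            assert t.ring_bounds[0][1] == pytest.approx(1.26)  # diameter 2.52 mm

    def test_same_ring_geometry_for_all_rods_of_a_set(self, rod_templates):
        t = rod_templates["rods_3"]
        assert len(t.centers) > 1
        # ring radii identical per rod by construction; sampled points pooled
        assert t.true_boundary_radius == pytest.approx(9.5 / 2.0)

    def test_samples_exclude_neighbouring_rods(self, spec, rod_templates):
        t = rod_templates["rods_6"]          # smallest, most densely packed
        rods = [(cx, cy, d / 2.0)
                for name, d in zip(sorted(spec.rod_centers), spec.rod_diameters)
                for cx, cy in spec.rod_centers[name]]
        for p in t.ring_points():
            for (cx, cy, r) in rods:
                d = np.hypot(p[:, 0] - cx, p[:, 1] - cy)
                inside = d < r - 1e-9
                if inside.any():
                    # only permissible inside a rod centre of this template
                    assert (cx, cy) in t.centers


class TestBackgroundTemplate:
    def test_eighteen_rings_outer_at_interior_radius(self, bg_template):
        assert bg_template.n_rings == 18
        assert bg_template.ring_bounds[-1][1] <= 105.0
        widths = [b - a for a, b in bg_template.ring_bounds[:-1]]
        assert all(w == pytest.approx(6.0) for w in widths)

    def test_no_sample_inside_insert_exclusion_zones(self, spec, bg_template):
        pts = np.concatenate(bg_template.ring_points(), axis=0)
        for (cx, cy, er) in bg_template.exclusions:
            d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
            assert d.min() > er  # clear of the insert and its vicinity


class TestEffectiveRadius:
    def test_area_weighted_formula(self):
        # closed form vs direct numerical area integral
        a, b = 4.0, 6.5
        r = np.linspace(a, b, 100001)
        num = np.trapezoid(r * r, r) / np.trapezoid(r, r)
        assert effective_radius(a, b) == pytest.approx(num, rel=1e-6)


class TestRegistrationTemplates:
    def test_nac_template_peripheral_enhancement(self, spec):
        """Mean chord attenuation suppresses the centre of a uniform object."""
        nac, _rod = make_registration_templates(spec, grid=2.0)
        mid = nac.values.shape[2] // 2
        sl = nac.values[:, :, mid]
        centre = sl[sl.shape[0] // 2, sl.shape[1] // 2]
        xs = nac.axis_coords(0)
        edge_i = int(np.argmin(np.abs(xs - 95.0)))
        edge = sl[edge_i, sl.shape[1] // 2]
        assert edge > centre > 0

    def test_attenuation_factor_against_brute_force_rays(self, spec):
        """Spot-check the factor with an independent dense ray integration."""
        pts = [(0.0, 0.0), (80.0, 0.0)]
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        fac = np.array([transaxial_attenuation_factor(spec, np.array([x]), np.array([y]))[0, 0]
                        for x, y in pts])
        # oracle: analytic chords through a uniform disk of water + shell
        mu_w, mu_a = 0.096, 0.117
        R_in, R_out = 105.0, 108.2
        n_ang = 720
        for i, (x, y) in enumerate(pts):
            total = 0.0
            for a in np.linspace(0, math.pi, n_ang, endpoint=False):
                c, s = math.cos(a), math.sin(a)
                # distance from centre to the line through (x, y) at angle a
                h = abs(-s * x + c * y)
                chord_in = 2 * math.sqrt(max(R_in**2 - h**2, 0.0))
                chord_out = 2 * math.sqrt(max(R_out**2 - h**2, 0.0))
                total += (mu_w * chord_in + mu_a * (chord_out - chord_in)) / 10.0
            oracle = math.exp(-0.5 * total / n_ang)
            assert fac[i] == pytest.approx(oracle, rel=0.05)

    def test_zero_attenuation_gives_unit_factor(self, spec):
        # where every ray misses the attenuating object the integral vanishes
        fac = transaxial_attenuation_factor(spec, np.array([400.0]), np.array([400.0]))
        assert fac[0, 0] == pytest.approx(1.0, abs=1e-9)

    def test_rod_template_zero_outside_rod_component(self, spec):
        _nac, rod = make_registration_templates(spec, grid=2.0)
        zs = rod.axis_coords(2)
        outside = (zs < -86.0) | (zs >= -19.0)
        assert np.all(rod.values[:, :, outside] == 0)
        assert rod.values[:, :, ~outside].max() > 0
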