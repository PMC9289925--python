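"""Knife-edge fitting: exact oracles, derived PSF metrics, contrast."""

import math

import numpy as np
import pytest
from scipy.special import erf

import acrpet
from acrpet.edge_resolution import (
    ErfFit,
    FitError,
    contrast_metrics,
    fit_knife_edge,
    resolution_metrics,
)
from acrpet.ring_sampling import EdgeProfile


def erf_profile(A, k, mu, b, x=None):
    x = np.linspace(2.0, 24.0, 12) if x is None else x
    y = A * erf(k * (x - mu)) + b
    return EdgeProfile("oracle", x, y, np.full(len(x), 100.0),
                       true_boundary_radius=mu)


class TestExactRecovery:
    def test_zero_residual_recovery(self):
        """Noise-free data from the model returns (A, k, mu, b) to 1e-6."""
        truth = (1000.0, 0.5, 12.5, 2000.0)
        fit = fit_knife_edge(erf_profile(*truth))
        for got, want in zip((fit.A, fit.k, fit.mu, fit.b), truth):
            assert abs(got - want) / abs(want) < 1e-6
        assert fit.rss < 1e-6

    def test_max_derivative_closed_form(self):
        fit = fit_knife_edge(erf_profile(1000.0, 0.5, 12.5, 2000.0))
        expected = 2.0 * 1000.0 * 0.5 / math.sqrt(math.pi)
        assert abs(fit.max_derivative - expected) < 1e-9 * expected
        assert expected == pytest.approx(564.19, abs=0.01)

    def test_sigma_fwhm_closed_form(self):
        k = 0.6651
        fit = ErfFit(A=1.0, k=k, mu=0.0, b=0.0, rss=0.0, x_min=-10, x_max=10)
        assert fit.sigma == pytest.approx(1.0633, abs=2e-4)
        assert fit.fwhm == pytest.approx(2.5038, abs=5e-4)
        assert fit.fwhm == pytest.approx(
            2.0 * math.sqrt(2.0 * math.log(2.0)) * fit.sigma, abs=1e-9)

    def test_psf_equals_model_derivative(self):
        """Eq-consistency: derivative of the fitted edge is the stated Gaussian."""
        from mpmath import mp, erf as merf, diff, mpf
        mp.dps = 30
        A, k, mu, b = 850.0, 0.71, 10.2, 3100.0
        fit = ErfFit(A=A, k=k, mu=mu, b=b, rss=0.0, x_min=0, x_max=25)
        for x in (8.0, 10.2, 12.5, 15.0):
            dK = float(diff(lambda t: A * merf(k * (t - mu)) + b, mpf(x)))
            assert abs(dK - fit.psf(np.array([x]))[0]) < 1e-9 * abs(dK)


class TestFitBehaviour:
    def test_short_profile_rejected(self):
        p = EdgeProfile("p", [1, 2, 3], [0, 1, 2], [1, 1, 1])
        with pytest.raises(FitError):
            fit_knife_edge(p)

    def test_nonfinite_rejected(self):
        p = erf_profile(100.0, 0.5, 12.5, 200.0)
        p.y[3] = np.nan
        with pytest.raises(FitError):
            fit_knife_edge(p)

    def test_amplitude_sign_tracks_edge_direction(self, noiseless_insert_image,
                                                  insert_templates):
        """Radially increasing (cold) edges fit A > 0, decreasing (hot) A < 0."""
        hot = fit_knife_edge(acrpet.sample_template(
            noiseless_insert_image, insert_templates["hot_25mm"]))
        cold = fit_knife_edge(acrpet.sample_template(
            noiseless_insert_image, insert_templates["cold_water"]))
        assert hot.A < 0 and hot.max_derivative < 0
        assert cold.A > 0 and cold.max_derivative > 0
        # polarity invariance: both edges blur with the same PSF
        assert abs(hot.fwhm - cold.fwhm) / cold.fwhm < 0.1

    def test_k_bound_flagged(self):
        # samples tight around a hard step: k runs into the upper bound
        x = np.array([2.0, 6.0, 10.0, 12.3, 12.7, 15.0, 19.0, 23.0])
        y = np.where(x < 12.5, 3000.0, 1000.0)
        p = EdgeProfile("step", x, y, np.full(len(x), 10.0),
                        true_boundary_radius=12.5)
        fit = fit_knife_edge(p)
        assert fit.k_at_bound


class TestResolutionMetrics:
    def test_width_validity_rule(self):
        fit = ErfFit(A=-1000, k=0.4, mu=12.5, b=3000, rss=0, x_min=1.0, x_max=21.0)
        m = resolution_metrics(fit, 12.5)
        # fwhm = 4.16 mm, span beyond boundary 8.5 mm >= 2*fwhm
        assert m["fwhm_valid"]
        tight = ErfFit(A=-1000, k=0.4, mu=6.35, b=3000, rss=0, x_min=0.6, x_max=7.3)
        assert not resolution_metrics(tight, 6.35)["fwhm_valid"]

    def test_boundary_offset_signed(self):
        fit = ErfFit(A=-1000, k=0.5, mu=12.1, b=3000, rss=0, x_min=1, x_max=21)
        m = resolution_metrics(fit, 12.5)
        assert m["boundary_offset"] == pytest.approx(-0.4)
        assert m["max_derivative_abs"] == pytest.approx(2 * 1000 * 0.5 / math.sqrt(math.pi))


class TestContrast:
    def test_exact_references_give_full_recovery(self):
        p = EdgeProfile("hot", [1, 3, 5, 7], [8203, 8000, 5000, 3281],
                        [10, 10, 10, 10], polarity="hot")
        m = contrast_metrics(p, reference_hot=8203.0, reference_bg=3281.0)
        assert m["recovery_percent"] == pytest.approx(100.0)
        assert m["absolute_contrast"] == 8203.0

    def test_cold_zero_minimum_is_full_recovery(self):
        p = EdgeProfile("cold", [1, 3, 5, 7], [0.0, 10.0, 2000.0, 3281.0],
                        [10, 10, 10, 10], polarity="cold")
        m = contrast_metrics(p, reference_hot=8203.0, reference_bg=3281.0)
        assert m["recovery_percent"] == pytest.approx(100.0)

    def test_partial_volume_orders_recovery_by_insert_size(self, spec,
                                                           insert_templates):
        from acrpet.pet_simulator import SimulationConfig, simulate_recon
        from conftest import INSERT_SLAB
        cfg = SimulationConfig(psf_fwhm=6.0, total_counts=1e8, noise=False,
                               render_voxel_size=1.0, voxel_size_out=1.0,
                               axial_range=INSERT_SLAB)
        img = simulate_recon(spec, cfg)
        rec = {}
        for name in ("hot_25mm", "hot_8mm"):
            prof = acrpet.sample_template(img, insert_templates[name])
            rec[name] = contrast_metrics(prof, 2.5 * cfg.background_concentration,
                                         cfg.background_concentration)["recovery_percent"]
        assert rec["hot_8mm"] < rec["hot_25mm"] <= 102.0

    def test_invalid_references_rejected(self):
        p = EdgeProfile("hot", [1, 3, 5, 7], [1, 2, 3, 4], [1, 1, 1, 1],
                        polarity="hot")
        with pytest.raises(ValueError):
            contrast_metrics(p, -1.0, 100.0)
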