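"""Photon transport: conservation, reproducibility, oracle agreement."""

import numpy as np
import pytest

from nirskin.mc_transport import (
    DetectorSpec,
    MCConfig,
    MCResult,
    SourceSpec,
    TransportInputError,
    UndefinedLogError,
    _run_stack,
    _stack_arrays,
    blood_perturbation_spectrum,
    farrell_diffusion_reflectance,
    homogeneous_medium,
    run_mc,
    simulate_ad_spectrum,
)
from nirskin.optical_properties import PerturbationSpec, build_optical_stack




class TestSpecs:
    def test_detector_rings_non_overlapping(self):
        with pytest.raises(TransportInputError):
            DetectorSpec(ring_centers=(0.9, 1.0), ring_width=0.2)

    def test_band_sample_weights_normalised(self):
        src = SourceSpec(1550.0, 52.0, spectral_mode="gaussian_band", n_samples=7)
        lam, w = src.band_samples()
        assert w.sum() == pytest.approx(1.0)
        assert len(lam) == 7
        assert lam[0] < 1550.0 < lam[-1]

    def test_monochromatic_default(self):
        lam, w = SourceSpec(1550.0, 52.0).band_samples()
        assert list(lam) == [1550.0]
        assert list(w) == [1.0]


class TestEnergyBudget:
    def test_exact_closure_without_roulette(self, skin_model, chromophores):
        cfg = MCConfig(n_photons=50_000, seed=2, roulette_enabled=False)
        res = run_mc(skin_model, chromophores, SourceSpec(1550.0), config=cfg)
        assert res.budget_closure().max() < 1e-6

    def test_closure_in_expectation_with_roulette(self, skin_model, chromophores):
        cfg = MCConfig(n_photons=100_000, seed=2, roulette_enabled=True)
        res = run_mc(skin_model, chromophores, SourceSpec(1550.0), config=cfg)
        assert res.budget_closure().max() < 2e-3

    def test_total_absorption_kills_detection(self):
        model, chrom = homogeneous_medium(mu_a=1e4, mu_s_prime=10.0)
        cfg = MCConfig(n_photons=20_000, seed=3, roulette_enabled=False)
        res = run_mc(model, chrom, SourceSpec(1550.0), config=cfg)
        assert res.detected_weight.max() == 0.0
        # everything that entered the medium was absorbed
        assert res.absorbed_weight.sum() == pytest.approx(
            1.0 - res.escaped_undetected_weight[0], abs=1e-9
        )


class TestReproducibility:
    def test_identical_config_bitwise_identical(self, skin_model, chromophores):
        cfg = MCConfig(n_photons=30_000, seed=11)
        a = run_mc(skin_model, chromophores, SourceSpec(1550.0), config=cfg)
        b = run_mc(skin_model, chromophores, SourceSpec(1550.0), config=cfg)
        np.testing.assert_array_equal(a.detected_weight, b.detected_weight)
        np.testing.assert_array_equal(a.absorbed_weight, b.absorbed_weight)
        np.testing.assert_array_equal(a.transmitted_weight, b.transmitted_weight)

    def test_different_seed_differs(self, skin_model, chromophores):
        a = run_mc(
            skin_model,
            chromophores,
            SourceSpec(1550.0),
            config=MCConfig(n_photons=30_000, seed=11),
        )
        b = run_mc(
            skin_model,
            chromophores,
            SourceSpec(1550.0),
            config=MCConfig(n_photons=30_000, seed=12),
        )
        assert not np.array_equal(a.detected_weight, b.detected_weight)


class TestRingStatistics:
    def test_detected_weight_decreases_with_radius(self, skin_model, chromophores):
        cfg = MCConfig(n_photons=300_000, seed=4)
        res = run_mc(skin_model, chromophores, SourceSpec(1550.0), config=cfg)
        w = res.detected_weight[0]
        se = res.detected_stderr[0]
        for j in range(4):
            assert w[j] - w[j + 1] > 3.0 * np.hypot(se[j], se[j + 1])

    def test_stderr_scales_with_photon_budget(self, skin_model, chromophores):
        base = dict(seed=9, n_batches=40)
        r1 = run_mc(
            skin_model,
            chromophores,
            SourceSpec(1550.0),
            config=MCConfig(n_photons=100_000, **base),
        )
        r2 = run_mc(
            skin_model,
            chromophores,
            SourceSpec(1550.0),
            config=MCConfig(n_photons=200_000, **base),
        )
        ratio = np.mean(r1.detected_stderr[0] / r2.detected_stderr[0])
        assert ratio == pytest.approx(np.sqrt(2.0), rel=0.2)


class TestDiffusionOracle:
    def test_farrell_monotone_in_rho_and_mu_a(self):
        rho = np.linspace(1.5, 8.0, 30)
        r = farrell_diffusion_reflectance(0.1, 10.0, 1.4, rho)
        assert np.all(np.diff(r) < 0)
        r_more_absorbing = farrell_diffusion_reflectance(0.3, 10.0, 1.4, rho)
        assert np.all(r_more_absorbing < r)

    def test_farrell_against_independent_scalar_form(self):
        # independent re-derivation of the dipole expression at one point
        mu_a, msp, n_rel, rho_mm = 0.1, 10.0, 1.4, 3.0
        rho = rho_mm / 10
        mu_t = mu_a + msp
        mu_eff = np.sqrt(3 * mu_a * mu_t)
        z0 = 1 / mu_t
        r_d = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
        zb = 2 * (1 + r_d) / (1 - r_d) / (3 * mu_t)
        r1 = np.hypot(z0, rho)
        r2 = np.hypot(z0 + 2 * zb, rho)
        expected = (
            z0 * (mu_eff + 1 / r1) * np.exp(-mu_eff * r1) / r1**2
            + (z0 + 2 * zb) * (mu_eff + 1 / r2) * np.exp(-mu_eff * r2) / r2**2
        ) / (4 * np.pi)
        got = farrell_diffusion_reflectance(mu_a, msp, n_rel, rho_mm)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_diffusion_regime_warning(self):
        with pytest.warns(RuntimeWarning):
            farrell_diffusion_reflectance(5.0, 10.0, 1.4, 3.0)

    def test_mc_matches_diffusion_dipole(self):
        """Homogeneous semi-infinite medium: spatially resolved reflectance
        within 15% of the diffusion closed form at 2-6 mm."""
        model, chrom = homogeneous_medium(mu_a=0.1, mu_s_prime=10.0, n=1.4)
        edges = np.arange(2.0, 6.01, 0.5)
        det = DetectorSpec(
            ring_centers=tuple((edges[:-1] + edges[1:]) / 2), ring_width=0.5
        )
        cfg = MCConfig(n_photons=1_200_000, seed=3)
        res = run_mc(model, chrom, SourceSpec(1550.0), det, cfg)
        area = np.pi * ((edges[1:] / 10) ** 2 - (edges[:-1] / 10) ** 2)
        r_mc = res.detected_weight[0] / area
        r_th = farrell_diffusion_reflectance(
            0.1, 10.0, 1.4, (edges[:-1] + edges[1:]) / 2
        )
        assert np.max(np.abs(r_mc / r_th - 1.0)) < 0.15


class TestADSimulation:
    @staticmethod
    def result_with_weights(weights):
        weights = np.asarray(weights, float)[None, :]
        return MCResult(
            wavelengths=np.array([1550.0]),
            ring_centers=np.array([0.9, 1.25, 1.7, 2.0, 2.3]),
            detected_weight=weights,
            detected_stderr=np.zeros_like(weights),
            absorbed_weight=np.zeros((1, 7)),
            layer_names=tuple("abcdefg"),
            transmitted_weight=np.zeros(1),
            escaped_undetected_weight=np.zeros(1),
            n_photons=1000,
            seed=0,
        )

    def test_log_ratio_of_counts(self, skin_model, chromophores):
        res = self.result_with_weights([0.002, 0.0015, 0.001, 0.0005, 0.0002])
        ad = simulate_ad_spectrum(
            skin_model, chromophores, result=res, pair=(0.9, 1.7)
        )
        assert ad.ad[0] == pytest.approx(np.log(2.0))

    def test_equal_intensities_zero(self, skin_model, chromophores):
        res = self.result_with_weights([0.001] * 5)
        ad = simulate_ad_spectrum(skin_model, chromophores, result=res)
        assert ad.ad[0] == 0.0

    def test_reversed_pair_rejected(self, skin_model, chromophores):
        res = self.result_with_weights([0.001] * 5)
        with pytest.raises(TransportInputError):
            simulate_ad_spectrum(
                skin_model, chromophores, result=res, pair=(1.7, 0.9)
            )

    def test_zero_weight_raises_undefined_log(self, skin_model, chromophores):
        res = self.result_with_weights([0.001, 0.001, 0.0, 0.0, 0.0])
        with pytest.raises(UndefinedLogError):
            simulate_ad_spectrum(
                skin_model, chromophores, result=res, pair=(0.9, 2.3)
            )


class TestPerturbationSpectrum:
    def test_null_perturbation_exactly_zero(self, skin_model, chromophores):
        cfg = MCConfig(n_photons=20_000, seed=6)
        _, delta, _ = blood_perturbation_spectrum(
            skin_model,
            chromophores,
            PerturbationSpec(delta_CB_rel=0.0),
            "both",
            sources=[SourceSpec(1550.0)],
            config=cfg,
        )
        assert np.all(delta == 0.0)

    def test_small_perturbation_channel_additivity(self, skin_model, chromophores):
        """For a small blood change the combined difference spectrum is the
        sum of the absorption and scattering channels to first order."""
        cfg = MCConfig(n_photons=60_000, seed=6)
        spec = PerturbationSpec(delta_CB_rel=0.05)
        src = [SourceSpec(1050.0), SourceSpec(1550.0)]
        kw = dict(sources=src, config=cfg)
        _, da, sa = blood_perturbation_spectrum(
            skin_model, chromophores, spec, "absorption_only", **kw
        )
        _, ds, ss = blood_perturbation_spectrum(
            skin_model, chromophores, spec, "scattering_only", **kw
        )
        _, db, sb = blood_perturbation_spectrum(
            skin_model, chromophores, spec, "both", **kw
        )
        tol = 3 * np.sqrt(sa**2 + ss**2 + sb**2) + 0.05 * np.abs(db) + 1e-4
        assert np.all(np.abs(db - (da + ds)) < tol)

    def test_absorption_increase_reduces_every_ring(self, skin_model, chromophores):
        """Raising mu_a in the blood-net layers can only lower each detected
        photon's reweighted contribution (paired-history comparison)."""
        stack = build_optical_stack(skin_model, chromophores, 1550.0)
        names = _stack_arrays(stack, skin_model)[5]
        dmu_t = np.array(
            [0.5 if "blood_net" in n else 0.0 for n in names]
        )
        det_b, det_pb, batch_w, *_ = _run_stack(
            stack,
            skin_model,
            DetectorSpec(),
            MCConfig(n_photons=50_000, seed=8),
            stream_key=0,
            pert=(dmu_t, np.zeros_like(dmu_t)),
        )
        base = det_b.T @ batch_w
        pert = det_pb.T @ batch_w
        assert np.all(pert <= base)
        assert np.all(pert[base > 0] < base[base > 0])

    def test_nonphysical_coefficients_rejected(self, skin_model, chromophores):
        from dataclasses import replace

        stack = build_optical_stack(skin_model, chromophores, 1550.0)
        bad = [replace(stack[0], mu_a=-1.0)] + list(stack[1:])
        with pytest.raises(TransportInputError):
            _stack_arrays(bad, skin_model)
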