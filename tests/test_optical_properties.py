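"""Layer absorption/scattering models and the blood-volume perturbation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirskin.optical_properties import (
    ChromophoreSet,
    InvalidInputError,
    InvalidPerturbationError,
    PerturbationSpec,
    SkinLayer,
    apply_perturbation,
    build_optical_stack,
    delta_mu_a,
    delta_mu_s_prime,
    mu_a_dermal,
    mu_a_living_epidermis,
    mu_a_stratum_corneum,
    mu_s_prime_graaff,
)


class TestStratumCorneumAbsorption:
    def test_printed_formula_micron_convention(self):
        # 0.1 - 8.3e-4 * 1.55 with no background term
        assert mu_a_stratum_corneum(1550.0, 0.0) == pytest.approx(0.0987135)

    def test_background_term_mixes_in(self):
        val = mu_a_stratum_corneum(1000.0, 0.8)
        assert val == pytest.approx(0.1 - 8.3e-4 + 0.125 * 0.8)

    def test_disabling_linear_term_leaves_constant(self):
        assert mu_a_stratum_corneum(1550.0, 0.0, linear_coeff_per_um=0.0) == 0.1

    def test_floor_applied_with_warning(self):
        # an nm-convention coefficient drives the value negative
        with pytest.warns(RuntimeWarning):
            val = mu_a_stratum_corneum(1550.0, 0.0, linear_coeff_per_um=8.3e-4 * 1000)
        assert val == 0.0

    def test_negative_background_rejected(self):
        with pytest.raises(InvalidInputError):
            mu_a_stratum_corneum(1550.0, -0.1)

    def test_out_of_band_wavelength_rejected(self):
        with pytest.raises(InvalidInputError):
            mu_a_stratum_corneum(900.0, 0.0)


class TestLivingEpidermisAbsorption:
    def test_dry_limit_power_law(self):
        # 0.5e10 * 1000^-3.33
        assert mu_a_living_epidermis(1000.0, 0.0, 0.0) == pytest.approx(
            0.5e10 * 1000.0**-3.33
        )

    def test_pure_water_limit(self):
        assert mu_a_living_epidermis(1234.0, 1.0, 7.7) == pytest.approx(7.7)

    def test_mixture_against_scalar_evaluation(self):
        lam, c, w = 1550.0, 0.2, 6.0
        expected = 0.8 * 0.5e10 * lam**-3.33 + 0.2 * w
        assert mu_a_living_epidermis(lam, c, w) == pytest.approx(expected)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            mu_a_living_epidermis(1550.0, 1.2, 5.0)


class TestDermalMixture:
    def test_pure_water_and_pure_blood_limits(self, tiny_chromophores):
        assert mu_a_dermal(1000.0, 0.0, 1.0, tiny_chromophores) == pytest.approx(0.5)
        assert mu_a_dermal(1000.0, 1.0, 0.0, tiny_chromophores) == pytest.approx(2.0)

    def test_table_fractions_against_scalar(self, tiny_chromophores):
        got = mu_a_dermal(1000.0, 0.3, 0.6, tiny_chromophores)
        assert got == pytest.approx(0.3 * 2.0 + 0.6 * 0.5 + 0.1 * 1.0)

    def test_mixing_bound(self, chromophores):
        # any admissible mixture lies within the envelope of its components
        rng = np.random.default_rng(7)
        for _ in range(50):
            cb = rng.uniform(0, 0.5)
            ch = rng.uniform(0, 1 - cb)
            lam = rng.uniform(1000, 1700)
            val = mu_a_dermal(lam, cb, ch, chromophores)
            comps = [
                chromophores.water(lam),
                chromophores.blood(lam),
                chromophores.other(lam),
            ]
            assert min(comps) - 1e-12 <= val <= max(comps) + 1e-12

    def test_overfilled_fractions_rejected_unless_extrapolated(
        self, tiny_chromophores
    ):
        with pytest.raises(InvalidInputError):
            mu_a_dermal(1000.0, 0.5, 0.6, tiny_chromophores)
        val = mu_a_dermal(
            1000.0, 0.5, 0.6, tiny_chromophores, allow_extrapolated=True
        )
        assert np.isfinite(val)


class TestDeltaMuA:
    def test_null_and_linearity(self, tiny_chromophores):
        assert np.all(delta_mu_a(0.0, tiny_chromophores) == 0.0)
        np.testing.assert_allclose(
            delta_mu_a(0.3, tiny_chromophores), 2 * delta_mu_a(0.15, tiny_chromophores)
        )

    def test_k_minus_one_is_blood_minus_other(self, tiny_chromophores):
        got = delta_mu_a(0.15, tiny_chromophores, k=-1.0)
        expected = 0.15 * (tiny_chromophores.mu_a_blood - tiny_chromophores.mu_a_other)
        np.testing.assert_allclose(got, expected)

    @settings(deadline=None, max_examples=50)
    @given(
        cb=st.floats(0.05, 0.4),
        ch=st.floats(0.0, 0.5),
        d=st.floats(-0.04, 0.2),
        lam=st.floats(1000.0, 1700.0),
    )
    def test_matches_finite_difference_of_mixture(self, chromophores, cb, ch, d, lam):
        """delta_mu_a with k=-1 equals the exact finite difference of the
        dermal mixture at fixed water content."""
        got = delta_mu_a(d, chromophores, k=-1.0, lam=lam)
        fd = mu_a_dermal(
            lam, cb + d, ch, chromophores, allow_extrapolated=True
        ) - mu_a_dermal(lam, cb, ch, chromophores, allow_extrapolated=True)
        assert got == pytest.approx(fd, abs=1e-10)


class TestScatteringModels:
    def test_graaff_linear_in_density(self):
        a = mu_s_prime_graaff(0.3, 1e9, 1550.0, 1.41, 1.33)
        b = mu_s_prime_graaff(0.3, 2e9, 1550.0, 1.41, 1.33)
        assert b == pytest.approx(2 * a)

    def test_graaff_unit_index_factor(self):
        # n_s/n_0 - 1 = 1 contributes exactly 1: compare against the
        # formula evaluated without the index factor
        r_cm, lam_cm, rho = 0.3e-4, 1550e-7, 1e9
        bare = 3.28 * np.pi * r_cm**2 * rho * (2 * np.pi * r_cm / lam_cm) ** 0.37
        assert mu_s_prime_graaff(0.3, 1e9, 1550.0, 2.0, 1.0) == pytest.approx(bare)

    def test_graaff_scalar_oracle(self):
        # independent scalar evaluation of the printed power law
        r_cm, lam_cm = 0.3e-4, 1.55e-4
        expected = (
            3.28
            * np.pi
            * r_cm**2
            * 1e9
            * (2 * np.pi * r_cm / lam_cm) ** 0.37
            * (1.09 - 1.0) ** 2.09
        )
        got = mu_s_prime_graaff(0.3, 1e9, 1550.0, 1.09 * 1.3, 1.3)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_graaff_invalid_indices(self):
        with pytest.raises(InvalidInputError):
            mu_s_prime_graaff(0.3, 1e9, 1550.0, 1.3, 1.4)

    def test_delta_mu_s_prime_is_relative_change(self):
        assert delta_mu_s_prime(12.0, -0.25) == pytest.approx(-3.0)
        assert delta_mu_s_prime(7.0, 0.0) == 0.0
        # the +50% table entry: relative scattering change = +50%
        msp = np.array([10.0, 20.0])
        np.testing.assert_allclose(delta_mu_s_prime(msp, 0.5) / msp, 0.5)


class TestStackAssembly:
    def test_default_model_matches_layer_table(self, skin_model):
        thick = [l.thickness for l in skin_model.layers]
        assert thick == [0.002, 0.008, 0.02, 0.01, 0.16, 0.012, 0.65]
        assert skin_model.total_depth == pytest.approx(sum(thick))
        cb = [l.C_B for l in skin_model.layers]
        assert cb == [0.0, 0.0, 0.04, 0.30, 0.04, 0.10, 0.05]
        assert skin_model.superstrate_n == 1.4
        assert skin_model.superstrate_thickness == pytest.approx(0.02)

    def test_epidermal_layers_blood_independent(self, skin_model, chromophores):
        stack = build_optical_stack(skin_model, chromophores, 1550.0)
        # stratum corneum / living epidermis mu_a contain no blood term:
        # recompute directly from the blood-free formulas
        assert stack[0].mu_a == pytest.approx(
            mu_a_stratum_corneum(1550.0, chromophores.other(1550.0))
        )
        assert stack[1].mu_a == pytest.approx(
            mu_a_living_epidermis(1550.0, 0.20, chromophores.water(1550.0))
        )

    def test_similarity_relation_isotropic_limit(self, chromophores):
        layer = SkinLayer(
            name="upper_blood_net_dermis",
            kind="dermal",
            thickness=0.01,
            C_B=0.1,
            C_H2O=0.6,
            mu_s_prime=np.full_like(chromophores.wavelengths, 15.0),
            g=0.0,
        )
        from nirskin.optical_properties import SkinModel

        model = SkinModel(layers=(layer,))
        stack = build_optical_stack(model, chromophores, 1300.0)
        assert stack[0].mu_s == pytest.approx(15.0)
        assert stack[0].mu_s_prime == pytest.approx(15.0)

    def test_bloodless_kind_requires_zero_blood(self, chromophores):
        with pytest.raises(InvalidInputError):
            SkinLayer(
                name="bad",
                kind="living_epidermis",
                thickness=0.01,
                C_B=0.1,
                C_H2O=0.2,
                mu_s_prime=np.full_like(chromophores.wavelengths, 10.0),
            )


class TestApplyPerturbation:
    def test_table_values(self, skin_model):
        with pytest.warns(RuntimeWarning):
            pert = apply_perturbation(skin_model, PerturbationSpec())
        assert pert.layer_named("upper_blood_net_dermis").C_B == pytest.approx(0.45)
        assert pert.layer_named("deep_blood_net_dermis").C_B == pytest.approx(0.15)

    def test_mu_s_scales_with_relative_blood_change(self, skin_model):
        with pytest.warns(RuntimeWarning):
            pert = apply_perturbation(skin_model, PerturbationSpec())
        for name in ("upper_blood_net_dermis", "deep_blood_net_dermis"):
            ratio = (
                pert.layer_named(name).mu_s_prime
                / skin_model.layer_named(name).mu_s_prime
            )
            np.testing.assert_allclose(ratio, 1.5)

    def test_untargeted_layers_untouched(self, skin_model):
        with pytest.warns(RuntimeWarning):
            pert = apply_perturbation(skin_model, PerturbationSpec())
        for name in ("stratum_corneum", "reticular_dermis", "subcutaneous_tissue"):
            a = skin_model.layer_named(name)
            b = pert.layer_named(name)
            assert a.C_B == b.C_B
            np.testing.assert_array_equal(a.mu_s_prime, b.mu_s_prime)

    def test_null_perturbation_identity(self, skin_model):
        pert = apply_perturbation(skin_model, PerturbationSpec(delta_CB_rel=0.0))
        for a, b in zip(skin_model.layers, pert.layers):
            assert a.C_B == b.C_B
            np.testing.assert_array_equal(a.mu_s_prime, b.mu_s_prime)

    @pytest.mark.parametrize("r", [0.5, 0.2, -0.3])
    def test_inverse_perturbation_recovers_original(self, skin_model, r):
        import warnings

        spec = PerturbationSpec(delta_CB_rel=r)
        inv = PerturbationSpec(delta_CB_rel=-r / (1 + r))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            back = apply_perturbation(apply_perturbation(skin_model, spec), inv)
        for a, b in zip(skin_model.layers, back.layers):
            assert b.C_B == pytest.approx(a.C_B, abs=1e-15)
            np.testing.assert_allclose(b.mu_s_prime, a.mu_s_prime, rtol=1e-14)

    def test_bloodless_target_rejected(self, skin_model):
        with pytest.raises(InvalidPerturbationError):
            apply_perturbation(
                skin_model, PerturbationSpec(target_layers={"stratum_corneum"})
            )

    def test_out_of_range_blood_fraction_rejected(self, skin_model):
        with pytest.raises(InvalidPerturbationError):
            apply_perturbation(skin_model, PerturbationSpec(delta_CB_rel=3.0))


class TestChromophoreSet:
    def test_negative_spectra_rejected(self):
        wl = np.array([1000.0, 1700.0])
        with pytest.raises(InvalidInputError):
            ChromophoreSet(wl, np.array([-1.0, 1.0]), np.ones(2), np.ones(2))

    def test_interpolation_and_range_guard(self, tiny_chromophores):
        assert tiny_chromophores.water(1175.0) == pytest.approx(5.25)
        with pytest.raises(InvalidInputError):
            tiny_chromophores.water(990.0)
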