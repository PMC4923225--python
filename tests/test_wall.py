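"""Layered-wall flux laws: closed forms vs numerical oracles, profiles,
flux balances, and the alveolar exchange law."""

import numpy as np
import pytest

from lungno.morphometry import ConstrictionProfile, WallLayerSpec, apply_alterations
from lungno.wall import (
    BODY_TEMPERATURE_K,
    GAS_CONSTANT,
    AlveolarParams,
    HattaNumbers,
    WallTransportParams,
    airway_flux_law,
    alveolar_flux_law,
    fraction_consumed,
    hatta_numbers,
    slab_flux_numerical,
    wall_profile,
)

PARAMS = WallTransportParams()
REST_HA = hatta_numbers(0.0030, 0.0015, 0.0, PARAMS)


def exponential_form_law(ha, ha_t, mu, p=PARAMS):
    """The flux-law coefficients written with exponentials, as an independent
    algebraic form of the same solution (used as a transcription check)."""
    e = np.exp
    den = -1 + mu + e(2 * (ha + ha_t)) * (1 + mu)
    a = p.pr * np.sqrt(p.d_no_t / p.k) * (e(ha_t) - 1) * (-1 + e(2 * ha + ha_t)) \
        / den * p.gamma
    b = p.lambda_t_air * np.sqrt(p.k * p.d_no_t) * (1 + e(2 * (ha + ha_t))) \
        / den * p.gamma
    return a, b


class TestHattaNumbers:
    def test_rest_values(self):
        assert REST_HA.ha == pytest.approx(0.739, abs=0.001)
        assert REST_HA.ha_tilde == pytest.approx(0.369, abs=0.001)
        assert REST_HA.mu == 0.0

    def test_linear_in_thickness(self):
        doubled = hatta_numbers(0.0060, 0.0030, 0.0010, PARAMS)
        half = hatta_numbers(0.0030, 0.0015, 0.0005, PARAMS)
        assert doubled.ha == pytest.approx(2 * half.ha, rel=1e-14)
        assert doubled.mu == pytest.approx(2 * half.mu, rel=1e-14)

    def test_gamma_is_ideal_gas_at_body_temperature(self):
        ideal = GAS_CONSTANT * BODY_TEMPERATURE_K / 1.0
        assert PARAMS.gamma == pytest.approx(ideal, rel=1e-3)


class TestAirwayFluxLaw:
    def test_matches_exponential_transcription(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            ha, ha_t, mu = rng.uniform(0.01, 2.0, 3)
            law = airway_flux_law(HattaNumbers(ha, ha_t, mu), PARAMS)
            a_ref, b_ref = exponential_form_law(ha, ha_t, mu)
            assert law.a == pytest.approx(a_ref, rel=1e-12)
            assert law.b == pytest.approx(b_ref, rel=1e-12)

    def test_mucus_free_limit_is_continuous(self):
        law0 = airway_flux_law(HattaNumbers(0.7, 0.35, 0.0), PARAMS)
        law_eps = airway_flux_law(HattaNumbers(0.7, 0.35, 1e-14), PARAMS)
        assert law_eps.a == pytest.approx(law0.a, rel=1e-12)
        assert law_eps.b == pytest.approx(law0.b, rel=1e-12)

    def test_consumption_coefficient_is_coth_form(self):
        # without mucus, b = gamma lambda sqrt(kD) coth(Ha + Ha~)
        law = airway_flux_law(REST_HA, PARAMS)
        tot = REST_HA.ha + REST_HA.ha_tilde
        expected = PARAMS.gamma * PARAMS.lambda_t_air * np.sqrt(PARAMS.k * PARAMS.d_no_t) \
            / np.tanh(tot)
        assert law.b == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("c_lumen", [0.0, 5e-9, 5e-8])
    def test_against_boundary_value_oracle(self, c_lumen):
        for ha_t in (HattaNumbers(0.739, 0.369, 0.0), HattaNumbers(0.9, 0.5, 0.12)):
            law = airway_flux_law(ha_t, PARAMS)
            oracle = slab_flux_numerical(ha_t, PARAMS, c_lumen, n=300)
            assert law(c_lumen) == pytest.approx(oracle, rel=1e-6)

    def test_degenerate_wall_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            airway_flux_law(HattaNumbers(0.0, 0.0, 0.0), PARAMS)

    def test_production_grows_with_layer_thickness(self):
        # thicker epithelium/muscle raise the residence time and the zero-
        # concentration flux; mucus is a pure barrier and lowers it
        base = airway_flux_law(HattaNumbers(0.7, 0.35, 0.0), PARAMS)
        thick_e = airway_flux_law(HattaNumbers(0.7, 0.50, 0.0), PARAMS)
        thick_m = airway_flux_law(HattaNumbers(1.0, 0.35, 0.0), PARAMS)
        with_mucus = airway_flux_law(HattaNumbers(0.7, 0.35, 0.3), PARAMS)
        assert thick_e.a > base.a
        assert thick_m.a > base.a
        assert with_mucus.a < base.a

    def test_strictly_decreasing_with_unique_root(self):
        law = airway_flux_law(REST_HA, PARAMS)
        c_star = law.equilibrium
        assert c_star > 0
        assert law(0.5 * c_star) > 0 > law(2.0 * c_star)


class TestWallProfile:
    def test_flux_consistency_with_law(self):
        for mu in (0.0, 0.2):
            ha = HattaNumbers(0.8, 0.4, mu)
            law = airway_flux_law(ha, PARAMS)
            for c in (0.0, 5e-9, 2e-7):
                prof = wall_profile(ha, PARAMS, c)
                assert prof.flux_to_lumen == pytest.approx(law(c), rel=1e-10)

    def test_interface_continuity(self):
        ha = HattaNumbers(0.739, 0.369, 0.1)
        prof = wall_profile(ha, PARAMS, 5e-9)
        dm, de = prof.delta_muscle, prof.delta_epithelium
        for x0 in (dm, dm + de):
            below, above = prof.concentration(x0 - 1e-13), prof.concentration(x0 + 1e-13)
            assert above == pytest.approx(below, rel=1e-6)
            eps = 1e-9
            g_below = (prof.concentration(x0 - eps) - prof.concentration(x0 - 3 * eps)) / (2 * eps)
            g_above = (prof.concentration(x0 + 3 * eps) - prof.concentration(x0 + eps)) / (2 * eps)
            assert g_above == pytest.approx(g_below, rel=1e-4)

    def test_blood_sink_and_positivity(self):
        prof = wall_profile(REST_HA, PARAMS, 0.0)
        x = np.linspace(0, prof.thickness, 500)
        c = prof.concentration(x)
        assert c[0] == 0.0
        assert np.all(c >= 0)

    def test_maximum_in_epithelium_at_zero_lumen(self):
        prof = wall_profile(REST_HA, PARAMS, 0.0)
        x = np.linspace(0, prof.thickness, 2000)
        xmax = x[np.argmax(prof.concentration(x))]
        assert prof.delta_muscle < xmax < prof.delta_muscle + prof.delta_epithelium

    def test_zero_production_zero_lumen_gives_zero(self):
        p0 = WallTransportParams(pr=1e-30)
        prof = wall_profile(REST_HA, p0, 0.0)
        x = np.linspace(0, prof.thickness, 50)
        assert np.all(np.abs(prof.concentration(x)) < 1e-25)

    def test_flux_balance(self):
        for c in (0.0, 5e-9, 1e-7):
            prof = wall_profile(HattaNumbers(0.9, 0.45, 0.05), PARAMS, c)
            assert prof.flux_to_lumen + prof.flux_to_blood + prof.consumed \
                == pytest.approx(prof.produced, rel=1e-9)


class TestFractionConsumed:
    def test_healthy_rest_band(self):
        assert 0.05 <= fraction_consumed(REST_HA, PARAMS, 0.0) <= 0.15

    def test_constricted_band(self, table):
        rest = apply_alterations(
            table, WallLayerSpec(), ConstrictionProfile.homogeneous_beta(0.9, 2, 15))
        ha = hatta_numbers(rest.delta_muscle[12], rest.delta_epithelium[12], 0.0, PARAMS)
        assert 0.15 <= fraction_consumed(ha, PARAMS, 0.0) <= 0.35

    def test_vanishes_without_reaction(self):
        slow = WallTransportParams(k=1e-9)
        ha = hatta_numbers(0.0030, 0.0015, 0.0, slow)
        assert fraction_consumed(ha, slow, 0.0) == pytest.approx(0.0, abs=1e-6)


class TestAlveolarFluxLaw:
    def test_equilibrium_near_two_ppb(self):
        alv = AlveolarParams()
        assert 2e-9 <= alv.equilibrium <= 3e-9
        law = alveolar_flux_law(alv, 1.0e5)
        assert law(alv.equilibrium) == pytest.approx(0.0, abs=1e-25)

    def test_surface_scaling_leaves_equilibrium(self):
        alv = AlveolarParams()
        law1 = alveolar_flux_law(alv, 2.0e5)
        law2 = alveolar_flux_law(alv, 4.0e5)
        assert law2.a == pytest.approx(law1.a / 2, rel=1e-14)
        assert law2.b == pytest.approx(law1.b / 2, rel=1e-14)
        assert law2.equilibrium == pytest.approx(law1.equilibrium, rel=1e-14)

    def test_zero_surface_rejected(self):
        with pytest.raises(ValueError):
            alveolar_flux_law(AlveolarParams(), 0.0)
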