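import numpy as np
import pytest
from scipy import constants as codata

from hyperpol.spectra import StickSpectrum
from hyperpol.synthetic import make_mode_set, make_table2_like_modes
from hyperpol.tensors import beta_vec, units
from hyperpol.vibrational import (
    KM_MOL_PER_AU_DIPDERIV_SQ,
    KM_MOL_PER_E2_AMU,
    NormalMode,
    beta_v_process,
    ir_intensity,
    mu_alpha_bracket,
    per_mode_beta_vec,
    raman_activity,
    raman_invariants,
)


def single_mode(d=0.01, p=0.02, wavenumber=1000.0, index=1):
    dalpha = np.zeros((3, 3))
    dalpha[0, 0] = p
    return NormalMode(
        index=index, wavenumber=wavenumber,
        dmu=np.array([d, 0.0, 0.0]), dalpha=dalpha,
    )


def brute_force_bracket(modes):
    """Explicit (i, j, k, mode) loop oracle for the double-harmonic sum."""
    out = np.zeros((3, 3, 3))
    for m in modes:
        w = m.wavenumber / units.HARTREE_TO_CM1
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    out[i, j, k] += (
                        m.dmu[i] * m.dalpha[j, k]
                        + m.dmu[j] * m.dalpha[i, k]
                        + m.dmu[k] * m.dalpha[i, j]
                    ) / w**2
    return out


class TestMuAlphaBracket:
    def test_single_mode_closed_form(self):
        d, p, w = 0.01, 0.02, 1000.0
        mode = single_mode(d, p, w)
        bracket = mu_alpha_bracket([mode])
        w_au = w / units.HARTREE_TO_CM1
        assert bracket[0, 0, 0] == pytest.approx(3 * d * p / w_au**2, rel=1e-12)
        # components without full overlap between dmu (x) and dalpha (xx) vanish
        mask = np.ones((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = False
        assert np.max(np.abs(bracket[mask])) == 0.0

    def test_additive_over_modes(self):
        m1 = single_mode(0.01, 0.02, 900.0, index=1)
        m2 = single_mode(-0.03, 0.01, 1500.0, index=2)
        total = mu_alpha_bracket([m1, m2])
        np.testing.assert_allclose(
            total, mu_alpha_bracket([m1]) + mu_alpha_bracket([m2]), rtol=1e-14
        )

    def test_brute_force_oracle_30_modes(self):
        modes, _ = make_mode_set(30, seed=4)
        np.testing.assert_allclose(
            mu_alpha_bracket(modes), brute_force_bracket(modes), rtol=1e-12
        )

    def test_recorded_tensor_recovery(self):
        modes, recorded = make_mode_set(12, seed=9)
        np.testing.assert_allclose(mu_alpha_bracket(modes), recorded, rtol=1e-12)

    def test_wavenumber_scaling_law(self):
        modes, _ = make_mode_set(8, seed=2)
        s = 1.7
        scaled = [
            NormalMode(m.index, m.wavenumber * s, m.dmu, m.dalpha) for m in modes
        ]
        np.testing.assert_allclose(
            mu_alpha_bracket(scaled), mu_alpha_bracket(modes) / s**2, rtol=1e-12
        )

    def test_non_positive_wavenumber_cites_mode(self):
        bad = NormalMode(index=3, wavenumber=-100.0, dmu=np.zeros(3), dalpha=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="mode 3"):
            mu_alpha_bracket([bad])

    def test_floor_excludes_rotations(self):
        low = single_mode(wavenumber=10.0, index=1)
        high = single_mode(wavenumber=1000.0, index=2)
        total = mu_alpha_bracket([low, high])
        np.testing.assert_allclose(total, mu_alpha_bracket([high]), rtol=1e-14)
        with_override = mu_alpha_bracket([low, high], wavenumber_floor=0.0)
        assert with_override[0, 0, 0] > total[0, 0, 0]

    def test_fully_index_symmetric(self):
        modes, _ = make_mode_set(5, seed=6)
        b = mu_alpha_bracket(modes)
        for perm in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
            np.testing.assert_allclose(b, np.transpose(b, perm), rtol=1e-13)


class TestProcessLimits:
    def test_shg_limit_is_zero(self):
        modes, _ = make_mode_set(6, seed=1)
        shg = beta_v_process(mu_alpha_bracket(modes), "SHG")
        assert np.max(np.abs(shg.tensor)) == 0.0

    def test_eope_is_one_third(self):
        modes, _ = make_mode_set(6, seed=1)
        bracket = mu_alpha_bracket(modes)
        eope = beta_v_process(bracket, "EOPE")
        np.testing.assert_allclose(eope.tensor, bracket / 3.0, rtol=1e-14)

    def test_eope_beta_vec_homogeneity(self):
        mode = single_mode()
        bracket = mu_alpha_bracket([mode])
        assert beta_vec(beta_v_process(bracket, "EOPE")) == pytest.approx(
            beta_vec(bracket) / 3.0, rel=1e-12
        )

    def test_unknown_process(self):
        with pytest.raises(ValueError, match="process"):
            beta_v_process(np.zeros((3, 3, 3)), "THG")

    def test_parameter_recovery_closed_form(self):
        modes, recorded = make_mode_set(10, seed=13)
        eope = beta_v_process(mu_alpha_bracket(modes), "EOPE")
        assert beta_vec(eope) == pytest.approx(
            beta_vec(recorded) / 3.0, rel=1e-12
        )


class TestPerMode:
    def test_single_mode_equals_total(self):
        mode = single_mode()
        contribs = per_mode_beta_vec([mode], "EOPE")
        total = beta_vec(beta_v_process(mu_alpha_bracket([mode]), "EOPE"))
        assert contribs[0].beta_vec == pytest.approx(total, rel=1e-12)

    def test_opposing_modes_cancel(self):
        m1 = single_mode(d=0.01, p=0.02, wavenumber=1000.0, index=1)
        m2 = single_mode(d=-0.01, p=0.02, wavenumber=1000.0, index=2)
        contribs = per_mode_beta_vec([m1, m2], "EOPE")
        total = beta_vec(beta_v_process(mu_alpha_bracket([m1, m2]), "EOPE"))
        assert total < sum(c.beta_vec for c in contribs)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_per_mode_matches_single_mode_recomputation(self):
        modes, _ = make_mode_set(10, seed=17)
        contribs = per_mode_beta_vec(modes, "EOPE")
        for mode, contrib in zip(modes, contribs):
            single = beta_vec(beta_v_process(mu_alpha_bracket([mode]), "EOPE"))
            assert contrib.beta_vec == pytest.approx(single, rel=1e-12)

    def test_low_mid_wavenumber_modes_dominate(self, fixture):
        """Table-shaped fixture: the strong IR+Raman C=O-like mode leads,
        while >3000 cm^-1 stretches contribute marginally (omega^2 penalty)."""
        modes = make_table2_like_modes("gas", include_stretch_modes=True)
        contribs = {c.index: c.beta_vec for c in per_mode_beta_vec(modes, "EOPE")}
        top_index = max(contribs, key=contribs.get)
        assert top_index == 25
        stretch_total = sum(
            v for idx, v in contribs.items()
            if next(m for m in modes if m.index == idx).wavenumber > 3000
        )
        assert stretch_total < 0.25 * contribs[25]


class TestIntensities:
    def test_zero_dipole_derivative(self):
        mode = NormalMode(index=1, wavenumber=500.0, dmu=np.zeros(3),
                          dalpha=np.eye(3) * 0.01)
        assert ir_intensity(mode) == 0.0

    def test_doubling_derivative_quadruples_intensity(self):
        m1 = single_mode(d=0.01)
        m2 = single_mode(d=0.02)
        assert ir_intensity(m2) == pytest.approx(4 * ir_intensity(m1), rel=1e-12)

    def test_ir_constant_from_fundamental_constants(self):
        # N_A pi / (3 c^2) * (e^2 / 4 pi eps0) / amu, folded to km/mol
        amu = codata.value("atomic mass constant")
        k = (
            codata.N_A * np.pi / (3.0 * codata.c**2)
            * codata.e**2 / (4.0 * np.pi * codata.epsilon_0) / amu
        ) / 1000.0
        assert KM_MOL_PER_E2_AMU == pytest.approx(k, rel=1e-12)
        assert KM_MOL_PER_E2_AMU == pytest.approx(974.8802, abs=2e-3)
        me_per_amu = amu / codata.m_e
        assert KM_MOL_PER_AU_DIPDERIV_SQ == pytest.approx(k * me_per_amu, rel=1e-12)

    def test_zero_polarizability_derivative(self):
        mode = NormalMode(index=1, wavenumber=500.0, dmu=np.ones(3) * 0.01,
                          dalpha=np.zeros((3, 3)))
        assert raman_activity(mode) == 0.0

    def test_isotropic_closed_form(self):
        p = 0.015
        mode = NormalMode(index=1, wavenumber=800.0, dmu=np.zeros(3),
                          dalpha=np.eye(3) * p)
        assert raman_activity(mode, practical_units=False) == pytest.approx(
            45.0 * p**2, rel=1e-12
        )

    def test_invariants_brute_force(self, rng):
        raw = rng.normal(0, 0.05, (3, 3))
        da = (raw + raw.T) / 2.0
        iso, g2 = raman_invariants(da)
        assert iso == pytest.approx((da[0, 0] + da[1, 1] + da[2, 2]) / 3.0)
        g2_bf = 0.5 * (
            (da[0, 0] - da[1, 1]) ** 2
            + (da[1, 1] - da[2, 2]) ** 2
            + (da[2, 2] - da[0, 0]) ** 2
            + 6.0 * (da[0, 1] ** 2 + da[1, 2] ** 2 + da[0, 2] ** 2)
        )
        assert g2 == pytest.approx(g2_bf, rel=1e-12)

    def test_table_shaped_fixture_reproduces_printed_sticks(self, fixture):
        modes = make_table2_like_modes("gas", include_stretch_modes=False)
        for mode, row in zip(modes, fixture.gas.modes):
            assert ir_intensity(mode) == pytest.approx(row.i_ir, rel=1e-9)
            assert raman_activity(mode) == pytest.approx(row.a_raman, rel=1e-9)


class TestNormalModeType:
    def test_asymmetric_dalpha_rejected(self):
        bad = np.array([[0.0, 0.02, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            NormalMode(index=1, wavenumber=100.0, dmu=np.zeros(3), dalpha=bad)

    def test_contribution_fields_non_negative(self):
        modes, _ = make_mode_set(6, seed=3)
        for c in per_mode_beta_vec(modes, "EOPE"):
            assert c.beta_vec >= 0 and c.i_ir >= 0 and c.a_raman >= 0
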