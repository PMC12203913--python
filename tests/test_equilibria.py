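"""Depletion isotherm, Kd fitting, the coupled mass-balance solver (checked
against an independent 1D-root-reduction oracle), and SPR steady state."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from curtainkit import synthetic
from curtainkit.config import EquilibriumParams, InvalidConfigError
from curtainkit.equilibria import (
    KdFitter,
    NonIdentifiableError,
    SprSteadyStateFitter,
    bound_fraction,
    enhancement_fold,
    fit_kd,
    solve_ux,
    spr_steady_state,
)


class TestBoundFraction:
    def test_zero_protein(self):
        assert bound_fraction(0.0, 4.0, 5.0) == 0.0

    def test_stoichiometric_limit(self):
        assert bound_fraction(10.0, 4.0, 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_quadratic_value(self):
        assert bound_fraction(10.0, 4.0, 5.0) == pytest.approx(0.603, abs=5e-4)

    def test_zero_dna_rejected(self):
        with pytest.raises(InvalidConfigError):
            bound_fraction(10.0, 0.0, 5.0)

    @given(
        st.floats(0.1, 100.0), st.floats(0.5, 20.0), st.floats(0.1, 100.0)
    )
    @settings(max_examples=100, derandomize=True)
    def test_agrees_with_root_search_oracle(self, p, d, kd):
        # independent oracle: root of (P-C)(D-C) - Kd*C on [0, min(P,D)]
        c = brentq(
            lambda x: (p - x) * (d - x) - kd * x, 0.0, min(p, d), xtol=1e-14
        )
        assert bound_fraction(p, d, kd) == pytest.approx(c / d, abs=1e-10)


class TestKdFitter:
    def test_noise_free_self_consistency(self, default_params):
        series = synthetic.simulate_titration(
            default_params, [0, 3, 5, 10, 15, 20, 30, 50], 4.0
        )
        kd, se = fit_kd(series)
        assert kd == pytest.approx(5.0, abs=1e-6)

    def test_recovery_under_noise_100_seeds(self, default_params):
        kds = []
        for seed in range(100):
            series = synthetic.simulate_titration(
                default_params, [0, 3, 5, 10, 15, 20, 30, 50], 4.0,
                noise_sd=0.05, seed=seed,
            )
            kds.append(fit_kd(series)[0])
        assert np.median(kds) == pytest.approx(5.0, rel=0.20)

    def test_flat_data_non_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            KdFitter(4.0).fit([0, 5, 10, 20], [0.5, 0.52, 0.51, 0.5])

    def test_sklearn_interface(self):
        est = KdFitter(dna_total_nM=10.0)
        assert est.get_params() == {"dna_total_nM": 10.0}
        concs = np.array([0, 2, 4, 6, 10, 18, 25.0])
        est.fit(concs, bound_fraction(concs, 10.0, 7.0))
        assert est.kd_nM_ == pytest.approx(7.0, abs=1e-6)
        np.testing.assert_allclose(
            est.predict(concs), bound_fraction(concs, 10.0, 7.0), atol=1e-6
        )


def _oracle_solve(params, substrate, u_tot, x_tot, d_tot):
    """Independent solver: reduce to a 1D root in free DNA.

    For fixed free DNA d, the two protein balances reduce to a quadratic in
    free U (after eliminating X), leaving a single equation in d solved by
    bisection. Valid without the 2:1 species.
    """
    k_ud, k_xd = params.kd_U(substrate), params.kd_X(substrate)
    k_ux, k_uxd = params.kd_UX_protein_nM, params.kd_UXdna(substrate)

    def free_proteins(d):
        alpha = 1.0 + d / k_ud
        beta = 1.0 + d / k_xd
        gamma = (1.0 + d / k_uxd) / k_ux
        # gamma*alpha*U^2 + (gamma*(X_tot - U_tot) + beta*alpha)*U - beta*U_tot = 0
        a = gamma * alpha
        b = gamma * (x_tot - u_tot) + beta * alpha
        c = -beta * u_tot
        u = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
        x = (x_tot - u_tot + u * alpha) / beta
        return u, x

    def d_balance(d):
        u, x = free_proteins(d)
        return d * (1 + u / k_ud + x / k_xd + u * x / (k_ux * k_uxd)) - d_tot

    d = brentq(d_balance, 1e-12, d_tot, xtol=1e-15)
    u, x = free_proteins(d)
    return {"U": u, "X": x, "D": d, "UX": u * x / k_ux, "UD": u * d / k_ud,
            "XD": x * d / k_xd, "UXD": u * x * d / (k_ux * k_uxd)}


class TestSolveUx:
    def test_decoupling_limit_matches_single_protein_quadratic(self):
        params = EquilibriumParams(
            kd_UX_protein_nM=1e9, totals={"U": 10.0, "X": 5.0, "D": 4.0}
        )
        state = solve_ux(params, "cpd")
        assert state.UXD == pytest.approx(0.0, abs=1e-6)
        expected_ud = bound_fraction(10.0, 4.0, 5.0) * 4.0
        # X competes for DNA even without complex formation
        params_no_x = EquilibriumParams(
            kd_UX_protein_nM=1e9, totals={"U": 10.0, "X": 0.0, "D": 4.0}
        )
        assert solve_ux(params_no_x, "cpd").UD == pytest.approx(expected_ud, rel=1e-6)

    def test_complex_loading_exceeds_solo_binding(self):
        # U=2, X=2, D=10 nM on undamaged DNA: DNA-bound U with a tight UX
        # complex exceeds the X-free quadratic value 0.533 nM
        params = EquilibriumParams(totals={"U": 2.0, "X": 2.0, "D": 10.0})
        state = solve_ux(params, "undamaged")
        solo = bound_fraction(2.0, 10.0, 26.0) * 10.0
        assert solo == pytest.approx(0.533, abs=2e-3)
        assert state.dna_bound_U > solo

    def test_mass_conservation(self):
        params = EquilibriumParams(
            kd_U2_nM=20.0, totals={"U": 8.0, "X": 3.0, "D": 6.0}
        )
        state = solve_ux(params, "cpd")
        u = state.U + state.UX + state.UD + state.UXD + 2 * state.U2D
        x = state.X + state.UX + state.XD + state.UXD
        d = state.D + state.UD + state.XD + state.UXD + state.U2D
        assert u == pytest.approx(8.0, rel=1e-9)
        assert x == pytest.approx(3.0, rel=1e-9)
        assert d == pytest.approx(6.0, rel=1e-9)

    @pytest.mark.parametrize("substrate", ["cpd", "undamaged"])
    def test_agrees_with_1d_reduction_oracle(self, substrate):
        rng = np.random.default_rng(6)
        for _ in range(20):
            u_tot, x_tot, d_tot = rng.uniform(0.5, 30.0, 3)
            params = EquilibriumParams(
                kd_UX_protein_nM=float(rng.uniform(0.2, 50.0)),
                totals={"U": u_tot, "X": x_tot, "D": d_tot},
            )
            state = solve_ux(params, substrate)
            oracle = _oracle_solve(params, substrate, u_tot, x_tot, d_tot)
            for name in ("U", "X", "D", "UX", "UD", "XD", "UXD"):
                assert getattr(state, name) == pytest.approx(
                    oracle[name], rel=1e-6, abs=1e-9
                ), name


class TestEnhancementFold:
    def test_no_partner_gives_unity(self):
        params = EquilibriumParams(totals={"U": 5.0, "X": 0.0, "D": 4.0})
        fold_u, _ = enhancement_fold(params, "cpd")
        assert fold_u == pytest.approx(1.0, rel=1e-9)

    def test_asymmetry_on_undamaged_dna(self):
        # X loads U onto DNA (fold_U > 1) but U does not load X (fold_X ~ 1)
        params = EquilibriumParams(totals={"U": 2.0, "X": 2.0, "D": 10.0})
        fold_u, fold_x = enhancement_fold(params, "undamaged")
        assert fold_u > 1.05
        assert fold_x == pytest.approx(1.0, abs=0.10)
        assert fold_u > fold_x

    def test_monotone_in_complex_affinity(self):
        folds = []
        for k_ux in (0.1, 1.0, 10.0, 1e6):
            params = EquilibriumParams(
                kd_UX_protein_nM=k_ux, totals={"U": 2.0, "X": 2.0, "D": 10.0}
            )
            folds.append(enhancement_fold(params, "undamaged")[0])
        assert all(a >= b - 1e-9 for a, b in zip(folds, folds[1:]))

    def test_infinite_complex_kd_limit_is_unity_without_competition(self):
        # with DNA in large excess the competition of X for DNA vanishes,
        # so an infinitely weak protein-protein complex gives fold 1
        params = EquilibriumParams(
            kd_UX_protein_nM=1e9, totals={"U": 2.0, "X": 2.0, "D": 1000.0}
        )
        fold_u, _ = enhancement_fold(params, "undamaged")
        assert fold_u == pytest.approx(1.0, abs=5e-3)


class TestSpr:
    def test_half_saturation_identity(self):
        est = SprSteadyStateFitter().fit(
            np.array([10, 25, 50, 100, 200, 400, 600.0]),
            100 * np.array([10, 25, 50, 100, 200, 400, 600.0])
            / (80.0 + np.array([10, 25, 50, 100, 200, 400, 600.0])),
        )
        assert est.predict(est.kd_nM_) == pytest.approx(est.ru_max_ / 2)
        assert est.kd_nM_ == pytest.approx(80.0, rel=1e-6)

    def test_recovery_with_noise(self):
        rng = np.random.default_rng(14)
        c = np.array([10, 25, 50, 100, 200, 400, 600.0])
        kds = []
        for _ in range(50):
            ru = 120 * c / (90.0 + c) * (1 + rng.normal(0, 0.03, c.size))
            kds.append(spr_steady_state(c, ru)[0])
        assert np.median(kds) == pytest.approx(90.0, rel=0.15)

    def test_non_saturating_warns(self):
        c = np.array([1.0, 2.0, 4.0, 8.0])
        ru = 100 * c / (1000.0 + c)
        with pytest.warns(RuntimeWarning):
            SprSteadyStateFitter().fit(c, ru)
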