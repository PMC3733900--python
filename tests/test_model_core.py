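"""Unit tests for the reaction-network core: parameters, rate equations,
propensities, and unit conversion."""
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import apoptosim as ap
from apoptosim.model import STOICHIOMETRY, SPECIES


class TestParameters:
    def test_nominal_defaults(self, params):
        # the published nominal set
        expected = dict(kf1=0.12, kf2=0.3, kf3=0.015, kr1=0.4, K_H=1.0,
                        K_K=0.5, K_L=0.3, K_P=0.1, K_U=0.1, k_u=0.03,
                        IAP=0.018, K_c=0.1, mu1=0.005, mu2=0.005, mu3=0.005,
                        mu4=0.005, mu5=0.005, Omega_EZ=0.05, Omega_9=0.05,
                        n=1.5)
        for k, v in expected.items():
            assert getattr(params, k) == v
        assert params.variant == "modified"
        assert params.V_c == 1000.0

    @pytest.mark.parametrize("field,value", [
        ("kf1", -0.1), ("V_c", 0.0), ("n", 0.5), ("variant", "legewie"),
    ])
    def test_invalid_parameters_rejected(self, field, value):
        with pytest.raises(ValueError):
            ap.ModelParameters(**{field: value})

    def test_fussenegger_forces_unit_cooperativity(self, params):
        f = params.replace(variant="fussenegger")
        assert f.effective_n == 1.0
        assert params.effective_n == 1.5

    def test_yaml_round_trip(self, params, tmp_path):
        p = params.replace(CC=0.37, variant="fussenegger", K_c=0.2)
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        assert ap.ModelParameters.from_yaml(path) == p

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            ap.ModelParameters.from_dict({"kf9": 1.0})


class TestConditions:
    def test_eight_study_conditions(self):
        assert len(ap.PAPER_CONDITIONS) == 8
        c9ps = {c.c9p_target for c in ap.PAPER_CONDITIONS}
        c3ps = {c.c3p_target for c in ap.PAPER_CONDITIONS}
        assert c9ps == {5e3, 1e4}
        assert c3ps == {10.0, 1e2, 1e3, 1e4}

    def test_apply_condition_rescales_synthesis(self, params):
        # 1e4 molecules at V_c=1000 recovers the nominal rate
        p = ap.apply_condition(params, ap.CopyNumberCondition(1e4, 10))
        assert p.Omega_9 == pytest.approx(0.05)
        assert p.Omega_EZ == pytest.approx(5e-5)
        assert p.kf1 == params.kf1

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            ap.CopyNumberCondition(1e4, 0)


class TestDerivatives:
    def test_zero_state_only_synthesis(self, params):
        d = ap.derivatives(ap.StateVector(), params.replace(CC=0.0))
        assert d == pytest.approx([0.0, 0.05, 0.0, 0.05, 0.0])

    def test_open_loop_balance_is_equilibrium(self, params):
        # c9p* = Omega_9/mu2 = 10, c3p* = Omega_EZ/mu4 = 10 at CC=0
        st = ap.StateVector(c9p=10.0, c3p=10.0)
        d = ap.derivatives(st, params.replace(CC=0.0))
        assert np.allclose(d, 0.0, atol=1e-14)

    def test_apoptosome_formation_term(self, params):
        # kf1*CC/(1+K_H*CC) = 0.12*1/(1+1) = 0.06 at CC=1, empty a1cc
        d = ap.derivatives(ap.StateVector(c9p=10, c3p=10),
                           params.replace(CC=1.0))
        assert d[0] == pytest.approx(0.06)

    def test_negative_state_rejected(self, params):
        with pytest.raises(ValueError):
            ap.derivatives(np.array([-0.1, 10, 0, 10, 0]), params)

    @pytest.mark.parametrize("i", range(5))
    def test_flow_preserves_nonnegativity(self, params, i):
        """d(species)/dt >= 0 whenever that species is 0 (boundary flow)."""
        rng = np.random.default_rng(7 + i)
        p = params.replace(CC=0.5)
        for _ in range(25):
            x = rng.uniform(0, 10, size=5)
            x[i] = 0.0
            assert ap.derivatives(x, p)[i] >= -1e-15

    def test_fussenegger_activation_independent_of_feedback(self, params):
        """In the original cascade the activation flux ignores CEA and is
        linear in a1cc (no feedback factor, no autocatalysis)."""
        p = params.replace(variant="fussenegger", CC=0.5)
        base = ap.derivatives([0.1, 5.0, 1.0, 5.0, 0.0], p)
        with_cea = ap.derivatives([0.1, 5.0, 1.0, 5.0, 3.0], p)
        assert base[1] == pytest.approx(with_cea[1])  # c9p consumption same
        doubled = ap.derivatives([0.2, 5.0, 1.0, 5.0, 0.0], p)
        flux = lambda d: p.Omega_9 - d[1] - p.mu2 * 5.0
        assert flux(doubled) == pytest.approx(2 * flux(base))

    def test_modified_activation_gated_by_feedback(self, params):
        """The modified variant's activation flux rises steeply with CEA."""
        p = params.replace(CC=0.5)
        lo = ap.derivatives([0.1, 5.0, 1.0, 5.0, 0.01], p)
        hi = ap.derivatives([0.1, 5.0, 1.0, 5.0, 1.0], p)
        flux = lambda d: p.Omega_9 - d[1] - p.mu2 * 5.0
        assert flux(hi) > 5 * flux(lo) > 0


class TestPropensities:
    def test_synthesis_only_at_zero_counts(self, params):
        a = ap.propensities(ap.CountState(cc_count=0), params)
        expected = np.zeros(12)
        expected[3] = expected[7] = 50.0  # 0.05 uM/min * 1000 molecules/uM
        assert np.allclose(a, expected)

    def test_first_order_unbinding(self, params):
        a = ap.propensities(ap.CountState(a1cc=100, cc_count=0), params)
        assert a[1] == pytest.approx(0.4 * 100)

    def test_consuming_reactions_vanish_without_substrate(self, params):
        a = ap.propensities(
            ap.CountState(a1cc=50, c9a=20, cc_count=100), params)
        for r in np.nonzero(a)[0]:
            consumed = np.nonzero(STOICHIOMETRY[r] < 0)[0]
            for s in consumed:
                assert getattr(ap.CountState(a1cc=50, c9a=20, cc_count=100),
                               SPECIES[s]) > 0

    @pytest.mark.parametrize("vc", [1e3, 1e5])
    def test_propensities_match_deterministic_fluxes(self, params, vc):
        """a_j / V_c equals the deterministic flux at counts/V_c exactly
        (the thermodynamic-limit consistency is by construction)."""
        p = params.replace(V_c=vc, CC=0.2)
        counts = ap.CountState(a1cc=int(0.05 * vc), c9p=int(8 * vc),
                               c9a=int(0.5 * vc), c3p=int(9 * vc),
                               CEA=int(0.3 * vc), cc_count=int(0.2 * vc))
        a = ap.propensities(counts, p) / vc
        d = ap.derivatives(counts.as_array() / vc, p)
        # reconstruct derivatives from propensities via stoichiometry
        assert np.allclose(STOICHIOMETRY.T @ a, d, rtol=1e-12, atol=1e-14)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ap.CountState(c9p=-1)


class TestConversion:
    def test_known_values(self, params):
        st = ap.StateVector(CEA=0.96)
        assert ap.to_counts(st, params).CEA == 960
        assert ap.to_counts(ap.StateVector(), params).CEA == 0
        back = ap.to_concentration(ap.CountState(CEA=55, cc_count=0), params)
        assert back.CEA == pytest.approx(0.055)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=100.0,
                     allow_nan=False, allow_infinity=False))
    def test_round_trip_error_bounded(self, cea):
        p = ap.ModelParameters()
        counts = ap.to_counts(ap.StateVector(CEA=cea), p)
        back = ap.to_concentration(counts, p)
        assert abs(back.CEA - cea) <= 0.5 / p.V_c + 1e-12
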