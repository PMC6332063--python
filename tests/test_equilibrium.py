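"""Speciation, fast-exchange shift and ITC heat forward models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from chpi.equilibrium import (
    ITCExperiment,
    ITCModelParams,
    TitrationPoint,
    predict_itc_heats,
    predict_shift,
    solve_1to1,
)

# ---------------------------------------------------------------------------
# independent oracles


def bisection_complex(H0, G0, K):
    """Root of the mass-balance residual f(x) = K (H0-x)(G0-x) - x by brentq."""
    if G0 == 0:
        return 0.0
    f = lambda x: K * (H0 - x) * (G0 - x) - x  # noqa: E731
    hi = min(H0, G0)
    return brentq(f, 0.0, hi, xtol=1e-30, rtol=1e-15)


def cumulative_heat_oracle(exp, params):
    """Heats from explicit mole bookkeeping of complex ever formed.

    Tracks totals through the displacement dilution, accumulates the
    moles of complex formed (in-cell plus expelled share) and
    differences the cumulative heat Q_i = dH * formed_i.
    """
    V0 = exp.cell_volume
    H, G = exp.cell_conc, 0.0
    bound_prev = 0.0
    formed = 0.0
    heats = []
    Q_prev = 0.0
    for v in exp.injection_volumes:
        expelled = bound_prev * v  # moles of pre-formed complex displaced
        H *= 1.0 - v / V0
        G = G * (1.0 - v / V0) + exp.syringe_conc * v / V0
        bound = bisection_complex(params.n * H, G, params.K)
        formed += (bound * V0) - (bound_prev * V0 - expelled)
        Q = params.dH * formed
        heats.append(Q - Q_prev)
        Q_prev = Q
        bound_prev = bound
    return np.array(heats)


# ---------------------------------------------------------------------------
# speciation


def test_no_guest_means_no_complex():
    s = solve_1to1(1.6e-3, 0.0, 5000.0)
    assert s.complex == 0.0
    assert s.free_host == 1.6e-3


def test_equimolar_millimolar_complex_value():
    # frozen from the bisection oracle at H0 = G0 = 1 mM, K = 1000
    s = solve_1to1(1e-3, 1e-3, 1000.0)
    assert s.complex == pytest.approx(3.8197e-4, rel=1e-4)
    assert s.complex == pytest.approx(bisection_complex(1e-3, 1e-3, 1000.0), rel=1e-12)


def test_stoichiometric_limit_at_huge_K():
    s = solve_1to1(1e-3, 2e-3, 1e12)
    assert s.complex == pytest.approx(1e-3, rel=1e-6)


def test_negative_inputs_rejected():
    with pytest.raises(ValueError):
        solve_1to1(-1e-3, 1e-3, 10.0)
    with pytest.raises(ValueError):
        solve_1to1(1e-3, -1e-3, 10.0)
    with pytest.raises(ValueError):
        solve_1to1(1e-3, 1e-3, 0.0)


@given(
    logH=st.floats(-6.0, 0.0),
    logG=st.floats(-6.0, 0.0),
    logK=st.floats(-1.0, 8.0),
)
@settings(max_examples=300, deadline=None)
def test_speciation_mass_balance_and_equilibrium(logH, logG, logK):
    H0, G0, K = 10.0**logH, 10.0**logG, 10.0**logK
    s = solve_1to1(H0, G0, K)
    assert s.free_host + s.complex == pytest.approx(H0, rel=1e-12)
    assert s.free_guest + s.complex == pytest.approx(G0, rel=1e-12)
    # equilibrium residual relative to the dominant scale
    resid = abs(K * s.free_host * s.free_guest - s.complex)
    assert resid <= 1e-10 * max(K * H0 * G0, s.complex)


@given(
    logH=st.floats(-5.0, -1.0),
    logG=st.floats(-5.0, -1.0),
    logK=st.floats(0.0, 7.0),
)
@settings(max_examples=200, deadline=None)
def test_quadratic_solver_matches_bisection(logH, logG, logK):
    H0, G0, K = 10.0**logH, 10.0**logG, 10.0**logK
    assert solve_1to1(H0, G0, K).complex == pytest.approx(
        bisection_complex(H0, G0, K), rel=1e-9, abs=1e-18
    )


# ---------------------------------------------------------------------------
# NMR shifts


def test_shift_is_free_limit_without_guest():
    p = TitrationPoint(1.6e-3, 0.0)
    assert predict_shift(p, 5150.0, 8.0, 10.0, "host") == 8.0


def test_shift_reaches_bound_limit_at_saturation():
    p = TitrationPoint(1.6e-3, 1.0)  # ~600 equivalents
    assert predict_shift(p, 5150.0, 8.0, 10.0, "host") == pytest.approx(10.0, abs=1e-2)


def test_shift_composes_with_speciation():
    p = TitrationPoint(1.6e-3, 3.2e-3)
    hg = bisection_complex(p.H0, p.G0, 5150.0)
    expected = 8.0 + 2.0 * hg / p.H0
    assert predict_shift(p, 5150.0, 8.0, 10.0, "host") == pytest.approx(
        expected, rel=1e-10
    )


def test_guest_signal_undefined_without_guest():
    with pytest.raises(ValueError, match="guest"):
        predict_shift(TitrationPoint(1e-3, 0.0), 100.0, 3.1, 2.6, "guest")


def test_shift_monotone_in_guest_concentration():
    K, H0 = 5150.0, 1.6e-3
    shifts = [
        predict_shift(TitrationPoint(H0, eq * H0), K, 8.0, 10.0, "host")
        for eq in np.linspace(0, 12, 30)
    ]
    assert np.all(np.diff(shifts) > 0)


# ---------------------------------------------------------------------------
# ITC heats


def make_exp(cell=2e-4, syringe=1.4e-3, V0=1.4e-3, n_inj=25, v=3e-6):
    return ITCExperiment(
        cell_conc=cell,
        syringe_conc=syringe,
        cell_volume=V0,
        injection_volumes=np.full(n_inj, v),
    )


def test_zero_enthalpy_means_zero_heat():
    q = predict_itc_heats(make_exp(), ITCModelParams(n=1.0, K=1e5, dH=0.0))
    assert np.all(q == 0.0)


def test_stoichiometric_heats_before_equivalence():
    exp = make_exp()
    q = predict_itc_heats(exp, ITCModelParams(n=1.0, K=1e12, dH=-5.0))
    per_injection = -5.0 * exp.syringe_conc * 3e-6  # dH * moles injected
    assert np.allclose(q, per_injection, rtol=1e-3)


def test_heats_match_cumulative_oracle():
    exp = make_exp()
    params = ITCModelParams(n=1.0, K=1.41e5, dH=-5.0)
    assert np.allclose(
        predict_itc_heats(exp, params), cumulative_heat_oracle(exp, params),
        rtol=1e-8, atol=1e-18,
    )


def test_heats_match_oracle_with_nonunit_stoichiometry():
    exp = make_exp(syringe=4e-3, n_inj=40, v=1e-5)
    params = ITCModelParams(n=1.7, K=2e4, dH=3.0)
    assert np.allclose(
        predict_itc_heats(exp, params), cumulative_heat_oracle(exp, params),
        rtol=1e-8, atol=1e-18,
    )


def test_heat_sign_follows_enthalpy():
    exp = make_exp()
    q_exo = predict_itc_heats(exp, ITCModelParams(n=1.0, K=1e5, dH=-5.0))
    q_endo = predict_itc_heats(exp, ITCModelParams(n=1.0, K=1e5, dH=5.0))
    assert np.allclose(q_exo, -q_endo)
    assert np.all(q_exo < 0)


def test_saturating_run_recovers_total_binding_enthalpy():
    # a steep, fast-saturating titration (equivalence within ~4 injections,
    # so little unbound host is displaced): total heat ~ n * dH * host moles
    exp = make_exp(cell=2e-4, syringe=4e-2, n_inj=25, v=2e-6)
    params = ITCModelParams(n=1.0, K=1e9, dH=-5.0)
    total = predict_itc_heats(exp, params).sum()
    expected = params.n * params.dH * exp.cell_conc * exp.cell_volume
    assert total == pytest.approx(expected, rel=0.01)


def test_isotherm_sharpens_with_c_parameter():
    # higher c (= n K [cell]) concentrates the heat drop near equivalence
    exp = make_exp(cell=2e-4, syringe=4e-3, n_inj=40, v=5e-6)
    q_low = predict_itc_heats(exp, ITCModelParams(n=1.0, K=5e3, dH=-5.0))
    q_high = predict_itc_heats(exp, ITCModelParams(n=1.0, K=5e6, dH=-5.0))
    drop = lambda q: np.max(-np.diff(q)) / -q[0]  # noqa: E731
    assert drop(q_high) > drop(q_low)


def test_invalid_experiment_rejected():
    with pytest.raises(ValueError):
        ITCExperiment(2e-4, 1.4e-3, 0.0, np.full(5, 3e-6))
    with pytest.raises(ValueError):
        ITCExperiment(2e-4, 1.4e-3, 1.4e-3, np.array([3e-6, -1e-6]))
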