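"""Markov I_Kr chain: conservation, stationary distribution, mutant
gain-of-function and drug-bound-state behaviour."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sqtpharm.ikr_markov import (HergBindingParams, MarkovIKrState,
                                 N588K_RATES, WT_RATES, heterozygote_current,
                                 ikr_current, ikr_markov_rhs,
                                 ikr_steady_state, transition_matrix)


def test_derivatives_conserve_probability():
    rng = np.random.default_rng(7)
    binding = HergBindingParams(k_A=0.01, l_A=0.005, k_I=0.002, l_I=0.004)
    for _ in range(200):
        s = rng.dirichlet(np.ones(7))
        V = rng.uniform(-120, 80)
        D = rng.uniform(0, 30)
        for rates in (WT_RATES, N588K_RATES):
            ds = ikr_markov_rhs(s, V, rates, binding, D)
            assert abs(ds.sum()) < 1e-14


def test_no_drug_keeps_bound_states_empty():
    s = np.array([0.2, 0.2, 0.2, 0.2, 0.2, 0.0, 0.0])
    ds = ikr_markov_rhs(s, 0.0, WT_RATES, HergBindingParams(), 0.0)
    assert ds[5] == 0.0 and ds[6] == 0.0


@pytest.mark.parametrize("V,D", [(-20.0, 2.0), (20.0, 0.0), (-80.0, 10.0)])
def test_integrated_steady_state_matches_nullspace_oracle(V, D):
    """Long ODE integration converges to the generator's null space."""
    binding = HergBindingParams(k_A=0.023, l_A=0.02)
    s0 = np.zeros(7)
    s0[0] = 1.0
    sol = solve_ivp(lambda t, s: ikr_markov_rhs(s, V, WT_RATES, binding, D),
                    (0.0, 60000.0), s0, method="LSODA",
                    rtol=1e-10, atol=1e-12)
    target = ikr_steady_state(V, WT_RATES, binding, D)
    assert np.max(np.abs(sol.y[:, -1] - target)) < 1e-6


def test_current_arithmetic_and_reversal():
    s = MarkovIKrState(C1=0.5, O=0.5)
    assert ikr_current(s, -88.0, 1.0, -88.0) == 0.0  # V == E_Kr
    assert ikr_current(MarkovIKrState(C1=1.0), 40.0, 1.0, -88.0) == 0.0
    assert ikr_current(s, -78.0, 1.0, -88.0) == pytest.approx(5.0)


def test_heterozygote_mixing():
    V, gkr, ekr = -30.0, 0.3, -88.0
    s_wt = ikr_steady_state(V, WT_RATES)
    s_mut = ikr_steady_state(V, N588K_RATES)
    i_wt = ikr_current(s_wt, V, gkr, ekr)
    i_mut = ikr_current(s_mut, V, gkr, ekr)
    het = heterozygote_current(s_wt, s_mut, V, gkr, ekr)
    assert het == pytest.approx(0.5 * (i_wt + i_mut))
    # degenerate mixing weights reproduce the pure populations
    assert heterozygote_current(s_wt, s_mut, V, gkr, ekr, w_mut=0.0) == \
        pytest.approx(i_wt)
    assert heterozygote_current(s_wt, s_mut, V, gkr, ekr, w_mut=1.0) == \
        pytest.approx(i_mut)
    # same rates in both populations collapse to the pure-WT current
    assert heterozygote_current(s_wt, s_wt, V, gkr, ekr) == pytest.approx(i_wt)
    with pytest.raises(ValueError):
        heterozygote_current(s_wt, s_mut, V, gkr, ekr, w_mut=1.5)


def test_n588k_gain_of_function_at_plus20():
    o_wt = ikr_steady_state(20.0, WT_RATES)[3]
    o_mut = ikr_steady_state(20.0, N588K_RATES)[3]
    assert o_mut > 3.0 * o_wt


def test_bound_fraction_monotone_in_concentration():
    binding = HergBindingParams(k_A=0.023, l_A=0.02)
    bound = [ikr_steady_state(0.0, WT_RATES, binding, D)[5:].sum()
             for D in (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0)]
    assert bound[0] == pytest.approx(0.0, abs=1e-12)
    assert np.all(np.diff(bound) > 0)


def test_generator_columns_sum_to_zero():
    A = transition_matrix(-10.0, N588K_RATES,
                          HergBindingParams(k_A=0.01, l_A=0.01), 3.0)
    assert np.max(np.abs(A.sum(axis=0))) < 1e-15
    with pytest.raises(ValueError):
        transition_matrix(0.0, WT_RATES, D=-1.0)
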