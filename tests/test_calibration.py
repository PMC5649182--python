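"""Clamp-protocol simulation, Hill fitting and bounded Nelder-Mead."""

import numpy as np
import pytest

from sqtpharm.calibration import (fit_binding_rates, fit_herg_binding,
                                  hill_block, ic50_from_curve,
                                  na_tonic_block, simulate_fractional_block)
from sqtpharm.drug_engine import DRUGS, NaBindingParams
from sqtpharm.ikr_markov import HergBindingParams
from sqtpharm.synthetic_data import SyntheticBlockSpec, gen_block_dataset


def test_hill_fit_recovers_exact_curve():
    D = np.geomspace(0.5, 50, 8)
    fit = ic50_from_curve(D, hill_block(D, 5.0, 1.0))
    assert fit.ok
    assert fit.ic50 == pytest.approx(5.0, abs=1e-6)
    assert fit.n_h == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError):
        ic50_from_curve([1.0, 2.0], [0.1, 0.2])
    flat = ic50_from_curve(D, np.full(8, 0.01))
    assert not flat.ok


def test_fractional_block_limits_and_monotonicity():
    binding = DRUGS["quinidine"].herg_binding["WT"]
    assert simulate_fractional_block("WT", binding, 0.0) == 0.0
    assert simulate_fractional_block("WT", binding, 62.0) > 0.95
    doses = np.geomspace(0.05, 20.0, 8)
    blocks = [simulate_fractional_block("WT", binding, d) for d in doses]
    assert np.all(np.diff(blocks) > 0)


def test_herg_fit_noise_free_objective_vanishes():
    truth = DRUGS["disopyramide"].herg_binding["WT"]
    ds = gen_block_dataset(SyntheticBlockSpec(
        kind="herg_dose_response", drug="disopyramide", true_params=truth,
        concentrations=(2.0, 5.0, 10.0, 20.0, 50.0), condition="WT",
        sigma=0.0))
    res = fit_herg_binding(ds, "WT", seed=0, n_starts=5)
    assert res.objective < 1e-8
    # the generating rates are recovered, not just the curve
    assert 10.0 ** res.params[0] == pytest.approx(truth.k_A, rel=0.01)
    assert 10.0 ** res.params[1] == pytest.approx(truth.l_A, rel=0.01)


def test_na_tonic_round_trip_recovers_ic50():
    """Noisy tonic dataset -> refit -> equilibrium IC50 within 5%."""
    truth = DRUGS["quinidine"].na_binding
    ds = gen_block_dataset(SyntheticBlockSpec(
        kind="na_tonic", drug="quinidine", true_params=truth,
        concentrations=(1.0, 3.0, 8.0, 17.0, 40.0, 100.0, 300.0),
        sigma=0.02, seed=11))
    from sqtpharm.calibration import fit_na_binding
    res = fit_na_binding(ds, seed=1, n_starts=3)
    refit = NaBindingParams(**{k: res.meta[k] for k in
                               ("k_A", "l_A", "k_I", "l_I", "k_R", "l_R")})
    doses = np.geomspace(1, 300, 10)
    fit = ic50_from_curve(doses, [na_tonic_block(refit, d) for d in doses])
    assert fit.ok
    assert fit.ic50 == pytest.approx(17.0, rel=0.05)


def test_nelder_mead_bounds_and_determinism():
    f = lambda x: float((x[0] - 0.3) ** 2 + (x[1] + 0.2) ** 2)
    r1 = fit_binding_rates(f, [(-1, 1), (-1, 1)], np.array([0.0, 0.0]),
                           seed=42)
    r2 = fit_binding_rates(f, [(-1, 1), (-1, 1)], np.array([0.0, 0.0]),
                           seed=42)
    assert np.array_equal(r1.params, r2.params)
    assert r1.objective < 1e-10
    assert np.allclose(r1.params, [0.3, -0.2], atol=1e-4)
    with pytest.raises(ValueError):
        fit_binding_rates(f, [(-1, 1), (-np.inf, 1)], np.array([0.0, 0.0]))
    with pytest.raises(ValueError):
        fit_binding_rates(f, [(-1, 1), (-1, 1)], np.array([2.0, 0.0]))
    # a hopeless budget reports non-convergence instead of raising
    r3 = fit_binding_rates(lambda x: float(np.sum(x ** 2)) + 1.0,
                           [(-5, 5)] * 4, np.full(4, 4.0), seed=0,
                           n_starts=1, maxiter=3)
    assert not r3.converged


def test_drug_free_reference_required():
    dead = HergBindingParams()
    with pytest.raises(ValueError):
        # a protocol that never opens the channel has no reference current
        from sqtpharm.calibration import ClampProtocol
        simulate_fractional_block(
            "WT", dead, 1.0,
            ClampProtocol(segments=((-120.0, 50.0),), n_pulses=1,
                          measure_segment=0))
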