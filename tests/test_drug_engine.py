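"""Guarded-receptor sodium block, Hill pore block and the drug registry."""

import numpy as np
import pytest

from sqtpharm.calibration import (NA_USE_DEPENDENCE_PROTOCOL, ClampProtocol,
                                  na_tonic_block, na_use_dependence)
from sqtpharm.drug_engine import (DRUGS, GuardedNaState, NaBindingParams,
                                  PoreBlockEntry, get_drug, guarded_na_rhs,
                                  ina_current, na_resting_block,
                                  pore_block_scale)


def test_pore_block_limits():
    entry = PoreBlockEntry("ICaL", ic50=14.9)
    assert pore_block_scale(2.0, 0.0, entry) == 2.0
    # quinidine on I_CaL at D = IC50 = 14.9 uM halves the conductance
    assert pore_block_scale(1.0, 14.9, entry) == pytest.approx(0.5)
    doses = np.linspace(0, 100, 30)
    g = [pore_block_scale(1.0, d, entry) for d in doses]
    assert np.all(np.diff(g) < 0)
    with pytest.raises(ValueError):
        PoreBlockEntry("ICaL", ic50=-1.0)
    with pytest.raises(ValueError):
        pore_block_scale(1.0, -2.0, entry)


def test_guarded_rhs_zero_drug_is_pure_unbinding():
    p = NaBindingParams(k_A=0.1, l_A=0.002, k_I=0.01, l_I=0.003,
                        k_R=0.001, l_R=0.004)
    b = GuardedNaState(0.2, 0.1, 0.05)
    db = guarded_na_rhs(b, 0.9, 0.5, 0.5, 0.0, p)
    assert np.allclose(db, [-0.002 * 0.2, -0.003 * 0.1, -0.004 * 0.05])


def test_resting_block_closed_form_matches_integration():
    """Frozen hyperpolarized gates: b_R -> k_R D/(k_R D + l_R), b_A=b_I~0."""
    p = NaBindingParams(k_A=0.1, l_A=0.002, k_I=1e-4, l_I=0.002,
                        k_R=2.78e-5, l_R=0.001)
    D = 36.0
    m, h, j = 0.0, 1.0, 1.0  # deep hyperpolarization
    b = np.zeros(3)
    dt = 1.0
    for _ in range(200000):
        b = b + dt * guarded_na_rhs(b, m, h, j, D, p)
    assert b[2] == pytest.approx(na_resting_block(D, p), abs=1e-6)
    assert b[0] == pytest.approx(0.0, abs=1e-9)
    assert na_resting_block(36.0, p) == pytest.approx(0.5, rel=1e-3)


def test_unblocked_fraction_stays_physical():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = NaBindingParams(*rng.uniform(0, 0.2, 6))
        b = np.zeros(3)
        for k in range(5000):
            m, h, j = rng.uniform(0, 1, 3)
            b = b + 0.05 * guarded_na_rhs(b, m, h, j, 10.0, p)
            total = b.sum()
            assert -1e-9 <= total <= 1.0 + 1e-9
            assert np.all(b >= -1e-9)


def test_ina_current_limits():
    assert ina_current(0.9, 0.8, 0.9, (0.3, 0.3, 0.4), -20.0, 23.0, 60.0) == 0.0
    free = ina_current(0.9, 0.8, 0.9, (0.0, 0.0, 0.0), -20.0, 23.0, 60.0)
    assert free == pytest.approx(23.0 * 0.9 ** 3 * 0.8 * 0.9 * (-80.0))


def test_use_dependence_accumulates_to_plateau():
    p = DRUGS["disopyramide"].na_binding
    series = na_use_dependence(p, 10.0)
    assert series.shape == (30,)
    assert np.all(np.diff(series) > -1e-6)           # non-decreasing
    assert series[-1] - series[-2] < 0.25 * (series[1] - series[0])  # plateau
    # faster pacing develops at least as much block
    slow = ClampProtocol(segments=((-100.0, 950.0), (-20.0, 50.0)),
                         n_pulses=30, measure_segment=1)
    b_2hz = na_use_dependence(p, 10.0, NA_USE_DEPENDENCE_PROTOCOL)[-1]
    b_1hz = na_use_dependence(p, 10.0, slow)[-1]
    assert b_2hz >= b_1hz


def test_tonic_block_monotone_and_half_at_ic50():
    p = DRUGS["quinidine"].na_binding
    doses = np.geomspace(0.5, 500, 12)
    blocks = [na_tonic_block(p, d) for d in doses]
    assert np.all(np.diff(blocks) > 0)
    assert na_tonic_block(p, 17.0) == pytest.approx(0.5, abs=0.01)


def test_registry_and_action_masks():
    with pytest.raises(KeyError):
        get_drug("amiodarone")
    quin = get_drug("quinidine").at(5.0, "ikr")
    assert quin.na_params().k_A == 0.0          # Na block masked off
    assert quin.herg_params("WT").k_A > 0
    assert quin.pore_scale("ICaL") == 1.0       # pore block masked off
    ina_only = get_drug("quinidine").at(5.0, "ina")
    assert ina_only.herg_params("N588K").k_A == 0.0
    assert ina_only.na_params().k_A > 0
    # disopyramide has no I_K1 / I_NaL action at all
    diso = get_drug("disopyramide").at(10.0)
    assert diso.pore_scale("IK1") == 1.0
    assert diso.pore_scale("INaL") == 1.0
    assert diso.pore_scale("Ito") < 1.0
    with pytest.raises(ValueError):
        get_drug("quinidine").at(-1.0)
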