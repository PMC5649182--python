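"""Tissue solver, pseudo-ECG, tissue biomarkers and re-entry machinery."""

import numpy as np
import pytest

from sqtpharm.cell_model import (CellParams, StimulusSpec, initial_state,
                                 integrate_cell, pack_params)
from sqtpharm.synthetic_data import gen_fixture_waveform
from sqtpharm.tissue import (PECGTrace, StrandConfig, TissueGrid,
                             cfl_limit, compute_pecg_1d, dominant_frequency,
                             init_reentry_phase_distribution, measure_qt,
                             reentry_lifespan, reference_cycle,
                             run_sheet_reentry, solve_monodomain,
                             spiral_phase_map, wavelength)


def test_wavelength_product():
    # printed-table arithmetic: CV x ERP in mm
    assert wavelength(60.2, 235.0) == pytest.approx(141.4, abs=0.2)
    assert wavelength(40.3, 481.0) == pytest.approx(194.0, abs=0.2)
    assert wavelength(0.0, 300.0) == 0.0


def test_pecg_uniform_field_is_zero():
    cfg = StrandConfig()
    t = np.arange(0.0, 10.0, 0.5)
    V = np.full((t.size, cfg.n), -85.0)
    V += np.linspace(0, 30, t.size)[:, None]  # uniform in space at all t
    pecg = compute_pecg_1d(t, V, cfg)
    assert np.max(np.abs(pecg.phi)) < 1e-12


def test_pecg_step_profile_matches_hand_sum():
    """Two-compartment static V step vs an independent discrete sum."""
    cfg = StrandConfig()
    t = np.array([0.0, 1.0])
    V = np.where(np.arange(cfg.n) < 50, -80.0, 20.0)[None, :].repeat(2, 0)
    pecg = compute_pecg_1d(t, V, cfg)
    # independent evaluation of sum_i dV/dx * (x_i - xe)/|x_i - xe|^3 * dx
    x = (np.arange(cfg.n) + 0.5) * cfg.dx
    xe = cfg.length + cfg.electrode_offset
    dvdx = np.gradient(V[0], x)
    expected = np.sum(dvdx * (x - xe) / np.abs(x - xe) ** 3 * cfg.dx)
    assert pecg.phi[0] == pytest.approx(expected, rel=1e-12)
    with pytest.raises(ValueError):
        compute_pecg_1d(t, V, StrandConfig(electrode_offset=-7.5))


def test_qt_tangent_on_analytic_qrst():
    t, phi, truth = gen_fixture_waveform("qrst_pecg")
    qt = measure_qt(PECGTrace(t=t, phi=phi), stim_start=5.0)
    assert qt == pytest.approx(truth["qt"], abs=2 * (t[1] - t[0]))
    # polarity-inverted T wave is handled the same way
    qt_inv = measure_qt(PECGTrace(t=t, phi=-phi), stim_start=5.0)
    assert qt_inv == pytest.approx(truth["qt"], abs=2 * (t[1] - t[0]))


def test_dominant_frequency_on_known_signals():
    t = np.arange(0.0, 4000.0, 1.0)
    five = np.sin(2e-3 * np.pi * 5.0 * t) + 0.3
    assert dominant_frequency(PECGTrace(t=t, phi=five)) == pytest.approx(
        5.0, abs=0.05)
    mix = np.sin(2e-3 * np.pi * 4.0 * t) + 0.3 * np.sin(2e-3 * np.pi * 7.0 * t)
    assert dominant_frequency(PECGTrace(t=t, phi=mix)) == pytest.approx(
        4.0, abs=0.05)
    tam, yam, truth = gen_fixture_waveform("am_sine")
    assert dominant_frequency(PECGTrace(t=tam, phi=yam)) == pytest.approx(
        truth["dominant_hz"], abs=0.05)
    flat = PECGTrace(t=t, phi=np.zeros_like(t))
    assert dominant_frequency(flat) is None
    with pytest.raises(ValueError):
        dominant_frequency(PECGTrace(t=t[:1000], phi=five[:1000]))


def test_reentry_lifespan_constructed():
    t = np.arange(0.0, 3000.0, 1.0)
    v = np.full((t.size, 2), -80.0)
    # site 0 fires at 200 and 1195 ms, quiescent afterwards
    for start in (200, 1195):
        v[start:start + 50, 0] = 10.0
    assert reentry_lifespan(t, v) == pytest.approx(1.2, abs=0.01)
    assert reentry_lifespan(t, np.full((t.size, 1), -80.0)) == 0.0


def test_phase_distribution_initiation():
    par = CellParams("ENDO", "SQT1")
    ref = reference_cycle(par, None, n_prebeats=3)
    const = init_reentry_phase_distribution(ref, np.zeros(16))
    assert np.all(const == const[0])  # constant phase -> uniform state
    pm = spiral_phase_map(4, 4)
    a = init_reentry_phase_distribution(ref, pm)
    b = init_reentry_phase_distribution(ref, pm)
    np.testing.assert_array_equal(a, b)  # deterministic
    with pytest.raises(ValueError):
        init_reentry_phase_distribution(ref, np.array([0.0, 1.0]))


def test_cfl_guard_refuses_unstable_step():
    cfg = StrandConfig()
    Y = np.tile(initial_state(), (cfg.n, 1))
    P = np.vstack([pack_params(CellParams(ct, "WT"))
                   for ct in cfg.cell_types()])
    bad_dt = 1.1 * cfl_limit(cfg.dx, cfg.diffusion)
    with pytest.raises(ValueError):
        solve_monodomain(Y, P, cfg.interface_diffusion(), cfg.dx, bad_dt, 10)


def test_single_cell_limit_reproduces_cell_model():
    """A one-node 'cable' integrates exactly like the isolated cell."""
    par = CellParams("ENDO", "WT")
    stim = StimulusSpec()
    y0 = initial_state()
    tr = integrate_cell(y0.copy(), par, stim, t_end=400.0, record_dt=0.5,
                        record_currents=False)
    Y = y0.copy().reshape(1, -1)
    P = pack_params(par).reshape(1, -1)
    t, V = solve_monodomain(Y, P, np.zeros(0), 0.15, 0.005,
                            int(400.0 / 0.005), stim=stim,
                            stim_mask=np.array([True]), rec_stride=100)
    assert np.max(np.abs(V[:, 0] - tr.V)) < 1e-9


def test_unstimulated_uniform_tissue_stays_uniform():
    cfg = StrandConfig(n_endo=20, n_mcell=0, n_epi=0, length=3.0)
    Y = np.tile(initial_state(), (20, 1))
    P = np.vstack([pack_params(CellParams("ENDO", "WT"))] * 20)
    t, V = solve_monodomain(Y, P, np.full(19, cfg.diffusion), cfg.dx,
                            0.005, 40000, rec_stride=2000)
    assert np.max(np.ptp(V, axis=1)) < 1e-9


def test_spiral_forms_on_small_sheet():
    """Phase-distribution initiation yields self-sustained re-excitation."""
    grid = TissueGrid(ny=40, nx=40, dx=0.5, diffusion=0.023,
                      condition="SQT1")
    pecg, (t, probes), _ = run_sheet_reentry(grid, duration=700.0, dt=0.01,
                                             n_prebeats=20)
    # at least one probe is re-excited after the initial wave has passed,
    # with no stimulus ever applied
    reactivated = 0
    for k in range(probes.shape[1]):
        v = probes[:, k]
        ups = np.flatnonzero((v[:-1] < -30) & (v[1:] >= -30))
        if ups.size and t[ups[-1]] > 400.0:
            reactivated += 1
    assert reactivated >= 1
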