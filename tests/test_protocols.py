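"""Biomarker extraction on analytic waveforms and protocol drivers."""

import numpy as np
import pytest

from sqtpharm.cell_model import CellParams, Trace
from sqtpharm.drug_engine import get_drug
from sqtpharm.protocols import (apd_restitution, concentration_sweep,
                                detect_ead, ead_assay, measure_apd90,
                                measure_muv)
from sqtpharm.synthetic_data import gen_fixture_waveform


def test_apd90_and_muv_on_trapezoid():
    t, v, truth = gen_fixture_waveform("trapezoid_ap")
    tr = Trace(t=t, V=v)
    assert measure_apd90(tr) == pytest.approx(truth["apd90"], abs=2 * tr.dt)
    assert measure_muv(tr) == pytest.approx(truth["muv"], rel=0.05)


def test_extraction_is_pure():
    t, v, _ = gen_fixture_waveform("trapezoid_ap")
    tr = Trace(t=t, V=v)
    assert measure_apd90(tr) == measure_apd90(tr)
    assert measure_muv(tr) == measure_muv(tr)


def test_unmeasurable_flags():
    t = np.arange(0.0, 100.0, 0.5)
    flat = Trace(t=t, V=np.full_like(t, -85.0))
    assert measure_apd90(flat) is None
    assert measure_muv(flat) is None
    # upstroke without repolarization inside the window
    t2, v2, _ = gen_fixture_waveform("trapezoid_ap",
                                     dict(plateau=400.0, t_end=300.0))
    assert measure_apd90(Trace(t=t2, V=v2)) is None


def test_ead_detection_on_constructed_bump():
    t, v, _ = gen_fixture_waveform("trapezoid_ap",
                                   dict(plateau=250.0, fall=80.0))
    tr = Trace(t=t, V=v.copy())
    assert not detect_ead(tr)
    # inject a sharp 12 mV hump midway through the repolarization ramp,
    # steep enough to produce a genuine net voltage rise
    vb = v.copy()
    vb += 20.0 * np.exp(-0.5 * ((t - 300.0) / 4.0) ** 2)
    assert detect_ead(Trace(t=t, V=vb))
    # a shallow hump that never reverses dV/dt is ignored
    vs = v.copy()
    vs += 1.5 * np.exp(-0.5 * ((t - 300.0) / 15.0) ** 2)
    assert not detect_ead(Trace(t=t, V=vs))


def test_concentration_sweep_baseline_only():
    df = concentration_sweep(get_drug("quinidine"), [], n_prebeats=2)
    assert len(df) == 1 and df.iloc[0].drug == "none"
    with pytest.raises(ValueError):
        concentration_sweep(get_drug("quinidine"), [5.0, 1.0], n_prebeats=2)


def test_restitution_validates_cycle_lengths():
    with pytest.raises(ValueError):
        apd_restitution(None, 0.0, [250.0])


def test_ead_assay_baseline_wt_clean():
    grid = ead_assay("WT", None, 0.0,
                     modifiers={"IKr": (1.0,), "IKs": (1.0,),
                                "ICaL": (1.0,)},
                     n_prebeats=16)
    assert len(grid) == 1
    assert not grid.ead.any()
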