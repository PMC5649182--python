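"""Single-cell experiment drivers and biomarker extraction.

Biomarkers follow standard cardiac-electrophysiology definitions: APD90 is
measured from the instant of maximum upstroke velocity (MUV) to the crossing
of 90% repolarization (V_peak - 0.9*(V_peak - V_rest), V_rest taken as the
pre-stimulus diastolic potential), with linear interpolation between
samples.  All extraction functions are pure: the same trace always yields
the same numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .cell_model import (CellParams, StimulusSpec, Trace, initial_state,
                         pack_params, voltage_table)
from .drug_engine import DrugSpec

__all__ = [
    "CellBiomarkers",
    "measure_apd90",
    "measure_muv",
    "detect_ead",
    "pace_cells",
    "paced_biomarkers",
    "concentration_sweep",
    "apd_restitution",
    "ead_assay",
]


@dataclass
class CellBiomarkers:
    """Summary biomarkers of one paced beat."""

    apd90: float | None
    muv: float | None
    v_rest: float
    v_peak: float
    ead: bool = False


def _upstroke_index(t, V):
    """Index of maximum dV/dt restricted to the rising phase above -60 mV."""
    dV = np.gradient(V, t)
    rising = (dV > 0) & (V > -60.0)
    if not rising.any():
        return None
    cand = np.flatnonzero(rising)
    return cand[np.argmax(dV[cand])]


def measure_apd90(trace: Trace, beat_window=None) -> float | None:
    """APD90 in ms, or None when no 90% repolarization is captured."""
    t, V = _windowed(trace, beat_window)
    iu = _upstroke_index(t, V)
    if iu is None:
        return None
    v_rest = V[0]
    v_peak = V.max()
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    ipk = int(np.argmax(V))
    below = np.flatnonzero(V[ipk:] < v90)
    if below.size == 0:
        return None
    ic = ipk + below[0]
    # linear interpolation of the crossing instant
    t_cross = t[ic - 1] + (t[ic] - t[ic - 1]) * (V[ic - 1] - v90) / (
        V[ic - 1] - V[ic])
    return float(t_cross - t[iu])


def measure_muv(trace: Trace, beat_window=None) -> float | None:
    """Maximum upstroke velocity (mV/ms) on the rising phase above -60 mV."""
    t, V = _windowed(trace, beat_window)
    iu = _upstroke_index(t, V)
    if iu is None:
        return None
    dV = np.gradient(V, t)
    return float(dV[iu])


def detect_ead(trace: Trace, beat_window=None, min_amp: float = 1.0) -> bool:
    """True when a positive voltage excursion >= ``min_amp`` mV occurs during
    repolarization (after the AP peak, before 90% repolarization)."""
    t, V = _windowed(trace, beat_window)
    iu = _upstroke_index(t, V)
    if iu is None:
        return False
    v_rest = V[0]
    ipk = int(np.argmax(V))
    v_peak = V[ipk]
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    below = np.flatnonzero(V[ipk:] < v90)
    iend = ipk + below[0] if below.size else len(V) - 1
    # plateau onset: the phase-2 dome peak (skip the spike-notch-dome
    # morphology of high-Ito cells, which is not an afterdepolarization)
    dome_from = np.searchsorted(t, t[iu] + 30.0)
    if dome_from >= iend:
        dome_from = ipk
    i0 = dome_from + int(np.argmax(V[dome_from:iend + 1]))
    seg = V[i0:iend + 1]
    if seg.size < 3:
        return False
    # largest rise from any running minimum during the repolarization phase
    running_min = np.minimum.accumulate(seg)
    return bool(np.max(seg - running_min) >= min_amp)


def _windowed(trace: Trace, beat_window):
    if beat_window is None:
        return trace.t, trace.V
    lo, hi = beat_window
    m = (trace.t >= lo) & (trace.t <= hi)
    return trace.t[m], trace.V[m]


def biomarkers_from_trace(trace: Trace, beat_window=None) -> CellBiomarkers:
    t, V = _windowed(trace, beat_window)
    return CellBiomarkers(
        apd90=measure_apd90(trace, beat_window),
        muv=measure_muv(trace, beat_window),
        v_rest=float(V[0]),
        v_peak=float(V.max()),
        ead=detect_ead(trace, beat_window),
    )


# ---------------------------------------------------------------------------
# paced drivers (vectorized over independent cells for efficiency)
# ---------------------------------------------------------------------------

def pace_cells(P: np.ndarray, stim: StimulusSpec, n_prebeats: int = 100,
               n_record_beats: int = 1, dt: float = 0.005,
               record_dt: float = 0.1, y0=None):
    """Pace uncoupled cells (rows of P) and record the final beat(s).

    Returns (t, V) with V of shape (nt, n_cells); states are updated in
    place when ``y0`` is supplied.
    """
    n = P.shape[0]
    if y0 is None:
        y0 = np.tile(initial_state(), (n, 1))
    tab, vmin, inv_dv = voltage_table(dt)
    mask = np.ones(n, dtype=np.bool_)
    nomask = np.zeros(n, dtype=np.bool_)
    empty = np.zeros((0, n, 6))
    if n_prebeats > 0:
        nst = int(round(n_prebeats * stim.period / dt))
        out = np.zeros((1, n))
        K.advance(y0, P, tab, vmin, inv_dv, dt, nst, 0.0,
                  mask, stim.amplitude, stim.duration, stim.period,
                  stim.start, nomask, 0.0, 0.0, 0.0,
                  np.zeros(1), 0.0, False, nst, out, empty, False)
    t_end = n_record_beats * stim.period
    nst = int(round(t_end / dt))
    stride = max(1, int(round(record_dt / dt)))
    nrec = nst // stride
    out_V = np.zeros((nrec, n))
    K.advance(y0, P, tab, vmin, inv_dv, dt, nst, 0.0,
              mask, stim.amplitude, stim.duration, stim.period, stim.start,
              nomask, 0.0, 0.0, 0.0,
              np.zeros(1), 0.0, False, stride, out_V, empty, False)
    t = (np.arange(nrec) + 1) * stride * dt
    return t, out_V


def paced_biomarkers(params: CellParams, drug: DrugSpec | None = None,
                     rate_hz: float = 1.0, n_prebeats: int = 100,
                     dt: float = 0.005) -> CellBiomarkers:
    """Steady-state biomarkers of one cell at a pacing rate (Hz)."""
    stim = StimulusSpec(period=1000.0 / rate_hz)
    P = pack_params(params, drug).reshape(1, -1)
    t, V = pace_cells(P, stim, n_prebeats=n_prebeats, dt=dt)
    return biomarkers_from_trace(Trace(t=t, V=V[:, 0]))


def concentration_sweep(drug: DrugSpec, concentrations,
                        condition: str = "SQT1", rate_hz: float = 1.0,
                        cell_type: str = "ENDO", n_prebeats: int = 100,
                        dt: float = 0.005, actions="all") -> pd.DataFrame:
    """Steady-state biomarkers vs drug concentration (baseline row included).

    All concentrations are integrated simultaneously as independent cells.
    """
    concentrations = list(concentrations)
    if any(np.diff(concentrations) < 0):
        raise ValueError("concentrations must be sorted ascending")
    params = CellParams(cell_type, condition)
    rows = [0.0] + concentrations
    P = np.vstack([
        pack_params(params, drug.at(c, actions) if c > 0 else None)
        for c in rows
    ])
    stim = StimulusSpec(period=1000.0 / rate_hz)
    t, V = pace_cells(P, stim, n_prebeats=n_prebeats, dt=dt)
    recs = []
    for i, c in enumerate(rows):
        bm = biomarkers_from_trace(Trace(t=t, V=V[:, i]))
        recs.append(dict(drug=drug.name if c > 0 else "none",
                         concentration_uM=c, apd90=bm.apd90, muv=bm.muv,
                         v_rest=bm.v_rest, v_peak=bm.v_peak, ead=bm.ead))
    return pd.DataFrame(recs)


def apd_restitution(drug: DrugSpec | None, concentration: float,
                    cycle_lengths, condition: str = "SQT1",
                    cell_type: str = "ENDO", n_prebeats: int = 50,
                    dt: float = 0.005) -> pd.DataFrame:
    """Steady-state (dynamic) APD restitution: APD90 at each cycle length.

    Cycle lengths below 300 ms are rejected; beats lost to 2:1 block are
    flagged and omitted (apd90 = NaN).
    """
    cls = list(cycle_lengths)
    if any(cl < 300 for cl in cls):
        raise ValueError("cycle lengths must be >= 300 ms")
    params = CellParams(cell_type, condition)
    d = drug.at(concentration) if drug is not None and concentration > 0 else None
    P = pack_params(params, d).reshape(1, -1)
    recs = []
    for cl in cls:
        stim = StimulusSpec(period=float(cl))
        t, V = pace_cells(P, stim, n_prebeats=n_prebeats, dt=dt)
        tr = Trace(t=t, V=V[:, 0])
        apd = measure_apd90(tr)
        captured = apd is not None and V[:, 0].max() > 0
        recs.append(dict(cl=cl, apd90=apd if captured else np.nan,
                         captured=captured))
    return pd.DataFrame(recs)


DEFAULT_EAD_GRID = {
    "IKr": (0.5, 1.0),
    "IKs": (0.25, 0.5, 1.0),
    "ICaL": (1.0, 1.5, 2.0),
}


def ead_assay(condition: str, drug: DrugSpec | None, concentration: float,
              modifiers: dict | None = None, rate_hz: float = 0.5,
              cell_type: str = "MCELL", n_prebeats: int = 30,
              dt: float = 0.005) -> pd.DataFrame:
    """EAD susceptibility grid in slowly paced mid-myocardial cells.

    ``modifiers`` maps current names to tuples of multiplicative scalings of
    repolarization-reserve currents / I_CaL agonism; every combination is
    simulated and flagged for early afterdepolarizations.
    """
    grid = DEFAULT_EAD_GRID if modifiers is None else modifiers
    keys = sorted(grid)
    combos = [()]
    for k in keys:
        combos = [c + (v,) for c in combos for v in grid[k]]
    d = drug.at(concentration) if drug is not None and concentration > 0 else None
    from .cell_model import DEFAULT_SCALES
    P = np.vstack([
        pack_params(CellParams(cell_type, condition,
                               scales={k: DEFAULT_SCALES[k] * v
                                       for k, v in zip(keys, combo)}), d)
        for combo in combos
    ])
    stim = StimulusSpec(period=1000.0 / rate_hz)
    t, V = pace_cells(P, stim, n_prebeats=n_prebeats, dt=dt)
    recs = []
    for i, combo in enumerate(combos):
        tr = Trace(t=t, V=V[:, i])
        rec = dict(zip(keys, combo))
        rec["ead"] = detect_ead(tr)
        recs.append(rec)
    return pd.DataFrame(recs)
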