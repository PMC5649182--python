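"""Human ventricular myocyte model (O'Hara-Rudy lineage).

The action-potential model is the ORd human ventricular myocyte with two
substitutions: the fast sodium current uses the Luo-Rudy m^3*h*j
formulation (which supports robust propagation in tissue), and I_Kr is the
two-population Markov chain of :mod:`sqtpharm.ikr_markov` (WT / N588K
kinetics with drug-bound states).  ENDO, MCELL and EPI variants follow the
ORd transmural parameter sets, except that the transmural I_Kr conductance
ratio is ENDO:MCELL:EPI = 1.0 : 1.0 : 1.6.

A per-current conductance-scaling hook (``scale``) is exposed for every
major current; the shipped default profile is calibrated so that the
drug-free 1D transmural strand yields QT ~ 350 ms (WT) and ~ 241 ms (SQT1
heterozygote) at 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .drug_engine import DrugSpec
from .ikr_markov import WT_RATES, N588K_RATES, ikr_steady_state

__all__ = [
    "CellParams",
    "CellState",
    "StimulusSpec",
    "Trace",
    "CELL_TYPES",
    "CONDITIONS",
    "DEFAULT_SCALES",
    "pack_params",
    "initial_state",
    "cell_rhs",
    "integrate_cell",
    "prepace",
]

CELL_TYPES = ("ENDO", "MCELL", "EPI")
# mutant-population weight of the Markov I_Kr mix
CONDITIONS = {"WT": 0.0, "SQT1": 0.5, "N588K": 1.0}

# Baseline ORd maximal conductances (ENDO) in model-native units.
BASE = {
    "INa": 23.0,       # mS/uF, Luo-Rudy
    "INaL": 0.0075,
    "Ito": 0.02,
    "ICaL": 0.0001,    # PCa
    "IKr": 0.046,
    "IKs": 0.0034,
    "IK1": 0.1908,
    "INaCa": 0.0008,
    "INaK": 30.0,
    "IKb": 0.003,
}

# ORd transmural multipliers; the I_Kr row implements the 1.0:1.0:1.6
# ENDO:MCELL:EPI conductance ratio used throughout this package.
REGIONAL = {
    "ENDO": {},
    "EPI": {"INaL": 0.6, "Ito": 4.0, "ICaL": 1.2, "IKr": 1.6, "IKs": 0.7,
            "IK1": 1.2, "INaCa": 1.1, "INaK": 0.9, "IKb": 0.6},
    "MCELL": {"INaL": 5.5, "Ito": 4.0, "ICaL": 2.6, "IKr": 1.0, "IKs": 1.6,
              "IK1": 0.9, "INaCa": 1.4, "INaK": 0.5},
}

# Calibrated default conductance-scaling profile (dimensionless multipliers
# applied on top of the ORd baseline); see docs/methods.md for how these
# were fixed against the drug-free QT / APD90 anchors.
DEFAULT_SCALES = {
    "INa": 1.0,
    "INaL": 1.0,
    "Ito": 1.0,
    "ICaL": 1.0,
    "IKr": 5.1,
    "IKs": 2.0,
    "IK1": 1.0,
    "INaCa": 1.0,
    "INaK": 1.0,
    "IKb": 1.0,
}


@dataclass(frozen=True)
class StimulusSpec:
    """Periodic square-pulse stimulus.

    ``amplitude`` follows the membrane-current sign convention: a
    depolarizing stimulus is a negative (inward) current in uA/uF.
    """

    amplitude: float = -80.0
    duration: float = 0.5
    period: float = 1000.0
    start: float = 10.0

    def __post_init__(self):
        if self.period > 0 and not self.duration < self.period:
            raise ValueError("stimulus duration must be shorter than period")


@dataclass(frozen=True)
class CellParams:
    """One myocyte's parameter set (cell type, scalings, drug context)."""

    cell_type: str = "ENDO"
    condition: str = "WT"
    scales: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {sorted(CONDITIONS)}")
        for k, v in self.scales.items():
            if k not in BASE:
                raise ValueError(f"unknown current {k!r} in scales")
            if v < 0:
                raise ValueError("conductance multipliers must be >= 0")


class CellState:
    """Thin wrapper over the packed state vector (see _kernels for layout)."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        if y.shape != (K.NS,):
            raise ValueError(f"state vector must have length {K.NS}")
        self.y = y

    @property
    def V(self) -> float:
        return float(self.y[K.iV])

    @property
    def gates_mhj(self):
        return tuple(self.y[K.iM:K.iJ + 1])

    @property
    def markov_wt(self) -> np.ndarray:
        return self.y[K.iMK1:K.iMK1 + 7].copy()

    @property
    def markov_mut(self) -> np.ndarray:
        return self.y[K.iMK2:K.iMK2 + 7].copy()

    @property
    def na_block(self) -> np.ndarray:
        return self.y[K.iBA:K.iBR + 1].copy()

    def validate(self) -> None:
        if not np.isfinite(self.y).all():
            bad = int(np.flatnonzero(~np.isfinite(self.y))[0])
            raise ValueError(f"non-finite state variable at index {bad}")
        for sl in (slice(K.iM, K.iISP + 1), slice(K.iDG, K.iFCAFP + 1),
                   slice(K.iXS1, K.iXK1 + 1)):
            g = self.y[sl]
            if np.any(g < -1e-9) or np.any(g > 1 + 1e-9):
                raise ValueError("gate out of [0, 1]")
        if np.any(self.y[K.iNAI:K.iCAJSR + 1] <= 0):
            raise ValueError("non-positive ionic concentration")


@dataclass
class Trace:
    """Uniformly sampled simulation output."""

    t: np.ndarray
    V: np.ndarray
    currents: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __post_init__(self):
        dts = np.diff(self.t)
        if dts.size and (np.any(dts <= 0)
                         or np.ptp(dts) > 1e-6 * abs(dts[0])):
            raise ValueError("trace time base must be strictly increasing "
                             "and uniform")


def pack_params(params: CellParams, drug: DrugSpec | None = None) -> np.ndarray:
    """Pack a CellParams (+ optional drug) into the kernel parameter vector."""
    p = np.zeros(K.NP)
    scales = {**DEFAULT_SCALES, **params.scales}
    reg = REGIONAL[params.cell_type]

    def g(cur):
        s = BASE[cur] * reg.get(cur, 1.0) * scales[cur]
        if drug is not None:
            target = {"ICaL": "ICaL", "Ito": "Ito", "IKs": "IKs",
                      "IK1": "IK1", "INaL": "INaL"}.get(cur)
            if target is not None:
                s *= drug.pore_scale(target)
        return s

    p[K.pGNA] = g("INa")
    p[K.pGNAL] = g("INaL")
    p[K.pGTO] = g("Ito")
    p[K.pPCA] = g("ICaL")
    p[K.pGKR] = g("IKr")
    p[K.pGKS] = g("IKs")
    p[K.pGK1] = g("IK1") * np.sqrt(K.KO)
    p[K.pGNCX] = g("INaCa")
    p[K.pPNAK] = g("INaK")
    p[K.pGKB] = g("IKb")
    p[K.pJRELSC] = 1.7 if params.cell_type == "MCELL" else 1.0
    p[K.pJUPSC] = 1.3 if params.cell_type == "MCELL" else 1.0
    p[K.pCMDNSC] = 1.3 if params.cell_type == "EPI" else 1.0
    p[K.pEPI] = 1.0 if params.cell_type == "EPI" else 0.0
    p[K.pWMUT] = CONDITIONS[params.condition]

    if drug is not None and drug.concentration > 0:
        p[K.pDRUG] = drug.concentration
        hb_wt = drug.herg_params("WT")
        hb_mut = drug.herg_params("N588K")
        p[K.pKA1], p[K.pLA1] = hb_wt.k_A, hb_wt.l_A
        p[K.pKI1], p[K.pLI1] = hb_wt.k_I, hb_wt.l_I
        p[K.pKA2], p[K.pLA2] = hb_mut.k_A, hb_mut.l_A
        p[K.pKI2], p[K.pLI2] = hb_mut.k_I, hb_mut.l_I
        nb = drug.na_params()
        p[K.pKAN], p[K.pLAN] = nb.k_A, nb.l_A
        p[K.pKIN], p[K.pLIN] = nb.k_I, nb.l_I
        p[K.pKRN], p[K.pLRN] = nb.k_R, nb.l_R
    else:
        # unbinding rates stay positive so zero-drug block pools decay
        p[K.pLA1] = p[K.pLI1] = p[K.pLA2] = p[K.pLI2] = 1.0
        p[K.pLAN] = p[K.pLIN] = p[K.pLRN] = 1.0
    return p


_TABLE_CACHE: dict = {}


def voltage_table(dt: float):
    """Cached voltage lookup table for the default WT/N588K kinetics."""
    key = round(dt, 9)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = K.build_voltage_table(dt, WT_RATES, N588K_RATES)
    return _TABLE_CACHE[key]


def initial_state(V0: float = -87.5) -> np.ndarray:
    """A resting-ish initial state (gates at steady state for V0).

    Pre-pace before measuring anything; this is only a starting point.
    """
    tab, vmin, inv_dv = voltage_table(0.005)
    Vgrid_idx = (V0 - vmin) * inv_dv
    i0 = int(Vgrid_idx)
    fr = Vgrid_idx - i0

    def lk(c):
        return tab[i0, c] + (tab[i0 + 1, c] - tab[i0, c]) * fr

    y = np.zeros(K.NS)
    y[K.iV] = V0
    y[K.iNAI] = 7.268
    y[K.iNASS] = 7.268
    y[K.iKI] = 144.65
    y[K.iKSS] = 144.65
    y[K.iCAI] = 8.6e-5
    y[K.iCASS] = 8.49e-5
    y[K.iCANSR] = 1.61
    y[K.iCAJSR] = 1.56
    for idx, c in ((K.iM, K.cMSS), (K.iH, K.cHSS), (K.iJ, K.cJSS),
                   (K.iML, K.cMLSS), (K.iHL, K.cHLSS), (K.iHLP, K.cHLPSS),
                   (K.iA, K.cASS), (K.iAP, K.cAPSS), (K.iDG, K.cDSS),
                   (K.iXS1, K.cXS1SS), (K.iXK1, K.cXK1SS)):
        y[idx] = lk(c)
    for idx in (K.iIF, K.iIS, K.iIFP, K.iISP):
        y[idx] = lk(K.cIFSS)
    for idx in (K.iFF, K.iFS, K.iFCAF, K.iFCAS, K.iJCA, K.iFFP, K.iFCAFP):
        y[idx] = lk(K.cFSS)
    y[K.iXS2] = lk(K.cXS1SS)
    y[K.iNCA] = 0.00275
    y[K.iCAMKT] = 0.0111
    y[K.iMK1:K.iMK1 + 7] = ikr_steady_state(V0, WT_RATES)
    y[K.iMK2:K.iMK2 + 7] = ikr_steady_state(V0, N588K_RATES)
    return y


def cell_rhs(state, params: CellParams, drug: DrugSpec | None = None,
             t: float = 0.0, istim: float = 0.0) -> np.ndarray:
    """Time derivative of every state variable (1/ms units).

    Computed as the small-step limit of one integrator step, which
    coincides with the analytic right-hand side for all state variables.
    """
    y = state.y if isinstance(state, CellState) else np.asarray(state, float)
    p = pack_params(params, drug)
    eps = 1e-7
    tab, vmin, inv_dv = voltage_table(eps)
    y1 = y.copy()
    cur = np.zeros(6)
    K._cell_update(y1, p, tab, vmin, inv_dv, eps, istim, 0.0, cur)
    dy = (y1 - y) / eps
    if not np.isfinite(dy).all():
        bad = int(np.flatnonzero(~np.isfinite(dy))[0])
        raise ArithmeticError(f"non-finite derivative for state index {bad}")
    return dy


def _run(y, p, stim: StimulusSpec, t_end, dt, t0=0.0, record_dt=1.0,
         record_currents=False):
    tab, vmin, inv_dv = voltage_table(dt)
    nsteps = int(round(t_end / dt))
    rec_stride = max(1, int(round(record_dt / dt)))
    nrec = nsteps // rec_stride
    out_V = np.zeros((nrec, 1))
    out_cur = np.zeros((nrec, 1, 6)) if record_currents else np.zeros((0, 1, 6))
    Y = y.reshape(1, -1)
    P = p.reshape(1, -1)
    mask = np.ones(1, dtype=np.bool_)
    nomask = np.zeros(1, dtype=np.bool_)
    K.advance(Y, P, tab, vmin, inv_dv, dt, nsteps, t0,
              mask, stim.amplitude, stim.duration, stim.period, stim.start,
              nomask, 0.0, 0.0, 0.0,
              np.zeros(1), 0.0, False,
              rec_stride, out_V, out_cur, record_currents)
    t = t0 + (np.arange(nrec) + 1) * rec_stride * dt
    return t, out_V[:, 0], out_cur


def integrate_cell(state0, params: CellParams, stimulus: StimulusSpec,
                   drug: DrugSpec | None = None, t_end: float = 1000.0,
                   dt: float = 0.005, record_dt: float = 0.1,
                   record_currents: bool = True) -> Trace:
    """Integrate one myocyte and return a uniformly sampled Trace.

    The returned trace includes V plus I_Kr, I_Na, I_CaL, I_Ks, the total
    fractional Na-channel block and the hERG drug-bound fraction.
    Deterministic for fixed inputs.  Raises on numerical instability.
    """
    if dt > 0.02:
        raise ValueError("dt must be <= 0.02 ms (explicit-Euler stability)")
    y = (state0.y if isinstance(state0, CellState) else
         np.asarray(state0, float)).copy()
    p = pack_params(params, drug)
    t, V, cur = _run(y, p, stimulus, t_end, dt, record_dt=record_dt,
                     record_currents=record_currents)
    if np.max(np.abs(V)) > 200 or not np.isfinite(V).all():
        raise ArithmeticError(
            "membrane potential diverged (|V| > 200 mV); reduce dt or check "
            "parameters")
    currents = {}
    if record_currents:
        currents = {"IKr": cur[:, 0, 0], "INa": cur[:, 0, 1],
                    "ICaL": cur[:, 0, 2], "IKs": cur[:, 0, 3],
                    "block_na": cur[:, 0, 4], "block_kr": cur[:, 0, 5]}
    state0_out = CellState(y)
    tr = Trace(t=t, V=V, currents=currents)
    tr.final_state = state0_out  # type: ignore[attr-defined]
    return tr


def prepace(params: CellParams, stimulus: StimulusSpec,
            drug: DrugSpec | None = None, n_beats: int = 100,
            dt: float = 0.005, y0: np.ndarray | None = None) -> np.ndarray:
    """Pace a cell for ``n_beats`` and return the end-diastolic state vector.

    100 beats is the package default pre-pacing protocol before any
    biomarker is measured.
    """
    y = initial_state() if y0 is None else np.asarray(y0, float).copy()
    p = pack_params(params, drug)
    _run(y, p, stimulus, n_beats * stimulus.period, dt,
         record_dt=stimulus.period, record_currents=False)
    return y
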