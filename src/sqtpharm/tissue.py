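"""Monodomain tissue models: transmural 1D strand and 2D sheet re-entry.

The 1D strand is the standard transmural human-ventricle preparation:
25 endocardial, 35 mid-myocardial and 40 epicardial cells over 15 mm,
isotropic diffusion except for a five-fold reduction at the MCELL-EPI
border, paced from the endocardial end.  A far-field unipolar pseudo-ECG is
computed at a virtual electrode 2 cm beyond the epicardial end,

    Phi = integral of (-grad V) . grad(1/r) dOmega,

and the QT interval is read from it with the T-wave tangent method (end of
T = intersection of the steepest descending-limb tangent with baseline).

Re-entry is studied on a reduced, isotropic 2D sheet: initial conditions
are built with the phase-distribution method (each node's full state taken
from one reference AP cycle at a node-specific phase), which develops into
a rotating spiral/multi-wavelet pattern; the dominant frequency is the
largest power-spectral-density peak of the pseudo-ECG.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from . import _kernels as K
from .cell_model import (CellParams, StimulusSpec, Trace, initial_state,
                         pack_params, voltage_table)
from .drug_engine import DrugSpec
from .protocols import pace_cells

__all__ = [
    "StrandConfig",
    "TissueGrid",
    "PECGTrace",
    "TissueBiomarkers",
    "StrandResult",
    "solve_monodomain",
    "run_strand",
    "compute_pecg_1d",
    "measure_qt",
    "measure_erp",
    "measure_cv",
    "measure_tdr",
    "wavelength",
    "reference_cycle",
    "spiral_phase_map",
    "init_reentry_phase_distribution",
    "run_sheet_reentry",
    "dominant_frequency",
    "reentry_lifespan",
    "strand_biomarkers",
]

# Diffusion coefficient (mm^2/ms) calibrated so the drug-free strand
# conducts at ~60 cm/s (see docs/methods.md).
DEFAULT_DIFFUSION = 0.0924


@dataclass(frozen=True)
class StrandConfig:
    """Transmural 1D strand layout."""

    n_endo: int = 25
    n_mcell: int = 35
    n_epi: int = 40
    length: float = 15.0          # mm
    diffusion: float = DEFAULT_DIFFUSION  # mm^2/ms
    border_factor: float = 5.0    # D reduction at the MCELL-EPI interface
    electrode_offset: float = 20.0  # mm beyond the epicardial end
    n_stim: int = 5               # endocardial nodes receiving the stimulus
    stim_amplitude: float = -100.0  # uA/uF
    stim_duration: float = 1.0      # ms
    condition: str = "WT"
    scales: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.n_endo + self.n_mcell + self.n_epi

    @property
    def dx(self) -> float:
        return self.length / self.n

    def cell_types(self):
        return (["ENDO"] * self.n_endo + ["MCELL"] * self.n_mcell
                + ["EPI"] * self.n_epi)

    def interface_diffusion(self) -> np.ndarray:
        dif = np.full(self.n - 1, self.diffusion)
        border = self.n_endo + self.n_mcell - 1  # MCELL/EPI junction
        dif[border] = self.diffusion / self.border_factor
        return dif


@dataclass(frozen=True)
class TissueGrid:
    """Isotropic 2D sheet (single transmural cell type)."""

    ny: int = 50
    nx: int = 50
    dx: float = 0.6               # mm
    diffusion: float = DEFAULT_DIFFUSION
    cell_type: str = "ENDO"
    condition: str = "SQT1"
    scales: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.ny * self.nx


@dataclass
class PECGTrace:
    t: np.ndarray
    phi: np.ndarray
    electrode: tuple = ()


@dataclass
class TissueBiomarkers:
    qt: float | None = None
    erp: float | None = None
    cv: float | None = None
    wl: float | None = None
    tdr: float | None = None
    df: float | None = None
    lifespan: float | None = None


@dataclass
class StrandResult:
    t: np.ndarray
    V: np.ndarray                # (nt, n)
    pecg: PECGTrace
    config: StrandConfig
    stim: StimulusSpec
    Y_final: np.ndarray
    Y_prebeat: np.ndarray        # snapshot just before the last S1
    P: np.ndarray


def _strand_P(config: StrandConfig, drug: DrugSpec | None) -> np.ndarray:
    return np.vstack([
        pack_params(CellParams(ct, config.condition, scales=config.scales),
                    drug)
        for ct in config.cell_types()
    ])


def cfl_limit(dx: float, diffusion: float, ndim: int = 1) -> float:
    return dx * dx / (2.0 * ndim * diffusion)


def solve_monodomain(Y, P, dif, dx, dt, nsteps, t0=0.0,
                     stim: StimulusSpec | None = None, stim_mask=None,
                     s2=None, s2_mask=None,
                     rec_stride: int = 100, ndim: int = 1):
    """Advance a coupled 1D cable; returns recorded V (nt, n).

    Refuses to run when dt violates the explicit-Euler CFL bound
    dt <= dx^2 / (2 * ndim * Dmax).
    """
    dif = np.asarray(dif, dtype=float)
    if dif.size:
        lim = cfl_limit(dx, float(np.max(dif)), ndim)
        if dt > lim:
            raise ValueError(
                f"dt={dt} violates CFL stability; use dt <= {lim:.4g} ms")
    n = Y.shape[0]
    tab, vmin, inv_dv = voltage_table(dt)
    if stim is None:
        stim = StimulusSpec(amplitude=0.0, period=0.0, start=0.0)
    if stim_mask is None:
        stim_mask = np.zeros(n, dtype=np.bool_)
    if s2 is None:
        amp2 = dur2 = start2 = 0.0
        s2_mask = np.zeros(n, dtype=np.bool_)
    else:
        amp2, dur2, start2 = s2
        s2_mask = np.asarray(s2_mask, dtype=np.bool_)
    nrec = nsteps // rec_stride
    out_V = np.zeros((nrec, n))
    empty = np.zeros((0, n, 6))
    K.advance(Y, P, tab, vmin, inv_dv, dt, nsteps, t0,
              np.asarray(stim_mask, dtype=np.bool_),
              stim.amplitude, stim.duration, stim.period, stim.start,
              s2_mask, amp2, dur2, start2,
              np.asarray(dif, dtype=float), 1.0 / (dx * dx), True,
              rec_stride, out_V, empty, False)
    t = t0 + (np.arange(nrec) + 1) * rec_stride * dt
    return t, out_V


_PREPACE_CACHE: dict = {}


def _prepaced_states(config: StrandConfig, drug: DrugSpec | None,
                     stim: StimulusSpec, n_prebeats: int, dt: float):
    """Single-cell pre-paced states per transmural cell type (cached)."""
    dkey = (None if drug is None else
            (drug.name, drug.concentration, tuple(sorted(drug.actions))))
    key = (config.condition, tuple(sorted(config.scales.items())), dkey,
           stim.period, n_prebeats, dt)
    if key not in _PREPACE_CACHE:
        P = np.vstack([
            pack_params(CellParams(ct, config.condition,
                                   scales=config.scales), drug)
            for ct in ("ENDO", "MCELL", "EPI")
        ])
        Y = np.tile(initial_state(), (3, 1))
        pace_cells(P, stim, n_prebeats=n_prebeats, n_record_beats=1,
                   dt=dt, y0=Y)
        _PREPACE_CACHE[key] = Y
    return _PREPACE_CACHE[key]


def run_strand(config: StrandConfig, drug: DrugSpec | None = None,
               rate_hz: float = 1.0, n_beats: int = 4,
               n_prebeats: int = 100, dt: float = 0.005,
               record_dt: float = 0.5) -> StrandResult:
    """Pace the strand to quasi-steady state and record the final beat.

    Cells are first pre-paced in isolation (``n_prebeats`` beats), then the
    coupled strand is paced for ``n_beats`` beats; V and the pseudo-ECG of
    the last beat are returned.
    """
    cl = 1000.0 / rate_hz
    stim = StimulusSpec(amplitude=config.stim_amplitude,
                        duration=config.stim_duration, period=cl)
    types = config.cell_types()
    singles = _prepaced_states(config, drug, StimulusSpec(period=cl),
                               n_prebeats, dt)
    order = {"ENDO": 0, "MCELL": 1, "EPI": 2}
    Y = np.vstack([singles[order[ct]] for ct in types])
    P = _strand_P(config, drug)
    dif = config.interface_diffusion()
    mask = np.zeros(config.n, dtype=np.bool_)
    mask[:config.n_stim] = True
    n_settle = max(0, n_beats - 1)
    if n_settle:
        solve_monodomain(Y, P, dif, config.dx, dt,
                         int(round(n_settle * cl / dt)), 0.0, stim, mask,
                         rec_stride=int(round(cl / dt)))
    Y_prebeat = Y.copy()
    stride = max(1, int(round(record_dt / dt)))
    t, V = solve_monodomain(Y, P, dif, config.dx, dt, int(round(cl / dt)),
                            0.0, stim, mask, rec_stride=stride)
    pecg = compute_pecg_1d(t, V, config)
    return StrandResult(t=t, V=V, pecg=pecg, config=config, stim=stim,
                        Y_final=Y, Y_prebeat=Y_prebeat, P=P)


def compute_pecg_1d(t, V, config: StrandConfig) -> PECGTrace:
    """Axial far-field unipolar potential of the strand."""
    n = V.shape[1]
    x = (np.arange(n) + 0.5) * config.dx
    xe = config.length + config.electrode_offset
    if 0.0 <= xe <= config.length:
        raise ValueError("electrode must lie outside the tissue")
    dVdx = np.gradient(V, x, axis=1)
    w = (x - xe) / np.abs(x - xe) ** 3 * config.dx
    phi = dVdx @ w
    return PECGTrace(t=t, phi=phi, electrode=(xe,))


def measure_qt(pecg: PECGTrace, stim_start: float = 10.0,
               qrs_window: float = 100.0) -> float | None:
    """QT interval (ms) by the tangent method.

    QRS onset: first deflection (2% of peak amplitude) after the stimulus.
    T end: intersection of the steepest descending-limb tangent with the
    pre-stimulus baseline.
    """
    t, phi = pecg.t, pecg.phi
    pre = t < stim_start
    base = phi[pre].mean() if pre.any() else phi[0]
    d = phi - base
    amp = np.max(np.abs(d))
    if amp < 1e-12:
        return None
    after = np.flatnonzero((t >= stim_start) & (np.abs(d) > 0.02 * amp))
    if after.size == 0:
        return None
    t_q = t[after[0]]
    # T wave: largest |deflection| after the QRS window
    m = t >= t_q + qrs_window
    if not m.any():
        return None
    seg = np.flatnonzero(m)
    ipk = seg[np.argmax(np.abs(d[seg]))]
    sgn = np.sign(d[ipk])
    # descending limb: from T peak until the deflection first falls below
    # 5% of the T amplitude (or the end of the trace)
    tail = sgn * d[ipk:]
    stop = np.flatnonzero(tail < 0.05 * tail[0])
    iend = ipk + (stop[0] if stop.size else len(tail) - 1)
    if iend - ipk < 2:
        return None
    dd = np.gradient(d, t)
    limb = slice(ipk, iend + 1)
    rel = np.argmin(sgn * dd[limb])
    istar = ipk + rel
    slope = dd[istar]
    if sgn * slope >= 0:
        return None
    t_end = t[istar] - d[istar] / slope
    return float(t_end - t_q)


def measure_cv(t, V, config: StrandConfig, i1: int = 20, i2: int = 80,
               thresh: float = -30.0) -> float | None:
    """Conduction velocity (cm/s) from activation times at interior sites."""
    t1 = _activation_time(t, V[:, i1], thresh)
    t2 = _activation_time(t, V[:, i2], thresh)
    if t1 is None or t2 is None or t2 <= t1:
        return None
    dist_mm = (i2 - i1) * config.dx
    return float(dist_mm / (t2 - t1) * 100.0)  # mm/ms -> cm/s


def _activation_time(t, v, thresh=-30.0):
    above = v >= thresh
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return None
    i = idx[0]
    return float(t[i] + (t[i + 1] - t[i]) * (thresh - v[i]) / (v[i + 1] - v[i]))


def _repolarization_time(t, v, frac: float = 0.9):
    v_rest = v[0]
    ipk = int(np.argmax(v))
    v90 = v[ipk] - frac * (v[ipk] - v_rest)
    below = np.flatnonzero(v[ipk:] < v90)
    if below.size == 0:
        return None
    i = ipk + below[0]
    return float(t[i - 1] + (t[i] - t[i - 1]) * (v[i - 1] - v90)
                 / (v[i - 1] - v[i]))


def measure_tdr(t, V, skip_edge: int = 2) -> float | None:
    """Maximal transmural dispersion of repolarization (ms)."""
    times = []
    for i in range(skip_edge, V.shape[1] - skip_edge):
        rt = _repolarization_time(t, V[:, i])
        if rt is None:
            return None
        times.append(rt)
    times = np.asarray(times)
    return float(times.max() - times.min())


def wavelength(cv: float, erp: float) -> float:
    """Re-entry wavelength WL = CV x ERP, in mm (CV in cm/s, ERP in ms)."""
    return cv * 10.0 * erp / 1000.0


def measure_erp(result: StrandResult, drug: DrugSpec | None = None,
                ci_lo: float = 120.0, ci_hi: float | None = None,
                resolution: float = 1.0, dt: float = 0.005) -> float | None:
    """Effective refractory period by S1-S2 binary search (1 ms default).

    Starting from the strand state just before a steady S1, an S1 is
    delivered on schedule and a premature endocardial S2 follows at coupling
    interval CI; the ERP is the shortest CI whose S2 propagates to the
    epicardial end.
    """
    config = result.config
    cl = result.stim.period
    if ci_hi is None:
        ci_hi = cl - 20.0
    P = result.P
    dif = config.interface_diffusion()
    mask = np.zeros(config.n, dtype=np.bool_)
    mask[:config.n_stim] = True
    probe = config.n - 3

    def propagates(ci: float) -> bool:
        Y = result.Y_prebeat.copy()
        s2_start = result.stim.start + ci
        t_end = s2_start + 100.0
        stride = max(1, int(round(0.5 / dt)))
        t, V = solve_monodomain(
            Y, P, dif, config.dx, dt, int(round(t_end / dt)), 0.0,
            result.stim, mask,
            s2=(result.stim.amplitude, result.stim.duration, s2_start),
            s2_mask=mask, rec_stride=stride)
        m = t > s2_start + 2.0
        at = _activation_time(t[m], V[m, probe])
        return at is not None

    if not propagates(ci_hi):
        return None
    lo, hi = ci_lo, ci_hi
    if propagates(lo):
        return float(lo)
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if propagates(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def strand_biomarkers(result: StrandResult, erp: float | None = None
                      ) -> TissueBiomarkers:
    qt = measure_qt(result.pecg, stim_start=result.stim.start)
    cv = measure_cv(result.t, result.V, result.config)
    tdr = measure_tdr(result.t, result.V)
    wl = wavelength(cv, erp) if cv is not None and erp is not None else None
    return TissueBiomarkers(qt=qt, erp=erp, cv=cv, wl=wl, tdr=tdr)


# ---------------------------------------------------------------------------
# 2D sheet re-entry
# ---------------------------------------------------------------------------

def reference_cycle(params: CellParams, drug: DrugSpec | None,
                    cl: float = 1000.0, n_prebeats: int = 50,
                    dt: float = 0.005, sample_dt: float = 1.0) -> np.ndarray:
    """Full state trajectory of one steady paced AP cycle, sampled at
    ``sample_dt`` — the reference for phase-distribution initiation."""
    stim = StimulusSpec(period=cl, start=1.0)
    P = pack_params(params, drug).reshape(1, -1)
    Y = initial_state().reshape(1, -1)
    pace_cells(P, stim, n_prebeats=n_prebeats, n_record_beats=1, dt=dt, y0=Y)
    nsamp = int(round(cl / sample_dt))
    out = np.zeros((nsamp, K.NS))
    tab, vmin, inv_dv = voltage_table(dt)
    mask = np.ones(1, dtype=np.bool_)
    nomask = np.zeros(1, dtype=np.bool_)
    empty = np.zeros((0, 1, 6))
    steps = int(round(sample_dt / dt))
    outv = np.zeros((1, 1))
    for i in range(nsamp):
        out[i] = Y[0]
        K.advance(Y, P, tab, vmin, inv_dv, dt, steps, i * sample_dt,
                  mask, stim.amplitude, stim.duration, stim.period,
                  stim.start, nomask, 0.0, 0.0, 0.0,
                  np.zeros(1), 0.0, False, steps, outv, empty, False)
    return out


def spiral_phase_map(ny: int, nx: int, center=None, turns: float = 1.0,
                     rotation: float = 0.0) -> np.ndarray:
    """Archimedean-spiral phase field in [0, 1); flattened row-major."""
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    cy, cx = center
    yy, xx = np.mgrid[0:ny, 0:nx]
    theta = np.arctan2(yy - cy, xx - cx) + rotation
    r = np.hypot(yy - cy, xx - cx)
    rmax = max(np.hypot(cy, cx), 1.0)
    phase = (theta / (2 * np.pi) + turns * r / rmax) % 1.0
    return phase.ravel()


def init_reentry_phase_distribution(ref_cycle: np.ndarray,
                                    phase_map: np.ndarray) -> np.ndarray:
    """Node states sampled from one reference AP cycle at per-node phases."""
    phase_map = np.asarray(phase_map, dtype=float)
    if np.any(phase_map < 0) or np.any(phase_map >= 1):
        raise ValueError("phases must lie in [0, 1)")
    nsamp = ref_cycle.shape[0]
    idx = (phase_map * nsamp).astype(np.int64) % nsamp
    return ref_cycle[idx].copy()


def run_sheet_reentry(grid: TissueGrid, drug: DrugSpec | None = None,
                      duration: float = 2500.0, dt: float = 0.01,
                      cl: float = 1000.0, phase_map: np.ndarray | None = None,
                      n_prebeats: int = 50, record_dt: float = 1.0,
                      electrode_height: float = 30.0,
                      field_every: float | None = None):
    """Initiate re-entry on the sheet by phase distribution and evolve it.

    Returns (pecg: PECGTrace, probes: (t, Vprobes), field or None).
    The virtual electrode sits ``electrode_height`` mm above the sheet
    center.
    """
    lim = cfl_limit(grid.dx, grid.diffusion, ndim=2)
    if dt > lim:
        raise ValueError(f"dt={dt} violates CFL stability; use dt <= {lim:.4g}")
    params = CellParams(grid.cell_type, grid.condition, scales=grid.scales)
    ref = reference_cycle(params, drug, cl=cl, n_prebeats=n_prebeats, dt=0.005)
    if phase_map is None:
        phase_map = spiral_phase_map(grid.ny, grid.nx)
    Y = init_reentry_phase_distribution(ref, phase_map)
    P = np.tile(pack_params(params, drug), (grid.n, 1))

    # lead-field weights for the pseudo-ECG
    yy, xx = np.mgrid[0:grid.ny, 0:grid.nx]
    x = (xx.ravel() + 0.5) * grid.dx
    y = (yy.ravel() + 0.5) * grid.dx
    xe = grid.nx * grid.dx / 2.0
    ye = grid.ny * grid.dx / 2.0
    ze = electrode_height
    r3 = ((x - xe) ** 2 + (y - ye) ** 2 + ze ** 2) ** 1.5
    wx = (x - xe) / r3 * grid.dx
    wy = (y - ye) / r3 * grid.dx

    # 3x3 probe grid for lifespan analysis
    py = np.linspace(grid.ny * 0.2, grid.ny * 0.8, 3).astype(int)
    px = np.linspace(grid.nx * 0.2, grid.nx * 0.8, 3).astype(int)
    probe_idx = np.array([iy * grid.nx + ix for iy in py for ix in px],
                         dtype=np.int64)

    nsteps = int(round(duration / dt))
    stride = max(1, int(round(record_dt / dt)))
    nrec = nsteps // stride
    out_pecg = np.zeros(nrec)
    out_probes = np.zeros((nrec, probe_idx.size))
    if field_every is not None:
        fstride = max(1, int(round(field_every / record_dt)))
        out_field = np.zeros((nrec // fstride + 1, grid.n))
    else:
        fstride = 1
        out_field = np.zeros((0, grid.n))
    tab, vmin, inv_dv = voltage_table(dt)
    K.advance_sheet(Y, P, tab, vmin, inv_dv, dt, nsteps, 0.0,
                    grid.ny, grid.nx, grid.diffusion, 1.0 / grid.dx ** 2,
                    stride, wx, wy, out_pecg, probe_idx, out_probes,
                    fstride, out_field)
    t = (np.arange(nrec) + 1) * stride * dt
    pecg = PECGTrace(t=t, phi=out_pecg, electrode=(xe, ye, ze))
    field = out_field if field_every is not None else None
    return pecg, (t, out_probes), field


def run_ring_reentry(condition: str = "SQT1", drug: DrugSpec | None = None,
                     n_cells: int = 140, dx: float = 0.5,
                     diffusion: float = 0.023, n_waves: int = 2,
                     duration: float = 2400.0, dt: float = 0.01,
                     cl: float = 1000.0, n_prebeats: int = 50,
                     cell_type: str = "ENDO", record_dt: float = 1.0,
                     electrode_height: float = 10.0):
    """Circulating re-entry on a 1D periodic ring (scaled-down analog).

    ``n_waves`` wavefronts are seeded by the phase-distribution method; a
    wave dies when the local wavelength (CV x ERP at the circulating rate)
    exceeds its share of the ring, reproducing the multi-wave -> single-wave
    -> termination sequence of larger re-entrant media at desk scale.
    Returns (pecg, (t, V)).
    """
    params = CellParams(cell_type, condition)
    ref = reference_cycle(params, drug, cl=cl, n_prebeats=n_prebeats,
                          dt=0.005)
    phases = (np.arange(n_cells) * n_waves / n_cells) % 1.0
    Y = init_reentry_phase_distribution(ref, phases)
    P = np.tile(pack_params(params, drug), (n_cells, 1))
    dif = np.full(n_cells, diffusion)
    lim = cfl_limit(dx, diffusion, ndim=1)
    if dt > lim:
        raise ValueError(f"dt={dt} violates CFL stability; use dt <= {lim:.4g}")
    tab, vmin, inv_dv = voltage_table(dt)
    nsteps = int(round(duration / dt))
    stride = max(1, int(round(record_dt / dt)))
    nrec = nsteps // stride
    out_V = np.zeros((nrec, n_cells))
    empty = np.zeros((0, n_cells, 6))
    nomask = np.zeros(n_cells, dtype=np.bool_)
    K.advance(Y, P, tab, vmin, inv_dv, dt, nsteps, 0.0,
              nomask, 0.0, 0.0, 0.0, 0.0,
              nomask, 0.0, 0.0, 0.0,
              dif, 1.0 / (dx * dx), True,
              stride, out_V, empty, False, True)
    t = (np.arange(nrec) + 1) * stride * dt
    # far-field potential: ring embedded on a circle, electrode off-axis
    radius = n_cells * dx / (2.0 * np.pi)
    theta = 2.0 * np.pi * np.arange(n_cells) / n_cells
    x, y = radius * np.cos(theta), radius * np.sin(theta)
    xe, ye, ze = radius + 20.0, 0.0, electrode_height
    r3 = ((x - xe) ** 2 + (y - ye) ** 2 + ze ** 2) ** 1.5
    # (-grad V) . grad(1/r) with the gradient taken along the ring arc
    tx, ty = -np.sin(theta), np.cos(theta)
    w = ((x - xe) * tx + (y - ye) * ty) / r3 * dx
    dVds = (np.roll(out_V, -1, axis=1) - np.roll(out_V, 1, axis=1)) / (2 * dx)
    phi = dVds @ w
    pecg = PECGTrace(t=t, phi=phi, electrode=(xe, ye, ze))
    return pecg, (t, out_V)


def dominant_frequency(pecg: PECGTrace, window=None, fmin: float = 0.5,
                       fmax: float = 20.0) -> float | None:
    """Largest PSD peak (Hz) of the detrended, Hann-tapered pseudo-ECG."""
    t, phi = pecg.t, pecg.phi
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, phi = t[m], phi[m]
    if t[-1] - t[0] < 2000.0:
        raise ValueError("dominant-frequency window must span >= 2 s")
    fs = 1000.0 / (t[1] - t[0])  # Hz
    x = signal.detrend(phi)
    if np.max(np.abs(x)) < 1e-12:
        return None
    nfft = int(2 ** np.ceil(np.log2(len(x) * 8)))
    f, pxx = signal.periodogram(x, fs=fs, window="hann", nfft=nfft)
    band = (f >= fmin) & (f <= fmax)
    if not band.any() or np.max(pxx[band]) <= 0:
        return None
    return float(f[band][np.argmax(pxx[band])])


def reentry_lifespan(t, probes, threshold: float = -30.0) -> float:
    """Last upward threshold crossing at any recording site (seconds)."""
    probes = np.asarray(probes)
    if probes.ndim == 1:
        probes = probes[:, None]
    last = 0.0
    for k in range(probes.shape[1]):
        v = probes[:, k]
        up = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold))
        if up.size:
            last = max(last, float(t[up[-1] + 1]))
    return last / 1000.0
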