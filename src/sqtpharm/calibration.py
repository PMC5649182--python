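"""Fitting drug-receptor parameters to voltage-clamp block data.

Two families of clamp experiments are simulated:

* hERG / I_Kr: a repeated depolarizing-step protocol (hold -80 mV, 2 s step
  to +20 mV, 500 ms tail at -40 mV, 0.25 Hz) on the Markov channel model;
  fractional block is measured on the peak tail-current (peak open-state
  occupancy during the tail segment) relative to the drug-free run.
  Because the clamp potential is piecewise constant, the chain is
  propagated exactly with matrix exponentials.

* sodium channels: equilibrium tonic block of the guarded-receptor model at
  a hyperpolarized holding potential (closed form), and a 30-pulse
  use-dependence protocol (50 ms steps from -100 mV to -20 mV at 2 Hz)
  integrated with the compiled clamp kernel.

Parameter fitting uses a bounded Nelder-Mead simplex (multi-start, seeded)
over log-transformed rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from . import _kernels as K
from .drug_engine import NaBindingParams
from .ikr_markov import (CONDITIONS, HergBindingParams, IKrRateParams,
                         NO_HERG_BINDING, transition_matrix)

__all__ = [
    "ClampProtocol",
    "HERG_TAIL_PROTOCOL",
    "NA_USE_DEPENDENCE_PROTOCOL",
    "HillFit",
    "FitResult",
    "simulate_herg_tail_peak",
    "simulate_fractional_block",
    "herg_dose_response",
    "na_tonic_block",
    "na_tonic_dose_response",
    "na_use_dependence",
    "ic50_from_curve",
    "hill_block",
    "fit_binding_rates",
    "fit_herg_binding",
    "fit_na_binding",
]


@dataclass(frozen=True)
class ClampProtocol:
    """Piecewise-constant voltage-clamp protocol.

    ``segments`` is a tuple of (voltage mV, duration ms); the protocol is
    repeated ``n_pulses`` times and the measurement is taken in segment
    ``measure_segment`` of the final pulse.
    """

    segments: tuple = ((-80.0, 1500.0), (20.0, 2000.0), (-40.0, 500.0))
    n_pulses: int = 10
    measure_segment: int = 2

    def __post_init__(self):
        if any(d <= 0 for _, d in self.segments):
            raise ValueError("segment durations must be positive")
        if not 0 <= self.measure_segment < len(self.segments):
            raise ValueError("measurement window must lie inside a segment")


HERG_TAIL_PROTOCOL = ClampProtocol()
# 30 pulses, 50 ms from -100 to -20 mV at 2 Hz
NA_USE_DEPENDENCE_PROTOCOL = ClampProtocol(
    segments=((-100.0, 450.0), (-20.0, 50.0)), n_pulses=30, measure_segment=1)


def simulate_herg_tail_peak(rates: IKrRateParams,
                            binding: HergBindingParams = NO_HERG_BINDING,
                            D: float = 0.0,
                            protocol: ClampProtocol = HERG_TAIL_PROTOCOL,
                            sample_dt: float = 1.0) -> float:
    """Peak open-state occupancy in the measurement segment (last pulse)."""
    props = [linalg.expm(transition_matrix(V, rates, binding, D) * dur)
             for V, dur in protocol.segments]
    s = np.zeros(7)
    s[0] = 1.0  # start fully closed (deep C1) at holding potential
    peak = 0.0
    for pulse in range(protocol.n_pulses):
        for j, (V, dur) in enumerate(protocol.segments):
            if pulse == protocol.n_pulses - 1 and j == protocol.measure_segment:
                A = transition_matrix(V, rates, binding, D)
                step = linalg.expm(A * sample_dt)
                n = int(round(dur / sample_dt))
                for _ in range(n):
                    s = step @ s
                    if s[3] > peak:
                        peak = s[3]
            else:
                s = props[j] @ s
    return float(peak)


def simulate_fractional_block(condition: str, binding: HergBindingParams,
                              D: float,
                              protocol: ClampProtocol = HERG_TAIL_PROTOCOL,
                              rates: IKrRateParams | None = None) -> float:
    """Fractional tail-current block, 1 - I_drug / I_drug_free."""
    if rates is None:
        rates = CONDITIONS[condition]
    ref = simulate_herg_tail_peak(rates, NO_HERG_BINDING, 0.0, protocol)
    if ref <= 1e-6:
        raise ValueError("drug-free tail current vanishes; block undefined")
    if D == 0:
        return 0.0
    drugged = simulate_herg_tail_peak(rates, binding, D, protocol)
    return float(1.0 - drugged / ref)


def herg_dose_response(condition: str, binding: HergBindingParams,
                       concentrations,
                       protocol: ClampProtocol = HERG_TAIL_PROTOCOL
                       ) -> pd.DataFrame:
    rows = [dict(condition=condition, concentration_uM=float(D),
                 fractional_block=simulate_fractional_block(
                     condition, binding, float(D), protocol))
            for D in concentrations]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sodium channel protocols
# ---------------------------------------------------------------------------

def _lr_gate_ss(V: float):
    x = V + 47.13
    am = 3.2 if abs(x) < 1e-6 else 0.32 * x / (1.0 - np.exp(-0.1 * x))
    bm = 0.08 * np.exp(-V / 11.0)
    if V < -40.0:
        ah = 0.135 * np.exp(-(80.0 + V) / 6.8)
        bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        aj = ((-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        bj = 0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    else:
        ah = aj = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
        bj = 0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    return am / (am + bm), ah / (ah + bh), aj / (aj + bj)


def na_tonic_block(p: NaBindingParams, D: float, v_hold: float = -100.0
                   ) -> float:
    """Equilibrium fractional block at a steady holding potential.

    With gates frozen at their steady state, the guarded-receptor system is
    linear and the equilibrium pools are b_X = r_X / (1 + sum r), with
    r_X = k_X [D] guard_X / l_X.
    """
    m, h, j = _lr_gate_ss(v_hold)
    m3, hj = m ** 3, h * j
    guards = (m3 * hj, 1.0 - hj, (1.0 - m3) * hj)
    ks = (p.k_A, p.k_I, p.k_R)
    ls = (p.l_A, p.l_I, p.l_R)
    r = [k * D * g / l if l > 0 else 0.0 for k, g, l in zip(ks, guards, ls)]
    return float(sum(r) / (1.0 + sum(r)))


def na_tonic_dose_response(p: NaBindingParams, concentrations,
                           v_hold: float = -100.0) -> pd.DataFrame:
    return pd.DataFrame([
        dict(concentration_uM=float(D),
             fractional_block=na_tonic_block(p, float(D), v_hold))
        for D in concentrations
    ])


def na_use_dependence(p: NaBindingParams, D: float,
                      protocol: ClampProtocol = NA_USE_DEPENDENCE_PROTOCOL,
                      dt: float = 0.01) -> np.ndarray:
    """Per-pulse use-dependent block of peak I_Na availability.

    Returns block_n = 1 - peak_n(drug) / peak_n(drug-free) for each pulse of
    the protocol (fractional block relative to the matching drug-free pulse).
    """
    nseg = len(protocol.segments) * protocol.n_pulses
    Vseq = np.empty(nseg)
    steps = np.empty(nseg, dtype=np.int64)
    for i in range(protocol.n_pulses):
        for j, (V, dur) in enumerate(protocol.segments):
            Vseq[i * len(protocol.segments) + j] = V
            steps[i * len(protocol.segments) + j] = int(round(dur / dt))
    peaks_free = np.zeros(nseg)
    K.clamp_na_block(Vseq, steps, dt, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0,
                     peaks_free)
    peaks = np.zeros(nseg)
    K.clamp_na_block(Vseq, steps, dt, D, p.k_A, p.l_A, p.k_I, p.l_I,
                     p.k_R, p.l_R, peaks)
    sel = np.arange(protocol.n_pulses) * len(protocol.segments) \
        + protocol.measure_segment
    ref = peaks_free[sel]
    return 1.0 - peaks[sel] / np.where(ref > 0, ref, 1.0)


# ---------------------------------------------------------------------------
# Hill fits and Nelder-Mead parameter fitting
# ---------------------------------------------------------------------------

def hill_block(D, ic50, n_h=1.0):
    """Fractional block 1 / (1 + (IC50/D)^nH)."""
    D = np.asarray(D, dtype=float)
    out = np.zeros_like(D)
    pos = D > 0
    out[pos] = 1.0 / (1.0 + (ic50 / D[pos]) ** n_h)
    return out


@dataclass
class HillFit:
    ic50: float
    n_h: float
    ok: bool


def ic50_from_curve(concentrations, blocks, fit_nh: bool = True) -> HillFit:
    """Least-squares Hill fit of a dose-response curve.

    Requires >= 4 concentrations spanning the transition; flags failure
    (ok=False) for non-monotone or saturated-flat data rather than raising.
    """
    D = np.asarray(concentrations, dtype=float)
    b = np.asarray(blocks, dtype=float)
    pos = D > 0
    D, b = D[pos], b[pos]
    if D.size < 4:
        raise ValueError("need at least 4 non-zero concentrations")
    # crude sanity: require overall increase across the sweep
    lo = b[np.argsort(D)][:2].mean()
    hi = b[np.argsort(D)][-2:].mean()
    if hi - lo < 0.05 or hi < 0.2:
        return HillFit(np.nan, np.nan, False)
    x0 = D[np.argmin(np.abs(b - 0.5))]
    try:
        if fit_nh:
            popt, _ = optimize.curve_fit(hill_block, D, b, p0=[x0, 1.0],
                                         maxfev=10000)
            ic50, nh = popt
        else:
            popt, _ = optimize.curve_fit(lambda d, i: hill_block(d, i), D, b,
                                         p0=[x0], maxfev=10000)
            ic50, nh = popt[0], 1.0
    except RuntimeError:
        return HillFit(np.nan, np.nan, False)
    ok = np.isfinite(ic50) and ic50 > 0 and nh > 0
    return HillFit(float(ic50), float(nh), bool(ok))


@dataclass
class FitResult:
    params: np.ndarray
    objective: float
    converged: bool
    bounds: tuple
    x0: np.ndarray
    seed: int | None = None
    meta: dict = field(default_factory=dict)


def fit_binding_rates(objective, bounds, x0, seed: int = 0,
                      n_starts: int = 5, xatol: float = 1e-8,
                      fatol: float = 1e-12, maxiter: int = 2000) -> FitResult:
    """Bounded Nelder-Mead simplex with seeded multi-start.

    ``objective`` maps a parameter vector (within ``bounds``) to a sum of
    squared residuals.  The best of ``n_starts`` runs (x0 plus seeded
    perturbations) is returned; deterministic for a fixed seed.
    """
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    x0 = np.asarray(x0, dtype=float)
    if any(not np.isfinite([lo, hi]).all() for lo, hi in bounds):
        raise ValueError("bounds must be finite")
    if any(not lo <= v <= hi for v, (lo, hi) in zip(x0, bounds)):
        raise ValueError("x0 must lie within bounds")
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_starts - 1):
        pert = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        starts.append(0.5 * (x0 + pert))
    best = None
    for s in starts:
        res = optimize.minimize(objective, s, method="Nelder-Mead",
                                bounds=bounds,
                                options=dict(xatol=xatol, fatol=fatol,
                                             maxiter=maxiter))
        if best is None or res.fun < best.fun:
            best = res
    # polish restart from the incumbent (helps on ridge-shaped surfaces)
    res = optimize.minimize(objective, best.x, method="Nelder-Mead",
                            bounds=bounds,
                            options=dict(xatol=xatol, fatol=fatol,
                                         maxiter=maxiter))
    if res.fun < best.fun:
        best = res
    return FitResult(params=np.asarray(best.x), objective=float(best.fun),
                     converged=bool(best.success), bounds=bounds, x0=x0,
                     seed=seed)


def fit_herg_binding(dataset: pd.DataFrame, condition: str,
                     protocol: ClampProtocol = HERG_TAIL_PROTOCOL,
                     seed: int = 0, n_starts: int = 3) -> FitResult:
    """Fit (k, l) of the hERG drug-bound open state to fractional-block data.

    ``dataset`` is tidy (concentration_uM, fractional_block [, pulse_index]);
    dose-response rows (pulse_index absent or NaN) are fitted on the final
    pulse.  Binding is open-state selective (no inactivated-state binding),
    matching the shipped drug models; parameters are searched in log10 space.
    """
    d = dataset[dataset["concentration_uM"] > 0]
    concs = d["concentration_uM"].to_numpy()
    obs = d["fractional_block"].to_numpy()
    rates = CONDITIONS[condition]

    def obj(x):
        k, l = 10.0 ** x
        binding = HergBindingParams(k_A=k, l_A=l)
        pred = np.array([simulate_fractional_block(condition, binding, D,
                                                   protocol, rates)
                         for D in np.unique(concs)])
        lut = dict(zip(np.unique(concs), pred))
        resid = obs - np.array([lut[c] for c in concs])
        return float(resid @ resid)

    res = fit_binding_rates(obj, bounds=((-6.0, 0.0), (-4.0, -0.5)),
                            x0=np.array([-3.0, -2.0]), seed=seed,
                            n_starts=n_starts)
    res.meta["condition"] = condition
    res.meta["k"], res.meta["l"] = (10.0 ** res.params).tolist()
    return res


def fit_na_binding(tonic: pd.DataFrame, use_dep: pd.DataFrame | None = None,
                   seed: int = 0, n_starts: int = 3) -> FitResult:
    """Fit guarded-receptor rates to tonic (and optional use-dependence) data.

    Tonic block constrains k_R/l_R; the 30-pulse series constrains the
    activated/inactivated-state kinetics.  Fitted in log10 space with the
    unbinding rates shared across A/I pools.
    """
    tc = tonic["concentration_uM"].to_numpy()
    tb = tonic["fractional_block"].to_numpy()
    if use_dep is not None:
        ud = use_dep.dropna(subset=["pulse_index"])
        ud_c = ud["concentration_uM"].to_numpy()
        ud_i = ud["pulse_index"].to_numpy().astype(int)
        ud_b = ud["fractional_block"].to_numpy()

    def obj(x):
        kA, lA, kI, kR, lR = 10.0 ** x
        p = NaBindingParams(k_A=kA, l_A=lA, k_I=kI, l_I=lA, k_R=kR, l_R=lR)
        resid = tb - np.array([na_tonic_block(p, D) for D in tc])
        ssr = float(resid @ resid)
        if use_dep is not None:
            for D in np.unique(ud_c):
                series = na_use_dependence(p, D)
                sel = ud_c == D
                r = ud_b[sel] - series[ud_i[sel] - 1]
                ssr += float(r @ r)
        return ssr

    res = fit_binding_rates(
        obj,
        bounds=((-3.0, 0.5), (-4.5, -2.0), (-7.0, -2.0), (-7.0, -2.0),
                (-4.5, -2.0)),
        x0=np.array([-1.0, -3.0, -4.5, -4.5, -3.0]),
        seed=seed, n_starts=n_starts)
    kA, lA, kI, kR, lR = (10.0 ** res.params).tolist()
    res.meta.update(dict(k_A=kA, l_A=lA, k_I=kI, l_I=lA, k_R=kR, l_R=lR))
    return res
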