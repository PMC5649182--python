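"""Synthetic voltage-clamp datasets and analytic fixture waveforms.

The voltage-clamp block datasets emulate the structure of the published
whole-cell measurements the drug models are calibrated against (fractional
hERG tail-current block vs concentration per WT/N588K condition, Na-channel
tonic block, and 30-pulse use-dependent block), with additive Gaussian
noise on the fractional block.  The fixture waveforms (trapezoidal action
potential, two-Gaussian QRS+T pseudo-ECG, amplitude-modulated sine) carry
closed-form ground-truth biomarkers for unit-testing the extraction code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (ClampProtocol, HERG_TAIL_PROTOCOL,
                          NA_USE_DEPENDENCE_PROTOCOL, herg_dose_response,
                          na_tonic_block, na_use_dependence)
from .drug_engine import NaBindingParams
from .ikr_markov import HergBindingParams

__all__ = [
    "SyntheticBlockSpec",
    "gen_block_dataset",
    "gen_fixture_waveform",
]


@dataclass
class SyntheticBlockSpec:
    """Recipe for one synthetic fractional-block dataset.

    ``kind`` is one of "herg_dose_response", "na_tonic", "na_use_dependence";
    ``true_params`` holds the generating binding parameters
    (HergBindingParams or NaBindingParams).  Noise is additive Gaussian on
    the fractional block (sigma default 0.02), clipped to [0, 1]; the
    clipping rate is reported on the returned frame's attrs.
    """

    kind: str
    drug: str
    true_params: object
    concentrations: tuple = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
    condition: str = "WT"
    protocol: ClampProtocol | None = None
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        kinds = ("herg_dose_response", "na_tonic", "na_use_dependence")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")


def gen_block_dataset(spec: SyntheticBlockSpec) -> pd.DataFrame:
    """Deterministic (seeded) tidy dataset:
    (condition, drug, concentration_uM, pulse_index, fractional_block).

    A drug-free row (concentration 0) is always included.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    if spec.kind == "herg_dose_response":
        protocol = spec.protocol or HERG_TAIL_PROTOCOL
        df = herg_dose_response(spec.condition, spec.true_params,
                                spec.concentrations, protocol)
        for _, r in df.iterrows():
            rows.append(dict(condition=spec.condition, drug=spec.drug,
                             concentration_uM=r.concentration_uM,
                             pulse_index=np.nan,
                             fractional_block=r.fractional_block))
        rows.insert(0, dict(condition=spec.condition, drug=spec.drug,
                            concentration_uM=0.0, pulse_index=np.nan,
                            fractional_block=0.0))
    elif spec.kind == "na_tonic":
        rows.append(dict(condition=spec.condition, drug=spec.drug,
                         concentration_uM=0.0, pulse_index=np.nan,
                         fractional_block=0.0))
        for D in spec.concentrations:
            rows.append(dict(condition=spec.condition, drug=spec.drug,
                             concentration_uM=float(D), pulse_index=np.nan,
                             fractional_block=na_tonic_block(
                                 spec.true_params, float(D))))
    else:  # na_use_dependence
        protocol = spec.protocol or NA_USE_DEPENDENCE_PROTOCOL
        for D in spec.concentrations:
            series = na_use_dependence(spec.true_params, float(D), protocol)
            for i, b in enumerate(series, start=1):
                rows.append(dict(condition=spec.condition, drug=spec.drug,
                                 concentration_uM=float(D), pulse_index=i,
                                 fractional_block=float(b)))
    out = pd.DataFrame(rows)
    clipped = 0
    if spec.sigma > 0:
        noisy = out["fractional_block"] + rng.normal(
            0.0, spec.sigma, len(out))
        clipped = int(((noisy < 0) | (noisy > 1)).sum())
        out["fractional_block"] = noisy.clip(0.0, 1.0)
    out.attrs["clipping_rate"] = clipped / max(len(out), 1)
    out.attrs["seed"] = spec.seed
    return out


def gen_fixture_waveform(kind: str, params: dict | None = None,
                         seed: int = 0):
    """Analytic waveform plus closed-form ground-truth biomarkers.

    kinds:
      * "trapezoid_ap": resting -> linear upstroke -> plateau -> linear
        repolarization; truth: apd90, muv, v_rest, v_peak.
      * "qrst_pecg": two Gaussians (QRS and T); truth: qt by the
        max-downslope tangent method and the 2%-of-peak QRS onset.
      * "am_sine": amplitude-modulated sine; truth: dominant frequency.

    Returns (t, y, truth_dict).  ``seed`` reserved for noisy variants
    (sigma in params); the analytic truth refers to the noise-free signal.
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "trapezoid_ap":
        v_rest = p.get("v_rest", -85.0)
        v_peak = p.get("v_peak", 35.0)
        rise = p.get("rise", 2.0)
        plateau = p.get("plateau", 200.0)
        fall = p.get("fall", 50.0)
        t0 = p.get("start", 20.0)
        dt = p.get("dt", 0.1)
        t_end = p.get("t_end", 500.0)
        t = np.arange(0.0, t_end, dt)
        y = np.full_like(t, v_rest)
        # quadratic-ease upstroke: dV/dt increases to its maximum exactly
        # at the end of the rise, so the MUV instant is unambiguous
        up = (t >= t0) & (t < t0 + rise)
        y[up] = v_rest + (v_peak - v_rest) * ((t[up] - t0) / rise) ** 2
        pl = (t >= t0 + rise) & (t < t0 + rise + plateau)
        y[pl] = v_peak
        fa = (t >= t0 + rise + plateau) & (t < t0 + rise + plateau + fall)
        y[fa] = v_peak - (v_peak - v_rest) * (t[fa] - (t0 + rise + plateau)) / fall
        # APD90: from the MUV instant (end of rise) to the 90% crossing on
        # the linear down ramp
        apd90 = (t0 + rise + plateau + 0.9 * fall) - (t0 + rise)
        truth = dict(apd90=apd90, muv=2.0 * (v_peak - v_rest) / rise,
                     v_rest=v_rest, v_peak=v_peak)
        return t, y, truth
    if kind == "qrst_pecg":
        aq = p.get("qrs_amp", 1.0)
        tq = p.get("qrs_center", 60.0)
        sq = p.get("qrs_sigma", 8.0)
        at = p.get("t_amp", 0.4)
        tt = p.get("t_center", 320.0)
        st = p.get("t_sigma", 25.0)
        dt = p.get("dt", 0.5)
        t_end = p.get("t_end", 600.0)
        t = np.arange(0.0, t_end, dt)
        y = (aq * np.exp(-0.5 * ((t - tq) / sq) ** 2)
             + at * np.exp(-0.5 * ((t - tt) / st) ** 2))
        # tangent at the T-wave inflection (steepest descent, t = tt + st)
        # meets the baseline at tt + 2*st; QRS onset at 2% of QRS peak.
        q_onset = tq - sq * np.sqrt(2.0 * np.log(aq / (0.02 * aq)))
        truth = dict(qt=(tt + 2.0 * st) - q_onset, q_onset=q_onset,
                     t_end_time=tt + 2.0 * st)
        return t, y, truth
    if kind == "am_sine":
        f = p.get("freq_hz", 6.0)
        fm = p.get("mod_hz", 0.5)
        dur = p.get("duration", 4000.0)
        dt = p.get("dt", 1.0)
        sigma = p.get("sigma", 0.0)
        t = np.arange(0.0, dur, dt)
        y = (1.0 + 0.3 * np.sin(2e-3 * np.pi * fm * t)) * np.sin(
            2e-3 * np.pi * f * t)
        if sigma > 0:
            y = y + rng.normal(0.0, sigma, t.size)
        return t, y, dict(dominant_hz=f)
    raise ValueError(f"unknown fixture kind {kind!r}")
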