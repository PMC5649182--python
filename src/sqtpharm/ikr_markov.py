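"""Markov-chain model of the rapid delayed rectifier current I_Kr.

The drug-free channel is a six-state chain

    C1 <-> C2 <-> C3 -> O,  C3 -> I,  O <-> I,  O -> C3,  I -> C3

with voltage-dependent transition rates.  Drug binding extends the chain by
a drug-bound open state O* and a drug-bound inactivated state I* (no binding
to closed states).  The wild-type (WT) and the N588K gain-of-function mutant
differ only in the inactivation pathway: the mutation attenuates C-type
inactivation without altering the voltage dependence of activation, which is
modelled here as a scaling of the O<->I rates (and, through microscopic
reversibility, of the I->C3 rate).

Only the drug-free open state conducts:

    I_Kr = g_Kr * O * (V - E_Kr)

The heterozygous SQT1 condition is represented as two independent channel
populations (50% WT kinetics, 50% N588K kinetics), each with its own drug
states, whose currents are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MarkovIKrState",
    "IKrRateParams",
    "HergBindingParams",
    "WT_RATES",
    "N588K_RATES",
    "rates_at",
    "transition_matrix",
    "ikr_markov_rhs",
    "ikr_steady_state",
    "ikr_current",
    "heterozygote_current",
]

# State ordering used throughout the package (and in the compiled kernels).
STATE_NAMES = ("C1", "C2", "C3", "O", "I", "Ostar", "Istar")
N_STATES = 7
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass
class MarkovIKrState:
    """Occupancies of the seven channel states (probabilities summing to 1)."""

    C1: float = 1.0
    C2: float = 0.0
    C3: float = 0.0
    O: float = 0.0
    I: float = 0.0
    Ostar: float = 0.0
    Istar: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.C1, self.C2, self.C3, self.O, self.I, self.Ostar, self.Istar]
        )

    @classmethod
    def from_array(cls, arr) -> "MarkovIKrState":
        return cls(*(float(x) for x in arr))

    def validate(self, tol: float = 1e-8) -> None:
        arr = self.as_array()
        if np.any(arr < -tol) or np.any(arr > 1 + tol):
            raise ValueError(f"occupancies outside [0, 1]: {arr}")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError(f"occupancies do not sum to 1: sum={arr.sum()!r}")


@dataclass(frozen=True)
class IKrRateParams:
    """Voltage-dependent transition rates of the I_Kr Markov chain (ms^-1).

    The activation pathway uses exponential-of-voltage rates in the
    Clancy-Rudy hERG lineage; the N588K mutant scales the inactivation
    pathway only (``inact_scale`` multiplies the O->I rate, ``rec_scale``
    the I->O rate), leaving activation untouched.
    """

    condition: str = "WT"
    # C1 <-> C2
    a_c12: float = 0.0555
    s_c12: float = 0.05547153
    v0_c12: float = 12.0
    a_c21: float = 0.002357
    s_c21: float = 0.036588
    # C2 <-> C3 (voltage independent)
    a_c23: float = 0.0023761
    a_c32: float = 0.0036778
    # C3 -> O and C3 -> I (shared rate alpha2); O -> C3 (beta2)
    a_co: float = 0.0655
    s_co: float = 0.05547153
    v0_co: float = 36.0
    a_oc: float = 0.0029357
    s_oc: float = 0.02158
    # O <-> I inactivation pathway: symmetric exponentials around the
    # half-inactivation voltage -v0_io, i.e. betai = a_oi*exp(s_oi*V) and
    # alphai = a_io*exp(-s_io*(V + v0_io)), giving a Boltzmann steady state
    # with V1/2 = -75 mV and slope 25 mV (37 degC physiological kinetics).
    a_oi: float = 0.3 * np.exp(0.02 * 75.0)
    s_oi: float = 0.02
    a_io: float = 0.3
    s_io: float = 0.02
    v0_io: float = 75.0
    # mutant modifiers of the inactivation pathway
    inact_scale: float = 1.0
    rec_scale: float = 1.0

    def rates(self, V: float) -> dict:
        """All nine transition rates at membrane potential ``V`` (mV)."""
        alpha = self.a_c12 * np.exp(self.s_c12 * (V - self.v0_c12))
        beta = self.a_c21 * np.exp(-self.s_c21 * V)
        alpha1 = self.a_c23 + 0.0 * V
        beta1 = self.a_c32 + 0.0 * V
        alpha2 = self.a_co * np.exp(self.s_co * (V - self.v0_co))
        beta2 = self.a_oc * np.exp(-self.s_oc * V)
        betai = self.inact_scale * self.a_oi * np.exp(self.s_oi * V)
        alphai = self.rec_scale * self.a_io * np.exp(-self.s_io * (V + self.v0_io))
        # I -> C3 rate constrained by microscopic reversibility around the
        # C3-O-I loop: alpha2*betai*mu_rev == alpha2*alphai*beta2.
        mu = alphai * beta2 / betai
        return dict(
            alpha=alpha, beta=beta, alpha1=alpha1, beta1=beta1,
            alpha2=alpha2, beta2=beta2, alphai=alphai, betai=betai, mu=mu,
        )


WT_RATES = IKrRateParams(condition="WT")
# N588K attenuates inactivation without altering activation: a +75 mV
# depolarizing shift of the inactivation pathway (reciprocal scalings
# exp(-+s*dV) of the two rates), within the +60..+90 mV range reported
# experimentally, combined with an overall slowing (x0.2) of both rates so
# the mutant pathway equilibrates slowly on the AP plateau.  Both factors
# are calibrated against the drug-free SQT1 anchors (single-cell APD90 and
# 1D-strand QT); see docs/methods.md.
_N588K_SHIFT = 75.0
_N588K_SLOW = 0.2
N588K_RATES = IKrRateParams(
    condition="N588K",
    inact_scale=_N588K_SLOW * float(np.exp(-0.02 * _N588K_SHIFT)),
    rec_scale=_N588K_SLOW * float(np.exp(0.02 * _N588K_SHIFT)),
)

CONDITIONS = {"WT": WT_RATES, "N588K": N588K_RATES}


def rates_at(params: IKrRateParams, V: float) -> dict:
    r = params.rates(V)
    if any(v < 0 for v in r.values()):
        raise ValueError(f"negative transition rate at V={V}: {r}")
    return r


@dataclass(frozen=True)
class HergBindingParams:
    """Drug binding (ms^-1 uM^-1) / unbinding (ms^-1) rates for O and I states."""

    k_A: float = 0.0
    l_A: float = 1.0
    k_I: float = 0.0
    l_I: float = 1.0

    def __post_init__(self):
        if min(self.k_A, self.l_A, self.k_I, self.l_I) < 0:
            raise ValueError("binding/unbinding rates must be non-negative")


NO_HERG_BINDING = HergBindingParams()


def transition_matrix(
    V: float,
    rates: IKrRateParams,
    binding: HergBindingParams = NO_HERG_BINDING,
    D: float = 0.0,
) -> np.ndarray:
    """Generator matrix A such that ds/dt = A @ s (columns sum to zero).

    Binding fluxes are concentration-scaled mass action, k*[D]*state.
    """
    if D < 0:
        raise ValueError("drug concentration must be non-negative")
    r = rates_at(rates, V)
    A = np.zeros((N_STATES, N_STATES))

    def add(src: str, dst: str, rate: float) -> None:
        i, j = _IDX[dst], _IDX[src]
        A[i, j] += rate
        A[j, j] -= rate

    add("C1", "C2", r["alpha"])
    add("C2", "C1", r["beta"])
    add("C2", "C3", r["alpha1"])
    add("C3", "C2", r["beta1"])
    add("C3", "O", r["alpha2"])
    add("C3", "I", r["alpha2"])
    add("O", "C3", r["beta2"])
    add("I", "C3", r["mu"])
    add("O", "I", r["betai"])
    add("I", "O", r["alphai"])
    add("O", "Ostar", binding.k_A * D)
    add("Ostar", "O", binding.l_A)
    add("I", "Istar", binding.k_I * D)
    add("Istar", "I", binding.l_I)
    return A


def ikr_markov_rhs(
    s,
    V: float,
    rates: IKrRateParams,
    binding: HergBindingParams = NO_HERG_BINDING,
    D: float = 0.0,
) -> np.ndarray:
    """Time derivatives of the seven occupancies (sums to zero exactly)."""
    s = np.asarray(s, dtype=float)
    return transition_matrix(V, rates, binding, D) @ s


def ikr_steady_state(
    V: float,
    rates: IKrRateParams,
    binding: HergBindingParams = NO_HERG_BINDING,
    D: float = 0.0,
) -> np.ndarray:
    """Stationary occupancy distribution at fixed V and [D] (null space of A)."""
    A = transition_matrix(V, rates, binding, D)
    # Replace one balance equation with the conservation constraint.
    M = A.copy()
    M[-1, :] = 1.0
    b = np.zeros(N_STATES)
    b[-1] = 1.0
    s = np.linalg.solve(M, b)
    return s


def ikr_current(s, V: float, g_Kr: float, E_Kr: float) -> float:
    """I_Kr = g_Kr * O * (V - E_Kr); only the drug-free open state conducts."""
    O = s.O if isinstance(s, MarkovIKrState) else np.asarray(s)[_IDX["O"]]
    return g_Kr * O * (V - E_Kr)


def heterozygote_current(
    s_wt,
    s_n588k,
    V: float,
    g_Kr: float,
    E_Kr: float,
    w_mut: float = 0.5,
) -> float:
    """Mixed-population I_Kr: (1-w)*I(WT pop) + w*I(mutant pop), default 50/50."""
    if not 0.0 <= w_mut <= 1.0:
        raise ValueError("mixing weight must be in [0, 1]")
    return (1.0 - w_mut) * ikr_current(s_wt, V, g_Kr, E_Kr) + w_mut * ikr_current(
        s_n588k, V, g_Kr, E_Kr
    )
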