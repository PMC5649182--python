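"""Drug-receptor models for disopyramide and quinidine.

Three mechanisms are represented:

* state-dependent block of the Markov I_Kr channel via drug-bound open and
  inactivated states (parameters in :mod:`sqtpharm.ikr_markov` /
  :class:`HergBindingParams`, values per drug and per WT/N588K condition;
  the shipped models bind the open state only, since neither agent relies
  on hERG inactivation to act);
* guarded-receptor block of the fast sodium current: the drug binds with
  constant affinity to activated, inactivated and resting channels, but
  access to each conformation is gated by the Hodgkin-Huxley variables
  (guards m^3*h*j, (1-h*j) and (1-m^3)*h*j respectively), giving tonic and
  use-dependent block;
* static Hill-type "pore block" of the secondary currents (I_CaL, I_to,
  I_Ks, and for quinidine also I_K1 and I_NaL), applied as a
  concentration-dependent conductance scaling.

Binding and unbinding rate constants were fitted with the bounded
Nelder-Mead machinery in :mod:`sqtpharm.calibration` against synthetic
voltage-clamp datasets (:mod:`sqtpharm.synthetic_data`) constructed around
the published half-maximal concentrations: hERG tail-current IC50s of
10.77 / 15.77 uM (disopyramide, WT / N588K) and 0.62 / 2.16 uM (quinidine),
and sodium-channel tonic-block IC50s of 36 uM (disopyramide) and 17 uM
(quinidine).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ikr_markov import HergBindingParams

__all__ = [
    "GuardedNaState",
    "NaBindingParams",
    "PoreBlockEntry",
    "DrugSpec",
    "ALL_ACTIONS",
    "ACTION_SCENARIOS",
    "DRUGS",
    "get_drug",
    "guarded_na_rhs",
    "na_resting_block",
    "ina_current",
    "pore_block_scale",
]

PORE_TARGETS = ("ICaL", "Ito", "IKs", "IK1", "INaL")
ALL_ACTIONS = frozenset({"ikr", "ina", "pore"})
# The hypothetical mechanism-isolation scenarios used for the ionic
# decomposition experiments: I_Kr block alone, I_Na block alone, combined
# I_Kr + I_Na, and the full multi-channel action.
ACTION_SCENARIOS = {
    "all": ALL_ACTIONS,
    "ikr": frozenset({"ikr"}),
    "ina": frozenset({"ina"}),
    "ikr+ina": frozenset({"ikr", "ina"}),
    "none": frozenset(),
}


@dataclass
class GuardedNaState:
    """Fractional block of activated (b_A), inactivated (b_I), resting (b_R)."""

    b_A: float = 0.0
    b_I: float = 0.0
    b_R: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.b_A, self.b_I, self.b_R])

    def validate(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12):
            raise ValueError("fractional block must be non-negative")
        if arr.sum() > 1 + 1e-9:
            raise ValueError("total fractional block exceeds 1")


@dataclass(frozen=True)
class NaBindingParams:
    """Guarded-receptor rate constants: k in ms^-1 uM^-1, l in ms^-1."""

    k_A: float = 0.0
    l_A: float = 1.0
    k_I: float = 0.0
    l_I: float = 1.0
    k_R: float = 0.0
    l_R: float = 1.0

    def __post_init__(self):
        vals = (self.k_A, self.l_A, self.k_I, self.l_I, self.k_R, self.l_R)
        if min(vals) < 0:
            raise ValueError("binding/unbinding rates must be non-negative")


@dataclass(frozen=True)
class PoreBlockEntry:
    """Hill-type conductance block of one target current."""

    target: str
    ic50: float  # uM
    n_h: float = 1.0

    def __post_init__(self):
        if self.ic50 <= 0:
            raise ValueError("IC50 must be positive")
        if self.n_h <= 0:
            raise ValueError("Hill coefficient must be positive")


@dataclass(frozen=True)
class DrugSpec:
    """One agent: concentration, binding kinetics per target, pore blocks."""

    name: str
    concentration: float = 0.0  # uM
    herg_binding: dict = field(default_factory=dict)  # condition -> HergBindingParams
    na_binding: NaBindingParams = field(default_factory=NaBindingParams)
    pore_blocks: tuple = ()
    actions: frozenset = ALL_ACTIONS

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("drug concentration must be non-negative")
        unknown = self.actions - ALL_ACTIONS
        if unknown:
            raise ValueError(f"unknown actions {sorted(unknown)}")

    def at(self, concentration: float, actions="all") -> "DrugSpec":
        """A copy of this spec at a given concentration / action scenario."""
        if isinstance(actions, str):
            actions = ACTION_SCENARIOS[actions]
        return replace(self, concentration=concentration, actions=frozenset(actions))

    def herg_params(self, condition: str) -> HergBindingParams:
        if "ikr" not in self.actions or self.concentration == 0:
            return HergBindingParams()
        return self.herg_binding[condition]

    def na_params(self) -> NaBindingParams:
        if "ina" not in self.actions or self.concentration == 0:
            return NaBindingParams()
        return self.na_binding

    def pore_scale(self, target: str) -> float:
        """Static conductance multiplier for a secondary target current."""
        if "pore" not in self.actions:
            return 1.0
        for entry in self.pore_blocks:
            if entry.target == target:
                return pore_block_scale(1.0, self.concentration, entry)
        return 1.0


def pore_block_scale(g_control: float, D: float, entry: PoreBlockEntry) -> float:
    """Hill block: g = g_control / (1 + (D/IC50)^nH); g(0) = g_control."""
    if D < 0:
        raise ValueError("drug concentration must be non-negative")
    if D == 0:
        return g_control
    return g_control / (1.0 + (D / entry.ic50) ** entry.n_h)


def guarded_na_rhs(b, m: float, h: float, j: float, D: float, p: NaBindingParams):
    """Derivatives (db_A/dt, db_I/dt, db_R/dt) of the guarded-receptor pools.

    Guards: activated m^3*h*j, inactivated (1 - h*j), resting (1 - m^3)*h*j;
    each binding flux scales the unblocked fraction (1 - b_A - b_I - b_R).
    """
    if isinstance(b, GuardedNaState):
        bA, bI, bR = b.b_A, b.b_I, b.b_R
    else:
        bA, bI, bR = b
    free = 1.0 - bA - bI - bR
    m3 = m**3
    hj = h * j
    dbA = p.k_A * D * m3 * hj * free - p.l_A * bA
    dbI = p.k_I * D * (1.0 - hj) * free - p.l_I * bI
    dbR = p.k_R * D * (1.0 - m3) * hj * free - p.l_R * bR
    return np.array([dbA, dbI, dbR])


def na_resting_block(D: float, p: NaBindingParams) -> float:
    """Closed-form equilibrium resting block at a hyperpolarized hold.

    With gates frozen at m ~ 0, h = j = 1, only the resting pathway is
    guarded open and b_R* = k_R D / (k_R D + l_R), b_A = b_I = 0.
    """
    denom = p.k_R * D + p.l_R
    return 0.0 if denom == 0 else p.k_R * D / denom


def ina_current(m, h, j, b, V, g_Na, E_Na):
    """I_Na = g_Na (1 - b_A - b_I - b_R) m^3 h j (V - E_Na)."""
    if isinstance(b, GuardedNaState):
        free = 1.0 - b.b_A - b.b_I - b.b_R
    else:
        free = 1.0 - float(np.sum(np.asarray(b)))
    return g_Na * free * m**3 * h * j * (V - E_Na)


# --------------------------------------------------------------------------
# Drug registry.  hERG association constants were fitted so that the
# re-simulated tail-current protocol reproduces the published IC50s at the
# chosen block-onset speed (l = 0.02/ms); the Na resting-pathway ratio
# l_R/k_R equals the published tonic-block IC50s, and the activated-state
# kinetics reproduce the published tissue CV dose pattern (docs/methods.md).
# Quinidine-only secondary targets (I_K1, I_NaL) are simply absent from the
# disopyramide entry ("no action" rather than infinite IC50).
# --------------------------------------------------------------------------

DISOPYRAMIDE = DrugSpec(
    name="disopyramide",
    herg_binding={
        # fitted: see calibration.fit_herg_binding / docs/methods.md
        "WT": HergBindingParams(k_A=3.1255e-02, l_A=0.02),
        "N588K": HergBindingParams(k_A=3.1752e-03, l_A=0.02),
    },
    na_binding=NaBindingParams(
        k_A=0.35, l_A=0.0004, k_I=2.3e-05, l_I=0.0004, k_R=2.78e-05, l_R=0.001
    ),
    pore_blocks=(
        PoreBlockEntry("ICaL", 1036.7),
        PoreBlockEntry("Ito", 20.9),
        PoreBlockEntry("IKs", 88.1),
    ),
)

QUINIDINE = DrugSpec(
    name="quinidine",
    herg_binding={
        "WT": HergBindingParams(k_A=5.4293e-01, l_A=0.02),
        "N588K": HergBindingParams(k_A=2.3182e-02, l_A=0.02),
    },
    na_binding=NaBindingParams(
        k_A=0.55, l_A=0.0003, k_I=3.0e-05, l_I=0.0003, k_R=5.88e-05, l_R=0.001
    ),
    pore_blocks=(
        PoreBlockEntry("ICaL", 14.9),
        PoreBlockEntry("Ito", 21.8),
        PoreBlockEntry("IKs", 44.0),
        PoreBlockEntry("IK1", 42.6),
        PoreBlockEntry("INaL", 12.0),
    ),
)

DRUGS = {d.name: d for d in (DISOPYRAMIDE, QUINIDINE)}


def get_drug(name: str) -> DrugSpec:
    try:
        return DRUGS[name]
    except KeyError:
        raise KeyError(
            f"unknown drug {name!r}; known drugs: {sorted(DRUGS)}"
        ) from None
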