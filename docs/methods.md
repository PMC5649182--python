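# Methods

`sqtpharm` is a multiscale in-silico pharmacology pipeline for hERG-linked
short QT syndrome variant 1 (SQT1): a human ventricular myocyte model with a
Markov-chain rapid delayed rectifier current (I_Kr), state-dependent drug
models for disopyramide and quinidine, and monodomain tissue simulations
from which clinical-style biomarkers (QT, ERP, CV, wavelength, TDR,
dominant frequency) are extracted. This note records the model equations as
implemented, the calibration procedure, the numerical choices, and the
known limitations.

## Cell model

The myocyte is the O'Hara–Rudy (ORd) human ventricular model with two
substitutions:

* **Fast Na⁺ current** uses the Luo–Rudy m³hj formulation (conductance
  23 mS/μF, host-model Nernst E_Na), which conducts robustly in coarse
  tissue grids. The ORd CaMK-phosphorylated I_Na pathway is dropped with
  it; CaMK regulation of I_NaL, I_CaL and SR fluxes is retained.
* **I_Kr** is a six-state Markov chain (three closed states C1–C2–C3, open
  O, inactivated I) extended by drug-bound open (O*) and inactivated (I*)
  states. Only O conducts: I_Kr = g_Kr·O·(V−E_K).

ENDO, MCELL and EPI variants use the ORd transmural multipliers with two
deliberate departures, both part of the calibrated default profile (see
Calibration): the transmural I_Kr conductance ratio is fixed at
ENDO:MCELL:EPI = 1.0:1.0:1.6 (transmural hERG expression), and the M-cell
uses a strengthened late current / weakened pump profile
(I_NaL ×5.5, I_CaL ×2.6, I_Ks ×1.6, I_K1 ×0.9, I_NaK ×0.5) so that the
mid-myocardial repolarization island survives electrotonic averaging in
tissue. Every maximal conductance also carries a dimensionless scaling hook
(`CellParams.scales`).

## Markov I_Kr and the N588K mutant

Activation-chain rates are exponential-of-voltage functions in the
Clancy–Rudy hERG lineage. The O↔I inactivation pathway uses symmetric
exponentials around the half-inactivation voltage,

    beta_i  = a·exp(s·(V + Vh)),   alpha_i = a·exp(−s·(V + Vh)),

giving a Boltzmann steady state with V½ = −Vh and slope 1/(2s). The
calibrated wild type has V½ = −75 mV, slope 25 mV, and a = 0.3 ms⁻¹. The
I→C3 rate is constrained by microscopic reversibility around the C3–O–I
loop (μ = α_i·β₂/β_i), so the drug-free chain is thermodynamically
consistent. The generator matrix has columns summing to zero; explicit
Euler therefore conserves total occupancy to machine precision.

N588K attenuates inactivation without altering activation. It is
implemented as a +75 mV depolarizing shift of the inactivation pathway
(reciprocal scalings exp(∓s·ΔV) of the two rates — a pure shift preserves
the Boltzmann shape), within the +60…+90 mV range reported experimentally,
combined with a ×0.2 slowing of both rates. The slowing makes the mutant
pathway equilibrate on the ~100 ms plateau time scale rather than
instantaneously, which differentiates long (M-cell) from short (ENDO)
action potentials and is required to reproduce the transmural pattern of
QT shortening. The heterozygous "SQT1" condition is a 50/50 mixture of two
independent channel populations (WT and N588K kinetics), each carrying its
own drug-bound states; homozygous mixing weights are supported.

## Drug models

**hERG block** adds O→O* and I→I* transitions with mass-action binding
k·[D] and unbinding l. Both disopyramide and quinidine are implemented as
open-state-selective blockers (k_I = 0): neither drug requires hERG
inactivation to act, which is also why both retain potency against N588K.
The unbinding rate l = 0.02 ms⁻¹ sets a ~50 ms block-equilibration time
(fast, quinidine-like onset); the association constants per condition were
fitted so that the re-simulated tail-current dose-response protocol (hold
−80 mV, 2 s step to +20 mV, 500 ms tail at −40 mV, 0.25 Hz, block measured
on peak tail occupancy) reproduces the published IC₅₀s: disopyramide
10.77 μM (WT) / 15.77 μM (N588K), quinidine 0.62 μM / 2.16 μM.

**Na⁺-channel block** uses the guarded-receptor formalism: the drug binds
activated (guard m³hj), inactivated (guard 1−hj) and resting (guard
(1−m³)hj) channels with constant affinity, each flux scaling the unblocked
fraction, and I_Na is multiplied by (1−b_A−b_I−b_R). At a hyperpolarized
hold the equilibrium block has the closed form b_X = r_X/(1+Σr) with
r_X = k_X[D]·guard_X/l_X, so the resting-pathway ratio l_R/k_R was set
directly from the published tonic-block IC₅₀s (36 μM disopyramide, 17 μM
quinidine). The activated-state kinetics (k_A, l_A) control use-dependent
block; they were chosen so the strand conduction-velocity dose pattern
matches the published table (e.g. CV ≈ 45 cm/s at 10 μM disopyramide from
a 60 cm/s baseline), with slow unbinding (τ = 1/l_A of 2.5–3.3 s) carrying
block accumulation across beats and producing stronger block at faster
pacing.

**Secondary currents** (I_CaL, I_to, I_Ks; quinidine also I_K1 and I_NaL)
are blocked by static Hill-type conductance scaling
g = g_control/(1+([D]/IC₅₀)^nH) with the published IC₅₀s and nH = 1 (Hill
coefficients are not published; the value is overridable per entry). Note
that the commonly printed form 1/(1+(IC₅₀/[D])^nH) describes the *blocked*
fraction — it tends to 0 conductance at zero drug — so the conventional
reading with g→g_control as [D]→0 is implemented. Targets a drug does not
touch are simply absent from its entry. An action mask
(`all`/`ikr`/`ina`/`ikr+ina`) supports the mechanism-isolation scenarios.

## Tissue models

The monodomain equation ∂V/∂t = ∇·(D∇V) − I_ion/C_m is solved by explicit
forward Euler finite differences with no-flux boundaries. The transmural
strand has 25 ENDO / 35 MCELL / 40 EPI cells over 15 mm (dx = 0.15 mm),
isotropic D = 0.0924 mm²/ms (calibrated so drug-free CV ≈ 60 cm/s measured
between interior cells 20 and 80) with a five-fold D reduction at the
single MCELL–EPI interface. Cells are pre-paced in isolation (100 beats
default) and the coupled strand is then paced for 4 beats; biomarkers are
measured on the final beat. The strand stimulus is −100 μA/μF for 1 ms on
the five endocardial nodes (a single-cell stimulus cannot capture against
the diffusive load); isolated cells use −80 μA/μF for 0.5 ms.

The pseudo-ECG is the far-field unipolar potential
Φ = ∫(−∇V)·∇(1/r) dΩ evaluated at a virtual electrode 2 cm beyond the
epicardial end (axial form in 1D). QT is measured from QRS onset (first 2%
deflection after the stimulus) to the intersection of the steepest
descending-limb tangent of the T wave with the pre-stimulus baseline;
the implementation handles either T polarity. ERP is the shortest S1–S2
coupling interval whose premature endocardial stimulus still propagates to
the epicardial end (binary search, 1 ms default resolution, from the
strand state just before a steady S1). CV uses activation-time differences
(−30 mV upstroke crossings) at interior sites; TDR is the spread of
per-cell 90%-repolarization times; WL = CV × ERP.

### Re-entry at desk scale

The study's 3D DT-MRI wedge geometry is not available, so re-entry is
studied on reduced, isotropic preparations whose *trends* — not absolute
dominant frequencies or lifespans — are the scientific output:

* a 2D sheet (default 75×75 nodes, dx 0.5 mm, 37.5 mm square) with
  diffusion reduced to D = 0.023 mm²/ms (CV ≈ 13 cm/s on this grid) so the
  re-entry wavelength fits the domain. Re-entry is initiated by the phase
  distribution method: each node's full state vector is sampled from one
  steady reference AP cycle at a node-specific phase (Archimedean-spiral
  phase map by default; any map is accepted). Drug-free SQT1 sustains
  multi-wavelet activity for the full 2.4 s window (DF ≈ 8 Hz from the
  pseudo-ECG power spectrum at an electrode 30 mm above the sheet center).
* a periodic ring (140 or 120 cells, dx 0.5 mm, same reduced D) seeded
  with two circulating waves. The ring reproduces, at a fraction of the
  cost, the wavelength physics of larger media: dominant frequency falls
  dose-dependently with either drug (CV slowing plus ERP prolongation),
  and on the tighter 60 mm ring quinidine ≥ 2 μM extinguishes re-entry
  within half a second while the drug-free condition circulates
  indefinitely.

The dominant frequency is the largest peak of the Hann-tapered,
zero-padded periodogram of the detrended pseudo-ECG over 0.5–20 Hz
(window ≥ 2 s); the re-entry lifespan is the last upward −30 mV crossing
at any recording site.

## Calibration

The published supplementary parameter tables (Markov rates, binding
constants) are not available, so the model is anchored to printed values,
in two stages:

1. **Drug-free anchors.** The WT inactivation V½/slope, the N588K shift
   and slowing, the global g_Kr scale (×5.1 on the ORd base), the global
   I_Ks scale (×2) and the MCELL/EPI regional profile were calibrated so
   that the drug-free 1D strand gives QT ≈ 350 ms (WT) and ≈ 241 ms
   (SQT1) at 1 Hz — a ~31% reduction, matching the clinical estimate for
   N588K carriers — with CV ≈ 60 cm/s, and the isolated SQT1 ENDO cell
   gives APD90 ≈ 195 ms. These anchors under-determine the composition of
   the repolarization reserve; the I_Ks share follows the published ionic
   decomposition of drug action as a secondary anchor.
2. **Drug anchors.** hERG association constants per condition from the
   four printed IC₅₀s; Na resting-pathway ratio from the two printed tonic
   IC₅₀s; Na activated-state kinetics from the printed tissue CV dose
   pattern. Everything else — drugged QT/ERP/WL at every concentration,
   the ionic decomposition, restitution, and all re-entry behavior — is
   then a genuine model prediction.

Round-trip identifiability is tested: refitting the binding rates by
bounded Nelder–Mead (multi-start, log-parameter space, polish restart)
against synthetic noisy datasets recovers the generating IC₅₀s within 5%.

## Numerics

Explicit forward Euler with Rush–Larsen updates for all Hodgkin–Huxley
gates; Markov occupancies and guarded-receptor pools advance by explicit
Euler (conservation is exact by construction; occupancy drift over 10 s of
paced simulation is < 10⁻⁶). Every purely voltage-dependent quantity (gate
steady states, per-step Rush–Larsen decay factors, Markov rates, GHK and
pump prefactors) is pre-tabulated on a 0.02 mV grid over −150…+100 mV and
linearly interpolated; the table is rebuilt per time step size. Default
dt = 0.005 ms for cells and the strand (APD90 changes < 1 ms when halved)
and 0.01 ms for the reduced-D re-entry preparations; the tissue solvers
refuse to run when dt exceeds the diffusive CFL bound dx²/(2·d·D_max).
GHK flux singularities at V = 0 use the analytic limits. Voltage-clamp
protocols on the isolated Markov chain are propagated exactly by matrix
exponentials per piecewise-constant segment. All simulations are
deterministic; synthetic-data noise is seeded (`numpy.random.default_rng`).

Problem sizes used by the shipped tests and the acceptance script — 100
pre-pacing beats, 4 coupled strand beats, 2.4 s re-entry windows, ring
rather than sheet re-entry for dose trends — were chosen as the smallest
preparations at which the measured biomarkers are converged (QT beat-to-
beat drift < 1 ms; DF resolution limited by the window, mitigated by
zero-padding).

## What the synthetic data do and do not cover

The synthetic voltage-clamp datasets reproduce the *structure* of the
published measurements (dose-response points per condition, tonic block,
30-pulse use dependence) with additive Gaussian noise (σ = 0.02 on
fractional block, clipped to [0,1] with the clipping rate reported). They
are generated by the same model family that is fitted to them, so
round-trip tests demonstrate identifiability of the calibration pipeline —
not the biological accuracy of the kinetics, which only the printed IC₅₀s
and tissue anchors constrain. Real patch-clamp data would add
rundown/leak artefacts, cell-to-cell variability and temperature scatter
that are not emulated.

## Known limitations

* The ionic decomposition of QT prolongation at 10 μM disopyramide
  attributes ~97% to combined I_Kr+I_Na block here versus 92.9% published:
  in this ORd-lineage implementation I_to block slightly *shortens* the
  M/EPI action potential (removing the notch recruits extra K⁺ current)
  and the I_Ks share compatible with the drug-free QT anchors is small, so
  the secondary blocks contribute almost nothing. Raising I_Ks far enough
  to close the gap collapses the WT–SQT1 QT separation that the primary
  anchors pin.
* Drug-free maximal TDR is slightly lower in SQT1 (~42 ms) than WT
  (~49 ms), whereas the source reports the opposite ordering; the mutation
  compresses the M–ENDO repolarization gradient here.
* The MCELL profile required by the QT anchors is more EAD-prone at slow
  pacing than the original model: 5 μM disopyramide elicits EADs in 3/18
  modifier combinations in SQT1 (published: none), and EADs are more
  likely in SQT1 than WT for quinidine (published: the reverse). Baseline
  (unmodified, drug-free) cells of all types are EAD-free.
* Absolute dominant frequencies and re-entry lifespans are
  geometry-dependent and not comparable to the 3D-wedge values; only dose
  trends are meaningful at desk scale.
* No closed-state hERG binding, no temperature scaling (all kinetics are
  37 °C by construction), no mixed WT/mutant tetramer stoichiometry, pore
  block without kinetics for secondary currents, monodomain electrics
  without fiber anisotropy in the reduced preparations.
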