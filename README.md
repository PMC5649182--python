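# sqtpharm

Multiscale in-silico pharmacology of the class Ia anti-arrhythmics
**disopyramide** and **quinidine** in hERG-linked **short QT syndrome
variant 1 (SQT1)**, in human ventricular models.

SQT1 is caused by the N588K gain-of-function mutation in hERG, which
attenuates inactivation of the rapid delayed rectifier current I_Kr,
abbreviates repolarization (QT intervals ≤ 300 ms) and predisposes to
re-entrant ventricular arrhythmias. Quinidine and disopyramide — drugs
that block hERG without requiring its inactivation, and additionally block
Na⁺ channels in a use-dependent manner — partially reverse the phenotype.
This package implements the full model hierarchy needed to study how:

* a six-state Markov chain for I_Kr (closed C1–C2–C3, open O, inactivated
  I, plus drug-bound O* and I*), with I_Kr = g_Kr·O·(V−E_K), WT and N588K
  kinetics, and a 50/50 heterozygote ("SQT1") formulation;
* drug–channel interaction models: mass-action binding k·[D] to the open
  hERG state, the guarded-receptor model of Na⁺-channel block
  (I_Na = g_Na(1−b_A−b_I−b_R)m³hj(V−E_Na), with binding to activated,
  inactivated and resting conformations gated by the Hodgkin–Huxley
  variables) and static Hill pore block g = g_control/(1+([D]/IC₅₀)^nH)
  of the secondary currents (I_CaL, I_to, I_Ks, I_K1, I_NaL);
* an O'Hara–Rudy-lineage myocyte (ENDO/MCELL/EPI) hosting these currents;
* monodomain tissue: a 15 mm transmural strand with pseudo-ECG
  (Φ = ∫(−∇V)·∇(1/r) dΩ) for QT (T-wave tangent method), ERP (S1–S2
  binary search), conduction velocity, re-entry wavelength WL = CV×ERP and
  transmural dispersion of repolarization; and reduced 2D-sheet / ring
  preparations for re-entry initiated by the phase-distribution method,
  with dominant-frequency analysis of the pseudo-ECG power spectrum.

The drug-free models are calibrated to printed anchors (WT/SQT1 strand QT
of 350/241 ms at 1 Hz, SQT1 endocardial APD90 of 195.3 ms, CV ≈ 60 cm/s);
drug binding constants are fitted so that re-simulated voltage-clamp
protocols reproduce the published IC₅₀s. Everything downstream — drugged
QT/ERP/WL dose responses, the ionic decomposition of drug action,
restitution, EAD susceptibility and re-entry dynamics — is then computed,
not assumed. See `docs/methods.md` for the full model description,
parameter provenance and known limitations.

## Worked example

Steady-state biomarkers of a single SQT1 endocardial cell at 1 Hz, drug
free and with 2 μM quinidine (100 pre-pacing beats):

```python
from sqtpharm.cell_model import CellParams
from sqtpharm.drug_engine import get_drug
from sqtpharm.protocols import paced_biomarkers

base = paced_biomarkers(CellParams("ENDO", "SQT1"))
quin = paced_biomarkers(CellParams("ENDO", "SQT1"),
                        drug=get_drug("quinidine").at(2.0))
print(f"drug-free : APD90 {base.apd90:6.1f} ms   MUV {base.muv:5.0f} mV/ms")
print(f"quinidine : APD90 {quin.apd90:6.1f} ms   MUV {quin.muv:5.0f} mV/ms")
```

```
drug-free : APD90  197.1 ms   MUV   396 mV/ms
quinidine : APD90  269.9 ms   MUV   300 mV/ms
```

The abbreviated SQT1 action potential (~197 ms vs ~293 ms in WT) is
markedly prolonged by 2 μM quinidine through block of the mutant-carrying
I_Kr, while the reduced maximum upstroke velocity reflects concurrent
use-dependent Na⁺-channel block.

The same experiment at tissue scale, from the command line:

```bash
sqtpharm strand --condition SQT1 --drug quinidine -c 2 --out strand.json
```

writes a report whose `strand` table contains the drug-free arm
(QT ≈ 240 ms — the short QT hallmark; compare ≈ 350 ms for
`--condition WT`) and the 2 μM quinidine arm (QT ≈ 333 ms, CV slowed from
≈ 60 to ≈ 57 cm/s). Other subcommands: `cell-sweep`, `erp`, `restitution`,
`ead-grid`, `reentry-2d`, `fit` (round-trip binding-rate refits on
synthetic clamp data), `report <preset>` for the shipped experiment
presets, and `run <config.yaml>` for custom pipelines.

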