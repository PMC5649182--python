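"""Compiled numerical kernels for the ventricular cell and tissue solvers.

The myocyte ODE system is an O'Hara-Rudy-lineage human ventricular model
with the fast sodium current in Luo-Rudy m^3*h*j form, a two-population
Markov I_Kr (WT / N588K kinetics) with drug-bound states, and the
guarded-receptor sodium-block pools.  Integration is explicit forward Euler
with Rush-Larsen updates for all Hodgkin-Huxley gates; every purely
voltage-dependent quantity (gate steady states, per-step exponential decay
factors, Markov transition rates, GHK/electrogenic-pump prefactors) is
pre-tabulated on a fine voltage grid and linearly interpolated, which is
what makes the strand and sheet solvers affordable.

Nothing in this module is public API; see cell_model/tissue for wrappers.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------- constants
R = 8314.0
T = 310.0
F = 96485.0
RTF = R * T / F

NAO = 140.0
CAO = 1.8
KO = 5.4

# cell geometry (cm / uL)
_L = 0.01
_RAD = 0.0011
VCELL = 1000.0 * 3.14 * _RAD * _RAD * _L
AGEO = 2.0 * 3.14 * _RAD * _RAD + 2.0 * 3.14 * _RAD * _L
ACAP = 2.0 * AGEO
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

# CaMK
KMCAMK = 0.15
ACAMK = 0.05
BCAMK = 0.00068
CAMKO = 0.05
KMCAM = 0.0015

# -------------------------------------------------------------- state index
iV = 0
iNAI, iNASS, iKI, iKSS, iCAI, iCASS, iCANSR, iCAJSR = 1, 2, 3, 4, 5, 6, 7, 8
iM, iH, iJ = 9, 10, 11
iML, iHL, iHLP = 12, 13, 14
iA, iIF, iIS, iAP, iIFP, iISP = 15, 16, 17, 18, 19, 20
iDG, iFF, iFS, iFCAF, iFCAS, iJCA, iNCA, iFFP, iFCAFP = 21, 22, 23, 24, 25, 26, 27, 28, 29
iXS1, iXS2, iXK1 = 30, 31, 32
iJRELNP, iJRELP, iCAMKT = 33, 34, 35
iMK1 = 36  # Markov population 1 (WT kinetics): C1,C2,C3,O,I,O*,I*
iMK2 = 43  # Markov population 2 (N588K kinetics)
iBA, iBI, iBR = 50, 51, 52
NS = 53

# ---------------------------------------------------------- parameter index
pGNA, pGNAL, pGTO, pPCA, pGKR, pGKS, pGK1, pGNCX, pPNAK, pGKB = range(10)
pJRELSC, pJUPSC, pCMDNSC, pEPI, pWMUT, pDRUG = 10, 11, 12, 13, 14, 15
pKA1, pLA1, pKI1, pLI1 = 16, 17, 18, 19  # hERG binding, population 1
pKA2, pLA2, pKI2, pLI2 = 20, 21, 22, 23  # hERG binding, population 2
pKAN, pLAN, pKIN, pLIN, pKRN, pLRN = 24, 25, 26, 27, 28, 29
NP = 30

# -------------------------------------------------------------- table index
(cMSS, cMEF, cHSS, cHEF, cJSS, cJEF,
 cMLSS, cMLEF, cHLSS, cHLEF, cHLPSS, cHLPEF,
 cASS, cAEF, cIFSS, cIFEF, cISEF, cAPSS, cAPEF, cIFPEF, cISPEF,
 cDSS, cDEF, cFSS, cFFEF, cFSEF, cFCAFEF, cFCASEF, cJCAEF, cFFPEF, cFCAFPEF,
 cXS1SS, cXS1EF, cXS2EF, cXK1SS, cXK1EF,
 cAIF, cAFCAF, cRK1, cXKB,
 cEV, cEV2, cA1, cA2, cHCA, cHNA, cKNAI, cKNAO,
 cMKA, cMKB, cMKA2, cMKB2,
 cAIWT, cBIWT, cMUWT, cAIMUT, cBIMUT, cMUMUT,
 cIFEFE, cISEFE, cIFPEFE, cISPEFE) = range(62)
NCOL = 62

MK_A1 = 0.0023761  # C2->C3, voltage independent
MK_B1 = 0.0036778  # C3->C2


def build_voltage_table(dt, rates_wt, rates_mut,
                        vmin=-150.0, vmax=100.0, dv=0.02):
    """Tabulate every voltage-dependent quantity for a fixed time step."""
    V = np.arange(vmin, vmax + dv / 2, dv)
    n = V.size
    tab = np.zeros((n, NCOL))

    def rl(ss, tau, css, cef):
        tab[:, css] = ss
        tab[:, cef] = np.exp(-dt / tau)

    # --- Luo-Rudy I_Na gates
    x = V + 47.13
    am = np.where(np.abs(x) < 1e-6, 3.2, 0.32 * x / (1.0 - np.exp(-0.1 * x)))
    bm = 0.08 * np.exp(-V / 11.0)
    lo = V < -40.0
    ah = np.where(lo, 0.135 * np.exp(-(80.0 + V) / 6.8), 0.0)
    bh = np.where(lo, 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V),
                  1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1))))
    aj = np.where(
        lo,
        (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
        * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))),
        0.0,
    )
    bj = np.where(
        lo,
        0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14))),
        0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0))),
    )
    rl(am / (am + bm), 1.0 / (am + bm), cMSS, cMEF)
    rl(ah / (ah + bh), 1.0 / (ah + bh), cHSS, cHEF)
    rl(aj / (aj + bj), 1.0 / (aj + bj), cJSS, cJEF)

    # --- I_NaL
    mlss = 1.0 / (1.0 + np.exp(-(V + 42.85) / 5.264))
    tm = 1.0 / (6.765 * np.exp((V + 11.64) / 34.77)
                + 8.552 * np.exp(-(V + 77.42) / 5.955))
    rl(mlss, tm, cMLSS, cMLEF)
    rl(1.0 / (1.0 + np.exp((V + 87.61) / 7.488)), 200.0, cHLSS, cHLEF)
    rl(1.0 / (1.0 + np.exp((V + 93.81) / 7.488)), 600.0, cHLPSS, cHLPEF)

    # --- I_to
    ass = 1.0 / (1.0 + np.exp(-(V - 14.34) / 14.82))
    ta = 1.0515 / (
        1.0 / (1.2089 * (1.0 + np.exp(-(V - 18.4099) / 29.3814)))
        + 3.5 / (1.0 + np.exp((V + 100.0) / 29.3814))
    )
    rl(ass, ta, cASS, cAEF)
    iss = 1.0 / (1.0 + np.exp((V + 43.94) / 5.711))
    delta_epi = 1.0 - 0.95 / (1.0 + np.exp((V + 70.0) / 5.0))
    tif = 4.562 + 1.0 / (0.3933 * np.exp(-(V + 100.0) / 100.0)
                         + 0.08004 * np.exp((V + 50.0) / 16.59))
    tis = 23.62 + 1.0 / (0.001416 * np.exp(-(V + 96.52) / 59.05)
                         + 1.780e-8 * np.exp((V + 114.1) / 8.079))
    tab[:, cIFSS] = iss
    tab[:, cIFEF] = np.exp(-dt / tif)
    tab[:, cISEF] = np.exp(-dt / tis)
    tab[:, cIFEFE] = np.exp(-dt / (tif * delta_epi))
    tab[:, cISEFE] = np.exp(-dt / (tis * delta_epi))
    assp = 1.0 / (1.0 + np.exp(-(V - 24.34) / 14.82))
    rl(assp, ta, cAPSS, cAPEF)
    with np.errstate(over="ignore"):
        dti_dev = 1.354 + 1.0e-4 / (np.exp((V - 167.4) / 15.89)
                                    + np.exp(-(V - 12.23) / 0.2154))
    dti_rec = 1.0 - 0.5 / (1.0 + np.exp((V + 70.0) / 20.0))
    tab[:, cIFPEF] = np.exp(-dt / (dti_dev * dti_rec * tif))
    tab[:, cISPEF] = np.exp(-dt / (dti_dev * dti_rec * tis))
    tab[:, cIFPEFE] = np.exp(-dt / (dti_dev * dti_rec * tif * delta_epi))
    tab[:, cISPEFE] = np.exp(-dt / (dti_dev * dti_rec * tis * delta_epi))
    tab[:, cAIF] = 1.0 / (1.0 + np.exp((V - 213.6) / 151.2))

    # --- I_CaL gating
    dss = 1.0 / (1.0 + np.exp(-(V + 3.94) / 4.23))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (V + 6.0)) + np.exp(0.09 * (V + 14.0)))
    rl(dss, td, cDSS, cDEF)
    fss = 1.0 / (1.0 + np.exp((V + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(V + 20.0) / 10.0)
                       + 0.0045 * np.exp((V + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (3.5e-5 * np.exp(-(V + 5.0) / 4.0)
                          + 3.5e-5 * np.exp((V + 5.0) / 6.0))
    tab[:, cFSS] = fss
    tab[:, cFFEF] = np.exp(-dt / tff)
    tab[:, cFSEF] = np.exp(-dt / tfs)
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(V - 4.0) / 7.0)
                         + 0.04 * np.exp((V - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-V / 3.0)
                           + 0.00012 * np.exp(V / 7.0))
    tab[:, cFCAFEF] = np.exp(-dt / tfcaf)
    tab[:, cFCASEF] = np.exp(-dt / tfcas)
    tab[:, cJCAEF] = np.exp(-dt / 75.0)
    tab[:, cFFPEF] = np.exp(-dt / (2.5 * tff))
    tab[:, cFCAFPEF] = np.exp(-dt / (2.5 * tfcaf))
    tab[:, cAFCAF] = 0.3 + 0.6 / (1.0 + np.exp((V - 10.0) / 10.0))

    # --- I_Ks
    xs1ss = 1.0 / (1.0 + np.exp(-(V + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((V + 48.28) / 17.80)
                          + 0.001292 * np.exp(-(V + 210.0) / 230.0))
    rl(xs1ss, txs1, cXS1SS, cXS1EF)
    txs2 = 1.0 / (0.01 * np.exp((V - 50.0) / 20.0)
                  + 0.0193 * np.exp(-(V + 66.54) / 31.0))
    tab[:, cXS2EF] = np.exp(-dt / txs2)

    # --- I_K1
    xk1ss = 1.0 / (1.0 + np.exp(-(V + 2.5538 * KO + 144.59)
                                / (1.5692 * KO + 3.8115)))
    txk1 = 122.2 / (np.exp(-(V + 127.2) / 20.36) + np.exp((V + 236.8) / 69.33))
    rl(xk1ss, txk1, cXK1SS, cXK1EF)
    tab[:, cRK1] = 1.0 / (1.0 + np.exp((V + 105.8 - 2.6 * KO) / 9.493))

    # --- I_Kb
    tab[:, cXKB] = 1.0 / (1.0 + np.exp(-(V - 14.48) / 18.34))

    # --- GHK prefactors (limits at V = 0 handled analytically)
    vfrt = V / RTF
    vffrt = V * F / RTF
    ev = np.exp(vfrt)
    ev2 = np.exp(2.0 * vfrt)
    tab[:, cEV] = ev
    tab[:, cEV2] = ev2
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = vffrt / (ev - 1.0)
        a2 = 4.0 * vffrt / (ev2 - 1.0)
    a1 = np.where(np.abs(V) < 1e-9, F, a1)
    a2 = np.where(np.abs(V) < 1e-9, 2.0 * F, a2)
    tab[:, cA1] = a1
    tab[:, cA2] = a2

    # --- INaCa / INaK voltage factors
    tab[:, cHCA] = np.exp(0.167 * vfrt)  # qca
    tab[:, cHNA] = np.exp(0.5224 * vfrt)  # qna
    tab[:, cKNAI] = 9.073 * np.exp(-0.155 * vfrt / 3.0)
    tab[:, cKNAO] = 27.78 * np.exp((1.0 + 0.155) * vfrt / 3.0)

    # --- Markov I_Kr rates (activation shared; inactivation per condition)
    for rates, cai_, cbi_, cmu_ in ((rates_wt, cAIWT, cBIWT, cMUWT),
                                    (rates_mut, cAIMUT, cBIMUT, cMUMUT)):
        alpha = rates.a_c12 * np.exp(rates.s_c12 * (V - rates.v0_c12))
        beta = rates.a_c21 * np.exp(-rates.s_c21 * V)
        alpha2 = rates.a_co * np.exp(rates.s_co * (V - rates.v0_co))
        beta2 = rates.a_oc * np.exp(-rates.s_oc * V)
        betai = rates.inact_scale * rates.a_oi * np.exp(rates.s_oi * V)
        alphai = rates.rec_scale * rates.a_io * np.exp(
            -rates.s_io * (V + rates.v0_io))
        mu = alphai * beta2 / betai
        tab[:, cMKA] = alpha
        tab[:, cMKB] = beta
        tab[:, cMKA2] = alpha2
        tab[:, cMKB2] = beta2
        tab[:, cai_] = alphai
        tab[:, cbi_] = betai
        tab[:, cmu_] = mu

    return tab, vmin, 1.0 / dv


@njit(cache=True, inline="always")
def _lk(tab, i0, fr, c):
    return tab[i0, c] + (tab[i0 + 1, c] - tab[i0, c]) * fr


@njit(cache=True, fastmath=True)
def _cell_update(y, p, tab, vmin, inv_dv, dt, istim, dvdiff, cur):
    """One forward-Euler / Rush-Larsen step for one cell (updates in place).

    ``cur`` (length >= 6) receives I_Kr, I_Na, I_CaL, I_Ks, total Na block,
    and the conducting-weighted hERG drug-bound fraction.
    """
    V = y[iV]
    x = (V - vmin) * inv_dv
    i0 = int(x)
    if i0 < 0:
        i0 = 0
        x = 0.0
    elif i0 > tab.shape[0] - 2:
        i0 = tab.shape[0] - 2
        x = float(i0)
    fr = x - i0

    nai = y[iNAI]
    nass = y[iNASS]
    ki = y[iKI]
    kss = y[iKSS]
    cai = y[iCAI]
    cass = y[iCASS]
    cansr = y[iCANSR]
    cajsr = y[iCAJSR]

    ENa = RTF * np.log(NAO / nai)
    EK = RTF * np.log(KO / ki)
    EKs = RTF * np.log((KO + 0.01833 * NAO) / (ki + 0.01833 * nai))

    CaMKb = CAMKO * (1.0 - y[iCAMKT]) / (1.0 + KMCAM / cass)
    CaMKa = CaMKb + y[iCAMKT]
    fphos = 1.0 / (1.0 + KMCAMK / CaMKa)

    # --- I_Na (Luo-Rudy form with guarded-receptor block)
    btot = y[iBA] + y[iBI] + y[iBR]
    m3hj = y[iM] ** 3 * y[iH] * y[iJ]
    INa = p[pGNA] * (1.0 - btot) * m3hj * (V - ENa)

    # --- I_NaL
    INaL = p[pGNAL] * (V - ENa) * y[iML] * (
        (1.0 - fphos) * y[iHL] + fphos * y[iHLP])

    # --- I_to
    AiF = _lk(tab, i0, fr, cAIF)
    ito_i = AiF * y[iIF] + (1.0 - AiF) * y[iIS]
    ito_ip = AiF * y[iIFP] + (1.0 - AiF) * y[iISP]
    Ito = p[pGTO] * (V - EK) * ((1.0 - fphos) * y[iA] * ito_i
                                + fphos * y[iAP] * ito_ip)

    # --- I_CaL / I_CaNa / I_CaK
    ev = _lk(tab, i0, fr, cEV)
    ev2 = _lk(tab, i0, fr, cEV2)
    a1 = _lk(tab, i0, fr, cA1)
    a2 = _lk(tab, i0, fr, cA2)
    PhiCaL = a2 * (cass * ev2 - 0.341 * CAO)
    PhiCaNa = a1 * (0.75 * nass * ev - 0.75 * NAO)
    PhiCaK = a1 * (0.75 * kss * ev - 0.75 * KO)
    Afcaf = _lk(tab, i0, fr, cAFCAF)
    f = 0.6 * y[iFF] + 0.4 * y[iFS]
    fca = Afcaf * y[iFCAF] + (1.0 - Afcaf) * y[iFCAS]
    fp = 0.6 * y[iFFP] + 0.4 * y[iFS]
    fcap = Afcaf * y[iFCAFP] + (1.0 - Afcaf) * y[iFCAS]
    PCa = p[pPCA]
    PCap = 1.1 * PCa
    gate_np = y[iDG] * (f * (1.0 - y[iNCA]) + y[iJCA] * fca * y[iNCA])
    gate_p = y[iDG] * (fp * (1.0 - y[iNCA]) + y[iJCA] * fcap * y[iNCA])
    ICaL = (1.0 - fphos) * PCa * PhiCaL * gate_np + fphos * PCap * PhiCaL * gate_p
    ICaNa = ((1.0 - fphos) * 0.00125 * PCa * PhiCaNa * gate_np
             + fphos * 0.00125 * PCap * PhiCaNa * gate_p)
    ICaK = ((1.0 - fphos) * 3.574e-4 * PCa * PhiCaK * gate_np
            + fphos * 3.574e-4 * PCap * PhiCaK * gate_p)

    # --- I_Kr from the two Markov populations (only O conducts)
    wmut = p[pWMUT]
    O1 = y[iMK1 + 3]
    O2 = y[iMK2 + 3]
    IKr = p[pGKR] * ((1.0 - wmut) * O1 + wmut * O2) * (V - EK)

    # --- I_Ks
    ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    IKs = p[pGKS] * ksca * y[iXS1] * y[iXS2] * (V - EKs)

    # --- I_K1 (gK1 parameter already includes sqrt(ko))
    IK1 = p[pGK1] * _lk(tab, i0, fr, cRK1) * y[iXK1] * (V - EK)

    # --- INaCa (myoplasmic and subspace components)
    hca = _lk(tab, i0, fr, cHCA)
    hna = _lk(tab, i0, fr, cHNA)
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    gncx = p[pGNCX]
    inaca_i = 0.0
    inaca_ss = 0.0
    for comp in range(2):
        if comp == 0:
            na = nai
            ca = cai
            frac = 0.8
        else:
            na = nass
            ca = cass
            frac = 0.2
        h1 = 1.0 + na / kna3 * (1.0 + hna)
        h2 = (na * hna) / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + na / kna1 * (1.0 + na / kna2)
        h5 = na * na / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        h7 = 1.0 + NAO / kna3 * (1.0 + 1.0 / hna)
        h8 = NAO / (kna3 * hna * h7)
        h9 = 1.0 / h7
        h10 = 12.5 + 1.0 + NAO / kna1 * (1.0 + NAO / kna2)
        h11 = NAO * NAO / (h10 * kna1 * kna2)
        h12 = 1.0 / h10
        k1 = h12 * CAO * kcaon
        k2 = kcaoff
        k3p = h9 * wca
        k3pp = h8 * wnaca
        k3 = k3p + k3pp
        k4p = h3 * wca / hca
        k4pp = h2 * wnaca
        k4 = k4p + k4pp
        k5 = kcaoff
        k6 = h6 * ca * kcaon
        k7 = h5 * h2 * wna
        k8 = h8 * h11 * wna
        x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
        x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
        x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
        x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
        s = x1 + x2 + x3 + x4
        e1 = x1 / s
        e2 = x2 / s
        e3 = x3 / s
        e4 = x4 / s
        allo = 1.0 / (1.0 + (1.5e-4 / ca) ** 2)
        jna = 3.0 * (e4 * k7 - e1 * k8) + e3 * k4pp - e2 * k3pp
        jca = e2 * k2 - e1 * k1
        cur_nc = frac * gncx * allo * (jna + 2.0 * jca)
        if comp == 0:
            inaca_i = cur_nc
        else:
            inaca_ss = cur_nc

    # --- INaK
    knai = _lk(tab, i0, fr, cKNAI)
    knao = _lk(tab, i0, fr, cKNAO)
    kki = 0.5
    kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    Hc = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P_ = eP / (1.0 + Hc / Khp + nai / Knap + ki / Kxkur)
    d_nai = (1.0 + nai / knai) ** 3 + (1.0 + ki / kki) ** 2 - 1.0
    d_nao = (1.0 + NAO / knao) ** 3 + (1.0 + KO / kko) ** 2 - 1.0
    a1k = 949.5 * (nai / knai) ** 3 / d_nai
    b1k = 182.4 * MgADP
    a2k = 687.2
    b2k = 39.4 * (NAO / knao) ** 3 / d_nao
    a3k = 1899.0 * (KO / kko) ** 2 / d_nao
    b3k = 79300.0 * P_ * Hc / (1.0 + MgATP / Kmgatp)
    a4k = 639.0 * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
    b4k = 40.0 * (ki / kki) ** 2 / d_nai
    x1 = a4k * a1k * a2k + b2k * b4k * b3k + a2k * b4k * b3k + b3k * a1k * a2k
    x2 = b2k * b1k * b4k + a1k * a2k * a3k + a3k * b1k * b4k + a2k * a3k * b4k
    x3 = a2k * a3k * a4k + b3k * b2k * b1k + b2k * b1k * a4k + a3k * a4k * b1k
    x4 = b4k * b3k * b2k + a3k * a4k * a1k + b2k * a4k * a1k + b3k * b2k * a1k
    s = x1 + x2 + x3 + x4
    e1 = x1 / s
    e2 = x2 / s
    e3 = x3 / s
    e4 = x4 / s
    JnakNa = 3.0 * (e1 * a3k - e2 * b3k)
    JnakK = 2.0 * (e4 * b1k - e3 * a1k)
    INaK = p[pPNAK] * (JnakNa + JnakK)

    # --- background / pump currents
    IKb = p[pGKB] * _lk(tab, i0, fr, cXKB) * (V - EK)
    INab = 3.75e-10 * a1 * (nai * ev - NAO)
    ICab = 2.5e-8 * a2 * (cai * ev2 - 0.341 * CAO)
    IpCa = 0.0005 * cai / (0.0005 + cai)

    Iion = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
            + inaca_i + inaca_ss + INaK + INab + IKb + IpCa + ICab)

    # ------------------------------------------------------- state updates
    # HH gates (Rush-Larsen with tabulated per-step decay factors)
    is_epi = p[pEPI] > 0.5
    y[iM] = _lk(tab, i0, fr, cMSS) + (y[iM] - _lk(tab, i0, fr, cMSS)) * _lk(tab, i0, fr, cMEF)
    y[iH] = _lk(tab, i0, fr, cHSS) + (y[iH] - _lk(tab, i0, fr, cHSS)) * _lk(tab, i0, fr, cHEF)
    y[iJ] = _lk(tab, i0, fr, cJSS) + (y[iJ] - _lk(tab, i0, fr, cJSS)) * _lk(tab, i0, fr, cJEF)
    y[iML] = _lk(tab, i0, fr, cMLSS) + (y[iML] - _lk(tab, i0, fr, cMLSS)) * _lk(tab, i0, fr, cMLEF)
    y[iHL] = _lk(tab, i0, fr, cHLSS) + (y[iHL] - _lk(tab, i0, fr, cHLSS)) * _lk(tab, i0, fr, cHLEF)
    y[iHLP] = _lk(tab, i0, fr, cHLPSS) + (y[iHLP] - _lk(tab, i0, fr, cHLPSS)) * _lk(tab, i0, fr, cHLPEF)
    y[iA] = _lk(tab, i0, fr, cASS) + (y[iA] - _lk(tab, i0, fr, cASS)) * _lk(tab, i0, fr, cAEF)
    iss = _lk(tab, i0, fr, cIFSS)
    if is_epi:
        y[iIF] = iss + (y[iIF] - iss) * _lk(tab, i0, fr, cIFEFE)
        y[iIS] = iss + (y[iIS] - iss) * _lk(tab, i0, fr, cISEFE)
        y[iIFP] = iss + (y[iIFP] - iss) * _lk(tab, i0, fr, cIFPEFE)
        y[iISP] = iss + (y[iISP] - iss) * _lk(tab, i0, fr, cISPEFE)
    else:
        y[iIF] = iss + (y[iIF] - iss) * _lk(tab, i0, fr, cIFEF)
        y[iIS] = iss + (y[iIS] - iss) * _lk(tab, i0, fr, cISEF)
        y[iIFP] = iss + (y[iIFP] - iss) * _lk(tab, i0, fr, cIFPEF)
        y[iISP] = iss + (y[iISP] - iss) * _lk(tab, i0, fr, cISPEF)
    y[iAP] = _lk(tab, i0, fr, cAPSS) + (y[iAP] - _lk(tab, i0, fr, cAPSS)) * _lk(tab, i0, fr, cAPEF)
    y[iDG] = _lk(tab, i0, fr, cDSS) + (y[iDG] - _lk(tab, i0, fr, cDSS)) * _lk(tab, i0, fr, cDEF)
    fss = _lk(tab, i0, fr, cFSS)
    y[iFF] = fss + (y[iFF] - fss) * _lk(tab, i0, fr, cFFEF)
    y[iFS] = fss + (y[iFS] - fss) * _lk(tab, i0, fr, cFSEF)
    y[iFCAF] = fss + (y[iFCAF] - fss) * _lk(tab, i0, fr, cFCAFEF)
    y[iFCAS] = fss + (y[iFCAS] - fss) * _lk(tab, i0, fr, cFCASEF)
    y[iJCA] = fss + (y[iJCA] - fss) * _lk(tab, i0, fr, cJCAEF)
    y[iFFP] = fss + (y[iFFP] - fss) * _lk(tab, i0, fr, cFFPEF)
    y[iFCAFP] = fss + (y[iFCAFP] - fss) * _lk(tab, i0, fr, cFCAFPEF)
    xs1ss = _lk(tab, i0, fr, cXS1SS)
    y[iXS1] = xs1ss + (y[iXS1] - xs1ss) * _lk(tab, i0, fr, cXS1EF)
    y[iXS2] = xs1ss + (y[iXS2] - xs1ss) * _lk(tab, i0, fr, cXS2EF)
    y[iXK1] = _lk(tab, i0, fr, cXK1SS) + (y[iXK1] - _lk(tab, i0, fr, cXK1SS)) * _lk(tab, i0, fr, cXK1EF)

    # nca (Euler)
    km2n = y[iJCA]
    anca = 1.0 / (1000.0 / km2n + (1.0 + 0.002 / cass) ** 4)
    y[iNCA] += dt * (anca * 1000.0 - y[iNCA] * km2n)

    # CaMK
    y[iCAMKT] += dt * (ACAMK * CaMKb * CaMKa - BCAMK * y[iCAMKT])

    # SR release
    relsc = p[pJRELSC]
    bt = 4.75
    jrel_inf = relsc * (0.5 * bt) * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    y[iJRELNP] += dt * (jrel_inf - y[iJRELNP]) / tau_rel
    btp = 1.25 * bt
    jrel_infp = relsc * (0.5 * btp) * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    y[iJRELP] += dt * (jrel_infp - y[iJRELP]) / tau_relp
    Jrel = (1.0 - fphos) * y[iJRELNP] + fphos * y[iJRELP]

    # SERCA uptake / leak / translocation
    upsc = p[pJUPSC]
    Jupnp = upsc * 0.004375 * cai / (cai + 0.00092)
    Jupp = upsc * 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = (1.0 - fphos) * Jupnp + fphos * Jupp - Jleak
    Jtr = (cansr - cajsr) / 100.0

    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    AF = ACAP / F
    y[iNAI] += dt * (-(INa + INaL + 3.0 * inaca_i + 3.0 * INaK + INab)
                     * AF / VMYO + JdiffNa * VSS / VMYO)
    y[iNASS] += dt * (-(ICaNa + 3.0 * inaca_ss) * AF / VSS - JdiffNa)
    y[iKI] += dt * (-(Ito + IKr + IKs + IK1 + IKb + istim - 2.0 * INaK)
                    * AF / VMYO + JdiffK * VSS / VMYO)
    y[iKSS] += dt * (-ICaK * AF / VSS - JdiffK)
    cmdn = p[pCMDNSC] * 0.05
    bcai = 1.0 / (1.0 + cmdn * 0.00238 / (0.00238 + cai) ** 2
                  + 0.07 * 0.0005 / (0.0005 + cai) ** 2)
    y[iCAI] += dt * bcai * (-(IpCa + ICab - 2.0 * inaca_i) * AF / (2.0 * VMYO)
                            - Jup * VNSR / VMYO + Jdiff * VSS / VMYO)
    bcass = 1.0 / (1.0 + 0.047 * 0.00087 / (0.00087 + cass) ** 2
                   + 1.124 * 0.0087 / (0.0087 + cass) ** 2)
    y[iCASS] += dt * bcass * (-(ICaL - 2.0 * inaca_ss) * AF / (2.0 * VSS)
                              + Jrel * VJSR / VSS - Jdiff)
    y[iCANSR] += dt * (Jup - Jtr * VJSR / VNSR)
    bcajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + cajsr) ** 2)
    y[iCAJSR] += dt * bcajsr * (Jtr - Jrel)

    # --- Markov I_Kr populations (explicit Euler; conservative by design)
    D = p[pDRUG]
    mka = _lk(tab, i0, fr, cMKA)
    mkb = _lk(tab, i0, fr, cMKB)
    mka2 = _lk(tab, i0, fr, cMKA2)
    mkb2 = _lk(tab, i0, fr, cMKB2)
    for pop in range(2):
        if pop == 0:
            base = iMK1
            ai = _lk(tab, i0, fr, cAIWT)
            bi = _lk(tab, i0, fr, cBIWT)
            mu = _lk(tab, i0, fr, cMUWT)
            kA = p[pKA1] * D
            lA = p[pLA1]
            kI = p[pKI1] * D
            lI = p[pLI1]
        else:
            base = iMK2
            ai = _lk(tab, i0, fr, cAIMUT)
            bi = _lk(tab, i0, fr, cBIMUT)
            mu = _lk(tab, i0, fr, cMUMUT)
            kA = p[pKA2] * D
            lA = p[pLA2]
            kI = p[pKI2] * D
            lI = p[pLI2]
        C1 = y[base]
        C2 = y[base + 1]
        C3 = y[base + 2]
        O = y[base + 3]
        I = y[base + 4]
        Os = y[base + 5]
        Is = y[base + 6]
        dC1 = mkb * C2 - mka * C1
        dC2 = mka * C1 + MK_B1 * C3 - (mkb + MK_A1) * C2
        dC3 = MK_A1 * C2 + mkb2 * O + mu * I - (MK_B1 + 2.0 * mka2) * C3
        dI = mka2 * C3 + bi * O + lI * Is - (mu + ai + kI) * I
        dO = mka2 * C3 + ai * I + lA * Os - (mkb2 + bi + kA) * O
        dOs = kA * O - lA * Os
        dIs = kI * I - lI * Is
        y[base] = C1 + dt * dC1
        y[base + 1] = C2 + dt * dC2
        y[base + 2] = C3 + dt * dC3
        y[base + 3] = O + dt * dO
        y[base + 4] = I + dt * dI
        y[base + 5] = Os + dt * dOs
        y[base + 6] = Is + dt * dIs

    # --- guarded-receptor Na block pools
    free = 1.0 - btot
    hj = y[iH] * y[iJ]
    m3 = y[iM] ** 3
    y[iBA] += dt * (p[pKAN] * D * m3 * hj * free - p[pLAN] * y[iBA])
    y[iBI] += dt * (p[pKIN] * D * (1.0 - hj) * free - p[pLIN] * y[iBI])
    y[iBR] += dt * (p[pKRN] * D * (1.0 - m3) * hj * free - p[pLRN] * y[iBR])

    # --- membrane potential
    y[iV] = V + dt * (-(Iion + istim) + dvdiff)

    cur[0] = IKr
    cur[1] = INa
    cur[2] = ICaL
    cur[3] = IKs
    cur[4] = btot
    herg_tot = ((1.0 - wmut) * (y[iMK1 + 5] + y[iMK1 + 6])
                + wmut * (y[iMK2 + 5] + y[iMK2 + 6]))
    cur[5] = herg_tot
    return Iion


@njit(cache=True, fastmath=True)
def advance(Y, P, tab, vmin, inv_dv, dt, nsteps, t0,
            stim_mask, amp, dur, period, start,
            s2_mask, amp2, dur2, start2,
            Dif, inv_dx2, coupled,
            rec_stride, out_V, out_cur, rec_currents,
            periodic=False):
    """Advance N cells (optionally resistively coupled as a 1D cable).

    Y: (N, NS) states, updated in place.  P: (N, NP) per-cell parameters.
    Dif: interface diffusion coefficients (mm^2/ms) when coupled — length
    N-1 for a no-flux cable, length N for a periodic ring (entry N-1
    couples the last and first nodes).
    Records V (and currents) every ``rec_stride`` steps.
    """
    n = Y.shape[0]
    cur = np.zeros(6)
    diff = np.zeros(n)
    irec = 0
    for k in range(nsteps):
        t = t0 + k * dt
        if coupled:
            for i in range(n):
                acc = 0.0
                if i > 0:
                    acc += Dif[i - 1] * (Y[i - 1, iV] - Y[i, iV])
                elif periodic:
                    acc += Dif[n - 1] * (Y[n - 1, iV] - Y[i, iV])
                if i < n - 1:
                    acc += Dif[i] * (Y[i + 1, iV] - Y[i, iV])
                elif periodic:
                    acc += Dif[n - 1] * (Y[0, iV] - Y[i, iV])
                diff[i] = acc * inv_dx2
        s1_on = False
        if period > 0.0:
            tm = (t - start) % period
            s1_on = t >= start and tm < dur
        s2_on = amp2 != 0.0 and start2 <= t < start2 + dur2
        for i in range(n):
            istim = 0.0
            if s1_on and stim_mask[i]:
                istim = amp
            if s2_on and s2_mask[i]:
                istim += amp2
            _cell_update(Y[i], P[i], tab, vmin, inv_dv, dt, istim,
                         diff[i] if coupled else 0.0, cur)
            if rec_currents and (k + 1) % rec_stride == 0:
                out_cur[irec, i, 0] = cur[0]
                out_cur[irec, i, 1] = cur[1]
                out_cur[irec, i, 2] = cur[2]
                out_cur[irec, i, 3] = cur[3]
                out_cur[irec, i, 4] = cur[4]
                out_cur[irec, i, 5] = cur[5]
        if (k + 1) % rec_stride == 0:
            for i in range(n):
                out_V[irec, i] = Y[i, iV]
            irec += 1
    return irec


@njit(cache=True, fastmath=True)
def advance_sheet(Y, P, tab, vmin, inv_dv, dt, nsteps, t0,
                  ny, nx, Dcoef, inv_dx2,
                  rec_stride, pecg_wx, pecg_wy, out_pecg,
                  probe_idx, out_probes,
                  field_stride, out_field):
    """Advance a 2D isotropic monodomain sheet (no-flux boundaries).

    Records a far-field unipolar pseudo-ECG each ``rec_stride`` steps using
    precomputed lead-field weights, voltage at probe nodes, and (optionally,
    if out_field is non-empty) the decimated V field every ``field_stride``
    recorded samples.
    """
    n = ny * nx
    cur = np.zeros(6)
    diff = np.zeros(n)
    irec = 0
    ifield = 0
    for k in range(nsteps):
        for iy in range(ny):
            for ix in range(nx):
                idx = iy * nx + ix
                v = Y[idx, iV]
                acc = 0.0
                if ix > 0:
                    acc += Y[idx - 1, iV] - v
                if ix < nx - 1:
                    acc += Y[idx + 1, iV] - v
                if iy > 0:
                    acc += Y[idx - nx, iV] - v
                if iy < ny - 1:
                    acc += Y[idx + nx, iV] - v
                diff[idx] = Dcoef * acc * inv_dx2
        for idx in range(n):
            _cell_update(Y[idx], P[idx], tab, vmin, inv_dv, dt, 0.0,
                         diff[idx], cur)
        if (k + 1) % rec_stride == 0:
            # pseudo-ECG: sum of (-grad V) . grad(1/r) via lead-field weights
            phi = 0.0
            for iy in range(ny):
                for ix in range(nx):
                    idx = iy * nx + ix
                    ixm = idx - 1 if ix > 0 else idx
                    ixp = idx + 1 if ix < nx - 1 else idx
                    iym = idx - nx if iy > 0 else idx
                    iyp = idx + nx if iy < ny - 1 else idx
                    dvx = 0.5 * (Y[ixp, iV] - Y[ixm, iV])
                    dvy = 0.5 * (Y[iyp, iV] - Y[iym, iV])
                    phi += dvx * pecg_wx[idx] + dvy * pecg_wy[idx]
            out_pecg[irec] = phi
            for pj in range(probe_idx.shape[0]):
                out_probes[irec, pj] = Y[probe_idx[pj], iV]
            if out_field.shape[0] > 0 and irec % field_stride == 0:
                if ifield < out_field.shape[0]:
                    for idx in range(n):
                        out_field[ifield, idx] = Y[idx, iV]
                    ifield += 1
            irec += 1
    return irec


@njit(cache=True, fastmath=True)
def clamp_na_block(Vseq, seg_steps, dt, D,
                   kA, lA, kI, lI, kR, lR,
                   out_peak_open):
    """Voltage-clamp the Luo-Rudy gates + guarded-receptor pools.

    Vseq/seg_steps describe piecewise-constant clamp segments.  Records, per
    segment, the peak unblocked availability (1-b)*m^3*h*j (proportional to
    peak I_Na at fixed driving force).
    """
    m = 0.0
    h = 1.0
    j = 1.0
    bA = 0.0
    bI = 0.0
    bR = 0.0
    for seg in range(Vseq.shape[0]):
        V = Vseq[seg]
        x = V + 47.13
        if abs(x) < 1e-6:
            am = 3.2
        else:
            am = 0.32 * x / (1.0 - np.exp(-0.1 * x))
        bm = 0.08 * np.exp(-V / 11.0)
        if V < -40.0:
            ah = 0.135 * np.exp(-(80.0 + V) / 6.8)
            bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
            aj = ((-1.2714e5 * np.exp(0.2444 * V)
                   - 3.474e-5 * np.exp(-0.04391 * V))
                  * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
            bj = (0.1212 * np.exp(-0.01052 * V)
                  / (1.0 + np.exp(-0.1378 * (V + 40.14))))
        else:
            ah = 0.0
            bh = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
            aj = 0.0
            bj = (0.3 * np.exp(-2.535e-7 * V)
                  / (1.0 + np.exp(-0.1 * (V + 32.0))))
        mss = am / (am + bm)
        mef = np.exp(-dt * (am + bm))
        hss = ah / (ah + bh)
        hef = np.exp(-dt * (ah + bh))
        jss = aj / (aj + bj)
        jef = np.exp(-dt * (aj + bj))
        peak = 0.0
        for k in range(seg_steps[seg]):
            m = mss + (m - mss) * mef
            h = hss + (h - hss) * hef
            j = jss + (j - jss) * jef
            free = 1.0 - bA - bI - bR
            m3 = m ** 3
            hj = h * j
            bA += dt * (kA * D * m3 * hj * free - lA * bA)
            bI += dt * (kI * D * (1.0 - hj) * free - lI * bI)
            bR += dt * (kR * D * (1.0 - m3) * hj * free - lR * bR)
            avail = (1.0 - bA - bI - bR) * m3 * hj
            if avail > peak:
                peak = avail
        out_peak_open[seg] = peak
    return bA + bI + bR
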