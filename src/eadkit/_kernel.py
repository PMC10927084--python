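"""Compiled right-hand side and explicit-Euler integrator.

The physics lives in :func:`_rhs`; the integration loop in
:func:`integrate_kernel`.  Both are numba-compiled; everything above this
module works with plain numpy arrays.

Unit conventions: time ms, voltage mV, concentrations mM, currents A/F
(equivalently pA/pF), volumes litres.  A membrane current ``I`` (A/F)
moves ``I * CM / (z * FARADAY)`` mmol of its ion per ms.
"""

import numpy as np
from numba import njit

from ._indices import (
    IV, IM, IH, IJ, ID, IF, IXR, IXS, IXTO, IYTO, IFCAJ, IFCASL,
    ICAJ, ICASL, ICAI, ICAJSR, ICANSR,
    IRYR_R, IRYR_O, IRYR_I, IRYR_RI, INAI,
    IBTNCL, IBTNCH, IBCAM, IBMYO, IBSRB,
    IBSLLJ, IBSLHJ, IBSLLSL, IBSLHSL, IF2, NSTATE,
    P_KMAX, P_JCASLMYO, P_PCA, P_GKS, P_INCXBAR, P_GNA, P_GKR, P_GK1,
    P_GTO, P_GCAB, P_GNAB, P_IBARNAK, P_IBARPCA, P_VMAXUP, P_KMF, P_KMR,
    P_HUP, P_TAUTR, P_KLEAK, P_JCAJXNSL, P_KOCA, P_KICA, P_KOM, P_KIM,
    P_EC50SR, P_MAXSR, P_MINSR, P_NAO, P_KO, P_CAO, P_KI,
    P_FSS_FLAT, P_FSS_VMIN, P_FSS_FMIN, P_FXCALJ, P_FXJ, P_ZEROCAFLUX,
    P_XS_VMID, P_XS_SLOPE, P_TAUXS_LO, P_TAUXS_HI, P_TAUF_SCALE,
    P_FSS_HAMP, P_FSS_HVMID, P_FSS_SLOPE, P_SRHILL,
    P_F2_VMID, P_F2_SLOPE, P_TAUF2, P_FSS_HSLOPE,
    C_IION, C_ISTI, C_INA, C_INAB, C_INAK, C_IKR, C_IKS, C_IK1, C_ITO,
    C_ICAL, C_ICAB, C_IPCA, C_INCX, C_ICALJ, C_ICALSL, C_INCXJ, C_INCXSL,
    C_IKSJ, C_IKSSL, NCUR,
    CL_CASUB, CL_VM, CL_ICAL, CL_INCX, CM_CONST, CM_TRACE, CM_RAMP,
)

FARADAY = 96485.0       # C/mol
RTONF = 26.712338       # RT/F at 310 K, mV
FORT = 1.0 / RTONF      # mV^-1
CM = 1.381e-10          # F, whole-cell capacitance

# cell geometry (litres); 33 pL cell, SB-style partitioning with the SR
# split 10/90 into junctional and network stores
VCELL = 3.3e-11
VMYO = 0.65 * VCELL
VSR = 0.035 * VCELL
VJSR = 0.1 * VSR
VNSR = 0.9 * VSR
VSL = 0.02 * VCELL
VJXN = 0.005 * VCELL

# sarcolemmal buffers (local Bmax, mM; kon mM^-1 ms^-1; koff ms^-1).
# The high-affinity site is kinetically slow, so both are ODE buffers.
BL_JXN = 0.60
BH_JXN = 0.215
BL_SL = 1.215
BH_SL = 0.4355
# effective (diffusion-limited) on-rates; Kd as in the parent model
KON_SLL = 10.0
KOFF_SLL = 0.13
KON_SLH = 10.0
KOFF_SLH = 0.003
KD_L = KOFF_SLL / KON_SLL
KD_H = KOFF_SLH / KON_SLH
# calsequestrin (JSR, fast -> rapid-buffer approximation)
B_CSQN = 26.0
KD_CSQN = 0.65

# cytosolic buffer constants: Bmax (mM), kon (mM^-1 ms^-1), koff (ms^-1)
BUF_TNCL = (0.07, 32.7, 0.0196)
BUF_TNCH = (0.14, 2.37, 3.2e-5)
BUF_CAM = (0.024, 34.0, 0.238)
BUF_MYO = (0.14, 13.8, 4.6e-4)
BUF_SRB = (0.0171, 100.0, 0.06)

# NCX kinetics (SB-style)
NCX_KMCAI = 0.00359
NCX_KMCAO = 1.3
NCX_KMNAI = 12.29
NCX_KMNAO = 87.5
NCX_KSAT = 0.27
NCX_ETA = 0.35
NCX_KDACT = 0.000256

# Ca-dependent inactivation gate of I_CaL
FCA_KON = 3.0      # mM^-1 ms^-1
FCA_KOFF = 0.0119  # ms^-1


@njit(cache=True, fastmath=True)
def fss_curve(v, hamp, hvmid, slope, hslope, flat, vmin, fmin):
    """Steady-state voltage inactivation of I_CaL.

    The control curve is non-monotonic: a falling sigmoid plus a rising
    late component (amplitude ``hamp``, midpoint ``hvmid``).  The
    flattened variant holds the curve at its minimum for voltages above
    the argmin.
    """
    val = 1.0 / (1.0 + np.exp((v + 35.06) / slope)) \
        + hamp / (1.0 + np.exp((hvmid - v) / hslope))
    if val > 1.0:
        val = 1.0
    if flat > 0.5 and v > vmin:
        val = fmin
    return val


@njit(cache=True, fastmath=True)
def _ghk_ca(v, ca_in, cao, pca):
    """GHK Ca flux of I_CaL in A/F for permeability pca (cm/s)."""
    if -1e-4 < v < 1e-4:
        v = 1e-4
    x = 2.0 * v * FORT
    ex = np.exp(x)
    return pca * 4.0 * v * FARADAY * FORT * 0.45 \
        * (0.341 * ca_in * ex - 0.341 * cao) / (ex - 1.0)


@njit(cache=True, fastmath=True)
def _ncx(v, nai, ca, nao, cao, ibar):
    """SB-style NCX current density (A/F); positive = reverse mode (Ca in)."""
    ka = 1.0 / (1.0 + (NCX_KDACT / ca) ** 2)
    na3 = nai ** 3
    nao3 = nao ** 3
    ef = np.exp(NCX_ETA * v * FORT)
    er = np.exp((NCX_ETA - 1.0) * v * FORT)
    num = ef * na3 * cao - er * nao3 * ca
    den = (NCX_KMCAI * nao3 * (1.0 + (nai / NCX_KMNAI) ** 3)
           + NCX_KMNAO ** 3 * ca * (1.0 + ca / NCX_KMCAI)
           + NCX_KMCAO * na3 + na3 * cao + nao3 * ca)
    return ibar * ka * num / (den * (1.0 + NCX_KSAT * er))


@njit(cache=True, fastmath=True)
def rhs(y, p, isti,
        ca_clamped, v_clamped, ical_clamped, ical_value,
        incx_clamped, incx_value, dy, cur, gate_inf, gate_tau):
    """Time derivatives and current snapshot at one state.

    Clamp contract: a clamped state variable gets derivative exactly 0; a
    clamped current is substituted both in the voltage equation and in the
    ion-flux equations.  ``gate_inf``/``gate_tau`` (length 9) receive the
    steady states and time constants of the HH gates m..yto so the
    integrator can advance them with exponential (Rush-Larsen) updates.
    """
    v = y[IV]
    nai = y[INAI]
    caj = y[ICAJ]
    casl = y[ICASL]
    cai = y[ICAI]
    cajsr = y[ICAJSR]
    cansr = y[ICANSR]

    nao = p[P_NAO]
    ko = p[P_KO]
    cao = p[P_CAO]
    ki = p[P_KI]

    ena = RTONF * np.log(nao / nai)
    ek = RTONF * np.log(ko / ki)
    eks = RTONF * np.log((ko + 0.01833 * nao) / (ki + 0.01833 * nai))

    # --- I_Na (m^3 h j) ---
    if -47.130001 < v < -47.129999:
        am = 3.2
    else:
        am = 0.32 * (v + 47.13) / (1.0 - np.exp(-0.1 * (v + 47.13)))
    bm = 0.08 * np.exp(-v / 11.0)
    if v >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    else:
        ah = 0.135 * np.exp(-(80.0 + v) / 6.8)
        bh = 3.56 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.35 * v)
        aj = (-1.2714e5 * np.exp(0.2444 * v) - 3.474e-5 * np.exp(-0.04391 * v)) \
            * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23)))
        bj = 0.1212 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    dy[IM] = am * (1.0 - y[IM]) - bm * y[IM]
    dy[IH] = ah * (1.0 - y[IH]) - bh * y[IH]
    dy[IJ] = aj * (1.0 - y[IJ]) - bj * y[IJ]
    gate_inf[IM - 1] = am / (am + bm)
    gate_tau[IM - 1] = 1.0 / (am + bm)
    gate_inf[IH - 1] = ah / (ah + bh)
    gate_tau[IH - 1] = 1.0 / (ah + bh)
    gate_inf[IJ - 1] = aj / (aj + bj)
    gate_tau[IJ - 1] = 1.0 / (aj + bj)
    ina = p[P_GNA] * y[IM] ** 3 * y[IH] * y[IJ] * (v - ena)
    inab = p[P_GNAB] * (v - ena)

    # --- I_NaK ---
    sigma = (np.exp(nao / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * v * FORT)
                  + 0.0365 * sigma * np.exp(-v * FORT))
    inak = p[P_IBARNAK] * fnak * ko / (ko + 1.5) / (1.0 + (11.0 / nai) ** 4)

    # --- I_Kr ---
    xrss = 1.0 / (1.0 + np.exp(-(v + 10.0) / 5.0))
    if -7.000001 < v < -6.999999:
        axr = 1.38e-3 * 10.0
    else:
        axr = 1.38e-3 * (v + 7.0) / (1.0 - np.exp(-0.123 * (v + 7.0)))
    if -10.000001 < v < -9.999999:
        bxr = 6.1e-4 / 0.145
    else:
        bxr = 6.1e-4 * (v + 10.0) / (np.exp(0.145 * (v + 10.0)) - 1.0)
    tauxr = 1.0 / (axr + bxr)
    dy[IXR] = (xrss - y[IXR]) / tauxr
    gate_inf[IXR - 1] = xrss
    gate_tau[IXR - 1] = tauxr
    rkr = 1.0 / (1.0 + np.exp((v + 33.0) / 22.4))
    ikr = p[P_GKR] * np.sqrt(ko / 5.4) * y[IXR] * rkr * (v - ek)

    # --- I_Ks ---
    # right-shifted activation keeps I_Ks a slowly building, moderate
    # repolarizing current at plateau voltages; deactivation below the
    # plateau is comparatively fast, which lets the current wane during
    # the dip of an afterdepolarization cycle
    xsss = 1.0 / (1.0 + np.exp(-(v - p[P_XS_VMID]) / p[P_XS_SLOPE]))
    tauxs = p[P_TAUXS_LO] + p[P_TAUXS_HI] / (1.0 + np.exp(-(v + 5.0) / 9.0))
    dy[IXS] = (xsss - y[IXS]) / tauxs
    gate_inf[IXS - 1] = xsss
    gate_tau[IXS - 1] = tauxs
    iks = p[P_GKS] * y[IXS] ** 2 * (v - eks)
    fxj = p[P_FXJ]
    iksj = fxj * iks
    ikssl = (1.0 - fxj) * iks

    # --- I_K1 ---
    ak1 = 1.02 / (1.0 + np.exp(0.2385 * (v - ek - 59.215)))
    bk1 = (0.49124 * np.exp(0.08032 * (v - ek + 5.476))
           + np.exp(0.06175 * (v - ek - 594.31))) \
        / (1.0 + np.exp(-0.5143 * (v - ek + 4.753)))
    ik1 = p[P_GK1] * np.sqrt(ko / 5.4) * ak1 / (ak1 + bk1) * (v - ek)

    # --- I_to ---
    xtoss = 1.0 / (1.0 + np.exp(-(v + 3.0) / 15.0))
    ytoss = 1.0 / (1.0 + np.exp((v + 33.5) / 10.0))
    tauxto = 9.0 / (1.0 + np.exp((v + 3.0) / 15.0)) + 0.5
    tauyto = 3000.0 / (1.0 + np.exp((v + 60.0) / 10.0)) + 30.0
    dy[IXTO] = (xtoss - y[IXTO]) / tauxto
    dy[IYTO] = (ytoss - y[IYTO]) / tauyto
    gate_inf[IXTO - 1] = xtoss
    gate_tau[IXTO - 1] = tauxto
    gate_inf[IYTO - 1] = ytoss
    gate_tau[IYTO - 1] = tauyto
    ito = p[P_GTO] * y[IXTO] * y[IYTO] * (v - ek)

    # --- I_CaL gating ---
    dss = 1.0 / (1.0 + np.exp(-(v + 14.5) / 6.0))
    if -14.500001 < v < -14.499999:
        taud = 1.0 / (0.035 * 6.0 * 2.0)  # limit of dss*(1-e^-x)/(0.035(V+14.5))
    else:
        taud = dss * (1.0 - np.exp(-(v + 14.5) / 6.0)) / (0.035 * (v + 14.5))
    fss = fss_curve(v, p[P_FSS_HAMP], p[P_FSS_HVMID], p[P_FSS_SLOPE],
                    p[P_FSS_HSLOPE],
                    p[P_FSS_FLAT], p[P_FSS_VMIN], p[P_FSS_FMIN])
    tauf = p[P_TAUF_SCALE] / (0.0197 * np.exp(-(0.0337 * (v + 14.5)) ** 2) + 0.02)
    dy[ID] = (dss - y[ID]) / taud
    dy[IF] = (fss - y[IF]) / tauf
    gate_inf[ID - 1] = dss
    gate_tau[ID - 1] = taud
    gate_inf[IF - 1] = fss
    gate_tau[IF - 1] = tauf
    dy[IFCAJ] = FCA_KON * caj * (1.0 - y[IFCAJ]) - FCA_KOFF * y[IFCAJ]
    dy[IFCASL] = FCA_KON * casl * (1.0 - y[IFCASL]) - FCA_KOFF * y[IFCASL]
    # slow voltage-dependent inactivation: terminates multi-second
    # plateau hovers without affecting sub-second repolarization
    f2ss = 1.0 / (1.0 + np.exp((v - p[P_F2_VMID]) / p[P_F2_SLOPE]))
    dy[IF2] = (f2ss - y[IF2]) / p[P_TAUF2]

    fxcalj = p[P_FXCALJ]
    gate = y[ID] * y[IF] * y[IF2]
    icalj = fxcalj * _ghk_ca(v, caj, cao, p[P_PCA]) * gate * (1.0 - y[IFCAJ])
    icalsl = (1.0 - fxcalj) * _ghk_ca(v, casl, cao, p[P_PCA]) * gate * (1.0 - y[IFCASL])
    if ical_clamped:
        icalj = fxcalj * ical_value
        icalsl = (1.0 - fxcalj) * ical_value
    ical = icalj + icalsl

    # --- I_NCX ---
    incxj = fxj * _ncx(v, nai, caj, nao, cao, p[P_INCXBAR])
    incxsl = (1.0 - fxj) * _ncx(v, nai, casl, nao, cao, p[P_INCXBAR])
    if incx_clamped:
        incxj = fxj * incx_value
        incxsl = (1.0 - fxj) * incx_value
    incx = incxj + incxsl

    # --- background Ca and sarcolemmal Ca pump ---
    ecaj = 0.5 * RTONF * np.log(cao / caj)
    ecasl = 0.5 * RTONF * np.log(cao / casl)
    icabj = fxj * p[P_GCAB] * (v - ecaj)
    icabsl = (1.0 - fxj) * p[P_GCAB] * (v - ecasl)
    icab = icabj + icabsl
    ipcaj = fxj * p[P_IBARPCA] * caj ** 1.6 / (caj ** 1.6 + 0.0005 ** 1.6)
    ipcasl = (1.0 - fxj) * p[P_IBARPCA] * casl ** 1.6 / (casl ** 1.6 + 0.0005 ** 1.6)
    ipca = ipcaj + ipcasl

    iion = ina + inab + inak + ikr + iks + ik1 + ito + ical + icab + ipca + incx
    if v_clamped:
        dy[IV] = 0.0
    else:
        dy[IV] = -iion + isti

    # --- RyR (4-state, luminal regulation through the JSR store) ---
    kcasr = p[P_MAXSR] - (p[P_MAXSR] - p[P_MINSR]) \
        / (1.0 + (p[P_EC50SR] / cajsr) ** p[P_SRHILL])
    koc = p[P_KOCA] / kcasr
    kic = p[P_KICA]
    # closed-state inactivation is kept weak so Ca-induced opening is not
    # suffocated at burst onset; open-state inactivation terminates bursts
    kic_r = 0.1 * kic
    rr = y[IRYR_R]
    ro = y[IRYR_O]
    ri = y[IRYR_I]
    rri = y[IRYR_RI]
    dy[IRYR_R] = p[P_KIM] * rri - kic_r * caj * rr - (koc * caj * caj * rr - p[P_KOM] * ro)
    dy[IRYR_O] = koc * caj * caj * rr - p[P_KOM] * ro - (kic * caj * ro - p[P_KIM] * ri)
    dy[IRYR_I] = kic * caj * ro - p[P_KIM] * ri - (p[P_KOM] * ri - koc * caj * caj * rri)
    dy[IRYR_RI] = p[P_KOM] * ri - koc * caj * caj * rri - (p[P_KIM] * rri - kic_r * caj * rr)

    jrel = p[P_KMAX] * ro * (cajsr - caj)          # mM/ms, myo-referenced
    jleak = p[P_KLEAK] * (cansr - caj)             # mM/ms, myo-referenced
    jup = p[P_VMAXUP] * ((cai / p[P_KMF]) ** p[P_HUP]
                         - (cansr / p[P_KMR]) ** p[P_HUP]) \
        / (1.0 + (cai / p[P_KMF]) ** p[P_HUP] + (cansr / p[P_KMR]) ** p[P_HUP])
    jtr = (cansr - cajsr) / p[P_TAUTR]             # mM/ms, JSR-referenced

    jdiff_js = p[P_JCAJXNSL] * (caj - casl)        # mmol/ms
    jdiff_sm = p[P_JCASLMYO] * (casl - cai)        # mmol/ms

    # --- cytosolic buffers ---
    db1 = BUF_TNCL[1] * cai * (BUF_TNCL[0] - y[IBTNCL]) - BUF_TNCL[2] * y[IBTNCL]
    db2 = BUF_TNCH[1] * cai * (BUF_TNCH[0] - y[IBTNCH]) - BUF_TNCH[2] * y[IBTNCH]
    db3 = BUF_CAM[1] * cai * (BUF_CAM[0] - y[IBCAM]) - BUF_CAM[2] * y[IBCAM]
    db4 = BUF_MYO[1] * cai * (BUF_MYO[0] - y[IBMYO]) - BUF_MYO[2] * y[IBMYO]
    db5 = BUF_SRB[1] * cai * (BUF_SRB[0] - y[IBSRB]) - BUF_SRB[2] * y[IBSRB]
    dy[IBTNCL] = db1
    dy[IBTNCH] = db2
    dy[IBCAM] = db3
    dy[IBMYO] = db4
    dy[IBSRB] = db5

    # --- membrane Ca fluxes per compartment (mM/ms, local volume) ---
    zero_flux = p[P_ZEROCAFLUX] > 0.5
    if zero_flux:
        jmem_j = 0.0
        jmem_sl = 0.0
    else:
        jmem_j = -(icalj + icabj + ipcaj - 2.0 * incxj) * CM / (2.0 * FARADAY * VJXN)
        jmem_sl = -(icalsl + icabsl + ipcasl - 2.0 * incxsl) * CM / (2.0 * FARADAY * VSL)

    # sarcolemmal buffer kinetics (local volumes)
    dbj1 = KON_SLL * caj * (BL_JXN - y[IBSLLJ]) - KOFF_SLL * y[IBSLLJ]
    dbj2 = KON_SLH * caj * (BH_JXN - y[IBSLHJ]) - KOFF_SLH * y[IBSLHJ]
    dbs1 = KON_SLL * casl * (BL_SL - y[IBSLLSL]) - KOFF_SLL * y[IBSLLSL]
    dbs2 = KON_SLH * casl * (BH_SL - y[IBSLHSL]) - KOFF_SLH * y[IBSLHSL]
    dy[IBSLLJ] = dbj1
    dy[IBSLHJ] = dbj2
    dy[IBSLLSL] = dbs1
    dy[IBSLHSL] = dbs2

    betajsr = 1.0 / (1.0 + B_CSQN * KD_CSQN / (KD_CSQN + cajsr) ** 2)

    dy[ICAJ] = ((jrel + jleak) * VMYO / VJXN
                + jmem_j - jdiff_js / VJXN - (dbj1 + dbj2))
    dy[ICASL] = jmem_sl + jdiff_js / VSL - jdiff_sm / VSL - (dbs1 + dbs2)
    dy[ICAI] = jdiff_sm / VMYO - jup * VNSR / VMYO - (db1 + db2 + db3 + db4 + db5)
    dy[ICAJSR] = betajsr * (jtr - jrel * VMYO / VJSR)
    dy[ICANSR] = jup - jtr * VJSR / VNSR - jleak * VMYO / VNSR

    if ca_clamped:
        dy[ICAJ] = 0.0
        dy[ICASL] = 0.0

    # --- Na balance ---
    if zero_flux:
        dy[INAI] = 0.0
    else:
        dy[INAI] = -(ina + inab + 3.0 * inak + 3.0 * incx) * CM / (FARADAY * VMYO)

    cur[C_IION] = iion
    cur[C_ISTI] = isti
    cur[C_INA] = ina
    cur[C_INAB] = inab
    cur[C_INAK] = inak
    cur[C_IKR] = ikr
    cur[C_IKS] = iks
    cur[C_IK1] = ik1
    cur[C_ITO] = ito
    cur[C_ICAL] = ical
    cur[C_ICAB] = icab
    cur[C_IPCA] = ipca
    cur[C_INCX] = incx
    cur[C_ICALJ] = icalj
    cur[C_ICALSL] = icalsl
    cur[C_INCXJ] = incxj
    cur[C_INCXSL] = incxsl
    cur[C_IKSJ] = iksj
    cur[C_IKSSL] = ikssl


@njit(cache=True, fastmath=True)
def _clamp_value(mode, t, t0, t1, v0, v1, ref, ref_dt):
    """Instantaneous target value of an active clamp directive."""
    if mode == CM_CONST:
        return v0
    elif mode == CM_TRACE:
        # ref is sampled on a uniform grid starting at t = 0
        idx = t / ref_dt
        i0 = int(idx)
        if i0 >= ref.shape[0] - 1:
            return ref[ref.shape[0] - 1]
        w = idx - i0
        return ref[i0] * (1.0 - w) + ref[i0 + 1] * w
    else:  # CM_RAMP
        return v0 + (v1 - v0) * (t - t0) / (t1 - t0)


@njit(cache=True)
def integrate_kernel(y0, p, dt, t_end,
                     stim_starts, stim_amp, stim_dur,
                     cl_target, cl_mode, cl_t0, cl_t1, cl_v0, cl_v1,
                     cl_ref, cl_ref_dt,
                     store_stride, stop_early):
    """Explicit-Euler trajectory with stimulus schedule and clamp directives.

    Returns (states, currents, n_stored, status, t_fail) where status is
    0 = ran to t_end, 1 = stopped early at rest, 2 = divergence.
    """
    n_steps = int(round(t_end / dt))
    n_store = n_steps // store_stride + 1
    out_y = np.empty((n_store, NSTATE))
    out_c = np.empty((n_store, NCUR))
    y = y0.copy()
    dy = np.empty(NSTATE)
    cur = np.empty(NCUR)
    ginf = np.empty(9)
    gtau = np.empty(9)
    ncl = cl_target.shape[0]
    # ramp/constant current clamps may need the onset value, resolved at t_on
    cl_v0w = cl_v0.copy()
    cl_started = np.zeros(ncl, dtype=np.int8)

    status = 0
    t_fail = -1.0
    n_stored = 0
    rest_count = 0
    last_stim_end = -1.0e30
    for k in range(stim_starts.shape[0]):
        e = stim_starts[k] + stim_dur
        if e > last_stim_end:
            last_stim_end = e
    last_cl_end = -1.0e30
    for k in range(ncl):
        if cl_t1[k] > last_cl_end:
            last_cl_end = cl_t1[k]

    i = 0
    while i <= n_steps:
        t = i * dt

        # stimulus
        isti = 0.0
        for k in range(stim_starts.shape[0]):
            if stim_starts[k] <= t < stim_starts[k] + stim_dur:
                isti = stim_amp
                break

        # resolve active clamps at this instant
        ca_cl = False
        v_cl = False
        ical_cl = False
        incx_cl = False
        ca_val = 0.0
        v_val = 0.0
        ical_val = 0.0
        incx_val = 0.0
        need_onset = -1
        for k in range(ncl):
            if cl_t0[k] <= t < cl_t1[k]:
                if cl_started[k] == 0:
                    cl_started[k] = 1
                    if np.isnan(cl_v0w[k]):
                        # hold-at-onset: needs the instantaneous value below
                        need_onset = k
                val = _clamp_value(cl_mode[k], t, cl_t0[k], cl_t1[k],
                                   cl_v0w[k], cl_v1[k], cl_ref[k], cl_ref_dt)
                tg = cl_target[k]
                if tg == CL_CASUB:
                    ca_cl = True
                    ca_val = val
                elif tg == CL_VM:
                    v_cl = True
                    v_val = val
                elif tg == CL_ICAL:
                    ical_cl = True
                    ical_val = val
                else:
                    incx_cl = True
                    incx_val = val

        if need_onset >= 0:
            # evaluate the unclamped current at clamp onset to seed the level
            rhs(y, p, isti, ca_cl, v_cl, False, 0.0, False, 0.0, dy, cur,
                ginf, gtau)
            k = need_onset
            if cl_target[k] == CL_ICAL:
                cl_v0w[k] = cur[C_ICAL]
            elif cl_target[k] == CL_INCX:
                cl_v0w[k] = cur[C_INCX]
            elif cl_target[k] == CL_VM:
                cl_v0w[k] = y[IV]
            else:
                cl_v0w[k] = y[ICASL]
            val = _clamp_value(cl_mode[k], t, cl_t0[k], cl_t1[k],
                               cl_v0w[k], cl_v1[k], cl_ref[k], cl_ref_dt)
            tg = cl_target[k]
            if tg == CL_CASUB:
                ca_val = val
            elif tg == CL_VM:
                v_val = val
            elif tg == CL_ICAL:
                ical_val = val
            else:
                incx_val = val

        # impose state clamps
        if ca_cl:
            # floor keeps Nernst/NCX terms defined when clamping to zero
            if ca_val < 1e-9:
                ca_val = 1e-9
            y[ICAJ] = ca_val
            y[ICASL] = ca_val
        if v_cl:
            y[IV] = v_val

        rhs(y, p, isti, ca_cl, v_cl, ical_cl, ical_val, incx_cl, incx_val,
            dy, cur, ginf, gtau)

        if i % store_stride == 0:
            for s in range(NSTATE):
                out_y[n_stored, s] = y[s]
            for s in range(NCUR):
                out_c[n_stored, s] = cur[s]
            n_stored += 1

        # divergence check
        if not np.isfinite(y[IV]) or abs(y[IV]) > 500.0:
            status = 2
            t_fail = t
            break

        # early stop once quiescent at rest with nothing pending
        if stop_early and t > last_stim_end + 100.0 and t > last_cl_end:
            if y[IV] < -75.0 and abs(dy[IV]) < 0.01:
                rest_count += 1
                if rest_count * dt > 200.0:
                    status = 1
                    break
            else:
                rest_count = 0

        # forward-Euler update; HH gates advance by their exact
        # exponential relaxation (Rush-Larsen) for stiffness at rest
        y[IV] = y[IV] + dt * dy[IV]
        for s in range(IM, IYTO + 1):
            y[s] = ginf[s - 1] + (y[s] - ginf[s - 1]) * np.exp(-dt / gtau[s - 1])
        for s in range(IFCAJ, NSTATE):
            y[s] = y[s] + dt * dy[s]
        # guard against transient undershoot of tiny-compartment Ca
        for s in range(ICAJ, ICANSR + 1):
            if y[s] < 1e-9:
                y[s] = 1e-9
        i += 1

    return out_y[:n_stored], out_c[:n_stored], n_stored, status, t_fail
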