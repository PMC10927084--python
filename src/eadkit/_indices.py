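"""Index layout shared by the compiled kernel and the Python API.

State vector (27 entries)
-------------------------
Voltage, channel gates, the Ca-dependent inactivation gates of I_CaL in the
two submembrane compartments, free Ca in five compartments, the four RyR
gate occupancies, intracellular Na, and the five cytosolic Ca buffers
(bound-Ca concentrations, mM).
"""

# --- state vector ---
IV = 0        # V_m (mV)
IM = 1        # I_Na activation m
IH = 2        # I_Na fast inactivation h
IJ = 3        # I_Na slow inactivation j
ID = 4        # I_CaL activation d
IF = 5        # I_CaL voltage inactivation f
IXR = 6       # I_Kr activation
IXS = 7       # I_Ks activation
IXTO = 8      # I_to activation
IYTO = 9      # I_to inactivation
IFCAJ = 10    # I_CaL Ca-dependent inactivation gate, JXN (bound fraction)
IFCASL = 11   # same, SL
ICAJ = 12     # [Ca]_JXN (mM)
ICASL = 13    # [Ca]_SL (mM)
ICAI = 14     # [Ca]_cyto (mM)
ICAJSR = 15   # free [Ca]_JSR (mM)
ICANSR = 16   # [Ca]_NSR (mM)
IRYR_R = 17   # RyR resting/closed
IRYR_O = 18   # RyR open
IRYR_I = 19   # RyR inactivated
IRYR_RI = 20  # RyR resting-inactivated
INAI = 21     # [Na]_i (mM)
IBTNCL = 22   # troponin C low-affinity site
IBTNCH = 23   # troponin C high-affinity site
IBCAM = 24    # calmodulin
IBMYO = 25    # myosin
IBSRB = 26    # SR membrane binding site
IBSLLJ = 27   # sarcolemmal low-affinity buffer, JXN (bound Ca, mM local)
IBSLHJ = 28   # sarcolemmal high-affinity buffer, JXN
IBSLLSL = 29  # sarcolemmal low-affinity buffer, SL
IBSLHSL = 30  # sarcolemmal high-affinity buffer, SL
IF2 = 31      # slow voltage-dependent inactivation gate of I_CaL
NSTATE = 32

# --- parameter vector ---
P_KMAX = 0       # ms^-1   maximal SR release rate constant (JSR-referenced)
P_JCASLMYO = 1   # l/ms    SL <-> cytosol Ca diffusive strength
P_PCA = 2        # cm/s    Ca permeability of I_CaL
P_GKS = 3        # mS/uF   maximal I_Ks conductance
P_INCXBAR = 4    # A/F     NCX current density
P_GNA = 5
P_GKR = 6
P_GK1 = 7
P_GTO = 8
P_GCAB = 9
P_GNAB = 10
P_IBARNAK = 11
P_IBARPCA = 12
P_VMAXUP = 13    # mM/ms (NSR-referenced)
P_KMF = 14
P_KMR = 15
P_HUP = 16
P_TAUTR = 17     # ms NSR->JSR transfer
P_KLEAK = 18     # ms^-1 (myo-referenced)
P_JCAJXNSL = 19  # l/ms JXN <-> SL diffusion
P_KOCA = 20      # RyR opening rate coefficient (mM^-2 ms^-1)
P_KICA = 21      # RyR inactivation rate coefficient (mM^-1 ms^-1)
P_KOM = 22
P_KIM = 23
P_EC50SR = 24    # mM, luminal regulation midpoint
P_MAXSR = 25
P_MINSR = 26
P_NAO = 27
P_KO = 28
P_CAO = 29
P_KI = 30
P_FSS_FLAT = 31  # 1.0 -> flattened f_ss variant
P_FSS_VMIN = 32  # argmin of f_ss (mV), precomputed
P_FSS_FMIN = 33  # min of f_ss, precomputed
P_FXCALJ = 34    # fraction of I_CaL in the JXN compartment
P_FXJ = 35       # fraction of NCX / I_Ks / background Ca currents in JXN
P_ZEROCAFLUX = 36  # 1.0 -> zero all transmembrane Ca fluxes (mass-balance test)
P_XS_VMID = 37     # I_Ks activation midpoint (mV)
P_XS_SLOPE = 38    # I_Ks activation slope (mV)
P_TAUXS_LO = 39    # I_Ks deactivation time constant floor (ms)
P_TAUXS_HI = 40    # additional activation time constant at depolarized V (ms)
P_TAUF_SCALE = 41  # scale on the I_CaL voltage-inactivation time constant
P_FSS_HAMP = 42    # amplitude of the late elevated portion of f_ss
P_FSS_HVMID = 43   # midpoint (mV) of the late elevated portion
P_FSS_SLOPE = 44   # slope (mV) of the falling sigmoid of f_ss
P_SRHILL = 45      # Hill coefficient of luminal RyR regulation
P_F2_VMID = 46     # slow I_CaL inactivation midpoint (mV)
P_F2_SLOPE = 47    # slow I_CaL inactivation slope (mV)
P_TAUF2 = 48       # slow I_CaL inactivation time constant (ms)
P_FSS_HSLOPE = 49  # slope (mV) of the late elevated portion of f_ss
NPARAM = 50

# --- current snapshot vector ---
C_IION = 0
C_ISTI = 1
C_INA = 2
C_INAB = 3
C_INAK = 4
C_IKR = 5
C_IKS = 6
C_IK1 = 7
C_ITO = 8
C_ICAL = 9
C_ICAB = 10
C_IPCA = 11
C_INCX = 12
C_ICALJ = 13
C_ICALSL = 14
C_INCXJ = 15
C_INCXSL = 16
C_IKSJ = 17
C_IKSSL = 18
NCUR = 19

# names for trace columns
STATE_NAMES = (
    "V_m", "m", "h", "j", "d", "f", "xr", "xs", "xto", "yto",
    "fca_jxn", "fca_sl", "Ca_jxn", "Ca_sl", "Ca_cyto", "Ca_jsr", "Ca_nsr",
    "ryr_r", "ryr_o", "ryr_i", "ryr_ri", "Na_i",
    "b_tncl", "b_tnch", "b_cam", "b_myo", "b_srb",
    "b_sll_jxn", "b_slh_jxn", "b_sll_sl", "b_slh_sl", "f2",
)
CURRENT_NAMES = (
    "I_ion", "I_sti", "I_Na", "I_Nab", "I_NaK", "I_Kr", "I_Ks", "I_K1",
    "I_to", "I_CaL", "I_Cab", "I_pCa", "I_NCX",
    "I_CaL_jxn", "I_CaL_sl", "I_NCX_jxn", "I_NCX_sl", "I_Ks_jxn", "I_Ks_sl",
)

# clamp target codes
CL_CASUB = 0
CL_VM = 1
CL_ICAL = 2
CL_INCX = 3

# clamp mode codes
CM_CONST = 0
CM_TRACE = 1
CM_RAMP = 2
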