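"""Numerical core: model right-hand side and fixed-step integrators.

Everything here operates on flat float64 arrays so it can be compiled with
numba and shared between the single-cell, parameter-sweep and tissue paths.
State layout and parameter layout are frozen by the index constants below
and by :data:`sansr.params.PARAM_ORDER`.

Conventions
-----------
* time is in seconds, voltages mV, currents pA, concentrations mM;
* ionic currents are positive outward; ``dV/dt = -(sum I_ion + i_inj)/C_m``
  so a *negative* ``i_inj`` at this level depolarizes.  The stimulus API
  (:mod:`sansr.stimulus`) uses the opposite, physiological convention
  (positive = depolarizing) and the simulation drivers negate it once.
* the canonical integrator is fixed-step forward Euler (default step
  0.01 ms) so stochastic forcing has a well-defined realization.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import PARAM_INDEX as _PI

# ---------------------------------------------------------------------------
# State vector layout
# ---------------------------------------------------------------------------
IV = 0        # membrane potential, mV
IDL = 1       # I_CaL activation
IFL = 2       # I_CaL voltage inactivation
IFCA = 3      # I_CaL Ca-dependent inactivation
IDT = 4       # I_CaT activation
IFT = 5       # I_CaT inactivation
IPAF = 6      # I_Kr fast activation
IPAS = 7      # I_Kr slow activation
IPI = 8       # I_Kr inactivation
IN = 9        # I_Ks activation
IQ = 10       # I_to inactivation
IR = 11       # I_to / I_sus activation
IY = 12       # I_f activation
IQA = 13      # I_st activation
IQI = 14      # I_st inactivation
ICAI = 15     # [Ca]_i, mM
ICASUB = 16   # [Ca]_sub, mM
ICANSR = 17   # [Ca]_nSR, mM
ICAJSR = 18   # [Ca]_jSR, mM
IRYR_R = 19   # RyR resting
IRYR_O = 20   # RyR open
IRYR_I = 21   # RyR inactivated
IRYR_RI = 22  # RyR resting-inactivated
IFTC = 23     # troponin-Ca occupancy
IFTMC = 24    # troponin-Mg site, Ca bound
IFTMM = 25    # troponin-Mg site, Mg bound
IFCMI = 26    # calmodulin occupancy, cytosol
IFCMS = 27    # calmodulin occupancy, submembrane
IFCQ = 28     # calsequestrin occupancy, jSR
N_STATE = 29

GATE_INDICES = np.array(
    [IDL, IFL, IFCA, IDT, IFT, IPAF, IPAS, IPI, IN, IQ, IR, IY, IQA, IQI,
     IRYR_R, IRYR_O, IRYR_I, IRYR_RI, IFTC, IFTMC, IFTMM, IFCMI, IFCMS, IFCQ],
    dtype=np.int64,
)
CONC_INDICES = np.array([ICAI, ICASUB, ICANSR, ICAJSR], dtype=np.int64)

# Hodgkin-Huxley gates occupy the contiguous state slice [IDL, IQI].
N_HH = IQI - IDL + 1

# Auxiliary (current) outputs of the RHS, pA
AUX_NAMES = (
    "I_CaL", "I_CaT", "I_Kr", "I_Ks", "I_to", "I_sus", "I_f", "I_st",
    "I_bNa", "I_NaK", "I_NCX", "I_KACh",
)
N_AUX = len(AUX_NAMES)

# Parameter indices resolved once at import time (module-level ints are
# compile-time constants for numba).
_P_CM = _PI["C_m"]; _P_GCAL = _PI["g_CaL"]; _P_GCAT = _PI["g_CaT"]
_P_GKR = _PI["g_Kr"]; _P_GKS = _PI["g_Ks"]; _P_GTO = _PI["g_to"]
_P_GSUS = _PI["g_sus"]; _P_GIF = _PI["g_If"]; _P_GST = _PI["g_st"]
_P_GBNA = _PI["g_bNa"]; _P_INAK = _PI["I_NaK_max"]; _P_KNCX = _PI["k_NCX"]
_P_ECAL = _PI["E_CaL"]; _P_ECAT = _PI["E_CaT"]; _P_EST = _PI["E_st"]
_P_VIFSH = _PI["V_If_shift"]
_P_NAI = _PI["Na_i"]; _P_KI = _PI["K_i"]; _P_NAO = _PI["Na_o"]
_P_KO = _PI["K_o"]; _P_CAO = _PI["Ca_o"]; _P_MGI = _PI["Mg_i"]
_P_TEMP = _PI["temperature"]
_P_PUP = _PI["P_up"]; _P_KUP = _PI["K_up"]; _P_TDIF = _PI["tau_dif_Ca"]
_P_TTR = _PI["tau_tr"]; _P_KS = _PI["k_s"]; _P_KOCA = _PI["k_oCa"]
_P_KOM = _PI["k_om"]; _P_KICA = _PI["k_iCa"]; _P_KIM = _PI["k_im"]
_P_EC50 = _PI["EC50_SR"]; _P_MAXSR = _PI["Max_SR"]; _P_MINSR = _PI["Min_SR"]
_P_HSR = _PI["H_SR"]
_P_VI = _PI["V_i"]; _P_VSUB = _PI["V_sub"]; _P_VNSR = _PI["V_nSR"]
_P_VJSR = _PI["V_jSR"]
_P_TCT = _PI["TC_tot"]; _P_TMCT = _PI["TMC_tot"]; _P_CMT = _PI["CM_tot"]
_P_CQT = _PI["CQ_tot"]
_P_KFTC = _PI["kf_TC"]; _P_KBTC = _PI["kb_TC"]; _P_KFTMC = _PI["kf_TMC"]
_P_KBTMC = _PI["kb_TMC"]; _P_KFTMM = _PI["kf_TMM"]; _P_KBTMM = _PI["kb_TMM"]
_P_KFCM = _PI["kf_CM"]; _P_KBCM = _PI["kb_CM"]; _P_KFCQ = _PI["kf_CQ"]
_P_KBCQ = _PI["kb_CQ"]
_P_GKACH = _PI["g_KACh"]

_F_CONST = 96.4853  # C/mmol; pA / (C/mmol * pL) = mM/s
_R_CONST = 8.3144598e3  # mJ/(mol K) so RT/F is in mV

_KM_FCA = 0.00035  # mM, Ca half-inactivation of I_CaL
_ALPHA_FCA = 21.0  # 1/s
_KM_KP = 1.4       # mM, Na/K pump K affinity
_KM_NAP = 14.0     # mM, Na/K pump Na affinity
# NCX (Kurata-type di-exchanger) constants
_KCI = 0.0207; _KCNI = 26.44; _KCO = 3.663
_K1NI = 395.3; _K2NI = 2.289; _K3NI = 26.44
_K1NO = 1628.0; _K2NO = 561.4; _K3NO = 4.663
_QCI = 0.1369; _QCO = 0.0; _QN = 0.4315


@njit(cache=True, fastmath=False)
def rhs(y, p, i_inj, j_lcr, dy, aux, ginf, gtau):
    """Time derivatives of the full state (per second).

    ``i_inj`` is in the outward-positive convention (see module docstring);
    ``j_lcr`` is an extra Ca flux into the submembrane shell (mM/s) used by
    the optional stochastic local-release mode.  ``dy``, ``aux``, ``ginf``
    and ``gtau`` are output buffers; the latter two carry the steady state
    and time constant (s) of each Hodgkin-Huxley gate (state indices
    ``IDL..IQI``) so integrators can apply the exponential (Rush-Larsen)
    gate update, which is unconditionally stable.
    """
    v = y[IV]
    # Gate rates/steady states are evaluated at a voltage clamped far outside
    # the physiological range; this keeps the exponentials finite when strong
    # stimuli push V_m to extreme values.  Driving forces use the true V_m.
    vr = min(max(v, -250.0), 150.0)
    rtf = _R_CONST * p[_P_TEMP] / 96485.3  # mV
    cm = p[_P_CM]

    e_na = rtf * np.log(p[_P_NAO] / p[_P_NAI])
    e_k = rtf * np.log(p[_P_KO] / p[_P_KI])
    e_ks = rtf * np.log((p[_P_KO] + 0.12 * p[_P_NAO]) /
                        (p[_P_KI] + 0.12 * p[_P_NAI]))

    # ---- L-type Ca current ----------------------------------------------
    i_cal = cm * p[_P_GCAL] * (v - p[_P_ECAL]) * y[IDL] * y[IFL] * y[IFCA]

    dl_inf = 1.0 / (1.0 + np.exp(-(vr + 13.5) / 6.0))
    vm35 = vr + 35.0
    if np.abs(vm35) < 1e-6:
        a_dl1 = 0.02839 * 2.5
    else:
        a_dl1 = -0.02839 * vm35 / (np.exp(-vm35 / 2.5) - 1.0)
    if np.abs(v) < 1e-6:
        a_dl2 = 0.0849 * 4.8
    else:
        a_dl2 = -0.0849 * vr / (np.exp(-vr / 4.8) - 1.0)
    vm5 = vr - 5.0
    if np.abs(vm5) < 1e-6:
        b_dl = 0.01143 * 2.5
    else:
        b_dl = 0.01143 * vm5 / (np.exp(vm5 / 2.5) - 1.0)
    tau_dl = 1e-3 / (a_dl1 + a_dl2 + b_dl)  # s
    dy[IDL] = (dl_inf - y[IDL]) / tau_dl
    ginf[IDL - IDL] = dl_inf
    gtau[IDL - IDL] = tau_dl

    fl_inf = 1.0 / (1.0 + np.exp((vr + 35.0) / 7.3))
    tau_fl = 1e-3 * (44.3 + 230.0 * np.exp(-((vr + 36.0) / 10.0) ** 2))
    dy[IFL] = (fl_inf - y[IFL]) / tau_fl
    ginf[IFL - IDL] = fl_inf
    gtau[IFL - IDL] = tau_fl

    cs_pos = max(y[ICASUB], 0.0)
    fca_inf = _KM_FCA / (_KM_FCA + cs_pos)
    tau_fca = fca_inf / _ALPHA_FCA
    dy[IFCA] = (fca_inf - y[IFCA]) / tau_fca
    ginf[IFCA - IDL] = fca_inf
    gtau[IFCA - IDL] = tau_fca

    # ---- T-type Ca current ----------------------------------------------
    i_cat = cm * p[_P_GCAT] * (v - p[_P_ECAT]) * y[IDT] * y[IFT]
    dt_inf = 1.0 / (1.0 + np.exp(-(vr + 26.3) / 6.0))
    tau_dt = 1e-3 / (1.068 * np.exp((vr + 26.3) / 30.0) +
                     1.068 * np.exp(-(vr + 26.3) / 30.0))
    dy[IDT] = (dt_inf - y[IDT]) / tau_dt
    ginf[IDT - IDL] = dt_inf
    gtau[IDT - IDL] = tau_dt
    ft_inf = 1.0 / (1.0 + np.exp((vr + 61.7) / 5.6))
    tau_ft = 1e-3 / (0.0153 * np.exp(-(vr + 61.7) / 83.3) +
                     0.015 * np.exp((vr + 61.7) / 15.38))
    dy[IFT] = (ft_inf - y[IFT]) / tau_ft
    ginf[IFT - IDL] = ft_inf
    gtau[IFT - IDL] = tau_ft

    # ---- rapid delayed rectifier ----------------------------------------
    i_kr = cm * p[_P_GKR] * (v - e_k) * (0.6 * y[IPAF] + 0.4 * y[IPAS]) * y[IPI]
    pa_inf = 1.0 / (1.0 + np.exp(-(vr + 23.2) / 10.6))
    tau_paf = 1e-3 * 0.84655354 / (0.0372 * np.exp(vr / 15.9) +
                                   0.00096 * np.exp(-vr / 22.5))
    tau_pas = 1e-3 * 0.84655354 / (0.0042 * np.exp(vr / 17.0) +
                                   0.00015 * np.exp(-vr / 21.6))
    dy[IPAF] = (pa_inf - y[IPAF]) / tau_paf
    ginf[IPAF - IDL] = pa_inf
    gtau[IPAF - IDL] = tau_paf
    dy[IPAS] = (pa_inf - y[IPAS]) / tau_pas
    ginf[IPAS - IDL] = pa_inf
    gtau[IPAS - IDL] = tau_pas
    pi_inf = 1.0 / (1.0 + np.exp((vr + 28.6) / 17.1))
    tau_pi = 1e-3 / (0.1 * np.exp(-vr / 54.645) + 0.656 * np.exp(vr / 106.157))
    dy[IPI] = (pi_inf - y[IPI]) / tau_pi
    ginf[IPI - IDL] = pi_inf
    gtau[IPI - IDL] = tau_pi

    # ---- slow delayed rectifier -----------------------------------------
    i_ks = cm * p[_P_GKS] * (v - e_ks) * y[IN] * y[IN]
    a_n = 0.014 / (1.0 + np.exp(-(vr - 40.0) / 9.0))
    b_n = 0.001 * np.exp(-vr / 45.0)
    n_inf = a_n / (a_n + b_n)
    tau_n = 1e-3 / (a_n + b_n)
    dy[IN] = (n_inf - y[IN]) / tau_n
    ginf[IN - IDL] = n_inf
    gtau[IN - IDL] = tau_n

    # ---- transient outward / sustained ----------------------------------
    i_to = cm * p[_P_GTO] * (v - e_k) * y[IQ] * y[IR]
    i_sus = cm * p[_P_GSUS] * (v - e_k) * y[IR]
    q_inf = 1.0 / (1.0 + np.exp((vr + 49.0) / 13.0))
    tau_q = 1e-3 * (6.06 + 39.102 /
                    (0.57 * np.exp(-0.08 * (vr + 44.0)) +
                     0.065 * np.exp(0.1 * (vr + 45.93))))
    dy[IQ] = (q_inf - y[IQ]) / tau_q
    ginf[IQ - IDL] = q_inf
    gtau[IQ - IDL] = tau_q
    r_inf = 1.0 / (1.0 + np.exp(-(vr - 19.3) / 15.0))
    tau_r = 1e-3 * (2.75 + 14.40516 /
                    (1.037 * np.exp(0.09 * (vr + 30.61)) +
                     0.369 * np.exp(-0.12 * (vr + 23.84))))
    dy[IR] = (r_inf - y[IR]) / tau_r
    ginf[IR - IDL] = r_inf
    gtau[IR - IDL] = tau_r

    # ---- funny current ---------------------------------------------------
    y2 = y[IY]
    i_f_na = cm * p[_P_GIF] * 0.3833 * y2 * (v - e_na)
    i_f_k = cm * p[_P_GIF] * 0.6167 * y2 * (v - e_k)
    i_f = i_f_na + i_f_k
    vh = -64.0 + p[_P_VIFSH]
    y_inf = 1.0 / (1.0 + np.exp((vr - vh) / 13.5))
    tau_y = 1e-3 * 0.7166529 / (np.exp(-(vr + 386.9) / 45.302) +
                                np.exp((vr - 73.08) / 19.231))
    dy[IY] = (y_inf - y[IY]) / tau_y
    ginf[IY - IDL] = y_inf
    gtau[IY - IDL] = tau_y

    # ---- sustained inward current ---------------------------------------
    i_st = cm * p[_P_GST] * (v - p[_P_EST]) * y[IQA] * y[IQI]
    qa_inf = 1.0 / (1.0 + np.exp(-(vr + 57.0) / 5.0))
    a_qa = 1.0 / (0.15 * np.exp(-vr / 11.0) + 0.2 * np.exp(-vr / 700.0))
    b_qa = 1.0 / (16.0 * np.exp(vr / 8.0) + 15.0 * np.exp(vr / 50.0))
    tau_qa = 1e-3 / (a_qa + b_qa)
    dy[IQA] = (qa_inf - y[IQA]) / tau_qa
    ginf[IQA - IDL] = qa_inf
    gtau[IQA - IDL] = tau_qa
    a_qi = 0.1504 / (3100.0 * np.exp(vr / 13.0) + 700.0 * np.exp(vr / 70.0))
    b_qi = 0.1504 / (95.0 * np.exp(-vr / 10.0) + 50.0 * np.exp(-vr / 700.0)) \
        + 0.000229 / (1.0 + np.exp(-v / 5.0))
    qi_inf = a_qi / (a_qi + b_qi)
    tau_qi = 1e-3 / (a_qi + b_qi)
    dy[IQI] = (qi_inf - y[IQI]) / tau_qi
    ginf[IQI - IDL] = qi_inf
    gtau[IQI - IDL] = tau_qi

    # ---- background, pump, exchanger ------------------------------------
    i_bna = cm * p[_P_GBNA] * (v - e_na)

    i_nak = cm * p[_P_INAK] \
        / (1.0 + (_KM_KP / p[_P_KO]) ** 1.2) \
        / (1.0 + (_KM_NAP / p[_P_NAI]) ** 1.3) \
        / (1.0 + np.exp(-(v - e_na + 110.0) / 20.0))

    casub = y[ICASUB]
    vfrt = v / rtf
    exp_qci = np.exp(-_QCI * vfrt)
    exp_qco = np.exp(_QCO * vfrt)
    exp_qn = np.exp(_QN * vfrt / 2.0)
    nai = p[_P_NAI]
    nao = p[_P_NAO]
    di = 1.0 + (casub / _KCI) * (1.0 + exp_qci + nai / _KCNI) \
        + (nai / _K1NI) * (1.0 + (nai / _K2NI) * (1.0 + nai / _K3NI))
    k12 = (casub / _KCI) * exp_qci / di
    k14 = (nai / _K1NI) * (nai / _K2NI) * (1.0 + nai / _K3NI) * exp_qn / di
    k41 = 1.0 / exp_qn
    k43 = nai / (_K3NI + nai)
    do_ = 1.0 + (p[_P_CAO] / _KCO) * (1.0 + exp_qco) \
        + (nao / _K1NO) * (1.0 + (nao / _K2NO) * (1.0 + nao / _K3NO))
    k21 = (p[_P_CAO] / _KCO) * exp_qco / do_
    k23 = (nao / _K1NO) * (nao / _K2NO) * (1.0 + nao / _K3NO) / exp_qn / do_
    k32 = exp_qn
    k34 = nao / (_K3NO + nao)
    x1 = k41 * k34 * (k23 + k21) + k21 * k32 * (k43 + k41)
    x2 = k32 * k43 * (k14 + k12) + k41 * k12 * (k34 + k32)
    x3 = k14 * k43 * (k23 + k21) + k12 * k23 * (k43 + k41)
    x4 = k23 * k34 * (k14 + k12) + k14 * k21 * (k34 + k32)
    i_ncx = cm * p[_P_KNCX] * (x2 * k21 - x1 * k12) / (x1 + x2 + x3 + x4)

    # ---- ACh-activated K current (carbachol state) ----------------------
    # mild inward rectification keeps the current mostly diastolic
    i_kach = cm * p[_P_GKACH] * (v - e_k) / (1.0 + np.exp((v + 20.0) / 20.0))

    # ---- membrane potential ---------------------------------------------
    i_tot = (i_cal + i_cat + i_kr + i_ks + i_to + i_sus + i_f + i_st +
             i_bna + i_nak + i_ncx + i_kach)
    dy[IV] = -(i_tot + i_inj) / cm * 1e3  # pA/pF -> mV/s

    # ---- RyR gating (luminal-Ca regulated) ------------------------------
    cajsr = y[ICAJSR]
    cj_pos = max(cajsr, 1e-9)
    k_casr = p[_P_MAXSR] - (p[_P_MAXSR] - p[_P_MINSR]) / \
        (1.0 + (p[_P_EC50] / cj_pos) ** p[_P_HSR])
    k_osrca = p[_P_KOCA] / k_casr
    k_isrca = p[_P_KICA] * k_casr
    cs2 = cs_pos * cs_pos
    dy[IRYR_R] = (p[_P_KIM] * y[IRYR_RI] - k_isrca * cs_pos * y[IRYR_R]
                  - (k_osrca * cs2 * y[IRYR_R] - p[_P_KOM] * y[IRYR_O]))
    dy[IRYR_O] = (k_osrca * cs2 * y[IRYR_R] - p[_P_KOM] * y[IRYR_O]
                  - (k_isrca * cs_pos * y[IRYR_O] - p[_P_KIM] * y[IRYR_I]))
    dy[IRYR_I] = (k_isrca * cs_pos * y[IRYR_O] - p[_P_KIM] * y[IRYR_I]
                  - (p[_P_KOM] * y[IRYR_I] - k_osrca * cs2 * y[IRYR_RI]))
    dy[IRYR_RI] = (p[_P_KOM] * y[IRYR_I] - k_osrca * cs2 * y[IRYR_RI]
                   - (p[_P_KIM] * y[IRYR_RI] - k_isrca * cs_pos * y[IRYR_R]))

    # ---- Ca fluxes -------------------------------------------------------
    j_rel = p[_P_KS] * y[IRYR_O] * (cajsr - casub)          # mM/s, per V_jSR
    cai = y[ICAI]
    j_up = p[_P_PUP] * cai / (cai + p[_P_KUP])              # mM/s, per V_nSR
    j_tr = (y[ICANSR] - cajsr) / p[_P_TTR]                  # mM/s, per V_jSR
    j_dif = (casub - cai) / p[_P_TDIF]                      # mM/s, per V_sub

    # ---- buffers ---------------------------------------------------------
    dy[IFTC] = p[_P_KFTC] * cai * (1.0 - y[IFTC]) - p[_P_KBTC] * y[IFTC]
    dy[IFTMC] = p[_P_KFTMC] * cai * (1.0 - y[IFTMC] - y[IFTMM]) \
        - p[_P_KBTMC] * y[IFTMC]
    dy[IFTMM] = p[_P_KFTMM] * p[_P_MGI] * (1.0 - y[IFTMC] - y[IFTMM]) \
        - p[_P_KBTMM] * y[IFTMM]
    dy[IFCMI] = p[_P_KFCM] * cai * (1.0 - y[IFCMI]) - p[_P_KBCM] * y[IFCMI]
    dy[IFCMS] = p[_P_KFCM] * casub * (1.0 - y[IFCMS]) - p[_P_KBCM] * y[IFCMS]
    dy[IFCQ] = p[_P_KFCQ] * cajsr * (1.0 - y[IFCQ]) - p[_P_KBCQ] * y[IFCQ]

    # ---- Ca compartment balances ----------------------------------------
    vi = p[_P_VI]; vsub = p[_P_VSUB]; vnsr = p[_P_VNSR]; vjsr = p[_P_VJSR]
    dy[ICAI] = (j_dif * vsub - j_up * vnsr) / vi \
        - (p[_P_CMT] * dy[IFCMI] + p[_P_TCT] * dy[IFTC] +
           p[_P_TMCT] * dy[IFTMC])
    dy[ICASUB] = j_rel * vjsr / vsub \
        - (i_cal + i_cat - 2.0 * i_ncx) / (2.0 * _F_CONST * vsub) \
        - j_dif + j_lcr - p[_P_CMT] * dy[IFCMS]
    dy[ICANSR] = j_up - j_tr * vjsr / vnsr
    dy[ICAJSR] = j_tr - j_rel - p[_P_CQT] * dy[IFCQ]

    aux[0] = i_cal; aux[1] = i_cat; aux[2] = i_kr; aux[3] = i_ks
    aux[4] = i_to; aux[5] = i_sus; aux[6] = i_f; aux[7] = i_st
    aux[8] = i_bna; aux[9] = i_nak; aux[10] = i_ncx; aux[11] = i_kach


@njit(cache=True)
def _release_exchange(y, p, dt):
    """Exact update of the stiff jSR -> submembrane release exchange.

    For a frozen RyR open fraction the release flux ``k_s*O*(Ca_jSR -
    Ca_sub)`` is a linear, volume-conserving exchange whose rate can exceed
    10^7/s during a synchronized dump — far too stiff for the explicit
    step.  The concentration difference decays exponentially with rate
    ``k_s*O*(1 + V_jSR/V_sub)``; applying that decay exactly is
    unconditionally stable and conserves total Ca to machine precision.
    Free-Ca buffering during the sub-step is handled by the explicit part.
    """
    k = p[_P_KS] * y[IRYR_O]
    if k <= 0.0:
        return
    w = p[_P_VJSR] / p[_P_VSUB]
    d = y[ICAJSR] - y[ICASUB]
    dn = d * np.exp(-k * (1.0 + w) * dt)
    moved = d - dn  # change of the gradient, mM
    y[ICAJSR] -= moved * (1.0 / (1.0 + w))
    y[ICASUB] += moved * (w / (1.0 + w))


@njit(cache=True)
def _strip_release(y, p, dy):
    """Remove the release flux from the explicit derivative (it is applied
    by :func:`_release_exchange` instead)."""
    j_rel = p[_P_KS] * y[IRYR_O] * (y[ICAJSR] - y[ICASUB])
    dy[ICASUB] -= j_rel * p[_P_VJSR] / p[_P_VSUB]
    dy[ICAJSR] += j_rel


@njit(cache=True)
def integrate_batch(y0, pmat, stim, stim_dt, lcr_flux, lcr_dt,
                    dt, n_steps, rec_every, neighbors, g_gap, vm_out,
                    casub_out, cai_out):
    """Forward-Euler integration of ``N`` cells, optionally gap-coupled.

    Parameters
    ----------
    y0 : (N, N_STATE) initial states; overwritten with final states.
    pmat : (N, N_PARAMS) per-cell parameter vectors.
    stim : (N, M) injected current, pA, *depolarizing positive*, sampled on
        a coarse grid of spacing ``stim_dt`` (sample-and-hold).  ``M == 0``
        disables stimulation.
    lcr_flux : (N, L) extra submembrane Ca flux (mM/s) on grid ``lcr_dt``;
        ``L == 0`` disables it.
    neighbors : (N, 4) neighbor indices, -1 where absent (no-flux border).
    g_gap : gap-junction conductance, nS.
    vm_out, casub_out, cai_out : (N, K) recorded traces with
        ``K = n_steps // rec_every + 1``.

    Returns ``(status, t_fail, cell_fail)``; status 0 means success and 1 a
    non-finite state (blow-up) at time ``t_fail`` in cell ``cell_fail``.
    """
    n_cells = y0.shape[0]
    m_stim = stim.shape[1]
    m_lcr = lcr_flux.shape[1]
    dy = np.empty(N_STATE)
    aux = np.empty(N_AUX)
    ginf = np.empty(N_HH)
    gtau = np.empty(N_HH)
    ynew = np.empty((n_cells, N_STATE))
    rec = 0
    for c in range(n_cells):
        vm_out[c, 0] = y0[c, IV]
        casub_out[c, 0] = y0[c, ICASUB]
        cai_out[c, 0] = y0[c, ICAI]
    for step in range(n_steps):
        t = step * dt
        if m_stim > 0:
            k_stim = min(int(t / stim_dt), m_stim - 1)
        else:
            k_stim = -1
        if m_lcr > 0:
            k_lcr = min(int(t / lcr_dt), m_lcr - 1)
        else:
            k_lcr = -1
        for c in range(n_cells):
            i_inj = 0.0
            if k_stim >= 0:
                i_inj = -stim[c, k_stim]  # depolarizing-positive -> outward(+)
            if g_gap > 0.0:
                acc = 0.0
                vc = y0[c, IV]
                for kk in range(4):
                    nb = neighbors[c, kk]
                    if nb >= 0:
                        acc += vc - y0[nb, IV]
                i_inj += g_gap * acc  # outward-positive coupling current, pA
            jl = lcr_flux[c, k_lcr] if k_lcr >= 0 else 0.0
            rhs(y0[c], pmat[c], i_inj, jl, dy, aux, ginf, gtau)
            _strip_release(y0[c], pmat[c], dy)
            for s in range(N_STATE):
                ynew[c, s] = y0[c, s] + dt * dy[s]
            for g in range(N_HH):
                s = IDL + g
                ynew[c, s] = ginf[g] + (y0[c, s] - ginf[g]) * \
                    np.exp(-dt / gtau[g])
            _release_exchange(ynew[c], pmat[c], dt)
            # catch instability before it propagates into gate-rate overflow
            if not (np.isfinite(ynew[c, IV]) and np.isfinite(ynew[c, ICASUB])
                    and np.abs(ynew[c, IV]) < 1500.0):
                return 1, (step + 1) * dt, c
        for c in range(n_cells):
            for s in range(N_STATE):
                y0[c, s] = ynew[c, s]
        if (step + 1) % rec_every == 0:
            rec += 1
            for c in range(n_cells):
                vm_out[c, rec] = y0[c, IV]
                casub_out[c, rec] = y0[c, ICASUB]
                cai_out[c, rec] = y0[c, ICAI]
    return 0, 0.0, -1


@njit(cache=True)
def integrate_single_full(y0, p, stim, stim_dt, lcr_flux, lcr_dt,
                          dt, n_steps, rec_every, state_out, aux_out):
    """Single-cell Euler integration recording the full state and currents.

    ``state_out`` is (K, N_STATE) and ``aux_out`` (K, N_AUX) with
    ``K = n_steps // rec_every + 1``.  Returns ``(status, t_fail)``.
    """
    m_stim = stim.shape[0]
    m_lcr = lcr_flux.shape[0]
    dy = np.empty(N_STATE)
    aux = np.empty(N_AUX)
    ginf = np.empty(N_HH)
    gtau = np.empty(N_HH)
    rhs(y0, p, -(stim[0] if m_stim > 0 else 0.0),
        lcr_flux[0] if m_lcr > 0 else 0.0, dy, aux, ginf, gtau)
    state_out[0] = y0
    aux_out[0] = aux
    rec = 0
    for step in range(n_steps):
        t = step * dt
        i_stim = 0.0
        if m_stim > 0:
            i_stim = stim[min(int(t / stim_dt), m_stim - 1)]
        jl = 0.0
        if m_lcr > 0:
            jl = lcr_flux[min(int(t / lcr_dt), m_lcr - 1)]
        rhs(y0, p, -i_stim, jl, dy, aux, ginf, gtau)
        _strip_release(y0, p, dy)
        yv = np.empty(N_HH)
        for g in range(N_HH):
            yv[g] = y0[IDL + g]
        for s in range(N_STATE):
            y0[s] = y0[s] + dt * dy[s]
        for g in range(N_HH):
            y0[IDL + g] = ginf[g] + (yv[g] - ginf[g]) * np.exp(-dt / gtau[g])
        _release_exchange(y0, p, dt)
        if not (np.isfinite(y0[IV]) and np.isfinite(y0[ICASUB])
                and np.abs(y0[IV]) < 1500.0):
            return 1, (step + 1) * dt
        if (step + 1) % rec_every == 0:
            rec += 1
            state_out[rec] = y0
            aux_out[rec] = aux
    return 0, 0.0
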