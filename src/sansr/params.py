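"""Parameters of the common-pool coupled-clock pacemaker cell model.

The model couples a sarcolemmal "membrane clock" (L- and T-type Ca currents,
delayed-rectifier K currents, funny current I_f, sustained inward current
I_st, Na/K pump and Na/Ca exchanger) to an intracellular "Ca clock"
(SERCA uptake into the network SR at maximal rate ``P_up``, diffusional
transfer to the junctional SR, and Ca-induced Ca release through a gated
RyR flux into a submembrane shell).  Two parameters — the L-type Ca
conductance density ``g_CaL`` and the SR pumping rate ``P_up`` — set the
strength of the two clocks and are the axes of the firing diagrams
produced by :mod:`sansr.sweep`.

All conductance densities are in nS/pF, concentrations in mM, volumes in
pL, voltages in mV, currents in pA and time constants/rates in seconds
unless a name says otherwise.  The shipped basal set lives in
``data/basal_params.json`` and is the package's versioned reference
parameterization.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "CellParams",
    "CarbacholResponse",
    "basal_params",
    "apply_carbachol",
    "load_params",
    "save_params",
]


@dataclasses.dataclass
class CellParams:
    """Full parameter set of the single-cell model.

    Instances are plain records; validation happens in :meth:`validate`,
    which every simulation entry point calls.
    """

    # --- membrane ---------------------------------------------------------
    C_m: float = 32.0               # capacitance, pF
    g_CaL: float = 0.464            # L-type Ca conductance, nS/pF
    g_CaT: float = 0.1832           # T-type Ca conductance, nS/pF
    g_Kr: float = 0.08113973        # rapid delayed rectifier, nS/pF
    g_Ks: float = 0.0259            # slow delayed rectifier, nS/pF
    g_to: float = 0.252             # transient outward, nS/pF
    g_sus: float = 0.02             # sustained 4-AP-sensitive, nS/pF
    g_If: float = 0.15              # funny current, nS/pF
    g_st: float = 0.021             # sustained inward current, nS/pF
    g_bNa: float = 0.000486         # background Na, nS/pF
    I_NaK_max: float = 2.88         # Na/K pump maximum, pA/pF
    k_NCX: float = 187.5            # Na/Ca exchanger scale, pA/pF
    E_CaL: float = 45.0             # apparent I_CaL reversal, mV
    E_CaT: float = 45.0             # apparent I_CaT reversal, mV
    E_st: float = 37.4              # I_st reversal, mV
    V_If_shift: float = 0.0         # shift of I_f activation midpoint, mV

    # --- fixed ionic milieu ----------------------------------------------
    Na_i: float = 10.0              # mM (clamped)
    K_i: float = 140.0
    Na_o: float = 140.0
    K_o: float = 5.4
    Ca_o: float = 2.0
    Mg_i: float = 2.5
    temperature: float = 310.15     # K

    # --- Ca clock ---------------------------------------------------------
    P_up: float = 12.0              # SERCA maximal uptake rate, mM/s
    K_up: float = 0.001             # uptake affinity, mM
    tau_dif_Ca: float = 0.04e-3     # submembrane -> cytosol diffusion, s
    tau_tr: float = 40.0e-3         # nSR -> jSR transfer, s
    k_s: float = 3.0e7              # RyR release rate constant, 1/s
    k_oCa: float = 10000.0          # RyR opening, 1/(mM^2 s)
    k_om: float = 60.0              # RyR closing, 1/s
    k_iCa: float = 500.0            # RyR inactivation, 1/(mM s)
    k_im: float = 5.0               # RyR recovery, 1/s
    EC50_SR: float = 0.45           # jSR Ca half-activation of release, mM
    Max_SR: float = 15.0            # luminal gating bounds (dimensionless)
    Min_SR: float = 1.0
    H_SR: float = 2.5

    # --- compartment volumes (pL) ----------------------------------------
    V_i: float = 1.58345            # myoplasm available to Ca
    V_sub: float = 0.035098         # submembrane shell
    V_nSR: float = 0.040815         # network SR
    V_jSR: float = 0.0042231        # junctional SR

    # --- Ca buffers -------------------------------------------------------
    TC_tot: float = 0.031           # troponin Ca site, mM
    TMC_tot: float = 0.062          # troponin Mg/Ca site, mM
    CM_tot: float = 0.045           # calmodulin (cytosol and shell), mM
    CQ_tot: float = 10.0            # calsequestrin (jSR), mM
    kf_TC: float = 88800.0          # 1/(mM s)
    kb_TC: float = 446.0            # 1/s
    kf_TMC: float = 227700.0
    kb_TMC: float = 7.51
    kf_TMM: float = 2277.0
    kb_TMM: float = 751.0
    kf_CM: float = 227700.0
    kb_CM: float = 542.0
    kf_CQ: float = 534.0
    kb_CQ: float = 445.0

    # --- cholinergic (carbachol) state ------------------------------------
    g_KACh: float = 0.0             # effective ACh-activated K conductance, nS/pF

    # --- optional stochastic local-release flux ---------------------------
    lcr_rate: float = 5.0           # Poisson event rate, 1/s
    lcr_flux: float = 1.0           # unitary release flux into Ca_sub, mM/s
    lcr_duration: float = 0.020     # event duration, s

    # ----------------------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on physically inadmissible parameters."""
        nonneg = [f.name for f in dataclasses.fields(self)]
        for name in nonneg:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {name} is not finite: {v!r}")
            if name != "V_If_shift" and v < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {v}")
        for name in ("C_m", "V_i", "V_sub", "V_nSR", "V_jSR", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")

    def copy(self, **overrides) -> "CellParams":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CellParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**d)

    def to_vector(self) -> np.ndarray:
        """Flatten to the fixed-order float vector consumed by the engine."""
        return np.array([getattr(self, n) for n in PARAM_ORDER], dtype=np.float64)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "CellParams":
        return cls(**{n: float(v[i]) for i, n in enumerate(PARAM_ORDER)})


#: Engine parameter-vector layout.  The numba kernels index parameters by
#: position; this list is the single source of truth for that layout.
PARAM_ORDER: tuple = tuple(
    f.name for f in dataclasses.fields(CellParams)
)
PARAM_INDEX: dict = {n: i for i, n in enumerate(PARAM_ORDER)}
N_PARAMS: int = len(PARAM_ORDER)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("sansr").joinpath("data", name)))


def basal_params() -> CellParams:
    """Load the shipped basal parameter fixture."""
    return load_params(_data_path("basal_params.json"))


def load_params(path) -> CellParams:
    with open(path) as fh:
        payload = json.load(fh)
    return CellParams.from_dict(payload.get("params", payload))


def save_params(params: CellParams, path, note: str = "") -> None:
    payload = {"format": "sansr-cell-params-v1", "note": note,
               "params": params.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Cholinergic (muscarinic) modulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CarbacholResponse:
    """Dose-response mapping for carbachol (an acetylcholine analog).

    Muscarinic stimulation is represented by three configurable Hill-type
    curves sharing one occupancy term f(c) = c^h / (c^h + ec50^h):

    * an ACh-activated K conductance turned on, ``g_KACh = g_KACh_max * f``;
    * the L-type conductance attenuated, ``g_CaL *= 1 - s_CaL * f``;
    * the SR pumping rate attenuated, ``P_up *= 1 - s_Pup * f``;
    * optionally the I_f activation midpoint shifted negative by
      ``shift_If * f`` (mV).

    The published study applied carbachol at 100, 300 and 1000 nM; the
    default curve renders the basal cell dormant at the highest dose.
    """

    ec50_nM: float = 300.0
    hill: float = 1.3
    g_KACh_max: float = 0.008   # nS/pF at saturating dose
    s_CaL: float = 0.25         # maximal fractional g_CaL inhibition
    s_Pup: float = 0.2          # maximal fractional P_up inhibition
    shift_If: float = 7.5       # maximal negative I_f shift, mV

    def occupancy(self, cch_nM: float) -> float:
        if cch_nM == 0:
            return 0.0
        c = cch_nM ** self.hill
        return c / (c + self.ec50_nM ** self.hill)


def apply_carbachol(params: CellParams, cch_nM: float,
                    response: CarbacholResponse | None = None) -> CellParams:
    """Return a copy of ``params`` modulated by a carbachol dose (nM).

    A zero dose returns an identical parameter set.  Attenuation factors are
    clipped to [0, 1] by construction of the Hill occupancy.
    """
    if not np.isfinite(cch_nM) or cch_nM < 0:
        raise ValueError(f"carbachol concentration must be >= 0 nM, got {cch_nM!r}")
    resp = response or CarbacholResponse()
    f = resp.occupancy(cch_nM)
    if f == 0.0:
        return params.copy()
    return params.copy(
        g_KACh=params.g_KACh + resp.g_KACh_max * f,
        g_CaL=params.g_CaL * (1.0 - resp.s_CaL * f),
        P_up=params.P_up * (1.0 - resp.s_Pup * f),
        V_If_shift=params.V_If_shift - resp.shift_If * f,
    )
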