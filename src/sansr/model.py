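"""Single-cell simulation API for the coupled-clock pacemaker model.

The heavy lifting happens in :mod:`sansr.engine` (numba kernels); this
module provides the typed surface: :class:`CellState`, :func:`derivatives`,
:func:`simulate_cell` and the :class:`SimResult` container.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path

import numpy as np

from . import engine
from .engine import (AUX_NAMES, CONC_INDICES, GATE_INDICES, N_AUX, N_STATE)
from .params import CellParams, basal_params
from .stimulus import StimulusTrace

__all__ = [
    "CellState", "SimResult", "derivatives", "ionic_currents",
    "simulate_cell", "initial_state",
]

#: Human-readable names for the flat state vector, in engine order.
STATE_NAMES = (
    "V_m", "d_L", "f_L", "f_Ca", "d_T", "f_T", "pa_F", "pa_S", "p_i", "n",
    "q", "r", "y", "q_a", "q_i", "Ca_i", "Ca_sub", "Ca_nSR", "Ca_jSR",
    "RyR_R", "RyR_O", "RyR_I", "RyR_RI",
    "f_TC", "f_TMC", "f_TMM", "f_CMi", "f_CMs", "f_CQ",
)


@dataclasses.dataclass
class CellState:
    """Dynamic state of one cell; fields mirror the engine state vector."""

    V_m: float = -60.0
    d_L: float = 0.0
    f_L: float = 1.0
    f_Ca: float = 0.7
    d_T: float = 0.0
    f_T: float = 1.0
    pa_F: float = 0.1
    pa_S: float = 0.1
    p_i: float = 0.8
    n: float = 0.05
    q: float = 0.5
    r: float = 0.01
    y: float = 0.1
    q_a: float = 0.3
    q_i: float = 0.3
    Ca_i: float = 1e-4
    Ca_sub: float = 2e-4
    Ca_nSR: float = 1.2
    Ca_jSR: float = 0.3
    RyR_R: float = 0.7
    RyR_O: float = 1e-6
    RyR_I: float = 1e-6
    RyR_RI: float = 0.3
    f_TC: float = 0.02
    f_TMC: float = 0.3
    f_TMM: float = 0.6
    f_CMi: float = 0.04
    f_CMs: float = 0.05
    f_CQ: float = 0.3

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=np.float64)

    @classmethod
    def from_vector(cls, v) -> "CellState":
        return cls(**{n: float(v[i]) for i, n in enumerate(STATE_NAMES)})

    def validate(self) -> None:
        v = self.to_vector()
        if not np.all(np.isfinite(v)):
            bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(v))]
            raise ValueError(f"non-finite state variables: {bad}")
        gates = v[GATE_INDICES]
        if np.any(gates < -1e-9) or np.any(gates > 1.0 + 1e-9):
            raise ValueError("gating/occupancy variables must lie in [0, 1]")
        if np.any(v[CONC_INDICES] < 0):
            raise ValueError("Ca concentrations must be nonnegative")


def _state_fixture_path() -> Path:
    return Path(str(resources.files("sansr").joinpath("data", "initial_state.json")))


def initial_state() -> CellState:
    """Shipped initial-state fixture (late-diastolic basal-model state)."""
    with open(_state_fixture_path()) as fh:
        payload = json.load(fh)
    return CellState(**payload["state"])


def derivatives(state: CellState, params: CellParams,
                i_inject: float = 0.0) -> CellState:
    """Time derivative of every state variable (per second).

    ``i_inject`` is a membrane current in pA in the same outward-positive
    convention as the ionic currents, so a positive value hyperpolarizes:
    ``dV_m/dt = -(sum I_ion + i_inject) / C_m``.  The stimulus layer
    (:mod:`sansr.stimulus`) uses depolarizing-positive amplitudes and the
    simulation drivers negate them before reaching this level.
    """
    params.validate()
    state.validate()
    y = state.to_vector()
    dy = np.empty(N_STATE)
    aux = np.empty(N_AUX)
    ginf = np.empty(engine.N_HH)
    gtau = np.empty(engine.N_HH)
    engine.rhs(y, params.to_vector(), float(i_inject), 0.0, dy, aux, ginf, gtau)
    return CellState.from_vector(dy)


def ionic_currents(state: CellState, params: CellParams) -> dict:
    """All membrane currents (pA, outward positive) at the given state."""
    params.validate()
    state.validate()
    dy = np.empty(N_STATE)
    aux = np.empty(N_AUX)
    ginf = np.empty(engine.N_HH)
    gtau = np.empty(engine.N_HH)
    engine.rhs(state.to_vector(), params.to_vector(), 0.0, 0.0, dy, aux,
               ginf, gtau)
    return dict(zip(AUX_NAMES, aux.tolist()))


@dataclasses.dataclass
class SimResult:
    """Traces from one simulation on a uniform time grid."""

    time: np.ndarray          # s
    vm: np.ndarray            # mV
    currents: dict            # name -> pA trace (outward positive)
    ca: dict                  # compartment -> mM trace
    stim: np.ndarray          # applied stimulus, pA, depolarizing positive
    states: np.ndarray        # (K, N_STATE) decimated full state
    final_state: CellState
    provenance: dict

    def to_frame(self):
        import pandas as pd
        cols = {"time_s": self.time, "V_m_mV": self.vm,
                "stim_pA": self.stim}
        for k, tr in self.ca.items():
            cols[f"{k}_mM"] = tr
        for k, tr in self.currents.items():
            cols[f"{k}_pA"] = tr
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_hdf5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as h5:
            h5.create_dataset("time", data=self.time)
            h5.create_dataset("vm", data=self.vm)
            h5.create_dataset("stim", data=self.stim)
            h5.create_dataset("states", data=self.states)
            g = h5.create_group("currents")
            for k, tr in self.currents.items():
                g.create_dataset(k, data=tr)
            g = h5.create_group("ca")
            for k, tr in self.ca.items():
                g.create_dataset(k, data=tr)
            h5.attrs["provenance"] = json.dumps(self.provenance)


class IntegrationBlowupError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""

    def __init__(self, t: float, cell: int | None = None):
        self.t = t
        self.cell = cell
        where = f" in cell {cell}" if cell is not None else ""
        super().__init__(
            f"integration produced a non-finite state at t = {t:.6f} s{where}; "
            "the time step may be too large for these parameters")


def _lcr_flux_train(duration: float, grid_dt: float, params: CellParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Poisson train of unitary submembrane Ca-release fluxes (mM/s)."""
    n = int(np.ceil(duration / grid_dt))
    flux = np.zeros(n)
    n_events = rng.poisson(params.lcr_rate * duration)
    starts = rng.uniform(0.0, duration, size=n_events)
    width = max(1, int(round(params.lcr_duration / grid_dt)))
    for t0 in starts:
        i0 = int(t0 / grid_dt)
        flux[i0:i0 + width] += params.lcr_flux
    return flux


def simulate_cell(params: CellParams,
                  stimulus: StimulusTrace | None = None,
                  duration: float = 20.0,
                  dt_ms: float = 0.01,
                  record_dt_ms: float = 1.0,
                  seed: int | None = None,
                  stochastic_lcr: bool = False,
                  init: CellState | None = None) -> SimResult:
    """Integrate the cell model and return recorded traces.

    Parameters
    ----------
    stimulus : optional injected-current waveform, depolarizing positive
        (pA); sampled onto the integration grid by sample-and-hold.
    duration : simulated time, s.
    dt_ms : fixed integration step, ms (forward Euler).
    record_dt_ms : decimation interval of the recorded traces, ms.
    seed : seeds the stochastic local-release train only; the noise inside
        a stimulus is owned by its segments' own seeds.
    stochastic_lcr : add a Poisson train of unitary Ca-release fluxes into
        the submembrane space (rate/flux/duration from ``params``).

    Identical inputs give bit-identical results.
    """
    params.validate()
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if dt_ms <= 0:
        raise ValueError("dt_ms must be > 0")
    dt = dt_ms * 1e-3
    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(record_dt_ms / dt_ms)))

    state0 = init if init is not None else initial_state()
    state0.validate()
    y = state0.to_vector()

    if stimulus is not None:
        stim_dt = min(1e-3, dt)  # sample-and-hold grid, never coarser than 1 ms
        stim_arr = stimulus.build_array(stim_dt, duration)
    else:
        stim_dt = 1.0
        stim_arr = np.zeros(0)

    if stochastic_lcr:
        rng = np.random.default_rng(seed)
        lcr_dt = 1e-3
        lcr_arr = _lcr_flux_train(duration, lcr_dt, params, rng)
    else:
        lcr_dt = 1.0
        lcr_arr = np.zeros(0)

    k_rec = n_steps // rec_every + 1
    state_out = np.empty((k_rec, N_STATE))
    aux_out = np.empty((k_rec, N_AUX))
    status, t_fail = engine.integrate_single_full(
        y, params.to_vector(), stim_arr, stim_dt, lcr_arr, lcr_dt,
        dt, n_steps, rec_every, state_out, aux_out)
    if status != 0:
        raise IntegrationBlowupError(t_fail)

    time = np.arange(k_rec) * rec_every * dt
    if stim_arr.size:
        idx = np.minimum((time / stim_dt).astype(np.int64), stim_arr.size - 1)
        stim_rec = stim_arr[idx]
    else:
        stim_rec = np.zeros(k_rec)
    currents = {name: aux_out[:, i].copy() for i, name in enumerate(AUX_NAMES)}
    ca = {"Ca_i": state_out[:, engine.ICAI].copy(),
          "Ca_sub": state_out[:, engine.ICASUB].copy(),
          "Ca_nSR": state_out[:, engine.ICANSR].copy(),
          "Ca_jSR": state_out[:, engine.ICAJSR].copy()}
    prov = {"dt_ms": dt_ms, "record_dt_ms": record_dt_ms, "seed": seed,
            "duration_s": duration, "stochastic_lcr": bool(stochastic_lcr),
            "integrator": "euler-fixed", "params": params.to_dict()}
    return SimResult(time=time, vm=state_out[:, engine.IV].copy(),
                     currents=currents, ca=ca, stim=stim_rec,
                     states=state_out, final_state=CellState.from_vector(y),
                     provenance=prov)


def total_calcium(state: CellState, params: CellParams) -> float:
    """Volume-weighted total Ca (free + buffered, all compartments), amol.

    Used by the closed-cell conservation check: with all sarcolemmal Ca
    fluxes disabled this quantity is a constant of motion.
    """
    p = params
    cyt = state.Ca_i + p.CM_tot * state.f_CMi + p.TC_tot * state.f_TC \
        + p.TMC_tot * state.f_TMC
    sub = state.Ca_sub + p.CM_tot * state.f_CMs
    jsr = state.Ca_jSR + p.CQ_tot * state.f_CQ
    return (cyt * p.V_i + sub * p.V_sub + state.Ca_nSR * p.V_nSR
            + jsr * p.V_jSR)
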