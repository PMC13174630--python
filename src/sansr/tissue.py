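"""2-D lattice of gap-junction-coupled pacemaker cells.

The tissue experiment: all cells share g_CaL = 0.37 nS/pF while per-cell
P_up values are drawn uniformly from (0, 9.5) mM/s, placing most cells in
the non-firing zone.  Without noise the few intrinsically firing cells are
loaded down by their dormant neighbors and the lattice progresses into
sinus arrest within a few cycles; with independent per-cell noise currents
the tissue keeps firing.  Nearest-neighbor resistive coupling
``g_gap * sum(V_self - V_neighbor)`` with no-flux borders; the coupling
current therefore sums to zero over the lattice at every instant.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import engine
from .ap_metrics import APTrain, detect_aps
from .model import IntegrationBlowupError, initial_state
from .params import CellParams, basal_params

__all__ = [
    "TissueConfig", "TissueResult", "build_tissue", "simulate_tissue",
    "detect_arrest", "neighbor_table",
]


@dataclasses.dataclass(frozen=True)
class TissueConfig:
    nx: int = 15
    ny: int = 15
    g_gap: float = 2.0            # nS (calibrated default, see methods note)
    g_cal: float = 0.37           # nS/pF, shared
    p_up_low: float = 0.0         # mM/s, exclusive lower bound
    p_up_high: float = 9.5        # mM/s
    noise_amp: float = 0.0        # pA per cell, 0 = none
    duration: float = 6.0         # s
    dt_ms: float = 0.02
    hold_ms: float = 1.0
    seed: int = 0                 # seeds the P_up draw

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if self.g_gap < 0:
            raise ValueError("g_gap must be >= 0")
        if not (0 <= self.p_up_low < self.p_up_high <= 12.0):
            raise ValueError("P_up interval must lie within [0, 12] mM/s")
        if self.noise_amp < 0 or self.duration <= 0 or self.dt_ms <= 0:
            raise ValueError("invalid noise amplitude, duration or dt")

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny


def neighbor_table(nx: int, ny: int) -> np.ndarray:
    """(n_cells, 4) von-Neumann neighbor indices, -1 at no-flux borders."""
    nb = np.full((nx * ny, 4), -1, dtype=np.int64)
    for iy in range(ny):
        for ix in range(nx):
            c = iy * nx + ix
            if ix > 0:
                nb[c, 0] = c - 1
            if ix < nx - 1:
                nb[c, 1] = c + 1
            if iy > 0:
                nb[c, 2] = c - nx
            if iy < ny - 1:
                nb[c, 3] = c + nx
    return nb


@dataclasses.dataclass
class Tissue:
    """Initialized lattice: per-cell parameters plus coupling topology."""

    config: TissueConfig
    cells: list                   # CellParams per cell, row-major
    p_up_draw: np.ndarray         # the seeded per-cell P_up values
    neighbors: np.ndarray


def build_tissue(config: TissueConfig,
                 base: CellParams | None = None) -> Tissue:
    """Draw per-cell P_up and lay out the coupled lattice."""
    base = base or basal_params()
    rng = np.random.default_rng(config.seed)
    p_up = rng.uniform(config.p_up_low, config.p_up_high,
                       size=config.n_cells)
    cells = [base.copy(g_CaL=config.g_cal, P_up=float(pu)) for pu in p_up]
    return Tissue(config=config, cells=cells, p_up_draw=p_up,
                  neighbors=neighbor_table(config.nx, config.ny))


@dataclasses.dataclass
class TissueResult:
    time: np.ndarray              # s
    vm: np.ndarray                # (n_cells, K) mV
    trains: list                  # APTrain per cell
    arrest_time: float | None
    config: TissueConfig
    noise_seed: int | None

    @property
    def mean_vm(self) -> np.ndarray:
        return self.vm.mean(axis=0)

    def per_cell_rates(self, window: tuple | None = None) -> np.ndarray:
        from .ap_metrics import firing_metrics
        w = window or (0.0, float(self.time[-1]))
        return np.array([firing_metrics(tr, w).mean_frequency
                         for tr in self.trains])

    def summary(self) -> dict:
        return {"arrest_time_s": self.arrest_time,
                "n_cells": self.config.n_cells,
                "noise_amp_pA": self.config.noise_amp,
                "duration_s": self.config.duration,
                "n_cells_with_aps": int(sum(len(t) > 0 for t in self.trains))}

    def to_json(self, path) -> None:
        payload = self.summary()
        payload["per_cell_rates_Hz"] = self.per_cell_rates().tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    def to_hdf5(self, path, decimate: int = 1) -> None:
        import h5py
        with h5py.File(path, "w") as h5:
            h5.create_dataset("time", data=self.time[::decimate])
            h5.create_dataset("vm", data=self.vm[:, ::decimate])
            h5.attrs["config"] = json.dumps(dataclasses.asdict(self.config))


def simulate_tissue(tissue: Tissue, noise_amp: float | None = None,
                    seed: int | None = None,
                    quiescence_window: float = 2.0) -> TissueResult:
    """Integrate the coupled lattice and diagnose arrest.

    ``noise_amp`` overrides the config amplitude; per-cell noise streams
    are independent and derived reproducibly from ``seed``.
    """
    cfg = tissue.config
    amp = cfg.noise_amp if noise_amp is None else noise_amp
    n = cfg.n_cells
    dt = cfg.dt_ms * 1e-3
    n_steps = int(round(cfg.duration / dt))
    rec_every = max(1, int(round(1e-3 / dt)))
    k_rec = n_steps // rec_every + 1

    y_init = initial_state().to_vector()
    y0 = np.tile(y_init, (n, 1))
    pmat = np.stack([c.to_vector() for c in tissue.cells])
    hold = cfg.hold_ms * 1e-3
    if amp > 0:
        n_hold = int(np.ceil(cfg.duration / hold))
        root = np.random.SeedSequence([0 if seed is None else int(seed),
                                       cfg.seed, 7])
        stim = np.empty((n, n_hold))
        for c, child in enumerate(root.spawn(n)):
            stim[c] = np.random.default_rng(child).uniform(-amp, amp, n_hold)
    else:
        stim = np.zeros((n, 0))

    vm_out = np.empty((n, k_rec))
    casub_out = np.empty((n, k_rec))
    cai_out = np.empty((n, k_rec))
    status, t_fail, c_fail = engine.integrate_batch(
        y0, pmat, stim, hold, np.zeros((n, 0)), 1.0, dt, n_steps, rec_every,
        tissue.neighbors, cfg.g_gap, vm_out, casub_out, cai_out)
    if status != 0:
        raise IntegrationBlowupError(t_fail, cell=c_fail)

    time = np.arange(k_rec) * rec_every * dt
    trains = [detect_aps(time, vm_out[c]) for c in range(n)]
    result = TissueResult(time=time, vm=vm_out, trains=trains,
                          arrest_time=None, config=dataclasses.replace(
                              cfg, noise_amp=amp),
                          noise_seed=seed)
    result.arrest_time = detect_arrest(result, quiescence_window)
    return result


def detect_arrest(result: TissueResult,
                  quiescence_window: float = 2.0) -> float | None:
    """Time of the last tissue-wide AP followed by >= ``quiescence_window``
    of silence in every cell; ``None`` if activity persists to the end."""
    if quiescence_window <= 0:
        raise ValueError("quiescence window must be > 0")
    all_times = np.sort(np.concatenate(
        [tr.times for tr in result.trains] or [np.empty(0)]))
    t_end = float(result.time[-1])
    if all_times.size == 0:
        return 0.0
    t_last = float(all_times[-1])
    if t_end - t_last >= quiescence_window:
        return t_last
    return None
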