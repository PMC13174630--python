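"""Two-parameter firing diagrams over (g_CaL, P_up).

The full-resolution diagram spans g_CaL 0.28-0.52 nS/pF in 0.0025 steps
(97 values) and P_up 0-12 mM/s in 0.2 steps (61 values): 5,917 cell models
per condition, 23,668 over the four basal/carbachol x noise conditions.
A reduced 13 x 9 grid is the desk-scale default; the full sweep is exposed
through the CLI.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import engine
from .model import CellState, IntegrationBlowupError, initial_state
from .params import CellParams, apply_carbachol, basal_params
from .ap_metrics import detect_aps, firing_metrics, FiringMetrics

__all__ = [
    "SweepGrid", "SweepDiagram", "arange_inclusive", "build_grid",
    "run_sweep", "diagram_delta", "FULL_GCAL_RANGE", "FULL_PUP_RANGE",
    "REDUCED_GCAL_RANGE", "REDUCED_PUP_RANGE",
]

#: Full-resolution axis specifications (start, stop, step).
FULL_GCAL_RANGE = (0.28, 0.52, 0.0025)
FULL_PUP_RANGE = (0.0, 12.0, 0.2)
#: Reduced desk-scale axes (13 x 9).
REDUCED_GCAL_RANGE = (0.28, 0.52, 0.02)
REDUCED_PUP_RANGE = (0.0, 12.0, 1.5)


def arange_inclusive(start: float, stop: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid with exact integer counting.

    The number of points is computed as ``round((stop-start)/step) + 1``
    with a half-step tolerance, so float axes like 0.28:0.0025:0.52 yield
    exactly 97 values with no accumulation drift.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if stop < start:
        raise ValueError("range must satisfy start <= stop")
    span = (stop - start) / step
    n = int(np.floor(span + 0.5)) + 1
    if abs(span - round(span)) > 0.5:  # stop not on the lattice: truncate
        n = int(np.floor(span)) + 1
    return start + step * np.arange(n)


@dataclasses.dataclass(frozen=True)
class SweepGrid:
    g_cal_values: np.ndarray     # nS/pF, ascending
    p_up_values: np.ndarray      # mM/s, ascending
    condition: str               # "basal" | "carbachol"
    noise_amp: float             # pA, 0 = deterministic
    carbachol_nM: float = 300.0  # dose used when condition == "carbachol"

    def __post_init__(self):
        for name in ("g_cal_values", "p_up_values"):
            v = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, v)
            if v.size == 0 or np.any(np.diff(v) <= 0) and v.size > 1:
                raise ValueError(f"{name} must be non-empty and ascending")
        if self.condition not in ("basal", "carbachol"):
            raise ValueError("condition must be 'basal' or 'carbachol'")
        if self.noise_amp < 0:
            raise ValueError("noise amplitude must be >= 0")

    @property
    def shape(self) -> tuple:
        return (self.g_cal_values.size, self.p_up_values.size)

    @property
    def n_points(self) -> int:
        return self.g_cal_values.size * self.p_up_values.size

    def cell_params(self, i: int, j: int,
                    base: CellParams | None = None) -> CellParams:
        p = (base or basal_params()).copy(
            g_CaL=float(self.g_cal_values[i]),
            P_up=float(self.p_up_values[j]))
        if self.condition == "carbachol":
            p = apply_carbachol(p, self.carbachol_nM)
        return p


def build_grid(gcal_range=FULL_GCAL_RANGE, pup_range=FULL_PUP_RANGE,
               condition: str = "basal", noise_amp: float = 0.0,
               carbachol_nM: float = 300.0) -> SweepGrid:
    """Construct a sweep grid from (start, stop, step) axis specs."""
    return SweepGrid(
        g_cal_values=arange_inclusive(*gcal_range),
        p_up_values=arange_inclusive(*pup_range),
        condition=condition, noise_amp=noise_amp,
        carbachol_nM=carbachol_nM)


@dataclasses.dataclass
class SweepDiagram:
    grid: SweepGrid
    metrics: list                # list of FiringMetrics, None for failed
    failed: np.ndarray           # bool per point
    seed: int
    duration: float
    discard: float

    def _field(self, getter, default=np.nan) -> np.ndarray:
        out = np.full(self.grid.shape, default, dtype=float)
        k = 0
        for i in range(self.grid.shape[0]):
            for j in range(self.grid.shape[1]):
                m = self.metrics[k]
                if m is not None:
                    out[i, j] = getter(m)
                k += 1
        return out

    @property
    def rates(self) -> np.ndarray:
        return self._field(lambda m: m.mean_frequency)

    @property
    def firing_mask(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=bool)
        k = 0
        for i in range(self.grid.shape[0]):
            for j in range(self.grid.shape[1]):
                m = self.metrics[k]
                out[i, j] = (m is not None and m.firing)
                k += 1
        return out

    @property
    def n_firing(self) -> int:
        return int(self.firing_mask.sum())

    @property
    def n_non_firing(self) -> int:
        return self.grid.n_points - self.n_firing

    def to_frame(self):
        import pandas as pd
        rows = []
        k = 0
        for i, g in enumerate(self.grid.g_cal_values):
            for j, pu in enumerate(self.grid.p_up_values):
                m = self.metrics[k]
                rows.append({
                    "g_CaL": g, "P_up": pu,
                    "rate_Hz": m.mean_frequency if m else np.nan,
                    "cv": m.cv if m else np.nan,
                    "class": m.cell_class if m else "failed",
                    "failed": bool(self.failed.flat[k]),
                })
                k += 1
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {"condition": self.grid.condition,
                "noise_amp_pA": self.grid.noise_amp,
                "n_points": self.grid.n_points,
                "n_firing": self.n_firing,
                "n_non_firing": self.n_non_firing,
                "n_failed": int(self.failed.sum()),
                "seed": self.seed}


def point_seed(master_seed: int, i: int, j: int, condition: str,
               noise_amp: float) -> np.random.SeedSequence:
    """Deterministic per-point seed so any point can be re-run alone."""
    cond_code = 0 if condition == "basal" else 1
    return np.random.SeedSequence(
        [int(master_seed), i, j, cond_code, int(round(noise_amp * 16))])


def run_sweep(grid: SweepGrid, duration: float = 20.0, discard: float = 5.0,
              dt_ms: float = 0.01, seed: int = 0, chunk: int = 256,
              hold_ms: float = 1.0, base: CellParams | None = None,
              progress: bool = False) -> SweepDiagram:
    """Simulate every grid point and compute firing metrics.

    All points run through the vectorized batch integrator (the tissue
    engine with zero coupling), chunked to bound memory.  Per-point noise
    realizations derive from ``seed`` via :func:`point_seed`.
    """
    base = base or basal_params()
    dt = dt_ms * 1e-3
    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(1e-3 / dt)))   # record every 1 ms
    k_rec = n_steps // rec_every + 1
    time = np.arange(k_rec) * rec_every * dt
    hold = hold_ms * 1e-3
    n_hold = int(np.ceil(duration / hold))

    y_init = initial_state().to_vector()
    points = [(i, j) for i in range(grid.shape[0]) for j in range(grid.shape[1])]
    metrics: list = [None] * len(points)
    failed = np.zeros(len(points), dtype=bool)

    no_neighbors = np.full((1, 4), -1, dtype=np.int64)
    for lo in range(0, len(points), chunk):
        block = points[lo:lo + chunk]
        nb = len(block)
        y0 = np.tile(y_init, (nb, 1))
        pmat = np.empty((nb, y_init.size * 0 + len(base.to_vector())))
        for b, (i, j) in enumerate(block):
            pmat[b] = grid.cell_params(i, j, base=base).to_vector()
        if grid.noise_amp > 0:
            stim = np.empty((nb, n_hold))
            for b, (i, j) in enumerate(block):
                rng = np.random.default_rng(
                    point_seed(seed, i, j, grid.condition, grid.noise_amp))
                stim[b] = rng.uniform(-grid.noise_amp, grid.noise_amp, n_hold)
        else:
            stim = np.zeros((nb, 0))
        vm_out = np.empty((nb, k_rec))
        casub_out = np.empty((nb, k_rec))
        cai_out = np.empty((nb, k_rec))
        status, t_fail, c_fail = engine.integrate_batch(
            y0, pmat, stim, hold, np.zeros((nb, 0)), 1.0, dt, n_steps,
            rec_every, np.broadcast_to(no_neighbors, (nb, 4)).copy(), 0.0,
            vm_out, casub_out, cai_out)
        if status != 0:
            # mark the failed point, rerun the rest of the chunk one by one
            for b, (i, j) in enumerate(block):
                try:
                    m = _single_point_metrics(
                        grid, i, j, base, duration, discard, dt_ms, seed,
                        hold_ms)
                    metrics[lo + b] = m
                except IntegrationBlowupError:
                    failed[lo + b] = True
        else:
            for b in range(nb):
                train = detect_aps(time, vm_out[b])
                metrics[lo + b] = firing_metrics(train, (discard, duration))
        if progress:
            print(f"sweep [{grid.condition}, {grid.noise_amp} pA]: "
                  f"{min(lo + chunk, len(points))}/{len(points)}")
    return SweepDiagram(grid=grid, metrics=metrics,
                        failed=failed.reshape(-1), seed=seed,
                        duration=duration, discard=discard)


def _single_point_metrics(grid, i, j, base, duration, discard, dt_ms, seed,
                          hold_ms) -> FiringMetrics:
    from .model import simulate_cell
    from .stimulus import StimulusTrace, noise_segment

    p = grid.cell_params(i, j, base=base)
    stim = None
    if grid.noise_amp > 0:
        ss = point_seed(seed, i, j, grid.condition, grid.noise_amp)
        stim = StimulusTrace(segments=[noise_segment(
            grid.noise_amp, duration, hold_ms=hold_ms, seed=ss)])
    res = simulate_cell(p, stimulus=stim, duration=duration, dt_ms=dt_ms)
    train = detect_aps(res.time, res.vm)
    return firing_metrics(train, (discard, duration))


@dataclasses.dataclass(frozen=True)
class DiagramDelta:
    awakened: int                # non-firing -> firing
    silenced: int                # firing -> non-firing
    mean_rate_change: float      # Hz, among always-firing points
    n_always_firing: int


def diagram_delta(d0: SweepDiagram, d1: SweepDiagram) -> DiagramDelta:
    """Quantify the firing-region change between two diagrams.

    ``d0`` is the reference (e.g. no noise), ``d1`` the comparison (e.g.
    with noise); grids must coincide in axes.
    """
    if (not np.array_equal(d0.grid.g_cal_values, d1.grid.g_cal_values)
            or not np.array_equal(d0.grid.p_up_values, d1.grid.p_up_values)):
        raise ValueError("diagram grids do not match")
    m0, m1 = d0.firing_mask, d1.firing_mask
    awakened = int((~m0 & m1).sum())
    silenced = int((m0 & ~m1).sum())
    both = m0 & m1
    if both.any():
        dr = float((d1.rates[both] - d0.rates[both]).mean())
    else:
        dr = float("nan")
    return DiagramDelta(awakened=awakened, silenced=silenced,
                        mean_rate_change=dr, n_always_firing=int(both.sum()))
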