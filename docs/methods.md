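# Methods

This note documents the models and procedures implemented in `sansr`, the
assumptions behind them, the parameters that matter, and the design choices
made where the design was genuinely open.

## The single-cell coupled-clock model

`sansr.model` implements a "common-pool" coupled-clock pacemaker cell of the
Kurata/Maltsev–Lakatta lineage: a sarcolemmal membrane clock (I_CaL, I_CaT,
I_Kr, I_Ks, I_to, I_sus, I_f, I_st, I_bNa, the Na/K pump and the Na/Ca
exchanger in the four-state electrogenic formulation) coupled to an
intracellular Ca clock (SERCA uptake into the network SR at maximal rate
P_up, diffusional nSR→jSR transfer with τ_tr = 40 ms, and Ca-induced Ca
release through a four-state RyR scheme with luminal-Ca-dependent gating).
Compartments: bulk myoplasm, a thin submembrane shell (where I_CaL, NCX and
RyR release meet), network SR and junctional SR, with troponin, calmodulin
and calsequestrin buffering. Intracellular Na⁺ and K⁺ are clamped, so the
cell has no slow drift in monovalent gradients; total Ca is conserved
exactly when the sarcolemmal Ca pathways are disabled, which the test suite
checks.

Two parameters define the cell's position in the firing landscape and are
the axes of all firing diagrams:

* `g_CaL` (nS/pF) — L-type conductance density, membrane-clock strength;
* `P_up` (mM/s) — SR pumping rate, Ca-clock strength.

The basal set (`sansr/data/basal_params.json`) fires spontaneously at
3.57 Hz with MDP ≈ −65 mV, peak ≈ +10 mV, diastolic Ca_i ≈ 0.1 µM and
systolic ≈ 0.4 µM. The shipped dormant-zone fixture (g_CaL = 0.37 nS/pF,
P_up = 1 mM/s) is silent with subthreshold membrane-potential drift, the
hallmark of a dormant cell.

### Provenance of the constants and the calibrated four

Most rate constants follow the published common-pool formulation this model
family is known by. Four constants were calibrated by us, because with the
literature values we could reconstruct offline the model stalled a few mV
below the I_CaL activation threshold instead of firing:

* `g_bNa` = 0.000486 nS/pF — a background Na conductance ten times larger
  produces ≈ −17 pA at diastolic potentials and creates a spurious stable
  equilibrium near −37 mV;
* `K_up` = 1.0 µM — SERCA affinity; together with
* `g_st` = 0.021 nS/pF — the sustained inward current density, this pair
  sets (i) the position of the firing boundary in the (g_CaL, P_up) plane
  (at g_CaL = 0.37 nS/pF cells fire only for P_up ≳ 7–8 mM/s, so the tissue
  draw below is mostly non-firing), and (ii) a *narrow* hysteresis between
  the firing and dormant attractors — cells started on the firing cycle at
  low P_up drop out within a few beats rather than free-running;
* `k_s` = 3×10⁷ s⁻¹ — RyR release rate scale consistent with millisecond
  release dynamics through the tiny junctional SR.

The funny-current activation gate enters linearly (y, not y²); with the
squared gate the reconstructed diastolic depolarization is ≈ 7 mV short.
The calibration targets were the qualitative behaviors this package is
about — basal rhythmic firing, a dormancy zone at low P_up/g_CaL, the
boundary location implied by the tissue parameter range, carbachol-induced
dormancy — not any particular published trace.

### Carbachol

Muscarinic stimulation is a parameter transformation
(`apply_carbachol`): a Hill occupancy f(c) = c^h/(c^h + EC50^h) with
EC50 = 300 nM and h = 1.3 drives three effects — an ACh-activated K⁺
conductance (up to 0.008 nS/pF, mildly inward-rectified), 25 % maximal
inhibition of g_CaL, 20 % maximal inhibition of P_up, and a −7.5 mV shift
of I_f activation. The published study does not print its dose–response
formulas; these defaults make the basal cell slow gradually through 100 and
300 nM (3.57 → 3.51 → 3.40 Hz) and become dormant at 1000 nM, the behavior
reported for the experimental dose ladder. All four curves are config
fields.

### Stochastic local-release option

`simulate_cell(..., stochastic_lcr=True)` adds a Poisson train of unitary
Ca-release fluxes into the submembrane shell (defaults: 5 s⁻¹, 1 mM/s,
20 ms). It exists to produce coupled subthreshold V_m–Ca fluctuations in
non-firing regimes — a one-dial stand-in for spontaneous local releases of
a spatially resolved Ca-release-unit network, which is out of scope here.
It is off by default and seeded.

## Numerics

The canonical integrator is fixed-step with dt = 0.01 ms so that stochastic
forcing has a well-defined realization:

* concentrations, buffers and the RyR Markov states advance by forward
  Euler;
* the 14 Hodgkin–Huxley gates advance by the exponential (Rush–Larsen)
  update, which is exact for frozen rates and unconditionally stable — the
  I_CaT activation time constant falls to ~0.5 µs at very negative
  voltages, where plain Euler explodes under strong noise;
* the jSR→submembrane release exchange, whose rate k_s·O can exceed
  10⁷ s⁻¹ during a synchronized dump, is split off and integrated exactly
  per step as a volume-conserving exponential relaxation of the
  concentration difference.

Gate rates are evaluated at a voltage clamped to [−250, +150] mV (far
outside the physiological range) so exponentials stay finite under extreme
stimuli; driving forces use the true V_m. If a state still becomes
non-finite (or |V_m| exceeds 1.5 V), integration aborts with an error
naming the time and, in tissue, the cell. Halving dt changes the basal
rate by < 0.02 %. Stimuli of ~2000 pA and above exceed the model's validity
and abort; the bell-shape analysis uses 1000 pA as its extreme point. The
batch/tissue paths default to dt = 0.02 ms (the arrest/rescue and
diagram results are unchanged, at half the cost); single-cell runs keep
0.01 ms.

## Stimuli

Sine epochs are `a·sin(2πFt)` with `a` the one-direction amplitude (peak
`a`, peak-to-peak `2a`); the alternative reading of the published waveform
expression (peak `2a`) is a one-line change in `sine_segment`. Noise
epochs are band-limited white noise as uniform sample-and-hold on
[−a, +a], default hold 1 ms: the bounded support matches the pA amplitude
language and the spectrum is flat far beyond the cell's sub-10-Hz
resonance band. Gaussian draws are available behind a flag. Segments are
pure functions of (parameters, seed).

## AP detection and firing metrics

The detector (`detect_aps`) marks upward crossings of −20 mV that open a
*suprathreshold event*: the event tolerates sub-10-ms dips below threshold
(debounce), must last 40–400 ms, must be smooth (median per-ms |ΔV| ≤
5 mV/ms) and must respect an 80 ms refractory period. The dwell and
smoothness bounds express AP stereotypy: a genuine AP holds a depolarized,
high-conductance, low-impedance plateau for tens of ms, whereas extreme
noise produces brief, jagged excursions. Measured on this model, real APs
dwell ≈ 82 ms with roughness 0.4–1.9 mV/ms at the study's amplitudes
(≤ 125 pA), while 1000 pA excursions dwell 3–27 ms with roughness
≈ 15 mV/ms — the criteria sit in the wide gap between the two. All
settings are keyword arguments.

Firing metrics: mean of per-beat instantaneous frequencies, CV = SD/mean
of those frequencies (sample SD; undefined below 3 APs, when the rate
falls back to count/window), population classes fast (> 2.5 Hz), moderate
(1–2.5 Hz), slow (< 1 Hz) and dormant (no APs). One-to-one capture:
|mean frequency − F| ≤ 0.1 Hz with ≥ 2 APs, evaluated after a 2 s settle
inside each sine epoch (entrainment establishes within one or two cycles).

On the shipped fixtures the basal cell captures 2–5 Hz at 25 pA and 2–6 Hz
at 50 pA (larger amplitudes capture supersets, extending toward higher
frequencies); the dormant fixture shows a band-pass-like spectrum centered
near 2 Hz rather than a pure low-frequency band — at amplitudes ≥ 15 pA it
also follows 5 Hz once awakened. Capture below ~1 Hz fails in this model
because the awakened cell free-runs near its own ≈ 3 Hz rhythm between
stimulus crests.

## Firing diagrams

`sansr.sweep` evaluates firing metrics over inclusive arithmetic grids of
(g_CaL, P_up) with exact integer point counting (the full-resolution axes
are 97 × 61 = 5,917 points per condition; four conditions = 23,668
models). Each point runs 20 s (defaults) with a 5 s settling discard from
the shipped late-diastolic initial state; per-point noise uses a
deterministic sub-seed derived from (master seed, i, j, condition,
amplitude), so any point can be re-run in isolation. The desk-scale
default is a reduced 13 × 9 grid; the full sweep is a CLI option. All
points are integrated in vectorized batches (the tissue engine with zero
coupling), chunked to bound memory.

## Tissue model

A 2-D lattice (default 15 × 15) of cells sharing g_CaL = 0.37 nS/pF with
per-cell P_up drawn i.i.d. uniform from (0, 9.5) mM/s — most cells land in
the non-firing zone. Nearest-neighbor resistive coupling adds
g_gap·Σ(V_self − V_neighbor) to each membrane equation with no-flux
borders, so the coupling current sums to zero over the lattice at every
step. Cells start from the shared late-diastolic basal state — the tissue
behaves like a preparation that was beating normally before being placed
in suppressed conditions: it fires a few synchronized cycles while each
cell's SR re-equilibrates to its own P_up, then the dormant majority loads
the few intrinsic firers and the lattice falls silent (sinus arrest,
detected as ≥ 2 s of tissue-wide silence after the last AP). With
independent per-cell noise at 125 pA — the largest amplitude of the
study's experimental series — firing persists for the whole run. The
contrast is robust over ≥ 5 heterogeneity draws.

`g_gap` defaults to 2 nS; arrest/rescue holds from 1 to at least 8 nS.
Per-cell noise at 25–50 pA does *not* rescue this lattice: gap junctions
shunt local fluctuations, raising the effective noise threshold above the
isolated-cell value (25 pA awakens an isolated dormant cell). Noise
streams are independent per cell (biological noise sources are local) and
reproducible from one seed.

## Ca-imaging analysis

* **Normalization** — per-pixel ΔF/F0 with F0 the 10th temporal
  percentile; non-positive-baseline pixels are masked.
* **Global-transient separation** — the AP-induced Ca transient lights the
  whole field with one shared time course, i.e. it is a rank-1 term of the
  pixel × time matrix. The leading principal component of the uncentered
  matrix (one component by default; a config key) is reconstructed and
  subtracted; the residual holds local activity. The published pipeline's
  dedicated matrix-decomposition denoiser is not reimplemented: the
  separation rests on the principal-component subtraction, and an optional
  denoising pass can be inserted upstream by the caller.
* **LCR detection** — the residual is thresholded at k·MAD (k = 3) per
  pixel over time, 26-connected components in (x, y, t) are extracted, and
  components shorter than 2 frames or smaller than 4 px² are dropped. An
  event's **path area** is the area of its 2-D spatial projection — the
  full territory swept over its lifetime, which credits propagating waves
  with everything they recruit. Path areas are reported in px² and µm².
* **Tail statistics** — unbiased sample L-moments via probability-weighted
  moments; L-kurtosis τ₄ = λ₄/λ₂ (0 for uniform, 1/6 for exponential),
  location/scale invariant. The mean-excess function
  e(u) = mean(x − u | x > u) is reported over a threshold ladder with a
  minimum-exceedance rule (default 10); flat ⇒ exponential tail,
  increasing with slope ξ/(1−ξ) ⇒ generalized-Pareto tail of shape ξ.
* **V_m–Ca cross-correlation** — both traces are linearly detrended over
  the analysis window and correlated with energy normalization (values
  bounded by 1); positive peak lag means Ca lags V_m. With the
  `subthreshold` flag the window must end before the first AP: once APs
  fire, each AP is strictly correlated with its own Ca transient and the
  correlation is trivially strong.

## Synthetic data

`sansr.synth` generates movies with the structure the analysis assumes:
an exactly rank-1 global part (one smooth gain map × baseline-plus-APCT
time course, 4 Hz, 20 ms rise / 120 ms decay), three local patterns —
propagating cell-width waves (50–150 µm/s, ~6 µm wide), small fast LCRs
(2–6 frames, binary-disk footprints whose areas are drawn from a
lognormal or generalized-Pareto family), and incoherent AP-like flashes
(cell-shaped footprints with APCT kinetics at jittered times) — plus
i.i.d. Gaussian sensor noise. Event amplitudes default to the APCT
amplitude (background signals comparable in magnitude to the global
transients). Every generator is a pure function of (spec, seed) and
returns a ground-truth table.

The LCR footprints are deliberately sharp-edged so that "path area" is
well defined independently of the detection threshold; real events have
soft edges, so area recovery on real data is threshold-dependent in a way
these tests do not probe. The generator also does not emulate motion,
photobleaching, or the spatial correlation structure of real sensor
noise — passing tests show the pipeline's correctness on its stated model
of the data, not robustness to those artifacts.

Paired V_m/Ca traces: a band-limited latent process (Gaussian-filtered
white noise, ~5 Hz bandwidth) enters V_m directly and Ca scaled by a
coupling in [0, 1] and delayed by a configurable lag, each with
independent additive noise; optional AP/transient pairs can be stamped on
top. AP trains: gamma-renewal with requested rate and CV (CV = 0 is
exactly periodic).

## Problem sizes used by the shipped checks

The test suite and the reproduction script run desk-scale versions of each
experiment: 20 s single-cell runs (5 s discard), the reduced 13 × 9
diagram at dt = 0.02 ms, tissue lattices of 10 × 10 (tests) or 15 × 15
(script) for 6 s, five seeds per stochastic claim, 10⁵-sample L-moment
checks and 300-frame 64 × 64 synthetic movies. The full 97 × 61 sweep is
reachable through `sansr sweep --full`.

## Known limitations

* The cell model is a common-pool reconstruction with four calibrated
  constants (above); it reproduces the qualitative firing landscape, not
  any specific published voltage trace.
* Intracellular Na⁺/K⁺ are clamped; slow autonomic/metabolic drift and
  species differences are out of scope.
* The dormant fixture's resonance spectrum is band-pass around ~2 Hz; the
  pure low-frequency capture band seen in some experimental dormant cells
  is not reproduced.
* The tissue lattice is a square grid with uniform coupling — no SAN
  geometry, fibrosis, or exit pathways.
* Experimental cohort statistics (ANOVA-style group comparisons) and
  reproduction of measured L-kurtosis values require the deposited
  recordings and are excluded.
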