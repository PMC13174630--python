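"""Single-cell model: derivatives structure, conservation, determinism,
rhythm, carbachol modulation and numerical convergence."""

import dataclasses

import numpy as np
import pytest

from sansr import (CellParams, CellState, IntegrationBlowupError,
                   apply_carbachol, derivatives, initial_state,
                   ionic_currents, simulate_cell, total_calcium)
from sansr.ap_metrics import detect_aps, firing_metrics
from sansr.engine import CONC_INDICES, GATE_INDICES
from sansr.model import STATE_NAMES
from sansr.stimulus import StimulusTrace, noise_segment

#: Frozen regression value: basal firing rate at the default step after the
#: 5 s settling window (dt-halving changes it by < 0.02%).
BASAL_RATE_HZ = 3.574


def _gate_steady_state(state, params):
    """Solve each gate's steady state from two derivative evaluations.

    For a first-order gate dy/dt = (y_inf - y)/tau, two evaluations at
    different gate values give y_inf = (y2*d1 - y1*d2)/(d1 - d2); this is
    an independent closed-form oracle, no access to the rate tables.
    """
    v = state.to_vector()
    gates = [i for i in GATE_INDICES if STATE_NAMES[i] not in
             ("RyR_R", "RyR_O", "RyR_I", "RyR_RI", "f_TC", "f_TMC", "f_TMM",
              "f_CMi", "f_CMs", "f_CQ")]
    out = v.copy()
    for i in gates:
        y1, y2 = 0.25, 0.75
        s1 = CellState.from_vector(np.where(np.arange(v.size) == i, y1, v))
        s2 = CellState.from_vector(np.where(np.arange(v.size) == i, y2, v))
        d1 = derivatives(s1, params).to_vector()[i]
        d2 = derivatives(s2, params).to_vector()[i]
        out[i] = (y2 * d1 - y1 * d2) / (d1 - d2)
    return CellState.from_vector(out)


class TestDerivatives:
    def test_fully_decoupled_system_is_static(self):
        p = CellParams(g_CaL=0, g_CaT=0, g_Kr=0, g_Ks=0, g_to=0, g_sus=0,
                       g_If=0, g_st=0, g_bNa=0, I_NaK_max=0, k_NCX=0,
                       P_up=0, k_s=0, k_oCa=0, k_iCa=0, k_om=0, k_im=0,
                       kf_TC=0, kb_TC=0, kf_TMC=0, kb_TMC=0, kf_TMM=0,
                       kb_TMM=0, kf_CM=0, kb_CM=0, kf_CQ=0, kb_CQ=0)
        # equal Ca everywhere kills transfer/diffusion gradients
        s = CellState(Ca_i=2e-4, Ca_sub=2e-4, Ca_nSR=2e-4, Ca_jSR=2e-4)
        s = _gate_steady_state(s, p)
        dy = derivatives(s, p).to_vector()
        assert np.allclose(dy, 0.0, atol=1e-7)

    def test_injected_current_linearity(self, basal, init_state):
        d0 = derivatives(init_state, basal, i_inject=0.0)
        d1 = derivatives(init_state, basal, i_inject=10.0)
        # outward-positive convention: +10 pA lowers dV_m/dt by 10/C_m (V/s)
        assert d1.V_m - d0.V_m == pytest.approx(-10.0 / basal.C_m * 1e3,
                                                rel=1e-12)

    def test_dvdt_equals_minus_summed_currents(self, basal, init_state):
        """One-current-at-a-time oracle: the full dV_m/dt equals the sum of
        individually computed current contributions (each current scales
        linearly with its own conductance/scale parameter)."""
        knobs = ["g_CaL", "g_CaT", "g_Kr", "g_Ks", "g_to", "g_sus", "g_If",
                 "g_st", "g_bNa", "I_NaK_max", "k_NCX", "g_KACh"]
        p_full = basal.copy(g_KACh=0.004)
        p_none = p_full.copy(**{k: 0.0 for k in knobs})
        dv_none = derivatives(init_state, p_none).V_m
        total = dv_none
        for k in knobs:
            p_only = p_none.copy(**{k: getattr(p_full, k)})
            total += derivatives(init_state, p_only).V_m - dv_none
        dv_full = derivatives(init_state, p_full).V_m
        assert dv_full == pytest.approx(total, rel=1e-12, abs=1e-9)

    def test_currents_match_reported_sum(self, basal, init_state):
        cur = ionic_currents(init_state, basal)
        dv = derivatives(init_state, basal).V_m
        assert dv == pytest.approx(-sum(cur.values()) / basal.C_m * 1e3,
                                   rel=1e-10)

    def test_nonfinite_state_rejected(self, basal, init_state):
        bad = dataclasses.replace(init_state, V_m=float("nan"))
        with pytest.raises(ValueError, match="non-finite"):
            derivatives(bad, basal)

    def test_invalid_params_rejected(self, init_state):
        with pytest.raises(ValueError):
            derivatives(init_state, CellParams(g_CaL=-1.0))


class TestSimulation:
    def test_basal_rhythm_and_frozen_rate(self, basal_run):
        m = firing_metrics(detect_aps(basal_run.time, basal_run.vm),
                           (5.0, 20.0))
        assert m.cell_class == "fast"
        assert m.cv < 0.05
        assert m.mean_frequency == pytest.approx(BASAL_RATE_HZ, abs=0.01)

    def test_dt_halving_convergence(self, basal):
        r2 = simulate_cell(basal, duration=20.0, dt_ms=0.005)
        m2 = firing_metrics(detect_aps(r2.time, r2.vm), (5.0, 20.0))
        assert abs(m2.mean_frequency - BASAL_RATE_HZ) / BASAL_RATE_HZ < 0.005

    def test_closed_cell_conserves_calcium(self, basal):
        p = basal.copy(g_CaL=0.0, g_CaT=0.0, k_NCX=0.0)
        r = simulate_cell(p, duration=10.0)
        tot = np.array([total_calcium(CellState.from_vector(s), p)
                        for s in r.states[::200]])
        assert (tot.max() - tot.min()) / tot[0] < 1e-3

    def test_bit_identical_reruns(self, dormant):
        stim = StimulusTrace(segments=[noise_segment(62.5, 5.0, seed=5)])
        r1 = simulate_cell(dormant, stimulus=stim, duration=5.0, seed=9,
                           stochastic_lcr=True)
        r2 = simulate_cell(dormant, stimulus=stim, duration=5.0, seed=9,
                           stochastic_lcr=True)
        assert np.array_equal(r1.vm, r2.vm)
        assert np.array_equal(r1.states, r2.states)

    def test_different_seed_changes_stochastic_part_only(self, dormant):
        r1 = simulate_cell(dormant, duration=5.0, seed=1, stochastic_lcr=True)
        r2 = simulate_cell(dormant, duration=5.0, seed=2, stochastic_lcr=True)
        r3 = simulate_cell(dormant, duration=5.0, seed=1)
        assert not np.array_equal(r1.ca["Ca_sub"], r2.ca["Ca_sub"])
        # without the stochastic release the seed is inert
        r4 = simulate_cell(dormant, duration=5.0, seed=2)
        assert np.array_equal(r3.vm, r4.vm)

    def test_gates_and_concentrations_stay_physical(self, dormant):
        stim = StimulusTrace(segments=[noise_segment(125.0, 8.0, seed=11)])
        r = simulate_cell(dormant, stimulus=stim, duration=8.0)
        states = r.states
        gates = states[:, GATE_INDICES]
        assert gates.min() >= -1e-9 and gates.max() <= 1.0 + 1e-9
        assert states[:, CONC_INDICES].min() >= 0.0

    def test_stochastic_lcr_produces_subthreshold_fluctuations(self, dormant):
        p = dormant.copy(lcr_rate=8.0, lcr_flux=2.0)
        r_off = simulate_cell(p, duration=10.0)
        r_on = simulate_cell(p, duration=10.0, seed=3, stochastic_lcr=True)
        late = r_on.time > 5.0
        assert r_on.ca["Ca_sub"][late].std() > 3 * r_off.ca["Ca_sub"][late].std()
        assert r_on.vm[late].std() > r_off.vm[late].std()

    def test_oversized_step_raises_blowup(self, basal):
        with pytest.raises(IntegrationBlowupError, match="t ="):
            simulate_cell(basal, duration=2.0, dt_ms=1.0)

    def test_stimulus_recorded_as_requested(self, dormant):
        stim = StimulusTrace(segments=[noise_segment(62.5, 3.0, seed=2)])
        r = simulate_cell(dormant, stimulus=stim, duration=3.0)
        # recorded samples fall exactly on hold boundaries, where float
        # division may resolve to either adjacent hold; accept both
        t = r.time[(r.time > 1e-3) & (r.time < 3.0 - 1e-3)]
        rec = r.stim[(r.time > 1e-3) & (r.time < 3.0 - 1e-3)]
        left = stim.sample(t - 0.25e-3)
        right = stim.sample(t + 0.25e-3)
        assert np.all(np.isclose(rec, left) | np.isclose(rec, right))


class TestCarbachol:
    def test_zero_dose_identity(self, basal):
        assert apply_carbachol(basal, 0.0) == basal

    def test_negative_dose_rejected(self, basal):
        with pytest.raises(ValueError):
            apply_carbachol(basal, -1.0)

    def test_dose_monotone_modulation(self, basal):
        doses = [100.0, 300.0, 1000.0]
        mods = [apply_carbachol(basal, d) for d in doses]
        g_kach = [m.g_KACh for m in mods]
        g_cal = [m.g_CaL for m in mods]
        p_up = [m.P_up for m in mods]
        assert g_kach == sorted(g_kach) and g_kach[0] > 0
        assert g_cal == sorted(g_cal, reverse=True)
        assert p_up == sorted(p_up, reverse=True)

    def test_rate_non_increasing_to_dormancy(self, basal):
        rates = []
        for dose in (0.0, 100.0, 300.0, 1000.0):
            r = simulate_cell(apply_carbachol(basal, dose), duration=20.0)
            m = firing_metrics(detect_aps(r.time, r.vm), (5.0, 20.0))
            rates.append(m.mean_frequency)
        assert all(a >= b - 1e-9 for a, b in zip(rates, rates[1:]))
        assert rates[-1] == 0.0   # dormancy at the configured high dose
        assert rates[0] > 3.0
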