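"""Membrane dynamics against closed-form solutions."""

import math

import numpy as np
import pytest

from v1plasticity.core import (
    GapJunctionParams,
    NetworkState,
    NeuronParams,
    NoiseParams,
    NumericalError,
    apply_threshold_and_reset,
    gap_junction_event,
    integrate_membrane_step,
)

DT = 0.1
PRM = NeuronParams()
NO_NOISE = NoiseParams(enabled=False)


def _state(n=1, v=-60.0):
    s = NetworkState.zeros(n)
    s.v[:] = v
    return s


def test_neuron_params_validated():
    with pytest.raises(ValueError):
        NeuronParams(g_l=-1.0)
    with pytest.raises(ValueError):
        NeuronParams(V_I=-50.0)  # violates V_I < V_l
    assert PRM.tau_m == pytest.approx(20.0)


def test_resting_fixed_point():
    s = _state()
    for _ in range(1000):
        integrate_membrane_step(s, PRM, NO_NOISE, None, DT)
    assert s.v[0] == pytest.approx(-60.0, abs=1e-12)


def test_single_euler_step_with_excitatory_conductance():
    # 1 nS driving force of 60 mV on 200 pF over 0.1 ms -> +0.03 mV
    s = _state()
    s.g_E[0] = 1.0
    integrate_membrane_step(s, PRM, NO_NOISE, None, DT)
    assert s.v[0] == pytest.approx(-60.0 + 0.03, abs=1e-12)
    # conductance decayed exactly
    assert s.g_E[0] == pytest.approx(math.exp(-DT / PRM.tau_E), rel=1e-12)


def test_passive_relaxation_matches_exponential():
    s = _state(v=-50.01)
    t = 0.0
    for _ in range(600):  # 60 ms ~ 3 membrane time constants
        integrate_membrane_step(s, PRM, NO_NOISE, None, DT)
        t += DT
        expected = PRM.V_l + (-50.01 - PRM.V_l) * math.exp(-t / PRM.tau_m)
        # forward-Euler error is O(dt/tau_m) relative to the deflection
        assert abs(s.v[0] - expected) < 2 * (DT / PRM.tau_m) * 10.0


def test_psp_matches_conductance_double_exponential():
    """A small conductance jump produces the linearised double-exponential PSP."""
    w = 0.01  # nS, small so the driving-force linearisation holds
    s = _state()
    s.g_E[0] = w
    tau_m, tau_s = PRM.tau_m, PRM.tau_E
    amp = w * (PRM.V_E - PRM.V_l) / PRM.C_m / (1 / tau_s - 1 / tau_m)
    t_peak = math.log(tau_m / tau_s) / (1 / tau_s - 1 / tau_m)
    traj = []
    for k in range(1500):
        integrate_membrane_step(s, PRM, NO_NOISE, None, DT)
        traj.append(s.v[0] - PRM.V_l)
    traj = np.asarray(traj)
    t = (np.arange(1500) + 1) * DT
    expected = amp * (np.exp(-t / tau_m) - np.exp(-t / tau_s))
    peak_err = abs(traj.max() - expected.max()) / expected.max()
    assert peak_err < 0.03  # Euler error at dt/tau_E = 2%
    assert abs(t[traj.argmax()] - t_peak) < 1.0  # ms


def test_threshold_inclusive_and_reset():
    s = _state(n=3)
    s.v[:] = [-49.9, -55.0, PRM.v_theta]  # above, below, exactly at threshold
    s, spikes = apply_threshold_and_reset(s, PRM)
    assert spikes.tolist() == [0, 2]
    assert s.v[0] == -60.0 and s.v[2] == -60.0
    assert s.v[1] == -55.0


def test_spikelet_increment_and_decay():
    gap = GapJunctionParams(pv_indices=np.arange(2))
    s = _state(n=2)
    gap_junction_event(s, gap, np.array([0]))
    assert s.I_spikelet[1] == pytest.approx(13.0)
    assert s.I_spikelet[0] == 0.0  # no self-coupling
    for _ in range(90):  # 9 ms = one spikelet time constant
        integrate_membrane_step(s, PRM, NO_NOISE, gap, DT)
    assert s.I_spikelet[1] == pytest.approx(13.0 / math.e, rel=1e-9)


def test_spikelet_charge_equals_cgap_tau():
    gap = GapJunctionParams(pv_indices=np.arange(2))
    s = _state(n=2)
    gap_junction_event(s, gap, np.array([0]))
    charge = 0.0
    for _ in range(2000):  # 200 ms >> tau_spikelet
        charge += s.I_spikelet[1] * DT
        integrate_membrane_step(s, PRM, NO_NOISE, gap, DT)
    assert charge == pytest.approx(gap.c_gap * gap.tau_spikelet, rel=0.01)


def test_gap_event_rejects_non_pv_spikes():
    gap = GapJunctionParams(pv_indices=np.arange(2, 4))
    s = _state(n=4)
    with pytest.raises(ValueError):
        gap_junction_event(s, gap, np.array([0]))


def test_gap_event_with_explicit_pairs():
    pairs = np.array([[0, 1], [1, 0], [0, 2]])
    gap = GapJunctionParams(pv_indices=np.arange(3), pairs=pairs)
    s = _state(n=3)
    gap_junction_event(s, gap, np.array([0]))
    assert s.I_spikelet.tolist() == [0.0, 13.0, 13.0]


def test_noise_stationary_sd_matches_documented_discretisation():
    """Empirical leak-only voltage s.d. equals sigma within 5%.

    The white-increment discretisation is constructed so the stationary
    voltage s.d. of the leak-only membrane equals sigma = 2 mV; pooled over
    50 neurons x 20 s (1000 neuron-seconds) after burn-in.
    """
    noise = NoiseParams()
    rng = np.random.default_rng(7)
    s = _state(n=50)
    n_burn, n_keep = 2000, 200_000
    for _ in range(n_burn):
        integrate_membrane_step(s, PRM, noise, None, DT, rng=rng)
    acc = 0.0
    acc2 = 0.0
    cnt = 0
    for _ in range(n_keep):
        integrate_membrane_step(s, PRM, noise, None, DT, rng=rng)
        acc += s.v.sum()
        acc2 += (s.v**2).sum()
        cnt += s.v.size
    var = acc2 / cnt - (acc / cnt) ** 2
    assert math.sqrt(var) == pytest.approx(noise.sigma, rel=0.05)


def test_conductances_remain_nonnegative_under_random_input():
    rng = np.random.default_rng(0)
    s = _state(n=10)
    for _ in range(500):
        s.g_E += rng.random(10) * 0.5
        s.g_I += rng.random(10) * 0.5
        integrate_membrane_step(s, PRM, NO_NOISE, None, DT)
        apply_threshold_and_reset(s, PRM)
        assert (s.g_E >= 0).all() and (s.g_I >= 0).all()
        assert (s.I_spikelet >= 0).all()


def test_nonfinite_state_raises_named_error():
    s = _state(n=3)
    s.v[1] = np.inf
    with pytest.raises(NumericalError, match="neuron 1"):
        integrate_membrane_step(s, PRM, NO_NOISE, None, DT)
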