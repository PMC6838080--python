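"""Connectivity sampling, weight initialisation and spike delivery."""

import numpy as np
import pytest
from scipy import stats

from v1plasticity.connectivity import (
    ConnectivitySpec,
    assemble_dense,
    default_connectivity,
    deliver_spikes,
    initialize_weights,
    sample_connectivity,
    truncated_normal,
)
from v1plasticity.core import NetworkState, PopulationSpec


def _populations():
    return [
        PopulationSpec("E", "E", 400, np.repeat(np.arange(4), 100)),
        PopulationSpec("P", "P", 120, None),
        PopulationSpec("S", "S", 120, np.repeat(np.arange(4), 30)),
        PopulationSpec("V", "V", 50, None),
    ]


@pytest.fixture(scope="module")
def sampled():
    spec = default_connectivity()
    rng = np.random.default_rng(123)
    groups = sample_connectivity(spec, _populations(), rng)
    initialize_weights(groups, spec, np.random.default_rng(5))
    return spec, {(g.pre_pop.name, g.post_pop.name): g for g in groups}


def test_probability_matrix_validation():
    bad = default_connectivity()
    bad.P = bad.P.copy()
    with pytest.raises(ValueError):
        ConnectivitySpec(P=np.full((4, 4), 1.5))


def test_connection_counts_within_binomial_bounds(sampled):
    spec, groups = sampled
    # every sampled pathway's realised count within the exact binomial 99% CI
    for (pre, post), g in groups.items():
        n_pairs = g.pre_pop.size * g.post_pop.size
        p = spec.prob(g.post_pop.cell_class, g.pre_pop.cell_class)
        if p == 1.0:
            expected = n_pairs - (g.pre_pop.size if pre == post else 0)
            assert g.n_connections == expected  # complete minus autapses
        else:
            lo, hi = stats.binom.ppf([0.005, 0.995], n_pairs, p)
            assert lo <= g.n_connections <= hi


def test_vip_to_pc_pathway_sparse(sampled):
    _, groups = sampled
    g = groups[("V", "E")]
    # P_EV = 0.125 over 50 x 400 ordered pairs -> about 2500 connections
    lo, hi = stats.binom.ppf([0.005, 0.995], 50 * 400, 0.125)
    assert lo <= g.n_connections <= hi


def test_no_autapses(sampled):
    _, groups = sampled
    for (pre, post), g in groups.items():
        if pre == post:
            assert not np.any(g.pre_idx == g.post_idx)


def test_vip_to_vip_weights_are_zero(sampled):
    _, groups = sampled
    g = groups[("V", "V")]
    assert np.all(g.w == 0.0)  # pathway effectively absent despite P_VV > 0


def test_fixed_weights_match_measured_values(sampled):
    _, groups = sampled
    assert np.all(groups[("E", "P")].w == 0.12)   # PC -> PV
    assert np.all(groups[("P", "E")].w == 0.55)   # PV -> PC
    assert np.all(groups[("S", "E")].w == 0.3)    # SST -> PC
    assert np.all(groups[("E", "S")].w == 0.07)   # PC -> SST


def test_plastic_flags_and_signs(sampled):
    _, groups = sampled
    assert groups[("E", "E")].plastic and groups[("E", "E")].sign == "exc"
    assert groups[("S", "P")].plastic and groups[("S", "P")].sign == "inh"
    assert not groups[("P", "E")].plastic
    assert groups[("P", "E")].sign == "inh"


def test_truncated_normal_mean():
    # rejection-sampled N(0.01, 0.01) truncated at 0:
    # mean = mu + sigma * phi(-1)/(1 - Phi(-1)) ~ 0.012876
    rng = np.random.default_rng(99)
    x = truncated_normal(0.01, 0.01, 200_000, rng)
    assert (x >= 0).all()
    expected = 0.01 + 0.01 * stats.norm.pdf(-1) / stats.norm.sf(-1)
    assert x.mean() == pytest.approx(expected, rel=0.02)


def test_ee_initial_weights_are_truncated_gaussian(sampled):
    _, groups = sampled
    w = groups[("E", "E")].w
    assert (w >= 0).all()
    expected = 0.01 + 0.01 * stats.norm.pdf(-1) / stats.norm.sf(-1)
    assert w.mean() == pytest.approx(expected, rel=0.03)


def test_sampling_reproducible():
    spec = default_connectivity()
    g1 = sample_connectivity(spec, _populations(), np.random.default_rng(7))
    g2 = sample_connectivity(spec, _populations(), np.random.default_rng(7))
    for a, b in zip(g1, g2):
        assert np.array_equal(a.pre_idx, b.pre_idx)
        assert np.array_equal(a.post_idx, b.post_idx)


def test_deliver_spikes_superposition(sampled):
    _, groups = sampled
    n = 690
    state = NetworkState.zeros(n)
    g = groups[("P", "E")]  # inhibitory PV -> PC
    # two presynaptic PVs spiking onto shared targets: increments add
    spikes = np.unique(g.pre_idx)[:2]
    deliver_spikes([g], spikes, state)
    expected = np.zeros(n)
    for j in spikes:
        sel = g.pre_idx == j
        np.add.at(expected, g.post_idx[sel], g.w[sel])
    assert np.allclose(state.g_I, expected)
    assert np.all(state.g_E == 0)
    # no spikes: nothing changes
    before = state.g_I.copy()
    deliver_spikes([g], np.array([], dtype=int), state)
    assert np.array_equal(state.g_I, before)


def test_dense_assembly_matches_group_delivery(sampled):
    """Column sums of the dense matrix equal per-group delivery (oracle)."""
    _, groups = sampled
    glist = list(groups.values())
    n = 690
    W, masks = assemble_dense(glist, n)
    rng = np.random.default_rng(17)
    spikes = rng.choice(n, size=25, replace=False)
    state_a = NetworkState.zeros(n)
    deliver_spikes(glist, spikes, state_a)
    # classify spiking neurons by the sign of the groups they are pre in
    exc_ids = {j for g in glist if g.sign == "exc" for j in g.pre_idx}
    gE = W[:, [s for s in spikes if s in exc_ids]].sum(axis=1)
    gI = W[:, [s for s in spikes if s not in exc_ids]].sum(axis=1)
    assert np.allclose(state_a.g_E, gE)
    assert np.allclose(state_a.g_I, gI)
    assert set(masks) == {("E", "E"), ("P", "S")}
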