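"""Cell-type connectivity: probabilities, initial weights, spike delivery.

Classes are ordered E (pyramidal), P (PV), S (SST), V (VIP).  The class-level
connection probability matrix ``P[post, pre]`` and initial weight matrix
``W[post, pre]`` (nS) follow measured mouse V1 L2/3 connectivity; two entries
are sampled per connection from Gaussians truncated at zero (E->E:
N(0.01, 0.01); S->P, i.e. the SST-to-PV pathway: N(0.2, 0.1)).  The PC->PC
and SST->PV pathways are plastic; all others are fixed.

Presynaptic sign follows the cell class: E (and the top-down relay) are
excitatory, P/S/V inhibitory.  A presynaptic spike increments the
postsynaptic g_E or g_I by the connection weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import NetworkState, PopulationSpec

__all__ = [
    "CLASSES",
    "ConnectivitySpec",
    "SynapseGroup",
    "default_connectivity",
    "sample_connectivity",
    "initialize_weights",
    "deliver_spikes",
    "assemble_dense",
    "truncated_normal",
]

CLASSES = ("E", "P", "S", "V")

# connection probabilities P[post][pre], order E, P, S, V
_P_DEFAULT = np.array(
    [
        [1.0, 1.0, 1.0, 0.125],
        [0.88, 1.0, 0.857, 0.125],
        [1.0, 0.125, 0.125, 1.0],
        [1.0, 1.0, 1.0, 0.125],
    ]
)

# initial weights (nS); tuples are (mean, sd) of a zero-truncated Gaussian
_W_DEFAULT: dict[tuple[str, str], float | tuple[float, float]] = {
    ("E", "E"): (0.01, 0.01), ("E", "P"): 0.55, ("E", "S"): 0.3, ("E", "V"): 0.0675,
    ("P", "E"): 0.12, ("P", "P"): 0.55, ("P", "S"): (0.2, 0.1), ("P", "V"): 0.0675,
    ("S", "E"): 0.07, ("S", "P"): 0.08, ("S", "S"): 0.0675, ("S", "V"): 0.195,
    ("V", "E"): 0.07, ("V", "P"): 0.12, ("V", "S"): 0.42, ("V", "V"): 0.0,
}

_PLASTIC_DEFAULT = frozenset({("E", "E"), ("P", "S")})
_WMAX_DEFAULT = {("E", "E"): 0.25, ("P", "S"): 1.0}


@dataclass
class ConnectivitySpec:
    """Class-level connection probabilities, initial weights, plastic set."""

    P: np.ndarray = field(default_factory=lambda: _P_DEFAULT.copy())
    W_init: dict = field(default_factory=lambda: dict(_W_DEFAULT))
    plastic_pathways: frozenset = _PLASTIC_DEFAULT
    w_max: dict = field(default_factory=lambda: dict(_WMAX_DEFAULT))

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (4, 4):
            raise ValueError("P must be 4x4 (classes E, P, S, V)")
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("connection probabilities must lie in [0, 1]")
        for key, val in self.W_init.items():
            if not isinstance(val, tuple) and val < 0:
                raise ValueError(f"negative fixed weight for {key}")

    def prob(self, post_class: str, pre_class: str) -> float:
        return float(self.P[CLASSES.index(post_class), CLASSES.index(pre_class)])

    def scale_pc_to_interneurons(self, factor: float) -> "ConnectivitySpec":
        """Return a copy with PC->PV/SST/VIP strengths multiplied by ``factor``.

        Used by the two-location (translation-invariance) network, where each
        interneuron pools input from twice as many PCs.
        """
        w = dict(self.W_init)
        for post in ("P", "S", "V"):
            w[(post, "E")] = w[(post, "E")] * factor
        return ConnectivitySpec(self.P.copy(), w, self.plastic_pathways,
                                dict(self.w_max))


def default_connectivity() -> ConnectivitySpec:
    return ConnectivitySpec()


@dataclass
class SynapseGroup:
    """One directed pathway between two populations.

    ``pre_idx``/``post_idx`` are parallel arrays of global neuron indices for
    the sampled connections; ``w`` the per-connection weights (nS).
    """

    pre_pop: PopulationSpec
    post_pop: PopulationSpec
    pre_idx: np.ndarray
    post_idx: np.ndarray
    w: np.ndarray
    sign: str  # 'exc' or 'inh'
    plastic: bool = False
    w_max: float = np.inf

    @property
    def n_connections(self) -> int:
        return self.pre_idx.shape[0]

    def check_bounds(self) -> None:
        if self.w.size and (self.w.min() < 0 or self.w.max() > self.w_max):
            raise ValueError(
                f"weights out of [0, {self.w_max}] in "
                f"{self.pre_pop.name}->{self.post_pop.name}"
            )


def _sign_of(cell_class: str) -> str:
    return "exc" if cell_class in ("E", "relay") else "inh"


def sample_connectivity(
    spec: ConnectivitySpec,
    populations: list[PopulationSpec],
    rng: np.random.Generator,
    offsets: dict[str, int] | None = None,
    exclude=None,
) -> list[SynapseGroup]:
    """Sample Bernoulli connectivity for every class pathway.

    ``populations`` must contain the E, P, S, V classes ('relay' populations
    are skipped; the reward pathway is wired by the engine).  Each ordered
    neuron pair across a pathway is connected independently with the class
    probability; autapses are excluded.  ``offsets`` maps population name to
    its first global neuron index (defaults to cumulative order).  ``exclude``
    is an optional ``f(post_pop, pre_pop) -> bool`` predicate to drop whole
    population pairs (e.g. cross-location PC->PC).
    """
    classes_present = {p.cell_class for p in populations}
    if not {"E", "P", "S", "V"} <= classes_present:
        raise ValueError("populations must include all four classes E, P, S, V")
    if offsets is None:
        offsets = {}
        start = 0
        for p in populations:
            offsets[p.name] = start
            start += p.size

    groups: list[SynapseGroup] = []
    for post in populations:
        if post.cell_class == "relay":
            continue
        for pre in populations:
            if pre.cell_class == "relay":
                continue
            if exclude is not None and exclude(post, pre):
                continue
            prob = spec.prob(post.cell_class, pre.cell_class)
            if prob == 0.0:
                continue
            conn = rng.random((post.size, pre.size)) < prob
            if post.name == pre.name:
                np.fill_diagonal(conn, False)  # no autapses
            post_loc, pre_loc = np.nonzero(conn)
            key = (post.cell_class, pre.cell_class)
            groups.append(
                SynapseGroup(
                    pre_pop=pre,
                    post_pop=post,
                    pre_idx=pre_loc + offsets[pre.name],
                    post_idx=post_loc + offsets[post.name],
                    w=np.zeros(post_loc.shape[0]),
                    sign=_sign_of(pre.cell_class),
                    plastic=key in spec.plastic_pathways,
                    w_max=spec.w_max.get(key, np.inf),
                )
            )
    return groups


def truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-truncated Gaussian by rejection sampling (redraw negatives)."""
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def initialize_weights(
    groups: list[SynapseGroup],
    spec: ConnectivitySpec,
    rng: np.random.Generator,
) -> list[SynapseGroup]:
    """Assign initial weights: fixed scalars, or truncated-Gaussian draws."""
    for g in groups:
        entry = spec.W_init[(g.post_pop.cell_class, g.pre_pop.cell_class)]
        if isinstance(entry, tuple):
            g.w = truncated_normal(entry[0], entry[1], g.n_connections, rng)
        else:
            g.w = np.full(g.n_connections, float(entry))
        assert (g.w >= 0).all()
    return groups


def deliver_spikes(
    groups: list[SynapseGroup], spikes: np.ndarray, state: NetworkState
) -> NetworkState:
    """Increment g_E/g_I of targets of this step's spiking presynaptic cells."""
    spikes = np.asarray(spikes)
    if spikes.size == 0:
        return state
    for g in groups:
        sel = np.isin(g.pre_idx, spikes)
        if sel.any():
            target = state.g_E if g.sign == "exc" else state.g_I
            np.add.at(target, g.post_idx[sel], g.w[sel])
    return state


def assemble_dense(
    groups: list[SynapseGroup], n_neurons: int
) -> tuple[np.ndarray, dict]:
    """Pack groups into one dense weight matrix W[post, pre] plus masks.

    Returns (W, masks) where masks maps each plastic group's
    (post_pop.name, pre_pop.name) to a boolean connection matrix over the full
    index space.  Fixed and plastic pathways share W; the engine delivers
    spikes via columns of W and updates plastic sub-blocks through the masks.
    """
    W = np.zeros((n_neurons, n_neurons))
    masks: dict[tuple[str, str], np.ndarray] = {}
    for g in groups:
        W[g.post_idx, g.pre_idx] = g.w
        if g.plastic:
            key = (g.post_pop.name, g.pre_pop.name)
            m = masks.setdefault(key, np.zeros((n_neurons, n_neurons), dtype=bool))
            m[g.post_idx, g.pre_idx] = True
    return W, masks
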