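"""Rate-coded point-neuron dynamics with k-winners-take-all inhibition.

Units are modeled as conductance-based point neurons whose membrane
potential Vm relaxes toward the conductance-weighted mean of three reversal
potentials (excitation, inhibition, leak) and whose output is a saturating
threshold-linear rate in [0, 1].  Layer-level inhibition is not simulated
with explicit interneurons: a single uniform inhibitory conductance per
inhibitory pool is set each step so that approximately ``k`` units can
remain above threshold (kWTA).

All state is held in :class:`LayerState`; :func:`settle` advances a set of
layers connected by gated :class:`Projection` objects for a fixed number of
synchronous steps, which is how each theta phase is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DynamicsParams",
    "LayerState",
    "Projection",
    "net_excitation",
    "step_membrane",
    "activation_fn",
    "threshold_conductance",
    "kwta_conductance",
    "settle",
]


@dataclass
class DynamicsParams:
    """Constants of the unit equations.

    g_l, gain and threshold are the framework constants (0.1, 100, 0.5);
    reversal potentials and the integration rate are config-exposed with
    the defaults below.  ``kwta_pt`` places the inhibitory conductance
    between the k-th and (k+1)-th threshold conductances (0 = at the
    (k+1)-th, 1 = at the k-th); 0.5 splits the gap evenly.
    """

    g_l: float = 0.1
    gain: float = 100.0
    threshold: float = 0.5
    e_rev_exc: float = 1.0
    e_rev_inh: float = 0.15
    e_rev_leak: float = 0.15
    # 0.3 lets activity traverse the three-synapse EC->CA1->EC chain well
    # within one 30-step phase; smaller rates leave downstream layers
    # sub-threshold at phase end.
    dt_vm: float = 0.3
    n_settle_steps: int = 30
    kwta_pt: float = 0.5

    def validate(self) -> None:
        if not (0.0 < self.dt_vm <= 1.0):
            raise ValueError(f"dt_vm must lie in (0, 1], got {self.dt_vm}")
        if self.n_settle_steps < 1:
            raise ValueError("n_settle_steps must be >= 1")
        if not (0.0 <= self.kwta_pt <= 1.0):
            raise ValueError("kwta_pt must lie in [0, 1]")


@dataclass
class LayerState:
    """Per-layer unit state.

    ``k_active`` is the kWTA winner target *per inhibitory pool*; layers
    with slot topology set ``n_pools`` to the slot count, in which case
    units are partitioned into ``n_pools`` contiguous equal blocks each
    with its own uniform inhibitory conductance.
    """

    name: str
    n_units: int
    k_active: int
    n_pools: int = 1
    vm: np.ndarray = field(init=False)
    ge: np.ndarray = field(init=False)
    gi: np.ndarray = field(init=False)
    y: np.ndarray = field(init=False)
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.n_units % self.n_pools != 0:
            raise ValueError(
                f"layer {self.name}: n_units={self.n_units} not divisible "
                f"by n_pools={self.n_pools}"
            )
        pool = self.n_units // self.n_pools
        if not (1 <= self.k_active <= pool):
            raise ValueError(
                f"layer {self.name}: k_active={self.k_active} outside "
                f"[1, {pool}] (pool size)"
            )
        self.vm = np.zeros(self.n_units)
        self.ge = np.zeros(self.n_units)
        self.gi = np.zeros(self.n_units)
        self.y = np.zeros(self.n_units)

    @property
    def pool_size(self) -> int:
        return self.n_units // self.n_pools

    def reset(self, params: DynamicsParams) -> None:
        """Zero activations and conductances; rest Vm at the leak reversal."""
        self.vm.fill(params.e_rev_leak)
        self.ge.fill(0.0)
        self.gi.fill(0.0)
        self.y.fill(0.0)
        self.clamped = False

    def clamp(self, pattern: np.ndarray) -> None:
        pattern = np.asarray(pattern, dtype=float)
        if pattern.shape != (self.n_units,):
            raise ValueError(
                f"layer {self.name}: clamp pattern shape {pattern.shape} "
                f"!= ({self.n_units},)"
            )
        self.y = pattern.copy()
        self.clamped = True

    def unclamp(self) -> None:
        self.clamped = False


@dataclass
class Projection:
    """Weighted connection between two layers.

    ``w`` holds weights in [0, 1] and is zero wherever ``mask`` is zero
    (absent synapses).  ``fanin`` is the per-receiver count of connected
    senders used to average (not sum) the weighted inputs.  ``rule`` tags
    which learning signal applies: ``"msp_error"`` (plus vs. trough),
    ``"tsp_error"`` (plus vs. peak), ``"hebbian"`` (plus only) or
    ``"fixed"``.  ``scale`` weights this projection's contribution when a
    layer averages over several open projections.

    ``sender_activity`` is the expected fraction of sender units active at
    any time; the averaged input is divided by it, so a projection from a
    sparse layer (whose senders are mostly silent by design) delivers
    conductances on the same scale as one from a dense layer.  Without
    this correction the plain mean over weighted inputs from a
    k-winners-take-all sender layer is diluted by its silent majority and
    cannot drive any receiver past threshold.
    """

    name: str
    sender: str
    receiver: str
    w: np.ndarray
    mask: np.ndarray
    rule: str = "fixed"
    scale: float = 1.0
    sender_activity: float = 1.0
    fanin: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.w.shape != self.mask.shape:
            raise ValueError(f"projection {self.name}: w/mask shape mismatch")
        self.mask = self.mask.astype(float)
        self.w = self.w * self.mask
        fanin = self.mask.sum(axis=0)
        if np.any(fanin == 0):
            raise ValueError(
                f"projection {self.name}: some receivers have no incoming "
                "synapses; lower sparsity or reseed connectivity"
            )
        self.fanin = fanin


def net_excitation(sender_activations: np.ndarray, weights: np.ndarray,
                   fanin: np.ndarray | None = None) -> np.ndarray:
    """Excitatory conductance: the average weighted input per receiver.

    ge_j = (1 / fanin_j) * sum_i x_i w_ij.  With full connectivity fanin is
    the sender count, i.e. the plain mean over weighted inputs; for partial
    connectivity the mean runs over connected synapses only.
    """
    x = np.asarray(sender_activations, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != x.shape[0]:
        raise ValueError(
            f"net_excitation: {x.shape[0]} senders but weight matrix has "
            f"{w.shape[0]} rows"
        )
    ge = x @ w
    if fanin is None:
        ge /= w.shape[0]
    else:
        ge /= fanin
    return ge


def step_membrane(vm: np.ndarray, ge: np.ndarray, gi: np.ndarray,
                  params: DynamicsParams) -> np.ndarray:
    """One explicit-Euler membrane update.

    dVm = dt * [ge(Ee - Vm) + gi(Ei - Vm) + gl(El - Vm)].  The fixed point
    is the conductance-weighted mean of the reversal potentials; for
    dt*(ge+gi+gl) <= 1 each step moves Vm monotonically toward it.
    """
    p = params
    dvm = (ge * (p.e_rev_exc - vm)
           + gi * (p.e_rev_inh - vm)
           + p.g_l * (p.e_rev_leak - vm))
    return vm + p.dt_vm * dvm


def activation_fn(vm: np.ndarray, gain: float = 100.0,
                  threshold: float = 0.5) -> np.ndarray:
    """Saturating threshold rate: y = g*(Vm - theta) / (g*(Vm - theta) + 1).

    Zero at and below threshold, strictly increasing above it, approaching
    1 from below.
    """
    drive = gain * np.maximum(np.asarray(vm, dtype=float) - threshold, 0.0)
    return drive / (drive + 1.0)


def threshold_conductance(ge: np.ndarray, params: DynamicsParams) -> np.ndarray:
    """The gi that would put each unit exactly at threshold at equilibrium.

    Setting the equilibrium Vm* = (ge*Ee + gi*Ei + gl*El)/(ge + gi + gl)
    equal to the firing threshold and solving for gi gives
    g_theta = [ge(Ee - theta) + gl(El - theta)] / (theta - Ei).
    Monotone increasing in ge (for theta > Ei); may be negative for units
    too weakly driven to fire even with zero inhibition.
    """
    p = params
    denom = p.threshold - p.e_rev_inh
    if denom <= 0:
        raise ValueError("kWTA requires threshold > e_rev_inh")
    return (ge * (p.e_rev_exc - p.threshold)
            + p.g_l * (p.e_rev_leak - p.threshold)) / denom


def kwta_conductance(excitations: np.ndarray, k: int,
                     params: DynamicsParams) -> float:
    """Set-point inhibition: a single gi allowing at most k winners.

    gi is placed between the threshold conductances of the k-th and
    (k+1)-th most excited unit (at ``kwta_pt`` of the gap).  When k equals
    the layer size gi drops below every unit's threshold conductance so no
    unit is suppressed.  Exact ties at the k/k+1 boundary collapse the gap,
    putting every tied unit exactly at threshold, i.e. silent — a
    deterministic, conservative tie rule.  gi is clipped at 0 (inhibition
    cannot be negative).
    """
    ge = np.asarray(excitations, dtype=float)
    n = ge.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"kWTA k={k} outside [1, {n}]")
    g_theta = np.sort(threshold_conductance(ge, params))[::-1]
    g_k = g_theta[k - 1]
    g_k1 = g_theta[k] if k < n else min(0.0, g_k)
    gi = g_k1 + params.kwta_pt * (g_k - g_k1)
    return max(gi, 0.0)


def _pooled_gi(layer: LayerState, params: DynamicsParams) -> np.ndarray:
    """Per-unit gi vector: one kWTA conductance per inhibitory pool."""
    if layer.n_pools == 1:
        return np.full(layer.n_units, kwta_conductance(layer.ge, layer.k_active, params))
    pools = layer.ge.reshape(layer.n_pools, layer.pool_size)
    g_theta = np.sort(threshold_conductance(pools, params), axis=1)[:, ::-1]
    k = layer.k_active
    g_k = g_theta[:, k - 1]
    if k < layer.pool_size:
        g_k1 = g_theta[:, k]
    else:
        g_k1 = np.minimum(0.0, g_k)
    gi = np.maximum(g_k1 + params.kwta_pt * (g_k - g_k1), 0.0)
    return np.repeat(gi, layer.pool_size)


def settle(layers: dict[str, LayerState],
           projections: list[Projection],
           gates: dict[str, float | bool],
           params: DynamicsParams,
           n_steps: int | None = None) -> dict[str, np.ndarray]:
    """Run a fixed number of synchronous settling steps; return activations.

    Each step: every open projection delivers averaged weighted input to
    its receiver; each unclamped layer then averages its open projections'
    contributions (weighted by projection scale), recomputes the kWTA
    inhibitory conductance, integrates the membrane potential once, and
    re-derives its rate.  Clamped layers hold their activation fixed.

    ``gates`` maps projection names to a strength factor: 0 (or False)
    fully inhibits the projection, 1 (or True) transmits at its normal
    scale, and larger values strengthen its influence relative to the
    other projections converging on the same layer.  Projections absent
    from ``gates`` transmit at strength 1.
    """
    if n_steps is None:
        n_steps = params.n_settle_steps
    strength = {p.name: float(gates.get(p.name, 1.0)) for p in projections}
    open_projs = [p for p in projections if strength[p.name] > 0.0]
    incoming: dict[str, list[Projection]] = {}
    for p in open_projs:
        incoming.setdefault(p.receiver, []).append(p)

    for _ in range(n_steps):
        y_prev = {name: lay.y for name, lay in layers.items()}
        new_ge: dict[str, np.ndarray] = {}
        for name, lay in layers.items():
            if lay.clamped:
                continue
            projs = incoming.get(name, [])
            if not projs:
                new_ge[name] = np.zeros(lay.n_units)
                continue
            total = np.zeros(lay.n_units)
            wsum = 0.0
            for p in projs:
                g = strength[p.name] * p.scale
                total += (g / p.sender_activity) * (y_prev[p.sender] @ p.w / p.fanin)
                wsum += g
            new_ge[name] = total / wsum
        for name, lay in layers.items():
            if lay.clamped:
                continue
            lay.ge = new_ge[name]
            lay.gi = _pooled_gi(lay, params)
            lay.vm = step_membrane(lay.vm, lay.ge, lay.gi, params)
            lay.y = activation_fn(lay.vm, params.gain, params.threshold)
    return {name: lay.y.copy() for name, lay in layers.items()}
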