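"""The hippocampal circuit: EC_in, DG, CA3, CA1, EC_out under theta gating.

Architecture
------------
Two routes connect cortex (entorhinal input, ``ec_in``) to the output
layer (``ec_out``):

* the monosynaptic pathway (MSP): slot-topographic, bidirectional
  EC <-> CA1 connections (``ec_in->ca1``, ``ec_out->ca1``, ``ca1->ec_out``),
  which learn an invertible sparse encoding of each EC slot over the
  corresponding CA1 slot;
* the trisynaptic pathway (TSP): diffuse EC_in -> DG -> CA3 -> CA1 with
  CA3 recurrence, whose sparse conjunctive CA3 code supports pattern
  completion; CA3 -> CA1 are the Schaffer collaterals.

``ec_in -> ec_out`` is a fixed one-to-one route, realised by clamping
``ec_out`` to the input pattern while its gate is open.

Theta cycle
-----------
Each stimulus presentation is three fixed-length settling phases whose
gates follow the phase table: trough (TT) — EC drives CA1, Schaffer input
suppressed; peak (TP) — Schaffer input drives CA1, direct EC->CA1
suppressed; plus — EC drives both CA1 and (one-to-one) EC_out, providing
the ground-truth target.  Activations are reset at trough onset and carry
over between the later phases.  MSP synapses learn from the plus-vs-trough
contrast, Schaffer collaterals from the plus-vs-peak contrast, and all
other plastic synapses are purely Hebbian on the plus phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import DynamicsParams, LayerState, Projection, settle
from .plasticity import (
    LearningParams,
    PhasePair,
    apply_delta,
    center_per_receiver,
    chl_delta,
    combined_delta,
    cpca_hebb_delta,
)

__all__ = [
    "ArchitectureConfig",
    "PHASE_GATES",
    "ThetaTrace",
    "Network",
    "ConditionParams",
    "build_network",
    "run_theta_cycle",
    "learn_from_trace",
    "recall",
    "pretrain_msp",
]

#: Phase gate table.  The first three columns are the three manipulated
#: projections (1.0 = "+" transmits, 0.0 = "-" fully inhibited); every
#: projection not listed is always open.  The EC_out -> CA1 back-projection
#: follows the monosynaptic pathway's phase profile: strong at trough and
#: plus, weak (0.3) at the peak, when CA1 is under Schaffer-collateral
#: control.  Leaving it fully open at the peak lets the output echo stand
#: in for the Schaffer input during training, which then never learns to
#: drive CA1 on its own; a weak echo keeps that learning pressure while
#: letting the settled output clean up CA3-driven recall.
PHASE_GATES: dict[str, dict[str, float]] = {
    "TT":   {"ec_in->ca1": 1.0, "ca3->ca1": 0.0, "ec_in->ec_out": 0.0,
             "ec_out->ca1": 1.0},
    "TP":   {"ec_in->ca1": 0.0, "ca3->ca1": 1.0, "ec_in->ec_out": 0.0,
             "ec_out->ca1": 0.3},
    "PLUS": {"ec_in->ca1": 1.0, "ca3->ca1": 0.0, "ec_in->ec_out": 1.0,
             "ec_out->ca1": 1.0},
}

#: Names of the projections silenced to lesion the trisynaptic pathway.
TSP_PROJECTIONS = frozenset(
    {"ec_in->dg", "ec_in->ca3", "dg->ca3", "ca3->ca3", "ca3->ca1"})


@dataclass
class ArchitectureConfig:
    """Sizes, sparseness and connectivity of the circuit.

    DG holds 5 units per CA3 unit (the anatomical ratio); ``n_dg`` is
    derived unless given explicitly, in which case the ratio is checked.
    kWTA winner counts are fractions of layer (or slot) size; EC layers
    use the stimulus sparsity (``ec_active_per_slot`` winners per slot).
    """

    n_slots: int = 8
    units_per_ec_slot: int = 40
    units_per_ca1_slot: int = 40
    ec_active_per_slot: int = 12
    n_ca3: int = 80
    n_dg: int | None = None
    dg_ca3_ratio: int = 5
    kwta_frac_dg: float = 0.02
    kwta_frac_ca3: float = 0.05
    kwta_frac_ca1_slot: float = 0.25
    density_ec_dg: float = 0.25
    density_ec_ca3: float = 0.25
    density_dg_ca3: float = 0.05
    w_init_low: float = 0.25
    w_init_high: float = 0.75
    # relative strength of the EC_out -> CA1 back-projection while the
    # target is imposed (plus phase); > 1 lets the clamped target dominate
    # CA1 so the plus-phase CA1 code stays stimulus-specific
    plus_ec_out_ca1_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.n_dg is None:
            self.n_dg = self.dg_ca3_ratio * self.n_ca3
        elif self.n_dg != self.dg_ca3_ratio * self.n_ca3:
            raise ValueError(
                f"n_dg={self.n_dg} violates the {self.dg_ca3_ratio}:1 "
                f"DG:CA3 ratio for n_ca3={self.n_ca3}")
        if not (1 <= self.ec_active_per_slot <= self.units_per_ec_slot):
            raise ValueError("ec_active_per_slot outside [1, units_per_ec_slot]")

    @property
    def n_ec(self) -> int:
        return self.n_slots * self.units_per_ec_slot

    @property
    def n_ca1(self) -> int:
        return self.n_slots * self.units_per_ca1_slot

    def k_for(self, layer: str) -> int:
        """kWTA winner target per inhibitory pool of the given layer."""
        if layer in ("ec_in", "ec_out"):
            return self.ec_active_per_slot
        if layer == "dg":
            return max(1, round(self.kwta_frac_dg * self.n_dg))
        if layer == "ca3":
            return max(1, round(self.kwta_frac_ca3 * self.n_ca3))
        if layer == "ca1":
            return max(1, round(self.kwta_frac_ca1_slot * self.units_per_ca1_slot))
        raise KeyError(layer)


@dataclass
class ThetaTrace:
    """End-of-phase activation snapshots for one stimulus presentation."""

    phases: dict[str, dict[str, np.ndarray]]
    input_pattern: np.ndarray
    mode: str  # "train" or "test"


@dataclass
class ConditionParams:
    """Learning configuration of one experimental condition.

    ``lmix_msp``/``lmix_tsp`` are the Hebbian proportions applied to the
    monosynaptic-pathway synapses and the Schaffer collaterals
    respectively (1.0 = purely Hebbian, 0.001 = error-driven).  Synapses
    tagged purely Hebbian in the architecture always learn with the CPCA
    rule at full strength, independent of condition.
    """

    lmix_msp: float = 0.001
    lmix_tsp: float = 0.001
    eps: float = 0.08
    soft_bound: bool = False
    pretrain_msp: bool = False
    #: subtractive normalization of the error delta (see
    #: plasticity.center_per_receiver); uniform weight offsets are the
    #: null direction of mean-driven input, and removing them keeps
    #: error learning in the graded-weight regime
    center_error: bool = True

    def params_for(self, rule: str) -> LearningParams:
        if rule == "msp_error":
            lmix = self.lmix_msp
        elif rule == "tsp_error":
            lmix = self.lmix_tsp
        elif rule == "hebbian":
            lmix = 1.0
        else:
            raise KeyError(rule)
        return LearningParams(lmix=lmix, eps=self.eps, soft_bound=self.soft_bound)


class Network:
    """Layers plus projections, with bookkeeping for settling steps."""

    def __init__(self, config: ArchitectureConfig, params: DynamicsParams,
                 layers: dict[str, LayerState], projections: list[Projection]):
        self.config = config
        self.params = params
        self.layers = layers
        self.projections = projections
        self.proj = {p.name: p for p in projections}
        self.step_count = 0
        #: set False to force the pure-numpy reference settle path
        self.use_fast = True
        self._fast = None
        self._weights_dirty = True

    def reset(self) -> None:
        for lay in self.layers.values():
            lay.reset(self.params)

    def mark_weights_dirty(self) -> None:
        self._weights_dirty = True

    def settle_phase(self, gates: dict[str, bool],
                     n_steps: int | None = None) -> dict[str, np.ndarray]:
        n = self.params.n_settle_steps if n_steps is None else n_steps
        snap = None
        if self.use_fast:
            from ._fastsettle import HAVE_NUMBA, FastState
            if HAVE_NUMBA:
                if self._fast is None:
                    self._fast = FastState(self.layers, self.projections,
                                           n_slots=self.config.n_slots)
                if self._weights_dirty:
                    self._fast.pack_weights(self.projections)
                    self._weights_dirty = False
                snap = self._fast.run(self.layers, gates, self.params, n)
        if snap is None:
            snap = settle(self.layers, self.projections, gates, self.params, n)
        self.step_count += n
        return snap

    def save_weights(self, path) -> None:
        """Checkpoint all projection weights to one ``.npz`` container."""
        np.savez_compressed(path, **{p.name: p.w for p in self.projections})

    def load_weights(self, path) -> None:
        """Restore weights saved by :meth:`save_weights` (shapes must match)."""
        with np.load(path) as data:
            for p in self.projections:
                w = data[p.name]
                if w.shape != p.w.shape:
                    raise ValueError(
                        f"checkpoint shape {w.shape} does not match projection "
                        f"{p.name} {p.w.shape}")
                p.w = w * p.mask
        self.mark_weights_dirty()

    def weight_checksum(self) -> float:
        """Cheap change detector over all projection weights."""
        return float(sum(p.w.sum() for p in self.projections))


def _random_mask(n_send: int, n_recv: int, density: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Fixed fan-in partial connectivity: each receiver draws
    max(1, round(density*n_send)) distinct senders."""
    n_conn = max(1, round(density * n_send))
    mask = np.zeros((n_send, n_recv), dtype=float)
    for j in range(n_recv):
        mask[rng.choice(n_send, size=n_conn, replace=False), j] = 1.0
    return mask


def _block_mask(n_slots: int, send_per_slot: int, recv_per_slot: int) -> np.ndarray:
    mask = np.zeros((n_slots * send_per_slot, n_slots * recv_per_slot))
    for s in range(n_slots):
        mask[s * send_per_slot:(s + 1) * send_per_slot,
             s * recv_per_slot:(s + 1) * recv_per_slot] = 1.0
    return mask


def build_network(config: ArchitectureConfig,
                  rng: np.random.Generator | int | None = None,
                  params: DynamicsParams | None = None) -> Network:
    """Construct the five-layer circuit with seeded weights and masks."""
    rng = np.random.default_rng(rng)
    params = params if params is not None else DynamicsParams()
    params.validate()
    c = config

    layers = {
        "ec_in": LayerState("ec_in", c.n_ec, c.k_for("ec_in"), n_pools=c.n_slots),
        "dg": LayerState("dg", c.n_dg, c.k_for("dg")),
        "ca3": LayerState("ca3", c.n_ca3, c.k_for("ca3")),
        "ca1": LayerState("ca1", c.n_ca1, c.k_for("ca1"), n_pools=c.n_slots),
        "ec_out": LayerState("ec_out", c.n_ec, c.k_for("ec_out"), n_pools=c.n_slots),
    }

    def init_w(mask: np.ndarray) -> np.ndarray:
        return rng.uniform(c.w_init_low, c.w_init_high, size=mask.shape) * mask

    # expected active fraction per sender layer, for net-input scaling
    activity = {
        "ec_in": c.ec_active_per_slot / c.units_per_ec_slot,
        "ec_out": c.ec_active_per_slot / c.units_per_ec_slot,
        "dg": c.k_for("dg") / c.n_dg,
        "ca3": c.k_for("ca3") / c.n_ca3,
        "ca1": c.k_for("ca1") / c.units_per_ca1_slot,
    }

    full = np.ones
    recurrent_mask = 1.0 - np.eye(c.n_ca3)
    specs = [
        ("ec_in->dg", "ec_in", "dg",
         _random_mask(c.n_ec, c.n_dg, c.density_ec_dg, rng), "hebbian"),
        ("ec_in->ca3", "ec_in", "ca3",
         _random_mask(c.n_ec, c.n_ca3, c.density_ec_ca3, rng), "hebbian"),
        ("dg->ca3", "dg", "ca3",
         _random_mask(c.n_dg, c.n_ca3, c.density_dg_ca3, rng), "hebbian"),
        ("ca3->ca3", "ca3", "ca3", recurrent_mask, "hebbian"),
        ("ca3->ca1", "ca3", "ca1", full((c.n_ca3, c.n_ca1)), "tsp_error"),
        ("ec_in->ca1", "ec_in", "ca1",
         _block_mask(c.n_slots, c.units_per_ec_slot, c.units_per_ca1_slot),
         "msp_error"),
        ("ec_out->ca1", "ec_out", "ca1",
         _block_mask(c.n_slots, c.units_per_ec_slot, c.units_per_ca1_slot),
         "hebbian"),
        ("ca1->ec_out", "ca1", "ec_out",
         _block_mask(c.n_slots, c.units_per_ca1_slot, c.units_per_ec_slot),
         "msp_error"),
    ]
    projections = [
        Projection(name=n, sender=s, receiver=r, w=init_w(m), mask=m, rule=rule,
                   sender_activity=activity[s])
        for n, s, r, m, rule in specs
    ]
    return Network(config, params, layers, projections)


def _gates_for(phase: str, closed: frozenset[str] = frozenset(),
               extra: dict[str, float] | None = None) -> dict[str, float]:
    gates = dict(PHASE_GATES[phase])
    if extra:
        gates.update(extra)
    for name in closed:
        gates[name] = 0.0
    return gates


def run_theta_cycle(net: Network, input_pattern: np.ndarray, mode: str = "train",
                    closed: frozenset[str] = frozenset()) -> ThetaTrace:
    """Present one stimulus for a full (train) or truncated (test) cycle.

    Train mode runs trough, peak and plus phases (3 x 30 steps); test mode
    stops after the peak, changes no weights and records no plus snapshot.
    ``closed`` force-closes additional projections (lesions, pretraining).
    """
    if mode not in ("train", "test"):
        raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
    pattern = np.asarray(input_pattern, dtype=float)
    if pattern.shape != (net.config.n_ec,):
        raise ValueError(
            f"input pattern shape {pattern.shape} != ({net.config.n_ec},)")

    net.reset()
    net.layers["ec_in"].clamp(pattern)
    phases: dict[str, dict[str, np.ndarray]] = {}
    phases["TT"] = net.settle_phase(_gates_for("TT", closed))
    phases["TP"] = net.settle_phase(_gates_for("TP", closed))
    if mode == "train":
        gates = _gates_for(
            "PLUS", closed,
            extra={"ec_out->ca1": net.config.plus_ec_out_ca1_strength})
        if gates.get("ec_in->ec_out", False):
            # fixed one-to-one route: EC_out is driven to the input pattern
            net.layers["ec_out"].clamp(pattern)
        phases["PLUS"] = net.settle_phase(gates)
        net.layers["ec_out"].unclamp()
    return ThetaTrace(phases=phases, input_pattern=pattern, mode=mode)


_MINUS_PHASE = {"msp_error": "TT", "tsp_error": "TP"}


def learn_from_trace(net: Network, trace: ThetaTrace, cond: ConditionParams,
                     only_rules: frozenset[str] | None = None) -> None:
    """Apply one weight update per plastic projection from a train trace.

    Error-capable projections blend CHL (plus vs. their minus phase) with
    the CPCA Hebbian delta at the condition's lmix; purely Hebbian
    projections apply the CPCA delta alone.  Fixed projections and absent
    synapses never change.  ``only_rules`` restricts the update to a
    subset of rule tags (used by MSP pretraining).
    """
    if trace.mode != "train" or "PLUS" not in trace.phases:
        raise ValueError("learn_from_trace requires a train-mode trace with a "
                         "plus-phase snapshot")
    plus = trace.phases["PLUS"]
    fast = None
    if not cond.soft_bound:
        from ._fastlearn import HAVE_NUMBA, update_projection
        if HAVE_NUMBA:
            fast = update_projection
    for proj in net.projections:
        if proj.rule == "fixed":
            continue
        if only_rules is not None and proj.rule not in only_rules:
            continue
        params = cond.params_for(proj.rule)
        x_plus = plus[proj.sender]
        y_plus = plus[proj.receiver]
        use_err = proj.rule != "hebbian"
        minus = trace.phases[_MINUS_PHASE[proj.rule]] if use_err else plus
        if fast is not None:
            fast(proj.w, proj.mask, proj.fanin, x_plus, y_plus,
                 minus[proj.sender], minus[proj.receiver],
                 params.eps, params.lmix, use_err, cond.center_error)
            continue
        hebb = cpca_hebb_delta(x_plus, y_plus, proj.w)
        if not use_err:
            delta = params.eps * hebb
        else:
            pair = PhasePair(x_minus=minus[proj.sender],
                             y_minus=minus[proj.receiver],
                             x_plus=x_plus, y_plus=y_plus,
                             minus_phase=_MINUS_PHASE[proj.rule])
            err = chl_delta(pair)
            if cond.center_error:
                err = center_per_receiver(err, proj.mask)
            delta = combined_delta(hebb, err, params)
        proj.w = apply_delta(proj.w, delta * proj.mask, params)
    net.mark_weights_dirty()


def recall(net: Network, cue: np.ndarray,
           closed: frozenset[str] = frozenset()) -> np.ndarray:
    """Read out EC_out after trough+peak settling on a (possibly partial) cue.

    Weight-read-only: no plus phase is run and no learning is applied.
    The returned snapshot is the end-of-peak EC_out activation, after
    CA3-driven pattern completion has propagated through CA1.
    """
    trace = run_theta_cycle(net, cue, mode="test", closed=closed)
    return trace.phases["TP"]["ec_out"]


def pretrain_msp(net: Network, training_set, cond: ConditionParams,
                 epochs: int = 15,
                 rng: np.random.Generator | int | None = None) -> Network:
    """Train only the monosynaptic pathway, with the TSP silenced.

    Runs ``epochs`` shuffled passes of theta cycles with all TSP
    projections closed, applying only MSP-tagged updates; DG/CA3 weights
    and the Schaffer collaterals are untouched.
    """
    rng = np.random.default_rng(rng)
    patterns = [p.ec_vector if hasattr(p, "ec_vector") else np.asarray(p, float)
                for p in training_set]
    for _ in range(epochs):
        for i in rng.permutation(len(patterns)):
            trace = run_theta_cycle(net, patterns[i], mode="train",
                                    closed=TSP_PROJECTIONS)
            learn_from_trace(net, trace, cond, only_rules=frozenset({"msp_error"}))
    return net
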