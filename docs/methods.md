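# Methods

`thetahippo` simulates a rate-coded model of the hippocampal circuit in
which the theta rhythm's phase structure turns ordinary activity
snapshots into error signals, and uses it to compare the storage
capacity of error-driven versus purely Hebbian learning.

## Unit and layer dynamics

Units are conductance-based point neurons.  Each settling step updates
the membrane potential by

    dVm = dt_vm * [ ge*(Ee - Vm) + gi*(Ei - Vm) + gl*(El - Vm) ]

whose fixed point is the conductance-weighted mean of the three reversal
potentials.  The output rate is a saturating threshold function,
`y = gain*(Vm - theta) / (gain*(Vm - theta) + 1)` for `Vm > theta`, else 0.
Constants follow the framework this model family is built on: leak
`gl = 0.1`, `gain = 100`, `theta = 0.5`, with reversal potentials
`Ee = 1.0`, `Ei = El = 0.15` (dimensionless, unit activation range 0-1).
All are exposed in `DynamicsParams`.

The membrane integration rate defaults to `dt_vm = 0.3`.  The model's
deepest readout chain (EC input -> CA1 -> EC output) is three synapses
long and each phase lasts a fixed 30 steps; at rates much below 0.3 the
downstream layers are still sub-threshold when the phase ends, which
silences the minus phase of the learning rule.  0.3 is also the parent
framework's own default.

Inhibition is not simulated with explicit interneurons.  Each layer (or
each slot of a slot-structured layer, which has its own inhibitory pool)
receives one uniform inhibitory conductance per step, chosen so that at
membrane equilibrium at most `k` units can exceed threshold
(k-winners-take-all).  The conductance is placed halfway
(`kwta_pt = 0.5`) between the threshold conductances of the k-th and
(k+1)-th most driven unit; exact ties at the boundary place every tied
unit exactly at threshold, i.e. silent — a deterministic, conservative
tie rule.

Excitatory drive is the *average* of weighted inputs: for one
projection, `ge_j = mean_i(x_i * w_ij)` over connected senders; a layer
with several open projections averages their contributions (equal
weights by default, a per-projection scale is available).  Because most
units of a sparse sender layer are silent by design, each projection's
average is further divided by the sender layer's expected active
fraction (`sender_activity`); without this correction no projection from
a kWTA layer could drive any receiver past threshold, and with it all
projections deliver conductances on a comparable scale regardless of
sender sparsity.

## Circuit

Five layers: `ec_in` (8 slots x 40 units), `dg`, `ca3`, `ca1`
(8 slots x 40), `ec_out` (mirror of `ec_in`).  DG holds 5 units per CA3
unit, the approximate anatomical ratio; capacity sweeps vary CA3 from 10
to 100 units (DG 50 to 500).

Projections and their learning tags:

| projection      | connectivity                  | rule       |
|-----------------|-------------------------------|------------|
| ec_in -> dg     | random, 25% density           | Hebbian    |
| ec_in -> ca3    | random, 25% density           | Hebbian    |
| dg -> ca3       | random, 5% density            | Hebbian    |
| ca3 -> ca3      | full minus self               | Hebbian    |
| ca3 -> ca1      | full (Schaffer collaterals)   | TSP error  |
| ec_in -> ca1    | block-diagonal by slot        | MSP error  |
| ec_out -> ca1   | block-diagonal by slot        | Hebbian    |
| ca1 -> ec_out   | block-diagonal by slot        | MSP error  |
| ec_in -> ec_out | fixed one-to-one (plus clamp) | fixed      |

Partial connectivity uses a fixed fan-in per receiver (deterministic
average), seeded.  Weights start uniform on [0.25, 0.75], seeded.

kWTA sparsities: DG 2% of the layer, CA3 5%, CA1 25% per slot
(10 of 40), EC layers at the stimulus sparsity (12 per slot).  CA1 at
25% follows the complementary-learning-systems lineage this circuit
descends from; we found much sparser CA1 codes (e.g. 10%) cannot carry a
~100-entry repertoire per slot and collapse onto a few winner sets.

## Theta cycle

Each presentation is three 30-step phases (90 steps per training
cycle); activations reset only at trough onset and carry over between
later phases.  The three manipulated projections follow the phase
table: trough `(+,-,-)`, peak `(-,+,-)`, plus `(+,-,+)` for
(EC_in->CA1, CA3->CA1, EC_in->EC_out).  All other projections stay
open, with one exception: the EC_out->CA1 back-projection follows the
monosynaptic pathway's phase profile — full strength at trough and
plus, weak (0.3) at the peak.  This matches the physiological picture
(EC influence on CA1 minimal at the peak, when CA3 dominates) and
matters computationally: if the output echo reaches CA1 at full
strength during the peak it stands in for the Schaffer input during
training, and the Schaffer collaterals never learn to drive CA1
unaided — recall of deleted slots then fails; fully closing it
forfeits a useful cleanup signal at recall.  0.3 balances the two,
chosen once on the memorization task.

During the plus phase EC_out is clamped one-to-one to the input
(the fixed superficial-to-deep EC route), providing the ground truth;
CA1 settles under EC_in and the clamped EC_out.

Test trials run trough and peak only and change no weights.  The
recall readout is phase-aware, per slot: a slot is read from the
end-of-trough EC_out snapshot, where the monosynaptic pathway
reconstructs directly-cued elements with high fidelity; a slot that is
silent at the trough — its cortical input was missing from the cue —
is read from the end-of-peak snapshot instead, after CA3-driven
completion has propagated through CA1.  Each pathway is thus read at
the phase where it carries signal (the encoding phase for
stimulus-present content, the retrieval phase for completed content);
single-phase readouts remain available as options.

## Learning

Weight changes are computed once per training cycle from the completed
phase snapshots:

* error-capable projections blend contrastive Hebbian learning with the
  CPCA Hebbian rule: `dW = eps * [lmix*hebb + (1-lmix)*err]`, where
  `err_ij = x+_i y+_j − x−_i y−_j`.  The minus phase is the trough
  snapshot for the EC<->CA1 pathway and the peak snapshot for the
  Schaffer collaterals; the plus snapshot is the target in both.
  `lmix = 0.001` defines the error-driven condition and `lmix = 1`
  the Hebbian condition.
* purely-Hebbian projections (the perforant path, mossy fibers, CA3
  recurrence, and the EC_out->CA1 feedback) always use the CPCA rule
  `dW_ij = eps * y+_j (x+_i − w_ij)` at full strength, regardless of
  condition — they carry no error component.

Weights are hard-clipped to [0, 1] (all principal connections are
excitatory); an exponential soft bound is available behind a flag.
The learning rate defaults to `eps = 0.08`, shared by all conditions.

Before blending, the error delta is subtractively normalized per
receiving unit (its mean over connected synapses is removed).  Because
net input is a mean of weighted inputs, a uniform offset on one unit's
weights shifts its drive equally for every stimulus and cannot change
any within-layer competition; that uniform component is the null
direction of the dynamics.  Left in place it dominates the update — the
plus phase relentlessly potentiates, whole weight matrices saturate at
the upper bound, the within-slot drive becomes uniform, and the kWTA
tie rule silences the layer (at which point the minus term vanishes and
the runaway is irreversible).  Removing it keeps error learning in the
graded-weight regime where differences between synapses, which carry
all the information, survive.  The purely Hebbian condition has no
error component and is therefore untouched by this normalization, so
the error-driven versus Hebbian comparison is not an artifact of it.

MSP pretraining (for the pretrained-variant condition) runs ordinary
theta cycles with every trisynaptic projection silenced and applies
only the MSP-error updates, leaving DG/CA3/Schaffer weights untouched.

## Synthetic stimuli

Each EC slot draws from a vocabulary of 100 binary patterns, 12 active
of 40 units, generated by rejection sampling under a minimum pairwise
Hamming distance of 10 (exhaustively verified).  The slot geometry is
the package's choice: the floor-of-10 constraint with substantially
sparser slots is combinatorially infeasible for 100 entries (with 6
active units, distance 10 forces pairwise overlap <= 1, and a packing
argument caps the vocabulary at 20 entries), while 12-of-40 keeps the
rejection rate below ~20%.  Stimuli are composites of one entry per
slot, drawn distinct; test cues delete whole slots (2 of 8 = 25% of the
pattern) — deletion only removes activity, never flips it.  A
unit-deletion mode is available for fractions that do not align with
slot boundaries.

Name Error scores a recalled pattern: each slot's output is compared to
all vocabulary entries by cosine similarity (robust to graded
activations; Euclidean distance is a config alternative), and the
pattern is correct only if every slot's strict argmax is its trained
entry — any tie, including an all-silent slot, counts as incorrect.

## Experiments

A capacity sweep runs a grid of (condition, CA3 size, set size, seed).
Per cell: a fresh network, a fresh training-set draw, 15 shuffled
epochs of training, then recall of every trained pattern from a
25%-deleted cue.  All randomness derives from a master seed through
named seed sequences; the condition is excluded from the cell's
entropy, so every condition at a cell sees identical initial weights,
training sets, presentation orders and cue corruptions (a paired
comparison).  Sweeps write delimited text with a commented metadata
header and resume from completed cells.

Conditions: `full_error_driven`, `full_hebbian`, `tsp_error_only`
(Schaffer error-driven, MSP Hebbian), `msp_error_only` (the converse),
and `pretrained_msp_variant` (MSP pretrained 15 epochs, then integrated
error-driven training).

Significance uses a pooled two-sided bootstrap on per-pattern binary
Name Error values (pooled across seeds at a grid cell): both groups are
pooled, resampled pairs of groups give a null distribution of mean
differences, and p is the (add-one smoothed) fraction of null
differences at least as extreme as observed.  Default 10,000 resamples;
the full-scale analysis threshold is p < 0.005, scaled analyses use
p < 0.05.

### Problem sizes

The packaged test suite exercises the full machinery at reduced scale,
chosen as the smallest sizes at which the qualitative phenomena are
stable: memorization at CA3 = 80 with 20 patterns, and a comparison
sweep at CA3 = 40 with set sizes {40, 200}, 3 seeds, 15 epochs, all
five conditions.  A compiled settle/update kernel (numba) carries these
runs; the pure-numpy reference implementation is asserted equivalent
in the tests and is used automatically where numba is unavailable.

## What the generator does and does not emulate

The synthetic vocabulary captures sparse, well-separated cortical
"names" with exactly uniform sparsity and independent slots.  Real EC
inputs are correlated across slots, graded, and drift over time; none
of that is modeled, so passing tests show the learning-rule comparison
under idealized separable inputs, not performance on naturalistic
stimulus statistics.  Slot deletion models clean partial cues;
noisy/corrupted (rather than missing) cues are out of scope.

## Known limitations

* No spiking, no conductance noise, no within-theta continuous phase —
  three discrete settling snapshots stand in for the oscillation.
* kWTA stands in for interneuron circuits; its hard tie rule can
  silence a pool given exactly uniform drive.
* The Hebbian comparison uses the same learning rate as the error-driven
  network; the underlying study leaves this unstated.
* Subiculum, CA2, and EC laminar structure are not modeled.
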