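"""Capacity experiments: training/testing harness, Name Error, sweeps, stats.

The capacity test trains a network on a set of composite patterns for a
fixed number of epochs, then probes recall with cues missing 25% of each
trained pattern.  Recall is scored with *Name Error*: the output of each
EC slot is compared (cosine similarity by default) against the whole
vocabulary, and a pattern counts as incorrect if any slot's closest
vocabulary entry is not the trained one.  Conditions differing only in
which pathways learn from the error signal are compared over a grid of
CA3 sizes and training-set sizes, with a pooled bootstrap on the
per-pattern Name Error values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams
from .network import (
    ArchitectureConfig,
    ConditionParams,
    Network,
    build_network,
    learn_from_trace,
    pretrain_msp,
    recall,
    run_theta_cycle,
)
from .patterns import (
    CompositePattern,
    Vocabulary,
    corrupt_cue,
    generate_vocabulary,
    make_training_set,
)

__all__ = [
    "CONDITIONS",
    "ExperimentConfig",
    "name_error",
    "train_network",
    "train_and_test",
    "capacity_sweep",
    "bootstrap_compare",
    "summarize",
    "load_results",
]

#: The experimental conditions: which pathway learns error-driven.
CONDITIONS: dict[str, dict] = {
    "full_error_driven": dict(lmix_msp=0.001, lmix_tsp=0.001, pretrain_msp=False),
    "full_hebbian": dict(lmix_msp=1.0, lmix_tsp=1.0, pretrain_msp=False),
    "tsp_error_only": dict(lmix_msp=1.0, lmix_tsp=0.001, pretrain_msp=False),
    "msp_error_only": dict(lmix_msp=0.001, lmix_tsp=1.0, pretrain_msp=False),
    "pretrained_msp_variant": dict(lmix_msp=0.001, lmix_tsp=0.001, pretrain_msp=True),
}


@dataclass
class ExperimentConfig:
    """Grid and parameters of a capacity sweep."""

    conditions: list[str] = field(
        default_factory=lambda: ["full_error_driven", "full_hebbian"])
    ca3_sizes: list[int] = field(default_factory=lambda: [40])
    set_sizes: list[int] = field(default_factory=lambda: [40, 200])
    n_seeds: int = 5
    n_epochs: int = 15
    eps: float = 0.08
    corrupt_fraction: float = 0.25
    bootstrap_n: int = 10_000
    alpha: float = 0.005
    master_seed: int = 0
    vocab_size: int = 100
    min_hamming: int = 10
    arch: ArchitectureConfig = field(default_factory=ArchitectureConfig)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)

    def validate(self) -> None:
        for cond in self.conditions:
            if cond not in CONDITIONS:
                raise ValueError(
                    f"unknown condition {cond!r}; choose from {sorted(CONDITIONS)}")
        if not self.ca3_sizes or not self.set_sizes:
            raise ValueError("ca3_sizes and set_sizes must be non-empty")
        if self.n_seeds < 1 or self.n_epochs < 0:
            raise ValueError("n_seeds must be >= 1 and n_epochs >= 0")

    def condition_params(self, name: str) -> ConditionParams:
        return ConditionParams(eps=self.eps, **CONDITIONS[name])


def name_error(ec_out_snapshot: np.ndarray,
               target_slot_indices: tuple[int, ...] | list[int],
               vocab: Vocabulary, metric: str = "cosine") -> int:
    """Binary per-pattern score: 0 iff every slot names its trained entry.

    Each slot's output vector is compared against all vocabulary entries;
    the slot is correct only if the trained entry is the *strict* argmax
    (any tie involving the target counts as incorrect).  One wrong slot
    makes the whole pattern incorrect (score 1).
    """
    v = vocab.entries.astype(float)  # (n_entries, slot_size)
    n_slots = len(target_slot_indices)
    slots = np.asarray(ec_out_snapshot, float).reshape(n_slots, vocab.slot_size)
    if metric == "cosine":
        vn = v / np.linalg.norm(v, axis=1, keepdims=True)
        sn = np.linalg.norm(slots, axis=1, keepdims=True)
        sn[sn == 0] = 1.0
        sims = (slots / sn) @ vn.T  # (n_slots, n_entries)
    elif metric == "euclidean":
        d2 = ((slots[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
        sims = -d2
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    for s, target in enumerate(target_slot_indices):
        row = sims[s]
        others = np.delete(row, target)
        if not row[target] > others.max():
            return 1
    return 0


def train_network(net: Network, training_set: list[CompositePattern],
                  cond: ConditionParams, n_epochs: int,
                  rng: np.random.Generator) -> None:
    """Shuffled-epoch training: one full theta cycle + update per pattern."""
    for _ in range(n_epochs):
        for i in rng.permutation(len(training_set)):
            trace = run_theta_cycle(net, training_set[i].ec_vector, mode="train")
            learn_from_trace(net, trace, cond)


def test_network(net: Network, training_set: list[CompositePattern],
                 vocab: Vocabulary, corrupt_fraction: float,
                 cue_rng: np.random.Generator,
                 metric: str = "cosine") -> np.ndarray:
    """Score recall of every trained pattern from a degraded cue.

    Returns the per-pattern binary Name Error vector.  The cue
    corruptions are drawn from ``cue_rng`` so that different conditions
    given an identically-seeded generator see identical corruptions.
    """
    errors = np.empty(len(training_set), dtype=np.int8)
    for i, pat in enumerate(training_set):
        cue = corrupt_cue(pat, fraction=corrupt_fraction, rng=cue_rng)
        out = recall(net, cue)
        errors[i] = name_error(out, pat.slot_indices, vocab, metric=metric)
    return errors


def train_and_test(config: ExperimentConfig, net: Network,
                   training_set: list[CompositePattern], vocab: Vocabulary,
                   rng: np.random.Generator,
                   cue_rng: np.random.Generator,
                   cond: ConditionParams) -> np.ndarray:
    """Train for the configured epochs, then return per-pattern Name Errors."""
    train_network(net, training_set, cond, config.n_epochs, rng)
    return test_network(net, training_set, vocab, config.corrupt_fraction, cue_rng)


def _cell_seeds(master_seed: int, ca3: int, set_size: int, seed_idx: int):
    """Independent child generators for one grid cell.

    The entropy excludes the condition, so every condition at a cell sees
    the same initial weights, training set, presentation orders and cue
    corruptions — a paired comparison.
    """
    ss = np.random.SeedSequence([master_seed, ca3, set_size, seed_idx])
    net_s, set_s, shuf_s, cue_s, pre_s = ss.spawn(5)
    return (np.random.default_rng(net_s), np.random.default_rng(set_s),
            np.random.default_rng(shuf_s), np.random.default_rng(cue_s),
            np.random.default_rng(pre_s))


def run_cell(config: ExperimentConfig, condition: str, ca3: int,
             set_size: int, seed_idx: int, vocab: Vocabulary) -> np.ndarray:
    """Run one grid cell from scratch; returns per-pattern Name Errors."""
    from dataclasses import replace

    net_rng, set_rng, shuf_rng, cue_rng, pre_rng = _cell_seeds(
        config.master_seed, ca3, set_size, seed_idx)
    arch = replace(config.arch, n_ca3=ca3, n_dg=None)
    net = build_network(arch, rng=net_rng, params=config.dynamics)
    training_set = make_training_set(vocab, set_size, arch.n_slots, rng=set_rng)
    cond = config.condition_params(condition)
    if cond.pretrain_msp:
        pretrain_msp(net, training_set, cond, epochs=config.n_epochs, rng=pre_rng)
    return train_and_test(config, net, training_set, vocab, shuf_rng,
                          cue_rng, cond)


def sweep_vocabulary(config: ExperimentConfig) -> Vocabulary:
    """The single vocabulary shared by every cell of a sweep."""
    vocab_rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, 2 ** 20]))
    return generate_vocabulary(
        n=config.vocab_size, slot_size=config.arch.units_per_ec_slot,
        n_active=config.arch.ec_active_per_slot,
        min_hamming=config.min_hamming, rng=vocab_rng)


def capacity_sweep(config: ExperimentConfig, out_path: str | Path | None = None,
                   progress: bool = False) -> pd.DataFrame:
    """Run the full (condition x ca3 x set size x seed) grid.

    One row per cell with the mean Name Error and the per-pattern binary
    errors (as a 0/1 digit string, for bootstrap resampling).  When
    ``out_path`` is given, results are flushed after every cell and an
    interrupted sweep resumes without recomputing finished cells.
    """
    config.validate()
    vocab = sweep_vocabulary(config)
    rows: list[dict] = []
    done: set[tuple] = set()
    out_path = Path(out_path) if out_path is not None else None
    if out_path is not None and out_path.exists():
        prev = load_results(out_path)
        rows = prev.to_dict("records")
        done = {(r["condition"], r["ca3_size"], r["set_size"], r["seed"])
                for r in rows}

    for condition in config.conditions:
        for ca3 in config.ca3_sizes:
            for set_size in config.set_sizes:
                for seed_idx in range(config.n_seeds):
                    key = (condition, ca3, set_size, seed_idx)
                    if key in done:
                        continue
                    errors = run_cell(config, condition, ca3, set_size,
                                      seed_idx, vocab)
                    rows.append({
                        "condition": condition,
                        "ca3_size": ca3,
                        "dg_size": config.arch.dg_ca3_ratio * ca3,
                        "set_size": set_size,
                        "seed": seed_idx,
                        "name_error": float(errors.mean()),
                        "errors": "".join(map(str, errors.tolist())),
                    })
                    if progress:
                        print(f"  {condition} ca3={ca3} n={set_size} "
                              f"seed={seed_idx}: NE={errors.mean():.3f}",
                              flush=True)
                    if out_path is not None:
                        save_results(pd.DataFrame(rows), config, out_path)
    df = pd.DataFrame(rows)
    if out_path is not None:
        save_results(df, config, out_path)
    return df


def save_results(df: pd.DataFrame, config: ExperimentConfig,
                 path: str | Path) -> None:
    """Delimited text with a commented metadata header block."""
    path = Path(path)
    buf = io.StringIO()
    meta = asdict(config)
    for key in ("arch", "dynamics"):
        sub = meta.pop(key)
        meta.update({f"{key}.{k}": v for k, v in sub.items()})
    for k, v in sorted(meta.items()):
        buf.write(f"# {k} = {v}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def load_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"errors": str})
    return df


def errors_array(df: pd.DataFrame, condition: str, set_size: int | None = None,
                 ca3_size: int | None = None) -> np.ndarray:
    """Pooled per-pattern Name Error values for a condition (optionally
    restricted to one grid cell), concatenated across seeds."""
    sel = df[df["condition"] == condition]
    if set_size is not None:
        sel = sel[sel["set_size"] == set_size]
    if ca3_size is not None:
        sel = sel[sel["ca3_size"] == ca3_size]
    if sel.empty:
        raise ValueError(f"no results for condition={condition!r} "
                         f"set_size={set_size} ca3_size={ca3_size}")
    return np.concatenate(
        [np.frombuffer(s.encode(), dtype=np.uint8) - ord("0")
         for s in sel["errors"]]).astype(float)


def bootstrap_compare(errors_a: np.ndarray, errors_b: np.ndarray,
                      n_boot: int = 10_000,
                      rng: np.random.Generator | int | None = None) -> float:
    """Two-sided pooled-bootstrap p-value for a difference in means.

    Both groups are pooled; resampled pairs of groups (with replacement,
    original sizes) provide the null distribution of mean differences.
    p is the fraction of null differences at least as extreme as the
    observed one (add-one smoothed so p is never exactly 0).
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(errors_a, float)
    b = np.asarray(errors_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("bootstrap_compare: both groups must be non-empty")
    obs = a.mean() - b.mean()
    pool = np.concatenate([a, b])
    null_a = rng.choice(pool, size=(n_boot, a.size), replace=True).mean(axis=1)
    null_b = rng.choice(pool, size=(n_boot, b.size), replace=True).mean(axis=1)
    null = null_a - null_b
    p = (1 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (n_boot + 1)
    return float(min(p, 1.0))


def summarize(df: pd.DataFrame) -> pd.DataFrame:
    """Mean Name Error per (condition, ca3_size, set_size), over seeds."""
    return (df.groupby(["condition", "ca3_size", "set_size"], as_index=False)
            ["name_error"].mean())
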