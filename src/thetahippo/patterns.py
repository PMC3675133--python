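"""Synthetic binary input patterns for the capacity experiments.

The entorhinal input layer is organised into slots, each representing a
separable cortical element.  Within a slot, inputs are drawn from a
*vocabulary* of sparse binary patterns generated by rejection sampling
under a minimum pairwise Hamming distance, emulating well-separated
representational repertoires.  A composite stimulus picks one vocabulary
entry per slot; test cues are degraded copies with a fraction of the
pattern deleted (zeroed, never flipped).

Default geometry: 100 entries of 12 active units out of 40 per slot, with
a Hamming floor of 10 (i.e. pairwise overlap of at most 7 active units).
This geometry keeps the rejection rate modest while honouring the floor;
sparser slots make a 100-entry vocabulary at distance 10 combinatorially
impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Vocabulary",
    "CompositePattern",
    "VocabularyGenerationError",
    "generate_vocabulary",
    "make_training_set",
    "corrupt_cue",
    "save_vocabulary",
    "load_vocabulary",
    "save_training_set",
    "load_training_set",
]

DEFAULT_N_ENTRIES = 100
DEFAULT_SLOT_SIZE = 40
DEFAULT_N_ACTIVE = 12
DEFAULT_MIN_HAMMING = 10


class VocabularyGenerationError(RuntimeError):
    """Raised when the requested vocabulary cannot be generated."""


@dataclass
class Vocabulary:
    """Per-slot repertoire of binary patterns with a pairwise Hamming floor."""

    entries: np.ndarray  # (n_entries, slot_size) uint8
    n_active: int
    min_hamming: int
    seed: int | None = None

    @property
    def n_entries(self) -> int:
        return self.entries.shape[0]

    @property
    def slot_size(self) -> int:
        return self.entries.shape[1]

    def pairwise_hamming_min(self) -> int:
        """Exhaustive minimum pairwise Hamming distance over all entries."""
        e = self.entries.astype(np.int64)
        overlap = e @ e.T
        # equal active counts: distance = 2*(n_active - overlap)
        dist = 2 * (self.n_active - overlap)
        iu = np.triu_indices(self.n_entries, k=1)
        return int(dist[iu].min())


@dataclass
class CompositePattern:
    """One vocabulary index per slot plus the concatenated binary vector."""

    slot_indices: tuple[int, ...]
    ec_vector: np.ndarray = field(repr=False)


def generate_vocabulary(n: int = DEFAULT_N_ENTRIES,
                        slot_size: int = DEFAULT_SLOT_SIZE,
                        n_active: int = DEFAULT_N_ACTIVE,
                        min_hamming: int = DEFAULT_MIN_HAMMING,
                        rng: np.random.Generator | int | None = None,
                        max_attempts: int = 500_000) -> Vocabulary:
    """Rejection-sample ``n`` binary patterns with the Hamming floor.

    Each candidate activates exactly ``n_active`` of ``slot_size`` units;
    it is accepted if its Hamming distance to every accepted entry is at
    least ``min_hamming``.  Fails with a named constraint if parameters
    are infeasible or the attempt budget runs out.
    """
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    if n_active > slot_size:
        raise VocabularyGenerationError(
            f"infeasible: n_active={n_active} > slot_size={slot_size}")
    if min_hamming > 2 * n_active:
        raise VocabularyGenerationError(
            f"infeasible: min_hamming={min_hamming} > 2*n_active={2 * n_active} "
            "(two patterns with equal active counts differ in at most "
            "2*n_active positions)")
    entries = np.zeros((n, slot_size), dtype=np.uint8)
    accepted = 0
    for _ in range(max_attempts):
        cand = np.zeros(slot_size, dtype=np.uint8)
        cand[rng.choice(slot_size, size=n_active, replace=False)] = 1
        if accepted:
            overlap = entries[:accepted].astype(np.int64) @ cand.astype(np.int64)
            if (2 * (n_active - overlap)).min() < min_hamming:
                continue
        entries[accepted] = cand
        accepted += 1
        if accepted == n:
            return Vocabulary(entries=entries, n_active=n_active,
                              min_hamming=min_hamming, seed=seed)
    raise VocabularyGenerationError(
        f"attempt budget exhausted: accepted {accepted}/{n} patterns in "
        f"{max_attempts} draws under min_hamming={min_hamming} with "
        f"n_active={n_active}, slot_size={slot_size}")


def make_training_set(vocab: Vocabulary, n_patterns: int, n_slots: int,
                      rng: np.random.Generator | int | None = None
                      ) -> list[CompositePattern]:
    """Draw distinct composite patterns from the slot-index product space."""
    rng = np.random.default_rng(rng)
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    space = vocab.n_entries ** n_slots  # exact (python int)
    if n_patterns > space:
        raise ValueError(
            f"n_patterns={n_patterns} exceeds the {vocab.n_entries}^{n_slots} "
            "distinct slot-index combinations")
    seen: set[tuple[int, ...]] = set()
    out: list[CompositePattern] = []
    while len(out) < n_patterns:
        idx = tuple(int(i) for i in rng.integers(0, vocab.n_entries, size=n_slots))
        if idx in seen:
            continue
        seen.add(idx)
        vec = np.concatenate([vocab.entries[i] for i in idx]).astype(float)
        out.append(CompositePattern(slot_indices=idx, ec_vector=vec))
    return out


def corrupt_cue(pattern: CompositePattern | np.ndarray, fraction: float = 0.25,
                rng: np.random.Generator | int | None = None,
                mode: str = "slot", n_slots: int | None = None) -> np.ndarray:
    """Degrade a stimulus by zeroing a fraction of it.

    ``mode="slot"`` (default) deletes whole slots: fraction*n_slots slots,
    chosen uniformly, are set to zero (2 of 8 at the defaults).  The
    fraction must then make the slot count integral.  ``mode="unit"``
    instead zeroes a uniform fraction of the *active* units.  Deleted
    content is zeroed, never flipped, so corruption only removes activity.
    """
    rng = np.random.default_rng(rng)
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must lie in [0, 1), got {fraction}")
    vec = pattern.ec_vector if isinstance(pattern, CompositePattern) else pattern
    cue = np.asarray(vec, dtype=float).copy()
    if fraction == 0.0:
        return cue
    if mode == "slot":
        if n_slots is None:
            if isinstance(pattern, CompositePattern):
                n_slots = len(pattern.slot_indices)
            else:
                raise ValueError("corrupt_cue: n_slots required for a bare vector")
        n_del = fraction * n_slots
        if abs(n_del - round(n_del)) > 1e-9:
            raise ValueError(
                f"fraction={fraction} deletes a non-integral number of the "
                f"{n_slots} slots; use mode='unit' for fractional deletion")
        n_del = round(n_del)
        slot_size = cue.shape[0] // n_slots
        for s in rng.choice(n_slots, size=n_del, replace=False):
            cue[s * slot_size:(s + 1) * slot_size] = 0.0
    elif mode == "unit":
        active = np.flatnonzero(cue > 0)
        n_del = round(fraction * active.size)
        cue[rng.choice(active, size=n_del, replace=False)] = 0.0
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return cue


# -- plain-text serialization ------------------------------------------------

def save_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    """One entry per line as a string of 0/1 digits, with a header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_active={vocab.n_active} min_hamming={vocab.min_hamming} "
                 f"seed={vocab.seed}\n")
        for row in vocab.entries:
            fh.write("".join(map(str, row.tolist())) + "\n")


def load_vocabulary(path: str | Path) -> Vocabulary:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[int]] = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
            continue
        if line.strip():
            rows.append([int(c) for c in line.strip()])
    entries = np.array(rows, dtype=np.uint8)
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return Vocabulary(entries=entries, n_active=int(meta["n_active"]),
                      min_hamming=int(meta["min_hamming"]), seed=seed)


def save_training_set(patterns: list[CompositePattern], path: str | Path) -> None:
    """One composite per line: comma-separated slot indices."""
    with Path(path).open("w") as fh:
        for p in patterns:
            fh.write(",".join(map(str, p.slot_indices)) + "\n")


def load_training_set(path: str | Path, vocab: Vocabulary) -> list[CompositePattern]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        idx = tuple(int(t) for t in line.split(","))
        vec = np.concatenate([vocab.entries[i] for i in idx]).astype(float)
        out.append(CompositePattern(slot_indices=idx, ec_vector=vec))
    return out
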