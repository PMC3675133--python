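"""Build the synthetic stimulus material: a slot vocabulary and composites.

Each entorhinal (EC) slot draws its content from a vocabulary of 100
sparse binary patterns (12 active of 40 units) kept at least Hamming
distance 10 apart, so every entry is a well-separated "name".  A stimulus
is one entry per slot; a test cue deletes 2 of the 8 slots (25% of the
pattern) to probe pattern completion.
"""

import numpy as np

from thetahippo.patterns import (
    corrupt_cue,
    generate_vocabulary,
    make_training_set,
)

vocab = generate_vocabulary(rng=42)
print(f"vocabulary: {vocab.n_entries} entries, {vocab.n_active} of "
      f"{vocab.slot_size} units active")
print(f"minimum pairwise Hamming distance (exhaustive): "
      f"{vocab.pairwise_hamming_min()}  (floor: {vocab.min_hamming})")

training_set = make_training_set(vocab, n_patterns=5, n_slots=8, rng=43)
print(f"\n{len(training_set)} composite stimuli; first uses vocabulary "
      f"entries {training_set[0].slot_indices} across its 8 slots")

cue = corrupt_cue(training_set[0], fraction=0.25, rng=44)
active = int(cue.sum())
print(f"a 25%-deleted cue keeps {active} of "
      f"{int(training_set[0].ec_vector.sum())} active units "
      f"({np.sum(cue.reshape(8, -1).sum(1) == 0)} slots fully deleted)")
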