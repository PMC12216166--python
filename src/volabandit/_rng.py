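"""Seed-stream discipline.

A single master seed is split into independent named substreams so that,
e.g., re-rolling the point splits never perturbs the reward sequence.
"""

from __future__ import annotations

import numpy as np

# Named substream keys. Values are arbitrary but frozen: changing one
# changes every downstream artefact generated from a given master seed.
STABLE_REWARDS = 0
VOLATILE_REWARDS = 1
STABLE_POINTS = 2
VOLATILE_POINTS = 3
FAMILIARISATION = 4
FAMILIARISATION_POINTS = 5
COHORT_PARAMS = 6
COHORT_SCHEDULES = 7
COHORT_CHOICES = 8
SDQ = 9
FIT = 10
KFOLD = 11
PPC = 12


def substream(seed: int, *keys: int) -> np.random.Generator:
    """Return an independent generator for (seed, keys).

    Distinct key tuples yield statistically independent streams for the
    same master seed (numpy SeedSequence spawn-key mechanism).
    """
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in keys)))


def child_seed(seed: int, *keys: int) -> int:
    """Derive a deterministic 31-bit child seed from (seed, keys)."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2**31))
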