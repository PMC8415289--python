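"""Seed fan-out.

A single top-level integer seed is expanded into independent, named
child streams (``fs_null``, ``phi_perm``, ``abc``, ...), so each stage
of a run is reproducible on its own and stages do not share state.
"""

from __future__ import annotations

import numpy as np


def child_seed_sequence(seed: int, name: str) -> np.random.SeedSequence:
    """Derive a named child ``SeedSequence`` from a master seed.

    The stream name is hashed into spawn-key integers so that distinct
    names give statistically independent streams and the mapping is
    stable across sessions (no reliance on Python's randomized
    ``hash``).
    """
    key = [int.from_bytes(name.encode("utf-8")[i : i + 4].ljust(4, b"\0"), "little")
           for i in range(0, max(len(name), 1), 4)]
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(key))


def child_rng(seed: int, name: str) -> np.random.Generator:
    """A ``numpy`` Generator on the named child stream."""
    return np.random.default_rng(child_seed_sequence(seed, name))


def child_int_seed(seed: int, name: str, index: int = 0) -> int:
    """A positive 31-bit integer seed for libraries that take plain ints.

    ``index`` selects successive seeds on the same named stream (for
    per-replicate seeding of external simulators).
    """
    ss = child_seed_sequence(seed, name)
    state = ss.generate_state(index + 1, dtype=np.uint32)
    return int(state[index] % (2**31 - 1)) + 1
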