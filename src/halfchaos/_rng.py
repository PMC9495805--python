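"""Named random substreams derived from one global seed.

Every stochastic component (topology, functions, initial state, disturbance
draws, regulation choices ...) pulls its own generator from the global seed
keyed by a component name, so one component can be varied without reseeding
the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for component `name` derived from `seed`.

    The (seed, name) pair deterministically identifies the stream; distinct
    names give statistically independent streams via SeedSequence spawning.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
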