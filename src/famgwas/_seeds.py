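"""Named random substreams derived from a single root seed.

Every stochastic routine in the package takes either an integer seed or a
:class:`numpy.random.Generator`.  When a root seed drives a multi-stage run,
each stage draws from a named substream so that stages are individually
reproducible and mutually independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_generator"]


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` under `root_seed`.

    The stream key is a CRC32 of the name, so the mapping is stable across
    sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(root_seed) & 0x7FFFFFFF, spawn_key=(key,))
    return np.random.default_rng(ss)


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
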