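"""Reproducible random-number streams.

A single root seed spawns independent, *named* substreams, one per signal
type (interest sources, background sources, interference noise, measurement
noise, geometry, ...).  Because each stream is keyed by name rather than by
draw order, toggling one simulation component (e.g. the evoked-response
flag) does not shift the random numbers consumed by any other component.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["RandomStreams", "substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the substream *name* of root *seed*.

    The mapping is deterministic: the same (seed, name) pair always yields
    the same stream, independent of any other stream's consumption.
    """
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.default_rng(ss)


class RandomStreams:
    """Family of named random substreams derived from one root seed."""

    def __init__(self, seed: int):
        self.seed = int(seed)

    def get(self, name: str) -> np.random.Generator:
        """Fresh generator for the named substream (restarts the stream)."""
        return substream(self.seed, name)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RandomStreams(seed={self.seed})"
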