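"""Reproducible random-number streams for Monte-Carlo work.

All randomness in the package flows from a single master seed through named
substreams, so replicate sets are reproducible and order-independent: the
generator for (stream, replicate) is the same whether replicates run
sequentially, in parallel, or alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RngSpec"]

# Fixed stream identifiers; adding a stream must not renumber existing ones.
_STREAMS = {
    "null": 0,
    "replace": 1,
    "agent": 2,
    "influence": 3,
    "layout": 4,
    "fixtures": 5,
}


@dataclass(frozen=True)
class RngSpec:
    """A master seed from which independent substreams are derived.

    ``generator(stream, *key)`` returns a fresh ``numpy.random.Generator``
    whose state depends only on (seed, stream, key). Identical arguments
    always reproduce the identical stream.
    """

    seed: int

    def generator(self, stream: str = "null", *key: int) -> np.random.Generator:
        try:
            sid = _STREAMS[stream]
        except KeyError:
            raise ValueError(f"unknown stream {stream!r}") from None
        ss = np.random.SeedSequence(self.seed, spawn_key=(sid, *map(int, key)))
        return np.random.default_rng(ss)
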