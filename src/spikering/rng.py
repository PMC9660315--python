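"""Named, counter-based random streams.

A single master seed fans out into independent child streams keyed by name
(e.g. ``("noise", "lif")`` or ``("connectivity", "ff")``).  Each stream is a
Philox counter-based generator, so the draws consumed by one purpose are
completely independent of every other purpose: structural randomness
(connectivity, delays, weights) never interacts with dynamical randomness
(membrane noise, Poisson spiking), and results are invariant to the number of
connectivity partitions or the bundle mode, which consume no randomness at all.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(master_seed: int, *names: str) -> np.random.Generator:
    """Return the child generator identified by ``names`` under ``master_seed``.

    The same ``(master_seed, names)`` pair always yields a generator in the
    same initial state; distinct name tuples yield statistically independent
    streams.
    """
    if not names:
        raise ValueError("at least one stream name is required")
    key = tuple(zlib.crc32(name.encode("utf-8")) for name in names)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=key)
    return np.random.Generator(np.random.Philox(ss))
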