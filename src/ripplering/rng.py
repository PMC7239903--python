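"""Named random-number streams.

All stochastic stages derive their generator from a single session seed plus
a short stream name, so that adding or removing one stage never perturbs the
draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stream `name` derived from `seed`.

    The same (seed, name) pair always yields an identical stream; distinct
    names yield statistically independent streams.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0xFFFFFFFF, tag]))
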