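"""Named, independent random substreams derived from one master seed.

Every stochastic component of a simulation (device-to-device sampling,
cycle-to-cycle sampling, spike-train encoding, weight initialization, ...)
draws from its own substream so that, e.g., changing the encoder's
consumption of random numbers cannot silently shift the device lottery.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _name_key(name: str) -> int:
    # stable across processes and platforms (unlike hash())
    return zlib.crc32(name.encode("utf-8"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of master ``seed``.

    The same (seed, name) pair always yields an identical stream; distinct
    names yield statistically independent streams (SeedSequence spawn keys).
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_name_key(name),))
    return np.random.Generator(np.random.PCG64(ss))
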