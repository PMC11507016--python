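"""Named random substreams.

All stochastic routines in the package draw from independent, named
substreams of a single master seed. Substreams are derived through
``numpy.random.SeedSequence`` spawn keys built from CRC32 hashes of the
stream names, so the layout is stable across platforms and versions of this
package. The practical consequence: toggling one mechanism (say, node loss)
consumes draws only from its own stream and never perturbs the history of
another mechanism run under the same master seed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "derive_seed"]


def _key(parts: tuple) -> tuple[int, ...]:
    return tuple(zlib.crc32(str(p).encode("utf-8")) for p in parts)


def substream(seed: int, *names) -> np.random.Generator:
    """Return a Generator for the substream of ``seed`` named by ``names``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=_key(names))
    return np.random.default_rng(ss)


def derive_seed(seed: int, *names) -> int:
    """Derive a fresh integer seed (< 2**31) for the named substream."""
    return int(substream(seed, *names).integers(2**31))
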