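"""Counter-based random substreams.

All randomness in the package flows from one user-supplied integer seed.
Independent stages derive their own generator from (seed, stage name[, index])
so any stage can be re-run in isolation and still reproduce bit-identically.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys``.

    String keys are hashed with crc32 (stable across platforms and runs);
    integer keys are used as-is. The same (seed, keys) always yields the
    same stream; distinct keys yield statistically independent streams.
    """
    spawn_key = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in keys
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key))
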