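"""Deterministic seed derivation.

Every random operation in a run derives its seed from the master seed
plus a textual stage tag, so the whole pipeline is a pure function of
(data, config, master seed) and independent stages can be re-run in
isolation with identical randomness.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(master: int, *tags) -> int:
    """Stable sub-seed from a master seed and hashable stage tags."""
    keys = [int(master) % (2**31)]
    for t in tags:
        if isinstance(t, (int, np.integer)):
            keys.append(int(t) % (2**31))
        else:
            keys.append(zlib.crc32(str(t).encode()) % (2**31))
    ss = np.random.SeedSequence(keys)
    return int(ss.generate_state(1)[0] % (2**31))
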