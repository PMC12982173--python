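"""Named random substreams.

All randomness in a run flows from one global seed; each module draws from a
named substream so changes in one module never shift another module's draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` under `seed`.

    The spawn key is derived from a CRC32 of the name, so the mapping is
    stable across processes and Python versions.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & (2**63 - 1),
                                                        spawn_key=(key,)))
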