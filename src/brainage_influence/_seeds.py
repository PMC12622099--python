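"""Deterministic fan-out of one master seed into per-stage seeds.

Every stochastic stage (jitter in MI estimation, CV fold shuffling,
undersampling, synthetic draws) receives its own seed derived from the run's
master seed plus a stage path such as ``("agemodel", k)``.  Any stage can
therefore be reproduced in isolation, and two stages never share a stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(master: int, *path: object) -> int:
    """A seed in [0, 2^31) determined by ``master`` and a stage path."""
    token = "/".join(str(p) for p in path)
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, zlib.crc32(token.encode())])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
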