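"""Deterministic seed derivation for experiment sub-streams.

Every stage of a replicated experiment draws its randomness from a seed that
is a pure function of (master seed, stage name, indices), obtained by
hashing the joined string with SHA-256. Adding a new stage therefore never
perturbs the streams of existing stages, and all derived seeds fit in 31
bits.
"""

from __future__ import annotations

import hashlib


def substream_seed(master_seed: int, *parts: object) -> int:
    """A 31-bit seed derived from the master seed and a stage identifier."""
    key = "|".join([str(int(master_seed)), *map(str, parts)])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
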