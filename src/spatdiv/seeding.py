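"""Deterministic sub-seed derivation.

One top-level seed fans out to per-stage seeds by hashing the stage name,
so stages can be re-run independently yet reproducibly.  Derived seeds stay
below 2**31.
"""

import zlib


def derive_seed(seed: int, name: str) -> int:
    """Stable sub-seed for a named stage under a base seed."""
    return zlib.crc32(f"{seed}:{name}".encode()) & 0x7FFFFFFF
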