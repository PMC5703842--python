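"""Deterministic per-stage seed derivation from a single master seed."""

from __future__ import annotations

import zlib


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from a master seed and stage name.

    Stable across runs and platforms (CRC32 of the stage name mixed with the
    master seed), so every stochastic stage of the pipeline is reproducible
    from one number.
    """
    h = zlib.crc32(stage.encode("utf-8")) & 0xFFFFFFFF
    return int((master_seed * 2654435761 + h) % (2**31 - 1))
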