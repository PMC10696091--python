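"""Deterministic fan-out of one root seed into per-module child seeds.

A single root seed in the pipeline config must reproduce every stage, and a
stage re-run in isolation must see the same stream it saw inside the full
pipeline.  Child seeds are therefore a pure function of (root seed, stage
name), via CRC-32 of the composed string, reduced mod 2**31.
"""

from __future__ import annotations

import zlib


def child_seed(root_seed: int, name: str) -> int:
    """Derive a stable child seed for a named module/stage.

    Parameters
    ----------
    root_seed : int
        The pipeline-level seed.
    name : str
        Stage identifier, e.g. ``"simulate"`` or ``"score:SAMPLE_01"``.
    """
    return zlib.crc32(f"{root_seed}:{name}".encode()) % (2**31)
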