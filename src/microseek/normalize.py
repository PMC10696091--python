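"""Read normalization ahead of scoring: the N and length rules.

Reads with more than one N are excluded outright.  A single N is replaced by
a seeded-random nucleotide for scoring only — the stored read keeps its N so
assembly can use the N-wildcard overlap rule.  75-base reads get one random
3' nucleotide appended, again for scoring only, to match the 76-base model
input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import BASES

EXCLUDED = "EXCLUDED"


@dataclass
class NormalizedRead:
    """Outcome of normalize_read.

    ``scoring_sequence`` is None iff the read is excluded.  When a single N
    was replaced, ``n_position``/``n_replacement`` record the substitution so
    downstream consumers (contig finalization) can reuse the same base.
    """

    status: str  # "ok" | "EXCLUDED"
    scoring_sequence: str | None
    reason: str = ""
    n_position: int | None = None
    n_replacement: str | None = None
    pad_base: str | None = None

    @property
    def excluded(self) -> bool:
        return self.status == EXCLUDED


def normalize_read(
    read: str, expected_length: int = 76, rng: np.random.Generator | None = None
) -> NormalizedRead:
    """Apply the exclusion, N-replacement and 3'-padding rules to one read."""
    if len(read) > expected_length:
        raise ValueError(f"read length {len(read)} exceeds expected {expected_length}")
    if len(read) < expected_length - 1:
        return NormalizedRead(EXCLUDED, None, reason="too_short")
    n_count = read.count("N")
    if n_count > 1:
        return NormalizedRead(EXCLUDED, None, reason="multiple_N")
    if rng is None:
        rng = np.random.default_rng(0)
    seq = read
    n_position = n_replacement = None
    if n_count == 1:
        n_position = seq.index("N")
        n_replacement = BASES[int(rng.integers(4))]
        seq = seq[:n_position] + n_replacement + seq[n_position + 1 :]
    pad_base = None
    if len(seq) == expected_length - 1:
        pad_base = BASES[int(rng.integers(4))]
        seq = seq + pad_base
    return NormalizedRead("ok", seq, n_position=n_position, n_replacement=n_replacement, pad_base=pad_base)
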