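"""Segmentation of labeled references into fixed-length training examples.

References are split into train/validation/test BEFORE segmentation, so no
segment of a held-out reference can leak into training.  Per-class strides
(defaults: human 26, viral 2, bacterial 130) compensate for unequal total
sequence per class so the per-class segment counts come out balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import ORIGIN_LABELS, ReferenceRecord

DEFAULT_STRIDES = {"human": 26, "viral": 2, "bacterial": 130}


@dataclass
class SegmentationConfig:
    segment_length: int = 76
    stride_by_class: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_STRIDES))
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)

    def __post_init__(self) -> None:
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if any(s < 1 for s in self.stride_by_class.values()):
            raise ValueError("strides must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def segment_reference(sequence: str, segment_length: int = 76, stride: int = 1) -> list[str]:
    """Full-length substrings starting at 0, stride, 2*stride, ...; N-containing dropped."""
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out = []
    for start in range(0, len(sequence) - segment_length + 1, stride):
        seg = sequence[start : start + segment_length]
        if "N" not in seg:
            out.append(seg)
    return out


@dataclass
class SegmentDataset:
    """Segments plus integer labels (index into ORIGIN_LABELS)."""

    segments: list[str]
    labels: np.ndarray
    source_accessions: list[str]

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class Datasets:
    train: SegmentDataset
    val: SegmentDataset
    test: SegmentDataset


def _allocate(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder split of n references across the three sets."""
    raw = [f * n for f in fractions]
    base = [int(np.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for b, r in zip(base, raw)])
    for i in range(rem):
        base[order[i]] += 1
    return base


def build_dataset(
    references: list[ReferenceRecord],
    config: SegmentationConfig | None = None,
    rng_seed: int = 0,
) -> Datasets:
    """Split references per class, then segment each split with its class stride."""
    config = config or SegmentationConfig()
    rng = np.random.default_rng(rng_seed)
    by_class: dict[str, list[ReferenceRecord]] = {lab: [] for lab in ORIGIN_LABELS}
    for r in references:
        if r.label not in by_class:
            raise ValueError(f"unknown origin label {r.label!r}")
        by_class[r.label].append(r)
    for lab, refs in by_class.items():
        if not refs:
            raise ValueError(f"class {lab!r} has no references")

    splits: dict[str, list[ReferenceRecord]] = {"train": [], "val": [], "test": []}
    for lab in ORIGIN_LABELS:
        refs = by_class[lab]
        perm = rng.permutation(len(refs))
        n_tr, n_va, _ = _allocate(len(refs), config.split_fractions)
        for j, idx in enumerate(perm):
            split = "train" if j < n_tr else ("val" if j < n_tr + n_va else "test")
            splits[split].append(refs[idx])

    def segment_split(refs: list[ReferenceRecord]) -> SegmentDataset:
        segs: list[str] = []
        labels: list[int] = []
        accs: list[str] = []
        for r in refs:
            stride = config.stride_by_class[r.label]
            pieces = segment_reference(r.sequence, config.segment_length, stride)
            segs.extend(pieces)
            labels.extend([ORIGIN_LABELS.index(r.label)] * len(pieces))
            accs.extend([r.accession] * len(pieces))
        return SegmentDataset(segs, np.array(labels, dtype=np.int64), accs)

    return Datasets(*(segment_split(splits[k]) for k in ("train", "val", "test")))
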