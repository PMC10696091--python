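"""Score-guided greedy assembly of putative microbial contigs.

Every read whose bacterial or viral score reaches the seed threshold
(default 0.46) becomes a seed.  Seeds are processed bacterial-first in
descending bacterial score, then viral in descending viral score, and each
is extended greedily in both directions by reads overlapping the contig end
by at least ``min_overlap`` bases with an exact match, where N on either
side matches any base and the non-N base is kept.  A read joins at most one
contig; reads consumed by an earlier contig are skipped as later seeds.

Candidate choice at an end (the underlying assembly strategy leaves this
open): the read giving the longest extension wins; ties break by higher
seed-class score, then lexicographic read id — making assembly fully
deterministic.  When a contig is finished, any unused read that aligns
wholly within it (wildcard-exact) is absorbed as a member: such reads are
copies of the same molecule, and absorbing them prevents them from seeding
redundant fragments of a transcript already assembled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .simulate import BASES


@dataclass
class AssemblyParams:
    seed_threshold: float = 0.46
    min_overlap: int = 24
    max_contig_length: int = 2000
    k_index: int | None = None  # defaults to min_overlap

    def __post_init__(self) -> None:
        if not (0.0 < self.seed_threshold < 1.0):
            raise ValueError("seed_threshold must be in (0, 1)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.k_index is None:
            self.k_index = self.min_overlap


@dataclass
class ScoredRead:
    """A stored (un-mutated) read plus its microbial scores.

    ``n_replacement`` is the random base used for this read's single N in
    the scoring path, reused if the N survives to a finished contig.
    """

    read_id: str
    sequence: str
    p_bacterial: float
    p_viral: float
    n_replacement: str | None = None

    def score_for(self, seed_class: str) -> float:
        return self.p_bacterial if seed_class == "bacterial" else self.p_viral


@dataclass
class Contig:
    contig_id: str
    sequence: str
    seed_read_id: str
    seed_class: str
    members: list[tuple[str, int]] = field(default_factory=list)  # (read_id, offset)
    left_extensions: int = 0
    right_extensions: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def member_read_ids(self) -> list[str]:
        return [rid for rid, _ in self.members]


def _wildcard_eq(a: str, b: str) -> bool:
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


def _expand_word(word: str, limit: int = 2) -> list[str]:
    """All A/C/G/T words matching a word with up to ``limit`` Ns."""
    n_count = word.count("N")
    if n_count == 0:
        return [word]
    if n_count > limit:
        return []
    positions = [i for i, ch in enumerate(word) if ch == "N"]
    out = []
    for combo in product(BASES, repeat=len(positions)):
        chars = list(word)
        for pos, base in zip(positions, combo):
            chars[pos] = base
        out.append("".join(chars))
    return out


class _ReadIndex:
    """Hash index on length-k read prefixes and suffixes (N expanded)."""

    def __init__(self, reads: dict[str, ScoredRead], k: int):
        self.k = k
        self.prefix: dict[str, list[str]] = {}
        self.suffix: dict[str, list[str]] = {}
        for rid in sorted(reads):
            seq = reads[rid].sequence
            if len(seq) < k:
                continue
            for word in _expand_word(seq[:k], limit=1):
                self.prefix.setdefault(word, []).append(rid)
            for word in _expand_word(seq[-k:], limit=1):
                self.suffix.setdefault(word, []).append(rid)

    def lookup(self, word: str, side: str) -> list[str]:
        table = self.prefix if side == "prefix" else self.suffix
        hits: list[str] = []
        for w in _expand_word(word):
            hits.extend(table.get(w, []))
        return hits


def select_and_sort_seeds(reads: list[ScoredRead], seed_threshold: float = 0.46) -> list[tuple[ScoredRead, str]]:
    """Reads meeting the threshold, with seed class, in assembly order.

    A read whose bacterial score reaches the threshold is classed bacterial
    even if its viral score is higher — bacterial seeds are prioritized.
    """
    seeds: list[tuple[ScoredRead, str]] = []
    for r in reads:
        if r.p_bacterial >= seed_threshold:
            seeds.append((r, "bacterial"))
        elif r.p_viral >= seed_threshold:
            seeds.append((r, "viral"))
    def key(item):
        r, cls = item
        return (0 if cls == "bacterial" else 1, -r.score_for(cls), r.read_id)
    return sorted(seeds, key=key)


def _best_candidate(
    contig: list[str],
    side: str,
    pool: dict[str, ScoredRead],
    index: _ReadIndex,
    used: set[str],
    consumed: set[str],
    seed_class: str,
    params: AssemblyParams,
) -> tuple[str, int] | None:
    """Find (read_id, overlap) of the best extension at one contig end."""
    k = index.k
    length = len(contig)
    best = None  # (-ext, -score, read_id, overlap)
    max_o = min(length, 76)
    for o in range(params.min_overlap, max_o + 1):
        if side == "right":
            word = "".join(contig[length - o : length - o + k])
            cand = index.lookup(word, "prefix")
        else:
            word = "".join(contig[o - k : o])
            cand = index.lookup(word, "suffix")
        contig_part = "".join(contig[length - o :]) if side == "right" else "".join(contig[:o])
        for rid in cand:
            if rid in used or rid in consumed:
                continue
            seq = pool[rid].sequence
            ext = len(seq) - o
            if ext <= 0:
                continue
            read_part = seq[:o] if side == "right" else seq[-o:]
            if not _wildcard_eq(contig_part, read_part):
                continue
            entry = (-ext, -pool[rid].score_for(seed_class), rid, o)
            if best is None or entry < best:
                best = entry
    if best is None:
        return None
    return best[2], best[3]


def extend_seed(
    seed: ScoredRead,
    seed_class: str,
    pool: dict[str, ScoredRead],
    params: AssemblyParams,
    index: _ReadIndex | None = None,
    consumed: set[str] | None = None,
    contig_id: str = "contig_0000",
) -> Contig:
    """Greedily extend one seed read bidirectionally into a contig."""
    index = index or _ReadIndex(pool, params.k_index)
    consumed = consumed or set()
    contig = list(seed.sequence)
    members: list[tuple[str, int]] = [(seed.read_id, 0)]
    used = {seed.read_id}
    n_left = n_right = 0

    def absorb_overlap(start: int, read_seq: str, read_start: int, length: int) -> None:
        # keep the non-N base wherever an N aligned against a base
        for i in range(length):
            if contig[start + i] == "N" and read_seq[read_start + i] != "N":
                contig[start + i] = read_seq[read_start + i]

    while len(contig) < params.max_contig_length:
        found = _best_candidate(contig, "right", pool, index, used, consumed, seed_class, params)
        if found is None:
            break
        rid, o = found
        seq = pool[rid].sequence
        absorb_overlap(len(contig) - o, seq, 0, o)
        members.append((rid, len(contig) - o))
        contig.extend(seq[o:])
        used.add(rid)
        n_right += 1

    while len(contig) < params.max_contig_length:
        found = _best_candidate(contig, "left", pool, index, used, consumed, seed_class, params)
        if found is None:
            break
        rid, o = found
        seq = pool[rid].sequence
        ext = len(seq) - o
        absorb_overlap(0, seq, ext, o)
        contig[:0] = list(seq[:ext])
        members = [(m, off + ext) for m, off in members] + [(rid, 0)]
        used.add(rid)
        n_left += 1

    # absorb unused reads lying wholly within the contig: they are copies of
    # the same molecule and must not seed redundant contigs later
    contig_str = "".join(contig)
    k = index.k
    word_pos: dict[str, list[int]] = {}
    for pos in range(len(contig_str) - k + 1):
        for word in _expand_word(contig_str[pos : pos + k], limit=1):
            word_pos.setdefault(word, []).append(pos)
    for rid in sorted(pool):
        if rid in used or rid in consumed:
            continue
        seq = pool[rid].sequence
        if len(seq) > len(contig_str) or len(seq) < k:
            continue
        for first_word in _expand_word(seq[:k], limit=1):
            placed = False
            for pos in word_pos.get(first_word, []):
                if pos + len(seq) <= len(contig_str) and _wildcard_eq(contig_str[pos : pos + len(seq)], seq):
                    members.append((rid, pos))
                    used.add(rid)
                    absorb_overlap(pos, seq, 0, len(seq))
                    placed = True
                    break
            if placed:
                break

    flags: list[str] = []
    if "N" in contig:
        # resolve leftover Ns from the member read that carried them
        for rid, off in members:
            r = pool[rid]
            npos = r.sequence.find("N")
            if npos >= 0 and contig[off + npos] == "N":
                contig[off + npos] = r.n_replacement or "A"
        if any(c == "N" for c in contig):  # pragma: no cover - defensive
            contig = [c if c != "N" else "A" for c in contig]
        flags.append("n_resolved_random")

    members.sort(key=lambda m: (m[1], m[0]))
    return Contig(
        contig_id=contig_id,
        sequence="".join(contig),
        seed_read_id=seed.read_id,
        seed_class=seed_class,
        members=members,
        left_extensions=n_left,
        right_extensions=n_right,
        flags=flags,
    )


def assemble_sample(reads: list[ScoredRead], params: AssemblyParams | None = None) -> list[Contig]:
    """Assemble all contigs for one sample in deterministic seed order."""
    params = params or AssemblyParams()
    pool = {r.read_id: r for r in reads}
    if len(pool) != len(reads):
        raise ValueError("duplicate read ids")
    index = _ReadIndex(pool, params.k_index)
    consumed: set[str] = set()
    contigs: list[Contig] = []
    for seed, seed_class in select_and_sort_seeds(reads, params.seed_threshold):
        if seed.read_id in consumed:
            continue
        contig = extend_seed(
            seed, seed_class, pool, params, index, consumed, f"contig_{len(contigs):04d}"
        )
        consumed.update(contig.member_read_ids)
        contigs.append(contig)
    return contigs


# ---------------------------------------------------------------------------
# Interop with the score table / FASTA output
# ---------------------------------------------------------------------------


def scored_reads_from_table(
    score_table: pd.DataFrame, sequences: dict[str, str], n_replacements: dict[str, str] | None = None
) -> list[ScoredRead]:
    """Join the scoring TSV with stored read sequences, dropping excluded reads."""
    n_replacements = n_replacements or {}
    out = []
    for row in score_table.itertuples(index=False):
        if bool(row.excluded):
            continue
        out.append(
            ScoredRead(
                row.read_id,
                sequences[row.read_id],
                float(row.p_bacterial),
                float(row.p_viral),
                n_replacements.get(row.read_id),
            )
        )
    return out


def contigs_to_fasta(contigs: list[Contig]) -> str:
    lines = []
    for c in contigs:
        flags = ",".join(c.flags) or "-"
        lines.append(f">{c.contig_id} {c.seed_class} {len(c.members)} {flags}")
        for i in range(0, len(c.sequence), 80):
            lines.append(c.sequence[i : i + 80])
    return "\n".join(lines) + ("\n" if lines else "")


def membership_table(contigs: list[Contig]) -> pd.DataFrame:
    rows = [
        (c.contig_id, rid, off, "+")
        for c in contigs
        for rid, off in c.members
    ]
    return pd.DataFrame(rows, columns=["contig_id", "read_id", "offset", "strand"])
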