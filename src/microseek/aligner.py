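"""Built-in ungapped seed-and-extend local aligner with E-value statistics.

Nucleotide search: exact word seeds (default word size 11), ungapped
extension with match +2 / mismatch -3 and an X-drop cutoff, both strands.
Translated search: all six reading frames, 3-mer seeds, BLOSUM62.

Significance follows Karlin-Altschul statistics for ungapped local
alignment, E = K * m * n * exp(-lambda * S) with m the query length and n
the total database length.  The nucleotide lambda is solved numerically
from the scoring scheme under uniform base composition; the BLOSUM62
constants are the standard published ungapped values.  E-values are monotone
decreasing in the raw score for a fixed search, which is the property the
ranking relies on; absolute parity with gapped BLAST statistics is not a
goal (an external BLAST+ backend is available where that matters).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.optimize import brentq

NT_MATCH = 2
NT_MISMATCH = -3
NT_WORD = 11
AA_WORD = 3
XDROP = 20
K_NT = 0.1  # order-of-magnitude ungapped K for simple match/mismatch scoring
LAMBDA_AA = 0.3176  # standard ungapped BLOSUM62 constants
K_AA = 0.134


@lru_cache(maxsize=None)
def nucleotide_lambda(match: int = NT_MATCH, mismatch: int = NT_MISMATCH) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base frequencies."""

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


@dataclass
class HSP:
    """One ungapped high-scoring segment pair."""

    record_index: int
    score: int
    q_start: int
    q_end: int  # exclusive
    s_start: int
    identity: float
    strand: int = 1  # +1 / -1 (nucleotide); reading frame sign for translated
    frame: int = 0  # +-1..3 for translated hits


def _extend(query: str, subject: str, qpos: int, spos: int, word: int, score_fn) -> tuple[int, int, int, int]:
    """X-drop ungapped extension around a seed word.

    Returns (score, q_start, q_end, matches).
    """
    score = sum(score_fn(query[qpos + i], subject[spos + i]) for i in range(word))
    matches = sum(query[qpos + i] == subject[spos + i] for i in range(word))
    # extend right
    best, run_score, run_matches = score, score, matches
    q_end = qpos + word
    i, j = qpos + word, spos + word
    cur, cur_m = score, matches
    while i < len(query) and j < len(subject):
        cur += score_fn(query[i], subject[j])
        cur_m += query[i] == subject[j]
        if cur > run_score:
            run_score, run_matches, q_end = cur, cur_m, i + 1
        if cur < run_score - XDROP:
            break
        i += 1
        j += 1
    # extend left
    best_score, best_matches = run_score, run_matches
    q_start = qpos
    i, j = qpos - 1, spos - 1
    cur, cur_m = run_score, run_matches
    while i >= 0 and j >= 0:
        cur += score_fn(query[i], subject[j])
        cur_m += query[i] == subject[j]
        if cur > best_score:
            best_score, best_matches, q_start = cur, cur_m, i
        if cur < best_score - XDROP:
            break
        i -= 1
        j -= 1
    return best_score, q_start, q_end, best_matches


class _WordIndex:
    def __init__(self, sequences: list[str], word: int):
        self.word = word
        self.table: dict[str, list[tuple[int, int]]] = {}
        for idx, seq in enumerate(sequences):
            for pos in range(len(seq) - word + 1):
                self.table.setdefault(seq[pos : pos + word], []).append((idx, pos))


def _nt_score(a: str, b: str) -> int:
    return NT_MATCH if a == b else NT_MISMATCH


_BLOSUM = substitution_matrices.load("BLOSUM62")


def _aa_score(a: str, b: str) -> int:
    try:
        return int(_BLOSUM[a, b])
    except (KeyError, IndexError):
        return -4


def _search_one(
    query: str, sequences: list[str], index: _WordIndex, score_fn, min_score: int = 0
) -> dict[int, HSP]:
    """Best HSP per database record for one query string."""
    word = index.word
    best: dict[int, HSP] = {}
    covered: dict[tuple[int, int], int] = {}  # (record, diagonal) -> q_end reached
    for qpos in range(len(query) - word + 1):
        hits = index.table.get(query[qpos : qpos + word])
        if not hits:
            continue
        for rec, spos in hits:
            diag = spos - qpos
            if covered.get((rec, diag), -1) >= qpos:
                continue
            score, q_start, q_end, matches = _extend(query, sequences[rec], qpos, spos, word, score_fn)
            covered[(rec, diag)] = q_end
            if score < min_score:
                continue
            length = q_end - q_start
            hsp = HSP(rec, score, q_start, q_end, spos - (qpos - q_start), matches / length)
            if rec not in best or score > best[rec].score:
                best[rec] = hsp
    return best


# ---------------------------------------------------------------------------
# Public alignment entry points
# ---------------------------------------------------------------------------


def evalue_nt(score: int, query_len: int, db_len: int) -> float:
    return float(K_NT * query_len * db_len * np.exp(-nucleotide_lambda() * score))


def evalue_aa(score: int, query_len: int, db_len: int) -> float:
    return float(K_AA * query_len * db_len * np.exp(-LAMBDA_AA * score))


def bit_score_nt(score: int) -> float:
    return float((nucleotide_lambda() * score - np.log(K_NT)) / np.log(2.0))


def bit_score_aa(score: int) -> float:
    return float((LAMBDA_AA * score - np.log(K_AA)) / np.log(2.0))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def nucleotide_hsps(query: str, sequences: list[str], index: _WordIndex) -> dict[int, HSP]:
    """Best nucleotide HSP per record, searching both strands."""
    best = _search_one(query, sequences, index, _nt_score)
    for rec, hsp in _search_one(revcomp(query), sequences, index, _nt_score).items():
        hsp.strand = -1
        if rec not in best or hsp.score > best[rec].score:
            best[rec] = hsp
    return best


def six_frame_translations(seq: str) -> list[tuple[int, str]]:
    """(frame, protein) for frames +1,+2,+3,-1,-2,-3; trailing partial codon dropped."""
    out = []
    rc = revcomp(seq)
    for frame_base, s in ((1, seq), (-1, rc)):
        for off in range(3):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            if len(sub) >= 3:
                out.append((frame_base * (off + 1), str(Seq(sub).translate())))
    return out


def translated_hsps(query_nt: str, sequences: list[str], index: _WordIndex) -> dict[int, HSP]:
    """Best translated HSP per protein record over all six frames."""
    best: dict[int, HSP] = {}
    for frame, prot in six_frame_translations(query_nt):
        for rec, hsp in _search_one(prot, sequences, index, _aa_score).items():
            hsp.frame = frame
            if rec not in best or hsp.score > best[rec].score:
                best[rec] = hsp
    return best


def build_index(sequences: list[str], word: int) -> _WordIndex:
    return _WordIndex(sequences, word)
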