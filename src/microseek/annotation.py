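"""Contig annotation: taxonomic assignment and protein-family mapping.

Each contig gets at most one nucleotide hit (top hit under e-value < 0.01;
ties break by bit score, then accession) carrying species/genus/kind, and
at most one translated six-frame hit (e-value < 1e-5) carrying a protein
family.  Known contaminant genera can be screened out, and per-sample hits
are pooled to the genus level for cohort statistics.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import aligner
from .assembly import Contig


@dataclass(frozen=True)
class NucleotideRecord:
    accession: str
    sequence: str
    species: str
    genus: str
    kind: str = "bacterial"  # bacterial | viral_reference | viral_novel


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str  # amino acids
    family: str


@dataclass
class AnnotationHit:
    contig_id: str
    accession: str
    e_value: float
    bit_score: float
    identity: float
    species: str = ""
    genus: str = ""
    kind: str = ""
    family: str = ""
    frame: int = 0


class NucleotideDB:
    def __init__(self, records: list[NucleotideRecord], word_size: int = aligner.NT_WORD):
        accs = [r.accession for r in records]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in nucleotide DB")
        for r in records:
            if r.kind == "bacterial" and not r.genus:
                raise ValueError(f"bacterial record {r.accession} lacks a genus")
        self.records = list(records)
        self.total_length = sum(len(r.sequence) for r in records)
        self.index = aligner.build_index([r.sequence for r in records], word_size)

    @classmethod
    def from_fasta(cls, text: str) -> "NucleotideDB":
        return cls(_parse_db_fasta(text, NucleotideRecord, 4))


class ProteinDB:
    def __init__(self, records: list[ProteinRecord], word_size: int = aligner.AA_WORD):
        accs = [r.accession for r in records]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in protein DB")
        self.records = list(records)
        self.total_length = sum(len(r.sequence) for r in records)
        self.index = aligner.build_index([r.sequence for r in records], word_size)

    @classmethod
    def from_fasta(cls, text: str) -> "ProteinDB":
        return cls(_parse_db_fasta(text, ProteinRecord, 3))


def _parse_db_fasta(text: str, record_cls, n_fields: int):
    records = []
    header, chunks = None, []
    def flush():
        if header is None:
            return
        fields = (header.split("|") + [""] * n_fields)[:n_fields]
        seq = "".join(chunks)
        if record_cls is NucleotideRecord:
            records.append(NucleotideRecord(fields[0], seq, fields[1], fields[2], fields[3] or "bacterial"))
        else:
            records.append(ProteinRecord(fields[0], seq, fields[1]))
    for line in text.splitlines():
        if line.startswith(">"):
            flush()
            header, chunks = line[1:].strip(), []
        elif line.strip():
            chunks.append(line.strip())
    flush()
    return records


def _as_pairs(contigs) -> list[tuple[str, str]]:
    out = []
    for c in contigs:
        if isinstance(c, Contig):
            out.append((c.contig_id, c.sequence))
        else:
            out.append((c[0], c[1]))
    return out


def nucleotide_search(contigs, db: NucleotideDB, e_max: float = 0.01) -> list[AnnotationHit]:
    """Top nucleotide hit per contig under the e-value cutoff."""
    hits: list[AnnotationHit] = []
    for cid, seq in _as_pairs(contigs):
        if "N" in seq:
            raise ValueError(f"contig {cid} contains N; contigs must be N-free")
        candidates = []
        for rec_idx, hsp in aligner.nucleotide_hsps(seq, [r.sequence for r in db.records], db.index).items():
            e = aligner.evalue_nt(hsp.score, len(seq), db.total_length)
            if e < e_max:
                rec = db.records[rec_idx]
                candidates.append(
                    (e, -aligner.bit_score_nt(hsp.score), rec.accession, hsp, rec)
                )
        if candidates:
            e, neg_bit, acc, hsp, rec = min(candidates)
            hits.append(
                AnnotationHit(cid, acc, e, -neg_bit, hsp.identity, rec.species, rec.genus, rec.kind)
            )
    return hits


def translated_search(contigs, db: ProteinDB, e_max: float = 1e-5) -> list[AnnotationHit]:
    """Top protein-family hit per contig over all six reading frames."""
    hits: list[AnnotationHit] = []
    for cid, seq in _as_pairs(contigs):
        if "N" in seq:
            raise ValueError(f"contig {cid} contains N; contigs must be N-free")
        if len(seq) < 3 * aligner.AA_WORD:
            continue
        candidates = []
        for rec_idx, hsp in aligner.translated_hsps(seq, [r.sequence for r in db.records], db.index).items():
            e = aligner.evalue_aa(hsp.score, len(seq) // 3, db.total_length)
            if e < e_max:
                rec = db.records[rec_idx]
                candidates.append((e, -aligner.bit_score_aa(hsp.score), rec.accession, hsp, rec))
        if candidates:
            e, neg_bit, acc, hsp, rec = min(candidates)
            hits.append(
                AnnotationHit(cid, acc, e, -neg_bit, hsp.identity, family=rec.family, frame=hsp.frame)
            )
    return hits


def screen_contaminants(
    hits: list[AnnotationHit], contaminant_genera: set[str] | list[str]
) -> tuple[list[AnnotationHit], list[AnnotationHit]]:
    """Split hits into (kept, removed-as-contaminant) by assigned genus."""
    contaminants = set(contaminant_genera)
    kept = [h for h in hits if h.genus not in contaminants or not h.genus]
    removed = [h for h in hits if h.genus and h.genus in contaminants]
    return kept, removed


def pool_to_genus(hits: list[AnnotationHit]) -> set[str]:
    """Distinct genera with at least one assigned contig in the sample."""
    return {h.genus for h in hits if h.genus}


def pool_to_family(hits: list[AnnotationHit]) -> set[str]:
    return {h.family for h in hits if h.family}


def hits_to_table(hits: list[AnnotationHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.contig_id, h.accession, h.e_value, h.bit_score, h.identity,
             h.species, h.genus, h.kind, h.family, h.frame)
            for h in hits
        ],
        columns=["contig_id", "accession", "e_value", "bit_score", "identity",
                 "species", "genus", "kind", "family", "frame"],
    )


# ---------------------------------------------------------------------------
# Optional external BLAST+ backend (config-selected; used as cross-check)
# ---------------------------------------------------------------------------


def blast_nucleotide_search(contigs, db: NucleotideDB, e_max: float = 0.01) -> list[AnnotationHit]:
    """Same contract as nucleotide_search, delegated to blastn.

    Requires the BLAST+ executables on PATH.  Top hit per contig by
    (e-value, bit score, accession).
    """
    pairs = _as_pairs(contigs)
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db_fa = tmp / "db.fasta"
        db_fa.write_text("".join(f">{r.accession}\n{r.sequence}\n" for r in db.records))
        q_fa = tmp / "q.fasta"
        q_fa.write_text("".join(f">{cid}\n{seq}\n" for cid, seq in pairs))
        subprocess.run(
            ["makeblastdb", "-in", str(db_fa), "-dbtype", "nucl"],
            check=True, capture_output=True,
        )
        res = subprocess.run(
            ["blastn", "-query", str(q_fa), "-db", str(db_fa), "-evalue", str(e_max),
             "-dust", "no",  # no masking: the built-in aligner does none
             "-outfmt", "6 qseqid sseqid evalue bitscore pident"],
            check=True, capture_output=True, text=True,
        )
    by_acc = {r.accession: r for r in db.records}
    best: dict[str, tuple] = {}
    for line in res.stdout.splitlines():
        cid, acc, e, bit, pid = line.split("\t")
        key = (float(e), -float(bit), acc)
        if cid not in best or key < best[cid][0]:
            best[cid] = (key, acc, float(e), float(bit), float(pid) / 100.0)
    hits = []
    for cid, _ in pairs:
        if cid in best:
            _, acc, e, bit, pid = best[cid]
            rec = by_acc[acc]
            hits.append(AnnotationHit(cid, acc, e, bit, pid, rec.species, rec.genus, rec.kind))
    return hits
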