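"""Sequence-comparison primitives: local protein alignment, E-values,
six-frame translation, and BLAST tabular I/O.

The desk-scale aligner is an exact Smith-Waterman under affine gaps
(BLOSUM62, gap open 11 / extend 1, the classic protein-search defaults),
with significance estimated by the ungapped Karlin-Altschul formula
E = K*m*n*exp(-lambda*S).  These are approximations to a heuristic gapped
search; downstream only the "E below threshold" semantics matter.  An
adapter for 12-column BLAST tabular output lets an external search engine
substitute for the built-in aligner.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .errors import ParseError

PROTEIN = "protein"
NUCLEOTIDE = "nucleotide"

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
# Ungapped Karlin-Altschul constants for BLOSUM62.
DEFAULT_K = 0.041
DEFAULT_LAMBDA = 0.267
DEFAULT_EVALUE_MAX = 1e-10

_NUC_ALPHABET = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence with a declared alphabet."""

    id: str
    sequence: str
    alphabet: str = PROTEIN

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.alphabet not in (PROTEIN, NUCLEOTIDE):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if self.alphabet == NUCLEOTIDE:
            bad = set(self.sequence.upper()) - _NUC_ALPHABET
            if bad:
                raise ValueError(f"record {self.id!r}: non-nucleotide residues {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment, mirroring the fields of BLAST tabular output.

    Spans are 1-based inclusive; ``frame`` is 0 for protein queries and in
    {-3..-1, 1..3} for translated nucleotide queries.  ``raw_score`` is None
    for hits parsed from external tabular output (bit score authoritative).
    """

    query_id: str
    subject_id: str
    bit_score: float
    e_value: float | None = None
    raw_score: int | None = None
    percent_identity: float = 0.0
    query_span: tuple[int, int] = (0, 0)
    subject_span: tuple[int, int] = (0, 0)
    frame: int = 0


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # BLAST convention: a gap of length L costs open + L*extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@lru_cache(maxsize=8)
def _matrix_alphabet(matrix_name: str) -> frozenset:
    return frozenset(substitution_matrices.load(matrix_name).alphabet)


def _sanitize(seq: str, matrix_name: str) -> str:
    """Uppercase and map residues outside the scoring alphabet to X."""
    alphabet = _matrix_alphabet(matrix_name)
    up = seq.upper()
    if all(c in alphabet for c in up):
        return up
    return "".join(c if c in alphabet else "X" for c in up)


def bit_score(raw_score: float, K: float = DEFAULT_K,
              lam: float = DEFAULT_LAMBDA) -> float:
    """Normalized (bit) score S' = (lambda*S - ln K) / ln 2."""
    return (lam * raw_score - math.log(K)) / math.log(2)


def evalue(raw_score: float, query_length: int, database_residues: int,
           K: float = DEFAULT_K, lam: float = DEFAULT_LAMBDA) -> float:
    """Karlin-Altschul expected hit count E = K*m*n*exp(-lambda*S)."""
    if query_length <= 0 or database_residues <= 0:
        raise ValueError("query length and database size must be positive")
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    return K * query_length * database_residues * math.exp(-lam * raw_score)


def smith_waterman(
    query: SequenceRecord,
    subject: SequenceRecord,
    matrix_name: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    score_only: bool = False,
) -> AlignmentHit:
    """Optimal local alignment of two protein records under affine gaps.

    Returns a hit with the raw score, bit score, percent identity over
    aligned columns (gap columns included) and 1-based spans.  A pair with
    no positive-scoring cell yields score 0 and empty (0, 0) spans.  With
    ``score_only`` the traceback is skipped (identity and spans left zero),
    which is much faster when only scores are ranked.
    """
    if query.alphabet != PROTEIN or subject.alphabet != PROTEIN:
        raise ValueError("smith_waterman requires protein records")
    q = _sanitize(query.sequence, matrix_name)
    s = _sanitize(subject.sequence, matrix_name)
    aligner = _aligner(matrix_name, gap_open, gap_extend)
    raw = int(round(aligner.score(q, s)))
    if raw <= 0:
        return AlignmentHit(query.id, subject.id, bit_score=bit_score(0),
                            raw_score=0, frame=0)
    hit = AlignmentHit(
        query_id=query.id, subject_id=subject.id,
        bit_score=bit_score(raw), raw_score=raw, frame=0,
    )
    if score_only:
        return hit
    best = aligner.align(q, s)[0]
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    pident = 100.0 * counts.identities / columns if columns else 0.0
    qblocks, sblocks = best.aligned
    return replace(
        hit,
        percent_identity=pident,
        query_span=(int(qblocks[0][0]) + 1, int(qblocks[-1][1])),
        subject_span=(int(sblocks[0][0]) + 1, int(sblocks[-1][1])),
    )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def six_frame_translate(record: SequenceRecord) -> list[SequenceRecord]:
    """Translate a nucleotide record in all six frames (standard code).

    Frames +1..+3 read the forward strand, -1..-3 the reverse complement;
    stop codons are emitted as '*' (the search is local, so stops simply
    score negatively rather than splitting the frame).
    """
    if record.alphabet != NUCLEOTIDE:
        raise ValueError("six_frame_translate requires a nucleotide record")
    seq = record.sequence.upper().replace("U", "T")
    frames: list[SequenceRecord] = []
    for strand, s in ((1, seq), (-1, reverse_complement(seq))):
        for off in range(3):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            prot = str(Seq(sub).translate(table=1)) if sub else ""
            frame = strand * (off + 1)
            if prot:
                frames.append(SequenceRecord(
                    id=f"{record.id}|frame{frame:+d}",
                    sequence=prot, alphabet=PROTEIN))
    return frames


def frame_of(translated_id: str) -> int:
    """Recover the frame number from an id produced by six_frame_translate."""
    return int(translated_id.rsplit("|frame", 1)[1])


_BLAST6_COLUMNS = 12


def parse_blast_tab(stream: TextIO | str) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular (outfmt-6) rows into hits."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    hits: list[AlignmentHit] = []
    for i, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != _BLAST6_COLUMNS:
            raise ParseError(
                f"expected {_BLAST6_COLUMNS} tab-separated columns, got {len(fields)}",
                line=i)
        try:
            hits.append(AlignmentHit(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                query_span=(int(fields[6]), int(fields[7])),
                subject_span=(int(fields[8]), int(fields[9])),
                e_value=float(fields[10]),
                bit_score=float(fields[11]),
            ))
        except ValueError as exc:
            raise ParseError(f"bad numeric field: {exc}", line=i) from None
    return hits


def write_blast_tab(hits: Iterable[AlignmentHit], stream: TextIO) -> None:
    """Write hits as 12-column BLAST tabular rows (mismatch/gapopen emitted as 0)."""
    for h in hits:
        stream.write("\t".join(map(str, [
            h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
            max(h.query_span[1] - h.query_span[0] + 1, 0), 0, 0,
            h.query_span[0], h.query_span[1],
            h.subject_span[0], h.subject_span[1],
            f"{h.e_value if h.e_value is not None else 0:.3g}",
            f"{h.bit_score:.1f}",
        ])) + "\n")


def best_hits(hits: Iterable[AlignmentHit]) -> list[AlignmentHit]:
    """Keep, per query id, the single best hit.

    Best = maximal bit score; ties broken by lower E-value (None sorts
    last), then ascending subject id.  Output ordered by query id.
    """
    by_query: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = by_query.get(h.query_id)
        if cur is None or _hit_order(h) < _hit_order(cur):
            by_query[h.query_id] = h
    return [by_query[q] for q in sorted(by_query)]


def _hit_order(h: AlignmentHit) -> tuple:
    ev = h.e_value if h.e_value is not None else math.inf
    return (-h.bit_score, ev, h.subject_id)


def search(
    queries: list[SequenceRecord],
    subjects: list[SequenceRecord],
    mode: str = "blastp",
    evalue_max: float | None = None,
) -> list[AlignmentHit]:
    """All-vs-all local search in one of three translated modes.

    blastp: protein vs protein; blastx: nucleotide queries translated in six
    frames vs protein subjects; tblastn: protein queries vs six-frame
    translations of nucleotide subjects.  E-values use the total subject
    residue count as the search-space size; hits above ``evalue_max`` are
    dropped when a threshold is given.
    """
    if mode == "blastp":
        qs = [(q, 0) for q in queries]
        subs = subjects
    elif mode == "blastx":
        qs = [(fr, frame_of(fr.id)) for q in queries
              for fr in six_frame_translate(q)]
        subs = subjects
    elif mode == "tblastn":
        qs = [(q, 0) for q in queries]
        subs = [fr for s in subjects for fr in six_frame_translate(s)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    db_residues = sum(len(s) for s in subs)
    hits = []
    for q, frame in qs:
        for s in subs:
            hit = smith_waterman(q, s)
            if hit.raw_score <= 0:
                continue
            ev = evalue(hit.raw_score, len(q), db_residues)
            if evalue_max is not None and ev >= evalue_max:
                continue
            qid = q.id.rsplit("|frame", 1)[0] if frame else q.id
            hits.append(replace(hit, query_id=qid, e_value=ev, frame=frame))
    hits.sort(key=lambda h: (h.query_id, _hit_order(h)))
    return hits


def read_fasta(path, alphabet: str = PROTEIN) -> list[SequenceRecord]:
    return [SequenceRecord(id=r.id, sequence=str(r.seq), alphabet=alphabet)
            for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")
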