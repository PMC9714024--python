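"""Sequence-side I/O and computation.

FASTA reading/writing (via Biopython), parsing of the 12-column tabular hit
format shared by BLAST ``-outfmt 6`` and MMseqs2 (the "m8" dialect), a
Smith-Waterman local aligner with affine gaps (Gotoh three-matrix
recurrence, numba-accelerated), and Karlin-Altschul statistics to turn raw
alignment scores into bit scores and E-values.

The aligner uses BLOSUM62 with gap open 11 / extend 1 and fixed gapped
Karlin-Altschul constants (lambda = 0.267, K = 0.041), the standard
protein-search parameterization.  A gap of length g costs
``gap_open + (g - 1) * gap_extend``: the first gapped residue pays the open
penalty, so setting gap_open = gap_extend recovers plain linear gap costs.
External search results (e.g. real MMseqs2 output) remain first-class input
through the m8 reader, so this aligner is needed only for re-scoring
embedding hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from numba import njit

from .hits import Hit, HitList, as_dict

GAP_OPEN_DEFAULT = 11
GAP_EXTEND_DEFAULT = 1
LAMBDA_DEFAULT = 0.267
K_DEFAULT = 0.041
EVALUE_CUTOFF_DEFAULT = 10_000.0

_NEG_INF = np.int32(-(10**9) // 2)


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TabularHit:
    """One line of the 12-column m8 dialect; coordinates 1-based inclusive."""

    query_id: str
    target_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    evalue: float
    bit_score: float


@dataclass
class AlignmentResult:
    """Optimal local alignment under affine gaps.

    Intervals are 1-based inclusive; an empty alignment (raw_score 0) has
    zeroed intervals.  ``identity`` is identical aligned pairs over aligned
    (non-gap) pairs.  bit_score/evalue are filled when Karlin-Altschul
    statistics are applied.
    """

    raw_score: int
    q_start: int = 0
    q_end: int = 0
    t_start: int = 0
    t_end: int = 0
    identity: float = 0.0
    bit_score: float | None = None
    evalue: float | None = None


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; the ID is the first whitespace-delimited header token."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence ID {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def sequence_db(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    db = {}
    for r in records:
        if r.id in db:
            raise ValueError(f"duplicate sequence ID {r.id!r}")
        db[r.id] = r
    return db


# ---------------------------------------------------------------------------
# m8 tabular hits


def parse_m8(path: str | Path) -> list[TabularHit]:
    """Parse 12-column tab-separated hits in file order."""
    hits = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, found {len(parts)}"
                )
            try:
                hit = TabularHit(
                    query_id=parts[0],
                    target_id=parts[1],
                    percent_identity=float(parts[2]),
                    alignment_length=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    t_start=int(parts[8]),
                    t_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bit_score=float(parts[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if hit.q_start > hit.q_end or hit.t_start > hit.t_end:
                raise ValueError(f"{path}:{lineno}: reversed coordinates")
            if hit.evalue < 0:
                raise ValueError(f"{path}:{lineno}: negative E-value")
            hits.append(hit)
    return hits


def write_m8(hits: Iterable[TabularHit], path: str | Path) -> None:
    """Write m8 lines; E-values in scientific notation, 3 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.percent_identity:.1f}\t"
                f"{h.alignment_length}\t{h.mismatches}\t{h.gap_opens}\t"
                f"{h.q_start}\t{h.q_end}\t{h.t_start}\t{h.t_end}\t"
                f"{h.evalue:.2e}\t{h.bit_score:.1f}\n"
            )


def hitlists_from_m8(
    hits: Iterable[TabularHit], log_base: float = 10.0, evalue_floor: float = 1e-300
) -> dict[str, HitList]:
    """Group tabular hits per query, scored as -log(E) ("higher is better")."""
    per_query: dict[str, dict[str, Hit]] = {}
    for h in hits:
        e = max(h.evalue, evalue_floor)
        score = -math.log(e) / math.log(log_base)
        bucket = per_query.setdefault(h.query_id, {})
        # keep the best entry per (query, target) pair
        if h.target_id not in bucket or bucket[h.target_id].score < score:
            bucket[h.target_id] = Hit(h.target_id, score, "neg_log_evalue")
    return {q: HitList(q, list(b.values())) for q, b in per_query.items()}


# ---------------------------------------------------------------------------
# Smith-Waterman (Gotoh affine gaps)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)
_CHAR_TO_CODE = {aa: i for i, aa in enumerate(_ALPHABET)}
_X_CODE = _CHAR_TO_CODE["X"]
_SUBMAT = np.array(_BLOSUM62, dtype=np.int32)


def _encode(sequence: str) -> np.ndarray:
    return np.array(
        [_CHAR_TO_CODE.get(aa, _X_CODE) for aa in sequence.upper()], dtype=np.int32
    )


@njit(cache=True)
def _gotoh_kernel(q, t, sub, gap_open, gap_extend):
    """Fill H/E/F and pointer matrices; return best score and end cell.

    Pointer codes for H: 0 stop (score 0), 1 diagonal, 2 from E (gap in
    query), 3 from F (gap in target).  E/F pointers: 1 opened from H, 0
    extended.  Best cell ties resolve to the first in row-major order.
    """
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), _NEG_INF, np.int32)
    F = np.full((m + 1, n + 1), _NEG_INF, np.int32)
    ph = np.zeros((m + 1, n + 1), np.uint8)
    pe = np.zeros((m + 1, n + 1), np.uint8)
    pf = np.zeros((m + 1, n + 1), np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                pe[i, j] = 1
            else:
                E[i, j] = e_ext
                pe[i, j] = 0
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                pf[i, j] = 1
            else:
                F[i, j] = f_ext
                pf[i, j] = 0
            diag = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            h = np.int32(0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = np.uint8(1)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(2)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(3)
            H[i, j] = h
            ph[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ph, pe, pf


@njit(cache=True)
def _score_kernel(q, t, sub, gap_open, gap_extend):
    """Score-only Gotoh with O(n) memory, for bulk re-scoring of hit lists."""
    m = q.shape[0]
    n = t.shape[0]
    Hrow = np.zeros(n + 1, np.int32)
    Erow = np.full(n + 1, _NEG_INF, np.int32)
    best = np.int32(0)
    Fcol = np.full(n + 1, _NEG_INF, np.int32)
    for i in range(1, m + 1):
        h_diag = Hrow[0]  # H[i-1, j-1]
        Hrow[0] = 0
        for j in range(1, n + 1):
            e = max(Hrow[j - 1] - gap_open, Erow[j - 1] - gap_extend)
            f = max(Hrow[j] - gap_open, Fcol[j] - gap_extend)
            diag = h_diag + sub[q[i - 1], t[j - 1]]
            h = np.int32(0)
            if diag > h:
                h = diag
            if e > h:
                h = e
            if f > h:
                h = f
            h_diag = Hrow[j]
            Hrow[j] = h
            Erow[j] = e
            Fcol[j] = f
            if h > best:
                best = h
    return best


def smith_waterman(
    query: SequenceRecord | str,
    target: SequenceRecord | str,
    substitution: np.ndarray | None = None,
    gap_open: int = GAP_OPEN_DEFAULT,
    gap_extend: int = GAP_EXTEND_DEFAULT,
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences with affine gaps."""
    qseq = query.sequence if isinstance(query, SequenceRecord) else query
    tseq = target.sequence if isinstance(target, SequenceRecord) else target
    if not qseq or not tseq:
        raise ValueError("sequences must be non-empty")
    sub = _SUBMAT if substitution is None else np.asarray(substitution, dtype=np.int32)
    qa = _encode(qseq)
    ta = _encode(tseq)
    score, bi, bj, ph, pe, pf = _gotoh_kernel(
        qa, ta, sub, np.int32(gap_open), np.int32(gap_extend)
    )
    if score <= 0:
        return AlignmentResult(raw_score=0)
    # traceback: state machine over H/E/F
    i, j = bi, bj
    state = "H"
    matches = 0
    pairs = 0
    while True:
        if state == "H":
            p = ph[i, j]
            if p == 0:
                break
            if p == 1:
                pairs += 1
                if qseq[i - 1].upper() == tseq[j - 1].upper():
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":  # gap in query: consume target residue
            opened = pe[i, j] == 1
            j -= 1
            if opened:
                state = "H"
        else:  # F: gap in target: consume query residue
            opened = pf[i, j] == 1
            i -= 1
            if opened:
                state = "H"
    return AlignmentResult(
        raw_score=int(score),
        q_start=i + 1,
        q_end=bi,
        t_start=j + 1,
        t_end=bj,
        identity=matches / pairs if pairs else 0.0,
    )


def sw_score(
    query: str,
    target: str,
    substitution: np.ndarray | None = None,
    gap_open: int = GAP_OPEN_DEFAULT,
    gap_extend: int = GAP_EXTEND_DEFAULT,
) -> int:
    """Raw Smith-Waterman score only (linear memory; no traceback)."""
    sub = _SUBMAT if substitution is None else np.asarray(substitution, dtype=np.int32)
    return int(
        _score_kernel(
            _encode(query), _encode(target), sub, np.int32(gap_open), np.int32(gap_extend)
        )
    )


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics


def evalue_karlin_altschul(
    raw_score: int,
    query_len: int,
    db_residues: int,
    lambda_: float = LAMBDA_DEFAULT,
    K: float = K_DEFAULT,
) -> tuple[float, float]:
    """Bit score and E-value for a raw local-alignment score.

    bit = (lambda * S - ln K) / ln 2; E = m * n * 2**(-bit), with m the query
    length and n the total residues in the searched database.
    """
    if lambda_ <= 0 or K <= 0:
        raise ValueError("lambda and K must be positive")
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    if query_len < 1 or db_residues < 1:
        raise ValueError("lengths must be >= 1")
    bit = (lambda_ * raw_score - math.log(K)) / math.log(2.0)
    evalue = float(query_len) * float(db_residues) * math.pow(2.0, -bit)
    return bit, evalue


# ---------------------------------------------------------------------------
# re-scoring embedding hit lists by alignment


def align_hitlist(
    knn_hits: Iterable[HitList] | Mapping[str, HitList],
    sequences: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    evalue_cutoff: float = EVALUE_CUTOFF_DEFAULT,
    gap_open: int = GAP_OPEN_DEFAULT,
    gap_extend: int = GAP_EXTEND_DEFAULT,
    lambda_: float = LAMBDA_DEFAULT,
    K: float = K_DEFAULT,
    log_base: float = 10.0,
) -> tuple[dict[str, HitList], int]:
    """Re-score embedding hits by Smith-Waterman E-value.

    Each (query, target) pair is aligned; hits with E-value <= cutoff are
    kept and ranked by ascending E-value (score -log(E)), the rest are
    dropped.  Returns the re-scored lists and the dropped-hit count,
    mirroring the dropped-homolog accounting of sequence-side re-alignment.
    The database size n is the total residue count of the target set.
    """
    if not isinstance(sequences, Mapping):
        sequences = sequence_db(sequences)
    knn_hits = as_dict(knn_hits)
    db_residues = sum(len(r) for r in sequences.values())
    log_b = math.log(log_base)
    out: dict[str, HitList] = {}
    dropped = 0
    for query_id in sorted(knn_hits):
        hl = knn_hits[query_id]
        if query_id not in sequences:
            raise KeyError(f"query sequence missing from database: {query_id!r}")
        qseq = sequences[query_id].sequence
        rescored = []
        for h in hl.hits:
            if h.target_id not in sequences:
                raise KeyError(f"target sequence missing from database: {h.target_id!r}")
            raw = sw_score(
                qseq,
                sequences[h.target_id].sequence,
                gap_open=gap_open,
                gap_extend=gap_extend,
            )
            _, evalue = evalue_karlin_altschul(
                raw, len(qseq), db_residues, lambda_=lambda_, K=K
            )
            if evalue <= evalue_cutoff:
                score = -math.log(max(evalue, 1e-300)) / log_b
                rescored.append(Hit(h.target_id, score, "neg_log_evalue"))
            else:
                dropped += 1
        out[query_id] = HitList(query_id, rescored)
    return out, dropped
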