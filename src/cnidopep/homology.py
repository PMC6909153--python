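"""Deterministic cross-dataset homology search.

A full dynamic-programming Smith-Waterman local aligner with affine
gaps stands in for a heuristic translated-BLAST search: at desk scale
(hundreds of ORFs, precursor-length queries) exhaustive DP is fast
enough and, unlike seeded heuristics, bit-reproducible.  A gap of
length L costs ``gap_open + gap_extend * L``.  No E-value statistics
are computed; hits are reported above a raw-score threshold together
with percent identity.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord, six_frame_translate

NEG_INF = float("-inf")


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load(name)
    out = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            out[(a, b)] = float(mat[a, b])
    return out


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    frame: int | None
    q_aln: str
    s_aln: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: float
    identity: float

    @property
    def length(self) -> int:
        return len(self.q_aln)


def local_align(
    query: SequenceRecord | str,
    subject: SequenceRecord | str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> HomologyHit:
    """Optimal local alignment by affine-gap dynamic programming.

    Traceback ties are broken diagonal > up (gap in subject) > left
    (gap in query); among equal-scoring end cells the first in row-major
    order is used.
    """
    q = query.seq if isinstance(query, SequenceRecord) else query
    s = subject.seq if isinstance(subject, SequenceRecord) else subject
    if not q or not s:
        raise ValueError("local_align requires non-empty sequences")
    sub = load_matrix(matrix)
    n, m = len(q), len(s)
    # M: match/mismatch state; X: gap in subject (consumes query, "up");
    # Y: gap in query ("left").  Pointer codes: 0 = local restart,
    # 1 = came from M, 2 = came from X, 3 = came from Y.
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    open_cost = gap_open + gap_extend
    for i in range(1, n + 1):
        qc = q[i - 1]
        for j in range(1, m + 1):
            a = M[i - 1][j] - open_cost
            b = X[i - 1][j] - gap_extend
            X[i][j], ptr_x[i][j] = (a, 1) if a >= b else (b, 2)
            a = M[i][j - 1] - open_cost
            b = Y[i][j - 1] - gap_extend
            Y[i][j], ptr_y[i][j] = (a, 1) if a >= b else (b, 3)
            sc = sub.get((qc, s[j - 1]), -4.0)
            # diagonal predecessor preference: M > X (up) > Y (left)
            dv, dp = M[i - 1][j - 1], 1
            if X[i - 1][j - 1] > dv:
                dv, dp = X[i - 1][j - 1], 2
            if Y[i - 1][j - 1] > dv:
                dv, dp = Y[i - 1][j - 1], 3
            val = dv + sc
            if val <= 0.0:
                if sc > 0.0:
                    M[i][j], ptr_m[i][j] = max(sc, 0.0), 0
                else:
                    M[i][j], ptr_m[i][j] = 0.0, 0
            else:
                if sc >= val:  # restarting locally scores at least as much
                    M[i][j], ptr_m[i][j] = sc, 0
                else:
                    M[i][j], ptr_m[i][j] = val, dp
    best = 0.0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i][j] > best:
                best, bi, bj = float(M[i][j]), i, j
    qa, sa = [], []
    i, j = bi, bj
    state = "M"
    while i > 0 and j > 0 and not (state == "M" and M[i][j] <= 0):
        if state == "M":
            qa.append(q[i - 1])
            sa.append(s[j - 1])
            p = ptr_m[i][j]
            i, j = i - 1, j - 1
            if p == 0:
                break
            state = {1: "M", 2: "X", 3: "Y"}[p]
        elif state == "X":
            qa.append(q[i - 1])
            sa.append("-")
            p = ptr_x[i][j]
            i -= 1
            state = {1: "M", 2: "X"}[p]
        else:
            qa.append("-")
            sa.append(s[j - 1])
            p = ptr_y[i][j]
            j -= 1
            state = {1: "M", 3: "Y"}[p]
    qa.reverse()
    sa.reverse()
    q_aln, s_aln = "".join(qa), "".join(sa)
    matches = sum(1 for a, b in zip(q_aln, s_aln) if a == b and a != "-")
    identity = matches / len(q_aln) if q_aln else 0.0
    return HomologyHit(
        query_id=getattr(query, "id", "query"),
        subject_id=getattr(subject, "id", "subject"),
        frame=getattr(subject, "frame", None),
        q_aln=q_aln, s_aln=s_aln,
        q_start=i, q_end=bi, s_start=j, s_end=bj,
        score=best, identity=identity,
    )


def search_translated(
    query: SequenceRecord,
    nucleotide_dataset: list[SequenceRecord],
    min_orf_aa: int = 30,
    score_threshold: float = 60.0,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[HomologyHit]:
    """Six-frame translate a nucleotide dataset and align the query to
    every ORF, reporting hits at or above ``score_threshold`` sorted by
    descending score (ties by subject id)."""
    hits: list[HomologyHit] = []
    for rec in nucleotide_dataset:
        for orf in six_frame_translate(rec, min_orf_aa=min_orf_aa):
            hit = local_align(query, orf, matrix=matrix,
                              gap_open=gap_open, gap_extend=gap_extend)
            if hit.score >= score_threshold:
                hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


def to_tabular(hits: list[HomologyHit]) -> list[dict]:
    """blast outfmt-6-style rows (qseqid, sseqid, pident, length, ..., score)."""
    rows = []
    for h in hits:
        rows.append({
            "qseqid": h.query_id, "sseqid": h.subject_id,
            "pident": round(100.0 * h.identity, 2), "length": h.length,
            "qstart": h.q_start, "qend": h.q_end,
            "sstart": h.s_start, "send": h.s_end,
            "score": h.score,
        })
    return rows
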