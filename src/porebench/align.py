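"""Global pairwise alignment and per-column expansion of aligner output.

The benchmark distinguishes two alignment routes. Short validation sequences
are aligned end-to-end with the Needleman-Wunsch algorithm under affine gap
penalties (match +2, mismatch -1, gap open -8, gap extend -4 by default); a
gap of length L costs open + (L-1)*extend, i.e. the first gap base pays the
opening penalty and each further base the extension. Full-length reads are
expected to arrive pre-aligned (SAM/PAF from minimap2) and are expanded here
into explicit per-column event paths over {M, X, I, D}:

    M  match      — read and reference base identical
    X  mismatch   — both bases present, different
    I  insertion  — read base with no reference counterpart
    D  deletion   — reference base with no read counterpart

An aligned column involving N counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .seq_io import RawAlignmentRecord, Read, ReferenceSequence, parse_cigar

__all__ = [
    "ScoringScheme",
    "Alignment",
    "AlignmentError",
    "global_align",
    "accuracy",
    "expand_alignment",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring; penalties are positive magnitudes and subtracted."""

    match_score: int = 2
    mismatch_penalty: int = 1
    gap_open_penalty: int = 8
    gap_extend_penalty: int = 4

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gap_open_penalty, self.gap_extend_penalty) < 0:
            raise ValueError("penalties must be non-negative magnitudes")


DEFAULT_SCORING = ScoringScheme()


@dataclass
class Alignment:
    """An expanded per-column event path between one read and a reference span.

    ``ops`` is the column-wise event string over {M, X, I, D};
    ``query_aligned``/``ref_aligned`` are the gapped sequences ('-' at D
    and I columns respectively). The query is stored in the orientation it
    aligns in: for strand '-' it is the reverse complement of the basecall.
    """

    read_id: str
    ref_id: str
    ops: str
    query_aligned: str
    ref_aligned: str
    ref_start: int = 0
    strand: str = "+"
    score: int | None = None

    def __post_init__(self) -> None:
        if not (len(self.ops) == len(self.query_aligned) == len(self.ref_aligned)):
            raise AlignmentError(
                f"alignment of {self.read_id!r}: ops/query/ref lengths differ"
            )
        for op, qb, rb in zip(self.ops, self.query_aligned, self.ref_aligned):
            ok = (
                (op == "M" and qb == rb and qb != "-")
                or (op == "X" and qb != "-" and rb != "-" and (qb != rb or "N" in (qb, rb)))
                or (op == "I" and qb != "-" and rb == "-")
                or (op == "D" and qb == "-" and rb != "-")
            )
            if not ok:
                raise AlignmentError(
                    f"alignment of {self.read_id!r}: inconsistent column "
                    f"({op}, {qb}, {rb})"
                )

    @property
    def ref_span(self) -> int:
        return len(self.ops) - self.ops.count("I")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span

    @property
    def query_length(self) -> int:
        return len(self.ops) - self.ops.count("D")

    @property
    def query_sequence(self) -> str:
        """The oriented basecall (gaps removed)."""
        return self.query_aligned.replace("-", "")

    def count(self, op: str) -> int:
        return self.ops.count(op)

    def columns(self) -> Iterator[tuple[str, int | None, int | None]]:
        """Yield (op, query_position, reference_position) per column.

        Positions are None where the column has no base on that side;
        reference positions are absolute (offset by ``ref_start``). Query
        positions index the oriented basecall.
        """
        q, r = 0, self.ref_start
        for op in self.ops:
            if op in "MX":
                yield op, q, r
                q += 1
                r += 1
            elif op == "I":
                yield op, q, None
                q += 1
            else:
                yield op, None, r
                r += 1

    def rescore(self, scoring: ScoringScheme = DEFAULT_SCORING) -> int:
        """Score this event path under ``scoring`` (affine gap convention)."""
        score = 0
        prev = ""
        for op in self.ops:
            if op == "M":
                score += scoring.match_score
            elif op == "X":
                score -= scoring.mismatch_penalty
            else:
                if op == prev:
                    score -= scoring.gap_extend_penalty
                else:
                    score -= scoring.gap_open_penalty
            prev = op
        return score


# traceback pointer codes for the three DP states
_DIAG, _DEL, _INS = 0, 1, 2
_NEG_INF = float("-inf")


def global_align(
    query: str,
    reference: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    max_length: int = 100_000,
    read_id: str = "query",
    ref_id: str = "reference",
) -> Alignment:
    """Optimal global (end-to-end) alignment with affine gap penalties.

    Three-state dynamic program (match/mismatch, deletion, insertion); a gap
    of length L costs open + (L-1)*extend. Ties are broken deterministically,
    preferring a diagonal step over a deletion over an insertion, so the
    returned event path is reproducible.

    Intended for short validation sequences; sequences longer than
    ``max_length`` are rejected — use an external aligner (minimap2) and
    :func:`expand_alignment` for full reads.
    """
    if not query or not reference:
        raise AlignmentError("global_align requires non-empty sequences")
    if len(query) > max_length or len(reference) > max_length:
        raise AlignmentError(
            f"sequence longer than {max_length} bases; use external aligner"
        )
    # The DP runs on the reversed pair so that traceback (which walks from
    # the alignment's end) emits columns in the original front-to-back
    # order: ties then resolve in favour of M/X (then D, then I) at the
    # *start* of the alignment, e.g. AA vs AAAA -> MMDD.
    query, reference = query[::-1], reference[::-1]
    n, m = len(query), len(reference)
    mt, pm = scoring.match_score, scoring.mismatch_penalty
    go, ge = scoring.gap_open_penalty, scoring.gap_extend_penalty

    # S[state][i][j]: best score of aligning query[:i] to reference[:j]
    # with the last column in `state`. ptr stores the predecessor state.
    S = [[[_NEG_INF] * (m + 1) for _ in range(n + 1)] for _ in range(3)]
    ptr = [[[0] * (m + 1) for _ in range(n + 1)] for _ in range(3)]
    S[_DIAG][0][0] = 0
    for j in range(1, m + 1):
        S[_DEL][0][j] = -(go + (j - 1) * ge)
        ptr[_DEL][0][j] = _DIAG if j == 1 else _DEL
    for i in range(1, n + 1):
        S[_INS][i][0] = -(go + (i - 1) * ge)
        ptr[_INS][i][0] = _DIAG if i == 1 else _INS

    def best(cands: list[tuple[float, int]]) -> tuple[float, int]:
        # max by score; on ties the earlier candidate wins (priority order)
        top = cands[0]
        for c in cands[1:]:
            if c[0] > top[0]:
                top = c
        return top

    for i in range(1, n + 1):
        qi = query[i - 1]
        row_d, row_x, row_y = S[_DIAG][i], S[_DEL][i], S[_INS][i]
        prev_d, prev_x, prev_y = S[_DIAG][i - 1], S[_DEL][i - 1], S[_INS][i - 1]
        for j in range(1, m + 1):
            # 'N' never matches: conservative mismatch
            sub = mt if (qi == reference[j - 1] and qi != "N") else -pm
            v, p = best(
                [
                    (prev_d[j - 1], _DIAG),
                    (prev_x[j - 1], _DEL),
                    (prev_y[j - 1], _INS),
                ]
            )
            row_d[j] = v + sub
            ptr[_DIAG][i][j] = p
            v, p = best(
                [
                    (row_d[j - 1] - go, _DIAG),
                    (row_x[j - 1] - ge, _DEL),
                    (row_y[j - 1] - go, _INS),
                ]
            )
            row_x[j] = v
            ptr[_DEL][i][j] = p
            v, p = best(
                [
                    (prev_d[j] - go, _DIAG),
                    (prev_x[j] - go, _DEL),
                    (prev_y[j] - ge, _INS),
                ]
            )
            row_y[j] = v
            ptr[_INS][i][j] = p

    final_score, state = best(
        [(S[_DIAG][n][m], _DIAG), (S[_DEL][n][m], _DEL), (S[_INS][n][m], _INS)]
    )
    ops: list[str] = []
    qa: list[str] = []
    ra: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev_state = ptr[state][i][j]
        if state == _DIAG:
            qb, rb = query[i - 1], reference[j - 1]
            ops.append("M" if (qb == rb and qb != "N") else "X")
            qa.append(qb)
            ra.append(rb)
            i -= 1
            j -= 1
        elif state == _DEL:
            ops.append("D")
            qa.append("-")
            ra.append(reference[j - 1])
            j -= 1
        else:
            ops.append("I")
            qa.append(query[i - 1])
            ra.append("-")
            i -= 1
        state = prev_state
    # columns were collected end-to-start of the reversed pair, i.e. already
    # start-to-end of the original pair
    return Alignment(
        read_id=read_id,
        ref_id=ref_id,
        ops="".join(ops),
        query_aligned="".join(qa),
        ref_aligned="".join(ra),
        ref_start=0,
        strand="+",
        score=int(final_score),
    )


def accuracy(alignment: Alignment, reference_length: int) -> float:
    """Matched bases divided by the total reference length."""
    if reference_length <= 0:
        raise ValueError("reference_length must be positive")
    if reference_length < alignment.ref_span:
        raise ValueError(
            f"reference_length {reference_length} shorter than aligned span "
            f"{alignment.ref_span}"
        )
    return alignment.count("M") / reference_length


def expand_alignment(
    record: RawAlignmentRecord, read: Read, reference: ReferenceSequence
) -> Alignment:
    """Expand a CIGAR record into a per-column event path.

    For strand '-' the basecall is reverse-complemented first, so every event
    column pairs a forward-strand reference base with the oriented basecall.
    Plain M operations are resolved into M/X by comparing bases against the
    reference; = and X operations are taken at face value but still verified
    against the sequences.
    """
    if not record.aligned:
        raise AlignmentError(f"read {record.read_id!r}: record is unaligned")
    query = read.sequence if record.strand == "+" else reverse_complement(read.sequence)
    ref_seq = reference.sequence
    ops_out: list[str] = []
    qa: list[str] = []
    ra: list[str] = []
    q, r = 0, record.ref_start
    for length, op in parse_cigar(record.cigar):
        if op in "M=X":
            if q + length > len(query) or r + length > len(ref_seq):
                raise AlignmentError(
                    f"read {record.read_id!r}: CIGAR overruns sequence ends"
                )
            for k in range(length):
                qb, rb = query[q + k], ref_seq[r + k]
                match = qb == rb and qb != "N" and rb != "N"
                if op == "=" and not match:
                    raise AlignmentError(
                        f"read {record.read_id!r}: CIGAR '=' at reference "
                        f"position {r + k} but bases differ ({qb} vs {rb})"
                    )
                ops_out.append("M" if match else "X")
                qa.append(qb)
                ra.append(rb)
            q += length
            r += length
        elif op == "I":
            if q + length > len(query):
                raise AlignmentError(
                    f"read {record.read_id!r}: CIGAR overruns read end"
                )
            ops_out.append("I" * length)
            qa.append(query[q : q + length])
            ra.append("-" * length)
            q += length
        elif op == "D":
            ops_out.append("D" * length)
            qa.append("-" * length)
            ra.append(ref_seq[r : r + length])
            r += length
        elif op in "SH":
            if op == "S":
                q += length  # soft-clipped bases are present in SEQ but unaligned
        elif op == "N":
            r += length
        else:
            raise AlignmentError(
                f"read {record.read_id!r}: unsupported CIGAR op {op!r}"
            )
    if q != len(query):
        raise AlignmentError(
            f"read {record.read_id!r}: CIGAR consumes {q} read bases, "
            f"read has {len(query)}"
        )
    return Alignment(
        read_id=record.read_id,
        ref_id=record.ref_id or reference.ref_id,
        ops="".join(ops_out),
        query_aligned="".join(qa),
        ref_aligned="".join(ra),
        ref_start=record.ref_start,
        strand=record.strand,
    )
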