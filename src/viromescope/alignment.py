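"""Seed-and-extend local nucleotide alignment.

A small BLASTN-like engine used for vOTU dereplication and prophage / CRISPR
host prediction.  The model:

1.  Exact ``word_size``-mer seeds locate candidate diagonals (megablast uses
    word size 20 for contig-scale comparisons; spacer matching uses 8).
2.  On each seeded diagonal, match/mismatch scores are accumulated and every
    maximal-scoring ungapped segment is extracted with the Ruzzo–Tompa
    algorithm.  Extension is ungapped: the divergence model targeted here is
    substitution-dominated, where ungapped segments recover the optimal local
    alignment; Smith–Waterman with affine gaps is the test-suite oracle.
3.  HSPs are merged on the query axis, overlaps counted once (best-scoring
    HSP wins the overlap), before identity and aligned fractions are
    computed:

    * ``merged_identity`` = 100 x (matched columns / total merged columns),
      i.e. length-weighted across merged HSPs;
    * ``aligned_fraction_query|subject|shorter`` = merged covered length of
      that sequence / its length.

Spurious-hit control at desk scale comes from the seed length plus a minimum
merged alignment length (default 100 columns) rather than an E-value, which
would require a database-size context this engine does not have.  Two
unrelated uniform-random 3 kb sequences share an exact 20-mer with
probability ~ L^2/4^20 << 1, so random pairs yield no alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_VALID_CHARS = frozenset("ACGTN")

# BLASTN-short Karlin–Altschul constants for reward +2 / penalty -3
# (used to express raw spacer-match scores in bits).
BLASTN_SHORT_LAMBDA = 0.625
BLASTN_SHORT_K = 0.41


@dataclass(frozen=True)
class HSP:
    """One ungapped high-scoring segment pair (half-open coordinates)."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    length: int
    score: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length


@dataclass
class AlignmentSummary:
    """Merged local-alignment summary for one query/subject pair."""

    query_id: str
    subject_id: str
    query_length: int
    subject_length: int
    hsps: list[HSP] = field(default_factory=list)
    merged_identity: float = 0.0       # percent, length-weighted
    total_matches: int = 0
    total_columns: int = 0
    aligned_fraction_query: float = 0.0
    aligned_fraction_subject: float = 0.0
    aligned_fraction_shorter: float = 0.0

    @property
    def aligned(self) -> bool:
        return self.total_columns > 0


def _check_sequence(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    seq = seq.upper()
    if not _VALID_CHARS.issuperset(seq):
        bad = sorted(set(seq) - _VALID_CHARS)
        raise ValueError(f"{name} sequence contains invalid characters: {bad}")
    return seq


def _seed_diagonals(query: str, subject: str, word_size: int) -> list[int]:
    """Diagonals (q_pos - s_pos) carrying at least one exact word match."""
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - word_size + 1):
        index.setdefault(subject[j : j + word_size], []).append(j)
    diagonals: set[int] = set()
    for i in range(len(query) - word_size + 1):
        positions = index.get(query[i : i + word_size])
        if positions:
            for j in positions:
                diagonals.add(i - j)
    return sorted(diagonals)


def _maximal_segments(scores: np.ndarray, min_score: float) -> list[tuple[int, int, float]]:
    """All maximal-scoring subsegments of a score vector (Ruzzo–Tompa).

    Runs over a compressed representation (match runs / mismatch runs) so the
    cost is proportional to the number of mismatch runs, not the diagonal
    length.  Returns (start, end, score) with half-open coordinates; segments
    begin and end on positive (match) atoms.
    """
    n = len(scores)
    if n == 0:
        return []
    # compress into maximal runs of equal sign
    positive = scores > 0
    change = np.flatnonzero(positive[1:] != positive[:-1]) + 1
    bounds = np.concatenate(([0], change, [n]))
    atoms: list[tuple[float, int, int]] = []  # (score, start, end)
    for k in range(len(bounds) - 1):
        s, e = int(bounds[k]), int(bounds[k + 1])
        atoms.append((float(scores[s:e].sum()), s, e))

    # Ruzzo–Tompa: maintain disjoint candidate subsequences as
    # [L_cum, R_cum, start, end]; only positive atoms create candidates.
    stack: list[list[float]] = []
    cum = 0.0
    for score, s, e in atoms:
        left = cum
        cum += score
        if score <= 0:
            continue
        entry = [left, cum, float(s), float(e)]
        while True:
            j = None
            for idx in range(len(stack) - 1, -1, -1):
                if stack[idx][0] < entry[0]:
                    j = idx
                    break
            if j is None:
                stack.append(entry)
                break
            if stack[j][1] >= entry[1]:
                stack.append(entry)
                break
            # merge candidate j..entry into one subsequence and re-test
            merged = [stack[j][0], entry[1], stack[j][2], entry[3]]
            del stack[j:]
            entry = merged
    return [
        (int(st), int(en), r - l)
        for l, r, st, en in stack
        if (r - l) >= min_score
    ]


def _subtract_intervals(
    start: int, end: int, covered: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Parts of [start, end) not covered by the sorted disjoint intervals."""
    pieces = []
    cur = start
    for cs, ce in covered:
        if ce <= cur:
            continue
        if cs >= end:
            break
        if cs > cur:
            pieces.append((cur, cs))
        cur = max(cur, ce)
        if cur >= end:
            break
    if cur < end:
        pieces.append((cur, end))
    return pieces


def _insert_interval(covered: list[tuple[int, int]], iv: tuple[int, int]) -> None:
    covered.append(iv)
    covered.sort()


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        else:
            last_end = max(last_end, e)
    return total


def local_align(
    query: str,
    subject: str,
    *,
    word_size: int = 20,
    match: int = 1,
    mismatch: int = -2,
    min_hsp_score: float | None = None,
    min_merged_length: int = 100,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentSummary:
    """Align ``query`` against ``subject`` and summarise merged local HSPs.

    Parameters follow the engine model described in the module docstring.
    ``min_hsp_score`` defaults to ``word_size * match`` (a bare seed);
    ``min_merged_length`` suppresses alignments whose merged span is shorter
    than 100 columns.  An :class:`AlignmentSummary` with ``aligned=False`` is
    returned when nothing passes.
    """
    q = _check_sequence(query, "query")
    s = _check_sequence(subject, "subject")
    if min_hsp_score is None:
        min_hsp_score = word_size * match
    summary = AlignmentSummary(
        query_id=query_id,
        subject_id=subject_id,
        query_length=len(q),
        subject_length=len(s),
    )
    if len(q) < word_size or len(s) < word_size:
        return summary

    qa = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
    sa = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    n_code = ord("N")

    hsps: list[HSP] = []
    for d in _seed_diagonals(q, s, word_size):
        q0 = max(0, d)
        q1 = min(len(q), len(s) + d)
        if q1 - q0 < word_size:
            continue
        seg_q = qa[q0:q1]
        seg_s = sa[q0 - d : q1 - d]
        eq = (seg_q == seg_s) & (seg_q != n_code)
        scores = np.where(eq, float(match), float(mismatch))
        for st, en, sc in _maximal_segments(scores, min_hsp_score):
            m = int(eq[st:en].sum())
            hsps.append(
                HSP(
                    q_start=q0 + st,
                    q_end=q0 + en,
                    s_start=q0 + st - d,
                    s_end=q0 + en - d,
                    matches=m,
                    length=en - st,
                    score=int(round(sc)),
                )
            )

    if not hsps:
        return summary

    # merge on the query axis: best-scoring HSP keeps contested columns
    hsps.sort(key=lambda h: (-h.score, h.q_start, h.s_start))
    covered: list[tuple[int, int]] = []
    accepted: list[HSP] = []
    for h in hsps:
        d = h.q_start - h.s_start
        for qs, qe in _subtract_intervals(h.q_start, h.q_end, covered):
            m = int(((qa[qs:qe] == sa[qs - d : qe - d]) & (qa[qs:qe] != n_code)).sum())
            length = qe - qs
            accepted.append(
                HSP(
                    q_start=qs,
                    q_end=qe,
                    s_start=qs - d,
                    s_end=qe - d,
                    matches=m,
                    length=length,
                    score=m * match + (length - m) * mismatch,
                )
            )
            _insert_interval(covered, (qs, qe))

    total_columns = sum(h.length for h in accepted)
    if total_columns < min_merged_length:
        return summary

    total_matches = sum(h.matches for h in accepted)
    q_cov = _union_length([(h.q_start, h.q_end) for h in accepted])
    s_cov = _union_length([(h.s_start, h.s_end) for h in accepted])
    summary.hsps = sorted(accepted, key=lambda h: h.q_start)
    summary.total_matches = total_matches
    summary.total_columns = total_columns
    summary.merged_identity = 100.0 * total_matches / total_columns
    summary.aligned_fraction_query = q_cov / len(q)
    summary.aligned_fraction_subject = s_cov / len(s)
    summary.aligned_fraction_shorter = (
        summary.aligned_fraction_query
        if len(q) <= len(s)
        else summary.aligned_fraction_subject
    )
    return summary


def best_local_score(
    query: str,
    subject: str,
    *,
    word_size: int = 8,
    match: int = 2,
    mismatch: int = -3,
) -> int:
    """Raw score of the best ungapped local segment (0 when nothing seeds).

    Scoring defaults are the blastn-short reward/penalty pair, which makes
    the bit-score conversion of :func:`bitscore` meaningful for short
    queries such as CRISPR spacers.
    """
    q = _check_sequence(query, "query")
    s = _check_sequence(subject, "subject")
    if len(q) < word_size or len(s) < word_size:
        return 0
    qa = np.frombuffer(q.encode("ascii"), dtype=np.uint8)
    sa = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    n_code = ord("N")
    best = 0
    for d in _seed_diagonals(q, s, word_size):
        q0 = max(0, d)
        q1 = min(len(q), len(s) + d)
        seg_q = qa[q0:q1]
        seg_s = sa[q0 - d : q1 - d]
        eq = (seg_q == seg_s) & (seg_q != n_code)
        scores = np.where(eq, float(match), float(mismatch))
        for _, _, sc in _maximal_segments(scores, word_size * match):
            if sc > best:
                best = int(round(sc))
    return best


def bitscore(raw_score: float) -> float:
    """Normalised bit-score (lambda*S - ln K)/ln 2 with blastn-short constants.

    For an ungapped perfect match of n bases at reward +2 the raw score is 2n,
    so bit(n) = (0.625*2n + 0.8916)/0.6931; a perfect 30-mer scores ~55.4 bits.
    """
    return (BLASTN_SHORT_LAMBDA * raw_score - np.log(BLASTN_SHORT_K)) / np.log(2.0)
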