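"""Translated homology search and pairwise protein alignment.

A tBLASTn-style search implemented as exact dynamic programming: a protein
query is aligned locally (Smith-Waterman
with affine gaps) against all six conceptual translations of a DNA target,
with no low-complexity masking and no heuristic seeding.  The EDC locus is
small (tens to hundreds of kb), so exact DP is the production path, not a
fallback.

Scoring follows the BLAST protein defaults: BLOSUM62, gap open 11, gap
extend 1 (a gap of length k costs 11 + k).  ``X`` scores 0 against every
residue, acting as a neutral placeholder for assembly gaps.  There is no
E-value model; hits are thresholded on raw score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .io_core import PROTEIN_ALPHABET, SequenceError, reverse_complement, translate

# Alphabet used by the scoring kernels.  '!' is an internal masking sentinel
# used for iterated suboptimal-hit search; it never appears in user input.
ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*!"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_NEG = -(10**6)
_MASK_SCORE = -(10**4)


@dataclass
class SubstitutionMatrix:
    """A residue scoring table plus affine gap costs.

    ``scores`` is indexed by :data:`ALPHABET`.  A gap of length k costs
    ``gap_open + k * gap_extend``.
    """

    scores: np.ndarray
    gap_open: int = 11
    gap_extend: int = 1
    name: str = "custom"

    @classmethod
    def blosum62(cls, gap_open: int = 11, gap_extend: int = 1) -> "SubstitutionMatrix":
        """The standard BLOSUM62 table with X neutralised to 0."""
        src = substitution_matrices.load("BLOSUM62")
        n = len(ALPHABET)
        scores = np.full((n, n), _MASK_SCORE, dtype=np.int32)
        for a in src.alphabet:
            for b in src.alphabet:
                scores[_INDEX[a], _INDEX[b]] = int(src[a, b])
        xi = _INDEX["X"]
        scores[xi, :] = 0
        scores[:, xi] = 0
        mi = _INDEX["!"]
        scores[mi, :] = _MASK_SCORE
        scores[:, mi] = _MASK_SCORE
        return cls(scores=scores, gap_open=gap_open, gap_extend=gap_extend,
                   name="BLOSUM62")

    def score(self, a: str, b: str) -> int:
        return int(self.scores[_INDEX[a], _INDEX[b]])

    def validate(self) -> None:
        core = [_INDEX[c] for c in "ARNDCQEGHILKMFPSTWYV"]
        sub = self.scores[np.ix_(core, core)]
        if not np.array_equal(sub, sub.T):
            raise ValueError("substitution matrix is not symmetric")


DEFAULT_MATRIX = SubstitutionMatrix.blosum62()


@dataclass
class AlignmentHit:
    """A scored local alignment of a protein query against a target.

    ``target_span`` is in residues for protein targets and forward-strand
    nucleotides for DNA targets (``frame``/``strand`` set in that case).
    """

    query_id: str
    target_id: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    score: int
    identity: float
    frame: int | None = None
    strand: str | None = None


@dataclass
class GlobalAlignment:
    aligned_a: str
    aligned_b: str
    score: int
    identity: float


def _encode(seq: str, *, allow_stop: bool = False) -> np.ndarray:
    allowed = PROTEIN_ALPHABET | ({"*"} if allow_stop else set())
    bad = set(seq) - allowed
    if bad:
        raise SequenceError(f"unknown residues in sequence: {sorted(bad)}")
    return np.fromiter((_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def _encode_masked(seq: str) -> np.ndarray:
    # like _encode but tolerates the internal '!' mask sentinel
    return np.fromiter((_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


# ---------------------------------------------------------------------------
# DP kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fill_local(q, t, S, go, ge):  # pragma: no cover - compiled
    n, m = q.shape[0], t.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    first = go + ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - first
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - first
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + S[q[i - 1], t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _fill_global(q, t, S, go, ge):  # pragma: no cover - compiled
    n, m = q.shape[0], t.shape[0]
    H = np.full((n + 1, m + 1), _NEG, np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)
    F = np.full((n + 1, m + 1), _NEG, np.int32)
    first = go + ge
    H[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = -(go + j * ge)
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -(go + i * ge)
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - first
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - first
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + S[q[i - 1], t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F


# ---------------------------------------------------------------------------
# traceback helpers
# ---------------------------------------------------------------------------


def _traceback(q, t, S, H, E, F, i, j, go, ge, *, local: bool):
    """Walk back from (i, j) returning aligned strings and column stats."""
    first = go + ge
    a_cols: list[str] = []
    b_cols: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if local and H[i, j] == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[q[i - 1], t[j - 1]]:
                a_cols.append(ALPHABET[q[i - 1]])
                b_cols.append(ALPHABET[t[j - 1]])
                i -= 1
                j -= 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = "E"
            elif i > 0 and H[i, j] == F[i, j]:
                state = "F"
            else:  # global boundary rows
                if i == 0:
                    state = "E"
                else:
                    state = "F"
        elif state == "E":
            a_cols.append("-")
            b_cols.append(ALPHABET[t[j - 1]])
            if j > 1 and E[i, j] == E[i, j - 1] - ge and not (
                E[i, j] == H[i, j - 1] - first
            ):
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            a_cols.append(ALPHABET[q[i - 1]])
            b_cols.append("-")
            if i > 1 and F[i, j] == F[i - 1, j] - ge and not (
                F[i, j] == H[i - 1, j] - first
            ):
                i -= 1
            else:
                i -= 1
                state = "H"
        if local and state == "H" and H[i, j] == 0:
            break
    return "".join(reversed(a_cols)), "".join(reversed(b_cols)), i, j


def _column_identity(a: str, b: str) -> float:
    aligned = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    if aligned == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / aligned


# ---------------------------------------------------------------------------
# public alignment operations
# ---------------------------------------------------------------------------


def local_align(
    query: str,
    target: str,
    matrix: SubstitutionMatrix | None = None,
    *,
    query_id: str = "query",
    target_id: str = "target",
    _target_encoded: np.ndarray | None = None,
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Ties are broken deterministically (earliest target end, then earliest
    query end, diagonal moves preferred in traceback).  A best score of 0
    yields empty spans.
    """
    matrix = matrix or DEFAULT_MATRIX
    if not query or not target:
        raise SequenceError("local_align requires non-empty sequences")
    q = _encode(query)
    t = _target_encoded if _target_encoded is not None else _encode(
        target, allow_stop=True
    )
    H, E, F = _fill_local(q, t, matrix.scores, matrix.gap_open, matrix.gap_extend)
    best = int(H.max())
    if best <= 0:
        return AlignmentHit(query_id, target_id, (0, 0), (0, 0), 0, 0.0)
    # earliest target column, then earliest query row
    cells = np.argwhere(H == best)
    order = np.lexsort((cells[:, 0], cells[:, 1]))
    i, j = (int(x) for x in cells[order[0]])
    a, b, i0, j0 = _traceback(
        q, t, matrix.scores, H, E, F, i, j, matrix.gap_open, matrix.gap_extend,
        local=True,
    )
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        query_span=(i0, i),
        target_span=(j0, j),
        score=best,
        identity=_column_identity(a, b),
    )


def global_align(
    a: str, b: str, matrix: SubstitutionMatrix | None = None
) -> GlobalAlignment:
    """Optimal global (Needleman-Wunsch) alignment, end gaps penalized."""
    matrix = matrix or DEFAULT_MATRIX
    if not a or not b:
        raise SequenceError("global_align requires non-empty sequences")
    qa = _encode(a)
    qb = _encode(b)
    H, E, F = _fill_global(qa, qb, matrix.scores, matrix.gap_open, matrix.gap_extend)
    score = int(H[len(a), len(b)])
    sa, sb, _, _ = _traceback(
        qa, qb, matrix.scores, H, E, F, len(a), len(b),
        matrix.gap_open, matrix.gap_extend, local=False,
    )
    return GlobalAlignment(sa, sb, score, _column_identity(sa, sb))


def global_score(a: str, b: str, matrix: SubstitutionMatrix | None = None) -> int:
    """Global alignment score only (no traceback)."""
    matrix = matrix or DEFAULT_MATRIX
    qa = _encode(a)
    qb = _encode(b)
    H, _, _ = _fill_global(qa, qb, matrix.scores, matrix.gap_open, matrix.gap_extend)
    return int(H[len(a), len(b)])


def _nt_span(frame: int, strand: str, length: int, p0: int, p1: int) -> tuple[int, int]:
    """Map a protein span on a translated frame to forward-strand nucleotides."""
    if strand == "+":
        return (frame + 3 * p0, frame + 3 * p1)
    return (length - (frame + 3 * p1), length - (frame + 3 * p0))


def translated_search(
    query: str,
    target_dna: str,
    matrix: SubstitutionMatrix | None = None,
    min_score: int = 40,
    max_hits_per_frame: int = 40,
    *,
    query_id: str = "query",
    target_id: str = "target",
) -> list[AlignmentHit]:
    """Align a protein query against all six translation frames of a target.

    For each frame, suboptimal non-overlapping hits are recovered by
    iteratively masking the best hit's span, so tandem multi-copy families
    yield one hit per copy.  Hit target spans are reported in forward-strand
    nucleotide coordinates.  Hits are sorted by score descending.
    """
    matrix = matrix or DEFAULT_MATRIX
    if len(target_dna) < 3:
        raise SequenceError("target shorter than one codon")
    if min_score < 1:
        raise ValueError("min_score must be >= 1")
    target_dna = target_dna.upper()
    hits: list[AlignmentHit] = []
    for strand in "+-":
        for frame in range(3):
            if len(target_dna) < frame + 3:
                continue
            prot = list(translate(target_dna, frame, strand))
            for _ in range(max_hits_per_frame):
                enc = _encode_masked("".join(prot))
                hit = local_align(
                    query, "".join(prot), matrix,
                    query_id=query_id, target_id=target_id,
                    _target_encoded=enc,
                )
                if hit.score < min_score:
                    break
                p0, p1 = hit.target_span
                hits.append(
                    AlignmentHit(
                        query_id=query_id,
                        target_id=target_id,
                        query_span=hit.query_span,
                        target_span=_nt_span(frame, strand, len(target_dna), p0, p1),
                        score=hit.score,
                        identity=hit.identity,
                        frame=frame,
                        strand=strand,
                    )
                )
                for k in range(p0, p1):
                    prot[k] = "!"
    hits.sort(key=lambda h: (-h.score, h.strand, h.frame, h.target_span))
    return hits
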