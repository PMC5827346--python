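"""Independent oracles used by the test suite.

Every function here recomputes a quantity by a route independent of the
production code: exhaustive enumeration, naive recursion, a third-party
exact implementation, or a closed form.  None of them import the modules
they are used to check (beyond shared constants).
"""

from __future__ import annotations

import itertools

from Bio.Align import PairwiseAligner, substitution_matrices

GAP_OPEN = 11
GAP_EXT = 1

_BL62 = substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> int:
    if a == "X" or b == "X":
        return 0
    return int(_BL62[a, b])


# ---------------------------------------------------------------------------
# alignment oracles
# ---------------------------------------------------------------------------


def enum_global_score(a: str, b: str) -> int:
    """Exhaustive enumeration over all affine-gap global alignments.

    Plain recursion over alignment columns, no memoisation: every monotone
    path is visited.  Gap of length k costs GAP_OPEN + k * GAP_EXT; end
    gaps are penalized.  Only viable for short sequences.
    """

    def rec(i: int, j: int, last: str) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = None
        if i < len(a) and j < len(b):
            s = blosum62_score(a[i], b[j]) + rec(i + 1, j + 1, "M")
            best = s if best is None else max(best, s)
        if j < len(b):  # gap in a, consume b[j]
            cost = GAP_EXT if last == "E" else GAP_OPEN + GAP_EXT
            s = -cost + rec(i, j + 1, "E")
            best = s if best is None else max(best, s)
        if i < len(a):  # gap in b, consume a[i]
            cost = GAP_EXT if last == "F" else GAP_OPEN + GAP_EXT
            s = -cost + rec(i + 1, j, "F")
            best = s if best is None else max(best, s)
        return best

    return rec(0, 0, "start")


def enum_local_score(a: str, b: str) -> int:
    """Local score as the max over all substring pairs, or 0."""
    best = 0
    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    best = max(best, enum_global_score(a[i0:i1], b[j0:j1]))
    return best


def _aligner(mode: str) -> PairwiseAligner:
    matrix = _BL62.copy()
    xi = list(matrix.alphabet).index("X")
    matrix[xi, :] = 0
    matrix[:, xi] = 0
    aln = PairwiseAligner()
    aln.mode = mode
    aln.substitution_matrix = matrix
    aln.open_gap_score = -(GAP_OPEN + GAP_EXT)
    aln.extend_gap_score = -GAP_EXT
    return aln


def reference_local_score(a: str, b: str) -> int:
    """Optimal local score from Biopython's exact aligner."""
    return int(_aligner("local").score(a, b))


def reference_global_score(a: str, b: str) -> int:
    """Optimal global score (end gaps penalized) from Biopython."""
    return int(_aligner("global").score(a, b))


# ---------------------------------------------------------------------------
# repeat-copy oracle
# ---------------------------------------------------------------------------


def _copy_ways(seq: str, start: int, positions, max_mm: int):
    """All (length, mismatches) a motif copy can take at ``start`` (naive)."""
    ways = set()

    def rec(pi: int, off: int, mm: int) -> None:
        if mm > max_mm:
            return
        if pi == len(positions):
            if off > 0:
                ways.add((off, mm))
            return
        residues, optional = positions[pi]
        if optional:
            rec(pi + 1, off, mm)
        if start + off < len(seq):
            rec(pi + 1, off + 1, mm + (0 if seq[start + off] in residues else 1))

    rec(0, 0, 0)
    return ways


def brute_repeat_copies(seq: str, positions, max_mm: int = 1,
                        max_spacer: int = 2) -> int:
    """Maximal tandem copy count by naive recursion over all decompositions.

    ``positions`` is a list of (allowed-residue set, optional flag).
    """

    def from_start(i: int) -> int:
        best = 0
        for length, _mm in _copy_ways(seq, i, positions, max_mm):
            for spacer in range(max_spacer + 1):
                nxt = i + length + spacer
                tail = from_start(nxt) if nxt < len(seq) else 0
                best = max(best, 1 + tail)
        return best

    return max((from_start(i) for i in range(len(seq))), default=0)


# ---------------------------------------------------------------------------
# Dollo oracle
# ---------------------------------------------------------------------------


def brute_dollo_events(tree, present: set[str]):
    """Minimal single-gain / any-losses history by exhaustive enumeration.

    Enumerates every 0/1 assignment to internal nodes, keeps those with
    exactly one gain (root presence counts as the gain) and tip states
    matching ``present``, and returns the (gain_tips, loss_tip_sets) of the
    loss-minimal assignment.  Clades are identified by their tip-name sets.
    """
    internals = tree.get_nonterminals()
    tips = tree.get_terminals()
    best = None
    for states in itertools.product([0, 1], repeat=len(internals)):
        assign = {id(n): s for n, s in zip(internals, states)}
        for t in tips:
            assign[id(t)] = 1 if t.name in present else 0
        gains, losses = [], []
        root = tree.root
        if assign[id(root)] == 1:
            gains.append(root)
        for node in internals:
            for child in node.clades:
                if assign[id(node)] == 0 and assign[id(child)] == 1:
                    gains.append(child)
                elif assign[id(node)] == 1 and assign[id(child)] == 0:
                    losses.append(child)
        if present and len(gains) != 1:
            continue
        if not present and (gains or assign[id(root)] == 1):
            continue
        key = (len(losses), len(gains))
        if best is None or key < best[0]:
            gain_set = (
                frozenset(t.name for t in gains[0].get_terminals())
                if gains
                else None
            )
            loss_sets = frozenset(
                frozenset(t.name for t in c.get_terminals()) for c in losses
            )
            best = (key, gain_set, loss_sets)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# closed-form ortholog identity
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _site_prob(old: str, new: str, d: float) -> float:
    if new == old:
        return 1.0 - d
    if new == _TRANSITION[old]:
        return d * 0.5
    return d * 0.25


def expected_protein_identity(codons: list[str], d: float, codon_table) -> float:
    """Expected residue identity under per-site substitution at rate ``d``
    with a 2:1 transition bias and stop-avoiding rejection.

    Enumerates all 64 outcome codons per input codon; outcomes that are
    stops have their probability mass reassigned to the original codon
    (the simulator rejects such substitutions).
    """
    total = 0.0
    for codon in codons:
        aa = codon_table[codon]
        p_same = 0.0
        for out in itertools.product(_BASES, repeat=3):
            out_codon = "".join(out)
            p = 1.0
            for o, n in zip(codon, out_codon):
                p *= _site_prob(o, n, d)
            if codon_table[out_codon] == "*":
                p_same += p  # rejected; original codon retained
            elif codon_table[out_codon] == aa:
                p_same += p
        total += p_same
    return total / len(codons)
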