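"""Degenerate tandem-repeat detection and ortholog architecture comparison.

The avian feather protein EDCRP consists of conserved N- and C-terminal
domains around a massively amplified internal peptide repeat with the
consensus CCDPCQ(K/-)(T/P)(V/-) — fixed residues, alternative residues in
parentheses, and ``-`` marking positions that may be absent.  Crocodilian
EDCRP-like proteins share the termini but lack the repeat entirely.  This
module counts copies of such degenerate motifs, discovers tandem repeats de
novo by self-periodicity, and compares the domain architecture of ortholog
pairs (terminal identity vs internal copy-number expansion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .homology_search import SubstitutionMatrix, global_align
from .io_core import ProteinRecord

Interval = tuple[int, int]


@dataclass(frozen=True)
class MotifPosition:
    residues: frozenset
    optional: bool = False


@dataclass
class RepeatMotifPattern:
    """A degenerate motif: fixed, alternative and optional positions."""

    positions: tuple[MotifPosition, ...]
    source: str = ""

    def __post_init__(self) -> None:
        required = sum(1 for p in self.positions if not p.optional)
        if required < 3:
            raise ValueError("pattern needs at least 3 non-optional positions")

    @property
    def min_length(self) -> int:
        return sum(1 for p in self.positions if not p.optional)

    @property
    def max_length(self) -> int:
        return len(self.positions)


def parse_pattern(text: str) -> RepeatMotifPattern:
    """Parse the string grammar, e.g. ``CCDPCQ(K|-)(T|P)(V|-)``.

    Fixed residues stand alone; alternatives are parenthesised and
    ``|``-separated; ``-`` inside a set marks the position optional.
    """
    positions: list[MotifPosition] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "(":
            j = text.index(")", i)
            alts = text[i + 1 : j].split("|")
            residues = frozenset(a for a in alts if a != "-")
            optional = "-" in alts
            if not residues:
                raise ValueError(f"empty alternative set at {i}")
            positions.append(MotifPosition(residues, optional))
            i = j + 1
        elif c.isalpha():
            positions.append(MotifPosition(frozenset(c)))
            i += 1
        else:
            raise ValueError(f"unexpected character {c!r} in pattern")
    return RepeatMotifPattern(tuple(positions), source=text)


@dataclass
class RepeatAnnotation:
    protein_id: str
    pattern: str
    copies: int
    span: Interval
    per_copy: list[tuple[Interval, str, int]] = field(default_factory=list)
    unit_consensus: str = ""


@dataclass
class RepeatParams:
    max_mismatch: int = 1  # deviations tolerated per copy
    max_spacer: int = 2  # residues allowed between adjacent copies
    min_period_identity: float = 0.7  # for de novo discovery


# ---------------------------------------------------------------------------
# fixed-pattern search
# ---------------------------------------------------------------------------


def _copy_matches(seq: str, start: int, pattern: RepeatMotifPattern, max_mm: int):
    """All (length, mismatches) ways one motif copy can match at ``start``.

    Optional positions may be consumed or skipped; consumed positions that
    fail their residue set count as mismatches.  Small exact DP.
    """
    results: dict[int, int] = {}  # consumed length -> min mismatches

    def step(pi: int, off: int, mm: int) -> None:
        if mm > max_mm:
            return
        if pi == len(pattern.positions):
            if off > 0 and (off not in results or mm < results[off]):
                results[off] = mm
            return
        pos = pattern.positions[pi]
        if pos.optional:
            step(pi + 1, off, mm)
        if start + off < len(seq):
            hit = seq[start + off] in pos.residues
            step(pi + 1, off + 1, mm + (0 if hit else 1))

    step(0, 0, 0)
    return sorted(results.items())


def count_motif_copies(
    protein,
    pattern: RepeatMotifPattern | str,
    params: RepeatParams | None = None,
) -> RepeatAnnotation | None:
    """Locate the maximal tandem array of a degenerate motif.

    Copies may deviate by up to ``max_mismatch`` residues and be separated
    by up to ``max_spacer`` residues.  The array with the most copies wins;
    ties break to the leftmost start.  Returns None when no copy matches.
    """
    params = params or RepeatParams()
    if isinstance(pattern, str):
        pattern = parse_pattern(pattern)
    pid, seq = (
        (protein.id, protein.sequence)
        if isinstance(protein, ProteinRecord)
        else ("protein", str(protein))
    )
    n = len(seq)

    match_table = {i: _copy_matches(seq, i, pattern, params.max_mismatch)
                   for i in range(n)}

    @lru_cache(maxsize=None)
    def chain(i: int) -> tuple[tuple[int, int, int], tuple]:
        """Best array starting at i: key (copies, -mismatches, length)."""
        best = ((0, 0, 0), ())
        for length, mm in match_table.get(i, []):
            tail = ((0, 0, 0), ())
            for spacer in range(params.max_spacer + 1):
                nxt = i + length + spacer
                if nxt <= n:
                    cand = chain(nxt) if nxt < n else ((0, 0, 0), ())
                    if cand[0] > tail[0]:
                        tail = cand
            entry = ((i, i + length), seq[i : i + length], mm)
            key = (
                1 + tail[0][0],
                tail[0][1] - mm,
                tail[0][2] + length,
            )
            if (key, (entry,) + tail[1])[0] > best[0]:
                best = (key, (entry,) + tail[1])
        return best

    best = ((0, 0, 0), ())
    for i in range(n):
        cand = chain(i)
        if cand[0] > best[0]:
            best = cand
    if best[0][0] == 0:
        return None
    per_copy = list(best[1])
    span = (per_copy[0][0][0], per_copy[-1][0][1])
    return RepeatAnnotation(
        protein_id=pid,
        pattern=pattern.source,
        copies=best[0][0],
        span=span,
        per_copy=per_copy,
    )


# ---------------------------------------------------------------------------
# de novo discovery
# ---------------------------------------------------------------------------


def _identity(a: str, b: str) -> float:
    if not a or len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _consensus(windows: list[str]) -> str:
    out = []
    for col in zip(*windows):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        out.append(max(sorted(counts), key=lambda c: counts[c]))
    return "".join(out)


def discover_tandem_repeats(
    protein,
    min_unit: int = 3,
    min_copies: int = 3,
    params: RepeatParams | None = None,
) -> list[RepeatAnnotation]:
    """Find tandem repeats by self-periodicity, no motif given.

    For each candidate unit length, runs of consecutive windows whose
    identity to the previous window reaches ``min_period_identity`` are
    collected; arrays with enough copies are reported with a majority-rule
    consensus.  Overlapping candidates resolve to the widest array, then
    the shortest unit.
    """
    params = params or RepeatParams()
    pid, seq = (
        (protein.id, protein.sequence)
        if isinstance(protein, ProteinRecord)
        else ("protein", str(protein))
    )
    n = len(seq)
    if not 2 <= min_unit or min_unit > n // max(min_copies, 1):
        raise ValueError("min_unit must satisfy 2 <= min_unit <= length/min_copies")
    candidates: list[RepeatAnnotation] = []
    for u in range(min_unit, n // min_copies + 1):
        s = 0
        while s + u * min_copies <= n:
            windows = [seq[s : s + u]]
            k = 1
            while s + (k + 1) * u <= n and _identity(
                seq[s + (k - 1) * u : s + k * u], seq[s + k * u : s + (k + 1) * u]
            ) >= params.min_period_identity:
                windows.append(seq[s + k * u : s + (k + 1) * u])
                k += 1
            if k >= min_copies:
                span = (s, s + k * u)
                cons = _consensus(windows)
                per_copy = [
                    ((s + i * u, s + (i + 1) * u), w, sum(
                        1 for a, b in zip(w, cons) if a != b
                    ))
                    for i, w in enumerate(windows)
                ]
                candidates.append(
                    RepeatAnnotation(
                        protein_id=pid,
                        pattern=f"denovo:{cons}",
                        copies=k,
                        span=span,
                        per_copy=per_copy,
                        unit_consensus=cons,
                    )
                )
                s += k * u
            else:
                s += 1
    # resolve overlaps: widest array first, then shortest unit, then leftmost
    candidates.sort(
        key=lambda r: (-(r.span[1] - r.span[0]), len(r.unit_consensus), r.span[0])
    )
    chosen: list[RepeatAnnotation] = []
    for cand in candidates:
        if all(
            cand.span[1] <= c.span[0] or c.span[1] <= cand.span[0] for c in chosen
        ):
            chosen.append(cand)
    chosen.sort(key=lambda r: r.span)
    return chosen


# ---------------------------------------------------------------------------
# ortholog architecture comparison
# ---------------------------------------------------------------------------


@dataclass
class ArchitectureReport:
    terminal_identity: float  # percent, over N+C terminal alignments
    copies_a: int
    copies_b: int
    expansion: int  # copies_b - copies_a, signed


def compare_ortholog_architecture(
    protein_a,
    protein_b,
    pattern: RepeatMotifPattern | str,
    params: RepeatParams | None = None,
    matrix: SubstitutionMatrix | None = None,
) -> ArchitectureReport:
    """Compare two orthologs: terminal conservation vs repeat expansion.

    Termini outside the detected repeat arrays are aligned globally; for a
    protein without the repeat, the terminus boundary falls at its midpoint.
    ``expansion`` is signed (positive: B carries more copies).
    """
    seq_a = protein_a.sequence if isinstance(protein_a, ProteinRecord) else protein_a
    seq_b = protein_b.sequence if isinstance(protein_b, ProteinRecord) else protein_b
    ann_a = count_motif_copies(seq_a, pattern, params)
    ann_b = count_motif_copies(seq_b, pattern, params)
    copies_a = ann_a.copies if ann_a else 0
    copies_b = ann_b.copies if ann_b else 0
    span_a = ann_a.span if ann_a else (len(seq_a) // 2, len(seq_a) // 2)
    span_b = ann_b.span if ann_b else (len(seq_b) // 2, len(seq_b) // 2)
    cols = 0
    matches = 0.0
    for part_a, part_b in (
        (seq_a[: span_a[0]], seq_b[: span_b[0]]),
        (seq_a[span_a[1] :], seq_b[span_b[1] :]),
    ):
        if not part_a or not part_b:
            continue
        g = global_align(part_a, part_b, matrix)
        aligned = sum(
            1 for x, y in zip(g.aligned_a, g.aligned_b) if x != "-" and y != "-"
        )
        matches += g.identity * aligned
        cols += aligned
    identity_pct = 100.0 * matches / cols if cols else 0.0
    return ArchitectureReport(
        terminal_identity=identity_pct,
        copies_a=copies_a,
        copies_b=copies_b,
        expansion=copies_b - copies_a,
    )
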