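"""Amino-acid composition and transglutamination-motif profiling.

EDC proteins are cross-linked into the cornified envelope and are strongly
enriched for a small set of residues — glycine, serine, proline, lysine,
cysteine and glutamine — often with a single residue exceeding 20% of the
sequence.  Their N- and C-termini carry lysine/glutamine-rich motifs, the
presumptive substrate sites of transglutamination
(N-epsilon-(gamma-glutamyl)lysine cross-links).

Composition percentages are exact per-residue tallies over the 20 standard
amino acids; ``X`` placeholders are excluded from the denominator (and
logged), since they carry no compositional information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_core import AA_LETTERS, ProteinRecord, SequenceError

logger = logging.getLogger(__name__)

ENRICHMENT_RESIDUES = "GSPKCQ"


@dataclass
class CompositionProfile:
    """Per-residue percentages (of total residues) for one protein."""

    protein_id: str
    percent: dict[str, float]
    length: int

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if self.length > 0 and abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {total}, not 100")


@dataclass
class TerminalMotif:
    terminus: str  # 'N' or 'C'
    span: tuple[int, int]  # protein coordinates, half-open
    kq_fraction: float


@dataclass
class MotifParams:
    terminal_window: int = 20
    min_length: int = 5
    min_kq: float = 0.4


def _seq_of(protein) -> tuple[str, str]:
    if isinstance(protein, ProteinRecord):
        return protein.id, protein.sequence
    return "protein", str(protein)


def composition(protein) -> CompositionProfile:
    """Exact amino-acid percentages, X excluded from the denominator."""
    pid, seq = _seq_of(protein)
    if not seq:
        raise SequenceError("empty protein sequence")
    n_x = seq.count("X")
    if n_x:
        logger.info("%s: %d X residues excluded from composition", pid, n_x)
    counted = len(seq) - n_x
    if counted == 0:
        raise SequenceError(f"protein {pid!r}: no countable residues")
    percent = {aa: 100.0 * seq.count(aa) / counted for aa in AA_LETTERS}
    return CompositionProfile(protein_id=pid, percent=percent, length=counted)


def count_residue(protein, residue: str) -> int:
    """Exact count of one residue type (e.g. cysteines in EDCRP)."""
    if len(residue) != 1 or residue not in AA_LETTERS + "X":
        raise ValueError(f"invalid residue {residue!r}")
    _, seq = _seq_of(protein)
    return seq.count(residue)


def enrichment_classes(
    profile: CompositionProfile,
    threshold: float = 20.0,
    residues: str | None = ENRICHMENT_RESIDUES,
) -> set[str]:
    """Residues whose percentage strictly exceeds the threshold.

    By default only the EDC-characteristic residues G, S, P, K, C, Q are
    considered; pass ``residues=None`` to consider all twenty.
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    pool = residues if residues is not None else AA_LETTERS
    return {aa for aa in pool if profile.percent.get(aa, 0.0) > threshold}


def _best_kq_subspan(window: str, offset: int, min_length: int):
    """Maximal K+Q-density subspan of length >= min_length (exhaustible)."""
    best = None
    for i in range(len(window)):
        for j in range(i + min_length, len(window) + 1):
            sub = window[i:j]
            frac = sum(1 for c in sub if c in "KQ") / len(sub)
            key = (frac, j - i, -i)  # density, then length, then leftmost
            if best is None or key > best[0]:
                best = (key, (offset + i, offset + j), frac)
    return best


def terminal_kq_motifs(
    protein, params: MotifParams | None = None
) -> list[TerminalMotif]:
    """Report K/Q-rich motifs in the N- and C-terminal windows.

    Within each terminal window the maximal-density subspan (ties: longer,
    then closer to the terminus) is reported when its K+Q fraction reaches
    ``min_kq``.
    """
    params = params or MotifParams()
    _, seq = _seq_of(protein)
    if len(seq) < params.terminal_window:
        raise SequenceError(
            f"protein shorter than terminal window {params.terminal_window}"
        )
    out: list[TerminalMotif] = []
    w = params.terminal_window
    for terminus, window, offset in (
        ("N", seq[:w], 0),
        ("C", seq[-w:], len(seq) - w),
    ):
        found = _best_kq_subspan(window, offset, params.min_length)
        if found is not None and found[2] >= params.min_kq:
            out.append(
                TerminalMotif(terminus=terminus, span=found[1], kq_fraction=found[2])
            )
    return out


def composition_table(proteins: list[ProteinRecord]):
    """Composition matrix (one row per protein) as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for p in proteins:
        prof = composition(p)
        row = {"protein_id": p.id, "length": prof.length}
        row.update({aa: round(prof.percent[aa], 2) for aa in AA_LETTERS})
        row["enriched"] = ",".join(sorted(enrichment_classes(prof))) or "-"
        rows.append(row)
    return pd.DataFrame(rows)
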