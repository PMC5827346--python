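"""Semiquantitative tissue expression by exact-match read counting.

A tBLASTn-style transcriptome screen: the whole amino acid sequence of
each candidate protein is used as a query, RNA-seq reads are translated in
all six frames, and a read is counted when one of its frame translations
shares a 100%-identical substring of at least ``min_match`` residues with
the query (default: the full translated read length).  Counts are
normalised against a ubiquitously expressed housekeeping control (ALAS1 is
the classic choice) rather than library size.  Each read counts at most
once per query.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_core import ProteinRecord, ReadRecord, SequenceError, translate


@dataclass
class ExpressionParams:
    min_match: int | None = None  # residues; None -> floor(read_length / 3)
    spec_fraction: float = 0.9  # share of normalised signal in one tissue
    min_total: int = 5  # raw reads below which a gene is 'undetected'


@dataclass
class ExpressionTable:
    """Read counts per (gene, tissue), zeros explicit, plus the control."""

    counts: pd.DataFrame  # columns: gene_id, tissue, read_count
    control_gene: str

    def count(self, gene_id: str, tissue: str) -> int:
        sel = self.counts[
            (self.counts.gene_id == gene_id) & (self.counts.tissue == tissue)
        ]
        return int(sel.read_count.iloc[0]) if len(sel) else 0

    def tissues(self) -> list[str]:
        return sorted(self.counts.tissue.unique())

    def per_tissue_totals(self) -> dict[str, int]:
        return self.counts.groupby("tissue").read_count.sum().to_dict()


def _frame_translations(read: str) -> list[str]:
    out = []
    for strand in "+-":
        for frame in range(3):
            if len(read) >= frame + 3:
                out.append(translate(read, frame, strand))
    return out


def count_exact_matches(
    query_protein,
    reads: list[ReadRecord],
    params: ExpressionParams | None = None,
) -> dict[str, int]:
    """Count reads matching the query at 100% identity, per tissue.

    A read counts iff one of its six frame translations contains a
    substring of >= ``min_match`` residues identical to a substring of the
    query.  With the default ``min_match`` this demands an entire
    translated read (full-read identity).
    """
    params = params or ExpressionParams()
    seq = (
        query_protein.sequence
        if isinstance(query_protein, ProteinRecord)
        else str(query_protein)
    )
    if not seq:
        raise SequenceError("empty query protein")
    counts: dict[str, int] = {}
    kmer_cache: dict[int, set[str]] = {}
    for read in reads:
        k = (
            params.min_match
            if params.min_match is not None
            else len(read.sequence) // 3
        )
        k = max(1, min(k, len(seq)))
        if k not in kmer_cache:
            kmer_cache[k] = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        kmers = kmer_cache[k]
        hit = False
        for aa in _frame_translations(read.sequence):
            if len(aa) < k:
                continue
            if any(aa[i : i + k] in kmers for i in range(len(aa) - k + 1)):
                hit = True
                break
        counts.setdefault(read.tissue, 0)
        if hit:
            counts[read.tissue] += 1
    return counts


def build_expression_table(
    queries: list[ProteinRecord],
    reads: list[ReadRecord],
    control_gene: str,
    params: ExpressionParams | None = None,
) -> ExpressionTable:
    """Exact-match counts for every query over tissue-labelled reads."""
    tissues = sorted({r.tissue for r in reads})
    rows = []
    for q in queries:
        per_tissue = count_exact_matches(q, reads, params)
        for t in tissues:
            rows.append(
                {"gene_id": q.id, "tissue": t, "read_count": per_tissue.get(t, 0)}
            )
    if control_gene not in {q.id for q in queries}:
        raise ValueError(f"control gene {control_gene!r} not among queries")
    return ExpressionTable(counts=pd.DataFrame(rows), control_gene=control_gene)


def tissue_specificity(
    table: ExpressionTable, params: ExpressionParams | None = None
) -> dict[str, str]:
    """Label each gene tissue-specific:<tissue>, broad, or undetected.

    Counts are normalised by the control gene's count in each tissue; a
    gene whose normalised signal concentrates (>= ``spec_fraction``) in one
    tissue is tissue-specific there.  Genes with fewer than ``min_total``
    raw reads overall are 'undetected'.
    """
    params = params or ExpressionParams()
    tissues = table.tissues()
    control = {t: table.count(table.control_gene, t) for t in tissues}
    missing = [t for t in tissues if control[t] == 0]
    if missing:
        raise ValueError(
            f"control gene {table.control_gene!r} has zero reads in "
            f"{missing}; normalisation undefined"
        )
    labels: dict[str, str] = {}
    for gene_id in table.counts.gene_id.unique():
        raw = {t: table.count(gene_id, t) for t in tissues}
        if sum(raw.values()) < params.min_total:
            labels[gene_id] = "undetected"
            continue
        norm = {t: raw[t] / control[t] for t in tissues}
        total = sum(norm.values())
        top = max(tissues, key=lambda t: (norm[t], t))
        if norm[top] / total >= params.spec_fraction:
            labels[gene_id] = f"tissue-specific:{top}"
        else:
            labels[gene_id] = "broad"
    return labels
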