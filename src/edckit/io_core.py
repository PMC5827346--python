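"""Sequence and annotation data model shared by every pipeline stage.

Conventions
-----------
* Internal coordinates are 0-based, half-open ``[start, end)`` on the forward
  strand of a scaffold.  All GFF3 emitted or consumed by this module is
  1-based inclusive, per the GFF3 standard.
* Gene models list exons in transcript orientation (5'->3' of the mRNA), so
  minus-strand models store exons in descending genomic order.
* Translation uses the standard nuclear genetic code; stop codons are
  rendered as ``*`` and any codon containing ``N`` translates to ``X``.
* Soft-masked (lowercase) sequence is uppercased on ingest; the homology
  search deliberately ignores low-complexity masking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]

DNA_ALPHABET = set("ACGTN")
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = set(AA_LETTERS) | {"X"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Codon -> amino acid map from the standard nuclear code.
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TABLE: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TABLE[_stop] = "*"


class SequenceError(ValueError):
    """Raised for malformed sequences or records."""


class GeneModelError(ValueError):
    """Raised when a gene model violates a structural invariant."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldRecord:
    """A genome scaffold: id, DNA sequence over {A,C,G,T,N}, species tag."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise SequenceError(f"scaffold {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise SequenceError(
                f"scaffold {self.id!r}: non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinRecord:
    """A protein sequence (20 letters + X), optionally tied to a gene."""

    id: str
    sequence: str
    source_gene: str | None = None
    species: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise SequenceError(f"protein {self.id!r}: empty sequence")
        if "*" in self.sequence:
            raise SequenceError(f"protein {self.id!r}: internal stop symbol")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise SequenceError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """A single RNA-seq read with its tissue of origin."""

    id: str
    sequence: str
    tissue: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise SequenceError(f"read {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise SequenceError(f"read {self.id!r}: non-DNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


GENE_CATEGORIES = ("SEDC", "SFTP", "CBP", "pseudogene", "marker")


@dataclass
class GeneModel:
    """An annotated gene: exons, coding span(s), category and completeness.

    ``exons`` and ``cds`` are lists of 0-based half-open intervals on the
    forward strand, ordered in transcript orientation.  SEDC genes carry
    their whole coding region on one exon; SFTP genes on exactly two.
    """

    id: str
    scaffold_id: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    category: str
    name: str = ""
    completeness: str = "complete"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"gene {self.id!r}: strand must be + or -")
        if self.category not in GENE_CATEGORIES:
            raise GeneModelError(
                f"gene {self.id!r}: unknown category {self.category!r}"
            )
        if self.completeness not in ("complete", "partial"):
            raise GeneModelError(
                f"gene {self.id!r}: completeness must be complete/partial"
            )
        self.exons = [tuple(e) for e in self.exons]
        self.cds = [tuple(c) for c in self.cds]

    # -- derived geometry ---------------------------------------------------

    @property
    def span(self) -> Interval:
        """Genomic footprint [min start, max end) over all exons."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return (min(starts), max(ends))

    @property
    def coding_span(self) -> Interval:
        starts = [s for s, _ in self.cds]
        ends = [e for _, e in self.cds]
        return (min(starts), max(ends))

    def n_coding_exons(self) -> int:
        return len(self.cds)

    def spliced_cds(self, scaffold_sequence: str) -> str:
        """Coding nucleotide sequence in reading orientation."""
        if self.strand == "+":
            return "".join(scaffold_sequence[s:e] for s, e in self.cds)
        # cds intervals are in transcript order (descending genomic coords)
        return "".join(
            reverse_complement(scaffold_sequence[s:e]) for s, e in self.cds
        )

    def spliced_transcript(self, scaffold_sequence: str) -> str:
        parts = [scaffold_sequence[s:e] for s, e in self.exons]
        mrna = "".join(parts) if self.strand == "+" else "".join(
            reverse_complement(scaffold_sequence[s:e]) for s, e in self.exons
        )
        return mrna

    def protein(self, scaffold_sequence: str) -> str:
        """Conceptual translation of the coding sequence (no trailing stop)."""
        aa = translate(self.spliced_cds(scaffold_sequence), 0, "+")
        return aa[:-1] if aa.endswith("*") else aa


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, frame: int = 0, strand: str = "+") -> str:
    """Translate ``dna`` codon-by-codon in the given frame and strand.

    Stops are rendered ``*``; codons containing N translate to ``X``.  The
    minus strand translates the reverse complement (frame offsets count from
    the 5' end of the reverse complement).
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be + or -, got {strand}")
    dna = dna.upper()
    bad = set(dna) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"non-DNA characters in input: {sorted(bad)}")
    if len(dna) < frame + 3:
        raise SequenceError(
            f"sequence of length {len(dna)} too short for frame {frame}"
        )
    if strand == "-":
        dna = reverse_complement(dna)
    out = []
    for i in range(frame, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def six_frame_translate(dna: str) -> list[tuple[int, str, str]]:
    """All six conceptual translations as (frame, strand, protein) tuples."""
    if len(dna) < 3:
        raise SequenceError("sequence shorter than one codon")
    frames = []
    for strand in "+-":
        for frame in range(3):
            if len(dna) >= frame + 3:
                frames.append((frame, strand, translate(dna, frame, strand)))
            else:
                frames.append((frame, strand, ""))
    return frames


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

_N_RUN = re.compile(r"N+")


def validate_gene_model(
    model: GeneModel, scaffold_sequence: str | None = None
) -> list[str]:
    """Check every structural invariant of a gene model.

    Raises :class:`GeneModelError` on violation.  Returns a list of warning
    strings for conditions that are suspicious but not fatal (currently:
    coding sequence overlapping an assembly-gap N run).
    """
    m = model
    if not m.exons:
        raise GeneModelError(f"gene {m.id!r}: no exons")
    if not m.cds:
        raise GeneModelError(f"gene {m.id!r}: no coding span")
    for s, e in m.exons + m.cds:
        if e <= s:
            raise GeneModelError(f"gene {m.id!r}: empty/inverted interval [{s},{e})")
    # transcript-orientation ordering and non-overlap
    keyed = m.exons if m.strand == "+" else [(-e, -s) for s, e in m.exons]
    for (s1, e1), (s2, e2) in zip(keyed, keyed[1:]):
        if s2 < e1:
            raise GeneModelError(
                f"gene {m.id!r}: exons overlap or are not in transcript order"
            )
    # CDS containment
    for c in m.cds:
        if not any(s <= c[0] and c[1] <= e for s, e in m.exons):
            raise GeneModelError(
                f"gene {m.id!r}: coding interval {c} not contained in an exon"
            )
    if m.category == "SEDC" and len(m.cds) != 1:
        raise GeneModelError(
            f"gene {m.id!r}: SEDC genes carry their coding region on one exon"
        )
    if m.category == "SFTP" and len(m.cds) != 2:
        raise GeneModelError(
            f"gene {m.id!r}: SFTP genes carry coding sequence on exactly two exons"
        )
    warnings: list[str] = []
    if scaffold_sequence is not None:
        lo, hi = m.span
        if hi > len(scaffold_sequence):
            raise GeneModelError(
                f"gene {m.id!r}: exceeds scaffold length {len(scaffold_sequence)}"
            )
        for run in _N_RUN.finditer(scaffold_sequence, lo, hi):
            if any(run.start() < e and s < run.end() for s, e in m.cds):
                warnings.append(
                    f"gene {m.id!r}: coding sequence overlaps N run at "
                    f"{run.start()}-{run.end()}"
                )
        if m.category not in ("pseudogene",) and m.completeness == "complete":
            aa = m.protein(scaffold_sequence)
            if not aa.startswith("M"):
                raise GeneModelError(
                    f"gene {m.id!r}: complete model does not start with M"
                )
            if "*" in aa:
                raise GeneModelError(
                    f"gene {m.id!r}: internal stop in complete model"
                )
    return warnings


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _check_unique_ids(ids: list[str], path) -> None:
    seen = set()
    for rid in ids:
        if rid in seen:
            raise SequenceError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)


def _prevalidate_fasta(path) -> None:
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                saw_header = True
                if len(line) == 1:
                    raise SequenceError(f"{path}:{lineno}: header with no id")
            elif not saw_header:
                raise SequenceError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )


def read_fasta(path, species: str = "") -> list[ScaffoldRecord]:
    """Read scaffold/DNA FASTA into :class:`ScaffoldRecord` objects."""
    _prevalidate_fasta(path)
    records = [
        ScaffoldRecord(rec.id, str(rec.seq), species)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_ids([r.id for r in records], path)
    return records


def read_protein_fasta(path, species: str = "") -> list[ProteinRecord]:
    _prevalidate_fasta(path)
    records = [
        ProteinRecord(rec.id, str(rec.seq).rstrip("*"), species=species)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_ids([r.id for r in records], path)
    return records


def write_fasta(records, path, width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_fastq(path, tissue: str = "") -> list[ReadRecord]:
    """Read a FASTQ file into tissue-labelled reads."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno % 4 == 1 and line.strip() and not line.startswith("@"):
                raise SequenceError(
                    f"{path}:{lineno}: expected FASTQ header starting with '@'"
                )
    records = [
        ReadRecord(rec.id, str(rec.seq), tissue)
        for rec in SeqIO.parse(str(path), "fastq")
    ]
    _check_unique_ids([r.id for r in records], path)
    return records


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (gene/exon/CDS rows, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            attrs = (
                f"ID={m.id};Name={m.name or m.id};category={m.category};"
                f"completeness={m.completeness}"
            )
            fh.write(
                f"{m.scaffold_id}\tedckit\tgene\t{lo + 1}\t{hi}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.scaffold_id}\tedckit\texon\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\tID={m.id}.exon{i};Parent={m.id}\n"
                )
            phase = 0
            for i, (s, e) in enumerate(m.cds, 1):
                fh.write(
                    f"{m.scaffold_id}\tedckit\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t{phase}\tID={m.id}.cds{i};Parent={m.id}\n"
                )
                phase = (3 - ((e - s) - phase) % 3) % 3


def _parse_attrs(field9: str) -> dict[str, str]:
    out = {}
    for part in field9.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[GeneModel]:
    """Parse GFF3 written by :func:`write_gff3` back into gene models."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise SequenceError(
                    f"{path}:{lineno}: expected {_GFF_COLS} columns, got {len(cols)}"
                )
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise SequenceError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if end < start:
                raise SequenceError(f"{path}:{lineno}: end < start")
            iv = (start - 1, end)  # to 0-based half-open
            attrs = _parse_attrs(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise SequenceError(f"{path}:{lineno}: gene row without ID")
                if gid in genes:
                    raise SequenceError(f"{path}:{lineno}: duplicate gene id {gid!r}")
                genes[gid] = {
                    "scaffold": seqid,
                    "strand": strand,
                    "exons": [],
                    "cds": [],
                    "name": attrs.get("Name", gid),
                    "category": attrs.get("category", "SEDC"),
                    "completeness": attrs.get("completeness", "complete"),
                }
                order.append(gid)
            elif ftype in ("exon", "CDS"):
                parent = attrs.get("Parent")
                if parent is None or parent not in genes:
                    raise SequenceError(
                        f"{path}:{lineno}: {ftype} row without known Parent"
                    )
                genes[parent]["exons" if ftype == "exon" else "cds"].append(iv)
    models = []
    for gid in order:
        g = genes[gid]
        rev = g["strand"] == "-"
        models.append(
            GeneModel(
                id=gid,
                scaffold_id=g["scaffold"],
                strand=g["strand"],
                exons=sorted(g["exons"], reverse=rev),
                cds=sorted(g["cds"], reverse=rev),
                category=g["category"],
                name=g["name"],
                completeness=g["completeness"],
            )
        )
    return models
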