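"""Ground-truthed synthetic EDC-like loci, ortholog pairs and tissue reads.

The generator emulates the genomic architecture of the epidermal
differentiation complex as found in archosaur genomes: a gene-dense locus
flanked by two S100A marker genes, populated by single-coding-exon (SEDC)
genes whose proteins are strongly biased toward G/S/P/K/C/Q, two-coding-exon
S100-fused-type (SFTP) genes, a tandem corneous-beta-protein-like (CBP)
cluster, and pseudogenes disrupted by premature stops and frameshifts.  Each
SEDC/SFTP gene carries the canonical anatomy: TATA box, 5' noncoding exon,
GT...AG intron, then the coding exon(s).

Every emitted scaffold comes with a :class:`GroundTruth` whose gene models
pass the io_core validator and whose proteins equal the translation of the
planted coding spans, so downstream predictors can be scored exactly.

Two deliberate structural guarantees keep the ground truth unambiguous:

* each planted start codon is immediately preceded by an in-frame stop, so
  the annotated ATG is the first ATG of its open reading frame;
* pseudogenes receive a premature stop followed by a single-nucleotide
  deletion, so no full-length stop-free translation survives and fragments
  of the broken frame do not resurface as spurious intact genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io_core import (
    CODON_TABLE,
    GeneModel,
    ReadRecord,
    ScaffoldRecord,
    reverse_complement,
    translate,
    validate_gene_model,
)

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

# residues favoured in EDC proteins; remaining mass is spread uniformly
DEFAULT_BIAS = {"G": 0.14, "S": 0.12, "P": 0.11, "K": 0.09, "C": 0.11, "Q": 0.09}

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# synonymous codons per residue (standard code)
SYNONYMOUS: dict[str, list[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    SYNONYMOUS.setdefault(_aa, []).append(_codon)
STOP_CODONS = tuple(sorted(SYNONYMOUS["*"]))

DEFAULT_TISSUES = ("skin", "heart", "liver")


@dataclass
class RepeatGeneSpec:
    """An EDCRP-like gene: conserved termini around a tandem peptide repeat."""

    unit: str = "CCDPCQKTV"
    copies: int = 8
    nterm_len: int = 40
    cterm_len: int = 40


@dataclass
class SyntheticConfig:
    """All tunable knobs of the locus generator.  ``seed`` is mandatory."""

    seed: int
    n_sedc: int = 20
    n_sftp: int = 2
    n_cbp_cluster: int = 6
    n_pseudogenes: int = 4
    composition_bias: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BIAS)
    )
    intergenic_length_range: Interval = (300, 800)
    tata_offset_range: Interval = (25, 35)
    intron_length_range: Interval = (300, 700)
    utr_length_range: Interval = (9, 30)
    noncoding_exon_length_range: Interval = (60, 120)
    protein_length_range: Interval = (80, 180)
    repeat_gene: RepeatGeneSpec | None = None
    fragmentation: list[int] | None = None  # cut before these locus-order indices
    read_length: int = 100
    reads_per_tissue: dict[str, int] = field(
        default_factory=lambda: {t: 300 for t in DEFAULT_TISSUES}
    )
    expression_profile: dict[str, dict[str, float]] | None = None
    read_error_rate: float = 0.0
    cbp_paralog_divergence: float = 0.15  # aa divergence between cluster copies
    ablate_tata_genes: tuple[int, ...] = ()  # SEDC indices built without TATA
    species: str = "synthA"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_sedc", "n_sftp", "n_cbp_cluster", "n_pseudogenes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if sum(self.composition_bias.values()) > 1.0 + 1e-9:
            raise ValueError("composition_bias fractions must sum to <= 1")


@dataclass
class GeneFeatures:
    """Promoter/splice bookkeeping for one planted gene (forward coords)."""

    tata: Interval | None = None
    tss: int | None = None
    introns: list[Interval] = field(default_factory=list)


@dataclass
class GroundTruth:
    genes: list[GeneModel] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)
    transcripts: dict[str, str] = field(default_factory=dict)
    features: dict[str, GeneFeatures] = field(default_factory=dict)
    gene_order: list[str] = field(default_factory=list)
    read_origins: dict[str, tuple[str, str]] = field(default_factory=dict)
    read_starts: dict[str, int] = field(default_factory=dict)  # transcript offset
    control_gene: str = ""
    marker_ids: tuple[str, str] = ("", "")
    region: list[tuple[str, Interval]] = field(default_factory=list)
    expression: dict[str, dict[str, float]] = field(default_factory=dict)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def intact_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.category in ("SEDC", "SFTP", "CBP")]


# ---------------------------------------------------------------------------
# low-level sampling helpers
# ---------------------------------------------------------------------------


def _aa_distribution(bias: dict[str, float]) -> tuple[list[str], np.ndarray]:
    probs = {}
    rest = [a for a in AA20 if a not in bias]
    remaining = 1.0 - sum(bias.values())
    for a in AA20:
        probs[a] = bias.get(a, remaining / len(rest))
    letters = list(AA20)
    p = np.array([probs[a] for a in letters])
    return letters, p / p.sum()


def _sample_protein(rng, length: int, bias: dict[str, float]) -> str:
    letters, p = _aa_distribution(bias)
    body = rng.choice(letters, size=length - 1, p=p)
    return "M" + "".join(body)


def _codons_for(rng, protein: str) -> str:
    return "".join(
        SYNONYMOUS[aa][rng.integers(len(SYNONYMOUS[aa]))] for aa in protein
    )


def _random_dna(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length)) if length > 0 else ""


def _scrub_motif(rng, seq: str, motifs: tuple[str, ...]) -> str:
    """Resample until none of ``motifs`` (with W-wildcards) occurs."""
    import re

    pats = [re.compile(m.replace("W", "[AT]")) for m in motifs]
    s = list(seq)
    for _ in range(100):
        hit = None
        for pat in pats:
            mobj = pat.search("".join(s))
            if mobj:
                hit = mobj
                break
        if hit is None:
            return "".join(s)
        for k in range(hit.start(), hit.end()):
            s[k] = "ACGT"[rng.integers(4)]
    return "".join(s)


# ---------------------------------------------------------------------------
# gene block builders (plus-strand layout; flipped afterwards if needed)
# ---------------------------------------------------------------------------


@dataclass
class _Block:
    """A plus-oriented gene cassette with local (block-relative) coordinates."""

    sequence: str
    exons: list[Interval]
    cds: list[Interval]
    features: GeneFeatures
    protein: str


def _uni(rng, lohi: Interval) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _build_intron(rng, cfg: SyntheticConfig) -> str:
    n = _uni(rng, cfg.intron_length_range)
    return "GT" + _random_dna(rng, n - 4) + "AG"


def _build_sedc_block(
    rng,
    cfg: SyntheticConfig,
    protein: str,
    *,
    with_tata: bool = True,
    category_intronless: bool = False,
) -> _Block:
    """[TATA]-[noncoding exon]-[GT..AG]-[UTR+stop]-[ATG..stop] cassette."""
    codons = _codons_for(rng, protein)
    cds_nt = codons + STOP_CODONS[rng.integers(len(STOP_CODONS))]
    if category_intronless:
        pad = _random_dna(rng, 20) + "TAA"  # in-frame stop directly upstream
        seq = pad + cds_nt
        cds = (len(pad), len(seq))
        return _Block(
            sequence=seq,
            exons=[cds],
            cds=[cds],
            features=GeneFeatures(),
            protein=protein,
        )
    tata_offset = _uni(rng, cfg.tata_offset_range)
    nc_len = _uni(rng, cfg.noncoding_exon_length_range)
    utr = _uni(rng, cfg.utr_length_range)
    nc_exon = _random_dna(rng, nc_len)
    intron = _build_intron(rng, cfg)
    utr_seq = _random_dna(rng, utr - 3) + "TAA"
    if with_tata:
        head = "TATAAA" + _random_dna(rng, tata_offset - 6)
    else:
        # an ablated promoter must carry no chance TATA anywhere the
        # predictor's promoter scan can reach
        head = _scrub_motif(rng, _random_dna(rng, tata_offset), ("TATAWA",))
        nc_exon = _scrub_motif(rng, nc_exon, ("TATAWA",))
        intron = (
            "GT" + _scrub_motif(rng, intron[2:-2], ("TATAWA",)) + "AG"
        )
        utr_seq = (
            _scrub_motif(rng, utr_seq[:-3], ("TATAWA",)) + "TAA"
        )
    parts = [head, nc_exon, intron, utr_seq, cds_nt]
    offs = np.cumsum([0] + [len(p) for p in parts])
    seq = "".join(parts)
    tss = int(offs[1])
    exon1 = (tss, int(offs[2]))
    exon2 = (int(offs[3]), int(offs[5]))
    cds = (int(offs[4]), int(offs[5]))
    feats = GeneFeatures(
        tata=(0, 6) if with_tata else None,
        tss=tss,
        introns=[(int(offs[2]), int(offs[3]))],
    )
    return _Block(seq, [exon1, exon2], [cds], feats, protein)


def _build_sftp_block(rng, cfg: SyntheticConfig, protein: str) -> _Block:
    """Two-coding-exon cassette with a phase-0 intron inside the CDS."""
    codons = [
        SYNONYMOUS[aa][rng.integers(len(SYNONYMOUS[aa]))] for aa in protein
    ]
    split = int(rng.integers(len(protein) // 3, 2 * len(protein) // 3))
    cds1 = "".join(codons[:split])
    cds2 = "".join(codons[split:]) + STOP_CODONS[rng.integers(len(STOP_CODONS))]
    tata_offset = _uni(rng, cfg.tata_offset_range)
    nc_len = _uni(rng, cfg.noncoding_exon_length_range)
    utr = _uni(rng, cfg.utr_length_range)
    head = "TATAAA" + _random_dna(rng, tata_offset - 6)
    nc_exon = _random_dna(rng, nc_len)
    intron1 = _build_intron(rng, cfg)
    utr_seq = _random_dna(rng, utr - 3) + "TAA"
    intron2 = _build_intron(rng, cfg)
    parts = [head, nc_exon, intron1, utr_seq, cds1, intron2, cds2]
    offs = np.cumsum([0] + [len(p) for p in parts])
    seq = "".join(parts)
    tss = int(offs[1])
    exon1 = (tss, int(offs[2]))
    exon2 = (int(offs[3]), int(offs[5]))  # UTR + first coding chunk
    exon3 = (int(offs[6]), int(offs[7]))
    cds = [(int(offs[4]), int(offs[5])), (int(offs[6]), int(offs[7]))]
    feats = GeneFeatures(
        tata=(0, 6),
        tss=tss,
        introns=[(int(offs[2]), int(offs[3])), (int(offs[5]), int(offs[6]))],
    )
    return _Block(seq, [exon1, exon2, exon3], cds, feats, protein)


def _surviving_orfs(seq: str, min_codons: int) -> list[tuple[int, int]]:
    """ATG-initiated stop-free ORFs of >= min_codons in any of six frames.

    Returned spans are on the given (forward) sequence in codon units
    convertible to nucleotides; used to verify pseudogene decay.
    """
    spans = []
    L = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for frame in range(3):
            if L < frame + 3:
                continue
            prot = translate(s, frame, "+")
            start = None
            for i, aa in enumerate(prot + "*"):
                if aa == "*" or i == len(prot):
                    if start is not None and i - start >= min_codons:
                        nt0 = frame + 3 * start
                        nt1 = frame + 3 * i
                        if strand == "-":
                            nt0, nt1 = L - nt1, L - nt0
                        spans.append((nt0, nt1, strand))
                    start = None
                elif aa == "M" and start is None:
                    start = i
    return spans


def _pseudogenize(rng, block: _Block) -> _Block:
    """Disrupt a gene cassette beyond repair.

    A premature stop plus a 1-nt deletion break the annotated frame; the
    sequence is then further decayed (stop codons planted mid-ORF) until no
    ATG-initiated stop-free ORF of >= 40 codons survives in any frame, as
    expected of a pseudogene with no functional reading frame left.
    """
    (c0, c1) = block.cds[0]
    n_codons = (c1 - c0) // 3
    k = int(rng.integers(12, max(13, min(40, n_codons - 10))))
    pos = c0 + 3 * k
    seq = block.sequence[:pos] + "TAA" + block.sequence[pos + 3 :]
    # frameshift just downstream of the premature stop
    seq = seq[: pos + 3] + seq[pos + 4 :]
    shift = -1

    def adj(x: int) -> int:
        return x + shift if x > pos + 3 else x

    exons = [(s, adj(e)) for s, e in block.exons]
    cds = [(s, adj(e)) for s, e in block.cds]
    for _ in range(60):
        orfs = _surviving_orfs(seq, 40)
        if not orfs:
            break
        nt0, nt1, strand = orfs[0]
        mid = (nt0 + nt1) // 2
        mid -= (mid - nt0) % 3  # stay in the ORF's frame
        stop = "TAA" if strand == "+" else "TTA"  # revcomp on minus strand
        if (nt1 - nt0) // 3 >= 3:
            seq = seq[:mid] + stop + seq[mid + 3 :]
    feats = replace(block.features)
    return _Block(seq, exons, cds, feats, block.protein)


def _flip_block(block: _Block) -> _Block:
    """Reverse-complement a cassette; intervals flip, exon order reverses."""
    n = len(block.sequence)

    def flip(iv: Interval) -> Interval:
        return (n - iv[1], n - iv[0])

    feats = GeneFeatures(
        tata=flip(block.features.tata) if block.features.tata else None,
        tss=(n - block.features.tss) if block.features.tss is not None else None,
        introns=[flip(iv) for iv in block.features.introns],
    )
    return _Block(
        sequence=reverse_complement(block.sequence),
        exons=[flip(iv) for iv in block.exons],  # stays transcript-ordered
        cds=[flip(iv) for iv in block.cds],
        features=feats,
        protein=block.protein,
    )


# ---------------------------------------------------------------------------
# locus assembly
# ---------------------------------------------------------------------------


def _mutate_protein(rng, protein: str, fraction: float) -> str:
    letters = list(AA20)
    out = list(protein)
    n_mut = int(round(fraction * (len(protein) - 1)))
    sites = rng.choice(np.arange(1, len(protein)), size=n_mut, replace=False)
    for s in sites:
        choices = [a for a in letters if a != out[s]]
        out[s] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_edc_locus(
    config: SyntheticConfig,
) -> tuple[list[ScaffoldRecord], GroundTruth]:
    """Emit a synthetic EDC locus and its ground truth.

    Gene order: 5' S100A12-like marker, SEDC genes (plus an optional
    EDCRP-like repeat gene), SFTP genes, the CBP cluster, pseudogenes,
    3' S100A11-like marker, and an ALAS1-like housekeeping control outside
    the inter-marker region.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0xED0])
    plan: list[tuple[str, str, str, _Block]] = []  # (id, name, category, block)
    gid = 0

    def next_id() -> str:
        nonlocal gid
        gid += 1
        return f"{cfg.species}_g{gid:03d}"

    def marker_block(name: str) -> _Block:
        prot = _sample_protein(rng, 100, {})
        return _build_sedc_block(rng, cfg, prot, category_intronless=True)

    plan.append((next_id(), "S100A12L", "marker", marker_block("S100A12L")))

    for i in range(cfg.n_sedc):
        length = _uni(rng, cfg.protein_length_range)
        prot = _sample_protein(rng, length, cfg.composition_bias)
        blk = _build_sedc_block(
            rng, cfg, prot, with_tata=i not in cfg.ablate_tata_genes
        )
        plan.append((next_id(), f"EDS{i + 1}", "SEDC", blk))

    if cfg.repeat_gene is not None:
        rg = cfg.repeat_gene
        nterm = _sample_protein(rng, rg.nterm_len, cfg.composition_bias)
        cterm = _sample_protein(rng, rg.cterm_len + 1, cfg.composition_bias)[1:]
        prot = nterm + rg.unit * rg.copies + cterm
        blk = _build_sedc_block(rng, cfg, prot)
        plan.append((next_id(), "EDCRPL1", "SEDC", blk))

    for i, nm in zip(range(cfg.n_sftp), ("CRNN", "SCFN", "SFTP3", "SFTP4")):
        length = _uni(rng, cfg.protein_length_range)
        prot = _sample_protein(rng, length, cfg.composition_bias)
        plan.append((next_id(), nm, "SFTP", _build_sftp_block(rng, cfg, prot)))

    if cfg.n_cbp_cluster > 0:
        base_len = _uni(rng, cfg.protein_length_range)
        base = _sample_protein(rng, base_len, cfg.composition_bias)
        for i in range(cfg.n_cbp_cluster):
            prot = (
                base
                if i == 0
                else _mutate_protein(rng, base, cfg.cbp_paralog_divergence)
            )
            blk = _build_sedc_block(rng, cfg, prot)
            plan.append((next_id(), f"CBP{i + 1}", "CBP", blk))

    for i in range(cfg.n_pseudogenes):
        length = _uni(rng, cfg.protein_length_range)
        prot = _sample_protein(rng, length, cfg.composition_bias)
        blk = _pseudogenize(rng, _build_sedc_block(rng, cfg, prot))
        plan.append((next_id(), f"EDPS{i + 1}", "pseudogene", blk))

    plan.append((next_id(), "S100A11L", "marker", marker_block("S100A11L")))
    plan.append((next_id(), "ALAS1L", "marker", marker_block("ALAS1L")))

    # ---- lay blocks on the scaffold, random strand per gene ----
    seq_parts: list[str] = []
    pos = 0
    placed: list[tuple[str, str, str, _Block, int, str]] = []
    scrub_next_gap = False  # 5' intergenic of a minus-strand ablated gene
    for rec_id, name, category, blk in plan:
        strand = "+" if rng.random() < 0.5 else "-"
        ablated = category == "SEDC" and blk.features.tata is None
        gap = _random_dna(rng, _uni(rng, cfg.intergenic_length_range))
        if scrub_next_gap or (ablated and strand == "+"):
            gap = _scrub_motif(rng, gap, ("TATAWA", "TWTATA"))
        scrub_next_gap = ablated and strand == "-"
        seq_parts.append(gap)
        pos += len(gap)
        placed_blk = blk if strand == "+" else _flip_block(blk)
        seq_parts.append(placed_blk.sequence)
        placed.append((rec_id, name, category, placed_blk, pos, strand))
        pos += len(placed_blk.sequence)
    tail_gap = _random_dna(rng, _uni(rng, cfg.intergenic_length_range))
    if scrub_next_gap:
        tail_gap = _scrub_motif(rng, tail_gap, ("TATAWA", "TWTATA"))
    seq_parts.append(tail_gap)
    scaffold_seq = "".join(seq_parts)

    truth = GroundTruth(expression=dict(cfg.expression_profile or {}))
    scaffold_id = f"{cfg.species}_scf1"
    models: list[GeneModel] = []
    for rec_id, name, category, blk, off, strand in placed:
        exons = [(s + off, e + off) for s, e in blk.exons]
        cds = [(s + off, e + off) for s, e in blk.cds]
        feats = GeneFeatures(
            tata=(blk.features.tata[0] + off, blk.features.tata[1] + off)
            if blk.features.tata
            else None,
            tss=(blk.features.tss + off) if blk.features.tss is not None else None,
            introns=[(s + off, e + off) for s, e in blk.features.introns],
        )
        model = GeneModel(
            id=rec_id,
            scaffold_id=scaffold_id,
            strand=strand,
            exons=exons,
            cds=cds,
            category=category,
            name=name,
        )
        models.append(model)
        truth.features[rec_id] = feats
        truth.proteins[rec_id] = blk.protein
        truth.gene_order.append(rec_id)

    truth.genes = models
    truth.marker_ids = (models[0].id, models[-2].id)
    truth.control_gene = models[-1].id

    scaffolds = [ScaffoldRecord(scaffold_id, scaffold_seq, cfg.species)]
    # inter-marker region on the single scaffold
    m5, m3 = models[0], models[-2]
    truth.region = [(scaffold_id, (m5.span[1], m3.span[0]))]

    if cfg.fragmentation:
        scaffolds, models = _fragment(
            cfg, scaffold_seq, models, sorted(set(cfg.fragmentation)), truth
        )
        truth.genes = models

    # transcripts + consistency checks
    seq_by_id = {s.id: s.sequence for s in scaffolds}
    for m in truth.genes:
        sseq = seq_by_id[m.scaffold_id]
        validate_gene_model(m, sseq)
        truth.transcripts[m.id] = m.spliced_transcript(sseq)
        if m.category != "pseudogene":
            assert m.protein(sseq) == truth.proteins[m.id], m.id
    return scaffolds, truth


def _fragment(cfg, seq, models, breaks, truth):
    """Cut the scaffold between genes at the requested locus-order indices."""
    cutpoints = []
    for b in breaks:
        if not (1 <= b < len(models)):
            raise ValueError(f"fragmentation index {b} out of range")
        prev_end = models[b - 1].span[1]
        nxt_start = models[b].span[0]
        cutpoints.append((prev_end + nxt_start) // 2)
    pieces = []
    starts = [0] + cutpoints
    ends = cutpoints + [len(seq)]
    new_models = []
    id2scf = {}
    for k, (s, e) in enumerate(zip(starts, ends), 1):
        scf_id = f"{cfg.species}_scf{k}"
        pieces.append(ScaffoldRecord(scf_id, seq[s:e], cfg.species))
        for m in models:
            if s <= m.span[0] and m.span[1] <= e:
                shifted = GeneModel(
                    id=m.id,
                    scaffold_id=scf_id,
                    strand=m.strand,
                    exons=[(a - s, b2 - s) for a, b2 in m.exons],
                    cds=[(a - s, b2 - s) for a, b2 in m.cds],
                    category=m.category,
                    name=m.name,
                    completeness=m.completeness,
                )
                new_models.append(shifted)
                id2scf[m.id] = (scf_id, s)
    for gid2, feats in truth.features.items():
        if gid2 in id2scf:
            _, s = id2scf[gid2]
            feats.tata = (
                (feats.tata[0] - s, feats.tata[1] - s) if feats.tata else None
            )
            feats.tss = feats.tss - s if feats.tss is not None else None
            feats.introns = [(a - s, b2 - s) for a, b2 in feats.introns]
    # region truth becomes per-fragment segments between the markers
    m5_id, m3_id = truth.marker_ids
    by_id = {m.id: m for m in new_models}
    m5, m3 = by_id[m5_id], by_id[m3_id]
    region = []
    for piece in pieces:
        lo, hi = 0, len(piece.sequence)
        if piece.id == m5.scaffold_id:
            lo = m5.span[1]
        if piece.id == m3.scaffold_id:
            hi = m3.span[0]
        has_locus_gene = any(
            m.scaffold_id == piece.id and m.id not in (truth.control_gene,)
            for m in new_models
        )
        if has_locus_gene and hi > lo:
            region.append((piece.id, (lo, hi)))
    truth.region = region
    return pieces, new_models


# ---------------------------------------------------------------------------
# ortholog pair
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def _substitute_base(rng, base: str) -> str:
    """Replacement base under a 2:1 transition:transversion bias."""
    r = rng.random()
    if r < 0.5:
        return _TRANSITION[base]
    tv = _TRANSVERSIONS[base]
    return tv[0] if r < 0.75 else tv[1]


def synonymous_single_change_fraction(codons: list[str]) -> float:
    """Exact fraction of single-nucleotide changes that are synonymous,
    averaged over the given codons under the 2:1 transition bias and
    conditioned on not creating a stop codon.

    This is the closed-form ingredient of the expected ortholog protein
    identity: p(residue identical) ~= (1-d)^3 + 3 d (1-d)^2 * f_syn.
    """
    syn_w = 0.0
    tot_w = 0.0
    for codon in codons:
        for i in range(3):
            for new, w in [(_TRANSITION[codon[i]], 0.5)] + [
                (tv, 0.25) for tv in _TRANSVERSIONS[codon[i]]
            ]:
                mutated = codon[:i] + new + codon[i + 1 :]
                if CODON_TABLE[mutated] == "*":
                    continue  # stop-avoiding simulation rejects these
                tot_w += w
                if CODON_TABLE[mutated] == CODON_TABLE[codon]:
                    syn_w += w
    return syn_w / tot_w if tot_w else 0.0


def generate_ortholog_pair(
    config: SyntheticConfig,
    divergence: float,
    repeat_expansion: int = 0,
    species_b: str = "synthB",
) -> tuple[
    tuple[list[ScaffoldRecord], GroundTruth],
    tuple[list[ScaffoldRecord], GroundTruth],
    dict[str, str],
]:
    """Derive a diverged second locus from a generated one.

    Per-site substitution at rate ``divergence`` with a 2:1 transition bias;
    coding substitutions never create stops, and functional anchors (start
    and stop codons, splice dinucleotides, TATA boxes) are preserved so the
    ortholog truth map pairs intact genes.  The designated repeat gene in
    locus B carries ``repeat_expansion`` extra tandem units.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    cfg = config
    if repeat_expansion and cfg.repeat_gene is None:
        cfg = replace(cfg, repeat_gene=RepeatGeneSpec())
    scaffolds_a, truth_a = generate_edc_locus(cfg)
    rng = np.random.default_rng([cfg.seed, 0x0B])

    seqs = {s.id: list(s.sequence) for s in scaffolds_a}
    models_b = {
        m.id: GeneModel(
            id=m.id.replace(cfg.species, species_b, 1),
            scaffold_id=m.scaffold_id.replace(cfg.species, species_b, 1),
            strand=m.strand,
            exons=list(m.exons),
            cds=list(m.cds),
            category=m.category,
            name=m.name,
            completeness=m.completeness,
        )
        for m in truth_a.genes
    }

    # --- repeat expansion: insert extra units into the repeat gene's CDS ---
    if repeat_expansion:
        rg = cfg.repeat_gene
        target = next(m for m in truth_a.genes if m.name == "EDCRPL1")
        unit_nt = _codons_for(rng, rg.unit * repeat_expansion)
        c0, c1 = target.cds[0]
        # insertion point at the 3' end of the existing repeat array
        offset_aa = rg.nterm_len + rg.copies * len(rg.unit)
        if target.strand == "+":
            ins = c0 + 3 * offset_aa
            ins_seq = unit_nt
        else:
            ins = c1 - 3 * offset_aa
            ins_seq = reverse_complement(unit_nt)
        scf = target.scaffold_id
        seqs[scf][ins:ins] = list(ins_seq)
        delta = len(ins_seq)

        def shift(iv: Interval) -> Interval:
            s, e = iv
            return (
                s + delta if s >= ins else s,
                e + delta if e > ins else e,
            )

        for m in models_b.values():
            if m.scaffold_id.replace(species_b, cfg.species, 1) == scf:
                m.exons = [shift(iv) for iv in m.exons]
                m.cds = [shift(iv) for iv in m.cds]

    # --- protected positions (relative to possibly-shifted B coordinates) ---
    protected: dict[str, set[int]] = {s.id: set() for s in scaffolds_a}
    scf_of = {
        m.id: m.scaffold_id.replace(species_b, cfg.species, 1)
        for m in models_b.values()
    }
    coding_pos: dict[str, set[int]] = {s.id: set() for s in scaffolds_a}
    for mb in models_b.values():
        scf = scf_of[mb.id]
        for s, e in mb.cds:
            coding_pos[scf].update(range(s, e))
        lo, hi = mb.coding_span
        # start codon and stop codon ends
        if mb.strand == "+":
            protected[scf].update(range(lo, lo + 3))
            protected[scf].update(range(hi - 3, hi))
        else:
            protected[scf].update(range(hi - 3, hi))
            protected[scf].update(range(lo, lo + 3))
        # splice dinucleotides around exon gaps (genomic order)
        genomic = sorted(mb.exons)
        for (s1, e1), (s2, _) in zip(genomic, genomic[1:]):
            protected[scf].update(range(e1, e1 + 2))
            protected[scf].update(range(s2 - 2, s2))
    for gid2, feats in truth_a.features.items():
        if feats.tata:
            mb = models_b[gid2]
            delta_ok = True  # tata positions lie upstream of any insertion
            protected[scf_of[mb.id]].update(range(*feats.tata))

    # --- apply substitutions, codon-aware inside CDS ---
    for scf_id, chars in seqs.items():
        hit = np.nonzero(rng.random(len(chars)) < divergence)[0]
        coding = coding_pos[scf_id]
        prot = protected[scf_id]
        # map coding position -> owning gene for codon lookups
        owner: dict[int, GeneModel] = {}
        for mb in models_b.values():
            if scf_of[mb.id] == scf_id:
                for s, e in mb.cds:
                    for p in range(s, e):
                        owner[p] = mb
        for p in hit:
            p = int(p)
            if p in prot:
                continue
            old = chars[p]
            if old == "N":
                continue
            new = _substitute_base(rng, old)
            if p in coding:
                mb = owner[p]
                if mb.category != "pseudogene" and _creates_stop(chars, mb, p, new):
                    continue
            chars[p] = new

    scaffolds_b = [
        ScaffoldRecord(
            s.id.replace(cfg.species, species_b, 1), "".join(seqs[s.id]), species_b
        )
        for s in scaffolds_a
    ]
    truth_b = GroundTruth(
        genes=sorted(models_b.values(), key=lambda m: m.span[0]),
        control_gene=truth_a.control_gene.replace(cfg.species, species_b, 1),
        marker_ids=tuple(
            mid.replace(cfg.species, species_b, 1) for mid in truth_a.marker_ids
        ),
        region=[
            (sid.replace(cfg.species, species_b, 1), iv)
            for sid, iv in truth_a.region
        ],
        expression=dict(truth_a.expression),
    )
    truth_b.gene_order = [
        g.replace(cfg.species, species_b, 1) for g in truth_a.gene_order
    ]
    seq_by_id = {s.id: s.sequence for s in scaffolds_b}
    for m in truth_b.genes:
        sseq = seq_by_id[m.scaffold_id]
        validate_gene_model(m, sseq)
        truth_b.transcripts[m.id] = m.spliced_transcript(sseq)
        if m.category != "pseudogene":
            truth_b.proteins[m.id] = m.protein(sseq)
    ortholog_map = {
        a: a.replace(cfg.species, species_b, 1) for a in truth_a.gene_order
    }
    return (scaffolds_a, truth_a), (scaffolds_b, truth_b), ortholog_map


def _creates_stop(chars, model: GeneModel, pos: int, new: str) -> bool:
    """Would substituting chars[pos] = new create an in-frame stop?"""
    # transcript-order CDS positions
    order = model.cds if model.strand == "+" else model.cds
    positions: list[int] = []
    for s, e in sorted(model.cds):
        positions.extend(range(s, e))
    if model.strand == "-":
        positions = positions[::-1]
    idx = positions.index(pos) if pos in set(positions) else -1
    if idx < 0:
        return False
    cstart = idx - idx % 3
    codon = []
    for k in range(cstart, cstart + 3):
        p = positions[k]
        base = new if p == pos else chars[p]
        if model.strand == "-":
            base = reverse_complement(base)
        codon.append(base)
    return CODON_TABLE["".join(codon)] == "*"


# ---------------------------------------------------------------------------
# tissue reads
# ---------------------------------------------------------------------------


def default_expression_profile(truth: GroundTruth) -> dict[str, dict[str, float]]:
    """EDC genes skin-only; the ALAS1-like control uniform across tissues."""
    profile: dict[str, dict[str, float]] = {}
    for g in truth.genes:
        if g.category in ("SEDC", "SFTP", "CBP"):
            profile[g.id] = {"skin": 1.0}
    profile[truth.control_gene] = {t: 1.0 for t in DEFAULT_TISSUES}
    return profile


def generate_tissue_reads(
    scaffolds: list[ScaffoldRecord],
    truth: GroundTruth,
    config: SyntheticConfig,
) -> dict[str, list[ReadRecord]]:
    """Sample error-free reads from spliced transcripts, per tissue.

    Counts per (gene, tissue) are multinomial under the expression profile;
    reads are exact substrings of the spliced transcript, so genes with a
    noncoding 5' exon naturally yield intron-spanning reads.  Origins are
    recorded in ``truth.read_origins``.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0x5EAD])
    profile = cfg.expression_profile or default_expression_profile(truth)
    unknown = set(profile) - set(truth.transcripts)
    if unknown:
        raise ValueError(f"expression profile references unknown genes: {unknown}")
    truth.expression = profile
    out: dict[str, list[ReadRecord]] = {}
    for tissue, n_reads in cfg.reads_per_tissue.items():
        genes, weights = [], []
        for gid2, tis_w in profile.items():
            w = tis_w.get(tissue, 0.0)
            if w <= 0:
                continue
            if len(truth.transcripts[gid2]) < cfg.read_length:
                logger.warning(
                    "gene %s transcript shorter than read length; skipped", gid2
                )
                continue
            genes.append(gid2)
            weights.append(w)
        reads: list[ReadRecord] = []
        if genes and n_reads > 0:
            p = np.array(weights) / sum(weights)
            counts = rng.multinomial(n_reads, p)
            idx = 0
            for gid2, cnt in zip(genes, counts):
                tx = truth.transcripts[gid2]
                for _ in range(cnt):
                    start = int(rng.integers(0, len(tx) - cfg.read_length + 1))
                    seq = tx[start : start + cfg.read_length]
                    if cfg.read_error_rate > 0:
                        seq = _with_errors(rng, seq, cfg.read_error_rate)
                    rid = f"{tissue}_r{idx:05d}"
                    idx += 1
                    reads.append(ReadRecord(rid, seq, tissue))
                    truth.read_origins[rid] = (gid2, tissue)
                    truth.read_starts[rid] = start
        out[tissue] = reads
    return out


def _with_errors(rng, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = _substitute_base(rng, chars[i])
    return "".join(chars)
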