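"""Locus delimitation, de novo gene prediction and read validation."""

import pytest

from edckit.homology_search import AlignmentHit
from edckit.io_core import ProteinRecord, ScaffoldRecord
from edckit.locus_annotation import (
    AnnotationParams,
    GenePrediction,
    MarkerNotFoundError,
    classify_gene_status,
    evaluate_predictions,
    find_flanked_region,
    order_scaffolds,
    predict_sedc_genes,
    predict_sftp_genes,
    validate_with_reads,
)
from edckit.synthetic_locus import (
    SyntheticConfig,
    generate_edc_locus,
    generate_tissue_reads,
)


# ---------------------------------------------------------------------------
# find_flanked_region
# ---------------------------------------------------------------------------


def test_region_equals_planted_inter_marker_interval(small_locus, marker_queries):
    scaffolds, truth = small_locus
    region = find_flanked_region(scaffolds, marker_queries)
    assert len(region.segments) == 1
    scf_id, interval, _ = region.segments[0]
    assert (scf_id, interval) == truth.region[0]
    assert region.discontinuity_flags == []


def test_missing_marker_is_an_error(small_locus):
    scaffolds, _ = small_locus
    # max attainable local score (perfect diagonal) is far below min_score
    absent = [ProteinRecord("m1", "MKW"), ProteinRecord("m2", "WKM")]
    with pytest.raises(MarkerNotFoundError, match="m1"):
        find_flanked_region(scaffolds, absent)


def test_fragmented_markers_give_flagged_segments():
    cfg = SyntheticConfig(
        seed=13, n_sedc=4, n_sftp=0, n_cbp_cluster=0, n_pseudogenes=0,
        fragmentation=[3],
    )
    scaffolds, truth = generate_edc_locus(cfg)
    markers = [ProteinRecord(m, truth.proteins[m]) for m in truth.marker_ids]
    region = find_flanked_region(scaffolds, markers)
    assert len(region.segments) == 2
    assert region.discontinuity_flags == [True]


# ---------------------------------------------------------------------------
# order_scaffolds
# ---------------------------------------------------------------------------


def _hit(family, scaffold, pos):
    return AlignmentHit(family, scaffold, (0, 10), (pos, pos + 30), 100, 1.0, 0, "+")


def test_order_scaffolds_by_reference_families():
    segments = [("scfB", (0, 1000), "+"), ("scfA", (0, 1000), "+")]
    hits = [_hit("EDS2", "scfB", 100), _hit("EDS1", "scfA", 100)]
    region = order_scaffolds(segments, ["EDS1", "EDS2"], hits)
    assert [s[0] for s in region.segments] == ["scfA", "scfB"]


def test_order_single_segment_identity():
    segments = [("scf1", (0, 500), "+")]
    hits = [_hit("EDS1", "scf1", 10)]
    region = order_scaffolds(segments, ["EDS1"], hits)
    assert region.segments == [("scf1", (0, 500), "+")]


def test_order_contradictory_anchors_flagged():
    segments = [("scf1", (0, 1000), "+")]
    hits = [
        _hit("EDS1", "scf1", 100),
        _hit("EDS3", "scf1", 200),
        _hit("EDS2", "scf1", 300),
    ]
    region = order_scaffolds(segments, ["EDS1", "EDS2", "EDS3"], hits)
    assert region.unplaced == ["scf1"]


def test_order_recovers_shuffled_fragmentation():
    cfg = SyntheticConfig(seed=17, n_sedc=6, n_sftp=0, n_cbp_cluster=0,
                          n_pseudogenes=0, fragmentation=[3, 5])
    scaffolds, truth = generate_edc_locus(cfg)
    truth_order = []
    for gid in truth.gene_order:
        scf = truth.gene(gid).scaffold_id
        if scf not in truth_order:
            truth_order.append(scf)
    segments = [
        (s.id, (0, len(s.sequence)), "+") for s in sorted(
            scaffolds, key=lambda s: s.id, reverse=True
        )
    ]
    hits = [
        _hit(truth.gene(gid).name, truth.gene(gid).scaffold_id,
             truth.gene(gid).span[0])
        for gid in truth.gene_order
    ]
    families = [truth.gene(g).name for g in truth.gene_order]
    region = order_scaffolds(segments, families, hits)
    assert [s[0] for s in region.segments] == truth_order


# ---------------------------------------------------------------------------
# predict_sedc_genes
# ---------------------------------------------------------------------------


def test_sedc_recovery_on_default_locus(small_locus):
    scaffolds, truth = small_locus
    sftp_queries = [
        ProteinRecord(g.id, truth.proteins[g.id])
        for g in truth.genes
        if g.category == "SFTP"
    ]
    sftp = predict_sftp_genes(
        scaffolds[0], sftp_queries, region=truth.region[0][1]
    )
    preds = predict_sedc_genes(
        scaffolds[0],
        region=truth.region[0][1],
        exclude_regions=[p.model.span for p in sftp],
    )
    for p in preds:
        p.status = classify_gene_status(p, scaffold_sequence=scaffolds[0].sequence)
    scores = evaluate_predictions(preds, truth)
    assert scores["recall"] == 1.0
    assert scores["precision"] >= 0.9
    assert scores["exactness"] >= 0.9


def test_min_codons_filters_short_orfs():
    # one planted 30-codon gene: below the default 50-codon floor
    cfg = SyntheticConfig(seed=19, n_sedc=1, n_sftp=0, n_cbp_cluster=0,
                          n_pseudogenes=0, protein_length_range=(30, 30))
    scaffolds, truth = generate_edc_locus(cfg)
    preds = predict_sedc_genes(scaffolds[0], region=truth.region[0][1])
    gene = next(g for g in truth.genes if g.category == "SEDC")
    assert not any(p.model.cds[0] == gene.cds[0] for p in preds)
    preds = predict_sedc_genes(
        scaffolds[0], region=truth.region[0][1],
        params=AnnotationParams(min_codons=25),
    )
    assert any(p.model.cds[0] == gene.cds[0] for p in preds)


def test_tata_ablation_drops_noncoding_exon():
    cfg = SyntheticConfig(seed=23, n_sedc=3, n_sftp=0, n_cbp_cluster=0,
                          n_pseudogenes=0, ablate_tata_genes=(1,))
    scaffolds, truth = generate_edc_locus(cfg)
    preds = predict_sedc_genes(scaffolds[0], region=truth.region[0][1])
    sedc = [g for g in truth.genes if g.category == "SEDC"]
    by_cds = {p.model.cds[0]: p for p in preds}
    ablated = by_cds[sedc[1].cds[0]]
    assert ablated.tata_position is None
    assert len(ablated.model.exons) == 1
    intact = by_cds[sedc[0].cds[0]]
    assert intact.tata_position is not None
    assert len(intact.model.exons) == 2


def test_predictions_pass_validator(small_locus):
    from edckit.io_core import validate_gene_model

    scaffolds, truth = small_locus
    preds = predict_sedc_genes(scaffolds[0], region=truth.region[0][1])
    for p in preds:
        validate_gene_model(p.model)


# ---------------------------------------------------------------------------
# predict_sftp_genes
# ---------------------------------------------------------------------------


def test_sftp_recovered_with_exact_intron(small_locus):
    scaffolds, truth = small_locus
    queries = [
        ProteinRecord(g.id, truth.proteins[g.id])
        for g in truth.genes
        if g.category == "SFTP"
    ]
    preds = predict_sftp_genes(scaffolds[0], queries, region=truth.region[0][1])
    assert len(preds) == 2  # the two planted SFTP genes, one end of the locus
    truth_cds = {tuple(g.cds) for g in truth.genes if g.category == "SFTP"}
    assert {tuple(p.model.cds) for p in preds} == truth_cds


def test_sftp_noncanonical_intron_gives_no_joined_model(small_locus):
    scaffolds, truth = small_locus
    gene = next(g for g in truth.genes if g.category == "SFTP")
    # mutate the donor dinucleotide of the internal (coding) intron
    genomic = sorted(gene.cds)
    donor = genomic[0][1] if gene.strand == "+" else genomic[1][0] - 2
    seq = list(scaffolds[0].sequence)
    seq[donor : donor + 2] = ["C", "C"]
    mutated = ScaffoldRecord(scaffolds[0].id, "".join(seq))
    queries = [ProteinRecord(gene.id, truth.proteins[gene.id])]
    preds = predict_sftp_genes(mutated, queries, region=truth.region[0][1])
    assert not any(
        p.status == "complete" and tuple(p.model.cds) == tuple(gene.cds)
        for p in preds
    )


def test_sftp_requires_queries(small_locus):
    scaffolds, _ = small_locus
    with pytest.raises(ValueError):
        predict_sftp_genes(scaffolds[0], [])


# ---------------------------------------------------------------------------
# classify_gene_status
# ---------------------------------------------------------------------------


def _prediction(model):
    return GenePrediction(model=model)


def test_classify_planted_pseudogene(small_locus):
    scaffolds, truth = small_locus
    from edckit.io_core import GeneModel

    pseudo = next(g for g in truth.genes if g.category == "pseudogene")
    pred = _prediction(
        GeneModel(
            id="x", scaffold_id=pseudo.scaffold_id, strand=pseudo.strand,
            exons=list(pseudo.exons), cds=list(pseudo.cds),
            category="SEDC", name="x",
        )
    )
    assert classify_gene_status(pred, scaffold_sequence=scaffolds[0].sequence) == (
        "pseudogene"
    )


def test_classify_cds_at_scaffold_edge_is_partial():
    from edckit.io_core import GeneModel

    seq = "ATGAAACCCGGG" + "C" * 50
    model = GeneModel(
        id="x", scaffold_id="s", strand="+", exons=[(0, 12)], cds=[(0, 12)],
        category="SEDC", name="x", completeness="partial",
    )
    assert classify_gene_status(_prediction(model), scaffold_sequence=seq) == (
        "partial"
    )


def test_classify_intact_gene_complete(small_locus):
    scaffolds, truth = small_locus
    gene = next(g for g in truth.genes if g.category == "SEDC")
    pred = _prediction(gene)
    assert classify_gene_status(pred, scaffold_sequence=scaffolds[0].sequence) == (
        "complete"
    )


def test_classify_invariant_to_scaffold_naming(small_locus):
    scaffolds, truth = small_locus
    gene = next(g for g in truth.genes if g.category == "SEDC")
    from dataclasses import replace

    renamed = replace(gene, scaffold_id="whatever")
    assert classify_gene_status(
        _prediction(renamed), scaffold_sequence=scaffolds[0].sequence
    ) == "complete"


# ---------------------------------------------------------------------------
# validate_with_reads
# ---------------------------------------------------------------------------


def test_read_support_equals_truth_counts(small_config, small_locus):
    scaffolds, truth = small_locus
    reads_by_tissue = generate_tissue_reads(scaffolds, truth, small_config)
    reads = [r for rl in reads_by_tissue.values() for r in rl]
    gene = next(g for g in truth.genes if g.category == "SEDC")
    truth_count = sum(
        1 for rid, (gid, _) in truth.read_origins.items() if gid == gene.id
    )
    pred = GenePrediction(model=gene)
    validate_with_reads(pred, reads, scaffolds[0].sequence)
    assert pred.read_support == truth_count
    assert pred.read_support >= pred.intron_spanning_reads
    if truth_count:
        assert pred.intron_spanning_reads > 0  # exon junction is covered


def test_unexpressed_gene_has_zero_support(small_config, small_locus):
    scaffolds, truth = small_locus
    reads_by_tissue = generate_tissue_reads(scaffolds, truth, small_config)
    reads = [r for rl in reads_by_tissue.values() for r in rl]
    pseudo = next(g for g in truth.genes if g.category == "pseudogene")
    pred = GenePrediction(model=pseudo)
    validate_with_reads(pred, reads, scaffolds[0].sequence)
    assert pred.read_support == 0


def test_min_overhang_threshold(small_locus):
    scaffolds, truth = small_locus
    from edckit.io_core import ReadRecord

    gene = next(
        g for g in truth.genes if g.category == "SEDC" and len(g.exons) == 2
    )
    tx = truth.transcripts[gene.id]
    junction = gene.exons[0][1] - gene.exons[0][0]
    read = ReadRecord("j1", tx[junction - 10 : junction + 10], "skin")
    pred = GenePrediction(model=gene)
    validate_with_reads(pred, [read], scaffolds[0].sequence,
                        AnnotationParams(min_overhang=5))
    assert (pred.read_support, pred.intron_spanning_reads) == (1, 1)
    validate_with_reads(pred, [read], scaffolds[0].sequence,
                        AnnotationParams(min_overhang=11))
    assert (pred.read_support, pred.intron_spanning_reads) == (1, 0)
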