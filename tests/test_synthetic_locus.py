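"""Generator ground truth: determinism, bias, divergence, reads."""

import numpy as np
import pytest
from scipy import stats

from _oracles import expected_protein_identity
from edckit.io_core import CODON_TABLE, translate, validate_gene_model
from edckit.synthetic_locus import (
    RepeatGeneSpec,
    SyntheticConfig,
    default_expression_profile,
    generate_edc_locus,
    generate_ortholog_pair,
    generate_tissue_reads,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(seed=1, n_sedc=-1)
    with pytest.raises(ValueError):
        SyntheticConfig(seed=1, composition_bias={"G": 0.7, "C": 0.4})


def test_gene_complement_matches_config(small_config, small_locus):
    _, truth = small_locus
    by_cat = {}
    for g in truth.genes:
        by_cat.setdefault(g.category, []).append(g)
    assert len(by_cat["SEDC"]) == small_config.n_sedc
    assert len(by_cat["SFTP"]) == small_config.n_sftp
    assert len(by_cat["CBP"]) == small_config.n_cbp_cluster
    assert len(by_cat["pseudogene"]) == small_config.n_pseudogenes
    for g in by_cat["SEDC"]:
        assert len(g.cds) == 1
    for g in by_cat["SFTP"]:
        assert len(g.cds) == 2


def test_determinism_byte_identical(small_config):
    s1, t1 = generate_edc_locus(small_config)
    s2, t2 = generate_edc_locus(small_config)
    assert s1[0].sequence == s2[0].sequence
    assert [g.exons for g in t1.genes] == [g.exons for g in t2.genes]


def test_truth_passes_validator_and_proteins_match(small_locus):
    scaffolds, truth = small_locus
    seq = scaffolds[0].sequence
    for g in truth.genes:
        validate_gene_model(g, seq)
        if g.category != "pseudogene":
            assert g.protein(seq) == truth.proteins[g.id]


def test_composition_bias_recovered():
    """Mean cysteine fraction under bias {C: 0.25} within binomial error."""
    cfg = SyntheticConfig(seed=5, n_sedc=20, composition_bias={"C": 0.25})
    _, truth = generate_edc_locus(cfg)
    fracs = [
        truth.proteins[g.id].count("C") / len(truth.proteins[g.id])
        for g in truth.genes
        if g.category == "SEDC"
    ]
    n_res = sum(
        len(truth.proteins[g.id]) for g in truth.genes if g.category == "SEDC"
    )
    se = np.sqrt(0.25 * 0.75 / n_res)
    assert abs(np.mean(fracs) - 0.25) < 4 * se + 0.01


def test_pseudogenes_never_translate_full_length(small_locus):
    scaffolds, truth = small_locus
    seq = scaffolds[0].sequence
    for g in truth.genes:
        if g.category != "pseudogene":
            continue
        aa = translate(g.spliced_cds(seq), 0, "+")
        body = aa[:-1] if aa.endswith("*") else aa
        assert "*" in body or not body.startswith("M")


def test_fragmentation_cuts_between_genes():
    cfg = SyntheticConfig(seed=3, fragmentation=[5])
    scaffolds, truth = generate_edc_locus(cfg)
    assert len(scaffolds) == 2
    seq_by_id = {s.id: s.sequence for s in scaffolds}
    for g in truth.genes:  # no gene is split
        validate_gene_model(g, seq_by_id[g.scaffold_id])


# ---------------------------------------------------------------------------
# ortholog pair
# ---------------------------------------------------------------------------


def test_zero_divergence_is_identity():
    (sa, ta), (sb, tb), omap = generate_ortholog_pair(
        SyntheticConfig(seed=9, n_sedc=4, n_cbp_cluster=2, n_pseudogenes=1), 0.0
    )
    assert sa[0].sequence == sb[0].sequence
    for g in ta.intact_genes():
        assert ta.proteins[g.id] == tb.proteins[omap[g.id]]


def test_divergence_out_of_range_rejected():
    with pytest.raises(ValueError):
        generate_ortholog_pair(SyntheticConfig(seed=1), 0.7)


def test_repeat_expansion_adds_units():
    spec = RepeatGeneSpec(unit="CCDPCQKTV", copies=5)
    cfg = SyntheticConfig(
        seed=4, n_sedc=3, n_cbp_cluster=0, n_pseudogenes=0, repeat_gene=spec
    )
    (sa, ta), (sb, tb), omap = generate_ortholog_pair(cfg, 0.0, repeat_expansion=50)
    ga = next(g for g in ta.genes if g.name == "EDCRPL1")
    pa, pb = ta.proteins[ga.id], tb.proteins[omap[ga.id]]
    assert len(pb) - len(pa) == 50 * len(spec.unit)
    assert pb.count("CCDPCQKTV") - pa.count("CCDPCQKTV") == 50


def test_divergence_matches_closed_form_expectation():
    """Observed ortholog protein identity vs the codon-enumeration
    expectation under the 2:1-transition, stop-avoiding model."""
    d = 0.1
    (sa, ta), (sb, tb), omap = generate_ortholog_pair(
        SyntheticConfig(seed=12), d
    )
    seq_a = {s.id: s.sequence for s in sa}
    codons, same = [], 0
    n = 0
    for g in ta.intact_genes():
        cds = g.spliced_cds(seq_a[g.scaffold_id])
        codons.extend(cds[i : i + 3] for i in range(3, len(cds) - 6, 3))
        pa, pb = ta.proteins[g.id], tb.proteins[omap[g.id]]
        assert len(pa) == len(pb)
        same += sum(x == y for x, y in zip(pa[1:], pb[1:]))  # start codon fixed
        n += len(pa) - 1
    observed = same / n
    expected = expected_protein_identity(codons, d, CODON_TABLE)
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(observed - expected) < 4 * se + 0.01


# ---------------------------------------------------------------------------
# tissue reads
# ---------------------------------------------------------------------------


def test_reads_are_exact_transcript_substrings(small_config, small_locus):
    scaffolds, truth = small_locus
    reads = generate_tissue_reads(scaffolds, truth, small_config)
    for tissue, rl in reads.items():
        for r in rl:
            gene_id, t = truth.read_origins[r.id]
            assert t == tissue
            assert r.sequence in truth.transcripts[gene_id]


def test_skin_only_profile_yields_no_visceral_reads(small_config, small_locus):
    scaffolds, truth = small_locus
    reads = generate_tissue_reads(scaffolds, truth, small_config)
    edc_ids = {g.id for g in truth.intact_genes()}
    for tissue in ("heart", "liver"):
        sources = {truth.read_origins[r.id][0] for r in reads[tissue]}
        assert sources == {truth.control_gene}
    assert any(
        truth.read_origins[r.id][0] in edc_ids for r in reads["skin"]
    )


def test_uniform_control_counts_chi_square():
    """A uniformly expressed gene gets statistically equal counts."""
    cfg = SyntheticConfig(seed=21, n_sedc=2, n_cbp_cluster=0, n_pseudogenes=0)
    scaffolds, truth = generate_edc_locus(cfg)
    profile = {
        truth.control_gene: {"skin": 1.0, "heart": 1.0, "liver": 1.0},
        truth.marker_ids[0]: {"skin": 1.0, "heart": 1.0, "liver": 1.0},
    }
    cfg = SyntheticConfig(
        seed=21, n_sedc=2, n_cbp_cluster=0, n_pseudogenes=0,
        expression_profile=profile,
        reads_per_tissue={"skin": 400, "heart": 400, "liver": 400},
    )
    reads = generate_tissue_reads(scaffolds, truth, cfg)
    counts = [
        sum(1 for r in reads[t] if truth.read_origins[r.id][0] == truth.control_gene)
        for t in ("skin", "heart", "liver")
    ]
    _, p = stats.chisquare(counts)
    assert p > 1e-4  # would reject only under gross non-uniformity


def test_short_transcript_skipped_with_warning(caplog):
    cfg = SyntheticConfig(seed=2, n_sedc=2, n_cbp_cluster=0, n_pseudogenes=0,
                          read_length=10_000)
    scaffolds, truth = generate_edc_locus(cfg)
    import logging

    with caplog.at_level(logging.WARNING):
        reads = generate_tissue_reads(scaffolds, truth, cfg)
    assert all(len(rl) == 0 for rl in reads.values())
    assert any("shorter than read length" in rec.message for rec in caplog.records)


def test_unknown_gene_in_profile_rejected(small_config, small_locus):
    scaffolds, truth = small_locus
    cfg = SyntheticConfig(seed=11, expression_profile={"nope": {"skin": 1.0}})
    with pytest.raises(ValueError, match="unknown genes"):
        generate_tissue_reads(scaffolds, truth, cfg)
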