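"""Orthology, family census, Dollo parsimony and the comparative map."""

import itertools

import pytest

from _oracles import brute_dollo_events
from edckit.io_core import ProteinRecord
from edckit.comparative import (
    FamilyCensus,
    build_locus_map,
    dollo_gain_loss,
    family_census,
    load_species_tree,
    reciprocal_best_hits,
)
from edckit.synthetic_locus import SyntheticConfig, generate_ortholog_pair

FIG_TREE = "(turtle,((chicken,ostrich),(alligator,crocodile)));"


def _locus_ordered(truth):
    genes = [g for g in truth.intact_genes()]
    genes.sort(key=lambda m: (m.scaffold_id, m.span[0]))
    return [ProteinRecord(g.id, truth.proteins[g.id]) for g in genes]


# ---------------------------------------------------------------------------
# RBH
# ---------------------------------------------------------------------------


def test_identical_sets_give_identity_map():
    prots = [ProteinRecord(f"g{i}", p) for i, p in enumerate(
        ["MKCWY" * 8, "MGGSS" * 8, "MPPQQ" * 8]
    )]
    omap = reciprocal_best_hits(prots, prots)
    assert omap.as_dict() == {p.id: p.id for p in prots}
    assert all(p.rbh and p.identity == 1.0 for p in omap.pairs)


def test_rbh_symmetry():
    cfg = SyntheticConfig(seed=31, n_sedc=5, n_sftp=1, n_cbp_cluster=2,
                          n_pseudogenes=0)
    (sa, ta), (sb, tb), _ = generate_ortholog_pair(cfg, 0.1)
    pa, pb = _locus_ordered(ta), _locus_ordered(tb)
    fwd = reciprocal_best_hits(pa, pb)
    rev = reciprocal_best_hits(pb, pa)
    assert sorted((p.gene_a, p.gene_b) for p in fwd.pairs) == sorted(
        (p.gene_b, p.gene_a) for p in rev.pairs
    )


def test_truth_map_recovery_at_divergence_01():
    cfg = SyntheticConfig(seed=33)
    (sa, ta), (sb, tb), omap = generate_ortholog_pair(cfg, 0.1)
    pa, pb = _locus_ordered(ta), _locus_ordered(tb)
    got = reciprocal_best_hits(pa, pb).as_dict()
    truth_pairs = [(g.id, omap[g.id]) for g in ta.intact_genes()]
    recovered = sum(1 for a, b in truth_pairs if got.get(a) == b)
    assert recovered / len(truth_pairs) >= 0.95


def test_unmatched_family_left_unpaired():
    a = [ProteinRecord("a1", "MKCWY" * 8), ProteinRecord("a2", "MHHEE" * 8)]
    b = [ProteinRecord("b1", "MKCWY" * 8)]
    omap = reciprocal_best_hits(a, b)
    assert omap.as_dict() == {"a1": "b1"}


def test_empty_set_rejected():
    with pytest.raises(ValueError):
        reciprocal_best_hits([], [ProteinRecord("b", "MK" * 5)])


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------


def test_census_counts_and_explicit_zeros():
    census = family_census(
        {
            "alligator": [("EDCH", "complete")] * 3 + [("EDCH", "pseudogene")],
            "chicken": [("EDPQ", "complete")],
        }
    )
    assert census.count("alligator", "EDCH", "complete") == 3
    assert census.count("alligator", "EDCH", "pseudogene") == 1
    assert census.count("chicken", "EDCH", "complete") == 0
    assert census.count("alligator", "EDPQ") == 0
    # totals conserved
    assert census.total("alligator", "EDCH") == 4


def test_census_totals_conserved_across_statuses():
    members = {
        "x": [("F1", "complete"), ("F1", "partial"), ("F1", "pseudogene"),
              ("F2", "complete")],
    }
    census = family_census(members)
    assert census.total("x", "F1") == 3
    assert census.total("x", "F2") == 1


# ---------------------------------------------------------------------------
# Dollo
# ---------------------------------------------------------------------------


def _presence_census(present, species, n=2):
    return family_census(
        {sp: ([("F", "complete")] * n if sp in present else []) for sp in species}
    )


def test_bird_loss_pattern():
    """Present in turtle + both crocodilians, absent in both birds: one
    gain on the turtle+archosaur stem, one loss on the bird stem."""
    species = ["turtle", "chicken", "ostrich", "alligator", "crocodile"]
    census = _presence_census(
        {"turtle", "alligator", "crocodile"}, species
    )
    events = dollo_gain_loss(census, FIG_TREE)
    gains = [e for e in events if e.type == "gain"]
    losses = [e for e in events if e.type == "loss"]
    assert len(gains) == 1 and len(losses) == 1
    assert set(gains[0].branch.split("+")) == set(species)  # the root stem
    assert set(losses[0].branch.split("+")) == {"chicken", "ostrich"}


def test_present_everywhere_single_root_gain():
    species = ["turtle", "chicken", "ostrich", "alligator", "crocodile"]
    census = _presence_census(set(species), species)
    events = dollo_gain_loss(census, FIG_TREE)
    assert [e.type for e in events] == ["gain"]


def test_never_infers_presence_without_descendants():
    species = ["turtle", "chicken", "ostrich", "alligator", "crocodile"]
    census = _presence_census({"chicken"}, species)
    events = dollo_gain_loss(census, FIG_TREE)
    assert [(e.type, e.branch) for e in events] == [("gain", "chicken")]


def test_absent_family_no_events():
    species = ["turtle", "chicken", "ostrich", "alligator", "crocodile"]
    census = _presence_census(set(), species)
    assert dollo_gain_loss(census, FIG_TREE) == []


def test_tip_mismatch_rejected():
    census = _presence_census({"a"}, ["a", "b"])
    with pytest.raises(ValueError, match="tips"):
        dollo_gain_loss(census, "(a,(c,d));")


@pytest.mark.parametrize(
    "newick",
    [
        "((a,b),(c,d));",
        "(a,(b,(c,d)));",
        "((a,(b,c)),(d,e));",
        "(a,((b,c),(d,(e,f))));",
    ],
)
def test_dollo_matches_exhaustive_enumeration(newick):
    """Gain/loss placement equals brute-force minimal-change enumeration
    for every presence pattern on 4-6 tip trees."""
    tree = load_species_tree(newick)
    species = sorted(t.name for t in tree.get_terminals())
    for bits in itertools.product([0, 1], repeat=len(species)):
        present = {sp for sp, b in zip(species, bits) if b}
        if not present:
            continue
        census = _presence_census(present, species)
        events = dollo_gain_loss(census, load_species_tree(newick))
        gain = next(e for e in events if e.type == "gain")
        got_gain = frozenset(gain.branch.split("+"))
        got_losses = frozenset(
            frozenset(e.branch.split("+")) for e in events if e.type == "loss"
        )
        exp_gain, exp_losses = brute_dollo_events(
            load_species_tree(newick), present
        )
        assert got_gain == exp_gain
        assert got_losses == exp_losses


def test_expansion_event_on_count_jump():
    species = ["turtle", "chicken", "ostrich", "alligator", "crocodile"]
    census = family_census(
        {
            "turtle": [],
            "chicken": [("EDCH", "complete")] * 4,
            "ostrich": [("EDCH", "complete")] * 3,
            "alligator": [("EDCH", "complete")] * 21,
            "crocodile": [("EDCH", "complete")] * 13,
        }
    )
    events = dollo_gain_loss(census, FIG_TREE)
    exp = [e for e in events if e.type == "expansion"]
    assert any(
        set(e.branch.split("+")) == {"alligator", "crocodile"} for e in exp
    )


def test_pseudogene_only_complement_counts_as_absent():
    species = ["turtle", "chicken", "ostrich", "alligator", "crocodile"]
    census = family_census(
        {
            "turtle": [("F", "complete")],
            "alligator": [("F", "complete")],
            "crocodile": [("F", "complete")],
            "chicken": [("F", "pseudogene")],
            "ostrich": [],
        }
    )
    events = dollo_gain_loss(census, FIG_TREE)
    losses = [e for e in events if e.type == "loss"]
    assert len(losses) == 1
    assert set(losses[0].branch.split("+")) == {"chicken", "ostrich"}


# ---------------------------------------------------------------------------
# locus map
# ---------------------------------------------------------------------------


def test_locus_map_boxes_links_and_gaps(small_locus):
    scaffolds, truth = small_locus
    genes = sorted(truth.genes, key=lambda m: m.span[0])
    families = {g.id: (g.name[:-1] if g.category == "CBP" else g.name)
                for g in genes}
    from edckit.comparative import OrthologMap, OrthologPair

    links = OrthologMap(
        pairs=[OrthologPair(genes[0].id, genes[0].id, True, 0, 1.0)]
    )
    lmap = build_locus_map(
        {"A": genes, "B": genes},
        families,
        ortholog_maps={("A", "B"): links},
        discontinuities={"B": [2]},
        cluster_threshold=3,
    )
    rendered = lmap.render_text()
    assert "[CBP #4]" in rendered  # the 4-member cluster boxed (threshold 3)
    assert "~" in rendered
    assert lmap.links == [(genes[0].id, genes[0].id)]


def test_locus_map_requires_two_species(small_locus):
    _, truth = small_locus
    with pytest.raises(ValueError):
        build_locus_map({"A": truth.genes}, {})
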