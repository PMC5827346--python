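"""Cross-species orthology, gene-family census and Dollo gain/loss.

Orthology in a tandem gene cluster cannot rest on sequence alone — the
locus is full of similar paralogs — so orthologs are called by reciprocal
best hits (RBH) *and* positional agreement (locus rank delta), mirroring
the shared-synteny argument of comparative EDC studies.  Family censuses
count complete / partial / pseudogene members per species, and family
histories are mapped onto a fixed species tree by Dollo parsimony: one
gain, any number of subsequent losses, with ancestral copy numbers
reconstructed by minimising total absolute count change along branches
(linear-cost Sankoff).  Copy-number jumps of at least ``expansion_fold``
between parent and child are reported as expansion/contraction events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import pandas as pd
from Bio import Phylo

from .homology_search import SubstitutionMatrix, global_align, global_score
from .io_core import GeneModel, ProteinRecord


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    rbh: bool
    positional_rank_delta: int
    identity: float


@dataclass
class OrthologMap:
    pairs: list[OrthologPair] = field(default_factory=list)

    def as_dict(self) -> dict[str, str]:
        return {p.gene_a: p.gene_b for p in self.pairs}

    def transpose(self) -> "OrthologMap":
        return OrthologMap(
            pairs=[
                OrthologPair(
                    p.gene_b, p.gene_a, p.rbh, p.positional_rank_delta, p.identity
                )
                for p in self.pairs
            ]
        )


def _best_index(scores: list[int], seqs, query: str, matrix) -> int:
    """Index of the best score; ties broken by identity, then order."""
    top = max(scores)
    tied = [i for i, s in enumerate(scores) if s == top]
    if len(tied) == 1:
        return tied[0]
    idents = [global_align(query, seqs[i].sequence, matrix).identity for i in tied]
    best = max(range(len(tied)), key=lambda k: (idents[k], -tied[k]))
    return tied[best]


def reciprocal_best_hits(
    proteins_a: list[ProteinRecord],
    proteins_b: list[ProteinRecord],
    matrix: SubstitutionMatrix | None = None,
    max_rank_delta: int = 3,
) -> OrthologMap:
    """Orthology by reciprocal best global-alignment hit plus synteny.

    Locus rank is each protein's index in its (locus-ordered) input list;
    an RBH pair is accepted only when the ranks differ by at most
    ``max_rank_delta``.  Each gene appears in at most one pair.
    """
    if not proteins_a or not proteins_b:
        raise ValueError("both protein sets must be non-empty")
    score = [
        [global_score(a.sequence, b.sequence, matrix) for b in proteins_b]
        for a in proteins_a
    ]
    best_b_of_a = [
        _best_index(row, proteins_b, a.sequence, matrix)
        for row, a in zip(score, proteins_a)
    ]
    best_a_of_b = [
        _best_index([score[i][j] for i in range(len(proteins_a))],
                    proteins_a, b.sequence, matrix)
        for j, b in enumerate(proteins_b)
    ]
    pairs = []
    for i, a in enumerate(proteins_a):
        j = best_b_of_a[i]
        if best_a_of_b[j] != i:
            continue
        delta = abs(i - j)
        if delta > max_rank_delta:
            continue
        identity = global_align(a.sequence, proteins_b[j].sequence, matrix).identity
        pairs.append(
            OrthologPair(
                gene_a=a.id,
                gene_b=proteins_b[j].id,
                rbh=True,
                positional_rank_delta=delta,
                identity=identity,
            )
        )
    return OrthologMap(pairs=pairs)


# ---------------------------------------------------------------------------
# family assignment and census
# ---------------------------------------------------------------------------


def assign_families(
    proteins: list[ProteinRecord],
    exemplars: dict[str, str],
    matrix: SubstitutionMatrix | None = None,
) -> dict[str, tuple[str, int]]:
    """Assign each protein to the family of its best-scoring exemplar.

    Proteins with no positive score against any exemplar are assigned to
    'unclassified' (never dropped); scores are returned for auditing.
    """
    out: dict[str, tuple[str, int]] = {}
    for p in proteins:
        best_fam, best_score = "unclassified", 0
        for fam in sorted(exemplars):
            s = global_score(p.sequence, exemplars[fam], matrix)
            if s > best_score:
                best_fam, best_score = fam, s
    # fall through keeps 'unclassified' when every score <= 0
        out[p.id] = (best_fam, best_score)
    return out


STATUSES = ("complete", "partial", "pseudogene")


@dataclass
class FamilyCensus:
    """Per-species, per-family counts split by completeness status."""

    table: pd.DataFrame  # columns: species, family, complete, partial, pseudogene
    species: list[str] = field(default_factory=list)

    def count(self, species: str, family: str, status: str = "complete") -> int:
        sel = self.table[
            (self.table.species == species) & (self.table.family == family)
        ]
        return int(sel[status].iloc[0]) if len(sel) else 0

    def total(self, species: str, family: str) -> int:
        return sum(self.count(species, family, s) for s in STATUSES)

    @property
    def families(self) -> list[str]:
        if self.table.empty:
            return []
        return sorted(self.table.family.unique())


def family_census(
    members_by_species: dict[str, list[tuple[str, str]]],
) -> FamilyCensus:
    """Tabulate (family, status) pairs per species, zeros explicit.

    ``members_by_species`` maps species -> list of (family, status) with
    status in {complete, partial, pseudogene}.
    """
    all_families = sorted(
        {fam for members in members_by_species.values() for fam, _ in members}
    )
    rows = []
    for species in sorted(members_by_species):
        members = members_by_species[species]
        for fam in all_families:
            row = {"species": species, "family": fam}
            for status in STATUSES:
                row[status] = sum(
                    1 for f, s in members if f == fam and s == status
                )
            rows.append(row)
    return FamilyCensus(
        table=pd.DataFrame(
            rows, columns=["species", "family", *STATUSES]
        ),
        species=sorted(members_by_species),
    )


# ---------------------------------------------------------------------------
# Dollo gain/loss on a fixed species tree
# ---------------------------------------------------------------------------


@dataclass
class GainLossEvent:
    family: str
    branch: str  # clade label: tip name or sorted tip-set string
    type: str  # gain | loss | expansion | contraction
    magnitude: int


def load_species_tree(newick: str):
    """Parse a rooted newick string into a Bio.Phylo tree."""
    return Phylo.read(StringIO(newick), "newick")


def _clade_label(clade) -> str:
    if clade.name:
        return clade.name
    return "+".join(sorted(t.name for t in clade.get_terminals()))


def _sankoff_counts(clade, counts: dict[str, int]) -> dict[int, int]:
    """Ancestral copy numbers minimising total |count change| (Sankoff,
    linear cost).  Returns {id(clade): value}; ties resolve to the smallest
    count (fewest inferred ancestral copies).
    """
    cmax = max(counts.values())
    states = range(cmax + 1)
    cost: dict[int, list[int]] = {}

    def up(node) -> None:
        if node.is_terminal():
            c = counts[node.name]
            cost[id(node)] = [0 if x == c else 10**9 for x in states]
            return
        for child in node.clades:
            up(child)
        cost[id(node)] = [
            sum(
                min(abs(x - y) + cost[id(ch)][y] for y in states)
                for ch in node.clades
            )
            for x in states
        ]

    up(clade)
    value: dict[int, int] = {}
    root_costs = cost[id(clade)]
    value[id(clade)] = min(states, key=lambda x: (root_costs[x], x))

    def down(node) -> None:
        for child in node.clades:
            px = value[id(node)]
            ccosts = cost[id(child)]
            value[id(child)] = min(
                states, key=lambda y: (abs(px - y) + ccosts[y], y)
            )
            down(child)

    down(clade)
    return value


def dollo_gain_loss(
    census: FamilyCensus,
    tree,
    expansion_fold: int = 4,
    presence_statuses: tuple[str, ...] = ("complete", "partial"),
) -> list[GainLossEvent]:
    """Family histories under Dollo parsimony with count reconstruction.

    Presence means at least one intact (complete or partial) member; a
    pseudogene-only complement counts as absence, matching how inactivated
    families are treated in comparative gene-complement studies.  Each
    family gains once (on the stem of the most recent common ancestor of
    the species possessing it) and may be lost on any branch below.
    Ancestral copy numbers minimise total absolute change; parent-to-child
    jumps of >= ``expansion_fold`` emit expansion/contraction events.
    """
    if isinstance(tree, str):
        tree = load_species_tree(tree)
    tips = {t.name for t in tree.get_terminals()}
    if tips != set(census.species):
        raise ValueError(
            f"tree tips {sorted(tips)} != census species {census.species}"
        )
    events: list[GainLossEvent] = []
    for family in census.families:
        counts = {
            sp: sum(census.count(sp, family, s) for s in presence_statuses)
            for sp in census.species
        }
        present = {sp for sp, c in counts.items() if c > 0}
        if not present:
            continue
        gain_clade = (
            tree.common_ancestor(sorted(present))
            if len(present) > 1
            else next(t for t in tree.get_terminals() if t.name in present)
        )
        # ancestral copy numbers within the gained subtree
        value = _sankoff_counts(gain_clade, counts)
        events.append(
            GainLossEvent(
                family=family,
                branch=_clade_label(gain_clade),
                type="gain",
                magnitude=value[id(gain_clade)],
            )
        )

        def walk(clade) -> None:
            for child in clade.clades:
                child_present = {
                    t.name for t in child.get_terminals()
                } & present
                if not child_present:
                    events.append(
                        GainLossEvent(
                            family=family,
                            branch=_clade_label(child),
                            type="loss",
                            magnitude=value[id(clade)],
                        )
                    )
                    continue  # Dollo: nothing to infer below a loss
                pv, cv = value[id(clade)], value[id(child)]
                if cv - pv >= expansion_fold:
                    events.append(
                        GainLossEvent(family, _clade_label(child), "expansion",
                                      cv - pv)
                    )
                elif cv > 0 and pv - cv >= expansion_fold:
                    events.append(
                        GainLossEvent(family, _clade_label(child), "contraction",
                                      cv - pv)
                    )
                walk(child)

        walk(gain_clade)
    return events


# ---------------------------------------------------------------------------
# comparative locus map
# ---------------------------------------------------------------------------


@dataclass
class MapElement:
    kind: str  # 'gene' | 'cluster' | 'gap'
    label: str
    strand: str = "+"
    count: int = 1
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class LocusMap:
    tracks: dict[str, list[MapElement]]
    links: list[tuple[str, str]]  # ortholog gene-id pairs across species

    def render_text(self) -> str:
        lines = []
        for species in sorted(self.tracks):
            parts = []
            for el in self.tracks[species]:
                if el.kind == "gap":
                    parts.append("~")
                elif el.kind == "cluster":
                    parts.append(f"[{el.label} #{el.count}]")
                else:
                    arrow = ">" if el.strand == "+" else "<"
                    parts.append(
                        f"{el.label}{arrow}" if el.strand == "+" else f"{arrow}{el.label}"
                    )
            lines.append(f"{species:12s} " + " ".join(parts))
        lines.append(f"# ortholog links: {len(self.links)}")
        return "\n".join(lines)


def build_locus_map(
    annotations_by_species: dict[str, list[GeneModel]],
    families: dict[str, str],
    ortholog_maps: dict[tuple[str, str], OrthologMap] | None = None,
    discontinuities: dict[str, list[int]] | None = None,
    cluster_threshold: int = 4,
) -> LocusMap:
    """Assemble a schematic comparative map of the locus.

    Genes are listed in locus order per species; runs of more than
    ``cluster_threshold`` consecutive members of one family collapse into
    a cluster box annotated with the member count.  Ortholog links come
    from the supplied maps; assembly discontinuities (gene-order indices)
    are rendered as '~' marks.
    """
    if len(annotations_by_species) < 2:
        raise ValueError("a comparative map needs at least two species")
    tracks: dict[str, list[MapElement]] = {}
    for species, models in annotations_by_species.items():
        breaks = set((discontinuities or {}).get(species, []))
        elements: list[MapElement] = []
        run: list[GeneModel] = []

        def flush() -> None:
            if not run:
                return
            fam = families.get(run[0].id, run[0].name)
            if len(run) > cluster_threshold:
                elements.append(
                    MapElement(
                        kind="cluster",
                        label=fam,
                        count=len(run),
                        gene_ids=[m.id for m in run],
                    )
                )
            else:
                for m in run:
                    elements.append(
                        MapElement(
                            kind="gene",
                            label=m.name or m.id,
                            strand=m.strand,
                            gene_ids=[m.id],
                        )
                    )
            run.clear()

        for idx, model in enumerate(models):
            if idx in breaks:
                flush()
                elements.append(MapElement(kind="gap", label="~"))
            fam = families.get(model.id, model.name)
            if run and families.get(run[0].id, run[0].name) != fam:
                flush()
            run.append(model)
        flush()
        tracks[species] = elements
    links = []
    for omap in (ortholog_maps or {}).values():
        links.extend((p.gene_a, p.gene_b) for p in omap.pairs)
    return LocusMap(tracks=tracks, links=links)
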