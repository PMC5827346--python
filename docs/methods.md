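# Methods

`edckit` re-implements, as a tested and reusable pipeline, the
comparative-genomics procedure used to characterise the Epidermal
Differentiation Complex (EDC) in crocodilian genomes: delimiting the locus
between its S100A marker genes, predicting short single-coding-exon genes
de novo, profiling protein composition and internal repeats, validating
expression by exact-match read counting, and inferring gene-family
gain/loss histories across species.  This note documents the models,
parameter choices and known limitations.

## Coordinate and sequence conventions

Internal coordinates are 0-based half-open on the forward scaffold strand;
all GFF3 emitted or read is 1-based inclusive.  Gene models store exons in
transcript orientation, so minus-strand models list exons in descending
genomic order.  Translation uses the standard nuclear genetic code; codons
containing N translate to X, and X is scored 0 against every residue in
alignments (a neutral placeholder for assembly gaps).  Soft-masked input is
uppercased on ingest: the translated search deliberately applies no
low-complexity masking, because EDC coding sequence *is* low-complexity and
would otherwise be filtered away.

## Translated homology search

The search aligns a protein query against all six conceptual translation
frames of a DNA target with exact Smith–Waterman dynamic programming under
affine gaps (Gotoh recurrences, numba-compiled kernels).  Scoring follows
the BLAST protein defaults: BLOSUM62, gap open 11, gap extend 1 (a gap of
length k costs 11 + k).  There is no seeding heuristic and no E-value
model: the locus under study is small (tens to hundreds of kb), so exact DP
is the production path and hits are thresholded on raw score
(`min_score`, default 40 — an explicit artifact choice, since the original
search reported hits rather than statistics).  Suboptimal hits within one
frame are recovered by iteratively masking the best hit's span, so tandem
multi-copy families yield one hit per copy.  Tie-breaking is deterministic
(earliest target end, then earliest query end; diagonal moves preferred in
traceback).

One consequence worth knowing: when an intron length is a multiple of
three, Smith–Waterman bridges it with a single long gap and one hit covers
both flanking exons; with any other intron phase the exons surface as
separate hits in different frames.  The two-exon gene assembler handles
both cases.

## Synthetic locus generator

The generator emulates the genomic architecture the analysis assumes, so
every stage can be scored against known truth without downloads.  A locus
consists of, in order: a 5' S100A12-like marker, `n_sedc` single-coding-exon
(SEDC) genes (optionally including an EDCRP-like gene with an internal
peptide repeat), `n_sftp` two-coding-exon (SFTP) genes, a tandem CBP-like
cluster, `n_pseudogenes` disrupted genes, a 3' S100A11-like marker, and an
ALAS1-like housekeeping control outside the inter-marker region.  Each gene
is placed on a random strand with intergenic spacers of 300–800 nt.

Gene anatomy follows the canonical SEDC/SFTP layout: a TATA box (literal
`TATAAA`) 25–35 nt upstream of the transcription start, a 60–120 nt
noncoding first exon, a GT…AG intron of 300–700 nt, a short 5' UTR
(9–30 nt), then the coding sequence.  SFTP genes carry a second, phase-0
intron inside the CDS.  Proteins are 80–180 residues sampled under a
composition bias favouring G (0.14), S (0.12), P (0.11), K (0.09), C
(0.11) and Q (0.09) — 0.66 combined, matching the strong G/S/P/K/C/Q
enrichment of real EDC proteins and keeping planted genes comfortably above
the predictor's 0.5 bias threshold; the remaining mass is uniform over the
other 14 residues.  Codons are drawn uniformly among synonyms.

Two structural guarantees keep ground truth unambiguous:

* every planted start codon is immediately preceded by an in-frame stop,
  so the annotated ATG is provably the first ATG of its open reading frame
  (otherwise a chance upstream in-frame ATG would make "the" true coding
  span ill-defined for roughly a quarter of genes);
* pseudogenes receive a premature stop plus a 1-nt deletion and are then
  further decayed — stop codons planted into any surviving reading frame —
  until no ATG-initiated stop-free ORF of ≥ 40 codons remains in any of
  the six frames.  A "pseudogene" that still contained a clean 100-codon
  biased ORF (as a single frameshift of low-complexity codons often leaves
  behind) would be operationally indistinguishable from a live gene.

For TATA-ablation experiments the ablated gene's promoter region, noncoding
exon, intron, UTR and adjacent upstream intergenic spacer are scrubbed of
chance TATAWA motifs, so "no TATA" is true of the whole region the
predictor can scan, not just of the planted box.

Ortholog pairs are derived by per-site substitution at a configurable rate
(transition:transversion 2:1).  Substitutions that would create an in-frame
stop are rejected, and functional anchors (start/stop codons, splice
dinucleotides, TATA boxes) are preserved — without this, 0.1 substitutions
per site would pseudogenize essentially every gene through chance nonsense
mutations and the ortholog truth map would be vacuous.  The expected
protein identity under this model is computable in closed form by
enumerating all 64 outcome codons per planted codon (reassigning
stop-outcome mass to the original codon), and the generator is tested
against that expectation.  CBP cluster paralogs are mutated 15% apart in
amino-acid space so that within-family paralogy does not swamp
between-species orthology at the divergences studied.  Indel divergence is
not modelled (substitutions plus repeat-unit insertion only).

Tissue reads are error-free by default (the downstream counting rule is
100% identity), exact substrings of spliced transcripts, with per-tissue
counts multinomial under the expression profile.  The default profile is
skin-only for every intact EDC gene and uniform across skin/heart/liver for
the housekeeping control, 300 reads of 100 nt per tissue.

## Locus annotation

`find_flanked_region` locates each marker by translated search, extends the
best hit to include its stop codon, and returns the inter-marker interval
(exclusive of marker coding spans); markers on different scaffolds yield
per-scaffold segments flagged as discontinuities.  `order_scaffolds`
arranges fragmented segments by the reference order of their hit families,
flagging segments whose own anchors are contradictory rather than placing
them silently.

`predict_sedc_genes` scans all six frames for ORFs (first ATG after a stop,
to the next stop) of ≥ `min_codons` (default 50 — EDC proteins are short;
the cutoff is an artifact choice).  An ORF becomes a candidate if it
overlaps a same-strand homology hit or if its G+S+P+K+C+Q fraction reaches
`bias_threshold` (default 0.5).  For each candidate the transcript strand
is searched upstream of the ATG for an acceptor AG within `utr_window`
(40 nt), donor GTs across the plausible intron range (50–1000 nt, longest
first), and a TATAWA motif within `promoter_window` (250 nt) of the donor;
the 5' noncoding exon is attached only when both TATA and splice evidence
exist (its start is set 25 nt downstream of the TATA box, a convention —
the true TSS is not observable from sequence alone).  Overlapping
candidates in other frames or strands are kept but flagged: within a
cluster of mutually overlapping coding spans only the longest unflagged
candidate represents the locus, which suppresses the antisense shadow ORFs
that biased codon streams inevitably produce.  ORFs truncated by the
sequence end are emitted as partial.

`predict_sftp_genes` anchors the start codon from the N-terminal-most
translated hit of each query, scans every phase-0 donor-GT/acceptor-AG pair
up to the C-terminal-most hit, and keeps the join whose translation best
matches the query — provided it beats the intron-free interpretation.
Joins broken by internal stops are demoted to pseudogene candidates.

`classify_gene_status` labels candidates complete (stop-free ATG-initiated
CDS in assembled sequence), partial (truncated by scaffold end or N run) or
pseudogene (internal stop, or ≥ 30% truncation relative to an intact family
member at ≥ 80% identity).  Pseudogenes are retained in output but flagged
out of protein-level analyses.  `validate_with_reads` counts reads exactly
matching the spliced transcript, and the subset straddling the
noncoding/coding junction with ≥ `min_overhang` (8 nt) on each side as
intron-spanning.  Because candidate acceptance has no single published
rule, predictions carry a tiered confidence label (homology+reads /
homology / composition-only) instead of a hard accept/reject decision.

## Protein profiling

Composition percentages are exact per-residue tallies; X is excluded from
the denominator (and logged), since an unknown residue carries no
compositional information.  Enrichment uses the strict rule "percentage
exceeds the threshold" (default 20%), restricted by default to the
EDC-characteristic residues G, S, P, K, C, Q.  Terminal
transglutamination-motif scanning reports, within each 20-residue terminal
window, the maximal K+Q-density subspan of ≥ 5 residues when its K+Q
fraction reaches 0.4; window length and density threshold are artifact
choices exposed as parameters, the motifs being described only
qualitatively in the literature.

## Repeat profiling

Degenerate motifs use a small grammar transcribing the avian EDCRP repeat
notation directly: fixed residues, parenthesised alternatives, and `-`
inside a set marking the position optional — `CCDPCQ(K|-)(T|P)(V|-)`.
Copy counting finds the maximal tandem array by dynamic programming with at
most `max_mismatch` deviations per copy (default 1, reflecting the
described C-terminal variability) and inter-copy spacers of ≤ `max_spacer`
residues (default 2, the package's explicit proxy for how interrupted
arrays are counted).  Ties resolve to more copies, then fewer total
mismatches, then longer matched span, then leftmost start.  De novo
discovery finds unit lengths whose consecutive windows exceed
`min_period_identity` (0.7) and reports majority-rule consensus units;
arrays may be reported in any rotational phase of the planted unit.
Ortholog architecture comparison aligns the termini outside detected repeat
spans globally and reports terminal identity together with the signed
copy-number expansion; a protein without the repeat contributes its
midpoint as the terminus boundary.

## Expression counting

Matching is protein-level, mirroring a tBLASTn screen: a read counts for a
query iff one of its six frame translations shares a 100%-identical
substring of ≥ `min_match` residues with the query, with `min_match`
defaulting to ⌊read length / 3⌋ (full-read identity).  A consequence of
protein-level matching is that only reads whose complete in-frame codons
lie within the coding region can ever count — reads overlapping the UTR or
noncoding exon are invisible to the protein query, and (for 100-nt reads)
one of the three codon phases yields only 32 complete codons and also fails
the 33-residue default.  The tests compute their expected counts from that
geometry rather than from raw read totals.  Each read counts at most once
per query.  Specificity labels normalise counts by the housekeeping
control's per-tissue counts (never by library size): a gene is
tissue-specific when ≥ 90% of its normalised signal falls in one tissue,
and undetected below 5 raw reads.

## Comparative analysis

Orthology requires reciprocal best global-alignment hits *and* positional
agreement (locus rank delta ≤ 3), because a tandem cluster of similar
paralogs defeats sequence-only orthology; this mirrors the shared-synteny
reasoning of comparative EDC work.  Family censuses count complete,
partial and pseudogene members per species with explicit zeros;
unassignable genes fall into an "unclassified" family rather than being
dropped.  Family histories are mapped by Dollo parsimony — a single gain
on the stem of the most recent common ancestor of the possessing species,
any number of subsequent losses — with presence meaning at least one
intact (complete or partial) member; a pseudogene-only complement counts
as absence.  Ancestral copy numbers minimise total absolute change along
branches (linear-cost Sankoff; ties resolve to the smallest count), and
parent-to-child jumps of ≥ `expansion_fold` copies (default 4) emit
expansion/contraction events.  The expansion rule is a change *magnitude*,
not a ratio: under minimum-change reconstruction the reference
archosaur-to-crocodilian EDCH jump is +9 copies from an ancestral 4, which
a ratio-of-4 rule would narrowly miss.  No rates are estimated anywhere —
the underlying data support only a schematic model.  The comparative locus
map lists genes in locus order per species, collapses runs of more than
four family members into cluster boxes annotated with counts, draws
ortholog links, and marks assembly discontinuities with `~`.

## Pipeline and reproducibility

The `run` subcommand orchestrates simulate → annotate → profile → repeats →
express → compare from one YAML config.  All randomness flows from a single
mandatory seed through independent named substreams, so identical configs
reproduce byte-identical artifacts; the manifest records SHA-256 hashes of
every output.  A failing stage halts the run with the stage named and
partial outputs moved to a quarantine directory.

## Problem sizes used in validation

The recovery study uses 20 seeded loci of 20 SEDC + 2 SFTP + 4 pseudogene +
6 CBP genes each (≈ 55 kb per locus); ortholog-map recovery uses 10 seeded
locus pairs at 0.1 substitutions per site; oracle-equivalence checks use
200 random alignment pairs (length ≤ 8), 200 random repeat proteins
(≤ 60 residues) and every presence pattern on three 4–6-tip trees.  These
sizes give stable aggregate statistics (≈ 500 genes, ≈ 280 ortholog pairs)
while keeping a full validation run within a couple of minutes.

## What passing tests do and do not show

The generator produces idealised data: error-free reads, canonical splice
sites only, no indel divergence between orthologs, uniform codon usage, and
intergenic sequence that is uniformly random rather than repeat-laden.
Recovery statistics near 1.0 on this surface demonstrate that the
algorithms are correct and self-consistent, not that real-genome annotation
would achieve them: real assemblies add sequencing error, fragmented and
gap-ridden scaffolds, non-canonical gene structures and paralog tangles
beyond the CBP-style cluster modelled here.  Claims about real genomes
(specific per-protein cysteine counts, per-species family censuses)
require the public assemblies and are deliberately outside the test
surface; the operations that would compute them (`count_residue`,
`count_motif_copies`, `family_census`) are exercised on synthetic and
fixture data instead.
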