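# Methods

## Overview

`hogqc` assesses the quality of a whole protein-coding gene repertoire
(a proteome FASTA) against a reference database of hierarchical
orthologous groups (HOGs). A HOG is a gene family represented as a
nested hierarchy: the root HOG is the family, sub-HOGs are the
subfamilies created by duplication, and every (sub)HOG is *defined* at
the taxonomic node where it emerged. Three questions are answered:

1. **Where does this proteome come from?** The taxonomic levels of the
   HOGs its proteins are placed into pile up along the path from the
   taxonomy root to the source species; a second overrepresented path is
   evidence of contamination.
2. **Is it complete?** Compare against the *conserved repertoire* — the
   HOGs defined at the query's ancestral reference lineage that cover at
   least 80% of the lineage's species — and classify each as single
   copy, duplicated (expected/unexpected) or missing.
3. **Is it consistent?** Classify each gene as taxonomically consistent
   (its placed HOG has a representative of the lineage), contaminant,
   inconsistent, or unknown (unplaceable), and flag gene models that are
   partial mappings or fragments.

## Placement model

Queries are compared to families through a k-mer index over member
sequences. For a query with `n` distinct k-mers sharing `s` of them with
a family whose indexed k-mers occupy a fraction `p` of the k-mer space,
the family score is the negative log binomial tail

    score = −ln P[X ≥ s],  X ~ Binomial(n, p),

i.e. the improbability of the observed sharing arising by chance; `p` is
floored at 1e-12. The best-scoring family wins (ties: more shared
k-mers, then the lexicographically smallest id). Placement then descends
into subfamilies greedily, following only *subtree-specific* k-mers —
k-mers found in one child subtree and nowhere else in the family —
because k-mers the whole family shares carry no information about which
duplicate the query is. A query sharing no k-mer with any family is
unplaced.

The binomial tail is computed as `logsumexp` over `binom.logpmf` terms:
the library tail function underflows to −∞ at the extreme tails real
matches reach (hundreds of shared k-mers at `p ≈ 1e-9`), and the score
must stay finite and comparable there.

**K-mer length (default k = 10 residues).** The false-placement rate of
an unrelated sequence with `m` k-mers is roughly `m·K/20^k`, where `K`
is the number of indexed k-mers. The default synthetic database indexes
`K ≈ 6×10^5` k-mers, so k = 6 would give double-digit percent spurious
placement for short random ORFs, while k = 10 puts the rate near 1e-6
with little sensitivity cost: at the ~2–12% within-family divergence of
the synthetic worlds, a true query still keeps a clean-window rate of
0.9^10 ≈ 0.35 or better, hundreds of shared k-mers for a full-length
protein and dozens even for a 25-residue fragment. `k` is configurable
per database; scale it with index load.

**Overlap and length ratio.** The matched span runs from the first to
the end of the last query k-mer hit against the winning family; interior
gaps count as covered, because the partial-mapping rule concerns
unmatched *extremities* only. A placement is *partial* when the span
covers <80% of the query (strict), and a non-partial placement is a
*fragment* when the query is shorter than 50% (strict) of the median
member length of the (sub)HOG it was placed to.

**Isoform selection.** When several isoforms share a gene, the one with
the highest family score — the lowest placement p-value — represents the
gene; genes with only unplaced isoforms keep their longest isoform.
Ties fall back to length, then id, so selection is deterministic.

## Species identification and contamination

For every *distinct* placed HOG, the clade at its defining level gains
one occurrence `N`; `N' = N / (number of HOGs defined at the clade)`
corrects for clades that simply host many families. Clades with `N ≥ 3`
("more than two") are kept, the taxonomy is pruned to them plus their
ancestors, and a postorder traversal keeps a child clade *relevant*
against its parent only when, strictly,

    N_child  > N_parent  · D(parent, child)          and
    N'_child > N'_parent · |S_child| / |S_parent|,

where `D(x, y)` is the fraction of HOGs at `x` with a child HOG defined
at `y` (duplication richness of the branch; 0 when no HOGs are defined
at `x`) and `|S|` is the clade's species count. One relevant child
passes its candidates up; several pass all of them (multiple source
species, i.e. contamination); none stops the traversal at the current
node. Relevance is evaluated per pruned-tree edge with each clade's own
occurrence values.

Each likely clade then receives the proteins placed strictly inside its
private subtree (below its first common ancestor with any other likely
clade); the clade with the most proteins is the main taxon, the rest are
contaminants. Private subtrees of distinct likely clades are disjoint
by construction, so "ambiguous contaminants" are defined as the
unattributed proteins whose placed level is ancestral to two or more
contaminant clades while lying outside the main taxon's private subtree
— placements that prove *some* contaminant without naming it. They are
counted inside the contaminant fraction and flagged separately.

A user-supplied taxon replaces the inferred main taxon for lineage
selection; likely clades on its lineage are treated as the query itself
and contamination detection still runs against the rest.

**Known blind spot.** Contamination by a close relative inside the query
lineage adds occurrences only to clades already on the query's path and
is not detected; this is inherent to the path-overrepresentation signal,
and the test suite pins it as expected behaviour rather than a defect.

## Repertoires and classification

The ancestral reference lineage is the most recent clade containing the
query taxon with at least 5 database-represented species (warning flags:
genus or below = too specific; phylum or above = too broad; unranked
nodes never warn, since without a rank the node cannot be positioned
against those bounds). The conserved repertoire holds the HOGs defined
at that level with species coverage ≥ 0.8 (the strict-> variant is a
config switch); the lineage repertoire adds every family that emerged
below the lineage level and survives in at least one lineage species.

Completeness counts, per conserved HOG, the selected placements landing
in the HOG or its subtree: one → single, two or more → duplicated
(*unexpected* when all copies sit in the ancestral HOG itself, i.e. the
database documents no such duplication; *expected* as soon as any copy
resolves to a subfamily), zero → missing unless a placement on the HOG's
direct ancestral line, claimed by no other conserved HOG, rescues it as
a single underspecific hit. Ancestral-line hits never create
duplications.

Consistency is evaluated at the placed (sub)HOG: a representative of at
least one lineage species among its subtree members makes the protein
consistent; otherwise membership in a contaminant clade's attributed set
makes it (ambiguous) contaminant; otherwise it is inconsistent; unplaced
proteins are unknown. The five classes partition the selected genes
exactly, as the completeness classes partition the conserved repertoire;
percentages are computed before rounding and printed to two decimals.

## The synthetic world

The generator emulates a study design, not the tree of life: a species
taxonomy (default 24 species; bifurcating power-of-two splits, ranks
assigned by node height), gene families that are born at nodes, then
duplicate (p = 0.015/branch/lineage), die (p = 0.005) and accumulate
substitutions (0.02/site/branch) down the tree, one protein deposited
per surviving lineage per species, and one held-out query species whose
proteome comes from the same process but is excluded from the database.

Family births are deliberately concentrated: 45% at a designated
reference clade (8 species; the assessment yardstick needs a repertoire
of ~100+ HOGs defined exactly at the query's ancestral lineage for
deletion-recovery measurements to have sub-percent noise), 30% spread
over a disjoint contaminant-source clade (so a contaminant species'
proteome is ~95% clade-private, as real cross-domain contaminants are),
1% at the root, 5% on leaves (species-private families), and the rest
across other internal nodes in proportion to clade size. Universal
root-born families are kept rare on purpose: in real databases the
universal core resolves into clade-specific subfamilies through ancient
duplications, substructure the toy duplication process cannot generate
at this scale; modelling many unresolvable shared families would make
contaminant proteins look consistent in a way real placements do not.

Evolution is substitution-only (no indels), so member lengths within a
family equal the ancestral length and the family median: the fragment
rule's length ratio is then exact, which is what makes the sharp
<45%-flagged / >55%-unflagged recovery test meaningful. Consequences of
these simplifications: the world says nothing about how the method
behaves under length variation within families, domain shuffling,
alternative splicing, or genuinely novel genes — passing tests
demonstrate the *mechanics* (placement, traversal, classification,
boundaries) and planted-signal recovery, not real-data accuracy.

The corruption procedures mirror standard annotation failure modes:
random gene deletion; random ORFs from uniform codons translated until a
stop (kept if >20 aa; raw length geometric with mean 61/3 sense codons)
or from the source's empirical amino-acid+stop distribution; truncation
of 10–90% of a protein from a random end; pairwise fusion with 0–20%
trims at the joining ends; spiking of foreign proteins without
replacement. Every procedure takes a seed, returns a manifest naming
the affected proteins, and leaves untouched records byte-identical.

## Numerical and degenerate-input choices

- Even-count medians take the mean of the central pair.
- `D(x, y)` with no HOGs at `x` returns 0 (no duplication evidence).
- Retention filter reads the exclusion conjunctively — a family is
  dropped only when it is both small (≤5 proteins) *and* sparse
  (coverage < 0.5); a disjunctive switch exists.
- Queries shorter than k are unplaced (logged), not errors.
- All tie-breaks (root choice, descent, isoform, main taxon) end at the
  lexicographically smallest identifier, making every pipeline stage
  deterministic; outputs contain no timestamps, so identical inputs
  produce byte-identical files.
- Sequences may contain non-standard residues (B, Z, X, U); k-mers
  containing them are skipped by the indexer. Stop marks are stripped
  on input.

## Problem sizes

Default test and acceptance runs use the 24-species / 320-family world
(~180-protein query proteomes, ~6×10^5 indexed 10-mers). The full
pipeline runs in ~0.2 s per proteome; the complete test suite, including
90 deletion-recovery assessments and 100+ traversal-oracle fixtures,
finishes in well under a minute on one CPU.
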