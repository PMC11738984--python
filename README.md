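# hogqc

Quality assessment of whole protein-coding gene repertoires against a
reference database of hierarchical orthologous groups (HOGs).

Genome annotation pipelines produce proteomes with characteristic
defects — missing genes, spurious gene models, fragmented or fused
proteins, cross-species contamination — that single-gene checks do not
see. `hogqc` evaluates a proteome as a whole, for annotators, database
curators and comparative genomicists who need a quality gate before
downstream analysis. It is built around three ideas:

- **Placement.** Each protein is assigned to a gene family by k-mer
  content, scored with the binomial tail `−ln P[X ≥ s]` for sharing `s`
  of `n` k-mers with a family of background match rate `p` — then
  refined into the subfamily whose subtree-specific k-mers it carries.
- **Species identification.** The taxonomic levels of the placed HOGs
  accumulate along the path to the source species. Clade occurrences
  `N` (distinct placed HOGs per defining level) and their normalized
  form `N′ = N / #HOGs(level)` drive a postorder traversal that keeps a
  child clade only while `N_child > N_parent·D` and
  `N′_child > N′_parent·|S_child|/|S_parent|`; a second surviving path
  is a contamination call.
- **Two repertoires.** Completeness is measured against the *conserved
  repertoire* (HOGs defined at the query's ancestral lineage covering
  ≥80% of its species): single copy / duplicated / missing. Consistency
  classifies every selected gene as consistent, inconsistent,
  contaminant or unknown, with partial-mapping (<80% overlap) and
  fragment (<50% of family median length) flags.

A seeded synthetic-world generator (species tree, family
birth/duplication/loss, per-branch substitutions, held-out query
species) plus the six classic proteome-corruption procedures make the
entire pipeline testable without any external database.

## Worked example

Generate a synthetic world (reference database + held-out query
proteome), then assess the query:

```sh
hogqc simulate world --seed 1 --out demo
hogqc assess --db demo/db --fasta demo/query_raaaaa.fa --out demo/run
cat demo/run_summary.txt
```

```
# Proteome quality assessment
ancestral_lineage	raa
lineage_warning	none
conserved_hogs	141
selected_genes	178

## Completeness (conserved ancestral repertoire)
single	133	94.33%
duplicated_expected	3	2.13%
duplicated_unexpected	2	1.42%
missing	3	2.13%

## Consistency (selected genes)
consistent	177	99.44%
inconsistent	0	0.00%
contaminant	0	0.00%
ambiguous_contaminant	0	0.00%
unknown	1	0.56%

## Gene-model structure
partial	0.00%
fragment	0.00%

## Detected contaminant clades
contaminant	none
```

Reading it: the query species was identified automatically and its
ancestral reference lineage is the clade `raa` (no rank warning). Of
the 141 gene families conserved in that lineage, 94.3% are present in
single copy, 3.6% are duplicated (2.1% with duplications the database
documents, 1.4% without) and 2.1% are missing — the held-out species
genuinely lost a few families. 99.4% of the genes belong to families
known from the lineage; one protein (0.6%) is a species-private family
absent from the database, hence unknown; nothing is flagged partial,
fragmented or contaminant.

Corrupt the proteome and the report moves accordingly, e.g. spiking 50
foreign proteins:

```sh
hogqc simulate contaminate --fasta demo/query_raaaaa.fa \
    --contaminant-fasta <foreign.fa> --n 50 --seed 7 --out demo/spiked
hogqc assess --db demo/db --fasta demo/spiked.fa --out demo/spiked_run
```

adds the foreign clade to the contaminant list and moves the spiked
proteins into the contaminant class.

Other entry points: `hogqc build-db` (database from taxonomy + family
tables), `hogqc simulate missing|erroneous|fragment|fuse|contaminate`
(each writes a corrupted FASTA plus a ground-truth manifest) and
`hogqc compare-fragments` (overlap of fragmented gene-family sets,
`|A∩B|/min(|A|,|B|)` or reference-denominator mode). Everything is also
available as a library (`hogqc.run_full_assessment`, `hogqc.simulate`,
…); see `docs/methods.md` for the model, parameters and their defaults.

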