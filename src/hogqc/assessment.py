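"""Completeness and consistency assessment of a whole proteome.

Completeness asks: of the gene families every member of the query's
lineage is expected to carry (the *conserved repertoire*), how many does
the query have, in how many copies?  Consistency asks the reverse: of the
genes the query carries, how many belong to families known from its
lineage, how many to detected contaminants, how many to neither, and how
many are unplaceable?  Both assessments run on one selected isoform per
gene and are reported as percentages that partition their universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hogdb import HOGDatabase
from .placement import (
    Placement,
    place_proteome,
    select_isoforms,
)
from .species_inference import (
    NoIdentifiableTaxonError,
    TaxaInference,
    attribute_proteins,
    count_clade_occurrences,
    infer_taxa,
)
__all__ = [
    "ThresholdConfig",
    "CompletenessClass",
    "ConsistencyClass",
    "QualityReport",
    "select_ancestral_lineage",
    "conserved_repertoire",
    "lineage_repertoire",
    "assess_completeness",
    "assess_consistency",
    "fragment_set_overlap",
    "run_full_assessment",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """All tunable thresholds of the assessment, with field defaults.

    conserved_coverage:
        Minimum fraction of lineage species a HOG must cover to count as
        conserved (default 0.8; ``conserved_strict`` switches the boundary
        from ≥ to >).
    min_lineage_species:
        Minimum number of database species a clade needs to serve as the
        ancestral reference lineage (default 5).
    partial_overlap:
        Overlap fraction below which a placement is a partial mapping
        (default 0.8, strict <).
    fragment_length:
        Length ratio below which a non-partial placement is a fragment
        (default 0.5, strict <).
    min_clade_occurrence:
        Occurrence floor for species identification (default 3, i.e.
        "more than two").
    """

    conserved_coverage: float = 0.8
    conserved_strict: bool = False
    min_lineage_species: int = 5
    partial_overlap: float = 0.8
    fragment_length: float = 0.5
    min_clade_occurrence: int = 3

    def __post_init__(self) -> None:
        for name in ("conserved_coverage", "partial_overlap", "fragment_length"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("min_lineage_species", "min_clade_occurrence"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


class CompletenessClass:
    SINGLE = "single"
    DUPLICATED_EXPECTED = "duplicated_expected"
    DUPLICATED_UNEXPECTED = "duplicated_unexpected"
    MISSING = "missing"


class ConsistencyClass:
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    CONTAMINANT = "contaminant"
    AMBIGUOUS_CONTAMINANT = "ambiguous_contaminant"
    UNKNOWN = "unknown"


@dataclass
class ProteinAssessment:
    protein_id: str
    gene_id: str
    category: str
    partial: bool = False
    fragment: bool = False
    placed_hog: str | None = None
    root_hog: str | None = None


@dataclass
class QualityReport:
    """Full quality assessment of one proteome."""

    ancestral_lineage: str
    lineage_warning: str
    conserved_total: int
    completeness: dict[str, str]
    proteins: list[ProteinAssessment]
    taxa: TaxaInference | None
    selected: list[Placement]
    isoform_listing: list[tuple[str, str]]
    notes: list[str] = field(default_factory=list)

    # -- summaries -----------------------------------------------------------

    def completeness_counts(self) -> dict[str, int]:
        counts = {
            CompletenessClass.SINGLE: 0,
            CompletenessClass.DUPLICATED_EXPECTED: 0,
            CompletenessClass.DUPLICATED_UNEXPECTED: 0,
            CompletenessClass.MISSING: 0,
        }
        for cls in self.completeness.values():
            counts[cls] += 1
        return counts

    def consistency_counts(self) -> dict[str, int]:
        counts = {
            ConsistencyClass.CONSISTENT: 0,
            ConsistencyClass.INCONSISTENT: 0,
            ConsistencyClass.CONTAMINANT: 0,
            ConsistencyClass.AMBIGUOUS_CONTAMINANT: 0,
            ConsistencyClass.UNKNOWN: 0,
        }
        for pa in self.proteins:
            counts[pa.category] += 1
        return counts

    def completeness_percentages(self) -> dict[str, float]:
        counts = self.completeness_counts()
        total = self.conserved_total
        if total == 0:
            return {k: 0.0 for k in counts}
        return {k: round(100.0 * v / total, 2) for k, v in counts.items()}

    def consistency_percentages(self) -> dict[str, float]:
        counts = self.consistency_counts()
        total = len(self.proteins)
        if total == 0:
            return {k: 0.0 for k in counts}
        return {k: round(100.0 * v / total, 2) for k, v in counts.items()}

    def structure_percentages(self) -> dict[str, float]:
        total = len(self.proteins)
        if total == 0:
            return {"partial": 0.0, "fragment": 0.0}
        return {
            "partial": round(
                100.0 * sum(p.partial for p in self.proteins) / total, 2
            ),
            "fragment": round(
                100.0 * sum(p.fragment for p in self.proteins) / total, 2
            ),
        }

    @property
    def contaminant_clades(self) -> list[str]:
        return [] if self.taxa is None else list(self.taxa.contaminants)


# -- lineage and repertoires ---------------------------------------------------


def database_species(db: HOGDatabase) -> set[str]:
    """Species with at least one protein in the database."""
    out: set[str] = set()
    for hog in db.hogs.values():
        out |= hog.member_species()
    return out


def select_ancestral_lineage(
    taxon: str, db: HOGDatabase, cfg: ThresholdConfig = ThresholdConfig()
) -> tuple[str, str]:
    """Pick the ancestral reference lineage for a query taxon.

    Walks from the taxon toward the root and returns the most recent
    clade represented by at least ``cfg.min_lineage_species`` species in
    the database, together with its rank warning (narrow lineages — genus
    or below — lack power; broad ones — phylum and above — lack
    resolution).
    """
    tree = db.taxonomy
    db_sp = database_species(db)
    for clade in reversed(tree.lineage_path(taxon)):
        n = len(tree.species_under(clade) & db_sp)
        if n >= cfg.min_lineage_species:
            return clade, tree.rank_warning(clade)
    raise ValueError(
        f"database holds fewer than {cfg.min_lineage_species} species in "
        f"total; no usable ancestral lineage"
    )


def conserved_repertoire(
    lineage: str, db: HOGDatabase, cfg: ThresholdConfig = ThresholdConfig()
) -> set[str]:
    """HOGs defined at the lineage level covering enough of its species.

    These stand for single ancestral genes of the lineage's common
    ancestor that most descendants kept — the completeness yardstick.
    """
    out = set()
    for hid in db.hogs_defined_at(lineage):
        cov = db.species_coverage(hid)
        keep = cov > cfg.conserved_coverage if cfg.conserved_strict \
            else cov >= cfg.conserved_coverage
        if keep:
            out.add(hid)
    return out


def lineage_repertoire(
    lineage: str, db: HOGDatabase, cfg: ThresholdConfig = ThresholdConfig()
) -> set[str]:
    """Conserved repertoire plus families that emerged inside the lineage.

    A family that originated below the lineage level belongs as long as
    at least one lineage species still carries it.
    """
    out = set(conserved_repertoire(lineage, db, cfg))
    lineage_species = db.taxonomy.species_under(lineage)
    for hid, hog in db.hogs.items():
        if hog.level == lineage or not db.taxonomy.is_descendant(hog.level, lineage):
            continue
        members = {m.species_id for m in db.subtree_members(hid)}
        if members & lineage_species:
            out.add(hid)
    return out


# -- completeness --------------------------------------------------------------


def assess_completeness(
    selected: list[Placement],
    conserved: set[str],
    db: HOGDatabase,
) -> dict[str, str]:
    """Classify each conserved HOG as single / duplicated / missing.

    A placement counts toward a conserved HOG when it lands in the HOG
    itself or any of its subfamilies.  To be robust to minor placement
    errors, a conserved HOG with no such hit still counts as single copy
    if a placement sits on its direct ancestral line (an underspecific
    hit) and no other conserved HOG claims that same placement;
    ancestral-line hits never create duplications.

    Duplicated HOGs are *expected* when the extra copies land in
    documented subfamilies, *unexpected* when every copy piles into the
    ancestral HOG itself (the database knows no such duplication).
    """
    subtree_of: dict[str, str] = {}
    for h in conserved:
        for hid in db.subtree_hog_ids(h):
            assert hid not in subtree_of, "conserved HOG subtrees overlap"
            subtree_of[hid] = h

    ancestors_of: dict[str, list[str]] = {}
    for h in conserved:
        chain = []
        cur = db.hog(h).parent_hog
        while cur is not None:
            chain.append(cur)
            cur = db.hog(cur).parent_hog
        ancestors_of[h] = chain

    direct_hits: dict[str, list[Placement]] = {h: [] for h in conserved}
    ancestor_claims: dict[str, set[str]] = {}
    for p in selected:
        if p.placed_hog is None:
            continue
        target = subtree_of.get(p.placed_hog)
        if target is not None:
            direct_hits[target].append(p)
        else:
            for h in conserved:
                if p.placed_hog in ancestors_of[h]:
                    ancestor_claims.setdefault(p.protein_id, set()).add(h)

    result: dict[str, str] = {}
    for h in conserved:
        hits = direct_hits[h]
        if len(hits) >= 2:
            all_in_ancestral = all(p.placed_hog == h for p in hits)
            result[h] = (
                CompletenessClass.DUPLICATED_UNEXPECTED
                if all_in_ancestral
                else CompletenessClass.DUPLICATED_EXPECTED
            )
        elif len(hits) == 1:
            result[h] = CompletenessClass.SINGLE
        else:
            rescued = any(
                h in claims and len(claims) == 1
                for claims in ancestor_claims.values()
            )
            result[h] = (
                CompletenessClass.SINGLE if rescued else CompletenessClass.MISSING
            )
    return result


# -- consistency ---------------------------------------------------------------


def assess_consistency(
    selected: list[Placement],
    lineage: str,
    taxa: TaxaInference | None,
    db: HOGDatabase,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> list[ProteinAssessment]:
    """Classify each selected protein and flag its gene-model structure.

    Categories: *unknown* (unplaced), *consistent* (the placed HOG has a
    representative of at least one lineage species), *contaminant* /
    *ambiguous contaminant* (attributed to detected contaminant clades),
    *inconsistent* (placed, but no lineage or contaminant evidence).

    Structure flags apply to every placed protein: *partial* when the
    matched span covers less than ``cfg.partial_overlap`` of the query;
    *fragment* when a non-partial protein is shorter than
    ``cfg.fragment_length`` of its placed HOG's median member length.
    """
    lineage_species = db.taxonomy.species_under(lineage)
    contaminant_ids: set[str] = set()
    ambiguous_ids: set[str] = set()
    if taxa is not None:
        contaminant_ids = taxa.contaminant_proteins()
        ambiguous_ids = set(taxa.ambiguous_contaminant)

    out: list[ProteinAssessment] = []
    for p in selected:
        if p.placed_hog is None:
            out.append(
                ProteinAssessment(
                    protein_id=p.protein_id,
                    gene_id=p.gene_id,
                    category=ConsistencyClass.UNKNOWN,
                )
            )
            continue
        members = {m.species_id for m in db.subtree_members(p.placed_hog)}
        if members & lineage_species:
            category = ConsistencyClass.CONSISTENT
        elif p.protein_id in contaminant_ids:
            category = ConsistencyClass.CONTAMINANT
        elif p.protein_id in ambiguous_ids:
            category = ConsistencyClass.AMBIGUOUS_CONTAMINANT
        else:
            category = ConsistencyClass.INCONSISTENT
        partial = p.overlap_fraction is not None and \
            p.overlap_fraction < cfg.partial_overlap
        fragment = (not partial) and p.length_ratio is not None and \
            p.length_ratio < cfg.fragment_length
        out.append(
            ProteinAssessment(
                protein_id=p.protein_id,
                gene_id=p.gene_id,
                category=category,
                partial=partial,
                fragment=fragment,
                placed_hog=p.placed_hog,
                root_hog=p.root_hog,
            )
        )
    return out


# -- fragment-set comparison ---------------------------------------------------


def fragment_set_overlap(a: set[str], b: set[str], mode: str = "symmetric") -> float:
    """Overlap between two sets of fragmented gene families (root HOGs).

    ``symmetric`` divides the intersection by the smaller set, so a small
    set fully nested in a large one still scores 1.0; ``reference``
    divides by ``|a|`` (treat ``a`` as the reference fragment set).
    """
    if mode not in ("symmetric", "reference"):
        raise ValueError(f"unknown mode {mode!r}")
    denom = min(len(a), len(b)) if mode == "symmetric" else len(a)
    if denom == 0:
        raise ValueError("empty denominator set")
    return len(a & b) / denom


# -- the full pipeline ---------------------------------------------------------


def run_full_assessment(
    records: list[tuple[str, str]],
    db: HOGDatabase,
    cfg: ThresholdConfig = ThresholdConfig(),
    taxon: str | None = None,
    gene_map: dict[str, str] | None = None,
) -> QualityReport:
    """Assess one proteome end to end.

    Pipeline: placement → isoform selection → clade-occurrence counting →
    species identification (skipped for lineage choice when ``taxon`` is
    given, but contamination detection still runs) → ancestral-lineage
    selection → conserved repertoire → completeness → consistency.
    """
    if not records:
        raise ValueError("empty proteome")
    notes: list[str] = []
    placements = place_proteome(records, db, gene_map=gene_map)
    selected, listing = select_isoforms(placements)

    occurrences = count_clade_occurrences(selected, db)
    taxa: TaxaInference | None = None
    try:
        likely = infer_taxa(occurrences, db,
                            min_occurrence=cfg.min_clade_occurrence)
        taxa = attribute_proteins(selected, likely, db)
        taxa.occurrences = {o.clade: o for o in occurrences}
    except NoIdentifiableTaxonError:
        if taxon is None:
            raise
        notes.append("species identification found no overrepresented clade; "
                     "using the user-supplied taxon only")

    if taxon is not None:
        main = taxon
        if taxa is not None:
            # contaminants are the likely clades unrelated to the user's
            # taxon; a clade on its lineage is the query itself
            tree = db.taxonomy
            related = [
                c for c in taxa.likely_clades
                if tree.is_descendant(taxon, c) or tree.is_descendant(c, taxon)
            ]
            taxa.main_taxon = related[0] if related else taxon
            taxa.contaminants = [
                c for c in taxa.likely_clades if c not in related
            ]
            if len(related) > 1:
                notes.append(
                    f"several likely clades lie on the lineage of {taxon}: "
                    f"{related}"
                )
    else:
        assert taxa is not None
        main = taxa.main_taxon

    lineage, warning = select_ancestral_lineage(main, db, cfg)
    conserved = conserved_repertoire(lineage, db, cfg)
    if not conserved:
        notes.append(f"conserved repertoire at {lineage} is empty")
    completeness = assess_completeness(selected, conserved, db)
    proteins = assess_consistency(selected, lineage, taxa, db, cfg)

    return QualityReport(
        ancestral_lineage=lineage,
        lineage_warning=warning,
        conserved_total=len(conserved),
        completeness=completeness,
        proteins=proteins,
        taxa=taxa,
        selected=selected,
        isoform_listing=listing,
        notes=notes,
    )
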