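"""Automatic species identification and contamination detection.

The taxonomic levels of the HOGs a proteome is placed into betray where
the proteome comes from: a clean proteome's placements pile up along the
path from the taxonomy root to its species, while contamination shows up
as a second, disjoint path with more placements than chance would give.

The detector counts, per clade, the number of distinct placed HOGs whose
defining level is that clade (the clade occurrence ``N``) and a
normalized occurrence ``N'`` = N divided by the number of HOGs defined at
the clade.  A recursive postorder traversal over a simplified taxonomy
then keeps descending toward clades that remain overrepresented after
correcting for duplication richness and species-sampling imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .hogdb import HOGDatabase
from .placement import Placement, _NegStr
from .taxonomy import TaxTree

__all__ = [
    "CladeOccurrence",
    "TaxaInference",
    "NoIdentifiableTaxonError",
    "count_clade_occurrences",
    "infer_taxa",
    "attribute_proteins",
]

#: Clades need an occurrence of more than this many distinct HOGs to take
#: part in species identification (noise floor).
MIN_CLADE_OCCURRENCE = 3


class NoIdentifiableTaxonError(ValueError):
    """No clade passed the occurrence filter: taxon cannot be inferred."""


@dataclass(frozen=True)
class CladeOccurrence:
    """Occurrence of one clade among the placements.

    ``n`` counts distinct placed HOGs defined at the clade; ``n_norm``
    divides by the number of HOGs the database defines there, correcting
    for clades that simply host many families.
    """

    clade: str
    n: int
    n_norm: float


@dataclass
class TaxaInference:
    """Outcome of species identification and protein attribution."""

    likely_clades: list[str]
    main_taxon: str
    contaminants: list[str] = field(default_factory=list)
    unambiguous: dict[str, set[str]] = field(default_factory=dict)
    ambiguous_contaminant: set[str] = field(default_factory=set)
    occurrences: dict[str, CladeOccurrence] = field(default_factory=dict)

    def contaminant_proteins(self) -> set[str]:
        out: set[str] = set()
        for clade in self.contaminants:
            out |= self.unambiguous.get(clade, set())
        return out


def count_clade_occurrences(
    placements: list[Placement], db: HOGDatabase
) -> list[CladeOccurrence]:
    """Tally occurrences per clade from the nonredundant placed-HOG list.

    Two proteins placed in the same HOG contribute once: the unit of
    evidence is the gene family (HOG), not the protein.
    """
    placed_hogs = {p.placed_hog for p in placements if p.placed_hog is not None}
    counts: dict[str, int] = {}
    for hid in placed_hogs:
        level = db.hog(hid).level
        counts[level] = counts.get(level, 0) + 1
    out = []
    for clade in sorted(counts):
        n = counts[clade]
        defined = db.n_hogs_defined_at(clade)
        assert n <= defined, "more distinct placed HOGs than HOGs defined"
        out.append(
            CladeOccurrence(clade=clade, n=n,
                            n_norm=n / defined if defined else 0.0)
        )
    return out


def _occurrence_maps(
    occurrences: list[CladeOccurrence],
) -> tuple[dict[str, int], dict[str, float]]:
    return (
        {o.clade: o.n for o in occurrences},
        {o.clade: o.n_norm for o in occurrences},
    )


def infer_taxa(
    occurrences: list[CladeOccurrence],
    db: HOGDatabase,
    min_occurrence: int = MIN_CLADE_OCCURRENCE,
) -> list[str]:
    """Return the likely taxa: independent overrepresented clades.

    Clades with occurrence below ``min_occurrence`` are dropped as noise;
    the taxonomy is pruned to the survivors, and a postorder traversal
    decides, edge by edge, whether a child clade stays *relevant* against
    its parent.  A child is relevant only if both hold strictly:

    - ``N_child > N_node * D(node, child)`` — its raw occurrence exceeds
      what the branch's documented duplication rate would push down;
    - ``N'_child > N'_node * |S_child| / |S_node|`` — its normalized
      occurrence exceeds what the branch's species-sampling share would.

    Exactly one relevant child passes its candidates up; several pass all
    of them up (multiple species in the proteome, i.e. contamination);
    none means the traversal stops at the current node.
    """
    n_map, nn_map = _occurrence_maps(occurrences)
    keep = {c for c, n in n_map.items() if n >= min_occurrence}
    if not keep:
        raise NoIdentifiableTaxonError(
            f"no clade has an occurrence of more than {min_occurrence - 1}"
        )
    pruned = db.taxonomy.prune_to_clades(keep)

    def n_of(clade: str) -> int:
        return n_map.get(clade, 0)

    def nn_of(clade: str) -> float:
        return nn_map.get(clade, 0.0)

    def _relevant(node: str, child: str) -> bool:
        d = db.duplication_fraction(node, child)
        s_node = len(db.taxonomy.species_under(node))
        s_child = len(db.taxonomy.species_under(child))
        cond1 = n_of(child) > n_of(node) * d
        cond2 = nn_of(child) > nn_of(node) * (s_child / s_node)
        return cond1 and cond2

    def _traverse(node: str) -> list[str]:
        children = pruned.node(node).children
        if not children:
            return [node]
        relevant = [c for c in children if _relevant(node, c)]
        if not relevant:
            return [node]
        out: list[str] = []
        for c in relevant:
            out.extend(_traverse(c))
        return out

    return _traverse(pruned.root_id)


def _first_common_ancestor(
    tree: TaxTree, clade: str, others: list[str]
) -> str | None:
    """Deepest ancestor that ``clade`` shares with any other likely clade."""
    if not others:
        return None
    best = None
    best_depth = -1
    for other in others:
        anc = tree.mrca(clade, other)
        depth = len(tree.lineage_path(anc))
        if depth > best_depth:
            best_depth = depth
            best = anc
    return best


def attribute_proteins(
    placements: list[Placement],
    likely_clades: list[str],
    db: HOGDatabase,
) -> TaxaInference:
    """Attribute proteins to likely clades and pick the main taxon.

    A protein belongs unambiguously to a clade when its placed HOG's
    level lies strictly inside that clade's private subtree — below the
    clade's first common ancestor with any other likely clade, on the
    branch leading to it.  The clade with the most unambiguous proteins
    is the main taxon; the rest are contaminants.

    Proteins placed at levels ancestral to several contaminant clades
    (but outside the main taxon's private subtree) cannot be pinned to
    one contaminant and are flagged ambiguous contaminants.
    """
    if not likely_clades:
        raise ValueError("likely_clades must be non-empty")
    tree = db.taxonomy
    # private subtree root per clade: the child of the first common
    # ancestor on the path toward the clade (whole tree if alone)
    private_root: dict[str, str] = {}
    for clade in likely_clades:
        others = [c for c in likely_clades if c != clade]
        fca = _first_common_ancestor(tree, clade, others)
        if fca is None:
            private_root[clade] = tree.root_id
        else:
            path = tree.lineage_path(clade)
            idx = path.index(fca)
            # clade may equal the fca if likely clades are nested; then
            # its private subtree is empty (represented by None below)
            private_root[clade] = path[idx + 1] if idx + 1 < len(path) else ""

    unambiguous: dict[str, set[str]] = {c: set() for c in likely_clades}
    unattributed: list[Placement] = []
    for p in placements:
        if p.placed_hog is None:
            continue
        level = db.hog(p.placed_hog).level
        hit = None
        for clade in likely_clades:
            root = private_root[clade]
            if root and tree.is_descendant(level, root):
                hit = clade
                break
        if hit is not None:
            unambiguous[hit].add(p.protein_id)
        else:
            unattributed.append(p)

    # main taxon: most unambiguous proteins; ties prefer the clade with
    # the larger distinct-HOG occurrence in its subtree, then the
    # smaller id
    occ = {c: 0 for c in likely_clades}
    placed_hogs = {p.placed_hog for p in placements if p.placed_hog}
    for hid in placed_hogs:
        level = db.hog(hid).level
        for clade in likely_clades:
            root = private_root[clade]
            if root and tree.is_descendant(level, root):
                occ[clade] += 1
    main = max(
        likely_clades,
        key=lambda c: (len(unambiguous[c]), occ[c], _NegStr(c)),
    )
    contaminants = [c for c in likely_clades if c != main]

    # ambiguous contaminants: level ancestral to >=2 contaminant clades,
    # outside the main taxon's private subtree
    ambiguous: set[str] = set()
    if len(contaminants) >= 2:
        main_root = private_root[main]
        for p in unattributed:
            level = db.hog(p.placed_hog).level
            if main_root and tree.is_descendant(level, main_root):
                continue
            n_below = sum(
                1 for c in contaminants if tree.is_descendant(c, level)
            )
            if n_below >= 2:
                ambiguous.add(p.protein_id)

    occurrences = {}  # filled by caller when available
    return TaxaInference(
        likely_clades=list(likely_clades),
        main_taxon=main,
        contaminants=contaminants,
        unambiguous=unambiguous,
        ambiguous_contaminant=ambiguous,
        occurrences=occurrences,
    )
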