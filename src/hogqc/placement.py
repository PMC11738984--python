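"""K-mer placement of query proteins into HOGs with binomial scoring.

Each query protein is compared to every gene family sharing at least one
k-mer with it.  The family match is scored by the upper tail of a binomial
distribution: the probability of sharing as many or more k-mers by chance,
given the family's background match rate.  The winning family is then
refined by greedy descent into the subfamily sharing the most k-mers.

This is a deliberately small stand-in for production k-mer placement
tools: it keeps the statistical scoring and the placement semantics, not
the engineering (no expected-count corrections, no compressed indexes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .hogdb import HOGDatabase, iter_kmers

__all__ = [
    "Placement",
    "family_score",
    "place_protein",
    "compute_overlap",
    "select_isoforms",
]


def family_score(shared: int, total: int, p_bg: float) -> float:
    """Negative log binomial tail: −ln P[X ≥ shared], X ~ Bin(total, p_bg).

    This is the family placement score: the improbability of sharing
    ``shared`` of ``total`` query k-mers with a family whose background
    match probability is ``p_bg``.  Monotone non-decreasing in ``shared``
    at fixed ``total``; zero when nothing is shared (P[X ≥ 0] = 1).

    Higher scores mean better (less probable by chance) matches.
    """
    if not 0 <= shared <= total:
        raise ValueError(f"need 0 <= shared <= total, got {shared}/{total}")
    if not 0.0 < p_bg < 1.0:
        raise ValueError(f"p_bg must be in (0, 1), got {p_bg}")
    if shared == 0:
        return 0.0
    # sum the tail in log space: binom.logsf underflows to -inf for the
    # extreme tails routinely reached by real family matches
    ks = np.arange(shared, total + 1)
    return float(-logsumexp(binom.logpmf(ks, total, p_bg)))


@dataclass
class Placement:
    """One query protein's best family assignment.

    ``placed_hog`` is the most specific (sub)HOG reached by descent;
    ``root_hog`` its family.  Both are ``None`` for unplaced proteins, in
    which case the score is 0 and overlap/length ratios are undefined
    (``None``).
    """

    protein_id: str
    gene_id: str
    query_length: int
    placed_hog: str | None = None
    root_hog: str | None = None
    score: float = 0.0
    shared_kmers: int = 0
    query_kmers: int = 0
    overlap_fraction: float | None = None
    length_ratio: float | None = None

    @property
    def is_placed(self) -> bool:
        return self.placed_hog is not None

    @property
    def is_partial(self) -> bool:
        """Matched span covers less than 80% of the query (strict)."""
        return self.is_placed and self.overlap_fraction is not None \
            and self.overlap_fraction < 0.8


def _query_kmers(seq: str, k: int) -> tuple[list[tuple[int, str]], set[str]]:
    positioned = list(iter_kmers(seq, k))
    return positioned, {km for _, km in positioned}


def compute_overlap(seq: str, root_hog: str, db: HOGDatabase) -> float:
    """Fraction of the query covered by the span of family k-mer hits.

    The covered span runs from the first matched k-mer position to the end
    of the last one; interior gaps count as covered — only unmatched
    *extremities* reduce the fraction, matching the partial-mapping rule.
    """
    root_kmers = db.subtree_kmers(root_hog)
    positions = [i for i, km in iter_kmers(seq, db.k) if km in root_kmers]
    if not positions:
        raise ValueError(f"no shared k-mers with {root_hog!r}: not placed there")
    span = positions[-1] + db.k - positions[0]
    return span / len(seq)


def place_protein(
    protein_id: str,
    seq: str,
    db: HOGDatabase,
    gene_id: str | None = None,
) -> Placement:
    """Place one query protein into the database's family hierarchy.

    The best root HOG maximizes the binomial family score among families
    sharing at least one k-mer (ties: more shared k-mers, then smallest
    family id).  Placement then descends greedily into the sub-HOG whose
    subtree shares the most k-mers with the query, stopping when no child
    subtree shares any.  Queries shorter than k, or sharing no k-mer with
    any family, come back unplaced.
    """
    placement = Placement(
        protein_id=protein_id,
        gene_id=gene_id or protein_id,
        query_length=len(seq),
    )
    positioned, qset = _query_kmers(seq, db.k)
    placement.query_kmers = len(qset)
    if not qset:
        return placement

    # tally shared k-mers per candidate root family
    shared_by_root: dict[str, int] = {}
    for km in qset:
        for root in db.kmer_index.get(km, ()):
            shared_by_root[root] = shared_by_root.get(root, 0) + 1
    if not shared_by_root:
        return placement

    best_root = None
    best_key: tuple[float, int, str] | None = None
    for root, shared in shared_by_root.items():
        score = family_score(shared, len(qset), db.p_bg(root))
        # sort key: higher score, then more shared, then smaller id
        key = (score, shared, _NegStr(root))
        if best_key is None or key > best_key:
            best_key = key
            best_root = root
    assert best_root is not None and best_key is not None

    # greedy descent into subfamilies, driven by subtree-specific
    # k-mers only: k-mers the whole family shares carry no signal about
    # which duplicate the query is
    current = best_root
    while True:
        children = db.hog(current).children_hogs
        best_child = None
        best_child_key: tuple[int, str] | None = None
        for child in children:
            shared = len(qset & db.specific_kmers(child))
            if shared == 0:
                continue
            key = (shared, _NegStr(child))
            if best_child_key is None or key > best_child_key:
                best_child_key = key
                best_child = child
        if best_child is None:
            break
        current = best_child

    placement.root_hog = best_root
    placement.placed_hog = current
    placement.score = best_key[0]
    placement.shared_kmers = shared_by_root[best_root]
    placement.overlap_fraction = compute_overlap(seq, best_root, db)
    ref_hog = current if db.subtree_members(current) else best_root
    placement.length_ratio = len(seq) / db.median_member_length(ref_hog)
    return placement


class _NegStr(str):
    """String whose ordering is reversed, so max() prefers smaller ids."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def place_proteome(
    records: Sequence[tuple[str, str]],
    db: HOGDatabase,
    gene_map: dict[str, str] | None = None,
) -> list[Placement]:
    """Place every record of a proteome; order follows the input."""
    gene_map = gene_map or {}
    return [
        place_protein(pid, seq, db, gene_id=gene_map.get(pid, pid))
        for pid, seq in records
    ]


def select_isoforms(
    placements: Iterable[Placement],
) -> tuple[list[Placement], list[tuple[str, str]]]:
    """Pick one reference isoform per gene.

    Among placed isoforms of a gene the one with the highest family score
    — that is, the lowest placement p-value — wins; genes whose isoforms
    are all unplaced keep their longest one.  Ties fall back to length,
    then to the smallest protein id, so selection is deterministic.

    Returns the selected placements (input order of their genes) and a
    ``(gene_id, protein_id)`` listing for the selection report.
    """
    groups: dict[str, list[Placement]] = {}
    order: list[str] = []
    seen_proteins: set[str] = set()
    for p in placements:
        if p.protein_id in seen_proteins:
            raise ValueError(f"protein {p.protein_id!r} appears twice")
        seen_proteins.add(p.protein_id)
        if p.gene_id not in groups:
            order.append(p.gene_id)
            groups[p.gene_id] = []
        groups[p.gene_id].append(p)

    selected: list[Placement] = []
    listing: list[tuple[str, str]] = []
    for gene in order:
        cands = groups[gene]
        best = max(
            cands,
            key=lambda p: (p.score, p.query_length, _NegStr(p.protein_id)),
        )
        selected.append(best)
        listing.append((gene, best.protein_id))
    return selected, listing


PLACEMENT_COLUMNS = [
    "protein_id",
    "gene_id",
    "hog_id",
    "root_id",
    "family_score",
    "shared_kmers",
    "query_kmers",
    "overlap_fraction",
    "length_ratio",
]


def placements_to_table(placements: Iterable[Placement]) -> str:
    """Stable tab-separated placement dump (header + one row per protein)."""
    lines = ["\t".join(PLACEMENT_COLUMNS)]
    for p in placements:
        lines.append(
            "\t".join(
                [
                    p.protein_id,
                    p.gene_id,
                    p.placed_hog or "NA",
                    p.root_hog or "NA",
                    f"{p.score:.6f}",
                    str(p.shared_kmers),
                    str(p.query_kmers),
                    "NA" if p.overlap_fraction is None else f"{p.overlap_fraction:.4f}",
                    "NA" if p.length_ratio is None else f"{p.length_ratio:.4f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"
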