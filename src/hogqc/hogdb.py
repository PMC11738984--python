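"""Reference database of nested gene families (HOGs) over a taxonomy.

A HOG (hierarchical orthologous group) is a gene family represented as a
nested hierarchy: the root HOG is the whole family, and sub-HOGs are the
subfamilies created by duplication events.  Every (sub)HOG is *defined* at
the taxonomic node where it emerged — the node right after the speciation
or duplication event that created it.  Member proteins are attached to the
most specific (sub)HOG they belong to.

The database couples the family hierarchy with a k-mer index over member
sequences, which is what the placement engine queries, plus the coverage,
duplication and length statistics the assessment stages need.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable

import yaml

from .taxonomy import TaxTree, TaxonomyError, UnknownNodeError

__all__ = [
    "HOGMember",
    "HOG",
    "HOGDatabase",
    "build_database",
    "read_family_table",
    "write_family_table",
    "DatabaseBuildError",
]

#: The 20 standard amino acids; k-mers containing anything else (B, Z, X,
#: U, stop marks...) are skipped by the indexer.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Floor for the per-family background k-mer match probability.
P_BG_FLOOR = 1e-12


class DatabaseBuildError(ValueError):
    """Raised when family definitions are inconsistent with the taxonomy."""


@dataclass(frozen=True)
class HOGMember:
    species_id: str
    protein_id: str
    length: int
    sequence: str | None = None


@dataclass
class HOG:
    """One (sub)family in the nested hierarchy.

    ``root_id`` equals ``hog_id`` for root HOGs and is filled in during
    database construction for sub-HOGs.
    """

    hog_id: str
    level: str
    parent_hog: str | None = None
    root_id: str = ""
    children_hogs: list[str] = field(default_factory=list)
    members: list[HOGMember] = field(default_factory=list)

    @property
    def is_root(self) -> bool:
        return self.parent_hog is None

    def member_species(self) -> set[str]:
        return {m.species_id for m in self.members}


def iter_kmers(sequence: str, k: int) -> Iterable[tuple[int, str]]:
    """Yield ``(position, kmer)`` for every valid k-mer of a sequence.

    K-mers containing non-standard residues are skipped; positions are
    0-based offsets into the (uppercased) sequence.
    """
    seq = sequence.upper()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if all(c in _AA_SET for c in kmer):
            yield i, kmer


class HOGDatabase:
    """Indexed, filtered collection of HOGs bound to a taxonomy.

    Use :func:`build_database` to construct one; the constructor assumes
    families already validated and filtered.
    """

    def __init__(self, taxonomy: TaxTree, hogs: dict[str, HOG], k: int):
        self.taxonomy = taxonomy
        self.hogs = hogs
        self.k = k
        self._subtree_members: dict[str, list[HOGMember]] = {}
        self._subtree_kmers: dict[str, frozenset[str]] = {}
        self._specific_kmers: dict[str, frozenset[str]] = {}
        self._by_level: dict[str, list[str]] = {}
        self._median_cache: dict[str, float] = {}
        self.kmer_index: dict[str, set[str]] = {}
        self._p_bg: dict[str, float] = {}
        self._reindex()

    # -- construction --------------------------------------------------------

    def _reindex(self) -> None:
        self._by_level.clear()
        for hog in self.hogs.values():
            self._by_level.setdefault(hog.level, []).append(hog.hog_id)
        # subtree member lists, bottom-up
        order = sorted(self.hogs, key=lambda h: -self._depth(h))
        for hid in order:
            hog = self.hogs[hid]
            acc = list(hog.members)
            for child in hog.children_hogs:
                acc.extend(self._subtree_members[child])
            self._subtree_members[hid] = acc
        # k-mer sets per HOG subtree, and global index over roots
        self.kmer_index.clear()
        for hid in order:
            hog = self.hogs[hid]
            kmers: set[str] = set()
            for m in hog.members:
                if m.sequence:
                    kmers.update(km for _, km in iter_kmers(m.sequence, self.k))
            for child in hog.children_hogs:
                kmers |= self._subtree_kmers[child]
            self._subtree_kmers[hid] = frozenset(kmers)
        # per-child specific k-mers: found in that child's subtree and
        # nowhere else under the parent; greedy placement descent must
        # not follow k-mers the whole family shares
        for hid, hog in self.hogs.items():
            own = set()
            for m in hog.members:
                if m.sequence:
                    own.update(km for _, km in iter_kmers(m.sequence, self.k))
            for child in hog.children_hogs:
                specific = set(self._subtree_kmers[child]) - own
                for sibling in hog.children_hogs:
                    if sibling != child:
                        specific -= self._subtree_kmers[sibling]
                self._specific_kmers[child] = frozenset(specific)
        space = float(len(AMINO_ACIDS)) ** self.k
        for hid, hog in self.hogs.items():
            if hog.is_root:
                for km in self._subtree_kmers[hid]:
                    self.kmer_index.setdefault(km, set()).add(hid)
                self._p_bg[hid] = max(
                    len(self._subtree_kmers[hid]) / space, P_BG_FLOOR
                )

    def _depth(self, hog_id: str) -> int:
        d = 0
        cur = self.hogs[hog_id]
        while cur.parent_hog is not None:
            cur = self.hogs[cur.parent_hog]
            d += 1
        return d

    # -- accessors -----------------------------------------------------------

    def hog(self, hog_id: str) -> HOG:
        try:
            return self.hogs[hog_id]
        except KeyError:
            raise UnknownNodeError(f"unknown HOG {hog_id!r}") from None

    def root_ids(self) -> list[str]:
        return [h for h, hog in self.hogs.items() if hog.is_root]

    def subtree_members(self, hog_id: str) -> list[HOGMember]:
        """All members attached to a HOG or any of its sub-HOGs."""
        self.hog(hog_id)
        return self._subtree_members[hog_id]

    def subtree_kmers(self, hog_id: str) -> frozenset[str]:
        self.hog(hog_id)
        return self._subtree_kmers[hog_id]

    def specific_kmers(self, hog_id: str) -> frozenset[str]:
        """K-mers unique to this sub-HOG's subtree within its parent.

        Empty (and undefined) for root HOGs, which have no siblings to
        be specific against.
        """
        self.hog(hog_id)
        return self._specific_kmers.get(hog_id, frozenset())

    def subtree_hog_ids(self, hog_id: str) -> list[str]:
        """The HOG itself plus all its descendant sub-HOG ids."""
        out = [hog_id]
        stack = list(self.hog(hog_id).children_hogs)
        while stack:
            hid = stack.pop()
            out.append(hid)
            stack.extend(self.hogs[hid].children_hogs)
        return out

    def p_bg(self, root_id: str) -> float:
        """Background k-mer match probability for one family.

        Fraction of the k-mer space indexed for that root HOG, floored to
        stay strictly positive: larger families match random queries more
        often by chance, and the binomial score must account for that.
        """
        return self._p_bg[root_id]

    # -- statistics ----------------------------------------------------------

    def species_coverage(self, hog_id: str) -> float:
        """Proportion of species under the HOG's level with a gene in it.

        Membership is evaluated over the whole subtree: a gene in a
        subfamily is a gene in the family.
        """
        hog = self.hog(hog_id)
        species = self.taxonomy.species_under(hog.level)
        if not species:
            raise TaxonomyError(
                f"level {hog.level!r} of HOG {hog_id!r} has no species"
            )
        present = {m.species_id for m in self._subtree_members[hog_id]}
        return len(present & species) / len(species)

    def hogs_defined_at(self, level: str) -> list[str]:
        """Ids of all HOGs — roots and subfamilies — defined at a level."""
        return list(self._by_level.get(level, []))

    def n_hogs_defined_at(self, level: str) -> int:
        return len(self._by_level.get(level, []))

    def duplication_fraction(self, x: str, y: str) -> float:
        """D_{x,y}: fraction of HOGs at clade x with a child HOG at clade y.

        A high value means the branch from x to y carries many documented
        duplications (for example an ancestral whole-genome duplication),
        which inflates placements into y.  Returns 0 when no HOGs are
        defined at x: absence of families is absence of duplication
        evidence.
        """
        if x == y or not self.taxonomy.is_descendant(y, x):
            raise TaxonomyError(f"{y!r} is not a strict descendant of {x!r}")
        at_x = self._by_level.get(x, [])
        if not at_x:
            return 0.0
        n_dup = 0
        for hid in at_x:
            if any(self.hogs[c].level == y for c in self.hogs[hid].children_hogs):
                n_dup += 1
        return n_dup / len(at_x)

    def median_member_length(self, hog_id: str) -> float:
        """Median protein length over the HOG's subtree members.

        Even counts take the mean of the central pair.
        """
        cached = self._median_cache.get(hog_id)
        if cached is not None:
            return cached
        members = self.subtree_members(hog_id)
        if not members:
            raise ValueError(f"HOG {hog_id!r} has no members")
        value = float(median(m.length for m in members))
        self._median_cache[hog_id] = value
        return value

    # -- serialization -------------------------------------------------------

    def save(self, path: str) -> None:
        """Write the database as a directory archive.

        Layout: ``meta.yaml`` (format version, k), ``taxonomy.tsv`` and
        ``hogs.tsv`` (one row per member, plus member-less structural
        rows).  The k-mer index is derived data and is rebuilt on load.
        """
        os.makedirs(path, exist_ok=True)
        with open(os.path.join(path, "meta.yaml"), "w") as fh:
            yaml.safe_dump({"format": "hogqc-db", "version": 1, "k": self.k}, fh)
        self.taxonomy.write_table(os.path.join(path, "taxonomy.tsv"))
        with open(os.path.join(path, "hogs.tsv"), "w") as fh:
            fh.write(write_family_table(self.hogs.values()))

    @classmethod
    def load(cls, path: str) -> "HOGDatabase":
        with open(os.path.join(path, "meta.yaml")) as fh:
            meta = yaml.safe_load(fh)
        if meta.get("format") != "hogqc-db":
            raise DatabaseBuildError(f"not a hogqc database: {path}")
        with open(os.path.join(path, "taxonomy.tsv")) as fh:
            taxonomy = TaxTree.from_table(fh.read())
        with open(os.path.join(path, "hogs.tsv")) as fh:
            families = read_family_table(fh.read())
        # families in an archive were already filtered at build time
        return build_database(taxonomy, families, k=int(meta["k"]),
                              apply_retention_filter=False)


# -- building ----------------------------------------------------------------

def _family_roots(hogs: Iterable[HOG]) -> list[HOG]:
    return [h for h in hogs if h.parent_hog is None]


def build_database(
    taxonomy: TaxTree,
    families: Iterable[HOG],
    k: int = 6,
    *,
    apply_retention_filter: bool = True,
    disjunctive_filter: bool = False,
) -> HOGDatabase:
    """Validate, filter and index family definitions into a database.

    Root HOGs that look spurious are dropped with their whole subtree.
    The default retention rule excludes a family only when it is both
    small (five or fewer proteins) and sparse (species coverage below
    0.5); ``disjunctive_filter=True`` switches to excluding families
    failing either criterion.

    Parameters
    ----------
    taxonomy:
        The reference taxonomy; every HOG level must be one of its nodes.
    families:
        All HOGs (roots and subfamilies) with members attached to their
        most specific HOG.
    k:
        K-mer length in residues (≥ 4).
    """
    if k < 4:
        raise ValueError("k must be at least 4 residues")
    hogs: dict[str, HOG] = {}
    for hog in families:
        if hog.hog_id in hogs:
            raise DatabaseBuildError(f"duplicate HOG id {hog.hog_id!r}")
        hogs[hog.hog_id] = hog

    # resolve hierarchy links and root ids
    for hog in hogs.values():
        hog.children_hogs = []
    for hog in hogs.values():
        if hog.parent_hog is not None:
            parent = hogs.get(hog.parent_hog)
            if parent is None:
                raise DatabaseBuildError(
                    f"HOG {hog.hog_id!r} references unknown parent "
                    f"{hog.parent_hog!r}"
                )
            parent.children_hogs.append(hog.hog_id)
    for hog in hogs.values():
        cur = hog
        while cur.parent_hog is not None:
            cur = hogs[cur.parent_hog]
        hog.root_id = cur.hog_id

    # validate levels
    for hog in hogs.values():
        if hog.level not in taxonomy:
            raise DatabaseBuildError(
                f"family {hog.root_id!r}: HOG {hog.hog_id!r} has level "
                f"{hog.level!r} not in the taxonomy"
            )
        if hog.parent_hog is not None:
            parent_level = hogs[hog.parent_hog].level
            if hog.level == parent_level or not taxonomy.is_descendant(
                hog.level, parent_level
            ):
                raise DatabaseBuildError(
                    f"family {hog.root_id!r}: sub-HOG {hog.hog_id!r} level "
                    f"{hog.level!r} is not a strict descendant of its "
                    f"parent's level {parent_level!r}"
                )
        member_species = hog.member_species()
        allowed = taxonomy.species_under(hog.level)
        stray = member_species - allowed
        if stray:
            raise DatabaseBuildError(
                f"HOG {hog.hog_id!r}: member species {sorted(stray)} are "
                f"not under level {hog.level!r}"
            )

    # retention filter on root HOGs
    if apply_retention_filter:
        kept: dict[str, HOG] = {}
        subtree: dict[str, list[str]] = {}

        def _collect(hid: str) -> list[str]:
            out = [hid]
            for child in hogs[hid].children_hogs:
                out.extend(_collect(child))
            return out

        for root in _family_roots(hogs.values()):
            ids = _collect(root.hog_id)
            members = [m for hid in ids for m in hogs[hid].members]
            n_prot = len(members)
            species = {m.species_id for m in members}
            clade_species = taxonomy.species_under(root.level)
            if not clade_species:
                raise TaxonomyError(
                    f"level {root.level!r} of HOG {root.hog_id!r} has no species"
                )
            coverage = len(species & clade_species) / len(clade_species)
            small = n_prot <= 5
            sparse = coverage < 0.5
            excluded = (small or sparse) if disjunctive_filter else (small and sparse)
            if not excluded:
                for hid in ids:
                    kept[hid] = hogs[hid]
        hogs = kept

    return HOGDatabase(taxonomy, dict(hogs), k)


# -- family table I/O ---------------------------------------------------------

_FAMILY_HEADER = "hog_id\tparent_hog\tlevel\tspecies\tprotein_id\tlength\tsequence"


def write_family_table(hogs: Iterable[HOG]) -> str:
    """Tab-separated family dump, one row per member.

    HOGs without members of their own emit a single structural row with
    empty member columns so the hierarchy survives a round-trip.
    """
    lines = [_FAMILY_HEADER]
    for hog in sorted(hogs, key=lambda h: h.hog_id):
        if hog.members:
            for m in hog.members:
                lines.append(
                    f"{hog.hog_id}\t{hog.parent_hog or ''}\t{hog.level}\t"
                    f"{m.species_id}\t{m.protein_id}\t{m.length}\t{m.sequence or ''}"
                )
        else:
            lines.append(f"{hog.hog_id}\t{hog.parent_hog or ''}\t{hog.level}\t\t\t\t")
    return "\n".join(lines) + "\n"


def read_family_table(text: str) -> list[HOG]:
    hogs: dict[str, HOG] = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines and lines[0].startswith("hog_id"):
        lines = lines[1:]
    for ln in lines:
        fields = ln.split("\t")
        if len(fields) != 7:
            raise DatabaseBuildError(f"bad family table row: {ln!r}")
        hog_id, parent, level, species, protein_id, length, sequence = fields
        hog = hogs.get(hog_id)
        if hog is None:
            hog = HOG(hog_id=hog_id, level=level, parent_hog=parent or None)
            hogs[hog_id] = hog
        if species:
            hog.members.append(
                HOGMember(
                    species_id=species,
                    protein_id=protein_id,
                    length=int(length),
                    sequence=sequence or None,
                )
            )
    return list(hogs.values())
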