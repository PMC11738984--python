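"""Rooted taxonomy trees with species sets, lineages, pruning and rank warnings.

The taxonomy is the scaffold for everything else in :mod:`hogqc`: gene
families are bound to taxonomic levels, species identification walks the
tree, and the ancestral reference lineage is picked along a lineage path.
Species are, by construction, exactly the leaves of the tree.

Node identifiers are opaque strings.  When a taxonomy is derived from NCBI
data the identifiers hold numeric taxids as strings; synthetic taxonomies
use whatever labels the generator assigned.  This keeps real and simulated
worlds interchangeable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = [
    "TaxNode",
    "TaxTree",
    "RankWarning",
    "TaxonomyError",
    "UnknownNodeError",
]


class TaxonomyError(ValueError):
    """Malformed taxonomy or invalid taxonomy operation."""


class UnknownNodeError(KeyError):
    """A node id was looked up that is not part of the tree."""


#: Canonical rank ordering, most specific first.  Used only to decide on
#: which side of the genus/phylum bounds a rank falls; ranks absent from
#: this list (including "no rank") never trigger a warning.
CANONICAL_RANKS = [
    "subspecies",
    "species",
    "subgenus",
    "genus",
    "subfamily",
    "family",
    "superfamily",
    "suborder",
    "order",
    "superorder",
    "subclass",
    "class",
    "superclass",
    "subphylum",
    "phylum",
    "superphylum",
    "kingdom",
    "superkingdom",
    "domain",
]

_RANK_INDEX = {r: i for i, r in enumerate(CANONICAL_RANKS)}
_GENUS_IDX = _RANK_INDEX["genus"]
_PHYLUM_IDX = _RANK_INDEX["phylum"]


class RankWarning:
    """Warning flags for ancestral-lineage rank sanity checks."""

    NONE = "none"
    TOO_SPECIFIC = "too_specific"
    TOO_BROAD = "too_broad"


@dataclass
class TaxNode:
    """One node of the taxonomy.

    Parameters
    ----------
    node_id:
        Stable opaque identifier.
    name:
        Human-readable label (defaults to the id).
    rank:
        Taxonomic rank label such as ``"species"``, ``"genus"``,
        ``"phylum"`` or ``"no rank"``.
    parent:
        Parent node id, or ``None`` for the root.
    children:
        Ordered child node ids.
    """

    node_id: str
    name: str = ""
    rank: str = "no rank"
    parent: str | None = None
    children: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            self.name = self.node_id

    @property
    def is_leaf(self) -> bool:
        return not self.children


class TaxTree:
    """A rooted taxonomy; leaves are species, internal nodes are clades.

    The constructor validates the tree shape: exactly one root, every
    parent pointer resolving inside the tree, no cycles, and parent/child
    pointers mutually consistent.
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        self._nodes: dict[str, TaxNode] = {}
        for node in nodes:
            if node.node_id in self._nodes:
                raise TaxonomyError(f"duplicate node id {node.node_id!r}")
            self._nodes[node.node_id] = node
        roots = [n for n in self._nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise TaxonomyError(
                f"taxonomy must have exactly one root, found {len(roots)}"
            )
        self._root_id = roots[0].node_id
        self._validate()
        self._species_cache: dict[str, frozenset[str]] = {}

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        for node in self._nodes.values():
            if node.parent is not None:
                if node.parent not in self._nodes:
                    raise TaxonomyError(
                        f"node {node.node_id!r} has unknown parent {node.parent!r}"
                    )
                if node.node_id not in self._nodes[node.parent].children:
                    raise TaxonomyError(
                        f"parent/child mismatch at {node.node_id!r}"
                    )
            for child in node.children:
                if child not in self._nodes:
                    raise TaxonomyError(
                        f"node {node.node_id!r} lists unknown child {child!r}"
                    )
                if self._nodes[child].parent != node.node_id:
                    raise TaxonomyError(
                        f"parent/child mismatch at {child!r}"
                    )
        # reachability doubles as the cycle check: every node must be
        # reachable from the single root by child pointers
        seen: set[str] = set()
        stack = [self._root_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise TaxonomyError("cycle detected in taxonomy")
            seen.add(nid)
            stack.extend(self._nodes[nid].children)
        if seen != set(self._nodes):
            orphans = set(self._nodes) - seen
            raise TaxonomyError(f"nodes unreachable from root: {sorted(orphans)}")

    # -- basic accessors -----------------------------------------------------

    @property
    def root_id(self) -> str:
        return self._root_id

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, node_id: str) -> TaxNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise UnknownNodeError(f"unknown taxonomy node {node_id!r}") from None

    def node_ids(self) -> Iterator[str]:
        return iter(self._nodes)

    def leaves(self) -> list[str]:
        """All species (leaf) ids, in insertion order."""
        return [nid for nid, n in self._nodes.items() if n.is_leaf]

    def postorder(self) -> Iterator[str]:
        """Node ids in postorder (children before parents)."""

        def _walk(nid: str) -> Iterator[str]:
            for child in self._nodes[nid].children:
                yield from _walk(child)
            yield nid

        return _walk(self._root_id)

    # -- core operations -----------------------------------------------------

    def species_under(self, clade: str) -> frozenset[str]:
        """All leaf descendants of ``clade`` (a leaf returns itself).

        The cardinality of the result is the clade's species count
        ``|S_clade|`` used throughout species identification.
        """
        if clade not in self._nodes:
            raise UnknownNodeError(f"unknown taxonomy node {clade!r}")
        cached = self._species_cache.get(clade)
        if cached is not None:
            return cached
        node = self._nodes[clade]
        if node.is_leaf:
            result = frozenset({clade})
        else:
            acc: set[str] = set()
            for child in node.children:
                acc |= self.species_under(child)
            result = frozenset(acc)
        self._species_cache[clade] = result
        return result

    def lineage_path(self, node_id: str) -> list[str]:
        """Path of node ids from the root down to ``node_id`` inclusive."""
        if node_id not in self._nodes:
            raise UnknownNodeError(f"unknown taxonomy node {node_id!r}")
        path: list[str] = []
        cur: str | None = node_id
        while cur is not None:
            path.append(cur)
            cur = self._nodes[cur].parent
        path.reverse()
        return path

    def is_descendant(self, node_id: str, ancestor: str) -> bool:
        """True when ``ancestor`` lies on the root-path of ``node_id``.

        A node counts as a descendant of itself.
        """
        return ancestor in self.lineage_path(node_id)

    def mrca(self, a: str, b: str) -> str:
        """Most recent common ancestor of two nodes."""
        pa = self.lineage_path(a)
        pb = set(self.lineage_path(b))
        for nid in reversed(pa):
            if nid in pb:
                return nid
        raise TaxonomyError("disconnected nodes")  # pragma: no cover

    def prune_to_clades(self, keep: set[str]) -> "TaxTree":
        """Simplified tree containing only branches leading to ``keep``.

        The result holds exactly the kept nodes plus all their ancestors;
        each surviving node's parent is its closest retained ancestor.
        """
        if not keep:
            raise TaxonomyError("no identifiable taxon: empty keep set")
        for nid in keep:
            if nid not in self._nodes:
                raise UnknownNodeError(f"unknown taxonomy node {nid!r}")
        retained: set[str] = set()
        for nid in keep:
            retained.update(self.lineage_path(nid))
        new_nodes: dict[str, TaxNode] = {}
        # walk the original tree in preorder so children stay ordered
        def _walk(nid: str, new_parent: str | None) -> None:
            if nid in retained:
                old = self._nodes[nid]
                new_nodes[nid] = TaxNode(
                    node_id=nid,
                    name=old.name,
                    rank=old.rank,
                    parent=new_parent,
                    children=[],
                )
                if new_parent is not None:
                    new_nodes[new_parent].children.append(nid)
                next_parent = nid
            else:
                next_parent = new_parent
            for child in self._nodes[nid].children:
                _walk(child, next_parent)

        _walk(self._root_id, None)
        return TaxTree(new_nodes.values())

    def rank_warning(self, clade: str) -> str:
        """Flag ancestral lineages that are suspiciously narrow or broad.

        Lineages at the genus level or below are flagged ``too_specific``;
        the phylum level and above, ``too_broad``.  Nodes whose rank is not
        a canonical rank (including ``"no rank"``) never warn: without a
        rank there is no defensible way to position the node relative to
        the genus/phylum bounds, so the flag stays ``none``.
        """
        node = self.node(clade)
        idx = _RANK_INDEX.get(node.rank.lower().strip())
        if idx is None:
            return RankWarning.NONE
        if idx <= _GENUS_IDX:
            return RankWarning.TOO_SPECIFIC
        if idx >= _PHYLUM_IDX:
            return RankWarning.TOO_BROAD
        return RankWarning.NONE

    # -- serialization -------------------------------------------------------

    def to_table(self) -> str:
        """3-column tab-separated dump: node_id, parent_id, rank.

        The root's parent field is an empty string.  Rows are emitted in
        preorder so the table can be rebuilt in a single pass.
        """
        lines = ["node_id\tparent_id\trank"]

        def _walk(nid: str) -> None:
            node = self._nodes[nid]
            lines.append(f"{nid}\t{node.parent or ''}\t{node.rank}")
            for child in node.children:
                _walk(child)

        _walk(self._root_id)
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "TaxTree":
        nodes: dict[str, TaxNode] = {}
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if lines and lines[0].startswith("node_id"):
            lines = lines[1:]
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) != 3:
                raise TaxonomyError(f"bad taxonomy table row: {ln!r}")
            nid, parent, rank = (f.strip() for f in fields)
            nodes[nid] = TaxNode(node_id=nid, rank=rank or "no rank",
                                 parent=parent or None)
        for node in nodes.values():
            if node.parent is not None:
                if node.parent not in nodes:
                    raise TaxonomyError(
                        f"node {node.node_id!r} has unknown parent {node.parent!r}"
                    )
                nodes[node.parent].children.append(node.node_id)
        return cls(nodes.values())

    def to_newick(self) -> str:
        """Newick string with internal-node labels and rank annotations.

        Ranks ride along in square-bracket comments so the newick dialect
        round-trips through :meth:`from_newick` without a side table.
        """

        def _fmt(nid: str) -> str:
            node = self._nodes[nid]
            label = node.node_id
            rank = f"[&&rank={node.rank}]" if node.rank != "no rank" else ""
            if node.is_leaf:
                return f"{label}{rank}"
            inner = ",".join(_fmt(c) for c in node.children)
            return f"({inner}){label}{rank}"

        return _fmt(self._root_id) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "TaxTree":
        import re

        ranks: dict[str, str] = {}

        def _grab(m: "re.Match[str]") -> str:
            return ""

        # pull rank comments out before handing to dendropy
        pattern = re.compile(r"\[&&rank=([^\]]+)\]")
        cleaned_parts: list[str] = []
        pos = 0
        for m in pattern.finditer(text):
            cleaned_parts.append(text[pos:m.start()])
            pos = m.end()
            # the label immediately precedes the comment
            label_m = re.search(r"([^(),;\[\]]+)$", text[:m.start()])
            if label_m:
                ranks[label_m.group(1)] = m.group(1)
        cleaned_parts.append(text[pos:])
        cleaned = "".join(cleaned_parts)

        dtree = dendropy.Tree.get(data=cleaned, schema="newick",
                                  suppress_internal_node_taxa=False)
        nodes: dict[str, TaxNode] = {}
        counter = [0]

        def _label(dnode: dendropy.Node) -> str:
            if dnode.taxon is not None and dnode.taxon.label:
                return dnode.taxon.label.replace(" ", "_")
            if dnode.label:
                return dnode.label.replace(" ", "_")
            counter[0] += 1
            return f"_anon{counter[0]}"

        def _walk(dnode: dendropy.Node, parent: str | None) -> None:
            nid = _label(dnode)
            nodes[nid] = TaxNode(node_id=nid,
                                 rank=ranks.get(nid, "no rank"),
                                 parent=parent)
            if parent is not None:
                nodes[parent].children.append(nid)
            for child in dnode.child_nodes():
                _walk(child, nid)

        _walk(dtree.seed_node, None)
        return cls(nodes.values())

    def write_newick(self, path: str) -> None:
        with io.open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def write_table(self, path: str) -> None:
        with io.open(path, "w") as fh:
            fh.write(self.to_table())
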