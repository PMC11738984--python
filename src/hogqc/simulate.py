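"""Synthetic reference world and proteome-corruption simulators.

The generator builds a self-contained miniature of the data a proteome
quality assessor needs: a species taxonomy, gene families that are born
at taxonomic nodes and then duplicate, die and accumulate substitutions
along branches, a filtered and k-mer-indexed database over the surviving
families, and held-out query species whose proteomes were produced by the
same evolutionary process but are excluded from the database — the
honest position of a real query.

The corruption procedures emulate the classic annotation failure modes:
randomly missing genes, spurious gene models (random open reading
frames, composition-matched or not), fragmented gene models, erroneously
fused gene models, and cross-species contamination.  Every procedure is
seeded, reproducible, and leaves untouched records byte-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .hogdb import AMINO_ACIDS, HOG, HOGDatabase, HOGMember, build_database
from .taxonomy import TaxNode, TaxTree

__all__ = [
    "WorldParams",
    "SyntheticWorld",
    "Manifest",
    "generate_world",
    "subsample_proteome",
    "random_orf_sequences",
    "fragment_proteome",
    "fuse_proteome",
    "contaminate",
]

Record = tuple[str, str]

#: ranks assigned by node height (distance to deepest leaf); the root is
#: always "domain"
_HEIGHT_RANKS = {0: "species", 1: "genus", 2: "family", 3: "order",
                 4: "class", 5: "phylum"}

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "TCAG"
_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_CODON_AA = {
    # standard genetic code
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class WorldParams:
    """Generation parameters; the defaults are the standard study world.

    The birth fractions shape where gene families originate.  Births
    concentrate at a designated *reference clade* (the assessment
    yardstick needs a sizable repertoire defined exactly at the query's
    ancestral lineage) and at a disjoint *contaminant clade* with its own
    private repertoire; families shared across the deepest split are kept
    rare, standing in for the fact that in real databases the universal
    core resolves into clade-specific subfamilies that a toy duplication
    process cannot reproduce.

    n_species:
        Leaves of the taxonomy (power-of-two splits, largest first).
    n_families:
        Total family births.
    root_birth_frac, reference_birth_frac, contaminant_birth_frac,
    leaf_birth_frac:
        Birth mass at the root, the reference clade, spread over the
        contaminant clade's subtree, and on leaves (species-private
        families); the remainder is spread over the other internal nodes
        proportionally to their species counts.
    p_loss, p_dup:
        Per-lineage, per-branch probabilities of gene loss and gene
        duplication.
    subst_rate:
        Per-site, per-branch substitution probability.
    len_range:
        Ancestral protein length drawn uniformly from this inclusive
        range (amino acids).
    k:
        K-mer length of the database index.
    n_query_species:
        Held-out species (taken from the reference clade, excluded from
        the database).
    """

    n_species: int = 24
    n_families: int = 320
    root_birth_frac: float = 0.01
    reference_birth_frac: float = 0.45
    contaminant_birth_frac: float = 0.30
    leaf_birth_frac: float = 0.05
    p_loss: float = 0.005
    p_dup: float = 0.015
    subst_rate: float = 0.02
    len_range: tuple[int, int] = (250, 550)
    k: int = 10
    n_query_species: int = 1

    def __post_init__(self) -> None:
        if self.n_species < 12:
            raise ValueError("need at least 12 species for a usable world")
        for name in ("p_loss", "p_dup", "subst_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        total = (self.root_birth_frac + self.reference_birth_frac
                 + self.contaminant_birth_frac + self.leaf_birth_frac)
        if total > 1.0:
            raise ValueError("birth fractions exceed 1")


@dataclass
class Manifest:
    """Ground-truth record of one corruption: what was done to whom."""

    operation: str
    seed: int
    params: dict
    affected: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["operation\tseed\tparams\taffected"]
        params = ";".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        lines.append(
            f"{self.operation}\t{self.seed}\t{params}\t{','.join(self.affected)}"
        )
        for note in self.notes:
            lines.append(f"# {note}")
        return "\n".join(lines) + "\n"


@dataclass
class SyntheticWorld:
    """A generated reference world plus its held-out query proteomes."""

    taxonomy: TaxTree
    families: list[HOG]
    database: HOGDatabase
    query_proteomes: dict[str, list[Record]]
    query_truth: dict[str, str]
    reference_clade: str
    contaminant_clade: str
    query_species: list[str]
    params: WorldParams
    seed: int

    def query_records(self, species: str | None = None) -> list[Record]:
        species = species or self.query_species[0]
        return list(self.query_proteomes[species])

    def species_records(self, species: str) -> list[Record]:
        """Proteome of a database species, assembled from its members."""
        records = []
        for hog in self.database.hogs.values():
            for m in hog.members:
                if m.species_id == species and m.sequence:
                    records.append((m.protein_id, m.sequence))
        records.sort()
        return records


# -- taxonomy construction -----------------------------------------------------


def _build_tree(n_species: int) -> TaxTree:
    """Bifurcating taxonomy with power-of-two splits, largest clade first.

    Node ids spell their path from the root (``r``, ``ra``, ``rb``,
    ``raa``...), so sibling order and ancestry are readable from the id.
    """
    nodes: dict[str, TaxNode] = {}

    def _split(n: int) -> tuple[int, int]:
        p = 1
        while p * 2 < n:
            p *= 2
        return p, n - p

    def _grow(node_id: str, n: int, parent: str | None) -> int:
        """Create the subtree; return its height."""
        node = TaxNode(node_id=node_id, parent=parent)
        nodes[node_id] = node
        if parent is not None:
            nodes[parent].children.append(node_id)
        if n == 1:
            node.rank = "species"
            return 0
        left, right = _split(n)
        ha = _grow(node_id + "a", left, node_id)
        hb = _grow(node_id + "b", right, node_id)
        height = max(ha, hb) + 1
        node.rank = _HEIGHT_RANKS.get(height, "phylum")
        return height

    _grow("r", n_species, None)
    nodes["r"].rank = "domain"
    return TaxTree(nodes.values())


# -- family evolution ----------------------------------------------------------


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    n_mut = rng.binomial(len(seq), rate)
    if n_mut == 0:
        return seq.copy()
    out = seq.copy()
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    shift = rng.integers(1, 20, size=n_mut)
    out[pos] = (out[pos] + shift) % 20
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


def _origin_weights(tree: TaxTree, params: WorldParams,
                    reference: str, contaminant: str) -> dict[str, float]:
    weights: dict[str, float] = {}
    weights[tree.root_id] = params.root_birth_frac
    weights[reference] = weights.get(reference, 0.0) + params.reference_birth_frac

    contam_nodes = [
        nid for nid in tree.node_ids()
        if tree.is_descendant(nid, contaminant) and not tree.node(nid).is_leaf
    ]
    contam_total = sum(len(tree.species_under(n)) for n in contam_nodes)
    for nid in contam_nodes:
        weights[nid] = weights.get(nid, 0.0) + (
            params.contaminant_birth_frac
            * len(tree.species_under(nid)) / contam_total
        )

    leaves = tree.leaves()
    for leaf in leaves:
        weights[leaf] = weights.get(leaf, 0.0) + params.leaf_birth_frac / len(leaves)

    background = 1.0 - (params.root_birth_frac + params.reference_birth_frac
                        + params.contaminant_birth_frac + params.leaf_birth_frac)
    bg_nodes = [
        nid for nid in tree.node_ids()
        if not tree.node(nid).is_leaf
        and nid != tree.root_id
        and nid != reference
        and not tree.is_descendant(nid, contaminant)
        and not tree.is_descendant(nid, reference)
    ]
    bg_total = sum(len(tree.species_under(n)) for n in bg_nodes)
    for nid in bg_nodes:
        weights[nid] = weights.get(nid, 0.0) + (
            background * len(tree.species_under(nid)) / bg_total
        )
    return weights


def _evolve_family(
    fam_idx: int,
    origin: str,
    tree: TaxTree,
    params: WorldParams,
    rng: np.random.Generator,
    held_out: set[str],
    query_members: dict[str, list[tuple[str, str, str]]],
) -> list[HOG]:
    """Gain/duplicate/lose one family along the subtree below its origin.

    Each surviving lineage deposits one protein per species it reaches;
    duplication on a branch into node v splits the lineage into two
    sub-HOGs defined at v.  Members of held-out species are diverted to
    the query proteomes instead of the database family.
    """
    length = int(rng.integers(params.len_range[0], params.len_range[1] + 1))
    ancestral = rng.integers(0, 20, size=length)
    root_id = f"fam{fam_idx:04d}"
    hogs: dict[str, HOG] = {
        root_id: HOG(hog_id=root_id, level=origin)
    }
    copy_counter = [0]

    def _deposit(hog_id: str, species: str, seq: np.ndarray) -> None:
        copy_counter[0] += 1
        pid = f"{species}.g{fam_idx:04d}.{copy_counter[0]}"
        if species in held_out:
            query_members[species].append((pid, _to_str(seq), hog_id))
        else:
            hogs[hog_id].members.append(
                HOGMember(species_id=species, protein_id=pid,
                          length=len(seq), sequence=_to_str(seq))
            )

    def _descend(node: str, hog_id: str, seq: np.ndarray) -> None:
        if tree.node(node).is_leaf:
            _deposit(hog_id, node, seq)
            return
        for child in tree.node(node).children:
            if rng.random() < params.p_loss:
                continue
            child_seq = _mutate(seq, params.subst_rate, rng)
            if rng.random() < params.p_dup:
                for tag in ("a", "b"):
                    sub_id = f"{hog_id}.{child}{tag}"
                    hogs[sub_id] = HOG(hog_id=sub_id, level=child,
                                       parent_hog=hog_id)
                    copy_seq = _mutate(child_seq, params.subst_rate, rng)
                    _descend(child, sub_id, copy_seq)
            else:
                _descend(child, hog_id, child_seq)

    if tree.node(origin).is_leaf:
        _deposit(root_id, origin, _mutate(ancestral, params.subst_rate, rng))
    else:
        _descend(origin, root_id, ancestral)
    return list(hogs.values())


def generate_world(params: WorldParams = WorldParams(), seed: int = 0) -> SyntheticWorld:
    """Generate a seeded reference world.

    Regenerating with the same parameters and seed reproduces the world
    byte for byte.  Raises if every family ends up excluded by the
    database retention filter.
    """
    rng = np.random.default_rng(seed)
    tree = _build_tree(params.n_species)

    # reference clade: first 8-or-so-species clade on the "a" side;
    # contaminant clade: the other side of the root split
    reference = "raa" if "raa" in tree else "ra"
    contaminant = "rb"
    held_out = set()
    ref_leaves = sorted(tree.species_under(reference))
    held_out.update(ref_leaves[: params.n_query_species])

    weights = _origin_weights(tree, params, reference, contaminant)
    nodes = sorted(weights)
    probs = np.array([weights[n] for n in nodes])
    probs = probs / probs.sum()
    origins = rng.choice(len(nodes), size=params.n_families, p=probs)

    query_members: dict[str, list[tuple[str, str, str]]] = {
        sp: [] for sp in held_out
    }
    families: list[HOG] = []
    for fam_idx, oi in enumerate(origins):
        families.extend(
            _evolve_family(fam_idx, nodes[int(oi)], tree, params, rng,
                           held_out, query_members)
        )

    database = build_database(tree, families, k=params.k)
    if not database.hogs:
        raise ValueError("no family survived the retention filter; "
                         "loss rate too high or families too small")

    query_proteomes = {
        sp: [(pid, seq) for pid, seq, _ in sorted(members)]
        for sp, members in query_members.items()
    }
    query_truth = {
        pid: hog_id
        for members in query_members.values()
        for pid, _, hog_id in members
    }
    return SyntheticWorld(
        taxonomy=tree,
        families=families,
        database=database,
        query_proteomes=query_proteomes,
        query_truth=query_truth,
        reference_clade=reference,
        contaminant_clade=contaminant,
        query_species=sorted(held_out),
        params=params,
        seed=seed,
    )


# -- corruption procedures -----------------------------------------------------


def subsample_proteome(
    records: list[Record], keep_fraction: float, seed: int
) -> tuple[list[Record], Manifest]:
    """Keep a random fraction of the proteins (missing-genes mode)."""
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_keep = int(round(keep_fraction * len(records)))
    idx = sorted(rng.choice(len(records), size=n_keep, replace=False))
    idx_set = set(idx)
    kept = [records[i] for i in idx]
    removed = [records[i][0] for i in range(len(records)) if i not in idx_set]
    return kept, Manifest(
        operation="subsample", seed=seed,
        params={"keep_fraction": keep_fraction}, affected=removed,
    )


def _draw_orf_uniform_nt(rng: np.random.Generator) -> str:
    """One raw open reading frame: uniform codons until a stop appears.

    The length before filtering is geometric with stop probability 3/64
    (three stop codons of 64), mean 61/3 ≈ 20.3 sense codons.
    """
    aas = []
    while True:
        codon = _CODONS[int(rng.integers(0, 64))]
        if codon in _STOP_CODONS:
            return "".join(aas)
        aas.append(_CODON_AA[codon])


def _aa_distribution(records: list[Record]) -> tuple[list[str], np.ndarray]:
    """Empirical residue distribution with stop as an extra symbol.

    Each protein contributes one (implicit) stop, so the stop mass is
    n_proteins / (n_residues + n_proteins) and the expected raw length
    matches the source's mean protein length.
    """
    counts: dict[str, int] = {}
    for _, seq in records:
        for ch in seq:
            counts[ch] = counts.get(ch, 0) + 1
    symbols = sorted(counts) + ["*"]
    weights = np.array([counts[s] for s in symbols[:-1]] + [len(records)],
                       dtype=float)
    return symbols, weights / weights.sum()


def random_orf_sequences(
    n: int,
    seed: int,
    mode: str = "uniform_nt",
    source: list[Record] | None = None,
    min_length: int = 21,
) -> list[str]:
    """Generate spurious protein sequences (erroneous-gene-model mode).

    ``uniform_nt`` draws codons independently and uniformly over the 64
    codons until a stop codon appears, then translates with the standard
    genetic code; ``aa_distribution`` draws residues from the source
    proteome's empirical amino-acid-plus-stop distribution.  Either way,
    sequences shorter than ``min_length`` (more than 20 amino acids by
    default) are rejected and redrawn.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if mode not in ("uniform_nt", "aa_distribution"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "aa_distribution" and not source:
        raise ValueError("aa_distribution mode needs a source proteome")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    if mode == "uniform_nt":
        while len(out) < n:
            seq = _draw_orf_uniform_nt(rng)
            if len(seq) >= min_length:
                out.append(seq)
    else:
        symbols, probs = _aa_distribution(source)
        while len(out) < n:
            aas = []
            while True:
                ch = symbols[int(rng.choice(len(symbols), p=probs))]
                if ch == "*":
                    break
                aas.append(ch)
            if len(aas) >= min_length:
                out.append("".join(aas))
    return out


def fragment_proteome(
    records: list[Record], fraction: float, seed: int,
    retained_range: tuple[float, float] = (0.10, 0.90),
) -> tuple[list[Record], Manifest]:
    """Truncate a random subset of proteins (fragmented-gene-model mode).

    Each selected protein keeps a uniform 10–90% of its length, cut from
    the N- or C-terminal end with equal probability; the truncated
    record replaces the original in place.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_frag = int(round(fraction * len(records)))
    idx = set(rng.choice(len(records), size=n_frag, replace=False).tolist())
    out: list[Record] = []
    affected: list[str] = []
    lo, hi = retained_range
    for i, (pid, seq) in enumerate(records):
        if i in idx:
            keep = lo + (hi - lo) * rng.random()
            n_keep = max(1, int(round(keep * len(seq))))
            if rng.random() < 0.5:
                seq = seq[:n_keep]  # cut from C-terminal end
            else:
                seq = seq[len(seq) - n_keep:]  # cut from N-terminal end
            affected.append(pid)
        out.append((pid, seq))
    return out, Manifest(
        operation="fragment", seed=seed,
        params={"fraction": fraction, "retained_range": retained_range},
        affected=affected,
    )


def fuse_proteome(
    records: list[Record], fraction: float, seed: int
) -> tuple[list[Record], Manifest]:
    """Fuse random disjoint pairs of proteins (fused-gene-model mode).

    Fusion trims a uniform 0–20% from the C-terminal end of the first
    protein and the N-terminal end of the second, concatenates them, and
    replaces both sources with the chimera; pairs are drawn until the
    requested fraction of the proteome (counted in proteins) is consumed.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if len(records) < 2:
        raise ValueError("need at least two proteins to fuse")
    rng = np.random.default_rng(seed)
    n_affected = int(round(fraction * len(records)))
    notes: list[str] = []
    if n_affected % 2 == 1:
        notes.append("odd target count; one selected protein left untouched")
        n_affected -= 1
    order = rng.permutation(len(records))
    chosen = order[:n_affected]
    by_id = dict(records)
    fused: list[Record] = []
    affected: list[str] = []
    for j in range(0, len(chosen), 2):
        pid_a, _ = records[chosen[j]]
        pid_b, _ = records[chosen[j + 1]]
        seq_a, seq_b = by_id[pid_a], by_id[pid_b]
        trim_a = int(round(0.20 * rng.random() * len(seq_a)))
        trim_b = int(round(0.20 * rng.random() * len(seq_b)))
        merged = seq_a[: len(seq_a) - trim_a] + seq_b[trim_b:]
        fused.append((f"fusion|{pid_a}|{pid_b}", merged))
        affected.extend([pid_a, pid_b])
    removed = set(affected)
    out = [(pid, seq) for pid, seq in records if pid not in removed]
    out.extend(fused)
    return out, Manifest(
        operation="fuse", seed=seed, params={"fraction": fraction},
        affected=affected, notes=notes,
    )


def contaminate(
    records: list[Record],
    contaminant_records: list[Record],
    n_proteins: int,
    seed: int,
    id_prefix: str = "contam|",
) -> tuple[list[Record], Manifest]:
    """Spike foreign proteins into a proteome (contamination mode).

    ``n_proteins`` distinct records are drawn without replacement from
    the contaminant proteome and appended with a recognizable id prefix
    so ground truth stays recoverable.
    """
    if n_proteins < 0:
        raise ValueError("n_proteins must be non-negative")
    if n_proteins > len(contaminant_records):
        raise ValueError(
            f"cannot draw {n_proteins} proteins from a contaminant "
            f"proteome of {len(contaminant_records)}"
        )
    rng = np.random.default_rng(seed)
    idx = sorted(
        rng.choice(len(contaminant_records), size=n_proteins, replace=False)
    )
    spiked = [
        (f"{id_prefix}{contaminant_records[i][0]}", contaminant_records[i][1])
        for i in idx
    ]
    return list(records) + spiked, Manifest(
        operation="contaminate", seed=seed,
        params={"n_proteins": n_proteins},
        affected=[pid for pid, _ in spiked],
    )
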