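"""Pairwise distances, neighbor-joining, bootstrap, and monophyly checks.

Distances are p-distances (mismatch proportion over comparable sites) or
their Jukes-Cantor correction ``-(3/4) ln(1 - 4p/3)``, computed over the
mask-true columns only.  Trees are built with the classic Saitou-Nei
neighbor-joining agglomeration, which is exact on additive matrices, and
are unrooted (the root node is a trifurcation).  Column-bootstrap
supports attach to internal edges as percentages.  Misidentified
accessions are flagged by testing species monophyly and greedily pruning
the leaves that break it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .errors import DistanceError, HerbitaError
from .seq_io_annotation import LabeledAlignment

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "MisassignmentReport",
    "pairwise_distance",
    "neighbor_joining",
    "build_nj_tree",
    "bootstrap_support",
    "flag_misassignments",
    "write_newick",
]

MODELS = ("p_distance", "jukes_cantor")
GAP_HANDLING = ("pairwise_deletion", "complete_deletion")


@dataclass
class DistanceMatrix:
    taxa: list
    values: np.ndarray
    model: str
    gap_handling: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise HerbitaError("distance matrix shape does not match taxa")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise HerbitaError("distance matrix must be symmetric with zero diagonal")
        if (v < 0).any() or not np.isfinite(v).all():
            raise HerbitaError("distances must be finite and non-negative")
        self.values = v


class TreeNode:
    """Node of an (unrooted) phylogenetic tree.

    ``length`` is the raw branch length to the parent (may be negative
    for NJ); display clamps at zero.  Internal nodes may carry a
    bootstrap ``support`` percentage.
    """

    __slots__ = ("name", "species", "children", "length", "support")

    def __init__(self, name=None, species=None, children=None, length=0.0, support=None):
        self.name = name
        self.species = species
        self.children: list[TreeNode] = children or []
        self.length = float(length)
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


class PhyloTree:
    """Unrooted tree presented with a trifurcating root node."""

    def __init__(self, root: TreeNode):
        self.root = root

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def set_species(self, mapping: Mapping[str, str]) -> "PhyloTree":
        for leaf in self.leaves():
            leaf.species = mapping.get(leaf.name, leaf.species)
        return self

    # -- splits ------------------------------------------------------
    def splits(self, internal_only: bool = True) -> dict:
        """Map each non-root node to its unrooted bipartition.

        A bipartition is a frozenset of the two leaf-name frozensets; the
        representation is invariant to rooting and taxon order.  With
        ``internal_only`` pendant (single-leaf) splits are skipped.
        """
        all_leaves = frozenset(self.leaf_names())
        out = {}

        def side(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            return frozenset().union(*(side(c) for c in node.children))

        for node in self.root.walk():
            if node is self.root:
                continue
            if internal_only and node.is_leaf:
                continue
            s = side(node)
            if len(s) in (0, len(all_leaves)):
                continue
            out[id(node)] = (node, frozenset([s, all_leaves - s]))
        return out

    def split_set(self, internal_only: bool = True) -> set:
        return {split for _, split in self.splits(internal_only).values()}

    # -- distances ---------------------------------------------------
    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """All-pairs leaf distances along branches (raw lengths)."""
        leaves = self.leaves()
        names = [l.name for l in leaves]
        index = {id(l): i for i, l in enumerate(leaves)}
        n = len(leaves)
        dist = np.zeros((n, n))

        def below(node: TreeNode) -> list[tuple[int, float]]:
            if node.is_leaf:
                return [(index[id(node)], 0.0)]
            groups = []
            for c in node.children:
                sub = [(i, d + c.length) for i, d in below(c)]
                for g in groups:
                    for i, di in g:
                        for j, dj in sub:
                            dist[i, j] = dist[j, i] = di + dj
                groups.append(sub)
            return [x for g in groups for x in g]

        below(self.root)
        return names, dist

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            length = max(node.length, 0.0)
            if node.is_leaf:
                return f"{node.name}:{length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(int(round(node.support)))
            return f"({inner}){label}:{length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = "" if self.root.support is None else str(int(round(self.root.support)))
        return f"({inner}){label};"


@dataclass(frozen=True)
class MisassignmentReport:
    flagged: list  # (accession, labeled_species, resolved_clade_species)
    monophyletic_species: set
    non_monophyletic_species: set
    untestable_species: set  # single-member species

    @property
    def flagged_accessions(self) -> set:
        return {f[0] for f in self.flagged}


# ---------------------------------------------------------------------------
# distances


def _codes(alignment: LabeledAlignment) -> np.ndarray:
    """Residues as integer codes: A..T -> 0..3, everything else -> -1."""
    mat = alignment.matrix()
    codes = np.full(mat.shape, -1, dtype=np.int8)
    for i, base in enumerate("ACGT"):
        codes[mat == base] = i
    return codes


def pairwise_distance(
    alignment: LabeledAlignment,
    model: str = "jukes_cantor",
    gap_handling: str = "pairwise_deletion",
) -> DistanceMatrix:
    """p or Jukes-Cantor distances over the unmasked columns.

    Only determinate bases (A/C/G/T) are comparable; gaps, Ns and
    ambiguity codes are deleted pairwise or across the whole column
    (``complete_deletion``).  A pair with zero comparable sites, or a
    mismatch proportion in the undefined region of the JC transform
    (p >= 3/4), raises :class:`DistanceError`.
    """
    if model not in MODELS:
        raise HerbitaError(f"unknown model {model!r}")
    if gap_handling not in GAP_HANDLING:
        raise HerbitaError(f"unknown gap handling {gap_handling!r}")
    members = alignment.members
    if len(members) < 2:
        raise HerbitaError("need >= 2 sequences")
    codes = _codes(alignment)[:, alignment.masked_columns()]
    det = codes >= 0
    if gap_handling == "complete_deletion":
        keep = det.all(axis=0)
        codes = codes[:, keep]
        det = det[:, keep]
    n = len(members)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = det[i] & det[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise DistanceError(
                    f"no comparable sites for pair "
                    f"({members[i].accession}, {members[j].accession})"
                )
            p = float((codes[i][both] != codes[j][both]).sum()) / comparable
            if model == "jukes_cantor":
                if p >= 0.75:
                    raise DistanceError(
                        f"JC distance undefined for pair "
                        f"({members[i].accession}, {members[j].accession}): p={p:.3f}"
                    )
                p = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = p
    return DistanceMatrix([m.accession for m in members], d, model, gap_handling)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Classic Saitou-Nei NJ with deterministic tie-breaking.

    At each step the pair minimising
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` is joined; exact ties resolve
    to the lowest current index pair.  The final three lineages attach
    to a trifurcating root with the three-point branch lengths.
    """
    n = len(D.taxa)
    if n < 3:
        raise HerbitaError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in D.taxa]
    d = D.values.astype(float).copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        q[np.tril_indices(m)] = np.inf
        # row-major argmin over the upper triangle = lowest-index pair tie-break
        i, j = divmod(int(np.argmin(q)), m)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        dn = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[1:, 1:] = d[np.ix_(keep, keep)]
        d_new[0, 1:] = d_new[1:, 0] = dn[keep]
        d = d_new
        nodes = [new] + [nodes[k] for k in keep]
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = 0.5 * (dab + dac - dbc)
    b.length = 0.5 * (dab + dbc - dac)
    c.length = 0.5 * (dac + dbc - dab)
    return PhyloTree(TreeNode(children=[a, b, c]))


def build_nj_tree(
    alignment: LabeledAlignment,
    model: str = "jukes_cantor",
    gap_handling: str = "pairwise_deletion",
) -> PhyloTree:
    """Distance matrix + NJ + species labels in one call."""
    D = pairwise_distance(alignment, model, gap_handling)
    return neighbor_joining(D).set_species(alignment.species_map())


def bootstrap_support(
    alignment: LabeledAlignment,
    replicates: int = 100,
    seed: int | None = None,
    model: str = "jukes_cantor",
    gap_handling: str = "pairwise_deletion",
) -> PhyloTree:
    """Column-bootstrap supports on the NJ tree of the full alignment.

    Masked-in columns are resampled with replacement per replicate, the
    NJ tree rebuilt, and each internal edge of the reference tree gets
    the percentage of successful replicates containing its bipartition.
    Replicates whose resample leaves some pair with no comparable sites
    are dropped, counted, and reported via a warning.
    """
    if replicates < 1:
        raise HerbitaError("replicates must be >= 1")
    if seed is None:
        raise HerbitaError("an explicit seed is required for the bootstrap")
    rng = np.random.default_rng(seed)
    reference = build_nj_tree(alignment, model, gap_handling)
    cols = alignment.masked_columns()
    tally: dict[frozenset, int] = {}
    succeeded = 0
    dropped = 0
    for _ in range(replicates):
        sample = rng.choice(cols, size=cols.size, replace=True)
        sub = alignment.subset_columns(sorted(int(c) for c in sample))
        try:
            rep_tree = build_nj_tree(sub, model, gap_handling)
        except DistanceError:
            dropped += 1
            continue
        succeeded += 1
        for split in rep_tree.split_set():
            tally[split] = tally.get(split, 0) + 1
    if dropped:
        warnings.warn(
            f"{dropped}/{replicates} bootstrap replicates dropped "
            "(pair with no comparable sites)",
            RuntimeWarning,
            stacklevel=2,
        )
    if succeeded == 0:
        raise DistanceError("every bootstrap replicate failed")
    for _, (node, split) in reference.splits(internal_only=True).items():
        node.support = 100.0 * tally.get(split, 0) / succeeded
    return reference


# ---------------------------------------------------------------------------
# misassignment flagging


def _foreign_count(sides: Sequence[frozenset], group: frozenset, removed: frozenset) -> int:
    """Extra leaves inside the smallest clade spanning ``group``.

    ``sides`` are the leaf sets of every edge side of the full tree; the
    removed leaves are discounted from both the group and the sides.
    Zero means the group (as currently constituted) is monophyletic.
    """
    g = group - removed
    if len(g) <= 1:
        return 0
    best = None
    for side in sides:
        s = side - removed
        if g <= s:
            extra = len(s) - len(g)
            if best is None or extra < best:
                best = extra
                if best == 0:
                    return 0
    return best if best is not None else 0


def flag_misassignments(tree: PhyloTree, k_nearest: int = 3) -> MisassignmentReport:
    """Flag leaves that break species monophyly on an unrooted tree.

    For every species with two or more leaves, monophyly holds when some
    edge bipartition isolates exactly that species' leaves.  For each
    non-monophyletic species, leaves are greedily removed — always the
    leaf whose removal most shrinks the foreign contingent of the
    species' minimal spanning clade, ties to the lowest accession —
    until the remainder is monophyletic.  Removed leaves are flagged and
    re-assigned to the majority species among their ``k_nearest``
    neighbours by patristic distance.
    """
    leaves = tree.leaves()
    if any(l.species is None for l in leaves):
        raise HerbitaError("all leaves need species labels")
    by_species: dict[str, set] = {}
    for l in leaves:
        by_species.setdefault(l.species, set()).add(l.name)
    if len(by_species) < 2:
        raise HerbitaError("need >= 2 species to test monophyly")

    all_names = frozenset(l.name for l in leaves)
    sides: list[frozenset] = [all_names]
    split_map = tree.splits(internal_only=False)
    for _, (_, split) in split_map.items():
        sides.extend(split)

    untestable = {sp for sp, mem in by_species.items() if len(mem) == 1}
    testable = {sp: frozenset(mem) for sp, mem in by_species.items()
                if sp not in untestable}
    monophyletic: set = set()
    non_monophyletic: set = set()
    union: set = set()
    for sp, group in sorted(testable.items()):
        if _foreign_count(sides, group, frozenset()) == 0:
            monophyletic.add(sp)
            continue
        non_monophyletic.add(sp)
        # minimal per-species repair: over every clade (edge side) C,
        # flagging the symmetric difference C ^ S isolates S & C exactly,
        # and the smallest difference is the per-species minimal-removal
        # optimum; among equal-cost repairs prefer the one discarding the
        # fewest of the species' own members, then the lowest accessions
        best: tuple | None = None
        for side in sides:
            flags = tuple(sorted(side ^ group))
            key = (len(flags), len(group - side), flags)
            if best is None or key < best:
                best = key
        union.update(best[2])

    # per-species repairs interact (one species' intruder is another's
    # stray): drop any flagged leaf that the union of the others already
    # renders redundant, approaching the global minimal removal set
    def all_mono(removed: frozenset) -> bool:
        return all(
            _foreign_count(sides, group, removed) == 0
            for group in testable.values()
        )

    for name in sorted(union):
        rest = frozenset(union - {name})
        if all_mono(rest):
            union.discard(name)

    flagged_names = sorted(union)
    # a species whose leaves were pruned while repairing another species'
    # clade is implicated in the violation even if it passed its own test
    species_of_leaf = {l.name: l.species for l in leaves}
    for name in flagged_names:
        sp = species_of_leaf[name]
        non_monophyletic.add(sp)
        monophyletic.discard(sp)
    names, dmat = tree.patristic_distances()
    idx = {n: i for i, n in enumerate(names)}
    species_of = {l.name: l.species for l in leaves}
    flagged = []
    for name in flagged_names:
        order = np.argsort(dmat[idx[name]], kind="stable")
        neighbours = [names[k] for k in order if names[k] != name][:k_nearest]
        counts: dict[str, int] = {}
        for nb in neighbours:
            counts[species_of[nb]] = counts.get(species_of[nb], 0) + 1
        top = max(counts.values())
        tied = [sp for sp, c in counts.items() if c == top]
        if len(tied) == 1:
            resolved = tied[0]
        else:
            resolved = next(species_of[nb] for nb in neighbours if species_of[nb] in tied)
        flagged.append((name, species_of[name], resolved))
    return MisassignmentReport(flagged, monophyletic, non_monophyletic, untestable)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    """Serialise with branch lengths (clamped at zero) and integer
    bootstrap supports as internal-node labels."""
    Path(path).write_text(tree.newick() + "\n")
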