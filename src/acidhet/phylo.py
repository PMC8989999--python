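"""Distance-based phylogenetics: JC-corrected distances, NJ, bootstrap.

Pairwise distances are observed mismatch proportions (pairwise deletion of
gapped sites) corrected with the generalized Jukes-Cantor formula for an
a-letter alphabet,

    d = -((a-1)/a) * ln(1 - (a/(a-1)) * p),

with a = 20 for proteins and a = 4 for nucleotides. Saturated pairs
(p >= (a-1)/a, where the correction diverges) are flagged and assigned a
configurable cap distance instead of raising, so large real alignments
still yield a tree. Trees are built with the classical Saitou-Nei
neighbor-joining algorithm and serialized as Newick via dendropy, with
bootstrap supports (Felsenstein column resampling) stored as internal node
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["GAP_CHARS", "DistanceMatrix", "p_distance", "jc_distance",
           "is_saturated", "alignment_distances", "neighbor_joining",
           "bootstrap_support", "tree_bipartitions", "write_newick",
           "read_newick", "write_phylip"]

GAP_CHARS = frozenset("-.")
DEFAULT_SATURATION_CAP = 5.0  # substitutions/site assigned to saturated pairs


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances in substitutions/site."""

    labels: list[str]
    d: np.ndarray
    saturated: np.ndarray | None = None  # boolean, per pair

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be >= 0")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Observed mismatch proportion with pairwise deletion of gapped sites."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned (equal length)")
    compared = mismatch = 0
    for x, y in zip(seq_a, seq_b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        compared += 1
        if x != y:
            mismatch += 1
    if compared == 0:
        raise ValueError("no comparable (gap-free) sites")
    return mismatch / compared


def is_saturated(p: float, alphabet_size: int) -> bool:
    """True when the JC correction diverges (p at or past (a-1)/a)."""
    return p >= (alphabet_size - 1) / alphabet_size


def jc_distance(p: float, alphabet_size: int,
                cap: float = DEFAULT_SATURATION_CAP) -> float:
    """Jukes-Cantor corrected distance for an a-letter alphabet.

    Returns ``cap`` for saturated pairs rather than raising.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a proportion in [0, 1]")
    a = alphabet_size
    if a < 2:
        raise ValueError("alphabet_size must be >= 2")
    if is_saturated(p, a):
        return cap
    return -((a - 1) / a) * np.log(1.0 - a / (a - 1) * p)


def _encode(seqs: dict[str, str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    labels = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must all have equal length")
    (L,) = lengths
    if L < 1:
        raise ValueError("alignment must have at least 1 column")
    mat = np.array([np.frombuffer(seqs[l].encode(), dtype=np.uint8)
                    for l in labels])
    gap = np.isin(mat, np.frombuffer("".join(GAP_CHARS).encode(), dtype=np.uint8))
    return labels, mat, gap


def alignment_distances(seqs: dict[str, str], alphabet_size: int,
                        cap: float = DEFAULT_SATURATION_CAP) -> DistanceMatrix:
    """JC-corrected distance matrix from an aligned set of sequences."""
    labels, mat, gap = _encode(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            compared = int(ok.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]} and {labels[j]}")
            p = int((mat[i, ok] != mat[j, ok]).sum()) / compared
            sat[i, j] = sat[j, i] = is_saturated(p, alphabet_size)
            d[i, j] = d[j, i] = jc_distance(p, alphabet_size, cap)
    return DistanceMatrix(labels=labels, d=d, saturated=sat)


def _clamped_limbs(dij: float, vi: float) -> tuple[float, float]:
    """Clamp negative limb lengths to 0, shifting the deficit to the sister."""
    vj = dij - vi
    if vi < 0:
        return 0.0, dij
    if vj < 0:
        return dij, 0.0
    return vi, vj


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a distance matrix.

    Iteratively joins the pair minimizing
    ``Q(i,j) = (n-2) d(i,j) - r_i - r_j`` (r = row sums); ties are broken
    by the lowest (row, column) index. Negative branch lengths are clamped
    to 0 with the deficit moved to the sister branch. Returns an unrooted
    dendropy tree (trifurcating seed node).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.labels)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(label)
        nodes.append(node)
    D = dm.d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        # argmin over the upper triangle in row-major order -> lowest (i, j) tie-break
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vi, vj = _clamped_limbs(D[i, j], vi)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = vi
        parent.add_child(nodes[j])
        nodes[j].edge.length = vj
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        d_new = np.clip(d_new, 0.0, None)
        keep = [x for x in range(m) if x != j]
        D = D[np.ix_(keep, keep)]
        d_new = d_new[keep]
        pos = keep.index(i)
        D[pos, :] = d_new
        D[:, pos] = d_new
        D[pos, pos] = 0.0
        nodes = [nodes[x] for x in keep]
        nodes[pos] = parent

    # closed-form limbs for the final three nodes
    center = dendropy.Node()
    limbs = [
        0.5 * (D[0, 1] + D[0, 2] - D[1, 2]),
        0.5 * (D[0, 1] + D[1, 2] - D[0, 2]),
        0.5 * (D[0, 2] + D[1, 2] - D[0, 1]),
    ]
    for node, limb in zip(nodes, limbs):
        center.add_child(node)
        node.edge.length = max(limb, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is represented by the frozenset of leaf labels on
    the side *not* containing the lexicographically smallest taxon, so the
    encoding is independent of rooting and input order.
    """
    all_labels = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = min(all_labels)
    bips = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = all_labels - side
        if 1 < len(side) < len(all_labels) - 1:
            bips.add(side)
    return bips


def bootstrap_support(seqs: dict[str, str], alphabet_size: int,
                      n_reps: int = 100, seed: int = 0,
                      cap: float = DEFAULT_SATURATION_CAP) -> dendropy.Tree:
    """NJ tree with Felsenstein bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``n_reps`` times;
    the support of each internal edge of the reference tree is the number
    of replicate trees containing the same bipartition (0..n_reps scale),
    stored as the internal node's label.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels, mat, _ = _encode(seqs)
    if len(labels) < 4:
        raise ValueError("need >= 4 taxa for informative supports")
    L = mat.shape[1]
    ref_tree = neighbor_joining(alignment_distances(seqs, alphabet_size, cap))
    ref_bips = tree_bipartitions(ref_tree)
    counts = {bip: 0 for bip in ref_bips}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = {lab: mat[i, cols].tobytes().decode()
                     for i, lab in enumerate(labels)}
        rep_tree = neighbor_joining(
            alignment_distances(resampled, alphabet_size, cap))
        for bip in tree_bipartitions(rep_tree):
            if bip in counts:
                counts[bip] += 1
    all_labels = frozenset(labels)
    anchor = min(all_labels)
    for node in ref_tree.preorder_node_iter():
        if node is ref_tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = all_labels - side
        if side in counts:
            node.label = str(counts[side])
    return ref_tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick; supports appear as internal node labels."""
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string; malformed input raises ``ValueError``."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parser error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return tree


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Write a distance matrix in square PHYLIP format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.d):
            name = label[:10].ljust(10)
            fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")
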