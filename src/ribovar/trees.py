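"""Distance-based trees: neighbor-joining and UPGMA with bootstrap support.

Both builders run on a :class:`~ribovar.distances.DistanceMatrix` and return
dendropy trees (NJ unrooted, UPGMA rooted and ultrametric).  Agglomeration
ties are broken on the lowest-index pair, so identical inputs always give
identical trees.  Negative NJ branch lengths are clamped to zero (the
conventional rendering) and logged.  Bootstrap support resamples alignment
columns with replacement, recomputes the distance matrix per replicate,
rebuilds the tree, and reports the percentage of replicates containing each
internal split of the point-estimate tree.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np

from .distances import (
    DistanceMatrix,
    NoComparableSitesError,
    encode_matrix,
    mcl_distance_matrix,
    p_distance_matrix,
)

logger = logging.getLogger("ribovar.trees")


def _check_matrix(dm: DistanceMatrix, min_taxa: int) -> np.ndarray:
    if len(dm) < min_taxa:
        raise ValueError(f"need at least {min_taxa} taxa, got {len(dm)}")
    if np.isnan(dm.d).any():
        raise ValueError("distance matrix contains saturated (NaN) pairs")
    return dm.d.astype(float).copy()


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("clamping negative branch length %.6g to 0 (%s)", length, context)
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; exact on additive matrices."""
    d = _check_matrix(dm, 3)
    taxa = dendropy.TaxonNamespace([str(i) for i in dm.ids])
    nodes = []
    for t in taxa:
        node = dendropy.Node(taxon=t)
        nodes.append(node)
    active = list(range(len(nodes)))

    while len(active) > 3:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)  # first = lowest index
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        parent = dendropy.Node()
        a, b = active[i], active[j]
        parent.add_child(nodes[a])
        nodes[a].edge.length = _clamp(li, f"nj join {dm.ids[0]}-matrix")
        parent.add_child(nodes[b])
        nodes[b].edge.length = _clamp(lj, "nj join")
        # distances from the new node to the remaining ones
        new_d = 0.5 * (d[a, :] + d[b, :] - dij)
        d = np.vstack([d, new_d[None, :]])
        new_col = np.append(new_d, 0.0)
        d = np.hstack([d, new_col[:, None]])
        nodes.append(parent)
        k = len(nodes) - 1
        active = [x for x in active if x not in (a, b)] + [k]

    # resolve the final three nodes around an (unrooted) central vertex
    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = _clamp(ln, "nj final join")
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def upgma_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage agglomeration; rooted, ultrametric by construction."""
    d = _check_matrix(dm, 2)
    taxa = dendropy.TaxonNamespace([str(i) for i in dm.ids])
    nodes = [dendropy.Node(taxon=t) for t in taxa]
    sizes = [1] * len(nodes)
    heights = [0.0] * len(nodes)
    active = list(range(len(nodes)))

    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        np.fill_diagonal(sub, np.inf)
        i, j = np.unravel_index(np.argmin(sub), sub.shape)
        if i > j:
            i, j = j, i
        a, b = active[i], active[j]
        h = d[a, b] / 2.0
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = h - heights[a]
        parent.add_child(nodes[b])
        nodes[b].edge.length = h - heights[b]
        wa = sizes[a] / (sizes[a] + sizes[b])
        wb = 1.0 - wa
        new_d = wa * d[a, :] + wb * d[b, :]
        d = np.vstack([d, new_d[None, :]])
        d = np.hstack([d, np.append(new_d, 0.0)[:, None]])
        nodes.append(parent)
        sizes.append(sizes[a] + sizes[b])
        heights.append(h)
        k = len(nodes) - 1
        active = [x for x in active if x not in (a, b)] + [k]

    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[active[0]])
    tree.is_rooted = True
    return tree


def _splits(tree: dendropy.Tree) -> dict:
    """Map internal node -> normalised leaf-id split.

    Rooted trees compare clades; unrooted trees compare bipartitions
    (normalised to the side not containing the alphabetically first leaf).
    """
    all_ids = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    anchor = min(all_ids)
    out = {}
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(side) < 2:
            continue
        if not tree.is_rooted:
            if len(side) > len(all_ids) - 2:
                continue
            if anchor in side:
                side = all_ids - side
        out[node] = side
    return out


def _split_set(tree: dendropy.Tree) -> set:
    return set(_splits(tree).values())


def build_matrix(codes: np.ndarray, ids, metric: str) -> DistanceMatrix:
    if metric == "p":
        return p_distance_matrix(codes, ids=ids)
    if metric == "tn93_mcl":
        return mcl_distance_matrix(codes, ids=ids)
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_support(
    seqs,
    ids=None,
    builder: str = "nj",
    metric: str = "p",
    n_reps: int = 1000,
    seed: int = 0,
) -> dendropy.Tree:
    """Point-estimate tree with column-resampling bootstrap supports.

    ``seqs`` are anchored equal-length sequences (list of strings/Sequence
    or a uint8 code matrix).  Supports are percentages in [0, 100], written
    as internal node labels.  Replicates in which some pair has no
    comparable sites are skipped and logged.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    build = {"nj": nj_tree, "upgma": upgma_tree}.get(builder)
    if build is None:
        raise ValueError(f"builder must be 'nj' or 'upgma', got {builder!r}")
    if isinstance(seqs, np.ndarray):
        codes = seqs
        if ids is None:
            ids = [f"seq{i}" for i in range(codes.shape[0])]
    else:
        seqs = list(seqs)
        if ids is None:
            ids = [getattr(s, "id", f"seq{i}") for i, s in enumerate(seqs)]
        codes = encode_matrix([getattr(s, "residues", s) for s in seqs])
    n_cols = codes.shape[1]
    if n_cols < 1:
        raise ValueError("alignment has no columns")

    point = build(build_matrix(codes, ids, metric))
    target = _splits(point)
    counts = {node: 0 for node in target}
    rng = np.random.default_rng(seed)
    n_used = 0
    for _ in range(n_reps):
        idx = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_tree = build(build_matrix(codes[:, idx], ids, metric))
        except (NoComparableSitesError, ValueError) as exc:
            logger.info("bootstrap replicate skipped: %s", exc)
            continue
        n_used += 1
        rep_splits = _split_set(rep_tree)
        for node, split in target.items():
            if split in rep_splits:
                counts[node] += 1
    if n_used == 0:
        raise RuntimeError("all bootstrap replicates failed")
    for node, c in counts.items():
        node.label = f"{100.0 * c / n_used:g}"
    return point


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def read_newick(path_or_str, from_string: bool = False) -> dendropy.Tree:
    if from_string:
        return dendropy.Tree.get(data=path_or_str, schema="newick")
    return dendropy.Tree.get(path=str(path_or_str), schema="newick")
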