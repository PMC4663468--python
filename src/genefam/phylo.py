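"""Gene trees, species-tree reconciliation, and ancestral copy counts.

Trees are neighbor-joining (Saitou–Nei) over Poisson-corrected protein
distances, with bootstrap supports from column resampling. Gene trees are
reconciled against a species tree by LCA mapping: each gene-tree node maps
to the lowest species-tree node containing its leaf species, and an internal
node is a duplication iff its children's leaf-species sets intersect.

The ancestral (MRCA) copy count at a species-tree divergence S counts gene
lineages present at the instant of that divergence: speciation nodes mapping
to S, plus gene-tree edges whose parent maps strictly above S and whose
child maps strictly below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger("genefam")

MIN_SHARED_COLUMNS = 30


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix must have zero diagonal")
        if not np.isfinite(m).all() or (m < 0).any():
            raise ValueError("distances must be finite and non-negative")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


def protein_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Poisson-corrected pairwise distances d = −ln(1 − p) over an aligned
    protein set; p is the fraction of differing shared non-gap columns."""
    labels = list(alignment)
    seqs = [alignment[k].upper() for k in labels]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i], seqs[j]
            shared = [(x, y) for x, y in zip(a, b) if x not in "-." and y not in "-."]
            if len(shared) < MIN_SHARED_COLUMNS:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}): only {len(shared)} shared "
                    f"non-gap columns (< {MIN_SHARED_COLUMNS})")
            p = sum(x != y for x, y in shared) / len(shared)
            if p >= 1 - 1e-9:
                raise ValueError(f"pair ({labels[i]}, {labels[j]}): saturated (p = {p})")
            mat[i, j] = mat[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(labels=labels, matrix=mat)


def nj_tree(dist: DistanceMatrix,
            taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Canonical neighbor-joining tree (Q-criterion, standard branch lengths).

    Ties in the Q matrix break deterministically by label order, so the
    result is invariant to input label permutation. Negative branch-length
    estimates are clamped at zero. The tree is returned unrooted, with a
    trifurcating seed node.
    """
    labels = list(dist.labels)
    if len(labels) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    tns = taxon_namespace or dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    nodes: dict[str, dendropy.Node] = {}
    for lab in labels:
        node = dendropy.Node()
        node.taxon = tns.require_taxon(label=lab)
        nodes[lab] = node

    # order-independent state: distances keyed by sorted label pair
    order = sorted(labels)
    d = {}
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            d[(a, b)] = dist.get(a, b)

    def D(a, b):
        return d[(a, b)] if (a, b) in d else d[(b, a)]

    active = list(order)
    next_id = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(D(a, b) for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * D(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = D(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        parent = dendropy.Node()
        parent.label = f"_nj{next_id}"
        next_id += 1
        nodes[a].edge.length = max(0.0, la)
        nodes[b].edge.length = max(0.0, lb)
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        new_lab = parent.label
        for c in active:
            if c not in (a, b):
                d[tuple(sorted((new_lab, c)))] = max(0.0, 0.5 * (D(a, c) + D(b, c) - dab))
        active = sorted([c for c in active if c not in (a, b)] + [new_lab])
        nodes[new_lab] = parent

    a, b, c = active
    la = 0.5 * (D(a, b) + D(a, c) - D(b, c))
    lb = 0.5 * (D(a, b) + D(b, c) - D(a, c))
    lc = 0.5 * (D(a, c) + D(b, c) - D(a, b))
    root = tree.seed_node
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        nodes[lab].edge.length = max(0.0, ln)
        root.add_child(nodes[lab])
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _leafset_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the side not containing the
    alphabetically first leaf label (an unrooted-tree canonical form)."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    all_set = set(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        side = below if ref not in below else all_set - below
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset(side))
    return out


def bootstrap_support(alignment: dict[str, str], n_reps: int = 100,
                      seed: int = 0) -> dendropy.Tree:
    """NJ tree with bootstrap supports (% of column-resampled replicates
    containing each bipartition of the point-estimate tree)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = nj_tree(protein_distance_matrix(alignment))
    target = {}
    leaves = sorted(l.taxon.label for l in point.leaf_node_iter())
    ref, all_set = leaves[0], set(leaves)
    for node in point.preorder_node_iter():
        if node.is_leaf() or node is point.seed_node:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        side = below if ref not in below else all_set - below
        if 1 < len(side) < len(leaves) - 1:
            target[node] = frozenset(side)

    rng = np.random.default_rng(seed)
    ncols = len(next(iter(alignment.values())))
    counts = {node: 0 for node in target}
    for _ in range(n_reps):
        cols = rng.integers(0, ncols, size=ncols)
        rep_aln = {k: "".join(v[c] for c in cols) for k, v in alignment.items()}
        rep_tree = nj_tree(protein_distance_matrix(rep_aln))
        rep_bips = _leafset_bipartitions(rep_tree)
        for node, bip in target.items():
            if bip in rep_bips:
                counts[node] += 1
    for node, bip in target.items():
        node.label = f"{100.0 * counts[node] / n_reps:g}"
    return point


# ---------------------------------------------------------------------------
# reconciliation

@dataclass
class ReconciledTree:
    gene_tree: dendropy.Tree          # rooted; nodes carry .species_map / .event
    species_tree: dendropy.Tree
    n_duplications: int = 0
    n_losses: int = 0
    species_of: dict[str, str] = field(default_factory=dict)

    def events(self) -> list[tuple[str, str, str]]:
        """(node id, event, mapped species-node label) per internal node."""
        out = []
        for i, node in enumerate(self.gene_tree.preorder_internal_node_iter()):
            out.append((f"node{i}", node.event, _species_label(node.species_map)))
        return out


def _species_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    return "+".join(sorted(l.taxon.label for l in node.leaf_iter()))


def _species_index(species_tree: dendropy.Tree):
    leaf_map = {}
    depth = {}
    parent = {}
    for node in species_tree.preorder_node_iter():
        parent[node] = node.parent_node
        depth[node] = 0 if node.parent_node is None else depth[node.parent_node] + 1
        if node.is_leaf():
            leaf_map[node.taxon.label] = node
    return leaf_map, depth, parent


def _lca(a, b, depth, parent):
    while depth[a] > depth[b]:
        a = parent[a]
    while depth[b] > depth[a]:
        b = parent[b]
    while a is not b:
        a, b = parent[a], parent[b]
    return a


def reconcile_lca(gene_tree: dendropy.Tree, species_tree: dendropy.Tree,
                  species_of: dict[str, str]) -> ReconciledTree:
    """LCA-map a rooted gene tree into the species tree and label each
    internal node duplication or speciation."""
    leaf_map, depth, parent = _species_index(species_tree)
    n_dup = 0
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            gid = node.taxon.label
            sp = species_of.get(gid)
            if sp is None or sp not in leaf_map:
                raise KeyError(f"gene {gid}: unknown species tag {sp!r}")
            node.species_map = leaf_map[sp]
            node.species_set = frozenset([sp])
            node.event = "leaf"
        else:
            children = node.child_nodes()
            m = children[0].species_map
            for c in children[1:]:
                m = _lca(m, c.species_map, depth, parent)
            node.species_map = m
            node.species_set = frozenset().union(*(c.species_set for c in children))
            overlap = False
            for i, c1 in enumerate(children):
                for c2 in children[i + 1:]:
                    if c1.species_set & c2.species_set:
                        overlap = True
            node.event = "duplication" if overlap else "speciation"
            if overlap:
                n_dup += 1
    n_loss = _count_losses(gene_tree, depth)
    return ReconciledTree(gene_tree=gene_tree, species_tree=species_tree,
                          n_duplications=n_dup, n_losses=n_loss,
                          species_of=dict(species_of))


def _count_losses(gene_tree: dendropy.Tree, depth) -> int:
    """Implied gene losses under the LCA reconciliation: per gene-tree edge
    (u, v), depth(map(v)) − depth(map(u)) minus one expected step when u is
    a speciation (clipped at zero)."""
    losses = 0
    for node in gene_tree.preorder_node_iter():
        u = node.parent_node
        if u is None:
            continue
        d = depth[node.species_map] - depth[u.species_map]
        if u.event == "speciation":
            d -= 1
        losses += max(0, d)
    return losses


def root_minimizing_duplications(gene_tree: dendropy.Tree,
                                 species_tree: dendropy.Tree,
                                 species_of: dict[str, str]) -> dendropy.Tree:
    """Root an unrooted gene tree on the edge minimising implied duplications;
    ties resolved by fewest implied losses, then by rooting closest to the
    midpoint of the tree."""
    leaves = sorted(l.taxon.label for l in gene_tree.leaf_node_iter())
    candidates = []
    n_edges = sum(1 for e in gene_tree.preorder_edge_iter()
                  if e.head_node is not gene_tree.seed_node)
    for k in range(n_edges):
        t = gene_tree.clone(depth=1)
        edges = [e for e in t.preorder_edge_iter() if e.head_node is not t.seed_node]
        edge = edges[k]
        L = edge.length or 0.0
        t.reroot_at_edge(edge, length1=L / 2, length2=L / 2,
                         update_bipartitions=False)
        t.is_rooted = True
        rec = reconcile_lca(t, species_tree, species_of)
        # midpoint proximity: imbalance of max root-to-leaf depths of the two sides
        sides = t.seed_node.child_nodes()
        depths = []
        for s in sides:
            depths.append(max((_root_dist(l, t.seed_node) for l in s.leaf_iter()),
                              default=0.0))
        imbalance = abs(depths[0] - depths[1]) if len(depths) == 2 else 0.0
        candidates.append((rec.n_duplications, rec.n_losses, imbalance, k, t))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    return candidates[0][4]


def _root_dist(leaf, root):
    d = 0.0
    node = leaf
    while node is not root and node is not None:
        d += node.edge.length or 0.0
        node = node.parent_node
    return d


def mrca_copy_count(reconciled: ReconciledTree, species_node) -> int:
    """Gene lineages present at the instant of the divergence ``species_node``
    (an internal species-tree node, given as a node or its label)."""
    species_tree = reconciled.species_tree
    if isinstance(species_node, str):
        match = [n for n in species_tree.preorder_node_iter()
                 if _species_label(n) == species_node]
        if not match:
            raise KeyError(f"no species-tree node labelled {species_node!r}")
        species_node = match[0]
    if species_node.is_leaf():
        raise ValueError("MRCA counts are defined at internal species-tree "
                         "nodes; use the per-genome census for leaves")
    _, depth, parent = _species_index(species_tree)

    def strictly_below(n):
        p = parent[n]
        while p is not None:
            if p is species_node:
                return True
            p = parent[p]
        return False

    def strictly_above(n):
        p = parent[species_node]
        while p is not None:
            if p is n:
                return True
            p = parent[p]
        return False

    count = 0
    for node in reconciled.gene_tree.preorder_node_iter():
        if getattr(node, "event", None) == "speciation" and node.species_map is species_node:
            count += 1
        if node.parent_node is not None:
            u = node.parent_node.species_map
            v = node.species_map
            if strictly_above(u) and strictly_below(v):
                count += 1
    return count


def reciprocal_best_pairs(dist: DistanceMatrix,
                          group_of: dict[str, str]) -> list[tuple[str, str]]:
    """Cross-group reciprocal nearest-neighbour pairs; ties break by label
    order (logged)."""
    groups = {g: group_of[g] for g in dist.labels}
    if len(set(groups.values())) < 2:
        return []

    def nearest_cross(g):
        others = [h for h in dist.labels if groups[h] != groups[g]]
        if not others:
            return None
        dists = [(dist.get(g, h), h) for h in others]
        dists.sort()
        if len(dists) > 1 and dists[0][0] == dists[1][0]:
            logger.warning("gene %s equidistant to %s and %s; tie broken by label",
                           g, dists[0][1], dists[1][1])
        return dists[0][1]

    best = {g: nearest_cross(g) for g in dist.labels}
    pairs = []
    for g in dist.labels:
        h = best[g]
        if h is not None and best.get(h) == g and g < h:
            pairs.append((g, h))
    return sorted(pairs)
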