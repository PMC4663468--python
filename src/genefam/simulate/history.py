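"""Gillespie birth/loss simulation of a gene family along a species tree.

One seed gene enters the species-tree root. Along every species-tree branch
each gene lineage independently gains copies (one rate per mechanism) and
dies (loss rate); at speciations every surviving lineage is inherited by
both descendant branches. The true gene tree, the event list, and the true
ancestral copy count at every species divergence (lineages present at that
instant) are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .config import MECHANISMS, TE_CLASS_OF, SimulationConfig


@dataclass
class GeneLineage:
    """Node of the true gene tree. ``edge_length`` is time below its parent."""

    name: str
    edge_length: float
    event: str                       # leaf | duplication | speciation
    children: list["GeneLineage"] = field(default_factory=list)
    species: str = ""                # leaves only
    mechanism: str = ""              # set on the new-copy edge of a duplication
    origin_event: int = -1           # event id that created this lineage
    fragment_type: int = 0           # TE events only

    def leaves(self):
        if not self.children:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.edge_length:.6g}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}){self.name}:{self.edge_length:.6g}"


@dataclass
class TruthLog:
    config: SimulationConfig
    seed: int
    gene_tree: GeneLineage | None
    events: list[dict]
    genes: dict[str, dict]           # extant gene id -> truth record
    mrca_counts: dict[str, int]
    site_classes: list[int]
    site_omegas: list[float]
    species: list[str]
    cds: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)
    te_elements: list[dict] = field(default_factory=list)
    expression_truth: dict = field(default_factory=dict)

    def species_of(self) -> dict[str, str]:
        return {g: rec["species"] for g, rec in self.genes.items()}

    def gene_tree_newick(self) -> str:
        return (self.gene_tree.newick() + ";") if self.gene_tree else ";"


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    return "+".join(sorted(l.taxon.label for l in node.leaf_iter()))


def simulate_family_history(config: SimulationConfig, seed: int) -> TruthLog:
    """Run the birth/loss process; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    sp_tree = dendropy.Tree.get(data=config.species_tree, schema="newick")
    species = sorted(l.taxon.label for l in sp_tree.leaf_node_iter())

    # expected-size guard: supercritical growth estimate
    b = sum(config.birth_rates.get(m, 0.0) for m in MECHANISMS)
    height = _tree_height(sp_tree)
    expected = len(species) * float(np.exp((b - config.loss_rate) * height))
    if expected > config.max_family_size:
        raise ValueError(
            f"expected family size ~{expected:.0f} exceeds {config.max_family_size}; "
            "reduce birth rates or shrink the species tree")

    mechs = list(MECHANISMS)
    rates = np.array([config.birth_rates.get(m, 0.0) for m in mechs])
    total_birth = rates.sum()
    total_rate = total_birth + config.loss_rate

    events: list[dict] = []
    mrca_counts: dict[str, int] = {}
    counters = {"node": 0, "leaf": {}, "event": 0}

    def new_node_name():
        counters["node"] += 1
        return f"n{counters['node']}"

    def new_leaf_name(sp):
        k = counters["leaf"].get(sp, 0) + 1
        counters["leaf"][sp] = k
        return f"{sp}_g{k:03d}"

    def evolve(species_node: dendropy.Node, t0: float) -> GeneLineage | None:
        """Lineage on the edge above ``species_node``, entered at time t0."""
        T = species_node.edge.length or 0.0
        t = t0
        while True:
            dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if t + dt >= T:
                break
            t += dt
            u = rng.random() * total_rate
            if u >= total_birth:  # loss
                events.append({"event_id": counters["event"], "branch": _node_label(species_node),
                               "time": t, "mechanism": "loss"})
                counters["event"] += 1
                return None
            mech = mechs[int(np.searchsorted(np.cumsum(rates), u, side="right"))]
            eid = counters["event"]
            counters["event"] += 1
            frag = 0
            if mech in TE_CLASS_OF:
                frag = 1 + int(rng.choice(4, p=np.asarray(config.fragment_type_probs)))
            events.append({"event_id": eid, "branch": _node_label(species_node),
                           "time": t, "mechanism": mech,
                           "te_class": TE_CLASS_OF.get(mech, ""),
                           "fragment_type": frag})
            cont = evolve(species_node, t)
            new = evolve(species_node, t)
            if new is not None:
                new.mechanism = mech
                new.origin_event = eid
                new.fragment_type = frag
            kids = [c for c in (cont, new) if c is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kids[0].edge_length += t - t0
                return kids[0]
            return GeneLineage(name=new_node_name(), edge_length=t - t0,
                               event="duplication", children=kids)
        # survived to the end of the branch
        if species_node.is_leaf():
            sp = species_node.taxon.label
            return GeneLineage(name=new_leaf_name(sp), edge_length=T - t0,
                               event="leaf", species=sp)
        label = _node_label(species_node)
        mrca_counts[label] = mrca_counts.get(label, 0) + 1
        kids = [evolve(c, 0.0) for c in species_node.child_nodes()]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].edge_length += T - t0
            return kids[0]
        return GeneLineage(name=new_node_name(), edge_length=T - t0,
                           event="speciation", children=kids)

    # seed gene sits at the species root divergence
    root_sp = sp_tree.seed_node
    root_label = _node_label(root_sp)
    mrca_counts[root_label] = 1
    kids = [evolve(c, 0.0) for c in root_sp.child_nodes()]
    kids = [k for k in kids if k is not None]
    if not kids:
        root = None
    elif len(kids) == 1:
        root = kids[0]
    else:
        root = GeneLineage(name=root_label, edge_length=0.0, event="speciation",
                           children=kids)

    n_extant = sum(1 for _ in root.leaves()) if root else 0
    if n_extant > config.max_family_size:
        raise ValueError(f"family size {n_extant} exceeds {config.max_family_size}")

    genes = _annotate_extant(root) if root else {}

    # per-site omega classes
    props = np.array([p for p, _ in config.omega_classes])
    omegas = [w for _, w in config.omega_classes]
    site_classes = rng.choice(len(omegas), size=config.n_codons, p=props)
    site_omegas = [omegas[c] for c in site_classes]

    return TruthLog(config=config, seed=seed, gene_tree=root, events=events,
                    genes=genes, mrca_counts=mrca_counts,
                    site_classes=[int(c) for c in site_classes],
                    site_omegas=[float(w) for w in site_omegas],
                    species=species)


def _tree_height(tree: dendropy.Tree) -> float:
    best = 0.0
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        best = max(best, d)
    return best


def _annotate_extant(root: GeneLineage) -> dict[str, dict]:
    """Per-extant-gene truth: species, origin mechanism/event, anchor parent
    (the same-species representative of the sibling lineage at the event)."""
    genes: dict[str, dict] = {}

    # attach sibling pointers at duplication nodes first
    def attach(node: GeneLineage):
        if node.event == "duplication" and len(node.children) == 2:
            a, b = node.children
            if b.mechanism:
                b._sibling = a
            elif a.mechanism:
                a._sibling = b
        for c in node.children:
            attach(c)

    attach(root)

    def walk(node: GeneLineage, origin):
        if node.mechanism:
            origin = (node.mechanism, node.origin_event, node.fragment_type,
                      getattr(node, "_sibling", None))
        if not node.children:
            mech, eid, frag, sib = origin
            anchor = ""
            if sib is not None:
                same = sorted(l.name for l in sib.leaves() if l.species == node.species)
                anchor = same[0] if same else ""
            genes[node.name] = {
                "species": node.species,
                "origin_mech": mech or "ancestral",
                "origin_event": eid,
                "te_class": TE_CLASS_OF.get(mech, "") if mech else "",
                "fragment_type": frag,
                "anchor_parent": anchor,
            }
            return
        for c in node.children:
            walk(c, origin)

    walk(root, ("", -1, 0, None))
    return genes
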