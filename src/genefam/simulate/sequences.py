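"""Codon sequence evolution along the simulated gene tree.

Sites evolve independently under the Muse–Gaut-style codon model with a
shared kappa and one omega per site class; no stop codons can arise because
the state space is the 61 sense codons. Alignment is known by construction
(no indels), so extant CDSs are column-comparable.
"""

from __future__ import annotations

import numpy as np

from .. import codons as C
from .config import SimulationConfig
from .history import GeneLineage, TruthLog


def ancestral_cds(config: SimulationConfig, seed: int) -> str:
    """The seed gene's codon sequence (deterministic in the run seed)."""
    rng = np.random.default_rng([seed, 17])
    idx = rng.integers(0, 61, size=config.n_codons)
    return "".join(C.SENSE_CODONS[i] for i in idx)


def evolve_codon_sequences(truth: TruthLog, config: SimulationConfig,
                           seed: int) -> dict[str, str]:
    """Evolve CDSs for every extant gene; fills truth.cds / truth.proteins."""
    rng = np.random.default_rng([seed, 1])
    anc = ancestral_cds(config, seed)
    anc_idx = np.array([C.CODON_INDEX[anc[3 * i:3 * i + 3]]
                        for i in range(config.n_codons)])
    classes = np.asarray(truth.site_classes)
    omegas = [w for _, w in config.omega_classes]
    pi = np.full(61, 1.0 / 61)
    eig = {}
    for k, w in enumerate(omegas):
        Q = C.rate_matrix(config.kappa, w, pi, scale="neutral")
        sq = np.sqrt(pi)
        B = 0.5 * ((Q * sq[:, None]) / sq[None, :] + ((Q * sq[:, None]) / sq[None, :]).T)
        vals, vecs = np.linalg.eigh(B)
        eig[k] = (vals, vecs / sq[:, None], vecs * sq[:, None])

    def pmatrix(k, t):
        vals, left, right = eig[k]
        P = (left * np.exp(vals * t)) @ right.T
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    out: dict[str, str] = {}

    def walk(node: GeneLineage, parent_idx: np.ndarray):
        child_idx = parent_idx.copy()
        if node.edge_length > 0:
            for k in range(len(omegas)):
                sites = np.nonzero(classes == k)[0]
                if sites.size == 0:
                    continue
                P = pmatrix(k, node.edge_length)
                cum = P.cumsum(axis=1)
                u = rng.random(sites.size)
                for j, s in enumerate(sites):
                    child_idx[s] = np.searchsorted(cum[child_idx[s]], u[j], side="right")
        if not node.children:
            out[node.name] = "".join(C.SENSE_CODONS[i] for i in child_idx)
            return
        for c in node.children:
            walk(c, child_idx)

    if truth.gene_tree is not None:
        walk(truth.gene_tree, anc_idx)

    truth.cds = out
    truth.proteins = {g: "".join(C.translate_codon(s[i:i + 3])
                                 for i in range(0, len(s), 3))
                      for g, s in out.items()}
    return out


def evolve_alignment(tree, site_omegas, kappa: float, seed: int,
                     scale: str = "neutral") -> dict[str, str]:
    """Evolve a codon alignment along an arbitrary dendropy tree.

    One omega per codon site; branch lengths are expected substitutions per
    codon at omega = 1 (``scale="neutral"``). Returns {leaf label: codons}.
    Used for selection-analysis calibration experiments.
    """
    import dendropy  # local import: dendropy trees are an input type here

    rng = np.random.default_rng(seed)
    omegas = np.asarray(site_omegas, dtype=float)
    n_sites = omegas.size
    pi = np.full(61, 1.0 / 61)
    pmats: dict[tuple[float, float], np.ndarray] = {}

    def pmatrix(w, t):
        key = (float(w), float(t))
        if key not in pmats:
            Q = C.rate_matrix(kappa, w, pi, scale=scale)
            pmats[key] = C.transition_probabilities(Q, pi, np.array([t]))[0]
        return pmats[key]

    out: dict[str, str] = {}
    root_state = rng.integers(0, 61, size=n_sites)

    def walk(node, state):
        t = node.edge.length or 0.0
        child = state.copy()
        if t > 0:
            for w in np.unique(omegas):
                P = pmatrix(w, t)
                cum = P.cumsum(axis=1)
                for s in np.nonzero(omegas == w)[0]:
                    child[s] = np.searchsorted(cum[child[s]], rng.random(),
                                               side="right")
        if node.is_leaf():
            out[node.taxon.label] = "".join(C.SENSE_CODONS[i] for i in child)
            return
        for c in node.child_nodes():
            walk(c, child)

    for c in tree.seed_node.child_nodes():
        walk(c, root_state)
    if tree.seed_node.is_leaf():  # degenerate single-leaf tree
        out[tree.seed_node.taxon.label] = "".join(C.SENSE_CODONS[i] for i in root_state)
    return out


def make_seed_alignment(config: SimulationConfig, seed: int, n_seqs: int = 6,
                        divergence: float = 0.15) -> dict[str, str]:
    """A synthetic seed-domain alignment for profile building.

    The ancestor's domain-region protein plus perturbed copies (each residue
    mutated with probability ``divergence``); gap-free, equal-length.
    """
    rng = np.random.default_rng([seed, 29])
    anc = ancestral_cds(config, seed)
    lo, hi = config.domain_span
    domain_prot = "".join(C.translate_codon(anc[3 * i:3 * i + 3])
                          for i in range(lo, hi))
    aas = "ACDEFGHIKLMNPQRSTVWY"
    aln = {f"seed1": domain_prot}
    for k in range(2, n_seqs + 1):
        chars = list(domain_prot)
        for i in range(len(chars)):
            if rng.random() < divergence:
                chars[i] = aas[rng.integers(0, 20)]
        aln[f"seed{k}"] = "".join(chars)
    return aln
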