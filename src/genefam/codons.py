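"""Genetic-code tables and codon substitution-model machinery.

The universal genetic code is fixed throughout the package. Codon models are
Muse–Gaut/Goldman–Yang style: instantaneous rates between codons differing at
a single nucleotide position, scaled by ``kappa`` for transitions and
``omega`` for nonsynonymous changes, weighted by the target-codon equilibrium
frequency. Rate matrices are normalised to one expected substitution per
codon site per unit branch length.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

NUCS = "TCAG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: the 61 sense codons of the universal code, in TCAG order
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCS, repeat=3)) if c not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def translate_codon(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) for a DNA codon."""
    return _CODE[codon.upper().replace("U", "T")]


def is_stop(codon: str) -> bool:
    return codon.upper() in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


def is_synonymous(c1: str, c2: str) -> bool:
    """True if two sense codons encode the same amino acid."""
    return _CODE[c1] == _CODE[c2]


def codon_neighbors(codon: str):
    """Yield (position, new_nucleotide, new_codon) for all 9 single-base changes."""
    for pos in range(3):
        for n in NUCS:
            if n != codon[pos]:
                yield pos, n, codon[:pos] + n + codon[pos + 1:]


@lru_cache(maxsize=None)
def _neighbor_table() -> list[tuple[int, int, bool, bool]]:
    """(i, j, is_transition, is_synonymous) for sense-codon pairs one change apart."""
    table = []
    for i, c1 in enumerate(SENSE_CODONS):
        for pos, n, c2 in codon_neighbors(c1):
            j = CODON_INDEX.get(c2)
            if j is not None:
                table.append((i, j, is_transition(c1[pos], n), is_synonymous(c1, c2)))
    return table


def rate_matrix(kappa: float, omega: float, pi: np.ndarray | None = None,
                scale: str = "own") -> np.ndarray:
    """61x61 codon rate matrix.

    Parameters
    ----------
    kappa : transition/transversion rate ratio.
    omega : nonsynonymous/synonymous rate ratio (dN/dS).
    pi : equilibrium codon frequencies (length 61, sums to 1); uniform if None.
    scale : "own" normalises to one expected substitution per codon per unit
        branch length at this omega; "neutral" normalises by the mean rate of
        the omega = 1 matrix, so sites with different omegas share one clock
        (a purifying site then accumulates fewer substitutions per unit time,
        a positively selected site more).
    """
    n = len(SENSE_CODONS)
    if pi is None:
        pi = np.full(n, 1.0 / n)
    Q = np.zeros((n, n))
    syn_flux = nonsyn_flux = 0.0
    for i, j, ts, syn in _neighbor_table():
        r = pi[j]
        if ts:
            r *= kappa
        flux = pi[i] * r
        if syn:
            syn_flux += flux
        else:
            nonsyn_flux += flux
            r *= omega
        Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale == "own":
        mu = -(pi * np.diag(Q)).sum()
    elif scale == "neutral":
        mu = syn_flux + nonsyn_flux
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if mu > 0:
        Q /= mu
    return Q


def transition_probabilities(Q: np.ndarray, pi: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = exp(Qt) for each branch length, via the reversible eigendecomposition.

    Returns an array of shape (len(lengths), 61, 61). Rounding noise is
    clipped at zero and rows renormalised.
    """
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    B = 0.5 * (B + B.T)
    w, U = np.linalg.eigh(B)
    left = U / sq[:, None]
    right = U * sq[:, None]
    P = np.einsum("ik,tk,jk->tij", left, np.exp(np.outer(lengths, w)), right)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def f3x4_frequencies(codon_seqs: list[str]) -> np.ndarray:
    """F3x4 codon frequencies from observed per-position nucleotide frequencies."""
    counts = np.full((3, 4), 1.0)  # +1 pseudocount per cell
    nuc_idx = {n: k for k, n in enumerate(NUCS)}
    for seq in codon_seqs:
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i:i + 3].upper()
            for pos in range(3):
                k = nuc_idx.get(codon[pos])
                if k is not None:
                    counts[pos, k] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [freqs[0, nuc_idx[c[0]]] * freqs[1, nuc_idx[c[1]]] * freqs[2, nuc_idx[c[2]]]
         for c in SENSE_CODONS]
    )
    return pi / pi.sum()
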