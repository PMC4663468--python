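"""Family census: profile scanning and domain-combination family calls.

Four sucrose-metabolism families are identified purely by Pfam domain
content: SuSy = PF00862, UDPGP = PF01704, SPS = PF00534 + PF05116 together,
SPP = PF05116 without a confirming PF00534 hit.

The profile model is a position-specific scoring matrix (PSSM) with affine
gaps scored in half-bits, scanned by local (Smith–Waterman) alignment.
E-values come from an empirical null: a Gumbel fitted by the method of
moments to scores of shuffled decoy sequences, with the Karlin–Altschul
``ln(length)`` location adjustment, multiplied by database size. The
decision thresholds (E <= 1.0 to search, E <= 0.01 to confirm) are the
analysis' fixed operating points.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import numpy as np

from .formats_io import DomainHitRecord

logger = logging.getLogger("genefam")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Robinson & Robinson (1991) background amino-acid frequencies
ROBINSON_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

FAMILY_DOMAINS = {
    "SuSy": frozenset({"PF00862"}),
    "SPS": frozenset({"PF00534", "PF05116"}),
    "SPP": frozenset({"PF05116"}),
    "UDPGP": frozenset({"PF01704"}),
}

DEFAULT_E_INIT = 1.0
DEFAULT_E_CONFIRM = 0.01
DEFAULT_MIN_COVERAGE = 0.7


@dataclass
class DomainProfile:
    """PSSM over consensus columns, scores in half-bits."""

    profile_id: str
    scores: np.ndarray        # (n_columns, 20) log-odds, half-bits
    consensus: str
    gap_open: float = 7.0
    gap_extend: float = 1.0
    n_seed: int = 0

    def __post_init__(self):
        if self.scores.shape != (len(self.consensus), 20):
            raise ValueError("score matrix shape must be (n_columns, 20)")
        if not np.isfinite(self.scores).all():
            raise ValueError("profile scores must be finite")
        if self.n_seed < 2:
            raise ValueError("a profile needs at least 2 seed sequences")

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass
class FamilyAssignment:
    gene_id: str
    family: str                       # SuSy | SPS | SPP | UDPGP | none
    supporting_hits: list[DomainHitRecord] = field(default_factory=list)
    status: str = "full"              # full | partial_excluded

    @property
    def best_e(self) -> float:
        return min((h.e_value for h in self.supporting_hits), default=float("inf"))

    @property
    def best_coverage(self) -> float:
        return max((h.profile_coverage for h in self.supporting_hits), default=0.0)


def build_domain_profile(
    seed_alignment: dict[str, str],
    background_freqs: dict[str, float] | None = None,
    profile_id: str = "profile",
    max_gap_fraction: float = 0.5,
    alpha: float = 0.5,
) -> DomainProfile:
    """Build a PSSM from an aligned set of seed domain sequences.

    Consensus columns are alignment columns with < ``max_gap_fraction`` gaps.
    Per-column probabilities use Laplace pseudocounts (``alpha`` per residue)
    mixed with background frequencies; scores are ``2*log2(p/background)``
    half-bits.
    """
    seqs = [s.upper() for s in seed_alignment.values()]
    if len(seqs) < 2:
        raise ValueError("need >= 2 seed sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"seed sequences have unequal lengths: {sorted(lengths)}")
    n_cols = lengths.pop()
    bg = background_freqs or ROBINSON_FREQS
    bg_vec = np.array([bg[a] for a in AMINO_ACIDS])
    bg_vec = bg_vec / bg_vec.sum()

    kept_scores = []
    consensus = []
    for j in range(n_cols):
        column = [s[j] for s in seqs]
        gaps = sum(c in "-." for c in column)
        if gaps / len(column) >= max_gap_fraction:
            continue
        counts = np.zeros(20)
        for c in column:
            i = _AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
        # pseudocount mass split in proportion to background
        probs = (counts + alpha * 20 * bg_vec) / (counts.sum() + alpha * 20)
        kept_scores.append(2.0 * np.log2(probs / bg_vec))
        consensus.append(AMINO_ACIDS[int(np.argmax(counts))])
    if not kept_scores:
        raise ValueError("all alignment columns were gap-dominated")
    return DomainProfile(
        profile_id=profile_id,
        scores=np.vstack(kept_scores),
        consensus="".join(consensus),
        n_seed=len(seqs),
    )


def _encode_protein(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)


try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a soft accelerator
    def njit(*a, **k):
        if a and callable(a[0]):
            return a[0]
        return lambda f: f


@njit(cache=True)
def _sw_pssm(enc, scores, gap_open, gap_extend):
    """Local affine-gap alignment of an encoded protein against a PSSM.

    Returns (best score, prot_start, prot_end, col_start, col_end),
    protein/profile coordinates 1-based inclusive.
    """
    L = enc.shape[0]
    M = scores.shape[0]
    H = np.zeros((L + 1, M + 1))
    E = np.full((L + 1, M + 1), -1e9)  # gap in profile (consuming protein)
    F = np.full((L + 1, M + 1), -1e9)  # gap in protein (consuming profile)
    ptr = np.zeros((L + 1, M + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        for j in range(1, M + 1):
            aa = enc[i - 1]
            s = scores[j - 1, aa] if aa >= 0 else 0.0
            E[i, j] = max(H[i - 1, j] - gap_open, E[i - 1, j] - gap_extend)
            F[i, j] = max(H[i, j - 1] - gap_open, F[i, j - 1] - gap_extend)
            h = H[i - 1, j - 1] + s
            val = h
            p = 1
            if E[i, j] > val:
                val = E[i, j]
                p = 2
            if F[i, j] > val:
                val = F[i, j]
                p = 3
            if val <= 0.0:
                val = 0.0
                p = 0
            H[i, j] = val
            ptr[i, j] = p
            if val > best:
                best = val
                bi = i
                bj = j
    # traceback for aligned spans
    i, j = bi, bj
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            i -= 1
            j -= 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return best, i + 1, bi, j + 1, bj


def score_protein(profile: DomainProfile, protein: str):
    """Best local PSSM score and aligned spans for one protein."""
    enc = _encode_protein(protein)
    if enc.size == 0:
        return 0.0, 0, 0, 0, 0
    return _sw_pssm(enc, profile.scores, profile.gap_open, profile.gap_extend)


def _fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Gumbel (location, scale) fit."""
    beta = float(np.std(scores)) * np.sqrt(6.0) / np.pi
    beta = max(beta, 1e-6)
    mu = float(np.mean(scores)) - 0.5772156649 * beta
    return mu, beta


def scan_proteins(
    profile: DomainProfile,
    proteins: dict[str, str],
    e_init: float = DEFAULT_E_INIT,
    n_shuffle: int = 200,
    seed: int = 0,
) -> list[DomainHitRecord]:
    """Scan a proteome with one profile; return hits with E <= ``e_init``.

    The null distribution is fitted to local-alignment scores of
    ``n_shuffle`` shuffled decoys drawn round-robin from the proteome; the
    per-comparison Gumbel p-value gets a ``beta*ln(n/n0)`` length adjustment
    and is multiplied by database size to give a per-scan E-value.
    """
    if not proteins:
        raise ValueError("empty proteome")
    names = sorted(proteins)
    usable = [n for n in names if proteins[n]]
    for n in names:
        if not proteins[n]:
            logger.warning("skipping empty protein %s", n)
    rng = random.Random(seed)
    decoy_scores = []
    decoy_lengths = []
    for k in range(n_shuffle):
        src = list(proteins[usable[k % len(usable)]])
        rng.shuffle(src)
        s, *_ = score_protein(profile, "".join(src))
        decoy_scores.append(s)
        decoy_lengths.append(len(src))
    mu0, beta = _fit_gumbel(np.array(decoy_scores))
    n0 = max(1.0, float(np.mean(decoy_lengths)))
    n_db = len(usable)

    hits = []
    for name in usable:
        seq = proteins[name]
        score, ps, pe, cs, ce = score_protein(profile, seq)
        mu = mu0 + beta * np.log(max(len(seq), 1) / n0)
        z = (score - mu) / beta
        # p = 1 - exp(-exp(-z)), computed stably
        p = float(-np.expm1(-np.exp(-z))) if z > -30 else 1.0
        e_value = n_db * p
        if e_value <= e_init and score > 0:
            coverage = (ce - cs + 1) / profile.length
            hits.append(DomainHitRecord(
                gene_id=name, profile_id=profile.profile_id,
                bit_score=score / 2.0, e_value=e_value,
                prot_start=ps, prot_end=pe,
                profile_coverage=min(coverage, 1.0),
            ))
    hits.sort(key=lambda h: (h.e_value, h.gene_id))
    return hits


def assign_families(
    hits: list[DomainHitRecord],
    e_confirm: float = DEFAULT_E_CONFIRM,
) -> list[FamilyAssignment]:
    """Apply the domain-combination rules to confirmed hits (E <= ``e_confirm``).

    A gene matching domains of two different families is assigned to the
    family whose supporting hits have the lowest E-value, with the conflict
    logged. The result is independent of input hit order.
    """
    by_gene: dict[str, dict[str, DomainHitRecord]] = {}
    for h in sorted(hits, key=lambda h: (h.gene_id, h.profile_id, h.e_value)):
        best = by_gene.setdefault(h.gene_id, {})
        if h.e_value > e_confirm:
            continue
        if h.profile_id not in best or h.e_value < best[h.profile_id].e_value:
            best[h.profile_id] = h

    assignments = []
    for gene_id in sorted(by_gene):
        domains = by_gene[gene_id]
        present = set(domains)
        candidates = []
        for family, required in FAMILY_DOMAINS.items():
            if family == "SPP":
                ok = "PF05116" in present and "PF00534" not in present
            else:
                ok = required <= present
            if ok:
                supp = [domains[d] for d in sorted(required)]
                candidates.append((min(h.e_value for h in supp), family, supp))
        if not candidates:
            assignments.append(FamilyAssignment(gene_id=gene_id, family="none"))
            continue
        candidates.sort(key=lambda c: (c[0], c[1]))
        if len({c[1] for c in candidates}) > 1:
            logger.warning("gene %s matches domains of multiple families %s; "
                           "assigned by lowest E-value", gene_id,
                           sorted({c[1] for c in candidates}))
        _, family, supp = candidates[0]
        assignments.append(FamilyAssignment(gene_id=gene_id, family=family,
                                            supporting_hits=supp))
    return assignments


def flag_partial_members(
    assignments: list[FamilyAssignment],
    expression_evidence: set[str] = frozenset(),
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[FamilyAssignment]:
    """Mark members lacking a full domain and expression evidence for removal.

    A member is ``partial_excluded`` only when its best hit covers less than
    ``min_coverage`` of the profile AND it has no expression evidence; either
    a full domain or expression keeps it.
    """
    out = []
    for a in assignments:
        status = a.status
        if a.family != "none":
            partial = a.best_coverage < min_coverage
            status = "partial_excluded" if partial and a.gene_id not in expression_evidence else "full"
        out.append(FamilyAssignment(gene_id=a.gene_id, family=a.family,
                                    supporting_hits=a.supporting_hits, status=status))
    return out
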