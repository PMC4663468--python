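"""Codon-level selection analysis.

Pairwise Ka/Ks uses Nei–Gojobori (1986) counting as the reference method:
fractional synonymous/nonsynonymous site counts per codon, observed
differences averaged over all orderings of multi-position mutation pathways
(stop-traversing pathways excluded with renormalisation), and Jukes–Cantor
correction of the proportions. A YN00-compatible mode re-weights site
counting by a transition/transversion ratio estimated from the pair and by
F3x4 codon frequencies.

The sitewise scan fits a Muse–Gaut-style codon model (single kappa, branch
scale) by maximum likelihood via Felsenstein pruning over the 61 sense
codons, then maximises each site's likelihood over omega in [0, 50] and
tests omega = 1 with a chi-square(1) likelihood-ratio test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import dendropy
import numpy as np
from scipy import optimize, stats

from . import codons as C

NAN = float("nan")


# ---------------------------------------------------------------------------
# codon alignments

@dataclass
class CodonAlignment:
    """Aligned codon sequences; the gap unit is '---'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        lens = {len(r) for r in self.rows}
        if len(lens) > 1 or (lens and next(iter(lens)) % 3 != 0):
            raise ValueError("codon alignment rows must share a length divisible by 3")
        for name, row in zip(self.ids, self.rows):
            for i in range(0, len(row), 3):
                codon = row[i:i + 3].upper()
                if codon != "---" and C.is_stop(codon):
                    raise ValueError(f"{name}: internal stop codon {codon} at codon {i // 3 + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon(self, row: int, site: int) -> str:
        return self.rows[row][3 * site:3 * site + 3].upper()

    def pair(self, a: int = 0, b: int = 1) -> "CodonAlignment":
        return CodonAlignment(ids=[self.ids[a], self.ids[b]],
                              rows=[self.rows[a], self.rows[b]])


def backtranslate(protein_alignment: dict[str, str],
                  cds_by_id: dict[str, str]) -> CodonAlignment:
    """Thread each CDS through its aligned protein, expanding gaps x3.

    Every codon must translate to its aligned amino acid (a terminal stop on
    the CDS is tolerated); a mismatch raises with the offending residue.
    """
    ids, rows = [], []
    for name, prot in protein_alignment.items():
        cds = cds_by_id.get(name, "").upper()
        if not cds:
            raise KeyError(f"no CDS for {name}")
        residues = [c for c in prot if c not in "-."]
        n_codons = len(cds) // 3
        if len(cds) % 3 != 0:
            raise ValueError(f"{name}: CDS length {len(cds)} not divisible by 3")
        if n_codons == len(residues) + 1 and C.is_stop(cds[-3:]):
            cds = cds[:-3]
            n_codons -= 1
        if n_codons != len(residues):
            raise ValueError(f"{name}: CDS has {n_codons} codons but alignment "
                             f"has {len(residues)} residues")
        out = []
        k = 0
        for pos, aa in enumerate(prot, start=1):
            if aa in "-.":
                out.append("---")
                continue
            codon = cds[3 * k:3 * k + 3]
            trans = C.translate_codon(codon)
            if trans != aa.upper() and aa.upper() != "X":
                raise ValueError(
                    f"{name}: residue {pos}: codon {codon} translates to "
                    f"{trans}, alignment has {aa}")
            out.append(codon)
            k += 1
        ids.append(name)
        rows.append("".join(out))
    return CodonAlignment(ids=ids, rows=rows)


@dataclass
class PairFilterResult:
    accepted: bool
    reason: str = ""
    overlap_bp: int = 0
    identity: float = 0.0


def filter_pair_alignment(pair: CodonAlignment, min_overlap_bp: int = 150,
                          min_identity: float = 0.70) -> PairFilterResult:
    """The pair filter for incomplete overlaps: require an ungapped overlap
    longer than ``min_overlap_bp`` with nucleotide identity >= ``min_identity``."""
    if len(pair.ids) != 2:
        raise ValueError("pair filter takes a 2-sequence alignment")
    a, b = pair.rows[0].upper(), pair.rows[1].upper()
    overlap = matches = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            overlap += 1
            matches += x == y
    if overlap <= min_overlap_bp:
        return PairFilterResult(False, "length", overlap,
                                matches / overlap if overlap else 0.0)
    ident = matches / overlap
    if ident < min_identity:
        return PairFilterResult(False, "identity", overlap, ident)
    return PairFilterResult(True, "", overlap, ident)


# ---------------------------------------------------------------------------
# NG86 / YN00-style pairwise Ka/Ks

@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: float          # NaN when Ks = 0
    S: float
    N: float
    Sd: float
    Nd: float
    method: str = "NG86"
    n_codons: int = 0

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.ratio)


@lru_cache(maxsize=None)
def _ng86_codon_sites(codon: str) -> float:
    """Synonymous site count of one sense codon (N = 3 - S).

    Per position, the synonymous fraction among the single-base changes that
    do not create a stop codon.
    """
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for n in C.NUCS:
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1:]
            if C.is_stop(alt):
                continue
            tot += 1
            syn += C.is_synonymous(codon, alt)
        if tot:
            s += syn / tot
    return s


@lru_cache(maxsize=None)
def _ng86_codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons,
    averaged over stop-free orderings of the single-base steps."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if C.is_stop(nxt):
                ok = False
                break
            if C.is_synonymous(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # every ordering passes a stop; fall back to all orderings
        for order in itertools.permutations(positions):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if C.is_synonymous(cur, nxt) and not C.is_stop(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _usable_codon_pairs(pair: CodonAlignment):
    out = []
    for site in range(pair.n_codons):
        c1, c2 = pair.codon(0, site), pair.codon(1, site)
        if "-" in c1 + c2 or "N" in c1 + c2:
            continue
        out.append((c1, c2))
    return out


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"saturated: proportion {p:.3f} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _estimate_kappa(codon_pairs) -> float:
    """Transition/transversion rate-ratio estimate (K80) from all aligned
    nucleotide positions of the pair; falls back to 2.0 when undefined."""
    ts = tv = tot = 0
    for c1, c2 in codon_pairs:
        for x, y in zip(c1, c2):
            tot += 1
            if x != y:
                if C.is_transition(x, y):
                    ts += 1
                else:
                    tv += 1
    if tot == 0:
        return 2.0
    P, Q = ts / tot, tv / tot
    try:
        a = 1.0 / (1.0 - 2.0 * P - Q)
        b = 1.0 / (1.0 - 2.0 * Q)
        d_ts = 0.5 * math.log(a) - 0.25 * math.log(b)
        d_tv = 0.5 * math.log(b)
        if d_tv <= 0 or d_ts <= 0:
            return 2.0
        return max(0.1, min(20.0, 2.0 * d_ts / d_tv))
    except (ValueError, ZeroDivisionError):
        return 2.0


def _weighted_codon_sites(codon: str, kappa: float, pi: np.ndarray) -> float:
    """Synonymous site count with mutation-opportunity weights: transitions
    weighted by kappa and target codons by their F3x4 frequency."""
    s = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for n in C.NUCS:
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1:]
            if C.is_stop(alt):
                continue
            w = pi[C.CODON_INDEX[alt]]
            if C.is_transition(codon[pos], n):
                w *= kappa
            tot_w += w
            if C.is_synonymous(codon, alt):
                syn_w += w
        if tot_w > 0:
            s += syn_w / tot_w
    return s


def kaks_pair(pair: CodonAlignment, method: str = "NG86") -> KaKsResult:
    """Pairwise Ka, Ks and their ratio from an aligned codon pair.

    Codon columns containing a gap or an ambiguous base are dropped pairwise.
    Raises on saturation (pS or pN >= 0.75); Ks = 0 yields ratio = NaN.
    """
    if method not in ("NG86", "YN00"):
        raise ValueError(f"unknown method {method!r}")
    codon_pairs = _usable_codon_pairs(pair)
    if not codon_pairs:
        raise ValueError("no usable codon columns")

    if method == "NG86":
        S = sum(_ng86_codon_sites(c1) + _ng86_codon_sites(c2)
                for c1, c2 in codon_pairs) / 2.0
    else:
        kappa = _estimate_kappa(codon_pairs)
        pi = C.f3x4_frequencies([c for p in codon_pairs for c in p])
        S = sum(_weighted_codon_sites(c1, kappa, pi) + _weighted_codon_sites(c2, kappa, pi)
                for c1, c2 in codon_pairs) / 2.0
    n_codons = len(codon_pairs)
    N = 3.0 * n_codons - S
    Sd = Nd = 0.0
    for c1, c2 in codon_pairs:
        sd, nd = _ng86_codon_diffs(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    ks = _jc_correct(pS)
    ka = _jc_correct(pN)
    ratio = ka / ks if ks > 0 else NAN
    return KaKsResult(ka=ka, ks=ks, ratio=ratio, S=S, N=N, Sd=Sd, Nd=Nd,
                      method=method, n_codons=n_codons)


# ---------------------------------------------------------------------------
# sitewise likelihood-ratio scan

@dataclass
class SitewiseResult:
    site: int                  # 1-based codon column
    omega_hat: float
    lnl_hat: float
    lnl_neutral: float
    lrt_stat: float
    p_value: float
    classification: str        # purifying | neutral | positive
    tested: bool = True


@dataclass
class _TreeShape:
    """Flattened rooted tree: postorder nodes, tips first in alignment order."""
    postorder: list[int]
    children: dict[int, list[int]]
    lengths: np.ndarray
    tip_of: dict[str, int]
    root: int


def _flatten_tree(tree: dendropy.Tree, ids: list[str]) -> _TreeShape:
    nodes = list(tree.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    children = {}
    lengths = np.zeros(len(nodes))
    tip_of = {}
    have_lengths = False
    for n in nodes:
        i = idx[id(n)]
        children[i] = [idx[id(c)] for c in n.child_nodes()]
        if n.edge.length is not None:
            have_lengths = True
            lengths[i] = max(float(n.edge.length), 1e-8)
        else:
            lengths[i] = 1.0
        if n.is_leaf():
            tip_of[n.taxon.label] = i
    missing = set(ids) - set(tip_of)
    if missing:
        raise KeyError(f"tree lacks taxa {sorted(missing)}")
    if not have_lengths:
        lengths[:] = 0.1
    return _TreeShape(postorder=list(range(len(nodes))), children=children,
                      lengths=lengths, tip_of=tip_of, root=idx[id(nodes[-1])])


def _encode_alignment(aln: CodonAlignment) -> np.ndarray:
    """(n_seqs, n_sites) codon indices, -1 for gap/ambiguous codons."""
    enc = np.full((len(aln.ids), aln.n_codons), -1, dtype=np.int64)
    for r in range(len(aln.ids)):
        for s in range(aln.n_codons):
            enc[r, s] = C.CODON_INDEX.get(aln.codon(r, s), -1)
    return enc


def _site_loglikes(enc, shape, ids, kappa, scale, omegas, pi):
    """Per-site log-likelihoods; ``omegas`` is one value per site (or scalar)."""
    n_sites = enc.shape[1]
    omegas = np.broadcast_to(np.asarray(omegas, dtype=float), (n_sites,))
    uniq = np.unique(omegas)
    lnl = np.zeros(n_sites)
    for w in uniq:
        mask = omegas == w
        cols = np.nonzero(mask)[0]
        Q = C.rate_matrix(kappa, w, pi, scale="neutral")
        P = C.transition_probabilities(Q, pi, shape.lengths * scale)
        partial = {}
        logscale = np.zeros(len(cols))
        for node in shape.postorder:
            kids = shape.children[node]
            if not kids:
                continue
            acc = np.ones((len(cols), 61))
            for k in kids:
                if not shape.children[k]:  # tip
                    label_idx = None
                    for lab, i in shape.tip_of.items():
                        if i == k:
                            label_idx = ids.index(lab)
                            break
                    states = enc[label_idx, cols]
                    M = np.where(states[:, None] >= 0,
                                 P[k][:, np.clip(states, 0, None)].T,
                                 1.0)
                else:
                    M = partial[k] @ P[k].T
                acc *= M
            mx = acc.max(axis=1, keepdims=True)
            mx[mx == 0] = 1.0
            partial[node] = acc / mx
            logscale += np.log(mx[:, 0])
        root_like = (partial[shape.root] * pi).sum(axis=1)
        lnl[cols] = np.log(np.maximum(root_like, 1e-300)) + logscale
    return lnl


@dataclass
class CodonModelFit:
    kappa: float
    scale: float
    omega: float
    lnl: float


def fit_global_codon_model(aln: CodonAlignment, tree: dendropy.Tree,
                           pi: np.ndarray | None = None) -> CodonModelFit:
    """Maximise the single-omega codon-model likelihood over (kappa, branch
    scale, omega) by Nelder–Mead on log parameters."""
    if len(aln.ids) < 3:
        raise ValueError("sitewise analysis needs >= 3 sequences")
    if pi is None:
        pi = np.full(61, 1.0 / 61)
    shape = _flatten_tree(tree, aln.ids)
    enc = _encode_alignment(aln)

    def neg(params):
        kappa, scale, omega = np.exp(params)
        if not np.isfinite(kappa + scale + omega):
            return 1e10
        lnl = _site_loglikes(enc, shape, aln.ids, kappa, scale, omega, pi).sum()
        if not np.isfinite(lnl):
            raise FloatingPointError("non-finite likelihood")
        return -lnl

    res = optimize.minimize(neg, x0=np.log([2.0, 1.0, 0.5]), method="Nelder-Mead",
                            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400})
    kappa, scale, omega = np.exp(res.x)
    return CodonModelFit(kappa=float(kappa), scale=float(scale),
                         omega=float(omega), lnl=float(-res.fun))


OMEGA_MAX = 50.0
# coarse profile over [0, 50]: evaluated for every site in one vectorised
# pass, then refined per site by bounded search between grid neighbours
_OMEGA_GRID = np.unique(np.concatenate([
    [1e-6], np.geomspace(0.02, OMEGA_MAX, 23), [1.0]]))


def sitewise_selection_scan(aln: CodonAlignment, tree: dendropy.Tree,
                            alpha: float = 0.05,
                            fit: CodonModelFit | None = None) -> list[SitewiseResult]:
    """Per-codon-site omega estimates and likelihood-ratio classification.

    The global stage estimates kappa and a branch-length scale (with a single
    omega) once; each site's likelihood is then maximised over omega in
    [0, 50] (coarse grid, then bounded refinement to |d omega| tolerance
    1e-4) and compared with omega = 1 via chi-square(1).
    """
    pi = np.full(61, 1.0 / 61)
    if fit is None:
        fit = fit_global_codon_model(aln, tree, pi)
    shape = _flatten_tree(tree, aln.ids)
    enc = _encode_alignment(aln)
    ids = aln.ids
    n_sites = aln.n_codons

    grid_lnl = np.vstack([
        _site_loglikes(enc, shape, ids, fit.kappa, fit.scale, w, pi)
        for w in _OMEGA_GRID])
    i_neutral = int(np.nonzero(_OMEGA_GRID == 1.0)[0][0])
    lnl_neutral = grid_lnl[i_neutral]

    results = []
    for s in range(n_sites):
        if (enc[:, s] < 0).all():
            results.append(SitewiseResult(site=s + 1, omega_hat=NAN, lnl_hat=NAN,
                                          lnl_neutral=NAN, lrt_stat=NAN,
                                          p_value=NAN, classification="neutral",
                                          tested=False))
            continue
        col = enc[:, s:s + 1]

        def neg(w):
            return -_site_loglikes(col, shape, ids, fit.kappa, fit.scale,
                                   max(w, 0.0), pi)[0]

        i_best = int(np.argmax(grid_lnl[:, s]))
        lo = _OMEGA_GRID[max(0, i_best - 1)]
        hi = _OMEGA_GRID[min(len(_OMEGA_GRID) - 1, i_best + 1)]
        best_w = float(_OMEGA_GRID[i_best])
        best_f = -float(grid_lnl[i_best, s])
        if hi > lo:
            r = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                         options={"xatol": 1e-4})
            if r.fun < best_f - 1e-12:
                best_w, best_f = float(r.x), float(r.fun)
        lnl_hat = -best_f
        lrt = max(0.0, 2.0 * (lnl_hat - lnl_neutral[s]))
        p = float(stats.chi2.sf(lrt, df=1))
        if p < alpha and best_w > 1.0:
            cls = "positive"
        elif p < alpha and best_w < 1.0:
            cls = "purifying"
        else:
            cls = "neutral"
        results.append(SitewiseResult(site=s + 1, omega_hat=best_w,
                                      lnl_hat=lnl_hat,
                                      lnl_neutral=float(lnl_neutral[s]),
                                      lrt_stat=lrt, p_value=p,
                                      classification=cls))
    return results
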