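"""Expansion-mechanism classification: tandem arrays, collinear (segmental)
blocks, TE-mediated copies, and retrogenes.

Tandem criteria (all four must hold for a pair): aligned region covers >= 30 %
of the query (shorter) protein at E < 0.01 under BLOSUM62 local alignment;
identity >= 70 %; <= 10 intervening genes; within the genome-class distance
window (100 kb compact / 350 kb standard). Qualifying pairs are merged into
arrays by single linkage. Segmental duplication is a chain of >= 5 collinear
anchor pairs found by DAG dynamic programming within 50 kb flanks of the
target genes. Retrogenes are single-exon members whose best multi-exon family
paralog passes identity >= 50 % and coverage >= 0.7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import GeneModel, GenomeAnnotation

logger = logging.getLogger("genefam")

# gapped BLOSUM62 (open 11 / extend 1) Karlin-Altschul constants
_KA_LAMBDA = 0.267
_KA_K = 0.041

TANDEM_MIN_COVERAGE = 0.30
TANDEM_MIN_IDENTITY = 70.0
TANDEM_MAX_INTERVENING = 10
TANDEM_MAX_E = 0.01

BLOCK_MIN_PAIRS = 5
BLOCK_GAP_PENALTY = 1.0
BLOCK_MAX_GAP = 10
SEGMENTAL_FLANK_BP = 50_000

RETRO_MIN_IDENTITY = 50.0
RETRO_MIN_COVERAGE = 0.7


@dataclass
class SimilarityPair:
    query_id: str
    subject_id: str
    identity: float          # % identical positions over aligned columns
    query_coverage: float    # aligned query span / query length
    aln_len: int
    score: float
    e_value: float


@dataclass
class TandemArray:
    chromosome: str
    member_ids: list[str]            # ordered by start coordinate
    genome_class: str
    evidence: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str, float]]
    chain_score: float
    orientation: int                 # +1 collinear, -1 inverted
    span_a: tuple[int, int] = (0, 0)
    span_b: tuple[int, int] = (0, 0)

    @property
    def n_pairs(self) -> int:
        return len(self.anchors)


@dataclass
class RetrogeneCall:
    retro_id: str
    parent_id: str
    identity: float
    coverage: float
    introns_lost: int


_MATRIX = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(str(_MATRIX.alphabet))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _MATRIX
    # BLAST convention: a gap of length k costs 11 + k
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def local_align_proteins(a: str, b: str, query_id: str = "a",
                         subject_id: str = "b") -> SimilarityPair:
    """Smith–Waterman local alignment under BLOSUM62 with affine gaps (11/1).

    Identity and coverage are read off the optimal traceback; the E-value is
    the Karlin–Altschul estimate ``K*m*n*exp(-lambda*S)`` with the standard
    gapped BLOSUM62 constants.
    """
    if not a or not b:
        raise ValueError("empty protein sequence")
    for name, s in ((query_id, a), (subject_id, b)):
        bad = set(s.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"{name}: non-amino-acid characters {sorted(bad)}")
    a, b = a.upper(), b.upper()
    alignments = _ALIGNER.align(a, b)
    aln = alignments[0]
    counts = aln.counts()
    cols = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / cols if cols else 0.0
    # coverage counts aligned (non-gap) query residues, the sum of the
    # aligned-region lengths on the query
    aligned_residues = int(sum(e - s for s, e in aln.aligned[0]))
    import math
    e_value = _KA_K * len(a) * len(b) * math.exp(-_KA_LAMBDA * aln.score)
    return SimilarityPair(
        query_id=query_id, subject_id=subject_id,
        identity=identity, query_coverage=aligned_residues / len(a),
        aln_len=int(cols), score=float(aln.score), e_value=e_value,
    )


def _pair_distance_bp(g1: GeneModel, g2: GeneModel) -> int:
    """Gap between gene bodies in bp (0 when they overlap)."""
    lo, hi = (g1, g2) if g1.start <= g2.start else (g2, g1)
    return max(0, hi.start - lo.end)


def tandem_pair_qualifies(g1: GeneModel, g2: GeneModel, window_bp: int,
                          pair: SimilarityPair | None = None) -> bool:
    """Apply the four tandem criteria to one within-chromosome gene pair.

    ``pair`` must be the alignment with the *shorter* protein as query;
    it is computed on demand when omitted.
    """
    if g1.chromosome != g2.chromosome:
        return False
    if abs(g1.rank - g2.rank) - 1 > TANDEM_MAX_INTERVENING:
        return False
    if _pair_distance_bp(g1, g2) > window_bp:
        return False
    if pair is None:
        short, long_ = sorted((g1, g2), key=lambda g: len(g.protein_seq))
        pair = local_align_proteins(short.protein_seq, long_.protein_seq,
                                    short.gene_id, long_.gene_id)
    return (pair.e_value < TANDEM_MAX_E
            and pair.query_coverage >= TANDEM_MIN_COVERAGE
            and pair.identity >= TANDEM_MIN_IDENTITY)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def detect_tandem_arrays(family_genes: list[str], annotation: GenomeAnnotation,
                         window_bp: int | None = None) -> list[TandemArray]:
    """Find tandem arrays among one family's genes by single-linkage closure
    over pairs satisfying all four tandem criteria."""
    window = window_bp if window_bp is not None else annotation.tandem_window_bp
    genes = []
    for gid in sorted(set(family_genes)):
        g = annotation.genes.get(gid)
        if g is None:
            raise KeyError(f"unknown gene {gid}")
        if not g.protein_seq:
            logger.warning("tandem scan: gene %s has no protein; excluded", gid)
            continue
        genes.append(g)

    uf = _UnionFind([g.gene_id for g in genes])
    evidence: dict[str, list[tuple[str, str]]] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.start)
        for i, g1 in enumerate(chrom_genes):
            for g2 in chrom_genes[i + 1:]:
                if tandem_pair_qualifies(g1, g2, window):
                    uf.union(g1.gene_id, g2.gene_id)
                    evidence.setdefault(uf.find(g1.gene_id), []).append(
                        (g1.gene_id, g2.gene_id))

    clusters: dict[str, list[GeneModel]] = {}
    for g in genes:
        clusters.setdefault(uf.find(g.gene_id), []).append(g)
    arrays = []
    for root in sorted(clusters):
        members = sorted(clusters[root], key=lambda g: g.start)
        if len(members) < 2:
            continue
        pairs = sorted({p for r, ev in evidence.items()
                        if uf.find(r) == uf.find(root) for p in ev})
        arrays.append(TandemArray(
            chromosome=members[0].chromosome,
            member_ids=[g.gene_id for g in members],
            genome_class=annotation.genome_class,
            evidence=pairs,
        ))
    arrays.sort(key=lambda a: (a.chromosome, a.member_ids[0]))
    return arrays


def chain_collinear_blocks(
    anchor_pairs: list[tuple[str, str, float]],
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation,
    min_pairs: int = BLOCK_MIN_PAIRS,
    gap_penalty: float = BLOCK_GAP_PENALTY,
    max_gap: int = BLOCK_MAX_GAP,
) -> list[CollinearBlock]:
    """Chain homologous anchor pairs into collinear blocks by DAG dynamic
    programming over gene ranks.

    Chain score = sum of anchor scores − ``gap_penalty`` × skipped rank
    units; consecutive anchors must advance strictly on both chromosomes
    (descending on b for inverted blocks) with rank gaps <= ``max_gap``.
    Maximal chains are extracted best-first; chains with fewer than
    ``min_pairs`` anchors are not reported.
    """
    for ga, gb, _ in anchor_pairs:
        if ga not in annotation_a.genes:
            raise KeyError(f"anchor references unknown gene {ga}")
        if gb not in annotation_b.genes:
            raise KeyError(f"anchor references unknown gene {gb}")

    anchors = [(annotation_a.genes[ga].rank, annotation_b.genes[gb].rank,
                annotation_a.genes[ga].chromosome, annotation_b.genes[gb].chromosome,
                ga, gb, float(sc))
               for ga, gb, sc in anchor_pairs]
    blocks: list[CollinearBlock] = []
    groups: dict[tuple[str, str], list] = {}
    for a in anchors:
        groups.setdefault((a[2], a[3]), []).append(a)

    for (ca, cb), group in sorted(groups.items()):
        remaining = sorted(group, key=lambda a: (a[0], a[1], a[4], a[5]))
        while True:
            best_chain = _best_chain(remaining, gap_penalty, max_gap)
            if best_chain is None or len(best_chain[1]) < min_pairs:
                break
            score, chain, orient = best_chain
            chain_set = {(a[4], a[5]) for a in chain}
            remaining = [a for a in remaining if (a[4], a[5]) not in chain_set]
            blocks.append(_make_block(ca, cb, chain, score, orient,
                                      annotation_a, annotation_b))
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, -b.chain_score))
    return blocks


def _best_chain(anchors, gap_penalty, max_gap):
    """Highest-scoring chain over anchors, trying both orientations."""
    best = None
    for orient in (1, -1):
        n = len(anchors)
        if n == 0:
            break
        order = sorted(range(n), key=lambda i: (anchors[i][0], orient * anchors[i][1]))
        dp = [anchors[i][6] for i in order]
        back = [-1] * n
        for xi in range(n):
            i = order[xi]
            ra_i, rb_i = anchors[i][0], anchors[i][1]
            for xj in range(xi):
                j = order[xj]
                ra_j, rb_j = anchors[j][0], anchors[j][1]
                ga = ra_i - ra_j - 1
                gb = orient * (rb_i - rb_j) - 1
                if ga < 0 or gb < 0 or ga > max_gap or gb > max_gap:
                    continue
                cand = dp[xj] + anchors[i][6] - gap_penalty * (ga + gb)
                if cand > dp[xi]:
                    dp[xi] = cand
                    back[xi] = xj
        xi = max(range(n), key=lambda x: dp[x])
        chain_idx = []
        x = xi
        while x != -1:
            chain_idx.append(order[x])
            x = back[x]
        chain = [anchors[i] for i in reversed(chain_idx)]
        cand = (dp[xi], chain, orient)
        if best is None or cand[0] > best[0] or (cand[0] == best[0] and len(cand[1]) > len(best[1])):
            best = cand
    return best


def _make_block(ca, cb, chain, score, orient, ann_a, ann_b) -> CollinearBlock:
    genes_a = [ann_a.genes[a[4]] for a in chain]
    genes_b = [ann_b.genes[a[5]] for a in chain]
    return CollinearBlock(
        chrom_a=ca, chrom_b=cb,
        anchors=[(a[4], a[5], a[6]) for a in chain],
        chain_score=score, orientation=orient,
        span_a=(min(g.start for g in genes_a), max(g.end for g in genes_a)),
        span_b=(min(g.start for g in genes_b), max(g.end for g in genes_b)),
    )


def classify_segmental(family_genes: list[str], blocks: list[CollinearBlock],
                       annotation: GenomeAnnotation,
                       flank_bp: int = SEGMENTAL_FLANK_BP) -> list[str]:
    """Genes that are anchors of a reported block, or lie inside a block's
    anchor span extended by ``flank_bp``, on either block chromosome."""
    out = []
    for gid in sorted(set(family_genes)):
        g = annotation.genes.get(gid)
        if g is None:
            continue
        hit = False
        for b in blocks:
            if any(gid in (ga, gb) for ga, gb, _ in b.anchors):
                hit = True
                break
            for chrom, (lo, hi) in ((b.chrom_a, b.span_a), (b.chrom_b, b.span_b)):
                if (g.chromosome == chrom and g.start <= hi + flank_bp
                        and g.end >= lo - flank_bp):
                    hit = True
                    break
            if hit:
                break
        if hit:
            out.append(gid)
    return out


def detect_retrogenes(family_genes: list[str], annotation: GenomeAnnotation,
                      min_identity: float = RETRO_MIN_IDENTITY,
                      min_coverage: float = RETRO_MIN_COVERAGE) -> list[RetrogeneCall]:
    """Single-exon family members whose best multi-exon family paralog passes
    the identity/coverage thresholds; introns_lost = parent exon count − 1."""
    genes = [annotation.genes[g] for g in sorted(set(family_genes))
             if g in annotation.genes and annotation.genes[g].protein_seq]
    singles = [g for g in genes if g.n_exons == 1]
    multis = [g for g in genes if g.n_exons >= 2]
    calls = []
    for s in singles:
        best = None
        for m in multis:
            pair = local_align_proteins(s.protein_seq, m.protein_seq,
                                        s.gene_id, m.gene_id)
            if pair.identity >= min_identity and pair.query_coverage >= min_coverage:
                key = (pair.identity, pair.query_coverage, m.gene_id)
                if best is None or key > best[0]:
                    best = (key, m, pair)
        if best is not None:
            _, parent, pair = best
            calls.append(RetrogeneCall(
                retro_id=s.gene_id, parent_id=parent.gene_id,
                identity=pair.identity, coverage=pair.query_coverage,
                introns_lost=parent.n_exons - 1,
            ))
    return calls


def summarize_mechanisms(
    family_by_gene: dict[str, str],
    tandem_arrays: list[TandemArray] = (),
    segmental_genes: list[str] = (),
    te_genes: list[str] = (),
    retro_calls: list[RetrogeneCall] = (),
) -> pd.DataFrame:
    """Per-gene mechanism label sets plus per-family counts and percentages.

    Labels are multi-valued: a gene may be, e.g., both TE-carried and inside
    a segmental block. Returns a tidy frame with one row per gene and the
    family-level summary available via :func:`mechanism_percentages`.
    """
    tandem_genes = {m for arr in tandem_arrays for m in arr.member_ids}
    seg = set(segmental_genes)
    te = set(te_genes)
    retro = {c.retro_id for c in retro_calls}
    rows = []
    for gid in sorted(family_by_gene):
        labels = sorted(
            lab for lab, members in (("tandem", tandem_genes), ("segmental", seg),
                                     ("TE", te), ("retrogene", retro))
            if gid in members
        )
        rows.append({"gene_id": gid, "family": family_by_gene[gid],
                     "mechanisms": ",".join(labels) if labels else "none"})
    return pd.DataFrame(rows, columns=["gene_id", "family", "mechanisms"])


def mechanism_percentages(summary: pd.DataFrame) -> pd.DataFrame:
    """Per family: count and percentage of genes carrying each mechanism label."""
    rows = []
    for family, grp in summary.groupby("family"):
        n = len(grp)
        for mech in ("tandem", "segmental", "TE", "retrogene", "none"):
            count = int(grp["mechanisms"].str.split(",").apply(lambda ls: mech in ls).sum())
            rows.append({"family": family, "mechanism": mech, "count": count,
                         "n_genes": n, "percent": 100.0 * count / n if n else 0.0})
    return pd.DataFrame(rows, columns=["family", "mechanism", "count", "n_genes", "percent"])
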