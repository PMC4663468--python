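import itertools
import random
from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from genefam import dupmech
from genefam.dupmech import (chain_collinear_blocks, classify_segmental,
                             detect_retrogenes, detect_tandem_arrays,
                             local_align_proteins, mechanism_percentages,
                             summarize_mechanisms, tandem_pair_qualifies)
from genefam.formats_io import GeneModel, GenomeAnnotation

AAS = "ACDEFGHIKLMNPQRSTVWY"
_B62 = substitution_matrices.load("BLOSUM62")


def rand_prot(rng, n):
    return "".join(rng.choice(AAS) for _ in range(n))


class TestLocalAlign:
    def test_self_alignment_is_perfect(self, rng):
        p = rand_prot(random.Random(0), 80)
        pair = local_align_proteins(p, p)
        assert pair.identity == 100.0
        assert pair.query_coverage == pytest.approx(1.0)

    def test_reversed_decoy_never_passes_the_pair_criteria(self):
        # an optimal local aligner does stitch weak islands between a random
        # protein and its reversal, so coverage alone is not the
        # discriminator; the identity rule (and usually the E-value) is
        pyrng = random.Random(1)
        coverages = []
        for _ in range(20):
            p = rand_prot(pyrng, 200)
            pair = local_align_proteins(p, p[::-1])
            coverages.append(pair.query_coverage)
            assert pair.identity < 70.0
        assert np.median(coverages) < 0.3

    def test_non_amino_acid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            local_align_proteins("MK1V", "MKV")

    def test_optimal_score_matches_exhaustive_enumeration(self):
        """Smith-Waterman score equals brute-force search over all local
        alignments with affine gaps (gap of length k costs 12 + (k-1))."""

        def brute_force_local(a, b):
            # best over all substring pairs of the best global alignment,
            # via memoised affine-gap recursion (states: M, gap-in-a, gap-in-b)
            @lru_cache(maxsize=None)
            def glob(i, j, li, lj, state):
                # best score aligning a[i:li] with b[j:lj], entering in `state`
                if i == li and j == lj:
                    return 0.0
                best = -1e9
                if i < li and j < lj:
                    s = _B62[a[i], b[j]] + glob(i + 1, j + 1, li, lj, "M")
                    best = max(best, s)
                if i < li:
                    cost = -12.0 if state != "A" else -1.0
                    best = max(best, cost + glob(i + 1, j, li, lj, "A"))
                if j < lj:
                    cost = -12.0 if state != "B" else -1.0
                    best = max(best, cost + glob(i, j + 1, li, lj, "B"))
                return best

            best = 0.0
            n, m = len(a), len(b)
            for i in range(n):
                for li in range(i + 1, n + 1):
                    for j in range(m):
                        for lj in range(j + 1, m + 1):
                            best = max(best, glob(i, j, li, lj, "M"))
            return best

        pyrng = random.Random(7)
        for _ in range(5):
            a, b = rand_prot(pyrng, 6), rand_prot(pyrng, 6)
            pair = local_align_proteins(a, b)
            assert pair.score == pytest.approx(brute_force_local(a, b))


def _toy_annotation(positions, proteins, chrom="chr1", length=10_000_000,
                    genome_class="compact", exon_counts=None):
    genes = {}
    for i, ((start, end), prot) in enumerate(zip(positions, proteins)):
        gid = f"g{i}"
        n_ex = (exon_counts or {}).get(gid, 1)
        exons = [(start, end)] if n_ex == 1 else [
            (start + k * 10, start + k * 10 + 4) for k in range(n_ex)]
        genes[gid] = GeneModel(gene_id=gid, chromosome=chrom, strand="+",
                               start=start, end=end, exons=exons,
                               protein_seq=prot)
    return GenomeAnnotation(genes=genes, chrom_lengths={chrom: length},
                            genome_class=genome_class)


def _mutate(prot, k, rng):
    """Substitute exactly k interior positions with different residues."""
    chars = list(prot)
    idx = rng.sample(range(1, len(prot) - 1), k)
    for i in idx:
        chars[i] = rng.choice([c for c in AAS if c != chars[i]])
    return "".join(chars)


class TestTandemCriteria:
    """The four tandem rules exercised at their decision boundaries."""

    @pytest.fixture(scope="class")
    def base_protein(self):
        return rand_prot(random.Random(42), 1000)

    def _pair_genes(self, prot_a, prot_b, gap_bp=50_000, intervening=3,
                    genome_class="compact"):
        positions = [(1000, 1500)]
        # intervening filler genes between the pair
        for k in range(intervening):
            positions.append((2000 + k * 100, 2050 + k * 100))
        start_b = 1500 + gap_bp
        positions.append((start_b, start_b + 500))
        prots = [prot_a] + [rand_prot(random.Random(k), 60) for k in range(intervening)] + [prot_b]
        ann = _toy_annotation(positions, prots, genome_class=genome_class)
        g1, g2 = ann.genes["g0"], ann.genes[f"g{len(positions) - 1}"]
        return g1, g2, ann

    @pytest.mark.parametrize("n_sub,expected", [(300, True), (301, False)])
    def test_identity_boundary_70_percent(self, base_protein, n_sub, expected):
        variant = _mutate(base_protein, n_sub, random.Random(1))
        g1, g2, ann = self._pair_genes(base_protein, variant)
        pair = local_align_proteins(base_protein, variant)
        assert (pair.identity >= 70.0) == expected
        assert tandem_pair_qualifies(g1, g2, ann.tandem_window_bp) == expected

    @pytest.mark.parametrize("frag_len,expected", [(300, True), (299, False)])
    def test_coverage_boundary_30_percent(self, base_protein, frag_len, expected):
        subject = base_protein[350:350 + frag_len]
        pair = local_align_proteins(base_protein, subject)
        assert pair.query_coverage == pytest.approx(frag_len / 1000)
        assert (pair.query_coverage >= 0.30) == expected

    @pytest.mark.parametrize("intervening,expected", [(10, True), (11, False)])
    def test_intervening_gene_boundary(self, base_protein, intervening, expected):
        g1, g2, ann = self._pair_genes(base_protein, base_protein,
                                       intervening=intervening)
        assert abs(g1.rank - g2.rank) - 1 == intervening
        assert tandem_pair_qualifies(g1, g2, ann.tandem_window_bp) == expected

    @pytest.mark.parametrize("genome_class,window", [("compact", 100_000),
                                                     ("standard", 350_000)])
    @pytest.mark.parametrize("delta,expected", [(0, True), (1, False)])
    def test_distance_window_boundaries(self, base_protein, genome_class,
                                        window, delta, expected):
        g1, g2, ann = self._pair_genes(base_protein, base_protein,
                                       gap_bp=window + delta,
                                       genome_class=genome_class)
        assert tandem_pair_qualifies(g1, g2, ann.tandem_window_bp) == expected


class TestTandemArrays:
    def test_single_linkage_closure(self):
        rng = random.Random(3)
        base = rand_prot(rng, 400)
        near = _mutate(base, 60, rng)     # ~85% identity to base
        far = _mutate(near, 60, rng)      # qualifies with near, maybe not base
        ann = _toy_annotation([(1000, 1400), (10_000, 10_400), (20_000, 20_400)],
                              [base, near, far])
        arrays = detect_tandem_arrays(["g0", "g1", "g2"], ann)
        assert len(arrays) == 1
        assert arrays[0].member_ids == ["g0", "g1", "g2"]

    @settings(derandomize=True, max_examples=10)
    @given(st.permutations(["g0", "g1", "g2"]))
    def test_invariant_to_input_gene_order(self, order):
        rng = random.Random(3)
        base = rand_prot(rng, 400)
        ann = _toy_annotation([(1000, 1400), (10_000, 10_400), (500_000, 500_400)],
                              [base, _mutate(base, 40, rng), _mutate(base, 45, rng)])
        ref = detect_tandem_arrays(["g0", "g1", "g2"], ann)
        out = detect_tandem_arrays(list(order), ann)
        assert [a.member_ids for a in out] == [a.member_ids for a in ref]

    def test_arrays_partition_members(self, annotation, small_dataset):
        fam = sorted(small_dataset["truth"].genes)
        arrays = detect_tandem_arrays(fam, annotation)
        seen = [m for a in arrays for m in a.member_ids]
        assert len(seen) == len(set(seen))


def _rank_annotation(ranks, chrom):
    genes = {}
    n = 0
    for gid, r in ranks.items():
        genes[gid] = GeneModel(gene_id=gid, chromosome=chrom, strand="+",
                               start=r * 1000, end=r * 1000 + 10)
        n = max(n, r)
    for r in range(1, n + 1):
        if r not in ranks.values():
            genes[f"fill{chrom}{r}"] = GeneModel(gene_id=f"fill{chrom}{r}",
                                                 chromosome=chrom, strand="+",
                                                 start=r * 1000, end=r * 1000 + 10)
    return GenomeAnnotation(genes=genes, chrom_lengths={chrom: 10_000_000})


class TestCollinearChaining:
    def _instance(self, ranks_a, ranks_b, scores):
        ann_a = _rank_annotation({f"a{i}": r for i, r in enumerate(ranks_a)}, "cA")
        ann_b = _rank_annotation({f"b{i}": r for i, r in enumerate(ranks_b)}, "cB")
        anchors = [(f"a{i}", f"b{i}", s) for i, s in enumerate(scores)]
        return anchors, ann_a, ann_b

    def test_five_collinear_anchors_form_one_block(self):
        anchors, a, b = self._instance(range(1, 6), range(1, 6), [10] * 5)
        blocks = chain_collinear_blocks(anchors, a, b)
        assert len(blocks) == 1 and blocks[0].n_pairs == 5

    def test_four_anchors_are_not_reported(self):
        anchors, a, b = self._instance(range(1, 5), range(1, 5), [10] * 4)
        assert chain_collinear_blocks(anchors, a, b) == []

    def test_inverted_blocks_are_chained(self):
        anchors, a, b = self._instance(range(1, 7), range(6, 0, -1), [10] * 6)
        blocks = chain_collinear_blocks(anchors, a, b)
        assert blocks and blocks[0].n_pairs == 6 and blocks[0].orientation == -1

    def test_unknown_anchor_gene_rejected(self):
        anchors, a, b = self._instance(range(1, 6), range(1, 6), [10] * 5)
        with pytest.raises(KeyError):
            chain_collinear_blocks(anchors + [("nope", "b0", 1.0)], a, b)

    def test_dp_matches_exhaustive_chain_search(self):
        """Best chain score equals brute force over all ordered anchor
        subsets, both orientations, on instances with <= 8 anchors."""

        def oracle(anchors, gap_penalty=1.0, max_gap=10):
            best = 0.0
            for r in range(1, len(anchors) + 1):
                for sub in itertools.permutations(range(len(anchors)), r):
                    for orient in (1, -1):
                        sc, ok = 0.0, True
                        for k, idx in enumerate(sub):
                            ra, rb, s = anchors[idx]
                            sc += s
                            if k:
                                pa, pb, _ = anchors[sub[k - 1]]
                                ga = ra - pa - 1
                                gb = orient * (rb - pb) - 1
                                if ga < 0 or gb < 0 or ga > max_gap or gb > max_gap:
                                    ok = False
                                    break
                                sc -= gap_penalty * (ga + gb)
                        if ok:
                            best = max(best, sc)
            return best

        nprng = np.random.default_rng(0)
        for _ in range(100):
            n = int(nprng.integers(1, 9))
            ra = (nprng.permutation(18)[:n] + 1).tolist()
            rb = (nprng.permutation(18)[:n] + 1).tolist()
            sc = nprng.uniform(1, 10, n).round(3).tolist()
            anchors, a, b = self._instance(ra, rb, sc)
            blocks = chain_collinear_blocks(anchors, a, b, min_pairs=1)
            got = max(bl.chain_score for bl in blocks)
            ranks = list(zip(ra, rb, sc))
            assert got == pytest.approx(oracle(ranks))


class TestClassifySegmental:
    def test_anchor_gene_is_segmental_and_outside_gene_is_not(self):
        ann_a = _rank_annotation({f"a{i}": i + 1 for i in range(5)}, "cA")
        ann_b = _rank_annotation({f"b{i}": i + 1 for i in range(5)}, "cB")
        anchors = [(f"a{i}", f"b{i}", 10.0) for i in range(5)]
        merged = GenomeAnnotation(
            genes={**ann_a.genes, **ann_b.genes,
                   "far": GeneModel(gene_id="far", chromosome="cA", strand="+",
                                    start=9_000_000, end=9_000_100)},
            chrom_lengths={"cA": 10_000_000, "cB": 10_000_000})
        blocks = chain_collinear_blocks(anchors, merged, merged)
        out = classify_segmental(["a0", "far"], blocks, merged)
        assert out == ["a0"]

    def test_no_blocks_gives_empty_list(self, annotation):
        assert classify_segmental(["A_g001"], [], annotation) == []


class TestRetrogenes:
    def test_single_exon_copy_of_multi_exon_parent_called(self):
        rng = random.Random(5)
        parent = rand_prot(rng, 300)
        retro = _mutate(parent, 30, rng)  # 90% identity
        ann = _toy_annotation([(1000, 5000), (100_000, 101_000)],
                              [parent, retro],
                              exon_counts={"g0": 5, "g1": 1})
        calls = detect_retrogenes(["g0", "g1"], ann)
        assert len(calls) == 1
        assert (calls[0].retro_id, calls[0].parent_id) == ("g1", "g0")
        assert calls[0].introns_lost == 4

    def test_multi_exon_gene_never_a_candidate(self):
        rng = random.Random(6)
        p = rand_prot(rng, 300)
        ann = _toy_annotation([(1000, 5000), (100_000, 104_000)], [p, p],
                              exon_counts={"g0": 5, "g1": 3})
        assert detect_retrogenes(["g0", "g1"], ann) == []

    def test_single_exon_gene_without_similar_parent_not_called(self):
        rng = random.Random(7)
        ann = _toy_annotation([(1000, 5000), (100_000, 101_000)],
                              [rand_prot(rng, 300), rand_prot(rng, 300)],
                              exon_counts={"g0": 5, "g1": 1})
        assert detect_retrogenes(["g0", "g1"], ann) == []


class TestMechanismSummary:
    def test_multi_valued_labels(self):
        from genefam.dupmech import RetrogeneCall, TandemArray

        arrays = [TandemArray(chromosome="c", member_ids=["g1", "g2"],
                              genome_class="standard")]
        summary = summarize_mechanisms(
            {"g1": "SuSy", "g2": "SuSy", "g3": "SuSy"},
            tandem_arrays=arrays, segmental_genes=["g2"], te_genes=["g2"],
            retro_calls=[RetrogeneCall("g3", "g1", 90.0, 0.9, 3)])
        by_gene = dict(zip(summary["gene_id"], summary["mechanisms"]))
        assert by_gene["g1"] == "tandem"
        assert by_gene["g2"] == "TE,segmental,tandem"
        assert by_gene["g3"] == "retrogene"
        pct = mechanism_percentages(summary)
        tandem_pct = pct[(pct.family == "SuSy") & (pct.mechanism == "tandem")]
        assert tandem_pct["percent"].iloc[0] == pytest.approx(100 * 2 / 3)
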