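import itertools
import math
import random

import dendropy
import numpy as np
import pytest
from Bio.Seq import Seq

from genefam import codons as C
from genefam.selection import (CodonAlignment, backtranslate,
                               filter_pair_alignment, fit_global_codon_model,
                               kaks_pair, sitewise_selection_scan,
                               _encode_alignment, _flatten_tree, _site_loglikes)
from genefam.simulate import evolve_alignment

SENSE = list(C.SENSE_CODONS)
STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# independent NG86 oracle (Biopython translation, explicit enumeration)

def oracle_codon_sites(codon):
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for n in "ACGT":
            if n == codon[pos]:
                continue
            alt = codon[:pos] + n + codon[pos + 1:]
            if alt in STOPS:
                continue
            valid += 1
            syn += str(Seq(alt).translate()) == str(Seq(codon).translate())
        if valid:
            total += syn / valid
    return total


def oracle_codon_diffs(c1, c2):
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOPS:
                ok = False
                break
            if str(Seq(nxt).translate()) == str(Seq(cur).translate()):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def random_codon_pair(rng, n_codons, max_diffs=2):
    c1 = [rng.choice(SENSE) for _ in range(n_codons)]
    c2 = []
    for c in c1:
        cur = c
        for _ in range(rng.choice([0, 0, 1, 1, 2])):
            while True:
                pos = rng.randrange(3)
                n = rng.choice([x for x in "ACGT" if x != cur[pos]])
                alt = cur[:pos] + n + cur[pos + 1:]
                if alt not in STOPS:
                    cur = alt
                    break
        c2.append(cur)
    return "".join(c1), "".join(c2)


class TestBacktranslate:
    def test_gapless_alignment_concatenates_cds(self):
        aln = backtranslate({"x": "MK", "y": "MR"},
                            {"x": "ATGAAA", "y": "ATGCGT"})
        assert aln.rows == ["ATGAAA", "ATGCGT"]

    def test_gap_becomes_triplet_gap(self):
        aln = backtranslate({"x": "M-K", "y": "MGK"},
                            {"x": "ATGAAA", "y": "ATGGGTAAA"})
        assert aln.rows[0] == "ATG---AAA"

    def test_terminal_stop_tolerated(self):
        aln = backtranslate({"x": "MK"}, {"x": "ATGAAATAA"})
        assert aln.rows == ["ATGAAA"]

    def test_mismatch_reports_residue_position(self):
        with pytest.raises(ValueError, match="residue 2"):
            backtranslate({"x": "MW"}, {"x": "ATGGCT"})

    def test_internal_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment(ids=["x"], rows=["ATGTAAAAA"])


class TestPairFilter:
    def test_short_overlap_rejected(self):
        pair = CodonAlignment(ids=["a", "b"], rows=["ATG" * 40, "ATG" * 40])
        out = filter_pair_alignment(pair)
        assert (out.accepted, out.reason) == (False, "length")

    def test_low_identity_rejected(self):
        rng = random.Random(0)
        a, b = random_codon_pair(rng, 100)
        # force < 70% nucleotide identity with heavy mutation
        b = "".join(rng.choice(SENSE) for _ in range(100))
        out = filter_pair_alignment(CodonAlignment(ids=["a", "b"], rows=[a, b]))
        assert (out.accepted, out.reason) == (False, "identity")

    def test_long_similar_overlap_accepted(self):
        rng = random.Random(1)
        a, b = random_codon_pair(rng, 100)
        out = filter_pair_alignment(CodonAlignment(ids=["a", "b"], rows=[a, b]))
        assert out.accepted


class TestKaKsNG86:
    def test_counts_match_pathway_enumeration_oracle(self):
        rng = random.Random(11)
        for _ in range(200):
            a, b = random_codon_pair(rng, 60)
            aln = CodonAlignment(ids=["a", "b"], rows=[a, b])
            try:
                res = kaks_pair(aln)
            except ValueError:
                continue  # saturated draw
            S = Sd = Nd = 0.0
            for i in range(0, 180, 3):
                c1, c2 = a[i:i + 3], b[i:i + 3]
                S += (oracle_codon_sites(c1) + oracle_codon_sites(c2)) / 2
                d = oracle_codon_diffs(c1, c2)
                Sd += d[0]
                Nd += d[1]
            assert res.S == pytest.approx(S, abs=1e-9)
            assert res.Sd == pytest.approx(Sd, abs=1e-9)
            assert res.Nd == pytest.approx(Nd, abs=1e-9)
            assert res.S + res.N == pytest.approx(180.0, abs=1e-6)

    def test_identical_sequences(self):
        a = "ATGGCTGAA" * 20
        res = kaks_pair(CodonAlignment(ids=["a", "b"], rows=[a, a]))
        assert res.ka == res.ks == 0.0 and math.isnan(res.ratio)

    def test_synonymous_only_changes_give_ratio_zero(self):
        a = "ATGGCTGAA" * 20
        b = "ATGGCCGAA" + "ATGGCTGAA" * 19
        res = kaks_pair(CodonAlignment(ids=["a", "b"], rows=[a, b]))
        assert res.ka == 0.0 and res.ratio == 0.0

    def test_symmetric_under_sequence_swap(self):
        rng = random.Random(2)
        a, b = random_codon_pair(rng, 80)
        r1 = kaks_pair(CodonAlignment(ids=["a", "b"], rows=[a, b]))
        r2 = kaks_pair(CodonAlignment(ids=["b", "a"], rows=[b, a]))
        assert (r1.ka, r1.ks, r1.S, r1.N) == (r2.ka, r2.ks, r2.S, r2.N)

    def test_codon_columns_with_gap_or_ambiguity_dropped(self):
        a = "ATGGCTGAA" * 20 + "ATG"
        b = "ATGGCTGAA" * 20 + "---"
        res = kaks_pair(CodonAlignment(ids=["a", "b"], rows=[a, b]))
        assert res.n_codons == 60
        c = "ATGGCTGAA" * 20 + "ATN"
        res2 = kaks_pair(CodonAlignment(ids=["a", "b"], rows=[a, c]))
        assert res2.n_codons == 60

    def test_saturation_is_an_error(self):
        a = "ATGAAA" * 30
        b = "ATGCTC" * 30  # nearly every codon multiply substituted
        with pytest.raises(ValueError, match="saturated"):
            kaks_pair(CodonAlignment(ids=["a", "b"], rows=[a, b]))


def _pair_tree(t):
    return dendropy.Tree.get(data=f"(a:{t / 2},b:{t / 2});", schema="newick")


def simulated_pair(omega, t, n_codons, seed, kappa=2.0):
    aln = evolve_alignment(_pair_tree(t), [omega] * n_codons, kappa=kappa, seed=seed)
    return CodonAlignment(ids=["a", "b"], rows=[aln["a"], aln["b"]])


class TestKaKsRecovery:
    @pytest.mark.parametrize("omega", [0.1, 0.5, 1.0, 2.0])
    def test_median_ratio_within_15_percent_of_truth(self, omega):
        """Simulated pairs at Ks ~ 0.3 under the estimator's own model
        (no transition bias): NG86 point estimates recover the generating
        omega. With kappa > 1 NG86 is deliberately misspecified and biased
        low; the YN00 mode covers that regime."""
        ratios = []
        for seed in range(50):
            aln = simulated_pair(omega, 0.8, 1000, seed, kappa=1.0)
            res = kaks_pair(aln)
            if res.ratio_defined:
                ratios.append(res.ratio)
        assert abs(np.median(ratios) - omega) <= 0.15 * omega

    def test_yn00_mode_agrees_with_ng86_within_tolerance(self):
        for seed in range(10):
            aln = simulated_pair(0.5, 0.4, 600, seed)
            r_ng = kaks_pair(aln, method="NG86")
            r_yn = kaks_pair(aln, method="YN00")
            assert abs(r_ng.ratio - r_yn.ratio) <= 0.2


class TestSitewiseScan:
    def test_single_site_likelihood_matches_direct_summation(self):
        tree = dendropy.Tree.get(data="(a:0.2,b:0.3,c:0.5);", schema="newick")
        aln = CodonAlignment(ids=["a", "b", "c"], rows=["ATG", "ATA", "CTG"])
        pi = np.full(61, 1 / 61)
        kappa, omega, scale = 2.3, 0.7, 1.1
        lnl = _site_loglikes(_encode_alignment(aln), _flatten_tree(tree, aln.ids),
                             aln.ids, kappa, scale, omega, pi)[0]
        Q = C.rate_matrix(kappa, omega, pi, scale="neutral")
        P = {t: C.transition_probabilities(Q, pi, np.array([t * scale]))[0]
             for t in (0.2, 0.3, 0.5)}
        xs = [C.CODON_INDEX[s] for s in ("ATG", "ATA", "CTG")]
        direct = sum(pi[r] * P[0.2][r, xs[0]] * P[0.3][r, xs[1]] * P[0.5][r, xs[2]]
                     for r in range(61))
        assert lnl == pytest.approx(np.log(direct), abs=1e-8)

    @pytest.fixture(scope="class")
    def quartet_scan(self):
        tree = dendropy.Tree.get(data="((a:0.5,b:0.5):0.1,(c:0.5,d:0.5):0.1);",
                                 schema="newick")
        omegas = [5.0] + [1.0] * 39
        aln_seqs = evolve_alignment(tree, omegas, kappa=2.0, seed=3)
        aln = CodonAlignment(ids=["a", "b", "c", "d"],
                             rows=[aln_seqs[k] for k in ("a", "b", "c", "d")])
        return sitewise_selection_scan(aln, tree)

    def test_invariant_column_is_neutral_with_zero_statistic(self):
        tree = dendropy.Tree.get(data="((a:0.3,b:0.3):0.1,(c:0.3,d:0.3):0.1);",
                                 schema="newick")
        aln = CodonAlignment(ids=["a", "b", "c", "d"], rows=["ATGGCT"] * 4)
        res = sitewise_selection_scan(aln, tree)
        for r in res:
            assert r.classification == "neutral"
            assert r.lrt_stat <= 1e-6

    def test_all_gap_column_reported_untested(self):
        tree = dendropy.Tree.get(data="((a:0.3,b:0.3):0.1,(c:0.3,d:0.3):0.1);",
                                 schema="newick")
        aln = CodonAlignment(ids=["a", "b", "c", "d"],
                             rows=["---ATGGCT"] * 4)
        res = sitewise_selection_scan(aln, tree)
        assert not res[0].tested and res[1].tested

    def test_positive_site_detected_on_informative_replicate(self, quartet_scan):
        assert quartet_scan[0].omega_hat > 1.0
        assert quartet_scan[0].classification == "positive"

    def test_classification_respects_invariants(self, quartet_scan):
        for r in quartet_scan:
            if r.classification == "positive":
                assert r.omega_hat > 1 and r.p_value < 0.05
            if r.classification == "purifying":
                assert r.omega_hat < 1 and r.p_value < 0.05

    def test_global_fit_recovers_generating_parameters(self):
        tree = dendropy.Tree.get(data="((a:0.5,b:0.5):0.2,(c:0.5,d:0.5):0.2);",
                                 schema="newick")
        aln_seqs = evolve_alignment(tree, [1.0] * 150, kappa=2.0, seed=5)
        aln = CodonAlignment(ids=list(aln_seqs), rows=list(aln_seqs.values()))
        fit = fit_global_codon_model(aln, tree)
        assert 1.3 <= fit.kappa <= 3.0
        assert 0.7 <= fit.scale <= 1.4
        assert 0.7 <= fit.omega <= 1.4


class TestEstimatorOrdering:
    def test_kaks_orders_omega_correctly_across_replicates(self):
        lows, highs = [], []
        for seed in range(15):
            lows.append(kaks_pair(simulated_pair(0.1, 0.4, 500, seed)).ratio)
            highs.append(kaks_pair(simulated_pair(2.0, 0.4, 500, 100 + seed)).ratio)
        assert np.median(lows) < np.median(highs)
        assert max(lows) < 1.0 < min(h for h in highs if not math.isnan(h))
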