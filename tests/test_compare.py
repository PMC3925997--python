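"""Cross-species link and neighbourhood conservation.

Hypergeometric tails are validated against an exact combinatorial
enumeration oracle built on math.comb (independent of scipy).
"""

import math

import numpy as np
import pytest

from crossnet.compare import (
    classify_genes,
    core_conservation,
    eligible_genes,
    link_conservation,
    multi_ortholog_summary,
    neighbourhood_test,
    randomized_link_conservation,
    reciprocal_classify,
    sequence_vs_regulation,
    compare_neighbourhoods,
    ConservationReport,
    NeighbourhoodTest,
)
from crossnet.io import OrthologMap
from conftest import make_network


def exact_upper_tail(N, k, n, x):
    """P(X >= x) for Hypergeometric(N, k, n) by direct summation."""
    denom = math.comb(N, n)
    return sum(
        math.comb(k, i) * math.comb(N - k, n - i)
        for i in range(x, min(n, k) + 1)
    ) / denom


def exact_lower_tail(N, k, n, x):
    denom = math.comb(N, n)
    return sum(
        math.comb(k, i) * math.comb(N - k, n - i)
        for i in range(0, min(x, n, k) + 1)
        if n - i <= N - k
    ) / denom


def identity_map(genes1, genes2=None, sp1="s1", sp2="s2"):
    genes2 = genes1 if genes2 is None else genes2
    groups = {
        f"G{i}": {(sp1, a), (sp2, b)} for i, (a, b) in enumerate(zip(genes1, genes2))
    }
    return OrthologMap(groups=groups)


class TestHypergeometricOracle:
    @staticmethod
    def realizable(N, n, k, x):
        # the network construction reserves one node for the focal gene
        return n <= N - 1 and (k - x) <= N - 1 - n

    def test_tails_match_exact_enumeration_small_N(self):
        # realizable parameterizations with N <= 30 (stride for speed)
        checked = 0
        for N in range(2, 31, 3):
            for n in range(0, N, 5):
                for k in range(0, N, 5):
                    for x in range(0, min(n, k) + 1):
                        if not self.realizable(N, n, k, x):
                            continue
                        t = _make_test(N, n, k, x)
                        assert t.p_conserved == pytest.approx(
                            exact_upper_tail(N, k, n, x), abs=1e-12
                        )
                        assert t.p_diverged == pytest.approx(
                            exact_lower_tail(N, k, n, x), abs=1e-12
                        )
                        checked += 1
        assert checked > 100

    def test_tails_share_point_mass(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 200:
            N = int(rng.integers(5, 60))
            n = int(rng.integers(0, N))
            k = int(rng.integers(0, N))
            x = int(rng.integers(0, min(n, k) + 1))
            if not self.realizable(N, n, k, x):
                continue
            t = _make_test(N, n, k, x)
            assert t.p_conserved + t.p_diverged >= 1.0 - 1e-12
            checked += 1


def _make_test(N, n, k, x):
    """Construct a network pair realizing exact (N, n, k, x) and test it."""
    sp1_genes = [f"a{i}" for i in range(N)]
    # neighbourhood of A: first n genes (excluding A itself, placed last)
    A = sp1_genes[-1]
    nbh = sp1_genes[:n]
    net1 = make_network([(A, g) for g in nbh], nodes=sp1_genes)
    # S2: ortholog A' with a neighbourhood mapping back to x overlap + (k-x) others
    mapped = nbh[:x] + [g for g in sp1_genes[n:-1]][: k - x]
    assert len(mapped) == k
    groups = {"GA": {("s1", A), ("s2", "Aprime")}}
    s2_nodes = ["Aprime"]
    for i, g in enumerate(mapped):
        s2 = f"b{i}"
        groups[f"G{i}"] = {("s1", g), ("s2", s2)}
        s2_nodes.append(s2)
    net2 = make_network([("Aprime", f"b{i}") for i in range(k)], nodes=s2_nodes)
    omap = OrthologMap(groups=groups)
    return neighbourhood_test(A, "Aprime", net1, net2, omap, "s1", "s2", N=N)


class TestNeighbourhoodTestExamples:
    def test_full_overlap(self):
        t = _make_test(20, 5, 5, 5)
        assert t.p_conserved == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap(self):
        t = _make_test(20, 5, 5, 0)
        assert t.p_conserved == pytest.approx(1.0)
        assert t.p_diverged == pytest.approx(
            math.comb(15, 5) / math.comb(20, 5), rel=1e-12
        )

    def test_no_mappable_neighbours_degenerate(self):
        t = _make_test(20, 5, 0, 0)
        assert t.p_conserved == 1.0
        assert t.p_diverged == 1.0

    def test_non_ortholog_rejected(self):
        net1 = make_network([("A", "B")])
        net2 = make_network([("X", "Y")])
        with pytest.raises(ValueError, match="not a predicted ortholog"):
            neighbourhood_test("A", "X", net1, net2, OrthologMap(), "s1", "s2")


class TestEligibility:
    def test_rules(self):
        net1 = make_network([("A", "B")], nodes=["A", "B", "C"])
        net2 = make_network([("A2", "B2")], nodes=["A2", "B2", "C2"])
        omap = identity_map(["A", "B", "C"], ["A2", "C2", "B2"])
        # A -> A2 connected both sides: eligible
        # B -> C2 isolated in S2: excluded ; C isolated in S1: excluded
        assert eligible_genes(net1, net2, omap, "s1", "s2") == {"A"}

    def test_identity_gives_all_connected(self):
        net = make_network([("A", "B"), ("B", "C")], nodes=["A", "B", "C", "D"])
        omap = identity_map(["A", "B", "C", "D"])
        assert eligible_genes(net, net, omap, "s1", "s2") == {"A", "B", "C"}


class TestLinkConservation:
    def test_identical_networks_fully_conserved(self):
        net = make_network([("A", "B"), ("B", "C")])
        omap = identity_map(["A", "B", "C"])
        frac, flags = link_conservation(net, net, omap, "s1", "s2")
        assert frac == 1.0

    def test_any_ortholog_pair_counts(self):
        net1 = make_network([("A", "B")])
        net2 = make_network([("A2p", "B2")], nodes=["A2", "A2p", "B2"])
        omap = OrthologMap(groups={
            "G1": {("s1", "A"), ("s2", "A2"), ("s2", "A2p")},
            "G2": {("s1", "B"), ("s2", "B2")},
        })
        frac, _ = link_conservation(net1, net2, omap, "s1", "s2")
        assert frac == 1.0

    def test_disjoint_edge_sets_zero(self):
        net1 = make_network([("A", "B")], nodes=list("ABCD"))
        net2 = make_network([("C", "D")], nodes=list("ABCD"))
        omap = identity_map(list("ABCD"))
        frac, flags = link_conservation(net1, net2, omap, "s1", "s2")
        # A-B is ineligible (A,B isolated in net2) -> no eligible links
        assert math.isnan(frac)

    def test_null_fractions_bounded_and_deterministic(self):
        net = make_network([("A", "B"), ("B", "C"), ("C", "D")])
        omap = identity_map(list("ABCD"))
        null1 = randomized_link_conservation(net, net, omap, "s1", "s2", 10, seed=3)
        null2 = randomized_link_conservation(net, net, omap, "s1", "s2", 10, seed=3)
        assert np.array_equal(null1, null2)
        assert np.all((null1 >= 0) & (null1 <= 1))


def _report(entries, sp1="s1", sp2="s2", fdr=0.05):
    """Build a ConservationReport from (gene, orth, q_cons, q_div[, bits])."""
    tests = []
    for e in entries:
        gene, orth, qc, qd = e[:4]
        bits = e[4] if len(e) > 4 else float("-inf")
        tests.append(
            NeighbourhoodTest(
                gene=gene, ortholog=orth, N=100, n=10, k=10,
                x=5 if qc < 0.05 else 1,
                p_conserved=qc, p_diverged=qd, bitscore=bits,
                q_conserved=qc, q_diverged=qd,
            )
        )
    per_gene: dict[str, list] = {}
    for t in tests:
        per_gene.setdefault(t.gene, []).append(t)
    category = {}
    for gene, ts in per_gene.items():
        c = any(t.q_conserved < fdr for t in ts)
        d = any(t.q_diverged < fdr for t in ts)
        category[gene] = (
            "Conserved-and-Diverged" if c and d else
            "Conserved" if c else "Diverged" if d else "None"
        )
    return ConservationReport(sp1, sp2, tests, category, fdr)


class TestClassification:
    def test_category_rules_via_classify(self):
        # build synthetic tests with extreme p-values so BH keeps the calls
        tests = [
            NeighbourhoodTest("gC", "o1", 100, 10, 10, 9, 1e-12, 1.0),
            NeighbourhoodTest("gB", "o1", 100, 10, 10, 9, 1e-12, 1.0),
            NeighbourhoodTest("gB", "o2", 100, 10, 10, 0, 1.0, 1e-12),
            NeighbourhoodTest("gN", "o1", 100, 10, 10, 2, 0.5, 0.6),
        ]
        rep = classify_genes(tests, fdr=0.05)
        assert rep.category == {
            "gC": "Conserved",
            "gB": "Conserved-and-Diverged",
            "gN": "None",
        }

    def test_empty_tests_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_genes([])

    def test_fdr_families_are_separate(self):
        # many strong conserved p-values must not drag diverged p-values
        # through the BH correction
        tests = [
            NeighbourhoodTest(f"g{i}", "o", 100, 10, 10, 9, 1e-9, 1.0)
            for i in range(20)
        ]
        tests.append(NeighbourhoodTest("gd", "o", 100, 10, 10, 1, 1.0, 0.04))
        rep = classify_genes(tests, fdr=0.05)
        # within the 21-member diverged family alone, BH adjusts 0.04 by the
        # full family size (rank 1 of 21): q = 0.84; pooling the 20 tiny
        # conserved p-values into one family would instead give rank 21 of 41
        # and q = 0.078 — the families must stay separate
        gd = next(t for t in rep.tests if t.gene == "gd")
        assert gd.q_diverged == pytest.approx(0.04 * 21, rel=1e-9)
        assert rep.category["gd"] == "None"


class TestReciprocal:
    def test_mutual_best_pairs_conserved(self):
        r12 = _report([("A", "A2", 1e-6, 1.0)])
        r21 = _report([("A2", "A", 1e-6, 1.0)], sp1="s2", sp2="s1")
        rec = reciprocal_classify(r12, r21)
        assert rec.category["A"] == "Conserved"

    def test_two_paralogs_only_one_reciprocal(self):
        # both paralogs' best match is A, but A's best is only one of them
        r12 = _report([("A", "Pa", 1e-9, 1.0), ("A", "Pb", 1e-4, 1.0)])
        r21 = _report(
            [("Pa", "A", 1e-9, 1.0), ("Pb", "A", 1e-4, 1.0)], sp1="s2", sp2="s1"
        )
        rec12 = reciprocal_classify(r12, r21)
        rec21 = reciprocal_classify(r21, r12)
        assert rec12.category["A"] == "Conserved"
        assert rec21.category["Pa"] == "Conserved"
        assert rec21.category["Pb"] == "None"  # its best match is taken

    def test_reciprocal_never_exceeds_nonreciprocal(self, study, study_networks):
        omap = study["omap"]
        nets = study_networks["networks"]
        t12 = compare_neighbourhoods(nets["sp1"][2.0], nets["sp2"][2.0], omap, "sp1", "sp2")
        t21 = compare_neighbourhoods(nets["sp2"][2.0], nets["sp1"][2.0], omap, "sp2", "sp1")
        r12 = classify_genes(t12, "sp1", "sp2")
        r21 = classify_genes(t21, "sp2", "sp1")
        rec = reciprocal_classify(r12, r21)
        cons_rec = rec.genes_in("Conserved", "Conserved-and-Diverged")
        cons_plain = r12.genes_in("Conserved", "Conserved-and-Diverged")
        assert cons_rec <= cons_plain


class TestMultiOrtholog:
    def omap_two_orths(self):
        return OrthologMap(groups={
            "G": {("s1", "A"), ("s2", "Pa"), ("s2", "Pb")},
        })

    def test_both_conserved_is_uniquely_conserved(self):
        rep = _report([("A", "Pa", 1e-6, 1.0), ("A", "Pb", 1e-6, 1.0)])
        out = multi_ortholog_summary(rep, self.omap_two_orths())
        assert out["A"] == "Uniquely conserved"

    def test_one_conserved_one_diverged(self):
        rep = _report([("A", "Pa", 1e-6, 1.0), ("A", "Pb", 1.0, 1e-6)])
        out = multi_ortholog_summary(rep, self.omap_two_orths())
        assert out["A"] == "Conserved-and-Diverged"

    def test_one_conserved_one_nonsignificant(self):
        rep = _report([("A", "Pa", 1e-6, 1.0), ("A", "Pb", 0.9, 0.9)])
        out = multi_ortholog_summary(rep, self.omap_two_orths())
        assert out["A"] == "Conserved"

    def test_single_ortholog_genes_excluded(self):
        rep = _report([("B", "X", 1e-6, 1.0)])
        omap = OrthologMap(groups={"G": {("s1", "B"), ("s2", "X")}})
        assert multi_ortholog_summary(rep, omap) == {}


class TestSequenceVsRegulation:
    def omap(self):
        return OrthologMap(
            groups={"G": {("s1", "A"), ("s2", "Pa"), ("s2", "Pb")}},
            bitscore={
                frozenset(("A", "Pa")): 100.0,
                frozenset(("A", "Pb")): 80.0,
            },
        )

    def test_conserved_ortholog_is_lower_bitscore(self):
        rep = _report([("A", "Pa", 1.0, 1e-6, 100.0), ("A", "Pb", 1e-6, 1.0, 80.0)])
        res = sequence_vs_regulation(rep, self.omap())
        assert res["frac_most_similar_is_most_conserved"] == 0.0
        assert res["overlap_split"]["diverged"] == 1

    def test_conserved_ortholog_is_higher_bitscore(self):
        rep = _report([("A", "Pa", 1e-6, 1.0, 100.0), ("A", "Pb", 1.0, 1e-6, 80.0)])
        res = sequence_vs_regulation(rep, self.omap())
        assert res["frac_most_similar_is_most_conserved"] == 1.0
        assert res["overlap_split"]["conserved"] == 1

    def test_missing_bitscores_excluded_and_counted(self):
        rep = _report([("A", "Pa", 1e-6, 1.0), ("A", "Pb", 1.0, 1e-6)])
        res = sequence_vs_regulation(rep, self.omap())
        assert res["n_excluded_missing_bitscore"] == 1

    def test_planted_half_rate_recovered(self, study, study_networks):
        # the generator gives the diverged copy the higher bit-score with
        # probability 1/2; the analysis pipeline should recover a rate whose
        # exact binomial CI covers 1/2
        from scipy.stats import binomtest

        omap = study["omap"]
        truth = study["truth"]
        nets = study_networks["networks"]
        tests = compare_neighbourhoods(
            nets["sp1"][2.0], nets["sp2"][2.0], omap, "sp1", "sp2"
        )
        rep = classify_genes(tests, "sp1", "sp2")
        res = sequence_vs_regulation(rep, omap)
        split = res["overlap_split"]
        n = split["conserved"] + split["diverged"] + split["not_agreeing"]
        assert n >= 15
        # most-similar-is-most-diverged should track the planted 0.5 coin
        ci = binomtest(split["diverged"], n).proportion_ci(0.99)
        assert ci.low <= 0.5 <= ci.high


class TestCoreConservation:
    def test_trio_rules(self):
        r_xy = _report([("A", "a1", 1e-6, 1.0), ("B", "b1", 1e-6, 1.0)], "x", "y")
        r_xz = _report([("A", "a2", 1e-6, 1.0), ("B", "b2", 0.9, 0.9)], "x", "z")
        reports = {("x", "y"): r_xy, ("x", "z"): r_xz}
        # fill remaining ordered pairs with empty-ish reports
        for pair in [("y", "x"), ("y", "z"), ("z", "x"), ("z", "y")]:
            reports[pair] = _report([("dummy", "d", 0.9, 0.9)], *pair)
        out = core_conservation(reports)
        assert out["x"]["conserved"] == 1  # A conserved vs both; B only vs y
        assert out["x"]["none"] >= 1

    def test_identity_trio_all_core(self):
        net = make_network([("A", "B"), ("B", "C")])
        genes = ["A", "B", "C"]
        species = ["x", "y", "z"]
        groups = {f"G{i}": {(sp, g) for sp in species} for i, g in enumerate(genes)}
        omap = OrthologMap(groups=groups)
        reports = {}
        for s1 in species:
            for s2 in species:
                if s1 != s2:
                    tests = compare_neighbourhoods(net, net, omap, s1, s2)
                    reports[(s1, s2)] = classify_genes(tests, s1, s2)
        out = core_conservation(reports)
        for sp in species:
            assert out[sp]["eligible"] == 3

    def test_two_species_rejected(self):
        reports = {("x", "y"): _report([("A", "a", 0.5, 0.5)], "x", "y"),
                   ("y", "x"): _report([("a", "A", 0.5, 0.5)], "y", "x")}
        with pytest.raises(ValueError, match="three species"):
            core_conservation(reports)


class TestCategoryFractionInvariant:
    def test_overlap_only_with_both_category(self, study, study_networks):
        nets = study_networks["networks"]
        tests = compare_neighbourhoods(
            nets["sp1"][2.0], nets["sp2"][2.0], study["omap"], "sp1", "sp2"
        )
        rep = classify_genes(tests, "sp1", "sp2")
        fr = rep.fractions()
        cons = fr["Conserved"] + fr["Conserved-and-Diverged"]
        div = fr["Diverged"] + fr["Conserved-and-Diverged"]
        if cons + div > 1.0:
            assert fr["Conserved-and-Diverged"] > 0
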