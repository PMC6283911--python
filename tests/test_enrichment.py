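"""Promoter extraction, cis enrichment, GSEA, DE filter, peak association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from earminer import (
    CisMotif,
    GeneModel,
    GeneSet,
    GeneSetCollection,
    GenomicInterval,
    SequenceRecord,
    associate_peaks,
    cis_enrichment,
    count_matches,
    de_filter,
    extract_promoters,
    gsea,
    simulate_expression,
    simulate_promoters,
)
from _oracles import hypergeom_tail

NT = np.array(list("ACGT"))


def _random_genome(rng, length=12000):
    return {"chr1": "".join(rng.choice(NT, size=length))}


class TestExtractPromoters:
    def test_plus_strand_window(self, rng):
        genome = _random_genome(rng)
        g = GeneModel("gA", "chr1", "+", 5001, 6000)
        (prom,) = extract_promoters(genome, [g], length=3000)
        assert prom.id == "gA"
        assert prom.seq == genome["chr1"][2000:5000]
        assert len(prom.seq) == 3000

    def test_minus_strand_is_revcomp_after_tss(self, rng):
        genome = _random_genome(rng)
        g = GeneModel("gB", "chr1", "-", 2001, 3000)
        (prom,) = extract_promoters(genome, [g], length=3000)
        comp = str.maketrans("ACGT", "TGCA")
        expected = genome["chr1"][3000:6000].translate(comp)[::-1]
        assert prom.seq == expected

    def test_truncated_at_contig_edge(self, rng):
        genome = _random_genome(rng, length=4000)
        plus = GeneModel("gC", "chr1", "+", 1001, 1500)
        minus = GeneModel("gD", "chr1", "-", 3000, 3800)
        proms = extract_promoters(genome, [plus, minus], length=3000)
        assert len(proms[0].seq) == 1000  # only 1000 nt upstream exist
        assert len(proms[1].seq) == 200   # contig ends 200 nt after the TSS

    def test_strand_symmetry(self, rng):
        """A - promoter equals the + extraction on the reverse-complemented contig."""
        seq = "".join(rng.choice(NT, size=2000))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        tss = 700  # 1-based on the forward contig
        minus = GeneModel("g", "chr1", "-", 600, tss)
        mirrored_tss = len(seq) - tss + 1
        plus = GeneModel("g", "chr1", "+", mirrored_tss, mirrored_tss + 100)
        (a,) = extract_promoters({"chr1": seq}, [minus], length=500)
        (b,) = extract_promoters({"chr1": rc}, [plus], length=500)
        assert a.seq == b.seq

    def test_missing_contig_rejected(self):
        with pytest.raises(ValueError, match="chrX"):
            extract_promoters({"chr1": "ACGT"}, [GeneModel("g", "chrX", "+", 2, 3)])


class TestCountMatches:
    def test_overlapping_matches_counted(self):
        proms = [SequenceRecord("p", "TATATA")]
        assert count_matches(proms, CisMotif("tata", "TATA")) == 2

    def test_absent_motif(self):
        assert count_matches([SequenceRecord("p", "CCCC")], CisMotif("m", "TATA")) == 0

    def test_additive_over_disjoint_sets(self, rng):
        proms = [
            SequenceRecord(f"p{i}", "".join(rng.choice(NT, size=200))) for i in range(10)
        ]
        m = CisMotif("m", "ACGT")
        total = count_matches(proms, m)
        assert total == count_matches(proms[:4], m) + count_matches(proms[4:], m)

    def test_both_strands_adds_revcomp(self):
        proms = [SequenceRecord("p", "TGACGTCA")]  # palindromic cis element
        m = CisMotif("m", "TGACGTCA")
        assert count_matches(proms, m) == 1
        assert count_matches(proms, m, both_strands=True) == 2


@pytest.fixture(scope="module")
def null_universe():
    proms, _ = simulate_promoters(
        n_query=0, n_background=300, length=1000, rate_background=1.0, seed=42
    )
    return proms


class TestCisEnrichment:
    def test_null_type_one_rate_and_uniformity(self, null_universe):
        motif = CisMotif("m", "TGACGTCA")
        rng = np.random.default_rng(7)
        ids = [p.id for p in null_universe]
        pvals = []
        for _ in range(200):
            q = list(rng.choice(ids, size=25, replace=False))
            (res,) = cis_enrichment(
                q, null_universe, [motif], n_random=200,
                seed=int(rng.integers(2**31)),
            )
            pvals.append(res.p)
        rate = np.mean(np.array(pvals) < 0.05)
        assert rate == pytest.approx(0.05, abs=0.02)
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.1

    def test_implanted_motif_detected(self):
        motif = CisMotif("m", "TGACGTCA")
        detected = 0
        for rep in range(30):
            proms, _ = simulate_promoters(
                n_query=25, n_background=275, length=1000,
                rate_query=5.0, rate_background=1.0, seed=5000 + rep,
            )
            q = [p.id for p in proms if p.id.startswith("q")]
            (res,) = cis_enrichment(q, proms, [motif], n_random=200, seed=rep)
            detected += res.p < 0.05
        assert detected >= int(0.95 * 30)

    def test_z_zero_when_observed_equals_mean(self, null_universe):
        # query = whole universe: every random list draws from the same counts
        motif = CisMotif("m", "TGACGTCA")
        ids = [p.id for p in null_universe]
        (res,) = cis_enrichment(ids, null_universe, [motif], n_random=50, seed=1)
        # whole-universe lists are identical, sigma == 0 and X == mu
        assert res.sigma == 0 and res.z == 0 and res.p == 1.0

    def test_z_formula_and_literal_mode(self, null_universe):
        motif = CisMotif("m", "TGACGTCA")
        ids = [p.id for p in null_universe][:25]
        (res,) = cis_enrichment(ids, null_universe, [motif], n_random=200, seed=3)
        n = res.n
        assert res.z == pytest.approx((res.x_bar - res.mu) / (res.sigma / np.sqrt(n)))
        assert res.z_raw == pytest.approx((res.x_bar - res.mu) / res.sigma)
        (lit,) = cis_enrichment(
            ids, null_universe, [motif], n_random=200, seed=3, literal=True
        )
        expected = stats.norm.cdf(lit.x_bar, loc=lit.mu, scale=lit.sigma / np.sqrt(n))
        assert lit.p == pytest.approx(expected)

    def test_query_outside_universe_rejected(self, null_universe):
        with pytest.raises(ValueError, match="not in universe"):
            cis_enrichment(["nope"], null_universe, [CisMotif("m", "AC")], n_random=5)


class TestGsea:
    def test_query_equals_set_closed_form(self):
        N, k = 20, 5
        universe = [f"g{i}" for i in range(N)]
        coll = GeneSetCollection([GeneSet("S", "", frozenset(universe[:k]))])
        (res,) = gsea(universe[:k], coll, universe)
        from math import comb

        assert res.p == pytest.approx(1 / comb(N, k))
        assert res.significant

    def test_fisher_equals_tail_enumeration(self, rng):
        for _ in range(200):
            N = int(rng.integers(5, 51))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            members = frozenset(universe[:K])
            query = list(rng.choice(universe, size=n, replace=False))
            coll = GeneSetCollection([GeneSet("S", "", members)])
            (res,) = gsea(query, coll, universe)
            k = len(members & set(query))
            assert res.p == pytest.approx(hypergeom_tail(k, N, K, n), rel=1e-9)

    def test_fisher_equals_scipy_fisher_exact(self, rng):
        for _ in range(20):
            N = int(rng.integers(10, 40))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(2, N - 1))
            n = int(rng.integers(2, N - 1))
            query = set(rng.choice(universe, size=n, replace=False))
            members = frozenset(universe[:K])
            (res,) = gsea(query, GeneSetCollection([GeneSet("S", "", members)]), universe)
            k = len(members & query)
            table = [[k, n - k], [K - k, N - K - n + k]]
            _, p = stats.fisher_exact(table, alternative="greater")
            assert res.p == pytest.approx(p, rel=1e-9)

    def test_disjoint_set_skipped_with_warning(self):
        coll = GeneSetCollection([GeneSet("S", "", frozenset({"zz"}))])
        with pytest.warns(UserWarning, match="disjoint"):
            assert gsea(["g1"], coll, ["g1", "g2"]) == []

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            gsea([], GeneSetCollection([]), [])

    def test_bh_correction_monotone(self):
        universe = [f"g{i}" for i in range(40)]
        sets = [GeneSet(f"S{j}", "", frozenset(universe[j : j + 10])) for j in range(5)]
        res = gsea(universe[:10], GeneSetCollection(sets), universe, bh_correct=True)
        for r in res:
            assert r.p_adj >= r.p - 1e-12


class TestDeFilter:
    def test_identical_groups_no_de(self):
        mat = pd.DataFrame(
            np.tile([10.0, 12.0, 11.0, 10.0], (5, 1)),
            index=[f"g{i}" for i in range(5)],
            columns=["a1", "a2", "b1", "b2"],
        )
        calls = de_filter(mat, ["a1", "a2"], ["b1", "b2"])
        assert not any(c.is_de for c in calls)

    def test_matches_direct_computation(self):
        mat, truth = simulate_expression(n_genes=100, n_de=20, seed=33)
        ga, gb = ["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]
        calls = {c.gene: c for c in de_filter(mat, ga, gb)}
        for gene in mat.index:
            a, b = mat.loc[gene, ga], mat.loc[gene, gb]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            lfc = np.log2(a.mean() / b.mean())
            c = calls[gene]
            assert c.t == pytest.approx(t) and c.p == pytest.approx(p)
            assert c.log2fc == pytest.approx(lfc)
            assert c.is_de == (p < 0.05 and abs(lfc) > 1)

    def test_clear_effect_called(self):
        rng = np.random.default_rng(0)
        a = 4 + 0.01 * rng.standard_normal(4)
        b = 1 + 0.01 * rng.standard_normal(4)
        mat = pd.DataFrame([np.r_[a, b]], index=["g"], columns=["a1", "a2", "a3", "a4",
                                                                "b1", "b2", "b3", "b4"])
        (c,) = de_filter(mat, ["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"])
        assert c.is_de and c.log2fc == pytest.approx(2, abs=0.05)

    def test_null_positive_rate_near_alpha(self):
        mat, _ = simulate_expression(n_genes=4000, n_de=0, seed=8)
        calls = de_filter(mat, ["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"],
                          lfc_cut=0.0)
        rate = np.mean([c.is_de for c in calls])
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_small_group_rejected(self):
        mat, _ = simulate_expression(n_genes=5, n_de=0, seed=1)
        with pytest.raises(ValueError):
            de_filter(mat, ["a1"], ["b1", "b2"])

    def test_nonpositive_mean_excluded_with_warning(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [-5.0, -5.0, 1.0, 1.0]],
            index=["ok", "bad"], columns=["a1", "a2", "b1", "b2"],
        )
        with pytest.warns(UserWarning, match="nonpositive"):
            calls = de_filter(mat, ["a1", "a2"], ["b1", "b2"])
        assert [c.gene for c in calls] == ["ok"]


class TestAssociatePeaks:
    GENES = [
        GeneModel("gP", "chr1", "+", 5001, 6000),
        GeneModel("gM", "chr1", "-", 8001, 9000),
    ]

    def test_boundary_inclusive_upstream(self):
        # peak covering [tss-1, tss) in 0-based coords: last upstream base
        peaks = {"mk": [GenomicInterval("chr1", 4999, 5000)]}
        assoc = associate_peaks(self.GENES, peaks, upstream_window=1000)
        assert assoc["gP"] == {"mk"}

    def test_half_open_exclusion_at_window_edge(self):
        # peak ending exactly at tss-W does not overlap [tss-W, tss)
        peaks = {"mk": [GenomicInterval("chr1", 3500, 4000)]}
        assoc = associate_peaks(self.GENES, peaks, upstream_window=1000)
        assert assoc["gP"] == set()

    def test_minus_strand_upstream_is_after_tss(self):
        peaks = {"mk": [GenomicInterval("chr1", 9100, 9200)]}
        assoc = associate_peaks(self.GENES, peaks, upstream_window=1000)
        assert assoc["gM"] == {"mk"}

    def test_gene_body_counts(self):
        peaks = {"mk": [GenomicInterval("chr1", 5500, 5600)]}
        assert associate_peaks(self.GENES, peaks)["gP"] == {"mk"}

    def test_matches_bruteforce_on_random_peaks(self, rng):
        genes = []
        for i in range(100):
            start = int(rng.integers(3000, 90000))
            end = start + int(rng.integers(200, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{i}", "chr1", strand, start, end))
        peaks = {
            "m1": [
                GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 500)))
                for s in rng.integers(0, 95000, size=250)
            ],
            "m2": [
                GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 500)))
                for s in rng.integers(0, 95000, size=250)
            ],
        }
        W = 1000
        assoc = associate_peaks(genes, peaks, upstream_window=W)
        for g in genes:
            body = (g.start - 1, g.end)
            tss0 = g.tss - 1
            up = (max(0, tss0 - W), tss0) if g.strand == "+" else (tss0 + 1, tss0 + 1 + W)
            expected = set()
            for mark, ivs in peaks.items():
                for iv in ivs:
                    if (iv.start < body[1] and body[0] < iv.end) or (
                        iv.start < up[1] and up[0] < iv.end
                    ):
                        expected.add(mark)
                        break
            assert assoc[g.gene_id] == expected
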