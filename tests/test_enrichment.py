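"""Hypergeometric over-representation and kappa annotation clustering."""

import math
from fractions import Fraction
from importlib import resources

import numpy as np
import pytest
from scipy.stats import hypergeom

from cnvseg.enrichment import (
    AnnotationCluster,
    EnrichmentRecord,
    TermSet,
    cluster_annotations,
    hypergeom_upper_tail,
    kappa_similarity,
    read_gmt,
    term_enrichment,
)


def exact_upper_tail(k, K, n, N) -> Fraction:
    """Independent oracle: integer-arithmetic tail sum of the pmf."""
    num = sum(math.comb(K, j) * math.comb(N - K, n - j)
              for j in range(k, min(K, n) + 1)
              if 0 <= n - j <= N - K)
    return Fraction(num, math.comb(N, n))


class TestHypergeomUpperTail:
    def test_k_zero_is_one(self):
        assert hypergeom_upper_tail(0, 5, 10, 20) == 1.0

    def test_matches_exact_rational_oracle(self, rng):
        for _ in range(300):
            N = int(rng.integers(1, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            exact = float(exact_upper_tail(k, K, n, N))
            got = hypergeom_upper_tail(k, K, n, N)
            assert got == pytest.approx(exact, rel=1e-10, abs=1e-300)

    def test_agrees_with_scipy_survival_function(self):
        # independent dual route through scipy's implementation
        for (k, K, n, N) in [(5, 5, 10, 20), (3, 8, 12, 40), (1, 2, 3, 6)]:
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                hypergeom.sf(k - 1, N, K, n), rel=1e-9
            )

    def test_census_draw_has_tail_one(self):
        assert hypergeom_upper_tail(7, 7, 20, 20) == 1.0

    def test_non_increasing_in_k(self):
        ps = [hypergeom_upper_tail(k, 10, 15, 40) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_permutation_estimate(self, rng):
        K, n, N, k = 6, 8, 25, 3
        draws = 100_000
        universe = np.arange(N)
        hits = 0
        for _ in range(draws):
            sample = rng.choice(universe, size=n, replace=False)
            if np.count_nonzero(sample < K) >= k:
                hits += 1
        p_mc = hits / draws
        p = hypergeom_upper_tail(k, K, n, N)
        assert abs(p - p_mc) < 4 * np.sqrt(p * (1 - p) / draws)

    def test_inconsistent_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(0, 11, 5, 10)


class TestTermEnrichment:
    def terms(self):
        return [
            TermSet("t1", "alpha", frozenset({"a", "b", "c"})),
            TermSet("t2", "beta", frozenset({"c", "d"})),
        ]

    def test_query_equals_universe_gives_p_one(self):
        universe = {"a", "b", "c", "d", "e"}
        records = term_enrichment(universe, universe, self.terms())
        assert all(r.p_value == 1.0 for r in records)

    def test_counts_filled_from_set_intersections(self):
        universe = {"a", "b", "c", "d", "e", "f"}
        records = term_enrichment({"a", "b"}, universe, self.terms())
        by_id = {r.term_id: r for r in records}
        assert (by_id["t1"].k, by_id["t1"].K, by_id["t1"].n, by_id["t1"].N) == (2, 3, 2, 6)
        assert by_id["t2"].k == 0

    def test_sorted_ascending_by_p(self):
        universe = set("abcdefgh")
        records = term_enrichment({"a", "b", "c"}, universe, self.terms())
        ps = [r.p_value for r in records]
        assert ps == sorted(ps)

    def test_feature_relabeling_invariance(self):
        universe = set("abcdef")
        relabel = {x: x.upper() for x in universe}
        terms = self.terms()
        terms_r = [TermSet(t.term_id, t.term_name,
                           frozenset(relabel[m] for m in t.members)) for t in terms]
        a = term_enrichment({"a", "c"}, universe, terms)
        b = term_enrichment({"A", "C"}, {relabel[x] for x in universe}, terms_r)
        assert [(r.term_id, r.p_value) for r in a] == [(r.term_id, r.p_value) for r in b]

    def test_ease_variant_is_more_conservative(self):
        universe = set("abcdefghij")
        plain = term_enrichment({"a", "b", "c"}, universe, self.terms())
        eased = term_enrichment({"a", "b", "c"}, universe, self.terms(), ease=True)
        for p, e in zip(plain, eased):
            assert e.p_value >= p.p_value

    def test_empty_query_and_escaping_query_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment(set(), {"a"}, self.terms())
        with pytest.raises(ValueError):
            term_enrichment({"z"}, {"a"}, self.terms())

    def test_onco_mirna_fixture_overlap(self):
        """The packaged miRNA sets reproduce the 3-of-3 onco-miRNA overlap
        for the amplified-region miRNAs."""
        with resources.as_file(
            resources.files("cnvseg.data") / "mirna_sets.gmt"
        ) as p:
            terms = read_gmt(p)
        with resources.as_file(
            resources.files("cnvseg.data") / "mirna_universe.txt"
        ) as p:
            universe = {l.strip() for l in open(p) if l.strip()}
        query = {"miR-24", "miR-27a", "miR-146b"}
        records = term_enrichment(query, universe, terms)
        onco = next(r for r in records if r.term_id == "onco_mirnas")
        assert onco.k == 3 and onco.K == 3
        assert records[0].term_id == "onco_mirnas"  # most enriched


class TestKappa:
    def test_identical_vectors_give_one(self):
        v = np.array([1, 0, 1, 1, 0], dtype=bool)
        assert kappa_similarity(v, v) == 1.0
        assert kappa_similarity(np.ones(4, bool), np.ones(4, bool)) == 1.0

    def test_hand_contingency(self):
        # 2x2 contingency a=3 (both), b=1, c=1, d=5 -> kappa = 7/12
        a = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        b = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0], dtype=bool)
        po, pe = 0.8, 0.4 * 0.4 + 0.6 * 0.6
        assert kappa_similarity(a, b) == pytest.approx((po - pe) / (1 - pe))
        assert kappa_similarity(a, b) == pytest.approx(7 / 12)

    def test_independent_vectors_near_zero(self, rng):
        a = rng.random(10_000) < 0.3
        b = rng.random(10_000) < 0.5
        assert abs(kappa_similarity(a, b)) < 0.05

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kappa_similarity([1, 0], [1, 0, 1])


class TestClusterAnnotations:
    def records(self, ps):
        return [EnrichmentRecord(t, 2, 3, 4, 20, p) for t, p in ps.items()]

    def test_disjoint_terms_form_singletons(self):
        memberships = {"t1": {"a", "b"}, "t2": {"c", "d"}}
        clusters = cluster_annotations(
            self.records({"t1": 0.01, "t2": 0.02}), memberships
        )
        assert len(clusters) == 2
        assert all(len(c.member_term_ids) == 1 for c in clusters)

    def test_representative_is_lowest_p(self):
        memberships = {"t1": {"a", "b", "c"}, "t2": {"a", "b", "c"}}
        clusters = cluster_annotations(
            self.records({"t1": 0.04, "t2": 0.01}), memberships
        )
        assert len(clusters) == 1
        assert clusters[0].representative_term_id == "t2"
        assert clusters[0].member_term_ids == ("t1", "t2")

    def test_cluster_without_significant_term_dropped(self):
        memberships = {"t1": {"a", "b"}, "t2": {"a", "b"}}
        clusters = cluster_annotations(
            self.records({"t1": 0.06, "t2": 0.30}), memberships
        )
        assert clusters == []

    def test_boundary_p_of_exactly_cutoff_dropped(self):
        memberships = {"t1": {"a", "b"}}
        assert cluster_annotations(self.records({"t1": 0.05}), memberships) == []

    def test_record_order_invariance(self):
        memberships = {f"t{i}": {f"g{i}", "shared"} for i in range(5)}
        recs = self.records({f"t{i}": 0.01 * (i + 1) for i in range(5)})
        a = cluster_annotations(recs, memberships)
        b = cluster_annotations(list(reversed(recs)), memberships)
        assert a == b

    def test_enrichment_score_is_mean_neg_log10_p(self):
        memberships = {"t1": {"a", "b"}, "t2": {"a", "b"}}
        (c,) = cluster_annotations(
            self.records({"t1": 0.01, "t2": 0.001}), memberships
        )
        assert c.enrichment_score == pytest.approx(-(np.log10(0.01) + np.log10(0.001)) / 2)


class TestReadGmt:
    def test_packaged_sets_parse(self):
        with resources.as_file(
            resources.files("cnvseg.data") / "mirna_sets.gmt"
        ) as p:
            terms = read_gmt(p)
        byid = {t.term_id: t for t in terms}
        assert byid["onco_mirnas"].members == {"miR-24", "miR-27a", "miR-146b"}
        assert byid["muscle_development"].members == {
            "miR-24", "miR-331", "miR-503", "miR-27a", "miR-185", "miR-424"
        }
        assert byid["cell_cycle"].members == {"miR-24", "miR-23a"}

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("t1\tname-only\n")
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(p)
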