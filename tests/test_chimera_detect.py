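import numpy as np
import pytest

from chimeraudit.chimera_detect import (
    FilterConfig,
    QueryInterval,
    cluster_intervals,
    clustering_filter,
    coverage_filter,
    scan,
    shrink_interval,
    subset_filter,
)
from chimeraudit.linking import link_annotations
from chimeraudit.synthetic import SimulationConfig, simulate

from .conftest import make_hit


def hits_with_medians(query, covs, q_len=1000, target_prefix="T"):
    return [
        make_hit(query, f"{target_prefix}{i}", q_start=1, q_end=round(c * q_len), q_len=q_len)
        for i, c in enumerate(covs)
    ]


class TestCoverageFilter:
    CFG = FilterConfig()

    def test_typical_chimera_passes(self):
        ref = hits_with_medians("r", [0.45])
        alt = hits_with_medians("a", [0.95])
        passed, rm, am = coverage_filter(ref, alt, self.CFG)
        assert passed and rm == 0.45 and am == 0.95

    def test_ref_median_exactly_at_threshold_fails(self):
        # retention requires median strictly below 60%
        passed, *_ = coverage_filter(
            hits_with_medians("r", [0.60]), hits_with_medians("a", [0.95]), self.CFG
        )
        assert not passed

    def test_alt_median_exactly_at_threshold_fails(self):
        # retention requires pooled alternate median strictly above 70%
        passed, *_ = coverage_filter(
            hits_with_medians("r", [0.45]), hits_with_medians("a", [0.70]), self.CFG
        )
        assert not passed

    def test_missing_hits_fail_cleanly(self):
        assert coverage_filter([], hits_with_medians("a", [0.9]), self.CFG)[0] is False
        assert coverage_filter(hits_with_medians("r", [0.4]), [], self.CFG)[0] is False


class TestSubsetFilter:
    def test_proper_subset_passes(self):
        ref = [make_hit("r", t) for t in ("T1", "T2", "T3")]
        alt = [make_hit("a", t) for t in ("T1", "T3")]
        assert subset_filter(ref, alt)

    def test_extra_alternate_target_fails(self):
        ref = [make_hit("r", "T1")]
        alt = [make_hit("a", t) for t in ("T1", "T4")]
        assert not subset_filter(ref, alt)

    def test_equal_sets_are_an_allowed_improper_subset(self):
        ref = [make_hit("r", t) for t in ("T1", "T2")]
        alt = [make_hit("a", t) for t in ("T2", "T1")]
        assert subset_filter(ref, alt)

    def test_empty_alternate_set_fails(self):
        assert not subset_filter([make_hit("r", "T1")], [])


class TestShrinkInterval:
    @pytest.mark.parametrize(
        "iv,frac,expected",
        [
            ((100, 300), 0.10, (110, 290)),  # floor(201*0.05)=10 per end
            ((5, 6), 0.10, (5, 6)),          # floor(0.1)=0: unchanged
            ((1, 1), 0.10, (1, 1)),          # degenerate preserved
            ((10, 11), 1.0, (10, 10)),       # would vanish -> midpoint
        ],
    )
    def test_shrink_arithmetic(self, iv, frac, expected):
        out = shrink_interval(QueryInterval(*iv), frac)
        assert (out.start, out.end) == expected


def brute_force_clusters(spans):
    """Union-find over explicit pairwise closed-interval overlap tests."""
    parent = list(range(len(spans)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            (s1, e1), (s2, e2) = spans[i], spans[j]
            if max(s1, s2) <= min(e1, e2):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(spans)):
        groups.setdefault(find(i), []).append(spans[i])
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g)) for g in groups.values()
    )


class TestClusterIntervals:
    def test_chained_overlaps_merge(self):
        ivs = [QueryInterval(1, 100), QueryInterval(90, 200), QueryInterval(400, 500)]
        clusters = cluster_intervals(ivs)
        assert [c.span for c in clusters] == [(1, 200), (400, 500)]

    def test_abutting_closed_intervals_do_not_merge(self):
        clusters = cluster_intervals([QueryInterval(1, 10), QueryInterval(11, 20)])
        assert [c.span for c in clusters] == [(1, 10), (11, 20)]

    def test_single_interval_single_cluster(self):
        assert [c.span for c in cluster_intervals([QueryInterval(5, 9)])] == [(5, 9)]

    def test_empty_input_empty_output(self):
        assert cluster_intervals([]) == []

    def test_agrees_with_union_find_oracle_on_random_instances(self):
        rng = np.random.default_rng(20240917)
        for _ in range(1000):
            n = int(rng.integers(1, 21))
            starts = rng.integers(1, 500, size=n)
            lengths = rng.integers(1, 120, size=n)
            spans = [(int(s), int(min(s + l, 500))) for s, l in zip(starts, lengths)]
            ivs = [QueryInterval(s, e) for s, e in spans]
            got = [c.span for c in cluster_intervals(ivs)]
            assert got == brute_force_clusters(spans)

    def test_more_shrinkage_never_reduces_cluster_count(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(2, 15))
            spans = [
                (int(s), int(s + l))
                for s, l in zip(rng.integers(1, 400, n), rng.integers(5, 150, n))
            ]
            ivs = [QueryInterval(s, e) for s, e in spans]
            counts = [
                len(cluster_intervals([shrink_interval(iv, f) for iv in ivs]))
                for f in (0.0, 0.1, 0.3, 0.6, 0.9)
            ]
            assert counts == sorted(counts)


class TestClusteringFilter:
    CFG = FilterConfig()

    def test_two_distant_groups_pass(self):
        hits = [
            make_hit("r", "T1", q_start=1, q_end=290, q_len=600),
            make_hit("r", "T2", q_start=310, q_end=600, q_len=600),
        ]
        passed, n, cov = clustering_filter(hits, 600, self.CFG)
        assert passed and n == 2
        assert cov == pytest.approx((290 + 291) / 600)

    def test_single_cluster_fails(self):
        hits = [
            make_hit("r", "T1", q_start=1, q_end=250, q_len=600),
            make_hit("r", "T2", q_start=20, q_end=240, q_len=600),
        ]
        passed, n, _ = clustering_filter(hits, 600, self.CFG)
        assert not passed and n == 1

    def test_exactly_half_total_coverage_fails(self):
        # two clusters but union covering exactly 50% is not enough (strict >)
        hits = [
            make_hit("r", "T1", q_start=1, q_end=250, q_len=1000),
            make_hit("r", "T2", q_start=401, q_end=650, q_len=1000),
        ]
        passed, n, cov = clustering_filter(hits, 1000, self.CFG)
        assert n == 2 and cov == 0.5 and not passed

    def test_coverage_uses_unshrunk_intervals(self):
        # shrunk intervals cover < 51% but original intervals just over
        hits = [
            make_hit("r", "T1", q_start=1, q_end=260, q_len=1000),
            make_hit("r", "T2", q_start=500, q_end=750, q_len=1000),
        ]
        passed, _, cov = clustering_filter(hits, 1000, self.CFG)
        assert cov == pytest.approx(0.511) and passed


class TestScan:
    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_planted_chimeras_recovered_exactly_for_each_k(self, k):
        cfg = SimulationConfig(
            seed=100 + k, n_genes=20, n_chimeras=4,
            component_count_weights={k: 1.0},
        )
        b = simulate(cfg)
        links = link_annotations(b.reference, b.alternate)
        calls = scan(b.reference, b.alternate, b.ref_hits, b.alt_hits, links)
        found = {c.ref_gene_id: c.cluster_count for c in calls if c.verdict == "candidate"}
        expected = {t.ref_gene_id: t.component_count for t in b.truth if t.is_chimera}
        assert found == expected

    def test_candidate_iff_all_filters_pass(self, bundle):
        links = link_annotations(bundle.reference, bundle.alternate)
        calls = scan(bundle.reference, bundle.alternate, bundle.ref_hits,
                     bundle.alt_hits, links)
        cfg = FilterConfig()
        for c in calls:
            cov_ok = (
                c.ref_median_cov is not None
                and c.alt_pooled_median_cov is not None
                and c.ref_median_cov < cfg.ref_median_cov_max
                and c.alt_pooled_median_cov > cfg.alt_median_cov_min
            )
            clu_ok = (
                c.cluster_count >= cfg.min_clusters
                and c.total_query_cov > cfg.min_total_query_cov
            )
            assert (c.verdict == "candidate") == (cov_ok and c.subset_ok and clu_ok)
            assert (c.verdict == "candidate") == (c.failed_filter == "none")

    def test_ordinary_gene_rejected_at_coverage(self, bundle):
        links = link_annotations(bundle.reference, bundle.alternate)
        calls = scan(bundle.reference, bundle.alternate, bundle.ref_hits,
                     bundle.alt_hits, links)
        normal = {t.ref_gene_id for t in bundle.truth if not t.is_chimera}
        for c in calls:
            if c.ref_gene_id in normal:
                assert c.verdict == "rejected"
                assert c.failed_filter == "coverage"  # median q_cov = 1.0

    def test_unknown_hit_query_is_consistency_error(self, bundle):
        from chimeraudit.errors import ConsistencyError
        from chimeraudit.homology import HitTable

        bad = HitTable(bundle.ref_hits.hits + [make_hit("ghost", "T1")])
        with pytest.raises(ConsistencyError, match="ghost"):
            scan(bundle.reference, bundle.alternate, bad, bundle.alt_hits, [])
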