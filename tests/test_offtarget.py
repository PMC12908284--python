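"""Hotspot clustering, off-target calling, translocation accounting, TSS profile."""

import numpy as np
import pandas as pd
import pytest

import editscope as es
from editscope.errors import ArgumentError

from conftest import make_records


def _transloc_records(positions, chrom="chr2"):
    return make_records([
        {"prey_chrom": chrom, "prey_pos": int(p), "prey_strand": "-"}
        for p in positions
    ])


def brute_force_single_linkage(records, min_junctions, window):
    """O(n^2) union-find oracle for hotspot clustering."""
    items = list(records[["prey_chrom", "prey_pos"]].itertuples(index=False))
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if items[i][0] == items[j][0] and abs(items[i][1] - items[j][1]) <= window:
                parent[find(i)] = find(j)
    sizes = {}
    for i in range(len(items)):
        sizes[find(i)] = sizes.get(find(i), 0) + 1
    return sorted(s for s in sizes.values() if s >= min_junctions)


class TestFindHotspots:
    def test_no_translocations_empty(self):
        assert es.find_hotspots(_transloc_records([])) == []

    def test_tight_cluster_is_one_candidate(self):
        rng = np.random.default_rng(1)
        records = _transloc_records(5_000 + rng.integers(0, 50, 10))
        candidates = es.find_hotspots(records, min_junctions=3)
        assert len(candidates) == 1 and candidates[0].count == 10

    def test_below_min_junctions_dropped(self):
        candidates = es.find_hotspots(_transloc_records([100, 150]), min_junctions=3)
        assert candidates == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        rows = []
        for chrom in ("chr1", "chr2", "chr3"):
            rows += [{"prey_chrom": chrom, "prey_pos": int(p)}
                     for p in rng.integers(0, 200_000, 70)]
        records = make_records(rows)
        candidates = es.find_hotspots(records, min_junctions=3, merge_window=100)
        oracle = brute_force_single_linkage(records, 3, 100)
        assert sorted(c.count for c in candidates) == oracle

    def test_center_is_lower_median(self):
        candidates = es.find_hotspots(_transloc_records([10, 20, 30, 40]),
                                      min_junctions=3)
        assert candidates[0].center == 20


class TestCallOfftargets:
    def _concentrated_cluster(self, site, n=30, jitter=2, rng=None):
        rng = rng or np.random.default_rng(0)
        return _transloc_records(site.nts_cut + rng.integers(-jitter, jitter + 1, n),
                                 chrom=site.chrom)

    @pytest.mark.parametrize("mismatches,expect_pass", [(3, True), (8, True),
                                                        (9, False)])
    def test_mismatch_filter_boundary(self, fresh_fixture, tnpb_spec,
                                      mismatches, expect_pass):
        fx = fresh_fixture(seed=41)
        sites = es.plant_sites(fx, tnpb_spec, 1, [mismatches])
        records = self._concentrated_cluster(sites[1])
        (cand,) = es.find_hotspots(records)
        (call,) = es.call_offtargets([cand], sites[0], tnpb_spec, fx)
        assert call.mismatches == mismatches
        assert call.pass_mismatch is expect_pass and call.passed is expect_pass
        assert call.pass_pattern

    def test_diffuse_junctions_fail_pattern_test(self, fresh_fixture, tnpb_spec):
        fx = fresh_fixture(seed=43)
        sites = es.plant_sites(fx, tnpb_spec, 1, [2])
        rng = np.random.default_rng(2)
        records = _transloc_records(
            sites[1].nts_cut + rng.integers(-500, 501, 40), chrom=sites[1].chrom)
        candidates = es.find_hotspots(records, merge_window=1_200)
        calls = es.call_offtargets(candidates, sites[0], tnpb_spec, fx)
        assert calls and not calls[0].pass_pattern and not calls[0].passed

    def test_minus_strand_off_target_found(self, fresh_fixture, tnpb_spec):
        fx = fresh_fixture(seed=47)
        sites = es.plant_sites(fx, tnpb_spec, 2, [0, 4])  # second site planted on '-'
        minus = sites[2]
        assert minus.strand == "-"
        records = self._concentrated_cluster(minus)
        (cand,) = es.find_hotspots(records)
        (call,) = es.call_offtargets([cand], sites[0], tnpb_spec, fx)
        assert call.strand == "-" and call.mismatches == 4 and call.passed

    def test_off_on_ratio_arithmetic(self, fresh_fixture, tnpb_spec):
        fx = fresh_fixture(seed=53)
        sites = es.plant_sites(fx, tnpb_spec, 1, [3])
        records = self._concentrated_cluster(sites[1], n=50)
        (cand,) = es.find_hotspots(records)
        (call,) = es.call_offtargets([cand], sites[0], tnpb_spec, fx,
                                     on_target_count=10_000)
        assert call.junction_count == 50
        assert call.off_on_percent == pytest.approx(0.5)

    def test_planted_recovery_no_spurious_calls(self, tnpb_spec):
        # background-free: every translocation routes to a planted off-target
        cfg = es.SimConfig(n_alleles=30_000, editing_prob=0.5, seed=71,
                           offtarget_fractions=(0.6, 0.4))
        run = es.run_site(tnpb_spec, cfg, fixture_seed=59, n_offtargets=2,
                          mismatch_counts=[3, 8])
        tr = run.dedup.loc[(run.calls["event_class"] == "translocation").to_numpy()]
        calls = es.call_offtargets(es.find_hotspots(tr), run.site, tnpb_spec,
                                   run.fixture)
        passed = [c for c in calls if c.passed]
        planted = {(s.chrom, s.cut_mid) for s in run.sites[1:]}
        assert len(passed) == 2
        for c in passed:
            assert any(c.chrom == chrom and abs(c.center - cut) <= 1_000
                       for chrom, cut in planted)
        assert sorted(c.mismatches for c in passed) == [3, 8]


class TestTranslocationSummary:
    def test_partition_is_exact_on_simulation(self, simulated_run):
        run = simulated_run
        tr = run.dedup.loc[(run.calls["event_class"] == "translocation").to_numpy()]
        on = es.on_target_junction_count(run.calls, run.dedup, run.site)
        offtargets = es.call_offtargets(
            es.find_hotspots(tr), run.site, run.spec, run.fixture,
            translocations=tr, on_target_count=on)
        summary = es.translocation_summary(run.calls, run.dedup, run.site,
                                           offtargets, run.fixture)
        assert summary.check_partition()
        assert summary.total == len(tr)
        assert sum(c.sum() for c in summary.bins_2mb.values()) == summary.total

    def test_all_near_target_means_no_general(self, fixture_small, tnpb_site):
        calls = pd.DataFrame({"event_class": ["translocation"] * 4 + ["deletion"]})
        records = make_records(
            [{"prey_chrom": tnpb_site.chrom, "prey_pos": tnpb_site.cut_mid + d,
              "prey_strand": "-"} for d in (-40_000, -100, 5, 20_000)]
            + [{"prey_pos": tnpb_site.cut_mid + 10}])
        summary = es.translocation_summary(calls, records, tnpb_site, [],
                                           fixture_small)
        assert summary.general == 0 and summary.near_target == 4

    def test_general_fraction_recovers_configured_rate(self, tnpb_spec):
        # all translocations are background on other chromosomes -> general
        p_tr = 0.03
        weights = {"deletion": 0.92, "insertion": 0.05, "translocation": p_tr,
                   "plasmid_integration": 0.0, "mito_integration": 0.0}
        cfg = es.SimConfig(n_alleles=50_000, editing_prob=0.5, seed=83,
                           event_weights=weights, tss_bias=0.0)
        run = es.run_site(tnpb_spec, cfg, fixture_seed=61)
        summary = es.translocation_summary(run.calls, run.dedup, run.site, [],
                                           run.fixture)
        n = summary.n_editing
        estimate = summary.general + summary.near_target  # chr1 backgrounds stay translocations
        assert abs(estimate - n * p_tr) <= 3 * np.sqrt(n * p_tr * (1 - p_tr))


def _tss_central_prob(fixture, half=500):
    """Exact uniform-background probability of landing within ``half`` bp of a
    TSS: interval-union length over genome length."""
    covered = 0
    for chrom, tss in fixture.tss.items():
        length = fixture.chrom_lengths[chrom]
        intervals = [(max(0, t - half), min(length, t + half)) for t in tss]
        last_end = -1
        for a, b in sorted(intervals):
            covered += max(0, b - max(a, last_end))
            last_end = max(last_end, b)
    return covered / sum(fixture.chrom_lengths.values())


class TestTssProfile:
    def test_junctions_exactly_at_tss_fill_central_bin(self, fixture_small):
        positions = fixture_small.tss["chr2"][:5]
        profile = es.tss_profile(_transloc_records(positions), fixture_small)
        central = profile.loc[(profile["bin_start"] == 0), "count"].iloc[0]
        assert central == 5 and profile["count"].sum() == 5

    def test_unbiased_background_consistent_with_uniform(self, tnpb_spec):
        cfg = es.SimConfig(n_alleles=40_000, editing_prob=0.5, seed=89,
                           tss_bias=0.0)
        run = es.run_site(tnpb_spec, cfg, fixture_seed=67)
        tr = run.dedup.loc[(run.calls["event_class"] == "translocation").to_numpy()]
        profile = es.tss_profile(tr, run.fixture, window=2_000, bin_size=100)
        n_tr = len(tr)
        p_central = _tss_central_prob(run.fixture)
        central = profile.loc[(profile["bin_start"] >= -500)
                              & (profile["bin_end"] <= 500), "count"].sum()
        assert abs(central - n_tr * p_central) <= \
            3 * np.sqrt(n_tr * p_central * (1 - p_central))

    def test_biased_background_enriched_near_tss(self, tnpb_spec):
        cfg = es.SimConfig(n_alleles=40_000, editing_prob=0.5, seed=91,
                           tss_bias=0.3)
        run = es.run_site(tnpb_spec, cfg, fixture_seed=67)
        tr = run.dedup.loc[(run.calls["event_class"] == "translocation").to_numpy()]
        profile = es.tss_profile(tr, run.fixture, window=2_000, bin_size=100)
        n_tr = len(tr)
        uniform_expect = n_tr * _tss_central_prob(run.fixture)
        central = profile.loc[(profile["bin_start"] >= -500)
                              & (profile["bin_end"] <= 500), "count"].sum()
        assert central > uniform_expect

    def test_missing_tss_annotation_rejected(self, fixture_small):
        bare = es.GenomeFixture(fixture_small.chromosomes, {"chr1": []},
                                fixture_small.plasmid, fixture_small.mito, 0)
        with pytest.raises(ArgumentError):
            es.tss_profile(_transloc_records([100]), bare)
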