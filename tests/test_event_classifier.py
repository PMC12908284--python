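"""Junction taxonomy, editing summaries, integration profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import editscope as es
from editscope.errors import ArgumentError, ValidationError

from conftest import make_records


def classify(rows, site, fixture, **kw):
    return es.classify_junctions(make_records(rows), site, fixture, **kw)


class TestClassifyJunction:
    def test_gap_is_deletion_with_stated_length(self, fixture_small, tnpb_site):
        calls = classify([{"bait_end": 1_000, "prey_pos": 1_037}],
                         tnpb_site, fixture_small)
        assert calls.loc[0, "event_class"] == "deletion"
        assert calls.loc[0, "del_len"] == 37
        assert (calls.loc[0, "del_start"], calls.loc[0, "del_end"]) == (1_000, 1_037)

    def test_leftward_bait_deletes_upstream(self, fixture_small, tnpb_site):
        calls = classify([{"bait_strand": "-", "prey_strand": "-",
                           "bait_end": 1_037, "prey_pos": 1_000}],
                         tnpb_site, fixture_small)
        assert calls.loc[0, "event_class"] == "deletion"
        assert calls.loc[0, "del_len"] == 37

    def test_other_chromosome_is_translocation(self, fixture_small, tnpb_site):
        calls = classify([{"prey_chrom": "chr2", "prey_pos": 5_000}],
                         tnpb_site, fixture_small)
        assert calls.loc[0, "event_class"] == "translocation"

    def test_strand_inversion_is_translocation(self, fixture_small, tnpb_site):
        calls = classify([{"bait_end": 1_000, "prey_pos": 1_050, "prey_strand": "-"}],
                         tnpb_site, fixture_small)
        assert calls.loc[0, "event_class"] == "translocation"

    def test_plasmid_substring_insert_is_integration(self, fixture_small, tnpb_site):
        insert = fixture_small.plasmid[500:530]  # 30-nt exact plasmid substring
        assert insert in fixture_small.plasmid  # oracle: exact substring search
        calls = classify([{"bait_end": 1_000, "prey_pos": 1_000, "insert_seq": insert}],
                         tnpb_site, fixture_small)
        assert calls.loc[0, "event_class"] == "plasmid_integration"
        assert calls.loc[0, "integ_pos"] == 500

    def test_short_insert_stays_insertion(self, fixture_small, tnpb_site):
        insert = fixture_small.plasmid[500:512]  # 12 nt: below match threshold
        calls = classify([{"bait_end": 1_000, "prey_pos": 1_000, "insert_seq": insert}],
                         tnpb_site, fixture_small)
        assert calls.loc[0, "event_class"] == "insertion"
        assert calls.loc[0, "ins_len"] == 12

    def test_prey_on_episome_is_integration(self, fixture_small, tnpb_site):
        calls = classify([{"prey_source": "mito", "prey_chrom": ".", "prey_pos": 77}],
                         tnpb_site, fixture_small)
        assert calls.loc[0, "event_class"] == "mito_integration"
        assert calls.loc[0, "integ_pos"] == 77

    @pytest.mark.parametrize("gap,ins,expected", [
        (10, 3, "deletion"),    # larger gap wins
        (3, 10, "insertion"),   # larger insertion wins
        (5, 5, "deletion"),     # tie goes to deletion
    ])
    def test_mixed_junctions_classed_by_larger_component(
            self, fixture_small, tnpb_site, gap, ins, expected):
        calls = classify([{"bait_end": 1_000, "prey_pos": 1_000 + gap,
                           "insert_seq": "A" * ins}], tnpb_site, fixture_small)
        assert calls.loc[0, "event_class"] == expected
        assert calls.loc[0, "del_len"] == gap and calls.loc[0, "ins_len"] == ins

    def test_contiguous_no_insert_is_germline(self, fixture_small, tnpb_site):
        calls = classify([{"bait_end": 1_000, "prey_pos": 1_000}],
                         tnpb_site, fixture_small)
        assert calls.loc[0, "event_class"] == "germline"

    def test_distant_same_strand_same_chrom_needs_big_chromosome(self, tnpb_site):
        big = es.build_fixture(seed=3, n_chromosomes=1, chromosome_length=1_200_000,
                               n_tss=5)
        calls = classify([{"bait_end": 1_000, "prey_pos": 900_000}], tnpb_site, big)
        assert calls.loc[0, "event_class"] == "translocation"

    def test_unknown_chromosome_raises(self, fixture_small, tnpb_site):
        with pytest.raises(ValidationError):
            classify([{"prey_chrom": "chr9"}], tnpb_site, fixture_small)

    def test_single_record_wrapper(self, fixture_small, tnpb_site):
        rec = make_records([{"bait_end": 10, "prey_pos": 60}]).iloc[0]
        call = es.classify_junction(rec, tnpb_site, fixture_small)
        assert call["event_class"] == "deletion" and call["del_len"] == 50


class TestOracleEquivalence:
    def test_noise_free_simulation_matches_truth(self, tnpb_spec):
        cfg = es.SimConfig(n_alleles=8_000, editing_prob=0.5, p_at_cut=1.0,
                           seed=17, offtarget_fractions=(0.2,))
        run = es.run_site(tnpb_spec, cfg, fixture_seed=19,
                          n_offtargets=1, mismatch_counts=[4])
        merged = run.dedup.assign(pred=run.calls["event_class"].to_numpy()) \
            .merge(run.truth[["rmb", "event_class"]], on="rmb")
        assert (merged["pred"] == merged["event_class"]).mean() >= 0.999

    def test_every_junction_gets_exactly_one_class(self, simulated_run):
        counts = simulated_run.calls["event_class"].value_counts()
        assert counts.sum() == len(simulated_run.dedup)
        assert set(counts.index) <= set(es.event_classifier.EVENT_ORDER)


class TestSummarizeEvents:
    @staticmethod
    def _calls_from_counts(dels=0, ins=0, tr=0, germ=0, del_lens=(), ins_lens=()):
        rows = []
        del_lens = list(del_lens) or [10] * dels
        ins_lens = list(ins_lens) or [2] * ins
        rows += [{"event_class": "deletion", "del_len": l, "ins_len": 0}
                 for l in del_lens]
        rows += [{"event_class": "insertion", "del_len": 0, "ins_len": l}
                 for l in ins_lens]
        rows += [{"event_class": "translocation", "del_len": 0, "ins_len": 0}] * tr
        rows += [{"event_class": "germline", "del_len": 0, "ins_len": 0}] * germ
        return pd.DataFrame(rows)

    def test_editing_efficiency_definition(self):
        calls = self._calls_from_counts(dels=60, ins=30, tr=10, germ=900)
        s = es.summarize_events(calls, total_alleles=1_000)
        assert s.editing_efficiency == pytest.approx(0.10)
        assert s.n_editing == 100

    def test_class_fractions_sum_to_one(self, simulated_run):
        s = es.summarize_events(simulated_run.calls, len(simulated_run.dedup))
        assert sum(s.class_fractions.values()) == pytest.approx(1.0)

    def test_small_large_split_exactly_at_100(self):
        calls = self._calls_from_counts(del_lens=[100, 101], germ=10)
        s = es.summarize_events(calls, total_alleles=12)
        assert (s.small_deletions, s.large_deletions) == (1, 1)
        assert s.median_large_deletion_bp == 101

    def test_insertion_length_bins(self):
        calls = self._calls_from_counts(ins_lens=[1, 5, 30, 41])
        s = es.summarize_events(calls, total_alleles=4)
        assert s.insertion_length_bins == {"1": 1, "2-25": 1, "25-40": 1, ">40": 1}
        assert s.insertion_small_large == {"<=20": 2, ">20": 2}

    def test_denominator_discipline(self):
        # editing-event fractions never use total alleles, and vice versa
        calls = self._calls_from_counts(dels=40, ins=10, germ=950,
                                        del_lens=[50] * 30 + [200] * 10)
        s = es.summarize_events(calls, total_alleles=1_000)
        n_edit = 50
        assert s.editing_efficiency == pytest.approx(n_edit / 1_000)
        assert s.class_fractions["deletion"] == pytest.approx(40 / n_edit)
        assert s.large_deletion_fraction == pytest.approx(10 / n_edit)

    def test_zero_alleles_rejected(self):
        with pytest.raises(ArgumentError):
            es.summarize_events(self._calls_from_counts(germ=1), total_alleles=0)


class TestIntegrationProfile:
    @staticmethod
    def _frame(n_del, n_plasmid, positions, n_mito=0):
        rows = [{"event_class": "deletion", "integ_pos": -1, "integ_source": "."}] * n_del
        rows += [{"event_class": "plasmid_integration", "integ_pos": p,
                  "integ_source": "plasmid"} for p in positions]
        rows += [{"event_class": "mito_integration", "integ_pos": 5,
                  "integ_source": "mito"}] * n_mito
        calls = pd.DataFrame(rows)
        records = make_records([{}] * len(calls))
        return calls, records

    def test_rate_per_100k_indels(self, fixture_small):
        calls, records = self._frame(70_000, 35, positions=[0] * 35)
        summary = es.integration_profile(calls, records, fixture_small)
        assert summary.plasmid_per_100k == pytest.approx(50.0)

    def test_no_integrations_zero_histogram(self, fixture_small):
        calls, records = self._frame(100, 0, positions=[])
        summary = es.integration_profile(calls, records, fixture_small)
        assert summary.plasmid_per_100k == 0.0
        assert np.all(summary.plasmid_hist == 0)

    def test_zero_indels_rates_not_applicable(self, fixture_small):
        calls, records = self._frame(0, 3, positions=[1, 2, 3])
        summary = es.integration_profile(calls, records, fixture_small)
        assert summary.plasmid_per_100k is None and summary.mito_per_100k is None

    def test_histogram_total_matches_normalized_count(self, fixture_small):
        calls, records = self._frame(5_000, 40, positions=list(range(0, 8_000, 200)))
        summary = es.integration_profile(calls, records, fixture_small)
        assert summary.plasmid_hist.sum() == pytest.approx(summary.plasmid_per_100k)

    def test_uniform_positions_pass_chi_square(self, fixture_small):
        rng = np.random.default_rng(42)
        positions = rng.integers(0, len(fixture_small.plasmid), 2_000)
        calls, records = self._frame(10_000, len(positions), positions=list(positions))
        summary = es.integration_profile(calls, records, fixture_small)
        res = stats.chisquare(summary.plasmid_hist_counts)
        assert res.pvalue > 0.01

    def test_planted_hot_bin_is_flagged(self, fixture_small):
        positions = [250] * 30 + list(range(0, 8_000, 400))
        calls, records = self._frame(1_000, len(positions), positions=positions)
        summary = es.integration_profile(calls, records, fixture_small)
        assert (200, 300) in summary.enriched_bins
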