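"""End-to-end convenience pipelines over the module-level operations.

These glue functions exist so the analysis drivers and validation scripts run
the same code path: simulate a bait library, deduplicate, classify, profile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .cleavage_profiler import CutModelEstimate, broken_end_profile, infer_cut_sites
from .event_classifier import classify_junctions, summarize_events
from .junction_io import dedup_junctions
from .nucleases import NucleaseSpec
from .synthetic_data import (
    GenomeFixture,
    SimConfig,
    TargetSite,
    build_fixture,
    plant_sites,
    simulate_library,
)


@dataclass
class SiteRun:
    """One simulated bait library taken through dedup and classification."""

    fixture: GenomeFixture
    sites: list[TargetSite]
    spec: NucleaseSpec
    config: SimConfig
    truth: pd.DataFrame
    records: pd.DataFrame      # raw reads
    dedup: pd.DataFrame        # one row per molecule
    calls: pd.DataFrame        # aligned 1:1 with dedup

    @property
    def site(self) -> TargetSite:
        return self.sites[0]

    @property
    def edited(self) -> pd.DataFrame:
        return self.dedup.loc[(self.calls["event_class"] != "germline").to_numpy()]


def run_site(
    spec: NucleaseSpec,
    config: SimConfig,
    *,
    fixture_seed: int = 1,
    fixture: GenomeFixture | None = None,
    n_offtargets: int = 0,
    mismatch_counts: list[int] | None = None,
    activities: list[float] | None = None,
) -> SiteRun:
    """Simulate one site's library and classify it."""
    if fixture is None:
        fixture = build_fixture(seed=fixture_seed)
    sites = plant_sites(fixture, spec, n_offtargets, mismatch_counts or [],
                        activities=activities)
    truth, records = simulate_library(fixture, sites, spec, config)
    dedup = dedup_junctions(records).reset_index(drop=True)
    calls = classify_junctions(dedup, sites[0], fixture)
    return SiteRun(fixture, sites, spec, config, truth, records, dedup, calls)


def estimate_cut_model(
    spec: NucleaseSpec,
    seed: int,
    n_junctions: int = 10_000,
    config: SimConfig | None = None,
) -> CutModelEstimate:
    """Simulate ``n_junctions`` edited, deduplicated junctions and infer the
    nuclease's cut model from the two strand-resolved broken-end profiles."""
    config = config or SimConfig()
    config = replace(config, n_alleles=n_junctions, editing_prob=1.0,
                     dup_mean=1.0, seed=seed)
    run = run_site(spec, config, fixture_seed=seed)
    profile_nts = broken_end_profile(run.edited, run.site, "non-target")
    profile_ts = broken_end_profile(run.edited, run.site, "target")
    return infer_cut_sites(profile_nts, profile_ts, spec)


def editing_summary_for(run: SiteRun):
    return summarize_events(run.calls, total_alleles=len(run.dedup))
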