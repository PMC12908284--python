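import numpy as np
import pandas as pd
import pytest

import editscope as es


@pytest.fixture(scope="session")
def fixture_small():
    return es.build_fixture(seed=11, n_chromosomes=3, chromosome_length=60_000,
                            n_tss=20, plasmid_length=8_000, mt_length=16_569)


@pytest.fixture(scope="session")
def tnpb_spec():
    return es.get_spec("ISYmu1")


@pytest.fixture(scope="session")
def cas9_spec():
    return es.get_spec("SpCas9")


@pytest.fixture(scope="session")
def tnpb_site(fixture_small, tnpb_spec):
    """On-target only, planted on a copy-free fixture (session-shared)."""
    sites = es.plant_sites(fixture_small, tnpb_spec, 0, [])
    return sites[0]


@pytest.fixture()
def fresh_fixture():
    """Per-test fixture safe to plant into (plant_sites edits in place)."""
    def _make(seed=21, **kw):
        kw.setdefault("chromosome_length", 60_000)
        kw.setdefault("n_tss", 20)
        return es.build_fixture(seed=seed, **kw)
    return _make


def make_records(rows):
    """Build a junction-record table from dicts, filling defaults."""
    defaults = dict(
        read_id="r0", rmb="A" * 14, bait_chrom="chr1", bait_strand="+",
        bait_end=0, prey_source="genome", prey_chrom="chr1", prey_pos=0,
        prey_strand="+", insert_seq="",
    )
    out = []
    for i, row in enumerate(rows):
        d = defaults | row
        if "read_id" not in row:
            d["read_id"] = f"r{i:04d}"
        out.append(d)
    return pd.DataFrame(out, columns=list(defaults))


@pytest.fixture(scope="session")
def record_builder():
    return make_records


@pytest.fixture(scope="session")
def simulated_run(tnpb_spec):
    """A mid-size noisy library shared by read-only tests."""
    cfg = es.SimConfig(n_alleles=20_000, editing_prob=0.4, seed=101,
                       offtarget_fractions=(0.1, 0.05))
    return es.run_site(tnpb_spec, cfg, fixture_seed=31, n_offtargets=2,
                       mismatch_counts=[3, 6])
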