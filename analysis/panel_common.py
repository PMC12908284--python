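"""Shared plumbing for the numbered panel-analysis drivers.

Each nuclease's simulated experiment is fully determined by the study seed:
driver 01 writes the deduplicated junction tables, and later drivers
reconstruct the identical fixture and planted sites from the same seeds
instead of re-serializing sequences.
"""

from pathlib import Path

import editscope as es

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

PANEL_ORDER = list(es.CONDITIONS)


def nuclease_seeds(seed: int, name: str) -> tuple[int, int]:
    """(fixture seed, simulation seed) for one nuclease, derived from the study seed."""
    idx = PANEL_ORDER.index(name)
    base = (seed * 1_000 + idx) % (2**31)
    return base, (base + 500_000_000) % (2**31)


def panel_inputs(name: str, seed: int):
    """Rebuild (condition, spec, fixture, sites) for one nuclease."""
    condition = es.CONDITIONS[name]
    fixture_seed, _ = nuclease_seeds(seed, name)
    fixture = es.build_fixture(seed=fixture_seed)
    sites = es.plant_sites(
        fixture, condition.spec, condition.n_offtargets,
        list(condition.mismatch_counts),
        activities=list(condition.offtarget_fractions),
    )
    return condition, condition.spec, fixture, sites


def junction_path(outdir: Path, name: str) -> Path:
    return Path(outdir) / f"{name}.junctions.tsv"
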