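#!/usr/bin/env python
"""Simulate the eight-nuclease panel: one bait library per system.

Each nuclease gets its own fixture genome with an on-target site and its
planted off-targets, then a junction library at the study conditions
(editing efficiency, event mix, off-target routing) for that system.
Writes per-nuclease deduplicated junction tables plus the raw read counts.

    python analysis/01_simulate_panel.py --seed 1 [--n-alleles 50000]
"""

import argparse
from pathlib import Path

import editscope as es
from panel_common import RESULTS, PANEL_ORDER, junction_path, nuclease_seeds, panel_inputs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-alleles", type=int, default=50_000)
    ap.add_argument("--outdir", type=Path, default=RESULTS / "panel")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    print(f"simulating {len(PANEL_ORDER)} nucleases, {args.n_alleles} alleles each")
    for name in PANEL_ORDER:
        condition, spec, fixture, sites = panel_inputs(name, args.seed)
        _, sim_seed = nuclease_seeds(args.seed, name)
        config = condition.sim_config(n_alleles=args.n_alleles, seed=sim_seed)
        truth, records = es.simulate_library(fixture, sites, spec, config)
        dedup = es.dedup_junctions(records)
        es.write_junctions(dedup, junction_path(args.outdir, name))
        edited = (truth["event_class"] != "germline").mean()
        print(f"  {name:11s} reads={len(records):7d} molecules={len(dedup):6d} "
              f"edited={edited:6.1%} offtargets={condition.n_offtargets}")
    print(f"junction tables in {args.outdir}")


if __name__ == "__main__":
    main()
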