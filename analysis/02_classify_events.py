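#!/usr/bin/env python
"""Classify every junction and tabulate per-nuclease editing outcomes.

Reads the junction tables from driver 01, labels each molecule (deletion /
insertion / translocation / plasmid or mtDNA integration / germline), and
writes the editing summary (efficiency, event-class shares, deletion size
classes, insertion length bins) and the integration rates per 100k indels.

    python analysis/02_classify_events.py --seed 1
"""

import argparse
from pathlib import Path

import pandas as pd

import editscope as es
from panel_common import RESULTS, PANEL_ORDER, junction_path, panel_inputs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=RESULTS)
    ap.add_argument("--paneldir", type=Path, default=RESULTS / "panel")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    editing_rows, integ_rows = [], []
    for name in PANEL_ORDER:
        _, spec, fixture, sites = panel_inputs(name, args.seed)
        dedup = es.load_junctions(junction_path(args.paneldir, name), fixture=fixture)
        calls = es.classify_junctions(dedup, sites[0], fixture)
        s = es.summarize_events(calls, total_alleles=len(dedup))
        integ = es.integration_profile(calls, dedup, fixture)
        editing_rows.append({
            "nuclease": name,
            "alleles": s.total_alleles,
            "editing_efficiency_pct": 100 * s.editing_efficiency,
            "deletion_pct_of_editing": 100 * s.class_fractions["deletion"],
            "insertion_pct_of_editing": 100 * s.class_fractions["insertion"],
            "translocation_pct_of_editing": 100 * s.class_fractions["translocation"],
            "large_deletion_pct_of_editing": 100 * s.large_deletion_fraction,
            "median_large_deletion_bp": s.median_large_deletion_bp,
            "ins_1bp": s.insertion_length_bins["1"],
            "ins_2_25bp": s.insertion_length_bins["2-25"],
            "ins_25_40bp": s.insertion_length_bins["25-40"],
            "ins_gt40bp": s.insertion_length_bins[">40"],
        })
        integ_rows.append({
            "nuclease": name,
            "indels": integ.n_indels,
            "plasmid_per_100k_indels": integ.plasmid_per_100k,
            "mito_per_100k_indels": integ.mito_per_100k,
            "enriched_plasmid_bins": len(integ.enriched_bins),
        })
        print(f"  {name:11s} efficiency={s.editing_efficiency:6.1%} "
              f"del={s.class_fractions['deletion']:5.1%} "
              f"plasmid/100k={integ.plasmid_per_100k:8.1f}")

    editing = pd.DataFrame(editing_rows)
    integ = pd.DataFrame(integ_rows)
    editing.to_csv(args.outdir / "editing_summary.tsv", sep="\t", index=False)
    integ.to_csv(args.outdir / "integration_rates.tsv", sep="\t", index=False)
    print(f"wrote {args.outdir / 'editing_summary.tsv'} and integration_rates.tsv")


if __name__ == "__main__":
    main()
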