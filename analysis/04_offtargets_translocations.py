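#!/usr/bin/env python
"""Call off-targets from translocation hotspots and account for translocations.

Clusters each nuclease's translocation prey junctions, calls off-target sites
(<= 8 mismatches to the on-target over protospacer+motif, cut-site junction
pattern), partitions translocations into near-target / off-target / general,
and profiles general-translocation positions around TSSs.

    python analysis/04_offtargets_translocations.py --seed 1
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

    ot_rows, tr_rows, tss_frames = [], [], []
    for name in PANEL_ORDER:
        _, spec, fixture, sites = panel_inputs(name, args.seed)
        site = sites[0]
        dedup = es.load_junctions(junction_path(args.paneldir, name), fixture=fixture)
        calls = es.classify_junctions(dedup, site, fixture)
        tr = dedup.loc[(calls["event_class"] == "translocation").to_numpy()]
        on = es.on_target_junction_count(calls, dedup, site)
        offtargets = es.call_offtargets(
            es.find_hotspots(tr), site, spec, fixture,
            translocations=tr, on_target_count=on)
        for i, c in enumerate(c for c in offtargets if c.passed):
            ot_rows.append({
                "nuclease": name, "offtarget": f"OT{i + 1}", "chrom": c.chrom,
                "position": c.center, "strand": c.strand, "sequence": c.sequence,
                "mismatches": c.mismatches, "junctions": c.junction_count,
                "off_on_percent": round(c.off_on_percent, 4),
                "motif_present": c.motif_present,
            })
        summary = es.translocation_summary(calls, dedup, site, offtargets, fixture)
        assert summary.check_partition()
        tr_rows.append({
            "nuclease": name,
            "translocation_junctions": summary.total,
            "near_target_500kb": summary.near_target,
            "offtarget_junctions": summary.offtarget_total,
            "general_translocations": summary.general,
            "general_pct_of_editing": round(summary.general_percent_of_editing, 3),
            "mean_off_on_percent": (round(summary.mean_off_on_percent, 4)
                                    if summary.mean_off_on_percent is not None else None),
            "called_offtargets": len([c for c in offtargets if c.passed]),
        })
        # TSS profile over junctions not attributable to target or off-targets
        excluded = {c.chrom for c in offtargets if c.passed}
        general = tr.loc[[
            not ((row.prey_chrom == site.chrom
                  and abs(row.prey_pos - site.cut_mid) <= 500_000)
                 or any(c.chrom == row.prey_chrom and abs(row.prey_pos - c.center) <= 100
                        for c in offtargets if c.passed))
            for row in tr.itertuples()
        ]]
        hist = es.tss_profile(general, fixture)
        hist.insert(0, "nuclease", name)
        tss_frames.append(hist)
        print(f"  {name:11s} offtargets={tr_rows[-1]['called_offtargets']} "
              f"general={summary.general_percent_of_editing:5.2f}% of editing")

    pd.DataFrame(ot_rows).to_csv(args.outdir / "offtargets.tsv", sep="\t", index=False)
    pd.DataFrame(tr_rows).to_csv(args.outdir / "translocations.tsv", sep="\t", index=False)
    pd.concat(tss_frames).to_csv(args.outdir / "tss_profiles.tsv", sep="\t", index=False)
    print(f"wrote offtargets.tsv, translocations.tsv, tss_profiles.tsv in {args.outdir}")


if __name__ == "__main__":
    main()
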