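#!/usr/bin/env python
"""Build the six-dimension scorecards (A, D, S, P, T, L) for the panel.

Re-derives every dimension from the junction tables (rather than trusting the
intermediate TSVs) and min-max normalizes across the eight systems; writes the
scorecard table with both raw and normalized values.

    python analysis/05_score_panel.py --seed 1
"""

import argparse
from pathlib import Path

import pandas as pd

import editscope as es
from editscope.scoring import DIMENSIONS, NucleasePanelEntry
from panel_common import RESULTS, PANEL_ORDER, junction_path, panel_inputs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=RESULTS)
    ap.add_argument("--paneldir", type=Path, default=RESULTS / "panel")
    ap.add_argument("--specificity", choices=["off_on_ratio", "on_target_proportion"],
                    default="off_on_ratio")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    panel: dict[str, NucleasePanelEntry] = {}
    for name in PANEL_ORDER:
        _, spec, fixture, sites = panel_inputs(name, args.seed)
        site = sites[0]
        dedup = es.load_junctions(junction_path(args.paneldir, name), fixture=fixture)
        calls = es.classify_junctions(dedup, site, fixture)
        editing = es.summarize_events(calls, total_alleles=len(dedup))
        integ = es.integration_profile(calls, dedup, fixture)
        tr = dedup.loc[(calls["event_class"] == "translocation").to_numpy()]
        on = es.on_target_junction_count(calls, dedup, site)
        offtargets = es.call_offtargets(
            es.find_hotspots(tr), site, spec, fixture,
            translocations=tr, on_target_count=on)
        summary = es.translocation_summary(calls, dedup, site, offtargets, fixture)
        panel[name] = NucleasePanelEntry(
            spec=spec, editing=[editing], integration=[integ],
            translocation=[summary],
            off_on_percents=[c.off_on_percent for c in offtargets
                             if c.passed and c.off_on_percent is not None],
        )

    cards = es.radar_scores(panel, specificity=args.specificity)
    rows = []
    for card in cards:
        row = {"nuclease": card.name}
        row |= {f"{d}_score": round(card.scores[d], 3) for d in DIMENSIONS}
        row |= {f"{d}_raw": card.raw[d] for d in DIMENSIONS}
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(args.outdir / "scorecards.tsv", sep="\t", index=False)
    print(table[["nuclease"] + [f"{d}_score" for d in DIMENSIONS]].to_string(index=False))
    print(f"wrote {args.outdir / 'scorecards.tsv'}")


if __name__ == "__main__":
    main()
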