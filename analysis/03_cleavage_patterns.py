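#!/usr/bin/env python
"""Infer each nuclease's cleavage pattern from bait broken-end distributions.

For each system, builds the target- and non-target-strand broken-end profiles
from the edited molecules and infers modal cut offsets, overhang length and
blunt/staggered character; writes the cut-model table and the per-offset
profiles.

    python analysis/03_cleavage_patterns.py --seed 1
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

    rows, profile_frames = [], []
    for name in PANEL_ORDER:
        _, spec, fixture, sites = panel_inputs(name, args.seed)
        site = sites[0]
        dedup = es.load_junctions(junction_path(args.paneldir, name), fixture=fixture)
        calls = es.classify_junctions(dedup, site, fixture)
        edited = dedup.loc[(calls["event_class"] != "germline").to_numpy()]
        p_nts = es.broken_end_profile(edited, site, "non-target")
        p_ts = es.broken_end_profile(edited, site, "target")
        est = es.infer_cut_sites(p_nts, p_ts, spec)
        rows.append({
            "nuclease": name,
            "motif": spec.motif,
            "motif_side": spec.motif_side,
            "nts_offset": est.nts_offset,
            "ts_offset": est.ts_offset,
            "ts_offset_past_guide": est.ts_offset - spec.guide_nt
            if spec.motif_side == "5prime" else None,
            "overhang_nt": est.overhang_nt,
            "blunt": est.blunt,
            "nts_modal_mass": round(est.nts_modal_mass, 4),
            "ts_modal_mass": round(est.ts_modal_mass, 4),
        })
        for p in (p_nts, p_ts, es.deletion_position_profile(calls, site)):
            frame = p.to_frame()
            frame.insert(0, "nuclease", name)
            profile_frames.append(frame)
        kind = "blunt" if est.blunt else f"{est.overhang_nt}-nt overhang"
        print(f"  {name:11s} NTS={est.nts_offset:>3} TS={est.ts_offset:>3} ({kind})")

    pd.DataFrame(rows).to_csv(args.outdir / "cut_models.tsv", sep="\t", index=False)
    pd.concat(profile_frames).to_csv(args.outdir / "position_profiles.tsv",
                                     sep="\t", index=False)
    print(f"wrote {args.outdir / 'cut_models.tsv'} and position_profiles.tsv")


if __name__ == "__main__":
    main()
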