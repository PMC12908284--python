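"""Off-target calling from translocation hotspots, and translocation accounting.

Off-target DSBs are visible in a PEM-seq library as clusters of translocation
prey junctions. The caller (i) clusters genomic prey coordinates by
single-linkage within a merge window, (ii) scans each cluster's neighbourhood
for the best protospacer+motif match to the on-target (minimum Hamming
distance over both strands, motif positions included), and (iii) accepts a
candidate as an off-target when the distance is at most 8 mismatches and the
cluster shows a cut-site junction pattern (at least half of its junctions
within +/-10 bp of the motif-implied cut). Off-target strength is the ratio of
junctions within +/-100 bp of the off-target to junctions within +/-100 bp of
the on-target.

General translocations are the remainder once junctions within +/-500 kb of
the target and off-target junctions are excluded — the genome-integrity
readout. Their genome-wide distribution is summarized in 2-Mb bins, and their
positions relative to transcription start sites in a signed-distance
histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .nucleases import NucleaseSpec, matches_iupac, revcomp
from .synthetic_data import GenomeFixture, TargetSite, site_from_span


@dataclass
class HotspotCandidate:
    chrom: str
    center: int
    count: int
    positions: np.ndarray


@dataclass
class OfftargetCall:
    chrom: str
    center: int
    strand: str
    sequence: str          # best-matching protospacer+motif, guide orientation
    mismatches: int
    junction_count: int    # junctions within +/-100 bp
    off_on_percent: float | None
    predicted_cut: int
    pass_mismatch: bool
    pass_pattern: bool
    motif_present: bool

    @property
    def passed(self) -> bool:
        return self.pass_mismatch and self.pass_pattern


def find_hotspots(
    translocations: pd.DataFrame,
    min_junctions: int = 3,
    merge_window: int = 100,
) -> list[HotspotCandidate]:
    """Single-linkage clustering of genomic prey coordinates.

    Prey positions on the same chromosome whose consecutive gaps are at most
    ``merge_window`` form one cluster; clusters with at least ``min_junctions``
    are returned, centered on the (lower) median coordinate, sorted by
    junction count descending.
    """
    out: list[HotspotCandidate] = []
    genomic = translocations.loc[translocations["prey_source"] == "genome"]
    for chrom, grp in genomic.groupby("prey_chrom"):
        pos = np.sort(grp["prey_pos"].to_numpy())
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > merge_window)
        for cluster in np.split(pos, breaks + 1):
            if cluster.size >= min_junctions:
                center = int(cluster[(cluster.size - 1) // 2])  # ties toward 5'
                out.append(HotspotCandidate(str(chrom), center, int(cluster.size), cluster))
    out.sort(key=lambda c: (-c.count, c.chrom, c.center))
    return out


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def call_offtargets(
    candidates: list[HotspotCandidate],
    site: TargetSite,
    spec: NucleaseSpec,
    fixture: GenomeFixture,
    max_mismatches: int = 8,
    *,
    translocations: pd.DataFrame | None = None,
    on_target_count: int | None = None,
    count_window: int = 100,
    pattern_window: int = 10,
    pattern_min_frac: float = 0.5,
    scan_extra: int = 25,
) -> list[OfftargetCall]:
    """Evaluate hotspot candidates against the on-target sequence.

    Every candidate is returned with its filter flags; sites that pass both
    the mismatch filter (<= ``max_mismatches`` over protospacer+motif) and the
    cut-site junction-pattern test (>= ``pattern_min_frac`` of cluster
    junctions within +/-``pattern_window`` of the implied cut) are the called
    off-targets (``.passed``). Off/on ratios are filled in when
    ``on_target_count`` is provided.
    """
    from .synthetic_data import site_sequence

    on_seq = site_sequence(fixture, site)
    L = spec.motif_len + spec.guide_nt
    reach = L + scan_extra
    calls: list[OfftargetCall] = []

    for cand in candidates:
        seq = fixture.chromosomes.get(cand.chrom)
        if seq is None:
            continue  # unreadable region: skipped
        best = None  # (dist, center_distance, start, strand, cand_seq)
        lo = max(0, cand.center - reach)
        hi = min(len(seq) - L, cand.center + reach)
        for s in range(lo, hi + 1):
            window = seq[s:s + L]
            mid_dist = abs(s + L // 2 - cand.center)
            for strand, cseq in (("+", window), ("-", revcomp(window))):
                d = _hamming(cseq, on_seq)
                key = (d, mid_dist, strand)
                if best is None or key < best[:3]:
                    best = (d, mid_dist, strand, s, cseq)
        if best is None:
            continue
        dist, _, strand, start, cseq = best
        ot_site = site_from_span(spec, cand.chrom, start, strand)
        predicted_cut = ot_site.cut_mid
        frac_at_cut = np.mean(np.abs(cand.positions - predicted_cut) <= pattern_window)
        motif_seq = cseq[: spec.motif_len] if spec.motif_side == "5prime" else cseq[spec.guide_nt:]

        if translocations is not None:
            on_chrom = translocations["prey_chrom"] == cand.chrom
            near = np.abs(translocations["prey_pos"] - cand.center) <= count_window
            count = int((on_chrom & near & (translocations["prey_source"] == "genome")).sum())
        else:
            count = int((np.abs(cand.positions - cand.center) <= count_window).sum())

        ratio = None
        if on_target_count:
            ratio = 100.0 * count / on_target_count

        calls.append(OfftargetCall(
            chrom=cand.chrom,
            center=cand.center,
            strand=strand,
            sequence=cseq,
            mismatches=dist,
            junction_count=count,
            off_on_percent=ratio,
            predicted_cut=predicted_cut,
            pass_mismatch=dist <= max_mismatches,
            pass_pattern=bool(frac_at_cut >= pattern_min_frac),
            motif_present=matches_iupac(motif_seq, spec.motif),
        ))
    return calls


@dataclass
class TranslocationSummary:
    """Exact partition of translocation junctions plus genome-wide profiles."""

    total: int
    near_target: int                     # within +/-500 kb of the target
    offtarget_counts: list[int]
    general: int
    on_target_count: int                 # indel junctions within +/-100 bp of the cut
    mean_off_on_percent: float | None
    general_percent_of_editing: float
    n_editing: int
    bins_2mb: dict[str, np.ndarray] = field(default_factory=dict)
    bin_size: int = 2_000_000

    @property
    def offtarget_total(self) -> int:
        return int(sum(self.offtarget_counts))

    def check_partition(self) -> bool:
        return self.total == self.near_target + self.offtarget_total + self.general


def on_target_junction_count(
    calls: pd.DataFrame,
    records: pd.DataFrame,
    site: TargetSite,
    window: int = 100,
) -> int:
    """Indel junctions whose prey lies within ``window`` bp of the target cut."""
    indel = calls["event_class"].isin(["deletion", "insertion"]).to_numpy()
    on_chrom = (records["prey_chrom"] == site.chrom).to_numpy()
    near = (np.abs(records["prey_pos"] - site.cut_mid) <= window).to_numpy()
    return int((indel & on_chrom & near).sum())


def translocation_summary(
    calls: pd.DataFrame,
    records: pd.DataFrame,
    site: TargetSite,
    offtargets: list[OfftargetCall],
    fixture: GenomeFixture,
    near_bound: int = 500_000,
    off_window: int = 100,
    bin_size: int = 2_000_000,
) -> TranslocationSummary:
    """Partition translocation junctions into near-target / off-target / general.

    The partition is exact: every translocation junction is assigned to exactly
    one bucket (near-target takes precedence over off-target). General
    translocations are expressed as a percentage of editing events.
    """
    if len(calls) != len(records):
        raise ArgumentError("calls and records must be aligned 1:1")
    mask = (calls["event_class"] == "translocation").to_numpy()
    tr = records.loc[mask & (records["prey_source"] == "genome").to_numpy()]
    total = len(tr)

    chrom = tr["prey_chrom"].to_numpy()
    pos = tr["prey_pos"].to_numpy()
    near = (chrom == site.chrom) & (np.abs(pos - site.cut_mid) <= near_bound)

    passed = [c for c in offtargets if c.passed]
    off_assign = np.full(total, -1)
    for j, ot in enumerate(passed):
        m = ~near & (off_assign < 0) & (chrom == ot.chrom) & (np.abs(pos - ot.center) <= off_window)
        off_assign[m] = j
    off_counts = [int((off_assign == j).sum()) for j in range(len(passed))]
    general = int((~near & (off_assign < 0)).sum())

    n_editing = int((calls["event_class"] != "germline").sum())
    on_count = on_target_junction_count(calls, records, site, window=off_window)
    mean_ratio = None
    if passed and on_count:
        mean_ratio = float(np.mean([100.0 * c / on_count for c in off_counts]))

    bins: dict[str, np.ndarray] = {}
    for cname, length in fixture.chrom_lengths.items():
        n_bins = max(1, -(-length // bin_size))
        counts = np.zeros(n_bins, dtype=int)
        sel = chrom == cname
        if sel.any():
            np.add.at(counts, np.minimum(pos[sel] // bin_size, n_bins - 1), 1)
        bins[cname] = counts

    return TranslocationSummary(
        total=total,
        near_target=int(near.sum()),
        offtarget_counts=off_counts,
        general=general,
        on_target_count=on_count,
        mean_off_on_percent=mean_ratio,
        general_percent_of_editing=(100.0 * general / n_editing if n_editing else 0.0),
        n_editing=n_editing,
        bins_2mb=bins,
        bin_size=bin_size,
    )


def tss_profile(
    translocations: pd.DataFrame,
    fixture: GenomeFixture,
    window: int = 2_000,
    bin_size: int = 100,
) -> pd.DataFrame:
    """Histogram of signed junction-to-nearest-TSS distances.

    Callers should pass translocation junctions with near-target and
    off-target junctions already excluded. Returns a DataFrame with
    ``bin_start``, ``bin_end`` (distances, negative = upstream of the TSS) and
    ``count``.
    """
    if not any(fixture.tss.values()):
        raise ArgumentError("fixture has no TSS annotation")
    distances = []
    for chrom, grp in translocations.groupby("prey_chrom"):
        tss = np.asarray(fixture.tss.get(chrom, ()), dtype=int)
        if tss.size == 0:
            continue
        pos = grp["prey_pos"].to_numpy()
        idx = np.searchsorted(tss, pos)
        left = tss[np.clip(idx - 1, 0, tss.size - 1)]
        right = tss[np.clip(idx, 0, tss.size - 1)]
        nearest = np.where(np.abs(pos - left) <= np.abs(right - pos), left, right)
        distances.append(pos - nearest)
    d = np.concatenate(distances) if distances else np.array([], dtype=int)
    edges = np.arange(-window, window + bin_size, bin_size)
    counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({
        "bin_start": edges[:-1],
        "bin_end": edges[1:],
        "count": counts,
    })
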