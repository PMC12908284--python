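"""Junction -> event-class labeling and per-site editing summaries.

Every deduplicated junction is assigned exactly one class:

``plasmid_integration`` / ``mito_integration``
    prey maps onto the episome, or the inserted nucleotides align to it
    (exact match >= 20 nt, or >= 90% identity over >= 25 nt);
``translocation``
    prey on another chromosome, strand-inverted, or beyond the rearrangement
    bound (500 kb) on the bait chromosome;
``deletion``
    prey resumes past the expected contiguous position (length = reference gap,
    microhomology assigned leftmost);
``insertion``
    net inserted nucleotides with contiguous (or deleted) flanks — junctions
    with both a gap and an insertion are classed by the larger component,
    ties going to deletion;
``germline``
    contiguous prey, no insertion.

Editing efficiency is the fraction of total alleles carrying any non-germline
event; abnormal-event frequencies (large deletions, translocations, plasmid
integrations) are reported relative to editing events, and integration rates
per 100k indels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ArgumentError, ValidationError
from .nucleases import revcomp
from .synthetic_data import GenomeFixture, TargetSite

EVENT_ORDER = (
    "deletion", "insertion", "translocation",
    "plasmid_integration", "mito_integration", "germline",
)

INSERTION_BINS = ("1", "2-25", "25-40", ">40")


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the junction classifier (all exposed, none magic)."""

    integration_min_exact: int = 20       # exact donor match length
    integration_min_approx: int = 25      # approximate-match minimum length
    integration_max_divergence: float = 0.10
    rearrangement_bound: int = 500_000    # same-chromosome deletion/translocation split


class _DonorIndex:
    """Exact k-mer index plus edlib fallback over a circular donor sequence."""

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        doubled = seq + seq[: max(k - 1, 0)]
        self.doubled = doubled
        self.kmers: dict[str, int] = {}
        for i in range(len(seq)):
            self.kmers.setdefault(doubled[i:i + k], i)
        self.rc = revcomp(seq)
        rc_doubled = self.rc + self.rc[: max(k - 1, 0)]
        self.rc_kmers: dict[str, int] = {}
        for i in range(len(seq)):
            self.rc_kmers.setdefault(rc_doubled[i:i + k], i)

    def match(self, insert: str, params: ClassifierParams) -> int | None:
        """Donor coordinate of a qualifying match of ``insert``, else None."""
        k = self.k
        if len(insert) >= k:
            for i in range(len(insert) - k + 1):
                pos = self.kmers.get(insert[i:i + k])
                if pos is not None:
                    return pos
                pos = self.rc_kmers.get(insert[i:i + k])
                if pos is not None:
                    return len(self.seq) - pos - k if pos + k <= len(self.seq) else 0
        if len(insert) >= params.integration_min_approx:
            import edlib

            budget = int(params.integration_max_divergence * len(insert))
            for target, reverse in ((self.doubled + self.seq, False), (self.rc + self.rc, True)):
                res = edlib.align(insert, target, mode="HW", task="locations", k=budget)
                if res["editDistance"] != -1 and res["locations"]:
                    start = res["locations"][0][0] % len(self.seq)
                    return (len(self.seq) - start) % len(self.seq) if reverse else start
        return None


def classify_junctions(
    records: pd.DataFrame,
    site: TargetSite,
    fixture: GenomeFixture,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Label each deduplicated junction; returns one EventCall row per record.

    Output columns: ``event_class, del_len, ins_len, ins_source, del_start,
    del_end, integ_source, integ_pos`` (integration coordinates are on the
    donor episome).
    """
    params = params or ClassifierParams()
    n = len(records)
    lengths = fixture.chrom_lengths

    bad = ~records["bait_chrom"].isin(lengths)
    genomic = records["prey_source"].to_numpy() == "genome"
    bad |= genomic & ~records["prey_chrom"].isin(lengths)
    if bad.any():
        name = records.loc[bad, "bait_chrom"].iloc[0]
        raise ValidationError(f"junction references unknown chromosome {name!r}")

    cls = np.full(n, "", dtype=object)
    del_len = np.zeros(n, dtype=int)
    ins_len = np.array([len(s) for s in records["insert_seq"]], dtype=int)
    ins_source = np.full(n, ".", dtype=object)
    del_start = np.full(n, -1)
    del_end = np.full(n, -1)
    integ_source = np.full(n, ".", dtype=object)
    integ_pos = np.full(n, -1)

    prey_source = records["prey_source"].to_numpy()
    prey_chrom = records["prey_chrom"].to_numpy()
    prey_pos = records["prey_pos"].to_numpy()
    prey_strand = records["prey_strand"].to_numpy()
    bait_chrom = records["bait_chrom"].to_numpy()
    bait_strand = records["bait_strand"].to_numpy()
    bait_end = records["bait_end"].to_numpy()
    inserts = records["insert_seq"].to_numpy()

    # (1)-(2) prey mapping onto an episome
    for source, cname in (("plasmid", "plasmid_integration"), ("mito", "mito_integration")):
        m = prey_source == source
        cls[m] = cname
        integ_source[m] = source
        integ_pos[m] = prey_pos[m]

    # (1)-(2) inserted nucleotides aligning to an episome
    min_len = min(params.integration_min_exact, params.integration_min_approx)
    pending = np.flatnonzero((cls == "") & (ins_len >= min_len))
    if pending.size:
        k = params.integration_min_exact
        donors = (
            ("plasmid", "plasmid_integration", _DonorIndex(fixture.plasmid, k)),
            ("mito", "mito_integration", _DonorIndex(fixture.mito, k)),
        )
        for i in pending:
            for source, cname, index in donors:
                pos = index.match(inserts[i], params)
                if pos is not None:
                    cls[i] = cname
                    integ_source[i] = source
                    integ_pos[i] = pos
                    break

    # (3) rearrangements
    open_ = cls == ""
    inter = open_ & (prey_chrom != bait_chrom)
    inverted = open_ & ~inter & (prey_strand != bait_strand)
    dirn = np.where(bait_strand == "+", 1, -1)
    gap = dirn * (prey_pos - bait_end)
    far = open_ & ~inter & ~inverted & (np.abs(gap) > params.rearrangement_bound)
    cls[inter | inverted | far] = "translocation"

    # (4)-(6) colinear junctions: gap vs net insertion
    open_ = cls == ""
    g = np.where(open_, gap, 0)
    dup = open_ & (g < 0)  # prey re-enters upstream: templated local duplication
    eff_ins = ins_len + np.where(dup, -g, 0)
    g = np.where(dup, 0, g)
    is_del = open_ & (g > 0) & (g >= eff_ins)
    is_ins = open_ & ~is_del & (eff_ins > 0)
    cls[is_del] = "deletion"
    cls[is_ins] = "insertion"
    cls[open_ & ~is_del & ~is_ins] = "germline"

    del_len[is_del] = g[is_del]
    keep = is_del | (is_ins & (g > 0))
    del_start[keep] = np.minimum(bait_end, prey_pos)[keep]
    del_end[keep] = np.maximum(bait_end, prey_pos)[keep]
    del_len[is_ins & (g > 0)] = g[is_ins & (g > 0)]
    ins_len = np.where(dup, eff_ins, ins_len)
    ins_source[is_ins] = "unassigned"

    return pd.DataFrame({
        "event_class": cls,
        "del_len": del_len,
        "ins_len": ins_len,
        "ins_source": ins_source,
        "del_start": del_start,
        "del_end": del_end,
        "integ_source": integ_source,
        "integ_pos": integ_pos,
    }, index=records.index)


def classify_junction(record, site, fixture, params=None):
    """Classify a single junction record (mapping or Series); returns a Series."""
    df = pd.DataFrame([dict(record)])
    return classify_junctions(df, site, fixture, params).iloc[0]


# ---------------------------------------------------------------------------
# summaries


@dataclass
class EditingSummary:
    """Per-site editing statistics with the field's standard denominators."""

    total_alleles: int
    n_editing: int
    editing_efficiency: float
    class_counts: dict[str, int]
    class_fractions: dict[str, float]          # of editing events
    small_deletions: int                        # <= 100 bp
    large_deletions: int                        # > 100 bp
    large_deletion_fraction: float              # of editing events
    median_large_deletion_bp: float | None
    insertion_length_bins: dict[str, int]       # 1 / 2-25 / 25-40 / >40 bp
    insertion_small_large: dict[str, int]       # <=20 / >20 bp

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


def summarize_events(calls: pd.DataFrame, total_alleles: int) -> EditingSummary:
    """Collapse one site's event calls into an :class:`EditingSummary`.

    ``total_alleles`` is the number of deduplicated sequenced alleles (the
    editing-efficiency denominator); fractions of abnormal events use editing
    events as the denominator.
    """
    if total_alleles <= 0:
        raise ArgumentError("total_alleles must be positive")
    counts = {c: int((calls["event_class"] == c).sum()) for c in EVENT_ORDER}
    n_edit = sum(v for c, v in counts.items() if c != "germline")
    if n_edit > total_alleles:
        raise ArgumentError("more editing events than total alleles")
    fractions = {
        c: (counts[c] / n_edit if n_edit else 0.0)
        for c in EVENT_ORDER if c != "germline"
    }

    dels = calls.loc[calls["event_class"] == "deletion", "del_len"].to_numpy()
    small = int((dels <= 100).sum())
    large = int((dels > 100).sum())
    large_frac = large / n_edit if n_edit else 0.0
    median_large = float(np.median(dels[dels > 100])) if large else None

    ins = calls.loc[calls["event_class"] == "insertion", "ins_len"].to_numpy()
    bins = {
        "1": int((ins == 1).sum()),
        "2-25": int(((ins >= 2) & (ins <= 25)).sum()),
        "25-40": int(((ins > 25) & (ins <= 40)).sum()),
        ">40": int((ins > 40).sum()),
    }
    small_large = {"<=20": int((ins <= 20).sum()), ">20": int((ins > 20).sum())}

    return EditingSummary(
        total_alleles=int(total_alleles),
        n_editing=n_edit,
        editing_efficiency=n_edit / total_alleles,
        class_counts=counts,
        class_fractions=fractions,
        small_deletions=small,
        large_deletions=large,
        large_deletion_fraction=large_frac,
        median_large_deletion_bp=median_large,
        insertion_length_bins=bins,
        insertion_small_large=small_large,
    )


@dataclass
class IntegrationSummary:
    """Plasmid/mtDNA capture rates normalized to 100k indels."""

    n_indels: int
    plasmid_count: int
    mito_count: int
    plasmid_per_100k: float | None
    mito_per_100k: float | None
    bin_size: int
    plasmid_hist: np.ndarray            # per-bin junctions per 100k indels
    plasmid_hist_counts: np.ndarray     # raw per-bin junction counts
    enriched_bins: list[tuple[int, int]] = field(default_factory=list)


def integration_profile(
    calls: pd.DataFrame,
    records: pd.DataFrame,
    fixture: GenomeFixture,
    bin_size: int = 100,
    enrichment_alpha: float = 1e-3,
) -> IntegrationSummary:
    """Integration rates per 100k indels and the plasmid positional histogram.

    Indels = deletions + insertions. The histogram bins the plasmid-side
    junction coordinate of each plasmid integration into ``bin_size``-bp bins
    and scales counts to 100k indels; bins exceeding the Poisson
    ``1 - enrichment_alpha`` quantile of a uniform layout are flagged enriched.
    """
    if len(calls) != len(records):
        raise ArgumentError("calls and records must be aligned 1:1")
    n_indels = int(calls["event_class"].isin(["deletion", "insertion"]).sum())
    plasmid_mask = (calls["event_class"] == "plasmid_integration").to_numpy()
    mito_count = int((calls["event_class"] == "mito_integration").sum())
    plasmid_count = int(plasmid_mask.sum())

    n_bins = math.ceil(len(fixture.plasmid) / bin_size)
    raw = np.zeros(n_bins, dtype=int)
    if plasmid_count:
        pos = calls.loc[plasmid_mask, "integ_pos"].to_numpy() % len(fixture.plasmid)
        np.add.at(raw, pos // bin_size, 1)

    if n_indels == 0:
        scale = None
    else:
        scale = 100_000 / n_indels
    hist = raw * scale if scale is not None else np.full(n_bins, np.nan)

    enriched: list[tuple[int, int]] = []
    if plasmid_count:
        expected = plasmid_count / n_bins
        cutoff = stats.poisson.isf(enrichment_alpha, expected)
        for b in np.flatnonzero(raw > cutoff):
            enriched.append((int(b * bin_size), int(min((b + 1) * bin_size, len(fixture.plasmid)))))

    return IntegrationSummary(
        n_indels=n_indels,
        plasmid_count=plasmid_count,
        mito_count=mito_count,
        plasmid_per_100k=(plasmid_count * scale if scale is not None else None),
        mito_per_100k=(mito_count * scale if scale is not None else None),
        bin_size=bin_size,
        plasmid_hist=hist,
        plasmid_hist_counts=raw,
        enriched_bins=enriched,
    )
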