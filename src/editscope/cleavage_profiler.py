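"""Cut-site and overhang inference from bait broken-end distributions.

A PEM-seq bait library observes, per read, the broken end on one strand of the
double-strand break. Histogramming those broken ends relative to the TAM/PAM
(5' motifs: nt downstream of the TAM; 3' motifs: nt upstream of the PAM) gives
a per-strand positional profile whose mode is the strand's cut position; the
distance between the two modal cut coordinates is the overhang (0 = blunt,
e.g. Cas9; ~6 nt for TnpB-class staggered cleavage).

A companion profile gives, for each reference position around the target, the
fraction of deletion events whose deleted interval covers that position —
higher between staggered cut sites, decaying symmetrically for blunt cutters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, EmptyProfileError
from .nucleases import NucleaseSpec
from .synthetic_data import TargetSite


@dataclass
class PositionProfile:
    """Offsets (anchored at the motif edge, away-from-motif positive) with
    per-offset probability mass (kind="mass") or coverage fraction
    (kind="coverage")."""

    anchor: str
    strand_label: str
    offsets: np.ndarray
    masses: np.ndarray
    kind: str = "mass"
    window: int = 50

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.kind == "mass" and len(self.masses):
            total = self.masses.sum()
            if not np.isclose(total, 1.0):
                raise ArgumentError(f"profile masses must sum to 1, got {total}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "anchor": self.anchor,
            "offset": self.offsets,
            "probability": self.masses,
            "strand": self.strand_label,
        })


@dataclass
class CutModelEstimate:
    """Modal per-strand cut offsets (NucleaseSpec convention) and overhang."""

    nts_offset: int
    ts_offset: int
    overhang_nt: int
    blunt: bool
    nts_modal_mass: float
    ts_modal_mass: float
    nts_tie: bool = False
    ts_tie: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _anchor_and_sign(site: TargetSite) -> tuple[int, int]:
    """(motif-edge coordinate, away-from-motif direction) for re-anchoring."""
    five_prime = (site.motif_interval[0] < site.protospacer_interval[0]) == (site.strand == "+")
    if five_prime:
        return (site.motif_interval[1], +1) if site.strand == "+" else (site.motif_interval[0], -1)
    return (site.motif_interval[0], -1) if site.strand == "+" else (site.motif_interval[1], +1)


def broken_end_profile(
    records: pd.DataFrame,
    site: TargetSite,
    strand: str,
    window: int = 50,
) -> PositionProfile:
    """Histogram of bait broken ends on one strand, re-anchored to the motif.

    ``records`` must be the edited (non-germline) deduplicated junctions of one
    site; ``strand`` is "non-target" or "target". Offsets beyond ``window`` are
    pooled into tail bins at +/-(window+1).
    """
    tag = site.bait_tag(strand)
    sel = records.loc[records["bait_strand"] == tag]
    if sel.empty:
        raise EmptyProfileError(f"no edited records observe the {strand} strand")
    edge, sign = _anchor_and_sign(site)
    offsets = sign * (sel["bait_end"].to_numpy() - edge)
    offsets = np.clip(offsets, -(window + 1), window + 1)
    values, counts = np.unique(offsets, return_counts=True)
    return PositionProfile(
        anchor="motif_edge",
        strand_label=strand,
        offsets=values,
        masses=counts / counts.sum(),
        kind="mass",
        window=window,
    )


def _modal(profile: PositionProfile) -> tuple[int, float, bool]:
    masses = profile.masses
    best = masses.max()
    at_best = profile.offsets[np.isclose(masses, best)]
    # ties broken toward the motif (smaller away-from-motif offset), flagged
    return int(at_best.min()), float(best), len(at_best) > 1


def infer_cut_sites(
    profile_nts: PositionProfile,
    profile_ts: PositionProfile,
    spec: NucleaseSpec | None = None,
) -> CutModelEstimate:
    """Combine per-strand broken-end profiles into a cut-model estimate.

    Both profiles share the motif-edge anchor, so the overhang is the absolute
    difference of the modal offsets; equal offsets mean a blunt cut.
    """
    if not len(profile_nts.offsets) or not len(profile_ts.offsets):
        raise EmptyProfileError("both strand profiles must be non-empty")
    nts, nts_mass, nts_tie = _modal(profile_nts)
    ts, ts_mass, ts_tie = _modal(profile_ts)
    overhang = abs(ts - nts)
    return CutModelEstimate(
        nts_offset=nts,
        ts_offset=ts,
        overhang_nt=overhang,
        blunt=overhang == 0,
        nts_modal_mass=nts_mass,
        ts_modal_mass=ts_mass,
        nts_tie=nts_tie,
        ts_tie=ts_tie,
    )


def deletion_position_profile(
    calls: pd.DataFrame,
    site: TargetSite,
    window: int = 50,
) -> PositionProfile:
    """Per-position probability that a deletion event removed that base.

    For each offset in ``[-window, window]`` (motif-edge anchored), the value
    is the fraction of deletion calls whose deleted interval ``[del_start,
    del_end)`` covers the corresponding reference base.
    """
    if "event_class" in calls:
        calls = calls.loc[calls["event_class"] == "deletion"]
    n = len(calls)
    offsets = np.arange(-window, window + 1)
    if n == 0:
        return PositionProfile("motif_edge", "deletion", offsets,
                               np.zeros_like(offsets, float), kind="coverage", window=window)
    edge, sign = _anchor_and_sign(site)
    ref = edge + offsets if sign > 0 else edge - 1 - offsets  # base index per offset
    lo, hi = int(ref.min()), int(ref.max())
    size = hi - lo + 1
    diff = np.zeros(size + 1, dtype=int)
    s = np.clip(calls["del_start"].to_numpy() - lo, 0, size)
    e = np.clip(calls["del_end"].to_numpy() - lo, 0, size)
    np.add.at(diff, s, 1)
    np.add.at(diff, e, -1)
    coverage = np.cumsum(diff)[:size] / n
    return PositionProfile(
        anchor="motif_edge",
        strand_label="deletion",
        offsets=offsets,
        masses=coverage[ref - lo],
        kind="coverage",
        window=window,
    )
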