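"""Six-dimension min-max scorecards for a nuclease panel.

Each nuclease is scored on activity (A: mean editing efficiency), deliverability
(D: reciprocal cargo size), specificity (S: 1 - mean off/on junction ratio),
and three safety margins — plasmid integration (P), general translocation (T)
and large deletion (L), each 1 minus the event's fraction of editing events.
Raw values are min-max normalized across the panel, so 0/1 mark the worst/best
system per dimension; scores are comparative, not absolute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError
from .event_classifier import EditingSummary, IntegrationSummary
from .nucleases import NucleaseSpec
from .offtarget import TranslocationSummary

DIMENSIONS = ("A", "D", "S", "P", "T", "L")


@dataclass
class ScoreCard:
    name: str
    scores: dict[str, float]      # min-max normalized, in [0, 1]
    raw: dict[str, float]         # pre-normalization values

    def __getitem__(self, dim: str) -> float:
        return self.scores[dim]


@dataclass
class NucleasePanelEntry:
    """One nuclease's inputs to the scorecard (site summaries + spec)."""

    spec: NucleaseSpec
    editing: list[EditingSummary]
    integration: list[IntegrationSummary]
    translocation: list[TranslocationSummary]
    off_on_percents: list[float]   # per called off-target site; empty = clean


def _mean(values) -> float:
    values = [v for v in values if v is not None]
    return float(np.mean(values)) if values else 0.0


def _raw_values(entry: NucleasePanelEntry, *, coding_length: bool,
                specificity: str, effective_threshold: float) -> dict[str, float]:
    eds = entry.editing
    effective = [e for e in eds if e.editing_efficiency > effective_threshold] or eds
    a = _mean([e.editing_efficiency for e in effective])
    d = 1.0 / entry.spec.delivery_size(coding_length=coding_length)
    if specificity == "off_on_ratio":
        s = 1.0 - _mean([p / 100.0 for p in entry.off_on_percents] or [0.0])
    elif specificity == "on_target_proportion":
        on = sum(t.on_target_count for t in entry.translocation)
        edit = sum(t.n_editing for t in entry.translocation)
        s = on / edit if edit else 0.0
    else:
        raise ArgumentError(f"unknown specificity mode {specificity!r}")
    p = 1.0 - _mean([
        e.class_fractions.get("plasmid_integration", 0.0) for e in effective
    ])
    t = 1.0 - _mean([ts.general_percent_of_editing / 100.0 for ts in entry.translocation])
    length = 1.0 - _mean([e.large_deletion_fraction for e in effective])
    return {"A": a, "D": d, "S": s, "P": p, "T": t, "L": length}


def minmax(values: np.ndarray) -> np.ndarray:
    """Min-max normalize; a constant vector maps to all ones (no information)."""
    lo, hi = values.min(), values.max()
    if np.isclose(hi, lo):
        warnings.warn("constant dimension: all nucleases score 1", stacklevel=2)
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def radar_scores(
    panel: dict[str, NucleasePanelEntry],
    *,
    coding_length: bool = True,
    specificity: str = "off_on_ratio",
    effective_threshold: float = 0.05,
) -> list[ScoreCard]:
    """Score a panel of nucleases on the six dimensions.

    ``coding_length=True`` sizes delivery as 3*aa + guide nt (a consistent
    nucleotide cargo proxy); ``False`` uses the literal aa + nt sum.
    ``specificity`` selects the off/on-ratio form (default) or the on-target
    proportion form. Per-site means for A/P/L are taken over effective sites
    (efficiency > ``effective_threshold``), falling back to all sites when
    none qualify.
    """
    if len(panel) < 2:
        raise ArgumentError("min-max normalization needs at least 2 nucleases")
    names = list(panel)
    raws = {
        name: _raw_values(panel[name], coding_length=coding_length,
                          specificity=specificity, effective_threshold=effective_threshold)
        for name in names
    }
    norm = {
        dim: minmax(np.array([raws[n][dim] for n in names], dtype=float))
        for dim in DIMENSIONS
    }
    return [
        ScoreCard(
            name=name,
            scores={dim: float(norm[dim][i]) for dim in DIMENSIONS},
            raw=raws[name],
        )
        for i, name in enumerate(names)
    ]
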