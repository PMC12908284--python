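"""Study conditions for the eight-nuclease panel comparison.

Each :class:`StudyCondition` translates a nuclease's reported editing-outcome
profile — median editing efficiency, deletion/insertion shares of editing
events, general-translocation percentage, plasmid and mtDNA capture rates per
100k indels, large-deletion share and median large-deletion length — into
generator parameters, so a simulated panel reproduces the comparative
structure of the real experiments at desk scale. These numbers are the fixed
conditions of the analysis, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nucleases import PANEL, NucleaseSpec
from .synthetic_data import SimConfig


@dataclass(frozen=True)
class StudyCondition:
    nuclease: str
    editing_prob: float             # median editing efficiency
    deletion_share: float           # of editing events
    insertion_share: float
    general_transloc_percent: float
    plasmid_per_100k: float         # per 100k indels
    mito_per_100k: float
    large_deletion_percent: float   # of editing events
    median_large_del_bp: float
    ins_p1: float                   # 1-bp share of insertions (Cas9-dominant)
    n_offtargets: int
    mismatch_counts: tuple[int, ...] = ()
    offtarget_fractions: tuple[float, ...] = ()

    @property
    def spec(self) -> NucleaseSpec:
        return PANEL[self.nuclease]

    def sim_config(self, n_alleles: int = 50_000, seed: int = 0) -> SimConfig:
        d, i = self.deletion_share, self.insertion_share
        t = self.general_transloc_percent / 100.0
        p = self.plasmid_per_100k / 100_000.0 * (d + i)
        m = self.mito_per_100k / 100_000.0 * (d + i)
        total = d + i + t + p + m
        weights = {
            "deletion": d / total,
            "insertion": i / total,
            "translocation": t / total,
            "plasmid_integration": p / total,
            "mito_integration": m / total,
        }
        # route extra translocation mass to planted off-targets on top of background
        large_among_dels = (self.large_deletion_percent / 100.0) / weights["deletion"]
        return SimConfig(
            n_alleles=n_alleles,
            editing_prob=self.editing_prob,
            event_weights=weights,
            del_small_weight=1.0 - large_among_dels,
            del_large_max=max(120, round(self.median_large_del_bp**2 / 101)),
            ins_p1=self.ins_p1,
            offtarget_fractions=self.offtarget_fractions or None,
            seed=seed,
        )


# Conditions per nuclease (efficiencies and event shares as reported for the
# panel; values not individually printed are set at the family's magnitude).
CONDITIONS: dict[str, StudyCondition] = {c.nuclease: c for c in [
    StudyCondition("ISDra2", 0.137, 0.910, 0.055, 4.00, 5_260, 38, 1.54, 280, 0.20,
                   n_offtargets=1, mismatch_counts=(5,), offtarget_fractions=(0.06,)),
    StudyCondition("ISDge10", 0.040, 0.890, 0.050, 5.23, 4_000, 30, 1.42, 270, 0.20,
                   n_offtargets=2, mismatch_counts=(4, 6), offtarget_fractions=(0.08, 0.04)),
    StudyCondition("ISAam1", 0.283, 0.880, 0.060, 4.50, 3_800, 20, 0.99, 250, 0.20,
                   n_offtargets=3, mismatch_counts=(3, 5, 7),
                   offtarget_fractions=(0.12, 0.05, 0.03)),
    StudyCondition("ISYmu1", 0.411, 0.917, 0.065, 3.09, 3_480, 17, 2.28, 300, 0.20,
                   n_offtargets=1, mismatch_counts=(6,), offtarget_fractions=(0.02,)),
    StudyCondition("AsCas12a", 0.513, 0.937, 0.024, 3.30, 2_500, 15, 1.35, 230, 0.20,
                   n_offtargets=2, mismatch_counts=(3, 6), offtarget_fractions=(0.10, 0.04)),
    StudyCondition("CasMINI", 0.022, 0.953, 0.025, 2.13, 2_000, 15, 0.97, 169, 0.20,
                   n_offtargets=1, mismatch_counts=(6,), offtarget_fractions=(0.03,)),
    StudyCondition("SpCas9", 0.628, 0.694, 0.251, 4.59, 4_500, 25, 3.20, 383, 0.70,
                   n_offtargets=3, mismatch_counts=(3, 4, 6),
                   offtarget_fractions=(0.10, 0.06, 0.04)),
    StudyCondition("eNme2-C.NR", 0.132, 0.688, 0.134, 5.01, 21_300, 30, 3.97, 350, 0.60,
                   n_offtargets=0),
]}
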