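"""Synthetic PEM-seq-style junction libraries with known ground truth.

The module builds a miniature reference ("fixture": a few desk-scale
chromosomes plus circular plasmid and mitochondrial sequences), plants a
nuclease target site and optional off-target sites into it, and simulates the
junction library a PEM-seq experiment would yield at the on-target bait:
germline (uncut) alleles, resected deletion junctions, templated and
untemplated insertions, plasmid/mtDNA integration junctions, translocations to
planted off-targets and to TSS-biased background loci, and RMB-tagged PCR
duplicates. Every allele is recorded in a truth table so downstream stages can
be validated against ground truth.

Coordinates are 0-based half-open; cut positions are inter-nucleotide indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConfigError, PlacementError
from .nucleases import IUPAC, NucleaseSpec, revcomp

EVENT_CLASSES = (
    "deletion",
    "insertion",
    "translocation",
    "plasmid_integration",
    "mito_integration",
)

JUNCTION_COLUMNS = [
    "read_id", "rmb", "bait_chrom", "bait_strand", "bait_end",
    "prey_source", "prey_chrom", "prey_pos", "prey_strand", "insert_seq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


# ---------------------------------------------------------------------------
# fixture


@dataclass
class GenomeFixture:
    """Miniature reference: chromosomes, TSS annotation, plasmid and mtDNA."""

    chromosomes: dict[str, str]
    tss: dict[str, list[int]]
    plasmid: str
    mito: str
    seed: int

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def write(self, outdir: str | Path) -> None:
        """Write genome/plasmid/mito FASTA and a TSS BED under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_fasta(outdir / "genome.fa", self.chromosomes)
        _write_fasta(outdir / "plasmid.fa", {"plasmid": self.plasmid})
        _write_fasta(outdir / "mito.fa", {"chrM": self.mito})
        with open(outdir / "tss.bed", "w") as fh:
            for chrom, positions in self.tss.items():
                for pos in positions:
                    fh.write(f"{chrom}\t{pos}\t{pos + 1}\tTSS\n")


def _write_fasta(path: Path, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def build_fixture(
    seed: int,
    n_chromosomes: int = 3,
    chromosome_length: int = 200_000,
    n_tss: int = 50,
    plasmid_length: int = 8_000,
    mt_length: int = 16_569,
) -> GenomeFixture:
    """Generate a seeded random fixture.

    ``n_tss`` is the number of TSS annotations per chromosome. Chromosomes must
    be at least 10 kb so hotspot/window analyses have room to operate.
    """
    if min(n_chromosomes, chromosome_length, n_tss, plasmid_length, mt_length) <= 0:
        raise ArgumentError("all fixture dimensions must be positive")
    if chromosome_length < 10_000:
        raise ArgumentError("chromosome_length must be >= 10000")
    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{i + 1}": _random_seq(rng, chromosome_length)
        for i in range(n_chromosomes)
    }
    tss = {
        name: sorted(
            np.unique(rng.integers(1_000, chromosome_length - 1_000, n_tss)).tolist()
        )
        for name in chroms
    }
    return GenomeFixture(
        chromosomes=chroms,
        tss=tss,
        plasmid=_random_seq(rng, plasmid_length),
        mito=_random_seq(rng, mt_length),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# target sites


@dataclass
class TargetSite:
    """A planted (or annotated) protospacer+motif site on the fixture."""

    chrom: str
    strand: str
    motif_interval: tuple[int, int]
    protospacer_interval: tuple[int, int]
    nts_cut: int
    ts_cut: int
    role: str = "on_target"          # on_target | off_target
    relative_activity: float = 0.0   # planted off-targets: fraction of translocations

    @property
    def cut_mid(self) -> int:
        return (self.nts_cut + self.ts_cut) // 2

    def bait_tag(self, strand_label: str) -> str:
        """Junction-record bait_strand tag carrying the given break.

        ``strand_label`` is "non-target" or "target". Records tagged "+" read
        the reference rightward from their bait end, "-" leftward; for a
        plus-strand site the non-target-strand break is the rightward-reading
        one.
        """
        if strand_label not in ("non-target", "target"):
            raise ArgumentError(f"strand must be 'non-target' or 'target', got {strand_label!r}")
        nts_tag = "+" if self.strand == "+" else "-"
        return nts_tag if strand_label == "non-target" else ("-" if nts_tag == "+" else "+")

    def span(self) -> tuple[int, int]:
        a = min(self.motif_interval[0], self.protospacer_interval[0])
        b = max(self.motif_interval[1], self.protospacer_interval[1])
        return a, b


def site_sequence(fixture: GenomeFixture, site: TargetSite) -> str:
    """Motif+protospacer sequence in guide orientation (motif first for 5' motifs)."""
    a, b = site.span()
    s = fixture.chromosomes[site.chrom][a:b]
    return s if site.strand == "+" else revcomp(s)


def sites_to_bed(sites: list[TargetSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            a, b = s.span()
            fh.write(f"{s.chrom}\t{a}\t{b}\t{s.role}_{i}\t0\t{s.strand}\n")


def _concretize_motif(rng: np.random.Generator, motif: str) -> str:
    return "".join(rng.choice(list(IUPAC[b])) for b in motif)


def site_from_span(spec: NucleaseSpec, chrom: str, span_start: int, strand: str) -> TargetSite:
    """Build a TargetSite for a motif+protospacer span starting at ``span_start``."""
    m, g = spec.motif_len, spec.guide_nt
    if (spec.motif_side == "5prime") == (strand == "+"):
        motif_iv = (span_start, span_start + m)
        proto_iv = (span_start + m, span_start + m + g)
    else:
        proto_iv = (span_start, span_start + g)
        motif_iv = (span_start + g, span_start + g + m)
    nts, ts = spec.predicted_cuts(motif_iv, strand)
    return TargetSite(chrom, strand, motif_iv, proto_iv, nts, ts)


def plant_sites(
    fixture: GenomeFixture,
    spec: NucleaseSpec,
    n_offtargets: int = 0,
    mismatch_counts: list[int] | None = None,
    activities: list[float] | None = None,
    strands: list[str] | None = None,
) -> list[TargetSite]:
    """Edit the fixture in place to contain an on-target and planted off-targets.

    The first returned site is the on-target (its motif substring satisfies the
    spec's IUPAC motif exactly); planted off-target ``i`` differs from the
    on-target over protospacer+motif by exactly ``mismatch_counts[i]``
    substitutions, placed in the guide body first and spilling into the motif
    only when the guide is exhausted. Sites are > 1 kb apart; off-targets are
    placed on chromosomes other than the on-target's whenever the fixture has
    more than one chromosome (a same-chromosome prey inside the rearrangement
    bound would be indistinguishable from a deletion).
    """
    mismatch_counts = list(mismatch_counts or [])
    if len(mismatch_counts) != n_offtargets:
        raise ArgumentError("mismatch_counts must have length n_offtargets")
    m, g = spec.motif_len, spec.guide_nt
    if any(k < 0 or k > m + g for k in mismatch_counts):
        raise ArgumentError("mismatch counts must lie in [0, guide+motif length]")
    if activities is None:
        activities = [0.1] * n_offtargets
    if strands is None:
        strands = ["+" if i % 2 == 0 else "-" for i in range(n_offtargets)]

    rng = np.random.default_rng([fixture.seed, 7919])
    chrom_names = list(fixture.chromosomes)
    site_len = m + g

    on_seq = _concretize_motif(rng, spec.motif) + _random_seq(rng, g)
    if spec.motif_side == "3prime":  # guide orientation: protospacer then motif
        on_seq = on_seq[m:] + on_seq[:m]

    def place(chrom: str, span_start: int, strand: str, guide_seq: str) -> TargetSite:
        seq = fixture.chromosomes[chrom]
        if span_start < 100 or span_start + site_len + 100 > len(seq):
            raise PlacementError(f"site does not fit on {chrom} at {span_start}")
        content = guide_seq if strand == "+" else revcomp(guide_seq)
        fixture.chromosomes[chrom] = (
            seq[:span_start] + content + seq[span_start + site_len:]
        )
        return site_from_span(spec, chrom, span_start, strand)

    used: dict[str, list[int]] = {c: [] for c in chrom_names}

    def next_start(chrom: str) -> int:
        length = len(fixture.chromosomes[chrom])
        start = length // 2 + 5_000 * len(used[chrom])
        for prev in used[chrom]:
            if abs(start - prev) <= max(1_000, site_len):
                raise PlacementError("cannot place sites > 1 kb apart")
        if start + site_len + 100 > length:
            raise PlacementError(f"ran out of room on {chrom}")
        used[chrom].append(start)
        return start

    sites = [place(chrom_names[0], next_start(chrom_names[0]), "+", on_seq)]
    sites[0].role = "on_target"

    other = chrom_names[1:] or chrom_names
    # Mutate the guide body first (off-target reads usually diverge there),
    # then the motif.
    proto_idx = (list(range(m, m + g)) if spec.motif_side == "5prime"
                 else list(range(0, g)))
    motif_idx = [i for i in range(site_len) if i not in proto_idx]
    for i, k in enumerate(mismatch_counts):
        chrom = other[i % len(other)]
        order = (list(rng.permutation(proto_idx)) + list(rng.permutation(motif_idx)))
        ot_seq = list(on_seq)
        for pos in order[:k]:
            choices = [b for b in "ACGT" if b != ot_seq[pos]]
            ot_seq[pos] = str(rng.choice(choices))
        site = place(chrom, next_start(chrom), strands[i], "".join(ot_seq))
        site.role = "off_target"
        site.relative_activity = float(activities[i])
        sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# simulation config


@dataclass
class SimConfig:
    """Parameters of a simulated junction library.

    Defaults emulate the broad structure of real editing-outcome libraries:
    deletion-dominated event mixes, mostly-small deletions with a long tail,
    insertions concentrated below 25 bp, rare vector/mtDNA capture, and
    translocation background enriched near TSSs.
    """

    n_alleles: int = 50_000
    editing_prob: float = 0.4
    # event mix over edited alleles (fractions of editing events)
    event_weights: dict[str, float] = field(default_factory=lambda: {
        "deletion": 0.875,
        "insertion": 0.055,
        "translocation": 0.035,
        "plasmid_integration": 0.034,
        "mito_integration": 0.001,
    })
    # deletion length mixture: geometric small component (<=100 bp) + log-uniform tail
    del_small_weight: float = 0.977
    del_small_p: float = 0.08
    del_large_min: int = 101
    del_large_max: int = 5_000
    # insertion lengths and sources
    ins_p1: float = 0.25
    ins_geom_p: float = 0.12
    ins_max: int = 40
    ins_source_weights: dict[str, float] = field(default_factory=lambda: {
        "untemplated": 0.80, "plasmid": 0.15, "mito": 0.05,
    })
    ins_templated_range: tuple[int, int] = (8, 19)
    # resection noise on broken ends: point mass at the cut + symmetric geometric decay
    p_at_cut: float = 0.6
    resection_decay: float = 0.5
    # translocation routing
    offtarget_fractions: tuple[float, ...] | None = None
    tss_bias: float = 0.3
    tss_halfwidth: int = 1_000
    # library chemistry
    rmb_length: int = 14
    dup_mean: float = 2.0
    seed: int = 0

    def __post_init__(self):
        def _check_weights(w: dict[str, float], what: str):
            if any(v < 0 for v in w.values()):
                raise ConfigError(f"{what} weights must be >= 0")
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{what} weights must sum to 1")

        _check_weights(self.event_weights, "event")
        _check_weights(self.ins_source_weights, "insertion source")
        if set(self.event_weights) != set(EVENT_CLASSES):
            raise ConfigError(f"event_weights must key exactly {EVENT_CLASSES}")
        for name in ("editing_prob", "del_small_weight", "ins_p1", "p_at_cut", "tss_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_alleles <= 0:
            raise ConfigError("n_alleles must be positive")
        if self.dup_mean < 1.0:
            raise ConfigError("dup_mean must be >= 1")
        if self.offtarget_fractions is not None:
            if any(f < 0 for f in self.offtarget_fractions):
                raise ConfigError("offtarget fractions must be >= 0")
            if sum(self.offtarget_fractions) > 1.0 + 1e-9:
                raise ConfigError("offtarget fractions must sum to <= 1")


# ---------------------------------------------------------------------------
# simulation


def _resection_noise(rng, n, config: SimConfig):
    at = rng.random(n) < config.p_at_cut
    mag = rng.geometric(config.resection_decay, n)
    sign = rng.choice([-1, 1], n)
    return np.where(at, 0, sign * mag)


def _deletion_lengths(rng, n, config: SimConfig):
    small = rng.random(n) < config.del_small_weight
    geo = np.minimum(rng.geometric(config.del_small_p, n), 100)
    lo, hi = np.log(config.del_large_min), np.log(config.del_large_max)
    tail = np.exp(rng.uniform(lo, hi, n)).astype(int)
    return np.where(small, geo, np.clip(tail, config.del_large_min, config.del_large_max))


def _rmb_strings(rng, n, length):
    arr = _BASES[rng.integers(0, 4, (n, length))]
    return [row.tobytes().decode() for row in arr]


def simulate_library(
    fixture: GenomeFixture,
    sites: list[TargetSite],
    spec: NucleaseSpec,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one bait library; returns ``(truth_table, junction_records)``.

    Each allele is germline with probability ``1 - editing_prob``; otherwise an
    event is drawn from the event mix. Broken ends sit at the strand-appropriate
    predicted cut coordinate plus resection noise. Each allele receives one RMB
    and is replicated into PCR duplicates (geometric with mean ``dup_mean``).
    Truth rows are per allele; junction rows are per read.
    """
    if not sites:
        raise ArgumentError("sites must be non-empty; first site is the on-target")
    site, offsites = sites[0], sites[1:]
    fractions = config.offtarget_fractions
    if fractions is None:
        fractions = tuple(s.relative_activity for s in offsites)
    if len(fractions) != len(offsites):
        raise ConfigError("offtarget_fractions length must match planted off-targets")
    if sum(fractions) > 1.0 + 1e-9:
        raise ConfigError("offtarget fractions must sum to <= 1")

    rng = np.random.default_rng(config.seed)
    n = config.n_alleles
    chrom_names = list(fixture.chromosomes)
    chrom_lens = np.array([len(fixture.chromosomes[c]) for c in chrom_names])

    edited = rng.random(n) < config.editing_prob
    classes = np.full(n, "germline", dtype=object)
    k = int(edited.sum())
    weights = [config.event_weights[c] for c in EVENT_CLASSES]
    classes[edited] = rng.choice(EVENT_CLASSES, size=k, p=weights)

    obs_ts = rng.random(n) < 0.5  # which strand's break this read observes
    nts_tag = site.bait_tag("non-target")
    ts_tag = site.bait_tag("target")
    tag = np.where(obs_ts, ts_tag, nts_tag).astype(object)
    dirn = np.where(tag == "+", 1, -1)
    cut = np.where(obs_ts, site.ts_cut, site.nts_cut)
    delta = _resection_noise(rng, n, config)
    delta[~edited] = 0
    bait_end = cut + delta

    prey_source = np.full(n, "genome", dtype=object)
    prey_chrom = np.full(n, site.chrom, dtype=object)
    prey_pos = bait_end.copy()
    prey_strand = tag.copy()
    insert_seq = np.full(n, "", dtype=object)
    insert_source = np.full(n, ".", dtype=object)
    del_start = np.full(n, -1)
    del_end = np.full(n, -1)

    # deletions: prey resumes L reference bp further along the bait reading direction
    idx = np.flatnonzero(classes == "deletion")
    if idx.size:
        L = _deletion_lengths(rng, idx.size, config)
        prey_pos[idx] = bait_end[idx] + dirn[idx] * L
        del_start[idx] = np.minimum(bait_end[idx], prey_pos[idx])
        del_end[idx] = np.maximum(bait_end[idx], prey_pos[idx])

    # insertions: contiguous flanks with net inserted nucleotides (< integration
    # threshold so they stay insertions, not vector-capture events)
    idx = np.flatnonzero(classes == "insertion")
    if idx.size:
        src = rng.choice(
            list(config.ins_source_weights),
            size=idx.size,
            p=list(config.ins_source_weights.values()),
        )
        one = rng.random(idx.size) < config.ins_p1
        lengths = np.where(
            one, 1, np.clip(1 + rng.geometric(config.ins_geom_p, idx.size), 2, config.ins_max)
        )
        lo, hi = config.ins_templated_range
        templ_len = rng.integers(lo, hi + 1, idx.size)
        for j, (i, s) in enumerate(zip(idx, src)):
            if s == "untemplated":
                insert_seq[i] = _random_seq(rng, int(lengths[j]))
            else:
                donor = fixture.plasmid if s == "plasmid" else fixture.mito
                ln = int(templ_len[j])
                start = int(rng.integers(0, len(donor)))
                insert_seq[i] = (donor * 2)[start:start + ln]
            insert_source[i] = s

    # translocations: planted off-targets per their fractions, else background
    idx = np.flatnonzero(classes == "translocation")
    if idx.size:
        u = rng.random(idx.size)
        edges = np.cumsum(np.asarray(fractions, dtype=float))
        route = np.searchsorted(edges, u)  # == len(fractions) -> background
        pstrand = rng.choice(["+", "-"], idx.size).astype(object)
        noise = _resection_noise(rng, idx.size, config)
        for j, i in enumerate(idx):
            r = int(route[j])
            if r < len(offsites):
                ot = offsites[r]
                prey_chrom[i] = ot.chrom
                prey_pos[i] = ot.nts_cut + noise[j]
                prey_strand[i] = pstrand[j]
            else:
                ci = int(rng.choice(len(chrom_names), p=chrom_lens / chrom_lens.sum()))
                c = chrom_names[ci]
                if rng.random() < config.tss_bias and fixture.tss.get(c):
                    t = int(rng.choice(fixture.tss[c]))
                    pos = t + int(rng.integers(-config.tss_halfwidth, config.tss_halfwidth + 1))
                    pos = int(np.clip(pos, 0, chrom_lens[ci] - 1))
                else:
                    pos = int(rng.integers(0, chrom_lens[ci]))
                prey_chrom[i] = c
                prey_pos[i] = pos
                prey_strand[i] = pstrand[j]
            # same-chromosome same-strand preys inside the rearrangement bound
            # would read as deletions on desk-scale chromosomes: invert instead
            if prey_chrom[i] == site.chrom and prey_strand[i] == tag[i]:
                prey_strand[i] = "-" if tag[i] == "+" else "+"

    # plasmid / mtDNA integrations: prey maps onto the episome
    for cls, source, donor in (
        ("plasmid_integration", "plasmid", fixture.plasmid),
        ("mito_integration", "mito", fixture.mito),
    ):
        idx = np.flatnonzero(classes == cls)
        if idx.size:
            prey_source[idx] = source
            prey_chrom[idx] = "."
            prey_pos[idx] = rng.integers(0, len(donor), idx.size)
            prey_strand[idx] = rng.choice(["+", "-"], idx.size)

    rmb = _rmb_strings(rng, n, config.rmb_length)
    if config.dup_mean <= 1.0:
        dup = np.ones(n, dtype=int)
    else:
        dup = rng.geometric(1.0 / config.dup_mean, n)

    truth = pd.DataFrame({
        "allele_id": np.arange(n),
        "event_class": classes,
        "bait_strand": tag,
        "bait_end": bait_end,
        "del_start": del_start,
        "del_end": del_end,
        "insert_seq": insert_seq,
        "insert_source": insert_source,
        "prey_source": prey_source,
        "prey_chrom": prey_chrom,
        "prey_pos": prey_pos,
        "prey_strand": prey_strand,
        "rmb": rmb,
        "dup_count": dup,
    })

    rep = np.repeat(np.arange(n), dup)
    records = pd.DataFrame({
        "read_id": [f"r{i:08d}" for i in range(rep.size)],
        "rmb": truth["rmb"].to_numpy()[rep],
        "bait_chrom": site.chrom,
        "bait_strand": truth["bait_strand"].to_numpy()[rep],
        "bait_end": truth["bait_end"].to_numpy()[rep],
        "prey_source": truth["prey_source"].to_numpy()[rep],
        "prey_chrom": truth["prey_chrom"].to_numpy()[rep],
        "prey_pos": truth["prey_pos"].to_numpy()[rep],
        "prey_strand": truth["prey_strand"].to_numpy()[rep],
        "insert_seq": truth["insert_seq"].to_numpy()[rep],
    })
    return truth, records
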