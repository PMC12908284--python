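# Methods

## Problem and data model

PEM-seq-style experiments interrogate the repair outcomes of a programmable
double-strand break (DSB): a bait primer anchored near the cut captures
whatever sequence was joined to the broken end, producing one *bait → prey
junction* per sequenced molecule. From a single junction library one can read
out indels at the target, vector and mitochondrial DNA capture, and
chromosomal translocations genome-wide. `editscope` operates entirely on
junction records — read-level alignment of raw sequencing data is upstream of
this package and out of scope.

A junction record carries: the bait broken-end coordinate and reading
orientation (`bait_strand` `+` = the junction continues rightward along the
reference, `-` = leftward), the prey source (`genome`/`plasmid`/`mito`),
prey coordinate and strand, any untemplated/templated inserted nucleotides,
and a random molecular barcode (RMB) used to collapse PCR duplicates. All
coordinates are 0-based half-open; cut positions are inter-nucleotide
indices.

## Cut-model convention

A nuclease's cleavage geometry is two per-strand offsets from the
protospacer-proximal edge of its motif, measured away from the motif:

* 5'-motif systems (TnpB, Cas12): nt **downstream of the TAM**. The packaged
  TnpB class cuts the non-target strand (NTS) at +15 and the target strand
  (TS) at +21 — one position past a 20-nt guide body — leaving a 6-nt 5'
  overhang. The ISAam1-class variant cuts the NTS at +16 (5-nt overhang).
  The Cas12a-class model uses 18/23 and the Cas12f-class model 20/24.
* 3'-motif systems (Cas9): nt **upstream of the PAM**; the packaged Cas9
  class cuts both strands at 3, i.e. blunt.

Overhang = |TS − NTS| in this shared frame; blunt ⇔ equal offsets. Only
ISDra2's protein size (408 aa) is an established constant; the other panel
protein sizes and guide lengths are editable defaults chosen at the right
order of magnitude, and affect only the deliverability score.

Re-anchoring choice: profiles anchor at the protospacer-proximal motif edge
(TAM/protospacer boundary for 5' motifs). Anchoring at the distal TAM edge
would shift every offset by the motif length; the proximal edge was chosen
because it makes the TS offset directly comparable to the guide length.

## Synthetic library generator

The generator emulates the statistical structure the analysis assumes, with
ground truth per allele:

* **Fixture**: seeded random genome (default 3 × 200 kb chromosomes, 50 TSS
  per chromosome), circular plasmid (8 kb) and mitochondrial (16,569 bp)
  sequences. Desk-scale chromosomes are deliberately shorter than the 500-kb
  rearrangement bound; consequences below.
* **Sites**: `plant_sites` writes a concrete motif+protospacer into the
  fixture, plus off-targets at exact Hamming distances (guide-body positions
  mutated first, mirroring how real off-targets diverge). Off-targets go on
  non-bait chromosomes whenever possible.
* **Event mix** (fractions of editing events; defaults): deletion 0.875,
  insertion 0.055, translocation 0.035, plasmid integration 0.034, mtDNA
  integration 0.001 — deletion-dominated, vector capture a few percent of
  editing, mtDNA capture ~30× rarer. Editing probability default 0.4.
* **Broken-end noise**: point mass `p_at_cut` = 0.6 exactly at the predicted
  cut plus a symmetric geometric tail (decay 0.5). The at-cut mass must
  exceed 0.5 for modal cut recovery to be well-posed; 0.6 keeps the mode
  clearly identifiable at a few thousand junctions while still exercising
  the profiler against resection.
* **Deletion lengths**: two-component mixture — geometric (p = 0.08,
  truncated at 100 bp) for the small-deletion regime and a log-uniform tail
  over 101 bp–5 kb for large deletions. The small-component weight (default
  0.977) sets the large-deletion share.
* **Insertions**: 1 bp with probability `ins_p1`, otherwise shifted
  geometric clipped to 40 bp; sources untemplated/plasmid/mito (0.8 /
  0.15 / 0.05), templated copies 8–19 nt (below the integration-match
  threshold, so they remain insertions by construction).
* **Translocations**: routed to planted off-targets per configured
  fractions, else background — uniform over the genome with a 30% point
  mass within ±1 kb of a TSS (the paper-scale observation is TSS
  *enrichment*; the generative rate is our stand-in and is configurable).
  Background preys landing on the bait chromosome are emitted
  strand-inverted: on sub-500-kb chromosomes a colinear same-chromosome prey
  is definitionally a deletion, so inversion keeps the simulated event a
  genuine rearrangement and the truth table consistent with the classifier.
* **Library chemistry**: 14-nt uniform RMBs; PCR duplication geometric with
  mean 2. Each read reports the broken end of one strand, chosen 50/50 —
  a stand-in for the two bait orientations a real two-library design
  provides.

What the generator does **not** emulate: microhomology-directed junction
placement, base-calling/alignment error, chromatin- or sequence-dependent
repair biases, bait-primer dropout, or realistic human TSS density.
Passing tests therefore validate the *bookkeeping and inference machinery*,
not biological effect sizes.

## Classification

Decision order per deduplicated junction: episome prey or insert aligning to
plasmid/mtDNA (exact ≥ 20 nt, or ≥ 90% identity over ≥ 25 nt via edlib
infix alignment) → integration; inter-chromosomal, strand-inverted, or
> 500 kb colinear gap → translocation; positive gap → deletion (length =
reference gap, microhomology assigned leftmost); net insertion with
contiguous flanks → insertion; mixed gap+insert junctions are classed by the
larger component with ties to deletion, both lengths retained; otherwise
germline. A prey re-entering upstream of the bait end (never generated by
the simulator) is treated as a templated local duplication and classed as an
insertion of the combined length.

Denominators follow the field's convention: editing efficiency = non-germline
molecules / total molecules; event-class shares, large-deletion and
general-translocation percentages are relative to *editing events*;
integration rates are per 100,000 indels (deletions + insertions). Deletion
size classes split at ≤ 100 / > 100 bp; insertion bins are 1, 2–25, 26–40
(reported under the conventional "25–40" label), > 40 bp, plus the ≤ 20 /
> 20 bp split.

## Off-target calling

Translocation prey coordinates are clustered by single-linkage with a 100-bp
merge window (verified against a brute-force union-find oracle in tests);
clusters of ≥ 3 junctions are candidates, centered on the lower-median
coordinate. For each candidate the ±(guide+motif+25) bp neighbourhood is
scanned on both strands for the minimum-Hamming protospacer+motif match to
the on-target (motif positions counted; ties resolved toward the cluster
center). A candidate passes when the distance is ≤ 8 mismatches **and** ≥
50% of its junctions lie within ±10 bp of the match-implied cut midpoint
(our operationalization of a "cut-site junction pattern" — the criterion is
named in the literature without a formula; both thresholds are exposed).
Off/on strength = junctions within ±100 bp of the off-target ÷ indel
junctions within ±100 bp of the on-target cut, as a percentage.

Translocation accounting partitions every genomic translocation junction
exactly once: within ±500 kb of the target → near-target; else within
±100 bp of a called off-target → off-target; else general. Near-target takes
precedence, so an off-target inside the 500-kb exclusion zone contributes no
off-target junctions. The partition identity (near + off + general = total)
is asserted on every run. Genome-wide distributions use 2-Mb bins; TSS
profiles histogram signed distances to the nearest TSS (±2 kb window,
100-bp bins).

## Scoring

Raw dimensions per nuclease: A = mean editing efficiency over effective
sites (efficiency > 5%, falling back to all sites when none qualify); D =
1 / delivery size, where delivery size defaults to 3·aa + guide nt — a
nucleotide cargo proxy that avoids summing amino acids with nucleotides; the
literal aa + nt form is available via `coding_length=False`. S = 1 − mean
off/on fraction over called off-targets (the alternative on-target-proportion
form is available via `specificity="on_target_proportion"`; the two
formulations circulate interchangeably and neither is privileged here). P, T,
L = 1 minus the plasmid-integration, general-translocation and
large-deletion fractions of editing events. Each dimension is min–max
normalized across the panel; a constant dimension carries no information and
maps every system to 1 with a warning. Scores are comparative within a
panel, never absolute.

## Panel study conditions

`editscope.panel.CONDITIONS` fixes each of the eight systems' generator
parameters (editing probability, event-mix shares, integration rates,
large-deletion share and median, 1-bp insertion dominance for Cas9-class,
planted off-target counts/mismatches/fractions) at the magnitudes reported
for the respective families, so the simulated panel reproduces the
comparative structure — Cas9-class: highest activity, most 1-bp insertions
and large deletions; Cas12/TnpB-class: deletion-dominated, staggered cuts;
the compact Cas9 variant: extreme plasmid capture. One bookkeeping caveat:
the configured translocation share is the *total* translocation rate, of
which background junctions landing near the bait and junctions routed to
off-targets are subtracted before the *general*-translocation percentage is
reported, so the reported value sits below the configured share by a
genome-geometry factor (≈ the off-bait-chromosome fraction).

## Numerical choices and degenerate inputs

* Modal offsets: exact tie → smaller offset (toward the motif) and a tie
  flag, never silent.
* Profiles pool offsets beyond the ±50-nt window into tail bins; mass
  profiles sum to 1 over the reported window, coverage profiles are
  per-position probabilities in [0, 1] and deliberately do not sum to 1.
* Zero indels → integration rates reported as not-applicable (None), not 0.
* Deduplication sorts by the full molecule key, making it deterministic and
  idempotent; equal-RMB records with different junction coordinates are kept
  (conservative toward barcode collisions).
* Enriched plasmid bins: raw bin count above the Poisson 99.9% quantile of a
  uniform layout.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; identical inputs give byte-identical outputs.

## Problem sizes

The analysis drivers simulate 50,000 alleles per nuclease (8 systems,
~100,000 reads each, ~15 s total); validation simulations use 5,000–50,000
junctions depending on the statistical check. These sizes put binomial
3-standard-deviation bands well inside the effects being verified while
keeping the whole suite interactive.

## Known limitations

* Junction records are the interchange format; FASTQ emission/alignment and
  substitution calling are out of scope (junction assays cannot see
  substitutions).
* The background translocation model is a uniform+TSS stand-in; empirical
  partner distributions are not modeled.
* Off-target calls far below ~30 junctions per site are not guaranteed to be
  recovered (hotspot candidacy needs ≥ 3 deduplicated junctions).
* Scores depend on panel composition through min–max normalization;
  adding/removing a system rescales everyone.
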