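"""Nuclease specifications: motif requirements, sizes and double-strand cut models.

A :class:`NucleaseSpec` describes where an RNA-guided nuclease nicks each strand
relative to its motif (TAM for TnpB-class enzymes, PAM for Cas9/Cas12), which is
all the downstream geometry needs: predicted cut coordinates, expected overhang,
and blunt/staggered character.

Cut-offset convention
---------------------
Offsets are inter-nucleotide positions measured from the protospacer-proximal
motif edge, *away from the motif*:

* 5'-motif nucleases (TnpB, Cas12): offset ``k`` means the cut sits ``k`` nt
  downstream of the TAM (offset 0 = the TAM/protospacer boundary).
* 3'-motif nucleases (Cas9): offset ``k`` means ``k`` nt upstream of the PAM.

With a 20-nt guide, a TnpB-class non-target-strand (NTS) cut at +15 and a
target-strand (TS) cut at +21 (one past the guide body) leave a 6-nt 5'
overhang; a Cas9-class cut at 3/3 is blunt.
"""

from __future__ import annotations

from dataclasses import dataclass

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def matches_iupac(seq: str, motif: str) -> bool:
    """True when ``seq`` satisfies the degenerate ``motif`` position by position."""
    if len(seq) != len(motif):
        return False
    return all(s in IUPAC.get(m, "") for s, m in zip(seq, motif))


@dataclass(frozen=True)
class NucleaseSpec:
    """A nuclease's recognition and cleavage geometry.

    Parameters
    ----------
    name:
        Display name of the system.
    protein_aa:
        Effector size in amino acids (enters the deliverability score).
    guide_nt:
        Length of the guide/spacer in nucleotides.
    motif:
        TAM/PAM as an IUPAC string, written 5'->3' on the protospacer strand.
    motif_side:
        ``"5prime"`` (TnpB/Cas12: motif 5' of protospacer) or ``"3prime"``
        (Cas9: motif 3' of protospacer).
    nts_cut_offset, ts_cut_offset:
        Per-strand cut offsets in the module-level convention.
    """

    name: str
    protein_aa: int
    guide_nt: int
    motif: str
    motif_side: str
    nts_cut_offset: int
    ts_cut_offset: int

    def __post_init__(self):
        if self.motif_side not in ("5prime", "3prime"):
            raise ValueError(f"motif_side must be 5prime/3prime, got {self.motif_side!r}")
        if any(b not in IUPAC for b in self.motif):
            raise ValueError(f"motif {self.motif!r} is not IUPAC")

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def blunt(self) -> bool:
        """True iff both strands are cut at the same inter-nucleotide position."""
        return self.nts_cut_offset == self.ts_cut_offset

    @property
    def overhang_nt(self) -> int:
        return abs(self.ts_cut_offset - self.nts_cut_offset)

    def predicted_cuts(self, motif_interval: tuple[int, int], strand: str) -> tuple[int, int]:
        """Reference (NTS, TS) cut coordinates for a site with this motif placement.

        ``motif_interval`` is 0-based half-open on the reference; ``strand`` is
        the protospacer strand. Cut coordinates are inter-nucleotide indices.
        """
        m0, m1 = motif_interval
        if self.motif_side == "5prime":
            edge, away = (m1, +1) if strand == "+" else (m0, -1)
        else:
            edge, away = (m0, -1) if strand == "+" else (m1, +1)
        return edge + away * self.nts_cut_offset, edge + away * self.ts_cut_offset

    def delivery_size(self, coding_length: bool = True) -> float:
        """Cargo-size proxy: 3*aa + guide nt (default) or aa + nt as sometimes quoted."""
        if coding_length:
            return 3 * self.protein_aa + self.guide_nt
        return self.protein_aa + self.guide_nt


def _tnpb(name, aa, motif, nts=15, ts=21, guide=20):
    return NucleaseSpec(name, aa, guide, motif, "5prime", nts, ts)


# Packaged panel. Cut models: TnpB-class staggered (NTS +15 past the TAM, TS one
# past the 20-nt guide body -> 6-nt overhang; ISAam1 NTS +16), Cas12a-like
# staggered (18/23), Cas12f-like staggered (20/24), Cas9-class blunt (3 nt
# upstream of the PAM on both strands). ISDra2's 408 aa is the experimentally
# established size; the remaining sizes/guide lengths are editable defaults at
# realistic magnitudes.
PANEL: dict[str, NucleaseSpec] = {
    "ISDra2": _tnpb("ISDra2", 408, "TTTAT"),
    "ISDge10": _tnpb("ISDge10", 420, "TTAT"),
    "ISAam1": _tnpb("ISAam1", 411, "TTTAA", nts=16),
    "ISYmu1": _tnpb("ISYmu1", 382, "TTTAT"),
    "AsCas12a": NucleaseSpec("AsCas12a", 1307, 20, "TTTV", "5prime", 18, 23),
    "CasMINI": NucleaseSpec("CasMINI", 529, 20, "TTTR", "5prime", 20, 24),
    "SpCas9": NucleaseSpec("SpCas9", 1368, 20, "NGG", "3prime", 3, 3),
    "eNme2-C.NR": NucleaseSpec("eNme2-C.NR", 1082, 22, "NNNNCC", "3prime", 3, 3),
}


def get_spec(name: str) -> NucleaseSpec:
    try:
        return PANEL[name]
    except KeyError:
        raise KeyError(f"unknown nuclease {name!r}; packaged: {sorted(PANEL)}") from None
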