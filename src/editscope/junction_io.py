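"""Junction-table serialization and molecular-barcode deduplication.

The interchange format is a tab-separated table with a single '#'-prefixed
header line and '.' for not-applicable fields:

    #read_id  rmb  bait_chrom  bait_strand  bait_end  prey_source  prey_chrom
    prey_pos  prey_strand  insert_seq

One line per sequenced read. PCR duplicates of the same molecule share their
RMB, bait broken end and prey coordinates; :func:`dedup_junctions` collapses
them to one representative per molecule.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError
from .synthetic_data import JUNCTION_COLUMNS, GenomeFixture

# key identifying one molecule (the spec of the RMB protocol: same barcode,
# same junction coordinates => same pre-amplification molecule)
DEDUP_KEY = [
    "rmb", "bait_chrom", "bait_strand", "bait_end",
    "prey_source", "prey_chrom", "prey_pos", "prey_strand", "insert_seq",
]

_NA = "."


def write_junctions(records: pd.DataFrame, path: str | Path) -> None:
    """Write a junction table in the documented TSV dialect."""
    out = records.loc[:, JUNCTION_COLUMNS].copy()
    out["insert_seq"] = out["insert_seq"].replace("", _NA)
    out["prey_chrom"] = out["prey_chrom"].replace("", _NA)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(JUNCTION_COLUMNS) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def load_junctions(path: str | Path, fixture: GenomeFixture | None = None) -> pd.DataFrame:
    """Load a junction TSV, validating structure and coordinates.

    Malformed lines are rejected with their 1-based line number. When a
    ``fixture`` is given, genomic coordinates are additionally checked against
    its chromosome lengths.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header.startswith("#"):
        raise FormatError(f"{path}: missing '#'-prefixed header line")
    cols = header[1:].split("\t")
    if cols != JUNCTION_COLUMNS:
        missing = set(JUNCTION_COLUMNS) - set(cols)
        raise FormatError(f"{path}: header mismatch (missing: {sorted(missing)})")

    df = pd.read_csv(
        path, sep="\t", skiprows=1, names=JUNCTION_COLUMNS, dtype=str,
        keep_default_na=False, skip_blank_lines=False,
    )
    if df.empty:
        df["bait_end"] = df["bait_end"].astype(int)
        df["prey_pos"] = df["prey_pos"].astype(int)
        return df

    lines = df.index.to_numpy() + 2  # 1-based, after the header
    for col in ("bait_end", "prey_pos"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            raise FormatError(f"{path}: non-integer {col} on line {lines[bad.to_numpy()][0]}")
        df[col] = converted.astype(int)

    for col in ("bait_end", "prey_pos"):
        neg = df[col] < 0
        if neg.any():
            raise ValidationError(
                f"negative {col} in {path.name}", line=int(lines[neg.to_numpy()][0])
            )
    bad_src = ~df["prey_source"].isin(["genome", "plasmid", "mito"])
    if bad_src.any():
        raise ValidationError(
            f"unknown prey_source {df['prey_source'][bad_src].iloc[0]!r}",
            line=int(lines[bad_src.to_numpy()][0]),
        )
    if fixture is not None:
        lengths = fixture.chrom_lengths
        for col_chrom, col_pos in (("bait_chrom", "bait_end"), ("prey_chrom", "prey_pos")):
            chroms = df[col_chrom]
            known = chroms.map(lengths)
            genomic = (chroms != _NA) if col_chrom == "prey_chrom" else pd.Series(True, index=df.index)
            if col_chrom == "prey_chrom":
                genomic &= df["prey_source"] == "genome"
            unknown = genomic & known.isna()
            if unknown.any():
                raise ValidationError(
                    f"unknown chromosome {chroms[unknown].iloc[0]!r}",
                    line=int(lines[unknown.to_numpy()][0]),
                )
            over = genomic & (df[col_pos] > known.fillna(float("inf")))
            if over.any():
                raise ValidationError(
                    f"{col_pos} beyond end of {chroms[over].iloc[0]}",
                    line=int(lines[over.to_numpy()][0]),
                )
    df["insert_seq"] = df["insert_seq"].replace(_NA, "")
    return df


def dedup_junctions(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse PCR duplicates: one representative per (RMB, junction) key.

    Records sharing the full :data:`DEDUP_KEY` are one molecule; records with
    the same RMB but different junction coordinates are kept apart (barcode
    collisions are tolerated rather than merged). Output is sorted by key, so
    the operation is deterministic and idempotent.
    """
    if records.empty:
        return records.copy()
    out = (
        records.sort_values(DEDUP_KEY + ["read_id"], kind="mergesort")
        .drop_duplicates(DEDUP_KEY, keep="first")
        .reset_index(drop=True)
    )
    return out


def bait_ends_to_bed(records: pd.DataFrame, path: str | Path) -> None:
    """Export bait broken ends as single-base BED intervals for browsing."""
    with open(path, "w") as fh:
        for row in records.itertuples(index=False):
            fh.write(
                f"{row.bait_chrom}\t{row.bait_end}\t{row.bait_end + 1}\t"
                f"{row.read_id}\t0\t{row.bait_strand}\n"
            )
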