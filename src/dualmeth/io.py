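"""Readers/writers for the on-disk formats, BED/FASTA export and flank extraction.

Conventions
-----------
* Beta and detection-p matrices are TSV: first column the probe id, header
  row of sample ids, missing entries written as the literal token ``NA``.
* Manifest coordinates (``MAPINFO``) are 1-based, Illumina style; every
  exported interval (BED, flank windows) is 0-based half-open.
* Probe annotation lives in a :class:`pandas.DataFrame` indexed by probe id
  with columns ``chrom`` (str), ``pos`` (int, 1-based), ``gene_entries``
  (tuple of ``(gene_symbol, region_group)`` pairs), ``island_relation``
  (str) and ``intergenic`` (bool).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGION_GROUPS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: manifest spellings normalised to the canonical vocabulary
_REGION_ALIASES = {"5'UTR": "5UTR", "3'UTR": "3UTR"}

MANIFEST_COLUMNS = [
    "IlmnID",
    "CHR",
    "MAPINFO",
    "UCSC_RefGene_Name",
    "UCSC_RefGene_Group",
    "Relation_to_UCSC_CpG_Island",
]

SAMPLE_SHEET_COLUMNS = ["sample_id", "species", "assay", "beadchip", "replicate_group"]
SPECIES = ("human", "monkey")
ASSAYS = ("BS", "TAB")


@dataclass
class FlankWindow:
    """A (merged) 0-based half-open window around one or more loci."""

    chrom: str
    start: int
    end: int
    member_probe_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end must exceed start: {self}")


# ---------------------------------------------------------------------------
# beta / detection-p matrices
# ---------------------------------------------------------------------------

def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes x samples matrix TSV; ``NA`` becomes NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df = df.astype(float)
    bad = df.to_numpy()
    with np.errstate(invalid="ignore"):
        if np.any((bad < 0) | (bad > 1)):
            raise ValueError("matrix contains values outside [0, 1]")
    return df


def write_beta_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


read_detection_p_matrix = read_beta_matrix
write_detection_p_matrix = write_beta_matrix


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        dupes = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    bad_sp = set(sheet["species"]) - set(SPECIES)
    if bad_sp:
        raise ValueError(f"unknown species labels: {sorted(bad_sp)}")
    bad_assay = set(sheet["assay"]) - set(ASSAYS)
    if bad_assay:
        raise ValueError(f"unknown assay labels: {sorted(bad_assay)}")
    # technical replicates never straddle species or assay
    for grp, sub in sheet.groupby("replicate_group"):
        if sub["species"].nunique() > 1 or sub["assay"].nunique() > 1:
            raise ValueError(f"replicate group {grp!r} mixes species or assay")
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifest / probe annotation
# ---------------------------------------------------------------------------

def _parse_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return []
    return [tok for tok in str(value).split(";")]


def read_manifest(path) -> pd.DataFrame:
    """Parse an HM450-style manifest CSV into a probe-annotation frame.

    Paired gene / region-group lists are zipped positionally; an empty
    island-relation field means open sea.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if raw["IlmnID"].duplicated().any():
        dupes = raw.loc[raw["IlmnID"].duplicated(), "IlmnID"].tolist()
        raise ValueError(f"duplicate probe ids in manifest: {dupes}")

    records = []
    for row in raw.itertuples(index=False):
        genes = _parse_multi(row.UCSC_RefGene_Name)
        groups = [_REGION_ALIASES.get(g, g) for g in _parse_multi(row.UCSC_RefGene_Group)]
        for g in groups:
            if g not in REGION_GROUPS:
                raise ValueError(f"unknown region-group token {g!r} for probe {row.IlmnID}")
        if len(genes) != len(groups):
            raise ValueError(
                f"probe {row.IlmnID}: {len(genes)} genes but {len(groups)} region groups"
            )
        island = row.Relation_to_UCSC_CpG_Island or "OpenSea"
        if island not in ISLAND_RELATIONS:
            raise ValueError(f"unknown island relation {island!r} for probe {row.IlmnID}")
        pos = int(row.MAPINFO)
        if pos < 1:
            raise ValueError(f"probe {row.IlmnID}: position {pos} < 1")
        entries = tuple(zip(genes, groups))
        records.append(
            {
                "probe_id": row.IlmnID,
                "chrom": str(row.CHR),
                "pos": pos,
                "gene_entries": entries,
                "island_relation": island,
                "intergenic": len(entries) == 0,
            }
        )
    ann = pd.DataFrame.from_records(records).set_index("probe_id")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    """Write annotation back to the manifest CSV layout (round-trippable)."""
    out = pd.DataFrame(
        {
            "IlmnID": ann.index,
            "CHR": ann["chrom"].to_numpy(),
            "MAPINFO": ann["pos"].to_numpy(),
            "UCSC_RefGene_Name": [";".join(g for g, _ in e) for e in ann["gene_entries"]],
            "UCSC_RefGene_Group": [";".join(r for _, r in e) for e in ann["gene_entries"]],
            "Relation_to_UCSC_CpG_Island": [
                "" if rel == "OpenSea" else rel for rel in ann["island_relation"]
            ],
        }
    )
    out.to_csv(path, index=False)


def read_whitelist(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def apply_probe_whitelist(betas: pd.DataFrame, whitelist: Iterable[str]) -> pd.DataFrame:
    """Restrict matrix rows to a probe whitelist, preserving original order."""
    wl = set(whitelist)
    if not wl:
        raise ValueError("probe whitelist is empty")
    keep = betas.index.isin(wl)
    absent = wl - set(betas.index)
    if absent:
        warnings.warn(
            f"{len(absent)} whitelist probes absent from matrix", stacklevel=2
        )
    if not keep.any():
        raise ValueError("whitelist does not intersect the matrix probes")
    return betas.loc[keep]


# ---------------------------------------------------------------------------
# BED / FASTA export
# ---------------------------------------------------------------------------

def export_bed(ann: pd.DataFrame, path) -> None:
    """Write one BED line per probe: chrom, pos-1, pos, probe_id (sorted)."""
    if (ann["pos"] < 1).any():
        bad = ann.index[ann["pos"] < 1].tolist()
        raise ValueError(f"positions < 1 cannot be exported to BED: {bad}")
    bed = pd.DataFrame(
        {
            "chrom": ann["chrom"].to_numpy(),
            "start": ann["pos"].to_numpy() - 1,
            "end": ann["pos"].to_numpy(),
            "name": ann.index.to_numpy(),
        }
    ).sort_values(["chrom", "start", "name"], kind="stable")
    bed.to_csv(path, sep="\t", header=False, index=False)


def merge_flank_windows(
    ann: pd.DataFrame, flank: int = 250, merge_gap: int = 500
) -> list[FlankWindow]:
    """Build merged flanking windows around loci without touching a genome.

    Loci on the same chromosome closer than ``merge_gap`` are clustered into
    one window spanning ``min_pos - 1 - flank`` to ``max_pos + flank``.  A
    gap of up to ``2 * flank`` is merged as well so windows never overlap.
    Coordinates are not yet clipped to chromosome bounds (no genome here).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    windows: list[FlankWindow] = []
    merge_at = max(merge_gap - 1, 2 * flank)
    for chrom, sub in ann.sort_values(["chrom", "pos"], kind="stable").groupby(
        "chrom", sort=True
    ):
        pos = sub["pos"].to_numpy()
        ids = sub.index.to_numpy()
        cluster_start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > merge_at:
                lo, hi = pos[cluster_start], pos[i - 1]
                windows.append(
                    FlankWindow(
                        chrom=str(chrom),
                        start=max(lo - 1 - flank, 0),
                        end=hi + flank,
                        member_probe_ids=list(ids[cluster_start:i]),
                    )
                )
                cluster_start = i
    return windows


def extract_flank_windows(
    ann: pd.DataFrame,
    genome_fasta,
    flank: int = 250,
    merge_gap: int = 500,
    fasta_out=None,
) -> list[FlankWindow]:
    """Merged flank windows plus their forward-strand sequences.

    ``genome_fasta`` is a path to an (indexable) FASTA.  Windows are clipped
    to chromosome bounds; one FASTA record per window with header
    ``chrom:start-end`` is written to ``fasta_out`` when given.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta))
    windows = merge_flank_windows(ann, flank=flank, merge_gap=merge_gap)
    records = []
    for w in windows:
        if w.chrom not in genome:
            raise ValueError(f"chromosome {w.chrom!r} absent from genome FASTA")
        chrom_len = len(genome[w.chrom])
        w.start = max(w.start, 0)
        w.end = min(w.end, chrom_len)
        seq = genome[w.chrom][w.start : w.end].seq
        records.append((f"{w.chrom}:{w.start}-{w.end}", seq))
    if fasta_out is not None:
        with open(fasta_out, "w") as fh:
            for header, seq in records:
                fh.write(f">{header}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
    return windows


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, index_label: str = "probe_id") -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def read_table(path, index_col: int | str | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"], keep_default_na=False)
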