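"""Readers, writers, and validated containers for every external table.

All tabular formats are plain TSV with a stable column order; protein
sequences are FASTA. Missing abundances are represented as absent (NaN),
never zero: zeros in input are coerced to missing with a warning, since a
zero reporter intensity in isobaric-label data almost always means
"not quantified" rather than a true zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

META_COLS = ["protein_id", "peptide", "start", "end"]

GROUPS = ("case", "control", "reference")

TOPOLOGY_CLASSES = (
    "single-pass type I",
    "single-pass type II",
    "GPI-anchored",
    "multi-pass",
    "secreted",
    "other",
)


class TableFormatError(ValueError):
    """Raised when an input table violates the schema."""


@dataclass
class PeptideQuantTable:
    """Peptide-level abundances with protein assignment and coordinates.

    `data` holds one row per (protein, peptide, start) with columns
    protein_id, peptide, start, end followed by one abundance column per
    sample; `groups` maps each sample column to 'case', 'control' or
    'reference'. Coordinates are 1-based inclusive residue positions.
    """

    data: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    @property
    def sample_cols(self) -> list[str]:
        return [c for c in self.data.columns if c in self.groups]

    def samples_in(self, group: str) -> list[str]:
        return [c for c in self.sample_cols if self.groups[c] == group]

    @property
    def reference_col(self) -> str | None:
        refs = self.samples_in("reference")
        return refs[0] if refs else None

    def validate(self, require_coords: bool = True) -> None:
        cols = list(self.data.columns)
        need = META_COLS if require_coords else META_COLS[:2]
        for c in need:
            if c not in cols:
                raise TableFormatError(f"missing required column '{c}'")
        for c in cols:
            if c in META_COLS:
                continue
            if c not in self.groups:
                raise TableFormatError(f"sample column '{c}' has no group assignment")
            if self.groups[c] not in GROUPS:
                raise TableFormatError(
                    f"sample '{c}' assigned unknown group '{self.groups[c]}'"
                )
        refs = self.samples_in("reference")
        if len(refs) > 1:
            raise TableFormatError(f"multiple reference columns: {refs}")
        if require_coords:
            start = self.data["start"]
            end = self.data["end"]
            bad = self.data.index[(start < 1) | (end < start)]
            if len(bad):
                raise TableFormatError(
                    f"malformed coordinates (start > end or start < 1) "
                    f"in row(s) {list(bad[:5])}"
                )
        vals = self.data[self.sample_cols]
        neg = vals.lt(0)
        if neg.any().any():
            col = neg.any().idxmax()
            row = neg[col].idxmax()
            raise TableFormatError(
                f"negative abundance at row {row}, column '{col}'"
            )


@dataclass
class ProteinQuantTable:
    """Protein x sample matrix of log2 ratio-to-reference values.

    `values` is indexed by protein_id with one column per sample (NaN
    allowed); `groups` maps samples to 'case' or 'control'.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def samples_in(self, group: str) -> list[str]:
        return [c for c in self.values.columns if self.groups.get(c) == group]

    def validate(self) -> None:
        for c in self.values.columns:
            if c not in self.groups:
                raise TableFormatError(f"sample column '{c}' has no group assignment")
        present = self.values.to_numpy()
        if np.isinf(present[~np.isnan(present)]).any():
            raise TableFormatError("non-finite values present")
        for g in ("case", "control"):
            if not self.samples_in(g):
                raise TableFormatError(f"group '{g}' has no samples")


def _coerce_zeros(frame: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    n_zero = int((frame[cols] == 0).sum().sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} zero abundance(s) treated as missing", stacklevel=3
        )
        frame = frame.copy()
        frame[cols] = frame[cols].replace(0.0, np.nan)
    return frame


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, group) into a mapping."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["sample_id", "group"]:
        raise TableFormatError(
            f"group map must have columns sample_id, group; got {list(frame.columns)}"
        )
    return dict(zip(frame["sample_id"], frame["group"]))


def write_group_map(groups: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_peptide_table(
    path: str | Path,
    group_map: dict[str, str] | str | Path,
    sep: str = "\t",
    duplicate_agg: str = "sum",
    require_coords: bool = True,
) -> PeptideQuantTable:
    """Read and validate a peptide quantification table.

    Every non-metadata column must appear in group_map. Duplicate
    (protein_id, peptide, start) rows are aggregated per sample by
    `duplicate_agg` ('sum', 'mean', or 'error' to reject).
    """
    if not isinstance(group_map, dict):
        group_map = read_group_map(group_map)
    frame = pd.read_csv(path, sep=sep)
    sample_cols = [c for c in frame.columns if c not in META_COLS]
    for c in sample_cols:
        if c not in group_map:
            raise TableFormatError(f"sample column '{c}' not in group map")
        frame[c] = pd.to_numeric(frame[c], errors="raise")
    frame = _coerce_zeros(frame, sample_cols)

    key = [c for c in ("protein_id", "peptide", "start") if c in frame.columns]
    if frame.duplicated(key).any():
        if duplicate_agg == "error":
            dup = frame[frame.duplicated(key, keep=False)]
            raise TableFormatError(f"duplicate peptide rows: {dup[key].values[:5]}")
        agg = {c: duplicate_agg for c in sample_cols}
        meta = [c for c in META_COLS if c in frame.columns and c not in key]
        agg.update({c: "first" for c in meta})
        frame = frame.groupby(key, as_index=False, sort=False).agg(agg)
        frame = frame[[c for c in META_COLS if c in frame.columns] + sample_cols]

    table = PeptideQuantTable(data=frame, groups=dict(group_map))
    table.validate(require_coords=require_coords)
    return table


def write_peptide_table(table: PeptideQuantTable, path: str | Path) -> None:
    meta = [c for c in META_COLS if c in table.data.columns]
    ordered = meta + [c for c in table.sample_cols if table.groups[c] != "reference"]
    ref = table.reference_col
    if ref:
        ordered.append(ref)
    table.data[ordered].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_protein_table(
    path: str | Path, group_map: dict[str, str] | str | Path
) -> ProteinQuantTable:
    if not isinstance(group_map, dict):
        group_map = read_group_map(group_map)
    frame = pd.read_csv(path, sep="\t", index_col="protein_id")
    table = ProteinQuantTable(values=frame, groups=dict(group_map))
    table.validate()
    return table


def write_protein_table(table: ProteinQuantTable, path: str | Path) -> None:
    out = table.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def _fasta_id(header_id: str) -> str:
    """Extract the accession: UniProt pipe format 'db|ACC|NAME' -> ACC."""
    parts = header_id.split("|")
    if len(parts) >= 2 and parts[1]:
        return parts[1]
    return header_id


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; ids de-piped from UniProt-style headers."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = _fasta_id(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise TableFormatError(f"empty sequence for '{pid}'")
        if pid in seqs:
            raise TableFormatError(f"duplicate FASTA id '{pid}'")
        seqs[pid] = seq
    if not seqs:
        raise TableFormatError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def map_peptide_positions(
    table: PeptideQuantTable, seqs: dict[str, str]
) -> PeptideQuantTable:
    """Assign 1-based coordinates by exact substring search.

    Peptides matching at multiple positions within their protein are
    dropped (positional ambiguity would corrupt the block statistic), as
    are peptides not found at all; both are logged. Leu and Ile are
    distinct. A protein absent from the FASTA is a hard error.
    """
    missing = set(table.data["protein_id"]) - set(seqs)
    if missing:
        raise KeyError(f"protein(s) absent from FASTA: {sorted(missing)[:5]}")
    starts: list[float] = []
    ends: list[float] = []
    keep = np.ones(len(table.data), dtype=bool)
    n_ambiguous = n_unmatched = 0
    for i, (pid, pep) in enumerate(
        zip(table.data["protein_id"], table.data["peptide"])
    ):
        seq = seqs[pid]
        first = seq.find(pep)
        if first < 0:
            keep[i] = False
            n_unmatched += 1
            starts.append(np.nan)
            ends.append(np.nan)
            continue
        if seq.find(pep, first + 1) >= 0:
            keep[i] = False
            n_ambiguous += 1
            starts.append(np.nan)
            ends.append(np.nan)
            continue
        starts.append(first + 1)
        ends.append(first + len(pep))
    if n_ambiguous:
        logger.info("dropped %d peptide(s) mapping ambiguously", n_ambiguous)
    if n_unmatched:
        logger.info("dropped %d peptide(s) not found in their protein", n_unmatched)
    data = table.data.copy()
    data["start"] = starts
    data["end"] = ends
    data = data.loc[keep].reset_index(drop=True)
    data["start"] = data["start"].astype(int)
    data["end"] = data["end"].astype(int)
    data = data[META_COLS + [c for c in data.columns if c not in META_COLS]]
    out = PeptideQuantTable(data=data, groups=dict(table.groups))
    out.validate()
    return out


def read_topology_table(path: str | Path) -> pd.Series:
    """Read protein_id -> topology class; vocabulary is enforced."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["protein_id", "topology"]:
        raise TableFormatError(
            f"topology table must have columns protein_id, topology; "
            f"got {list(frame.columns)}"
        )
    bad = set(frame["topology"]) - set(TOPOLOGY_CLASSES)
    if bad:
        raise TableFormatError(f"unknown topology class(es): {sorted(bad)}")
    if frame["protein_id"].duplicated().any():
        raise TableFormatError("duplicate protein_id in topology table")
    return frame.set_index("protein_id")["topology"]


def write_topology_table(topology: pd.Series, path: str | Path) -> None:
    frame = topology.rename("topology").rename_axis("protein_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_protease_db(path: str | Path) -> pd.DataFrame:
    """Read a protease-substrate relationship table (MEROPS-style TSV).

    Columns: protease_id, substrate_id, evidence. Duplicate
    (protease, substrate) pairs are merged, concatenating evidence tags.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    need = ["protease_id", "substrate_id"]
    if list(frame.columns[: len(need)]) != need:
        raise TableFormatError(
            f"protease db must start with columns {need}; got {list(frame.columns)}"
        )
    if "evidence" not in frame.columns:
        frame["evidence"] = ""
    frame = (
        frame.groupby(need, as_index=False, sort=False)["evidence"]
        .agg(lambda tags: ";".join(sorted({t for t in tags if t})))
    )
    return frame[need + ["evidence"]]


def write_protease_db(db: pd.DataFrame, path: str | Path) -> None:
    db.to_csv(path, sep="\t", index=False)
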