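"""Sequence, region-table and manifest input/output.

The analysis is anchored on a reference protein (rat TRPV1 in the shipped
region table): domain/motif coordinates are 1-based inclusive residue indices
on the *ungapped* reference sequence. Unknown residues are kept as ``'X'`` and
treated downstream as missing data, matching the pairwise-deletion convention
used for the distance statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: residues legal in a (possibly gapped) analysis sequence
ALPHABET = AA20 | {"-", "X"}

#: canonical lineage tags carried in the manifest ``group`` column
LINEAGE_TAGS = ("mammal", "bird_reptile", "fish", "amphibian", "outgroup", "other")


class FastaFormatError(ValueError):
    """Malformed or inconsistent FASTA input."""


class RegionTableError(ValueError):
    """Malformed region-definition table."""


@dataclass(frozen=True)
class ProteinRecord:
    """One species' protein sequence plus identity metadata.

    ``sequence`` is upper-case over the 20 amino acids plus ``'-'`` (gap) and
    ``'X'`` (unknown); it may be gapped (a row of an alignment) or ungapped.
    """

    id: str
    sequence: str
    species: str = ""
    group: str = "other"

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("record id must be non-empty")
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)!r}"
            )

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")

    def with_metadata(self, species: str, group: str) -> "ProteinRecord":
        return dataclasses.replace(self, species=species, group=group)


@dataclass(frozen=True)
class Alignment:
    """An ordered protein multiple alignment; all rows share one width."""

    records: tuple[ProteinRecord, ...]

    def __init__(self, records: Iterable[ProteinRecord]):
        object.__setattr__(self, "records", tuple(records))
        if not self.records:
            raise FastaFormatError("alignment needs at least one record")
        widths = {len(r.sequence) for r in self.records}
        if len(widths) != 1:
            raise FastaFormatError(
                f"ragged alignment: row lengths {sorted(widths)}"
            )

    @property
    def width(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def get(self, record_id: str) -> ProteinRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(f"id {record_id!r} not in alignment")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class RegionDef:
    """A named region on the reference, 1-based inclusive coordinates."""

    name: str
    start: int
    end: int
    category: str = "other"

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise RegionTableError(f"region {self.name!r}: non-integer coordinates")
        if not (1 <= self.start <= self.end):
            raise RegionTableError(
                f"region {self.name!r}: invalid span {self.start}-{self.end}"
            )

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA. Ids are the header token before the first
    whitespace; sequences are upper-cased and a single terminal ``'*'`` stop
    is stripped. Raises :class:`FastaFormatError` on empty files, duplicate
    ids or illegal characters.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in seen:
            raise FastaFormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.species)
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_alignment(path: str | Path) -> Alignment:
    return Alignment(read_fasta(path))


def load_region_table(path: str | Path | None = None) -> list[RegionDef]:
    """Load a region table (TSV: name, start, end, category).

    With ``path=None`` the packaged TRPV1 table is returned: all 28 domains,
    motifs and interacting sites on the rat reference (N-terminal 1-432
    through PIP-2 778-819). Overlapping regions are permitted (e.g. CBD
    577-593 inside TM-5 577-596).
    """
    if path is None:
        source = resources.files("trpcons.data") / "trpv1_regions.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "start", "end", "category"}
    missing = required - set(df.columns)
    if missing:
        raise RegionTableError(f"region table missing columns {sorted(missing)}")
    regions: list[RegionDef] = []
    names: set[str] = set()
    for row in df.itertuples(index=False):
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise RegionTableError(
                f"region {row.name!r}: non-integer coordinates"
            ) from exc
        if row.name in names:
            raise RegionTableError(f"duplicate region name {row.name!r}")
        names.add(row.name)
        regions.append(RegionDef(row.name, start, end, row.category))
    return regions


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest TSV (id, species, group; optional
    divergence_time_mya). Lineage group is supplied here, never inferred."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "species": str, "group": str})
    required = {"id", "species", "group"}
    missing = required - set(df.columns)
    if missing:
        raise RegionTableError(f"manifest missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise RegionTableError(f"duplicate manifest id {dup!r}")
    return df


def apply_manifest(
    records: Sequence[ProteinRecord], manifest: pd.DataFrame
) -> list[ProteinRecord]:
    """Attach species/group metadata from a manifest to matching records."""
    meta = {row.id: (row.species, row.group) for row in manifest.itertuples(index=False)}
    out = []
    for rec in records:
        if rec.id in meta:
            species, group = meta[rec.id]
            rec = rec.with_metadata(str(species), str(group))
        out.append(rec)
    return out


def _format_cell(value) -> str:
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_tsv(rows: Sequence[Mapping[str, object]], path: str | Path,
              columns: Sequence[str] | None = None) -> None:
    """Write homogeneous dict rows as UTF-8 TSV with a header; floats are
    rendered at 6 significant digits. Empty ``rows`` requires ``columns`` to
    emit a header-only file."""
    if columns is None:
        if not rows:
            raise ValueError("empty rows: pass explicit columns for a header-only file")
        columns = list(rows[0].keys())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_format_cell(row[c]) for c in columns) + "\n")
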