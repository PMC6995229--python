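"""Readers/writers and the boundary data model for alignments and qPCR tables.

Sequence data enter the pipeline as multi-record FASTA alignments with a
sidecar metadata table mapping each record id to its isochromosomal line,
chromosomal arrangement (cold-climate O_ST vs warm-climate O_3+4+7), and
hsp70 gene copy (A or B).  Expression data enter as a tidy delimited table of
raw qPCR threshold cycles (Ct), one row per technical replicate per gene.

Coordinates are 0-based half-open internally; user-facing reports are
1-based inclusive.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentLengthError,
    AlphabetError,
    FormatError,
    SchemaError,
    TableValueError,
)

ALPHABET = frozenset("ACGTN-")


class Arrangement(str, enum.Enum):
    """Chromosomal gene arrangement of the O chromosome."""

    OST = "OST"
    O347 = "O347"
    OTHER = "OTHER"


class GeneCopy(str, enum.Enum):
    A = "A"
    B = "B"
    NA = "NA"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"


class Gene(str, enum.Enum):
    TARGET = "target"
    REFERENCE = "reference"


_ARRANGEMENT_SYNONYMS = {
    "OST": Arrangement.OST,
    "ST": Arrangement.OST,
    "O347": Arrangement.O347,
    "347": Arrangement.O347,
    "OTHER": Arrangement.OTHER,
}

_SEX_SYNONYMS = {
    "F": Sex.F,
    "FEMALE": Sex.F,
    "M": Sex.M,
    "MALE": Sex.M,
}

_GENE_SYNONYMS = {
    "TARGET": Gene.TARGET,
    "HSP70": Gene.TARGET,
    "REFERENCE": Gene.REFERENCE,
    "REF": Gene.REFERENCE,
    "RP49": Gene.REFERENCE,
}


def parse_arrangement(value) -> Arrangement:
    if isinstance(value, Arrangement):
        return value
    key = str(value).strip().upper().replace("_", "").replace("+", "").replace(" ", "")
    try:
        return _ARRANGEMENT_SYNONYMS[key]
    except KeyError:
        raise TableValueError(f"unrecognized arrangement label: {value!r}") from None


def parse_gene_copy(value) -> GeneCopy:
    if isinstance(value, GeneCopy):
        return value
    key = str(value).strip().upper()
    if key in ("", "NA", "NONE", "-"):
        return GeneCopy.NA
    try:
        return GeneCopy[key]
    except KeyError:
        raise TableValueError(f"unrecognized gene copy label: {value!r}") from None


def parse_sex(value) -> Sex:
    if isinstance(value, Sex):
        return value
    try:
        return _SEX_SYNONYMS[str(value).strip().upper()]
    except KeyError:
        raise TableValueError(f"unrecognized sex label: {value!r}") from None


def parse_gene(value) -> Gene:
    if isinstance(value, Gene):
        return value
    try:
        return _GENE_SYNONYMS[str(value).strip().upper()]
    except KeyError:
        raise TableValueError(f"unrecognized gene label: {value!r}") from None


def normalize_sequence(seq: str, record_id: str = "<seq>") -> str:
    """Upper-case, map U to T, and validate against {A,C,G,T,N,-}.

    Raises :class:`AlphabetError` naming the record and the 1-based column of
    the first offending character.
    """
    up = seq.upper().replace("U", "T")
    for col, ch in enumerate(up, start=1):
        if ch not in ALPHABET:
            raise AlphabetError(
                f"record {record_id!r}: character {ch!r} at column {col} "
                f"is outside the alphabet {{A,C,G,T,U,N,-}}"
            )
    return up


@dataclass
class SequenceRecord:
    """One aligned haplotype with its line/arrangement/copy identity."""

    id: str
    sequence: str
    line_id: str = ""
    arrangement: Arrangement = Arrangement.OTHER
    gene_copy: GeneCopy = GeneCopy.NA

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record id must be non-empty")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        self.sequence = normalize_sequence(self.sequence, self.id)
        self.arrangement = parse_arrangement(self.arrangement)
        self.gene_copy = parse_gene_copy(self.gene_copy)
        if not self.line_id:
            self.line_id = self.id

    @property
    def ungapped(self) -> str:
        return self.sequence.replace("-", "")


@dataclass
class AlignedSequenceSet:
    """An ordered multiple sequence alignment with per-record metadata."""

    records: tuple

    def __post_init__(self):
        self.records = tuple(self.records)
        if len(self.records) < 2:
            raise AlignmentLengthError("an alignment needs at least 2 records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            detail = ", ".join(f"{r.id}:{len(r.sequence)}" for r in self.records)
            raise AlignmentLengthError(f"ragged alignment (lengths {detail})")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate record ids in alignment: {dupes}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0].sequence)

    @property
    def ids(self) -> tuple:
        return tuple(r.id for r in self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def subset(self, ids: Iterable[str]) -> "AlignedSequenceSet":
        """Sub-alignment restricted to ``ids``, preserving alignment order."""
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return AlignedSequenceSet(tuple(r for r in self.records if r.id in wanted))

    def matrix(self) -> np.ndarray:
        """(n_records, n_columns) array of single characters."""
        return np.array([list(r.sequence) for r in self.records], dtype="<U1")


def _metadata_for(record_id: str, metadata):
    """Resolve (line, arrangement, copy) from the sidecar mapping or a
    pipe-delimited header fallback ``id|line|arrangement|copy``."""
    if metadata and record_id in metadata:
        entry = metadata[record_id]
        if isinstance(entry, Mapping):
            return (
                entry.get("line_id", record_id),
                entry.get("arrangement", Arrangement.OTHER),
                entry.get("gene_copy", GeneCopy.NA),
            )
        line, arr, copy = entry
        return line, arr, copy
    if metadata is None and record_id.count("|") >= 3:
        base, line, arr, copy = record_id.split("|")[:4]
        return line, arr, copy
    return record_id, Arrangement.OTHER, GeneCopy.NA


def read_fasta_alignment(path, metadata=None) -> AlignedSequenceSet:
    """Read a multi-record FASTA alignment and join per-record metadata.

    Parameters
    ----------
    path : path-like
        FASTA file, wrapped or unwrapped.
    metadata : mapping, optional
        ``id -> (line_id, arrangement, gene_copy)`` (tuples or dicts).  Ids
        absent from the mapping fall back to arrangement OTHER / copy NA.
        When omitted entirely, pipe-delimited headers
        (``id|line|arrangement|copy``) are honoured as a fallback.
    """
    path = Path(path)
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FormatError(f"{path}: no FASTA records found")
    records = []
    for rec in parsed:
        name = rec.id if rec.id.count("|") >= 3 else rec.description.split()[0]
        line, arr, copy = _metadata_for(name, metadata)
        rec_id = name.split("|")[0] if (metadata is None and name.count("|") >= 3) else name
        records.append(
            SequenceRecord(
                id=rec_id,
                sequence=str(rec.seq),
                line_id=str(line),
                arrangement=arr,
                gene_copy=copy,
            )
        )
    return AlignedSequenceSet(tuple(records))


def write_fasta_alignment(aln: AlignedSequenceSet, path, line_width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in aln:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.sequence), line_width):
                fh.write(r.sequence[i : i + line_width] + "\n")


def read_metadata_table(path) -> dict:
    """Sidecar CSV with columns id, line, arrangement, gene_copy."""
    path = Path(path)
    out = {}
    with path.open() as fh:
        reader = csv.DictReader(fh)
        cols = {c.lower().strip(): c for c in reader.fieldnames or []}
        for want in ("id", "line", "arrangement", "gene_copy"):
            if want not in cols:
                raise SchemaError(f"{path}: metadata table missing column {want!r}")
        for row in reader:
            out[row[cols["id"]].strip()] = (
                row[cols["line"]].strip(),
                row[cols["arrangement"]].strip(),
                row[cols["gene_copy"]].strip(),
            )
    return out


def write_metadata_table(aln: AlignedSequenceSet, path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "line", "arrangement", "gene_copy"])
        for r in aln:
            writer.writerow([r.id, r.line_id, r.arrangement.value, r.gene_copy.value])


@dataclass
class CtRecord:
    """One technical-replicate qPCR measurement."""

    line_id: str
    arrangement: Arrangement
    sex: Sex
    bio_rep: int
    tech_rep: int
    gene: Gene
    ct: float

    def __post_init__(self):
        self.arrangement = parse_arrangement(self.arrangement)
        self.sex = parse_sex(self.sex)
        self.gene = parse_gene(self.gene)
        self.bio_rep = int(self.bio_rep)
        self.tech_rep = int(self.tech_rep)
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise TableValueError(
                f"replicate indices must be >= 1 (got bio {self.bio_rep}, tech {self.tech_rep})"
            )
        self.ct = float(self.ct)
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise TableValueError(f"Ct must be a finite positive cycle count, got {self.ct}")


_CT_COLUMNS = ("line", "arrangement", "sex", "bio_rep", "tech_rep", "gene", "ct")


def read_ct_table(path) -> list:
    """Read a delimited Ct table (CSV or TSV, header required).

    Required columns: line, arrangement, sex, bio_rep, tech_rep, gene, ct.
    Raises :class:`SchemaError` for a missing column and
    :class:`TableValueError` naming the (1-based data) row for a bad cell.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _CT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: Ct table missing column(s) {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        try:
            ct = float(d["ct"])
        except (TypeError, ValueError):
            raise TableValueError(
                f"{path}: row {i}: non-numeric ct value {d['ct']!r}"
            ) from None
        try:
            records.append(
                CtRecord(
                    line_id=str(d["line"]).strip(),
                    arrangement=d["arrangement"],
                    sex=d["sex"],
                    bio_rep=int(float(d["bio_rep"])),
                    tech_rep=int(float(d["tech_rep"])),
                    gene=d["gene"],
                    ct=ct,
                )
            )
        except TableValueError as exc:
            raise TableValueError(f"{path}: row {i}: {exc}") from None
    return records


_DCT_COLUMNS = ("line", "arrangement", "sex", "bio_rep", "delta_ct")


def read_delta_ct_table(path) -> list:
    """Read a table of pre-computed delta-Ct values, one row per biological
    replicate (columns: line, arrangement, sex, bio_rep, delta_ct).

    Returns :class:`hspreg.expression_stats.CtObservation` records, the same
    container :func:`aggregate_and_transform` produces from raw Ct data.
    """
    from .expression_stats import CtObservation

    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _DCT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: delta-Ct table missing column(s) {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = dict(zip(df.columns, row))
        try:
            dct = float(d["delta_ct"])
        except (TypeError, ValueError):
            raise TableValueError(
                f"{path}: row {i}: non-numeric delta_ct value {d['delta_ct']!r}"
            ) from None
        out.append(
            CtObservation(
                line_id=str(d["line"]).strip(),
                arrangement=d["arrangement"],
                sex=d["sex"],
                bio_rep=int(float(d["bio_rep"])),
                delta_ct=dct,
            )
        )
    return out


def write_ct_table(records: Sequence[CtRecord], path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CT_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.line_id,
                    r.arrangement.value,
                    r.sex.value,
                    r.bio_rep,
                    r.tech_rep,
                    r.gene.value,
                    repr(r.ct),
                ]
            )
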