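"""Readers and writers for every external representation the pipeline touches.

FASTA (protein and nucleotide), tab-separated identity/distance matrices and
cluster tables, and the packaged genome-characteristics table for the 29
cocci-shaped *Sporosarcina* strains.

Conventions
-----------
* FASTA headers are split at the first whitespace into ``id`` and
  ``description``; sequences are upper-cased on input and trailing ``*`` stop
  characters are stripped (with a logged warning).
* All intervals elsewhere in the package are 0-based half-open.
* Matrix files are tab-separated with the strain labels as both the first row
  and the first column; values carry 4 decimal places.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_LETTERS = frozenset("ACGTN")

_ALPHABETS = {"protein": PROTEIN_LETTERS, "dna": DNA_LETTERS}


class FastaFormatError(ValueError):
    """Raised for malformed or invalid FASTA input."""


class TableSchemaError(ValueError):
    """Raised when a genome table does not match the expected schema."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence: the unit stored in proteome and genome FASTA files."""

    id: str
    sequence: str
    description: str = ""
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FastaFormatError(f"invalid record id {self.id!r}")
        if len(self.sequence) < 1:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        allowed = _ALPHABETS.get(self.alphabet)
        if allowed is None:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        for pos, letter in enumerate(self.sequence):
            if letter not in allowed:
                raise FastaFormatError(
                    f"illegal {self.alphabet} residue {letter!r} at position "
                    f"{pos} of record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeProteome:
    """One strain's identified protein set; the unit of all comparisons."""

    genome_id: str
    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FastaFormatError(
                f"duplicate record id(s) {dup} in proteome {self.genome_id!r}"
            )

    @property
    def total_residues(self) -> int:
        return sum(len(r) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GenomeTableRow:
    """One genome's row of the general-characteristics table.

    The prophage column is kept as raw text: the printed table's footnote
    (complete vs total prophage counts) is internally inconsistent, so the
    field is preserved verbatim and never summarized numerically.
    """

    accession: str
    strain: str
    genome_bp: int
    gc_percent: float
    cds: int
    trnas: int
    plasmids: int
    prophage_field: str
    is_elements: int

    def __post_init__(self) -> None:
        if self.genome_bp <= 0:
            raise TableSchemaError(f"{self.accession}: genome_bp must be > 0")
        if not 0.0 <= self.gc_percent <= 100.0:
            raise TableSchemaError(f"{self.accession}: gc_percent out of range")
        for name in ("cds", "trnas", "plasmids", "is_elements"):
            if getattr(self, name) < 0:
                raise TableSchemaError(f"{self.accession}: {name} must be >= 0")


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Wrapped sequence lines are joined, sequences are upper-cased, and protein
    stop characters (``*``) are stripped with a warning. Raises
    :class:`FastaFormatError` for an empty file, duplicate ids, or residues
    outside the alphabet.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "protein" and "*" in seq:
            logger.warning("stripping '*' stop character(s) from record %r", rec.id)
            seq = seq.replace("*", "")
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(id=rec.id, sequence=seq, description=desc, alphabet=alphabet)
        )
    if not records:
        raise FastaFormatError(f"no records in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 70
) -> Path:
    """Write records as wrapped FASTA; round-trips exactly through read_fasta."""
    if width < 1:
        raise ValueError("width must be a positive integer")
    path = Path(path)
    bio_records = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio_records)
    return path


def read_proteome(path: str | Path, genome_id: str | None = None) -> GenomeProteome:
    """Read one strain's protein FASTA as a :class:`GenomeProteome`.

    ``genome_id`` defaults to the file's stem.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    return GenomeProteome(genome_id=gid, records=tuple(read_fasta(path, "protein")))


_TABLE_COLUMNS = [
    "accession",
    "strain",
    "genome_bp",
    "gc_percent",
    "cds",
    "trnas",
    "plasmids",
    "prophages",
    "is_elements",
]


def load_genome_table(path: str | Path) -> list[GenomeTableRow]:
    """Load a tab-separated genome-characteristics table.

    Numeric fields are parsed with thousands separators removed; the prophage
    column is kept as raw text.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise TableSchemaError(f"no records in {path}") from None
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableSchemaError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise TableSchemaError(f"no records in {path}")
    rows: list[GenomeTableRow] = []
    for _, raw in df.iterrows():
        def _int(col: str) -> int:
            text = str(raw[col]).replace(",", "").strip()
            try:
                return int(text)
            except ValueError:
                raise TableSchemaError(
                    f"{path}: non-numeric {col}={raw[col]!r} in row "
                    f"{raw['accession']!r}"
                ) from None
        rows.append(
            GenomeTableRow(
                accession=str(raw["accession"]),
                strain=str(raw["strain"]),
                genome_bp=_int("genome_bp"),
                gc_percent=float(str(raw["gc_percent"]).replace(",", "")),
                cds=_int("cds"),
                trnas=_int("trnas"),
                plasmids=_int("plasmids"),
                prophage_field=str(raw["prophages"]),
                is_elements=_int("is_elements"),
            )
        )
    return rows


def load_packaged_genome_table() -> list[GenomeTableRow]:
    """The packaged 29-strain cocci-shaped *Sporosarcina* characteristics table."""
    ref = resources.files("sporopan.data") / "sporosarcina_table1.tsv"
    with resources.as_file(ref) as path:
        return load_genome_table(path)


def write_matrix(
    labels: Sequence[str], values: np.ndarray, path: str | Path
) -> Path:
    """Write a labelled square matrix as tab-separated text (4 decimals)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix is not square: shape {values.shape}")
    if values.shape[0] != len(labels):
        raise ValueError(
            f"matrix dimension {values.shape[0]} != label count {len(labels)}"
        )
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.4f", index_label="")
    return Path(path)


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a labelled square matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if labels != [str(x) for x in df.columns]:
        raise ValueError(f"{path}: row and column labels differ")
    return labels, df.to_numpy(dtype=float)
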