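"""Reading, writing and validation of sequence records and alignments.

Sequences are handled as plain uppercase DNA strings over ``{A,C,G,T,N,-}``.
RNA (``U``) is mapped to ``T`` on ingest; IUPAC ambiguity codes other than
``N`` are mapped to ``N`` with a logged warning.  All user-facing coordinates
are 1-based and inclusive; internal indexing is 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")
_AMBIGUITY = set("RYSWKMBDHV")

FASTA_WIDTH = 70


class DuplicateIdError(ValueError):
    """Raised when two records in one collection share an id."""


class RaggedAlignmentError(ValueError):
    """Raised when an expected alignment has unequal sequence lengths."""


def _clean_residues(raw: str, record_id: str) -> str:
    """Uppercase, map U->T, map non-N ambiguity codes to N."""
    s = raw.upper().replace("U", "T")
    bad = set(s) - ALPHABET
    if bad:
        unknown = bad - _AMBIGUITY
        if unknown:
            raise ValueError(
                f"record {record_id!r}: characters {sorted(unknown)} are not "
                "valid DNA residues"
            )
        logger.warning(
            "record %r: ambiguity codes %s mapped to N", record_id, sorted(bad)
        )
        s = "".join("N" if c in _AMBIGUITY else c for c in s)
    return s


@dataclass
class SequenceRecord:
    """A labeled, possibly gapped DNA sequence with optional metadata."""

    id: str
    residues: str
    description: str = ""
    declared_taxon: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        self.residues = _clean_residues(self.residues, self.id)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


class Msa:
    """A multiple sequence alignment: equal-length records with column access."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment must contain at least one record")
        _check_unique_ids(records)
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            offenders = _ragged_ids(records)
            raise RaggedAlignmentError(
                f"unequal sequence lengths; offending ids: {offenders}"
            )
        self.records: list[SequenceRecord] = records
        self.ncols: int = lengths.pop()
        self._array: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def to_array(self) -> np.ndarray:
        """Alignment as an (nseq, ncols) array of single-byte strings."""
        if self._array is None or self._array.shape[0] != len(self.records):
            self._array = np.array(
                [list(r.residues) for r in self.records], dtype="U1"
            )
        return self._array

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.ncols:
            raise IndexError(f"column {col} outside 1..{self.ncols}")
        return "".join(r.residues[col - 1] for r in self.records)

    def select_columns(self, kept_1based: Sequence[int]) -> "Msa":
        """New alignment restricted to the given 1-based columns, in order."""
        idx = [c - 1 for c in kept_1based]
        out = []
        for r in self.records:
            out.append(
                SequenceRecord(
                    id=r.id,
                    residues="".join(r.residues[i] for i in idx) or "-",
                    description=r.description,
                    declared_taxon=r.declared_taxon,
                    metadata=dict(r.metadata),
                )
            )
        return Msa(out)


def _check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise DuplicateIdError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)


def _ragged_ids(records: Sequence[SequenceRecord]) -> list[str]:
    from collections import Counter

    counts = Counter(len(r) for r in records)
    majority = counts.most_common(1)[0][0]
    return [r.id for r in records if len(r) != majority]


def read_fasta(path, expect_aligned: bool = False):
    """Read a multi-FASTA file.

    Returns an :class:`Msa` when ``expect_aligned`` is true (raising
    :class:`RaggedAlignmentError` if lengths differ), otherwise a list of
    :class:`SequenceRecord` in file order.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq),
                           description=rec.description)
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    _check_unique_ids(records)
    if expect_aligned:
        return Msa(records)
    return records


def write_fasta(records, path, width: int = FASTA_WIDTH) -> None:
    """Write records (an Msa or iterable of SequenceRecord) as FASTA.

    Output is uppercase, UTF-8, LF line endings, wrapped at ``width``.
    """
    if isinstance(records, Msa):
        records = records.records
    bio = [
        _BioRecord(Seq(r.residues), id=r.id,
                   description=r.description if r.description != r.id else "")
        for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


_METADATA_COLUMNS = (
    "id", "declared_taxon", "source", "country",
    "latitude", "longitude", "elevation",
)


def read_metadata(path) -> dict[str, dict]:
    """Read a tab-separated metadata table keyed by sequence id.

    The table must have a header containing an ``id`` column; other
    recognised columns are declared_taxon, source, country, latitude,
    longitude and elevation.  Missing optional fields are simply absent from
    the returned per-record dicts.  Latitude/longitude are validated against
    their geographic domains.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: metadata table lacks an 'id' column")
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        entry: dict = {}
        for col in df.columns:
            if col == "id":
                continue
            val = row[col]
            if pd.isna(val) or (isinstance(val, str) and not val.strip()):
                continue
            entry[col] = val
        lat = entry.get("latitude")
        if lat is not None and not -90.0 <= float(lat) <= 90.0:
            raise ValueError(f"row {row['id']!r}: latitude {lat} out of range")
        lon = entry.get("longitude")
        if lon is not None and not -180.0 <= float(lon) <= 180.0:
            raise ValueError(f"row {row['id']!r}: longitude {lon} out of range")
        out[str(row["id"])] = entry
    return out


def attach_metadata(records, meta: Mapping[str, Mapping]) -> None:
    """Attach metadata entries to matching records in place.

    Metadata rows with no matching record id produce a warning, not an
    error.  Records with an empty/absent declared_taxon stay unassigned
    (``declared_taxon`` is None).
    """
    if isinstance(records, Msa):
        records = records.records
    by_id = {r.id: r for r in records}
    for rid, entry in meta.items():
        rec = by_id.get(rid)
        if rec is None:
            warnings.warn(f"metadata row {rid!r} matches no sequence record")
            continue
        entry = dict(entry)
        taxon = entry.pop("declared_taxon", None)
        if taxon is not None and str(taxon).strip():
            rec.declared_taxon = str(taxon).strip()
        rec.metadata.update(entry)
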