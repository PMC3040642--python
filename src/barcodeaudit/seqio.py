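"""Reading, writing and filtering of barcode libraries.

A *library* is an ordered collection of COI-5' barcode records, one per
specimen, aligned to a common nominal amplicon length (658 bp by default,
the fragment recovered by the standard barcoding primer pair).  FASTA
headers carry the specimen metadata in delimited fields, BOLD-style::

    >BC0001|Thera variata|Alps
    ACGT...

Sequences shorter than the nominal length are right-padded with ``-`` so
that positions line up; the padded positions are ignored pairwise when
distances are computed.  No indels are assumed within the amplicon, the
usual convention for COI-5' protein-coding barcodes.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CHARS",
    "BarcodeRecord",
    "Library",
    "HeaderScheme",
    "read_fasta",
    "write_fasta",
    "filter_by_length",
    "write_tsv",
]

#: Allowed sequence characters: the 15 IUPAC nucleotide codes plus gap.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: Non-gap count defining a "full-length" record of the 658 bp amplicon.
#: A small tolerance below 658 avoids off-by-trim artifacts; the exact
#: 658 class is still reachable with ``filter_by_length(lib, 658)``.
FULL_LENGTH_MIN = 640


class HeaderError(ValueError):
    """A FASTA header does not parse under the active header scheme."""


@dataclass(frozen=True)
class HeaderScheme:
    """How FASTA headers map to specimen metadata.

    ``fields`` names the delimited header fields in order; it must contain
    ``specimen_id`` and ``species``, and may contain ``region``.  Fields
    beyond those present in a given header are treated as absent, so the
    default scheme accepts both ``id|species`` and ``id|species|region``.
    """

    delimiter: str = "|"
    fields: tuple[str, ...] = ("specimen_id", "species", "region")

    def __post_init__(self) -> None:
        if "specimen_id" not in self.fields or "species" not in self.fields:
            raise ValueError("header scheme must include specimen_id and species")

    def parse(self, header: str) -> dict:
        parts = [p.strip() for p in header.split(self.delimiter)]
        out: dict = {}
        for name, value in zip(self.fields, parts):
            out[name] = value
        missing = {"specimen_id", "species"} - {k for k, v in out.items() if v}
        if missing:
            raise HeaderError(
                f"header {header!r}: missing field(s) {sorted(missing)} "
                f"under scheme {self.delimiter!r}-delimited {self.fields}"
            )
        return out

    def format(self, rec: "BarcodeRecord") -> str:
        vals = {
            "specimen_id": rec.specimen_id,
            "species": rec.species,
            "region": rec.region or "",
        }
        parts = [vals.get(f, "") for f in self.fields]
        while parts and parts[-1] == "":
            parts.pop()
        return self.delimiter.join(parts)


@dataclass(frozen=True)
class BarcodeRecord:
    """One specimen's barcode sequence plus its annotations.

    ``species`` is a binomial ("Genus epithet"); the genus is its first
    whitespace token.  ``length`` counts non-gap characters; ``N`` counts
    toward length but is skipped pairwise when distances are computed.
    """

    specimen_id: str
    species: str
    sequence: str
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise ValueError("specimen_id must be non-empty")
        if len(self.species.split()) < 2:
            raise ValueError(
                f"record {self.specimen_id!r}: species {self.species!r} is not "
                "a binomial (need at least two whitespace-separated tokens)"
            )
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - IUPAC_CHARS
        if bad:
            raise ValueError(
                f"record {self.specimen_id!r}: invalid sequence characters {sorted(bad)}"
            )
        if self.length == 0:
            raise ValueError(f"record {self.specimen_id!r}: sequence has no bases")

    @property
    def genus(self) -> str:
        return self.species.split()[0]

    @property
    def length(self) -> int:
        """Number of non-gap positions."""
        return len(self.sequence) - self.sequence.count("-")


@dataclass(frozen=True)
class Library:
    """An ordered barcode library padded to a common alignment length."""

    records: tuple[BarcodeRecord, ...]
    alignment_length: int = 658

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a library must contain at least one record")
        padded = []
        for rec in self.records:
            s = rec.sequence
            if len(s) > self.alignment_length:
                raise ValueError(
                    f"record {rec.specimen_id!r} is {len(s)} positions, longer "
                    f"than alignment_length={self.alignment_length}"
                )
            if len(s) < self.alignment_length:
                rec = BarcodeRecord(
                    rec.specimen_id,
                    rec.species,
                    s + "-" * (self.alignment_length - len(s)),
                    rec.region,
                )
            padded.append(rec)
        ids = [r.specimen_id for r in padded]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen_id(s): {dupes}")
        object.__setattr__(self, "records", tuple(padded))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species(self) -> tuple[str, ...]:
        """Distinct species names, in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return tuple(seen)


def read_fasta(
    path: str | Path,
    header_scheme: HeaderScheme | None = None,
    alignment_length: int = 658,
) -> Library:
    """Read a barcode library from FASTA.

    Each header must parse into at least (specimen_id, species) under
    ``header_scheme``.  Sequences are upper-cased and right-padded with
    ``-`` to ``alignment_length`` positions.  Malformed headers, duplicate
    specimen ids and empty files raise ``ValueError``.
    """
    scheme = header_scheme or HeaderScheme()
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        meta = scheme.parse(entry.description)
        try:
            records.append(
                BarcodeRecord(
                    specimen_id=meta["specimen_id"],
                    species=meta["species"],
                    sequence=str(entry.seq),
                    region=meta.get("region") or None,
                )
            )
        except ValueError as e:
            raise ValueError(f"FASTA entry {entry.description!r}: {e}") from e
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return Library(tuple(records), alignment_length=alignment_length)


def write_fasta(
    lib: Library, path: str | Path, header_scheme: HeaderScheme | None = None
) -> None:
    """Write a library as FASTA (sequences wrapped at 80 columns).

    ``read_fasta(write_fasta(lib))`` is the identity on records.
    """
    scheme = header_scheme or HeaderScheme()
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=scheme.format(r), description="")
        for r in lib.records
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(seqrecords)


def filter_by_length(lib: Library, min_len: int) -> Library:
    """Keep records with at least ``min_len`` non-gap positions.

    Mirrors the usual library QC length classes (>500 bp analyzable,
    full-length 658 bp).  Raises if nothing survives.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = tuple(r for r in lib.records if r.length >= min_len)
    if not kept:
        raise ValueError(f"no records of length >= {min_len}; nothing to analyze")
    return Library(kept, alignment_length=lib.alignment_length)


def write_tsv(
    rows: Iterable[Sequence], columns: Sequence[str], path: str | Path
) -> None:
    """Write report rows as a UTF-8 TSV with an explicit header row."""
    import pandas as pd

    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")
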