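"""Sequence records, FASTA/TSV I/O, pairwise identity and ribotype dedup.

A *ribotype* is a unique partial-SSU barcode string; fruit-body specimens
carrying byte-identical sequences collapse onto one ribotype whose abundance
is the number of specimens. Pairwise identity follows the convention of
greedy-clustering tools: matches divided by alignment columns of an optimal
free-end-gap global alignment, terminal gaps excluded, internal gap columns
counted as non-matches, IUPAC ambiguity codes never counted as matches.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from . import _align
from .errors import DataError, FormatError

log = logging.getLogger(__name__)

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

#: metadata TSV columns understood by :func:`load_inventory`
METADATA_COLUMNS = ("id", "year", "site", "elevation_m", "morphospecies", "genus")


@dataclass
class SequenceRecord:
    """One barcode sequence with optional specimen/sample metadata."""

    id: str
    sequence: str
    source: str = "reference"  # fruit | soil | reference
    morphospecies: str | None = None
    genus: str | None = None
    year: int | None = None
    site: str | None = None
    elevation: float | None = None
    abundance: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise DataError(f"record {self.id!r}: non-IUPAC characters {sorted(bad)}")
        if self.source not in ("fruit", "soil", "reference"):
            raise DataError(f"record {self.id!r}: unknown source {self.source!r}")
        if self.abundance < 1:
            raise DataError(f"record {self.id!r}: abundance must be >= 1")


@dataclass(frozen=True)
class IdentityResult:
    """Outcome of a pairwise identity computation."""

    identity: float
    aligned_length: int
    matches: int


@dataclass
class Ribotype:
    """A unique sequence with the ids of all records carrying it."""

    id: str
    sequence: str
    abundance: int
    member_ids: list[str] = field(default_factory=list)


def _validate(seq: str) -> str:
    if not seq:
        raise DataError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise DataError(f"non-IUPAC characters {sorted(bad)}")
    return seq


@lru_cache(maxsize=262144)
def _identity_cached(a: str, b: str) -> IdentityResult:
    if a == b and set(a) <= set("ACGT"):
        return IdentityResult(1.0, len(a), len(a))
    m, cols = _align.nw_identity(_align.encode(a), _align.encode(b))
    ident = m / cols if cols else 0.0
    return IdentityResult(ident, cols, m)


def global_identity(a: str, b: str) -> IdentityResult:
    """Identity between two DNA strings from an optimal global alignment.

    Symmetric in its arguments; identity = matches / aligned_length where
    aligned_length excludes terminal gap columns.
    """
    a = _validate(a)
    b = _validate(b)
    if b < a:  # symmetry lets us cache one orientation only
        a, b = b, a
    return _identity_cached(a, b)


def dedup_ribotypes(records: Sequence[SequenceRecord]) -> list[Ribotype]:
    """Collapse records to unique ribotypes (exact string dedup).

    Output is ordered by decreasing summed abundance, ties broken by the
    lexicographically smallest member id; ribotype ids are RT001, RT002, ...
    in that order. Total abundance is conserved.
    """
    if not records:
        raise DataError("dedup_ribotypes: no records")
    by_seq: dict[str, Ribotype] = {}
    for rec in records:
        rt = by_seq.get(rec.sequence)
        if rt is None:
            by_seq[rec.sequence] = Ribotype("", rec.sequence, rec.abundance, [rec.id])
        else:
            rt.abundance += rec.abundance
            rt.member_ids.append(rec.id)
    out = sorted(by_seq.values(), key=lambda r: (-r.abundance, min(r.member_ids)))
    width = max(3, len(str(len(out))))
    for k, rt in enumerate(out, 1):
        rt.id = f"RT{k:0{width}d}"
        rt.member_ids.sort()
    return out


def load_inventory(
    fasta_path: str | Path, metadata_path: str | Path | None = None, source: str = "reference"
) -> list[SequenceRecord]:
    """Read a FASTA file, optionally joined with a TSV metadata table on id.

    Metadata rows whose id is absent from the FASTA are logged as warnings
    and dropped; fields missing from the table stay absent (None).
    """
    records: dict[str, SequenceRecord] = {}
    for bio in SeqIO.parse(str(fasta_path), "fasta"):
        if bio.id in records:
            raise FormatError(f"duplicate FASTA id {bio.id!r} in {fasta_path}")
        records[bio.id] = SequenceRecord(id=bio.id, sequence=str(bio.seq), source=source)
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype={"id": str, "site": str})
        if "id" not in meta.columns:
            raise FormatError(f"metadata {metadata_path} lacks an 'id' column")
        for row in meta.itertuples(index=False):
            rec = records.get(row.id)
            if rec is None:
                msg = f"metadata id {row.id!r} not present in {fasta_path}; ignored"
                log.warning(msg)
                warnings.warn(msg, stacklevel=2)
                continue
            for col, attr in (
                ("year", "year"),
                ("site", "site"),
                ("elevation_m", "elevation"),
                ("morphospecies", "morphospecies"),
                ("genus", "genus"),
                ("abundance", "abundance"),
            ):
                if col in meta.columns:
                    val = getattr(row, col)
                    if pd.notna(val):
                        if attr == "year":
                            val = int(val)
                        elif attr == "elevation":
                            val = float(val)
                        elif attr == "abundance":
                            val = int(val)
                        setattr(rec, attr, val)
    return list(records.values())


def write_fasta(records: Iterable[SequenceRecord | Ribotype], path: str | Path) -> None:
    """Write records to FASTA, wrapped at 80 columns."""
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=80).write_file(bio)


def write_metadata(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write the specimen metadata TSV (id, year, site, elevation_m, ...)."""
    rows = [
        {
            "id": r.id,
            "year": r.year,
            "site": r.site,
            "elevation_m": r.elevation,
            "morphospecies": r.morphospecies,
            "genus": r.genus,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def min_length_filter(records: Sequence[SequenceRecord], min_length: int = 250) -> list[SequenceRecord]:
    """Optional length filter; barcodes shorter than ``min_length`` are dropped."""
    kept = [r for r in records if len(r.sequence) >= min_length]
    if len(kept) != len(records):
        log.info("min_length_filter dropped %d/%d records", len(records) - len(kept), len(records))
    return kept
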