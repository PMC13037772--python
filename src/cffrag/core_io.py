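"""Readers and writers for fragments, alignments, references, and sample sheets.

All genomic coordinates in this package are 0-based half-open (BED/BAM
convention): a fragment covers reference positions ``start .. end - 1`` and its
length is ``end - start``.  This module is the single place where those
conventions are enforced; everything downstream may assume validated input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

__all__ = [
    "Fragment",
    "SampleRecord",
    "Genome",
    "FormatError",
    "FragmentTableError",
    "read_fragments_from_alignment",
    "read_long_read_fragments",
    "read_fragment_tsv",
    "write_fragment_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_feature_table",
    "write_feature_table",
    "fragment_lengths",
]

#: Fragment lengths above this are lumped into an overflow bucket by histograms.
MAX_FRAGMENT_LENGTH = 10_000

VALID_GROUPS = {"healthy", "cancer"}
VALID_TIMEPOINTS = {"pretreatment", "posttreatment", "na"}
SAMPLE_SHEET_COLUMNS = ["sample_id", "subject_id", "group", "timepoint", "species"]

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


class FormatError(ValueError):
    """Input file violates its format contract (sorting, pairing, columns)."""


class FragmentTableError(FormatError):
    """A fragment table row fails validation; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class Fragment(NamedTuple):
    """One cfDNA molecule as a genomic interval (0-based half-open)."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self) -> "Fragment":
        if self.end <= self.start:
            raise FragmentTableError(
                f"fragment end ({self.end}) must exceed start ({self.start})"
            )
        if self.start < 0:
            raise FragmentTableError(f"negative start {self.start}")
        return self


@dataclass(frozen=True)
class SampleRecord:
    """One plasma sample and the subject (dog or human) it came from."""

    sample_id: str
    subject_id: str
    group: str
    timepoint: str = "na"
    species: str = "canine"

    def __post_init__(self):
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if self.group not in VALID_GROUPS:
            raise ValueError(f"group must be one of {sorted(VALID_GROUPS)}, got {self.group!r}")
        if self.timepoint not in VALID_TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


@dataclass
class Genome:
    """In-memory reference: contig name -> uppercase sequence over {A,C,G,T,N}."""

    contigs: dict[str, str]
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        fa = Fasta(str(path), sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 80) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path

    def encoded(self, name: str) -> np.ndarray:
        """Contig as uint8 codes A=0 C=1 G=2 T=3, anything else 255. Cached."""
        if name not in self._encoded:
            raw = np.frombuffer(self.contigs[name].encode("ascii"), dtype=np.uint8)
            self._encoded[name] = _BASE_CODE[raw]
        return self._encoded[name]

    def slice(self, chrom: str, start: int, end: int) -> str:
        return self.contigs[chrom][start:end]


def revcomp(seq: str) -> str:
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


# ---------------------------------------------------------------------------
# Alignment readers
# ---------------------------------------------------------------------------

def _check_coordinate_sorted(af: pysam.AlignmentFile, path) -> None:
    so = (af.header.to_dict().get("HD") or {}).get("SO")
    if so != "coordinate":
        raise FormatError(f"{path}: alignments must be coordinate-sorted (HD SO={so!r})")


def read_fragments_from_alignment(
    path: str | Path,
    min_mapq: int = 30,
    keep_duplicates: bool = False,
) -> Iterator[Fragment]:
    """Convert paired-end alignments into fragments.

    One fragment is emitted per properly paired, primary, non-duplicate pair
    (from the leftmost mate, i.e. the one with positive template length), so
    each pair is counted exactly once.  The fragment spans the leftmost mate
    start to start + |TLEN|; pairs with TLEN == 0 are dropped.  Both mates must
    have MAPQ >= ``min_mapq`` (the mate's MAPQ is taken from the MQ tag when
    present).
    """
    n = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        _check_coordinate_sorted(af, path)
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired:
                raise FormatError(f"{path}: unpaired read {read.query_name!r} in paired-end input")
            if not read.is_proper_pair:
                continue
            if read.is_duplicate and not keep_duplicates:
                continue
            if read.mapping_quality < min_mapq:
                continue
            tlen = read.template_length
            if tlen <= 0:  # emit from the leftmost mate only; drop TLEN == 0
                continue
            if read.has_tag("MQ") and read.get_tag("MQ") < min_mapq:
                continue
            n += 1
            yield Fragment(read.reference_name, read.reference_start, read.reference_start + tlen)
    if n == 0:
        warnings.warn(f"{path}: no read pairs survived filtering", stacklevel=2)


def read_long_read_fragments(path: str | Path, min_mapq: int = 30) -> Iterator[Fragment]:
    """Fragments from single-end long-read alignments.

    One fragment per primary mapped alignment; length is the reference span of
    the alignment (robust to soft-clipped ends).
    """
    n = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            n += 1
            yield Fragment(read.reference_name, read.reference_start, read.reference_end)
    if n == 0:
        warnings.warn(f"{path}: no alignments survived filtering", stacklevel=2)


# ---------------------------------------------------------------------------
# Fragment TSV
# ---------------------------------------------------------------------------

def read_fragment_tsv(path: str | Path) -> Iterator[Fragment]:
    """Read a 3-column (chrom, start, end) TSV of fragments, validating each row."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:3] == ["chrom", "start", "end"]:
                continue
            if len(parts) < 3:
                raise FragmentTableError(f"expected 3 columns, got {len(parts)}", lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FragmentTableError(f"non-integer coordinate: {exc}", lineno) from None
            if start < 0 or end <= start:
                raise FragmentTableError(
                    f"invalid interval [{start}, {end}): need 0 <= start < end", lineno
                )
            yield Fragment(parts[0], start, end)


def write_fragment_tsv(fragments: Iterable[Fragment], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for frag in fragments:
            fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\n")
    return path


def fragment_lengths(fragments: Iterable[Fragment]) -> np.ndarray:
    """Lengths of an iterable of fragments as an int array."""
    return np.fromiter((f.end - f.start for f in fragments), dtype=np.int64)


# ---------------------------------------------------------------------------
# Sample sheets and feature tables
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    bad = set(df["group"]) - VALID_GROUPS
    if bad:
        raise FormatError(f"{path}: unknown group value(s) {sorted(bad)}")
    # raises on invalid timepoint / empty subject via SampleRecord validation
    for row in df.itertuples(index=False):
        SampleRecord(row.sample_id, row.subject_id, row.group, row.timepoint, row.species)
    return df[SAMPLE_SHEET_COLUMNS].copy()


def write_sample_sheet(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df[SAMPLE_SHEET_COLUMNS].to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_feature_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
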