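"""Domain containers and the plain-text formats the pipeline reads and writes.

The screen stages move three objects around: an :class:`SgRNALibrary`
(guide -> gene map with 20-nt targeting sequences), a :class:`SampleSheet`
(sample barcodes plus the paired control/treated design labels) and a
guide x sample count matrix held as a plain :class:`pandas.DataFrame`.
All on-disk formats are TSV/CSV/GMT/FASTQ text.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd

VALID_BASES = frozenset("ACGT")
GUIDE_LENGTH = 20
BARCODE_LENGTH = 6


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read (FASTQ record)."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.quality)})"
            )


@dataclass
class SgRNALibrary:
    """Guide -> gene map with unique 20-nt sequences.

    Parameters
    ----------
    guide_ids, gene_ids, sequences
        Parallel lists; one entry per guide. Sequences must be unique
        uppercase 20-mers over ACGT — duplicate sequences would make exact
        read-to-guide assignment ambiguous and are rejected at load time.
    """

    guide_ids: list[str]
    gene_ids: list[str]
    sequences: list[str]
    _seq_to_guide: dict[str, str] = field(init=False, repr=False)
    _guide_to_gene: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.guide_ids)
        if not (len(self.gene_ids) == len(self.sequences) == n):
            raise ValueError("guide_ids, gene_ids and sequences must be parallel")
        if n == 0:
            raise ValueError("library is empty")
        self.sequences = [s.upper() for s in self.sequences]
        for s in self.sequences:
            if len(s) != GUIDE_LENGTH or not set(s) <= VALID_BASES:
                raise ValueError(f"invalid guide sequence {s!r}: need 20 nt over ACGT")
        if len(set(self.guide_ids)) != n:
            raise ValueError("guide_ids are not unique")
        if len(set(self.sequences)) != n:
            raise ValueError("guide sequences are not unique")
        self._seq_to_guide = dict(zip(self.sequences, self.guide_ids))
        self._guide_to_gene = dict(zip(self.guide_ids, self.gene_ids))

    def __len__(self) -> int:
        return len(self.guide_ids)

    @property
    def seq_to_guide(self) -> dict[str, str]:
        return self._seq_to_guide

    @property
    def guide_to_gene(self) -> dict[str, str]:
        return self._guide_to_gene

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"guide_id": self.guide_ids, "gene_id": self.gene_ids, "sequence": self.sequences}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SgRNALibrary":
        required = {"guide_id", "gene_id", "sequence"}
        if not required <= set(df.columns):
            raise ValueError(f"library table needs columns {sorted(required)}")
        return cls(
            guide_ids=df["guide_id"].astype(str).tolist(),
            gene_ids=df["gene_id"].astype(str).tolist(),
            sequences=df["sequence"].astype(str).tolist(),
        )


def read_library(path) -> SgRNALibrary:
    """Read a guide library TSV with header guide_id, gene_id, sequence."""
    return SgRNALibrary.from_frame(pd.read_csv(path, sep="\t"))


def write_library(library: SgRNALibrary, path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SampleSheet:
    """Sample barcodes and the paired screen design labels.

    One row per sequencing sample: ``sample_id``, a 6-nt demultiplexing
    ``barcode``, the ``condition`` (e.g. control/treated) and the
    ``replicate`` token pairing one control with one treated sample.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "barcode", "condition", "replicate"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        self.frame = self.frame.astype(
            {c: str for c in ("sample_id", "barcode", "condition", "replicate")}
        ).reset_index(drop=True)
        barcodes = self.frame["barcode"]
        for b in barcodes:
            if len(b) != BARCODE_LENGTH or not set(b) <= VALID_BASES:
                raise ValueError(f"invalid barcode {b!r}: need 6 nt over ACGT")
        if barcodes.duplicated().any():
            raise ValueError("barcodes are not unique")
        if self.frame["sample_id"].duplicated().any():
            raise ValueError("sample_ids are not unique")
        if self.frame.duplicated(subset=["condition", "replicate"]).any():
            raise ValueError("(condition, replicate) pairs are not unique")

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def barcode_to_sample(self) -> dict[str, str]:
        return dict(zip(self.frame["barcode"], self.frame["sample_id"]))


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t"))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


# -- count matrix ------------------------------------------------------------

def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a guide x sample count matrix (non-negative integers)."""
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise ValueError("count matrix has duplicated guide or sample labels")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix has negative entries")
    return counts.astype(int)


def read_counts(path) -> pd.DataFrame:
    return validate_counts(pd.read_csv(path, sep="\t", index_col=0))


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="guide_id")


# -- FASTQ -------------------------------------------------------------------

def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ records (plain or gzip), qualities Phred+33."""
    from Bio import SeqIO

    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            yield ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                quality="".join(chr(q + 33) for q in quals),
            )


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as handle:
        for r in reads:
            handle.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


# -- gene sets ---------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with _open_text(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with _open_text(path, "wt") as handle:
        for name, members in sets.items():
            handle.write("\t".join([name, "na", *members]) + "\n")
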