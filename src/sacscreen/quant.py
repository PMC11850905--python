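"""Raw-read quantification: barcode demultiplexing and key-sequence guide counting.

Read layout: a 6-nt sample barcode at the start of the read, a variable
stuffer, the key sequence ``CGAAACACC`` starting somewhere in a fixed window
(1-based positions 16-44 of the read by default), then the 20-nt sgRNA
targeting sequence — sometimes preceded by a single extra G. Counting is by
exact lookup of the extracted 20-mer(s) in the library; qualities are ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import BARCODE_LENGTH, ReadRecord, SampleSheet, SgRNALibrary, validate_counts

logger = logging.getLogger(__name__)

DEFAULT_KEY = "CGAAACACC"
DEFAULT_WINDOW = (16, 44)  # 1-based inclusive positions of the key's first base
GUIDE_LENGTH = 20


@dataclass
class SampleQuantStats:
    n_reads: int = 0
    n_no_key: int = 0
    n_unmatched: int = 0
    n_ambiguous: int = 0
    n_assigned: int = 0

    def check(self) -> None:
        if self.n_reads != self.n_no_key + self.n_unmatched + self.n_ambiguous + self.n_assigned:
            raise AssertionError("per-sample read categories do not partition n_reads")


@dataclass
class QuantReport:
    """Per-sample read accounting for a quantification run.

    ``n_no_barcode`` counts reads whose first six bases matched no sample
    barcode (or that were shorter than six bases). Within each sample,
    ``n_reads = n_no_key + n_unmatched + n_ambiguous + n_assigned``; ambiguous
    reads (both extraction candidates hit distinct guides) are still counted
    toward the matrix under the candidate-A priority rule, so column sums
    equal ``n_assigned + n_ambiguous``.
    """

    per_sample: dict[str, SampleQuantStats] = field(default_factory=dict)
    n_no_barcode: int = 0

    def to_dict(self) -> dict:
        return {
            "n_no_barcode": self.n_no_barcode,
            "samples": {
                s: {
                    "n_reads": st.n_reads,
                    "n_no_key": st.n_no_key,
                    "n_unmatched": st.n_unmatched,
                    "n_ambiguous": st.n_ambiguous,
                    "n_assigned": st.n_assigned,
                }
                for s, st in self.per_sample.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def demultiplex(
    reads: Iterable[ReadRecord], sheet: SampleSheet
) -> tuple[dict[str, list[ReadRecord]], int]:
    """Sort reads into per-sample bins by exact 6-nt barcode prefix.

    Returns ``(reads_by_sample, n_unassigned)``. Reads shorter than the
    barcode, or with no exactly-matching barcode, go to the unassigned tally.
    """
    barcode_to_sample = sheet.barcode_to_sample
    by_sample: dict[str, list[ReadRecord]] = {s: [] for s in sheet.sample_ids}
    n_unassigned = 0
    n_short = 0
    for read in reads:
        if len(read.sequence) < BARCODE_LENGTH:
            n_unassigned += 1
            n_short += 1
            continue
        sample = barcode_to_sample.get(read.sequence[:BARCODE_LENGTH].upper())
        if sample is None:
            n_unassigned += 1
        else:
            by_sample[sample].append(read)
    if n_short:
        logger.warning("%d reads shorter than the %d-nt barcode", n_short, BARCODE_LENGTH)
    return by_sample, n_unassigned


def find_key(
    seq: str, key: str = DEFAULT_KEY, window: tuple[int, int] = DEFAULT_WINDOW
) -> int | None:
    """Locate the key sequence within the allowed window.

    Returns the smallest 1-based position ``p`` in ``[window[0], window[1]]``
    with ``seq[p .. p+len(key)-1] == key``, or ``None`` if the key does not
    start inside the window.
    """
    seq = seq.upper()
    lo, hi = window
    for p0 in range(lo - 1, hi):  # 0-based candidate start positions
        if seq[p0 : p0 + len(key)] == key:
            return p0 + 1
    return None


def extract_candidates(
    seq: str, key: str = DEFAULT_KEY, window: tuple[int, int] = DEFAULT_WINDOW
) -> list[str]:
    """Extract up to two candidate 20-mers following the key sequence.

    Candidate A is the 20 bases immediately after the key; if the base right
    after the key is a G (an occasional extra template base), candidate B is
    the 20 bases after that G. Truncated (<20 nt) candidates are dropped.
    """
    seq = seq.upper()
    p = find_key(seq, key=key, window=window)
    if p is None:
        return []
    start = p - 1 + len(key)  # 0-based position just after the key
    candidates = []
    cand_a = seq[start : start + GUIDE_LENGTH]
    if len(cand_a) == GUIDE_LENGTH:
        candidates.append(cand_a)
    if start < len(seq) and seq[start] == "G":
        cand_b = seq[start + 1 : start + 1 + GUIDE_LENGTH]
        if len(cand_b) == GUIDE_LENGTH:
            candidates.append(cand_b)
    return candidates


def count_guides(
    reads_by_sample: Mapping[str, Iterable[ReadRecord]],
    library: SgRNALibrary,
    key: str = DEFAULT_KEY,
    window: tuple[int, int] = DEFAULT_WINDOW,
    n_no_barcode: int = 0,
) -> tuple[pd.DataFrame, QuantReport]:
    """Convert demultiplexed reads into a guide x sample count matrix.

    Each read's extraction candidates are matched exactly against the library.
    Exactly one match: that guide's count increments. Both candidates match
    distinct guides: the read is tallied ambiguous and candidate A's guide
    wins (deterministic priority). No match: unmatched. 'N' bases never match.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    seq_to_guide = library.seq_to_guide
    samples = list(reads_by_sample.keys())
    counts = pd.DataFrame(
        np.zeros((len(library), len(samples)), dtype=int),
        index=pd.Index(library.guide_ids, name="guide_id"),
        columns=samples,
    )
    report = QuantReport(n_no_barcode=n_no_barcode)
    for sample in samples:
        stats = SampleQuantStats()
        col = counts[sample]
        for read in reads_by_sample[sample]:
            stats.n_reads += 1
            candidates = extract_candidates(read.sequence, key=key, window=window)
            if not candidates:
                stats.n_no_key += 1
                continue
            hits: list[str] = []
            for cand in candidates:
                guide = seq_to_guide.get(cand)
                if guide is not None and guide not in hits:
                    hits.append(guide)
            if not hits:
                stats.n_unmatched += 1
            elif len(hits) == 1:
                stats.n_assigned += 1
                col[hits[0]] += 1
            else:
                stats.n_ambiguous += 1
                col[hits[0]] += 1  # candidate-A priority
                logger.info(
                    "read %s matches guides %s; counting first", read.read_id, hits
                )
        stats.check()
        report.per_sample[sample] = stats
    return validate_counts(counts), report


def quantify_fastq(
    fastq_path,
    library: SgRNALibrary,
    sheet: SampleSheet,
    key: str = DEFAULT_KEY,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, QuantReport]:
    """FASTQ -> count matrix in one call: demultiplex then count."""
    from .io import read_fastq

    by_sample, n_unassigned = demultiplex(read_fastq(fastq_path), sheet)
    return count_guides(
        by_sample, library, key=key, window=window, n_no_barcode=n_unassigned
    )
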