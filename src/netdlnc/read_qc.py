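"""Windowed-adaptive read quality trimming and library-level filters.

Implements the QC stage of the sequencing pipeline: Sickle-style
windowed-adaptive trimming of both read ends against a Phred threshold
(default Q20, i.e. 99% base-call accuracy), a minimum retained-length rule
(default two-thirds of the original read, with an absolute override),
paired-end synchronisation, and removal of highly repetitive sequences
(any exact sequence exceeding 2% of the library).
"""

from __future__ import annotations

import gzip
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Read:
    """A sequencing read: name, sequence and per-base Phred scores."""

    name: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.name!r}: sequence and quality lengths differ"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def phred_from_accuracy(accuracy: float) -> float:
    """Phred score for a base-call accuracy: -10*log10(1 - accuracy).

    0.99 -> 20, 0.999 -> 30.
    """
    if not 0.0 < accuracy < 1.0:
        raise ValueError("accuracy must be in the open interval (0, 1)")
    return -10.0 * math.log10(1.0 - accuracy)


def accuracy_from_phred(q: float) -> float:
    """Inverse of :func:`phred_from_accuracy`."""
    return 1.0 - 10.0 ** (-q / 10.0)


def trim_read(
    read: Read,
    q_threshold: float = 20.0,
    window_frac: float = 0.1,
    min_length_frac: float = 2.0 / 3.0,
    min_length_abs: Optional[int] = None,
) -> Optional[Read]:
    """Trim both ends of a read by windowed mean quality; None = discard.

    A window of size ``max(1, round(window_frac * len(read)))`` slides over
    the read. The retained interval starts at the first window whose mean
    quality reaches ``q_threshold`` and ends at the last such window's end.
    If no window passes, or the retained length falls below the minimum
    (fractional by default; ``min_length_abs`` overrides when given), the
    read is discarded.
    """
    n = len(read)
    if n == 0:
        raise ValueError("empty read")
    if not 0.0 < window_frac <= 1.0:
        raise ValueError("window_frac must be in (0, 1]")
    w = max(1, round(window_frac * n))
    q = np.asarray(read.qualities, dtype=float)
    csum = np.concatenate(([0.0], np.cumsum(q)))
    means = (csum[w:] - csum[:-w]) / w  # mean of q[i:i+w] at index i
    passing = np.flatnonzero(means >= q_threshold)
    if passing.size == 0:
        return None
    start = int(passing[0])
    end = int(passing[-1]) + w
    kept = end - start
    min_len = min_length_abs if min_length_abs is not None else min_length_frac * n
    if kept < min_len:
        return None
    return Read(read.name, read.sequence[start:end], read.qualities[start:end])


def trim_pair(
    r1: Read,
    r2: Read,
    q_threshold: float = 20.0,
    window_frac: float = 0.1,
    min_length_frac: float = 2.0 / 3.0,
    min_length_abs: Optional[int] = None,
) -> Optional[tuple[Read, Read]]:
    """Trim both mates together; the pair is dropped if either mate fails.

    Keeping mates synchronized is required by downstream paired-end
    consumers.
    """
    t1 = trim_read(r1, q_threshold, window_frac, min_length_frac, min_length_abs)
    if t1 is None:
        return None
    t2 = trim_read(r2, q_threshold, window_frac, min_length_frac, min_length_abs)
    if t2 is None:
        return None
    return t1, t2


def filter_repetitive(
    library: Iterable[Read], max_frac: float = 0.02
) -> tuple[list[Read], dict]:
    """Remove every copy of any exact sequence exceeding ``max_frac``.

    A sequence whose frequency is strictly greater than ``max_frac`` of the
    library is considered highly repetitive and removed entirely. A
    singleton is never repetitive, whatever the library size. Returns the
    filtered library and a report.
    """
    if not 0.0 < max_frac < 1.0:
        raise ValueError("max_frac must be in (0, 1)")
    reads = list(library)
    n = len(reads)
    counts = Counter(r.sequence for r in reads)
    repetitive = {seq for seq, c in counts.items() if c > max_frac * n and c >= 2}
    kept = [r for r in reads if r.sequence not in repetitive]
    report = {
        "reads_in": n,
        "reads_out": len(kept),
        "repetitive_sequences": len(repetitive),
        "reads_removed": n - len(kept),
    }
    return kept, report


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33, gzip-transparent) via Biopython


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[Read]:
    """Iterate reads from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield Read(
                rec.id,
                str(rec.seq),
                tuple(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(reads: Iterable[Read], path) -> int:
    """Write reads as Phred+33 FASTQ; returns the record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.name, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def trim_fastq_pair(
    in1,
    in2,
    out1,
    out2,
    q_threshold: float = 20.0,
    window_frac: float = 0.1,
    min_length_frac: float = 2.0 / 3.0,
    min_length_abs: Optional[int] = None,
    dup_frac: float = 0.02,
) -> dict:
    """Full QC pass over a read-pair library; returns the QC report.

    Pairs are trimmed together (either mate failing drops the pair); the
    repetitive-sequence filter then runs per mate file on the trimmed
    output, again dropping whole pairs to keep mates synchronized.
    """
    reads1 = list(read_fastq(in1))
    reads2 = list(read_fastq(in2))
    if len(reads1) != len(reads2):
        raise ValueError(
            f"mate count mismatch: {len(reads1)} vs {len(reads2)} reads"
        )
    trimmed: list[tuple[Read, Read]] = []
    bases_in = sum(len(r) for r in reads1) + sum(len(r) for r in reads2)
    for r1, r2 in zip(reads1, reads2):
        pair = trim_pair(r1, r2, q_threshold, window_frac, min_length_frac,
                         min_length_abs)
        if pair is not None:
            trimmed.append(pair)
    kept1, rep1 = filter_repetitive([p[0] for p in trimmed], dup_frac)
    kept_names = {r.name for r in kept1}
    pairs = [p for p in trimmed if p[0].name in kept_names]
    kept2, rep2 = filter_repetitive([p[1] for p in pairs], dup_frac)
    kept_names2 = {r.name for r in kept2}
    pairs = [p for p in pairs if p[1].name in kept_names2]
    write_fastq([p[0] for p in pairs], out1)
    write_fastq([p[1] for p in pairs], out2)
    bases_out = sum(len(p[0]) + len(p[1]) for p in pairs)
    return {
        "pairs_in": len(reads1),
        "pairs_out": len(pairs),
        "pairs_dropped_trimming": len(reads1) - len(trimmed),
        "pairs_dropped_repetitive": len(trimmed) - len(pairs),
        "bases_in": bases_in,
        "bases_out": bases_out,
        "bases_trimmed": bases_in - bases_out,
        "repetitive_sequences": rep1["repetitive_sequences"]
        + rep2["repetitive_sequences"],
    }
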