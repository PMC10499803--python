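"""Read QC, 3' adapter trimming and collapsing to unique tags.

A read survives quality control iff every base quality among its first
25 nucleotides (or all of them, for shorter reads) is at least Q30, the
threshold the small-RNA pipeline applies before any alignment. After
exact 3'-adapter removal, inserts shorter than 18 nt are dropped, as are
reads in which no adapter was found (an untrimmed read could carry
templated genomic 3' bases that would masquerade as untemplated tails).
Surviving reads are collapsed to unique tags with multiplicities and
position-wise mean qualities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

MIN_INSERT_LEN = 18


@dataclass
class ReadTag:
    """A collapsed unique read sequence with multiplicity."""

    sequence: str
    count: int
    mean_quals: np.ndarray  # per-position mean Phred score

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


def quality_filter(
    fastq: str | Path, min_q: int = 30, first_n: int = 25
) -> Iterator[tuple[str, str]]:
    """Yield ``(sequence, quality_string)`` for reads passing QC.

    A read passes iff all of its first ``min(first_n, len)`` base
    qualities are >= ``min_q`` (Sanger/+33 encoding).
    """
    floor = chr(33 + min_q)
    try:
        with open(fastq) as fh:
            for i, (_title, seq, qual) in enumerate(FastqGeneralIterator(fh)):
                if len(seq) != len(qual):
                    raise ValueError(
                        f"{fastq}: record {i}: sequence/quality length mismatch"
                    )
                head = qual[:first_n]
                if head and min(head) < floor:
                    continue
                yield seq.upper(), qual
    except ValueError as err:
        raise ValueError(f"malformed FASTQ {fastq}: {err}") from err


def trim_adapter(
    reads: Iterable[tuple[str, str]],
    adapter3: str,
    min_overlap: int = 6,
    min_len: int = MIN_INSERT_LEN,
) -> Iterator[tuple[str, str]]:
    """Remove the 3' adapter (exact match, >= ``min_overlap`` nt).

    The longest read suffix equal to a prefix of ``adapter3`` is removed.
    Reads without any adapter hit, and inserts shorter than ``min_len``,
    are discarded.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    adapter3 = adapter3.upper()
    probe = adapter3[:min_overlap]
    alen = len(adapter3)
    for seq, qual in reads:
        i = seq.find(probe)
        cut = -1
        while i != -1:
            tail_len = len(seq) - i
            if tail_len <= alen and seq[i:] == adapter3[:tail_len]:
                cut = i
                break
            i = seq.find(probe, i + 1)
        if cut < min_len:  # no hit (cut == -1) or insert too short
            continue
        yield seq[:cut], qual[:cut]


def collapse(reads: Iterable[tuple[str, str]]) -> list[ReadTag]:
    """Merge identical sequences into :class:`ReadTag` records.

    Output is sorted by descending count, then lexicographically by
    sequence, so identical inputs always produce identical tag lists.
    """
    acc: dict[str, list] = {}
    for seq, qual in reads:
        q = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.float64) - 33
        entry = acc.get(seq)
        if entry is None:
            acc[seq] = [1, q]
        else:
            entry[0] += 1
            entry[1] += q
    tags = [
        ReadTag(seq, count, qsum / count)
        for seq, (count, qsum) in acc.items()
    ]
    tags.sort(key=lambda t: (-t.count, t.sequence))
    return tags
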