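"""Quality filtering and 3' adapter trimming of raw small-RNA FASTQ reads.

Produces the "clean reads" that feed the annotation cascade: mean-quality
filter, leftmost adapter-overlap trimming, and a 15-45 nt length window that
brackets miRNAs (~22 nt), tRNA fragments (17-26 nt) and tRNA halves
(30-40 nt).  Reads with no detectable adapter are retained when their full
length already lies within the window.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "CleanRead",
    "TrimStats",
    "PreprocessParams",
    "trim_adapter",
    "quality_filter",
    "preprocess_fastq",
    "write_clean_fastq",
]

LENGTH_MIN = 15
LENGTH_MAX = 45


@dataclass(frozen=True)
class CleanRead:
    """A read surviving quality filtering and adapter removal."""

    read_id: str
    sequence: str  # insert only, adapter removed
    quality: str
    original_length: int

    def __post_init__(self) -> None:
        if not LENGTH_MIN <= len(self.sequence) <= LENGTH_MAX:
            raise ValueError("clean read length outside [15, 45]")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("clean read alphabet restricted to ACGTN")


@dataclass
class TrimStats:
    """Read-fate tally; every input read lands in exactly one bucket."""

    n_input: int = 0
    n_adapter_found: int = 0
    n_too_short: int = 0
    n_too_long: int = 0
    n_low_quality: int = 0
    n_clean: int = 0

    def check(self) -> None:
        dropped = self.n_too_short + self.n_too_long + self.n_low_quality
        if self.n_clean != self.n_input - dropped:
            raise AssertionError("TrimStats buckets do not partition the input")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k, v in vars(self).items():
                fh.write(f"{k}\t{v}\n")


@dataclass
class PreprocessParams:
    adapter: str
    min_overlap: int = 10
    max_mismatch_rate: float = 0.1
    mean_q_min: float = 20.0
    max_n_fraction: float = 0.1
    length_min: int = LENGTH_MIN
    length_max: int = LENGTH_MAX


def trim_adapter(read_seq: str, adapter: str, min_overlap: int = 10,
                 max_mismatch_rate: float = 0.1) -> str | None:
    """Return the insert preceding the best adapter occurrence, or None.

    The adapter may occur internally (full or prefix, followed by anything)
    or as a suffix overlap of at least ``min_overlap`` bases at the read's
    3' end.  Among occurrences within the per-occurrence mismatch budget
    (``max_mismatch_rate`` x overlap length, floored), the leftmost one with
    the fewest mismatches wins.
    """
    if not read_seq:
        raise ValueError("empty read")
    if not adapter:
        raise ValueError("empty adapter")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")

    n, m = len(read_seq), len(adapter)
    # fast path: exact occurrence of the longest possible overlap at each offset
    pos = read_seq.find(adapter)
    if pos == -1 and n >= min_overlap:
        # exact suffix overlap of the adapter prefix at the read's 3' end
        for start in range(max(0, n - m + 1), n - min_overlap + 1):
            if read_seq[start:] == adapter[: n - start]:
                pos = start
                break
    if pos != -1:
        return read_seq[:pos]

    best: tuple[int, int] | None = None  # (start, mismatches)
    for start in range(0, n - min_overlap + 1):
        overlap = min(m, n - start)
        budget = int(max_mismatch_rate * overlap)
        mm = 0
        for a, b in zip(read_seq[start:start + overlap], adapter):
            if a != b:
                mm += 1
                if mm > budget:
                    break
        else:
            if best is None or mm < best[1]:
                best = (start, mm)
                if mm == 0:
                    break
    if best is None:
        return None
    return read_seq[: best[0]]


def quality_filter(sequence: str, quality: str, mean_q_min: float = 20.0,
                   max_n_fraction: float = 0.1) -> bool:
    """True iff mean Phred >= ``mean_q_min`` and N fraction <= ``max_n_fraction``."""
    if len(sequence) != len(quality):
        raise ValueError("sequence and quality differ in length")
    if not sequence:
        return False
    mean_q = sum(ord(c) - 33 for c in quality) / len(quality)
    n_frac = sequence.count("N") / len(sequence)
    return mean_q >= mean_q_min and n_frac <= max_n_fraction


def preprocess_fastq(fastq_in: str | Path,
                     params: PreprocessParams) -> tuple[list[CleanRead], TrimStats]:
    """Quality-filter, adapter-trim and length-select a FASTQ file.

    Order of operations per read: quality filter on the raw read, adapter
    trimming, then the [length_min, length_max] window on the insert.
    Output preserves input order; dropped reads are tallied once each.
    """
    stats = TrimStats()
    clean: list[CleanRead] = []
    with open(fastq_in) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            stats.n_input += 1
            read_id = title.split()[0]
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {stats.n_input} in {fastq_in}")
            if not quality_filter(seq, qual, params.mean_q_min,
                                  params.max_n_fraction):
                stats.n_low_quality += 1
                continue
            insert = trim_adapter(seq, params.adapter, params.min_overlap,
                                  params.max_mismatch_rate)
            if insert is None:
                insert = seq  # untrimmed reads kept if already in-window
            else:
                stats.n_adapter_found += 1
            if len(insert) < params.length_min:
                stats.n_too_short += 1
                continue
            if len(insert) > params.length_max:
                stats.n_too_long += 1
                continue
            stats.n_clean += 1
            clean.append(CleanRead(read_id=read_id, sequence=insert,
                                   quality=qual[: len(insert)],
                                   original_length=len(seq)))
    stats.check()
    return clean, stats


def write_clean_fastq(reads: list[CleanRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
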