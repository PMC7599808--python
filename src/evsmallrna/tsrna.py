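"""Typing and summarisation of tRNA-derived small RNAs (tsRNAs).

tRNA-mapped reads are typed as 5' halves, 3' halves, or fragments.  Halves
are 30+ nt cleavage products anchored at a mature-tRNA terminus (1 nt ragged
ends allowed); anything shorter than 30 nt is a fragment, including the
27-29 nt gap between the canonical fragment (17-26 nt) and half (30-40 nt)
ranges.  Reads >= 30 nt anchored at neither end are flagged nonstandard and
counted with the fragments.

Also provides per-tRNA coverage profiles with a percentile meta-profile
(halves from anticodon-loop cleavage pile up on the 5' or 3' half of the
mature sequence), length histograms, and per-isoacceptor abundance tables.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .annotate import AnnotatedRead
from .refsim import MatureTRNA, ReferenceSet

__all__ = [
    "TsRNARecord",
    "IsoacceptorTable",
    "CoverageProfile",
    "classify_tsrna",
    "build_tsrna_records",
    "isoacceptor_abundance",
    "coverage_profiles",
    "tsrna_length_histogram",
]

HALF_MIN_LEN = 30
FRAGMENT_MIN_LEN = 17
END_TOLERANCE = 1  # ragged-end allowance at either terminus


@dataclass(frozen=True)
class TsRNARecord:
    read_id: str
    trna_name: str
    ref_start: int
    ref_end: int
    tsrna_type: str  # half_5p | half_3p | fragment
    nonstandard: bool = False

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class IsoacceptorTable:
    """Per-isoacceptor read counts and percentages of all tRNA-mapped reads.

    Rows sorted by descending percentage, ties by name; ``dominant_type`` is
    the majority tsRNA type on that isoacceptor (ties resolved toward the
    half types).
    """

    rows: list[tuple[str, int, float, str]]  # name, count, percentage, dominant

    def __post_init__(self) -> None:
        total = sum(r[2] for r in self.rows)
        if self.rows and abs(total - 100.0) > 0.01:
            raise AssertionError("isoacceptor percentages must sum to 100")

    def percentage(self, name: str) -> float:
        for row in self.rows:
            if row[0] == name:
                return row[2]
        raise KeyError(name)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("trna\tcount\tpercentage\tdominant_type\n")
            for name, count, pct, dom in self.rows:
                fh.write(f"{name}\t{count}\t{pct:.4f}\t{dom}\n")


@dataclass(frozen=True)
class CoverageProfile:
    """Per-position read depth on each mature tRNA plus a percentile meta-profile."""

    per_trna: dict[str, np.ndarray]
    meta: np.ndarray  # 100 percentile bins, depth summed across tRNAs


def classify_tsrna(ann: AnnotatedRead, trna: MatureTRNA) -> tuple[str, bool]:
    """Type one tRNA-mapped read; returns (tsrna_type, nonstandard flag).

    Rules: length >= 30 anchored at the 5' end (ref_start <= 1) -> half_5p;
    length >= 30 anchored at the 3' end (ref_end >= len - 1) -> half_3p;
    length 17-29 -> fragment.  Reads >= 30 nt anchored at neither end, and
    reads < 17 nt, are fragments flagged nonstandard.
    """
    if ann.category != "tRNA":
        raise ValueError(f"read {ann.read_id} is not tRNA-annotated")
    if ann.ref_name != trna.name:
        raise ValueError(f"read {ann.read_id} maps to {ann.ref_name}, "
                         f"not {trna.name}")
    length = ann.ref_end - ann.ref_start
    if length >= HALF_MIN_LEN:
        if ann.ref_start <= END_TOLERANCE:
            return "half_5p", False
        if ann.ref_end >= len(trna.sequence) - END_TOLERANCE:
            return "half_3p", False
        return "fragment", True
    if length >= FRAGMENT_MIN_LEN:
        return "fragment", False
    return "fragment", True


def build_tsrna_records(annotated: list[AnnotatedRead],
                        refs: ReferenceSet) -> list[TsRNARecord]:
    """Type every tRNA-annotated read against its reference."""
    trnas = {t.name: t for t in refs.trnas}
    out = []
    for ann in annotated:
        if ann.category != "tRNA":
            continue
        trna = trnas.get(ann.ref_name)
        if trna is None:
            raise KeyError(f"unknown tRNA reference {ann.ref_name!r}")
        ttype, nonstd = classify_tsrna(ann, trna)
        out.append(TsRNARecord(ann.read_id, ann.ref_name, ann.ref_start,
                               ann.ref_end, ttype, nonstd))
    return out


def isoacceptor_abundance(records: list[TsRNARecord]) -> IsoacceptorTable:
    """Aggregate tsRNA reads per isoacceptor, as percentages of tRNA reads."""
    if not records:
        raise ValueError("no tsRNA records")
    counts: Counter[str] = Counter(r.trna_name for r in records)
    types: dict[str, Counter] = defaultdict(Counter)
    for r in records:
        types[r.trna_name][r.tsrna_type] += 1
    total = sum(counts.values())
    rows = []
    for name in counts:
        tc = types[name]
        # majority type; ties resolved toward halves, then 5' before 3'
        order = {"half_5p": 0, "half_3p": 1, "fragment": 2}
        dominant = max(tc, key=lambda t: (tc[t], -order[t]))
        rows.append((name, counts[name], 100.0 * counts[name] / total,
                     dominant))
    rows.sort(key=lambda r: (-r[2], r[0]))
    return IsoacceptorTable(rows=rows)


def coverage_profiles(records: list[TsRNARecord],
                      refs: ReferenceSet,
                      n_bins: int = 100) -> CoverageProfile:
    """Per-position depth on each tRNA and a percentile-binned meta-profile.

    Position p on a tRNA of length L contributes its depth to meta bin
    floor(n_bins * p / L).
    """
    trnas = {t.name: t for t in refs.trnas}
    per: dict[str, np.ndarray] = {}
    meta = np.zeros(n_bins)
    depth_by_trna: dict[str, np.ndarray] = {}
    for r in records:
        trna = trnas.get(r.trna_name)
        if trna is None:
            raise KeyError(f"unknown tRNA reference {r.trna_name!r}")
        L = len(trna.sequence)
        if not (0 <= r.ref_start < r.ref_end <= L):
            raise ValueError(f"record {r.read_id} outside {r.trna_name} bounds")
        if r.trna_name not in depth_by_trna:
            depth_by_trna[r.trna_name] = np.zeros(L)
        # interval accumulation via difference array
        depth_by_trna[r.trna_name][r.ref_start] += 1
        if r.ref_end < L:
            depth_by_trna[r.trna_name][r.ref_end] -= 1
    for name, diff in depth_by_trna.items():
        depth = np.cumsum(diff)
        per[name] = depth
        L = len(depth)
        bins = np.minimum((n_bins * np.arange(L)) // L, n_bins - 1)
        np.add.at(meta, bins, depth)
    return CoverageProfile(per_trna=per, meta=meta)


def tsrna_length_histogram(records: list[TsRNARecord],
                           lo: int = 15, hi: int = 45) -> dict[int, int]:
    """Histogram of tsRNA read lengths over [lo, hi]."""
    hist = {length: 0 for length in range(lo, hi + 1)}
    for r in records:
        if lo <= r.length <= hi:
            hist[r.length] += 1
    return hist
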