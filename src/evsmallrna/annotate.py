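"""Hierarchical small-RNA read annotation.

Clean reads are assigned to classes by a strict cascade: tRNA first (ungapped,
up to 1 mismatch), then mature miRNA (0 mismatches but tolerating a 1-3 nt
untemplated 3' A/T tail), then rRNA, mRNA, other small RNAs and finally a
genome stage (each up to 1 mismatch); reads surviving all stages are
unmapped.  A read is assigned at the first stage with any hit; within a
stage ties are broken by fewest mismatches, then smallest reference start,
then reference name.

Matching is ungapped and sense-strand only, as appropriate for reads derived
from mature transcripts.  The public :func:`match_substring` /
:func:`match_mirna_with_tail` expose single-reference matching; the cascade
uses a seed-and-verify index over each class for speed, with identical
semantics (two disjoint 7-mer seeds guarantee completeness at <=1 mismatch
for reads of >= 14 nt).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

from .preprocess import CleanRead
from .refsim import MatureMiRNA, ReferenceSet

__all__ = [
    "AnnotatedRead",
    "ClassComposition",
    "CATEGORIES",
    "STAGES",
    "match_substring",
    "match_mirna_with_tail",
    "cascade_annotate",
    "composition",
    "length_histogram",
    "write_annotation_tsv",
    "read_annotation_tsv",
]

#: cascade stages in mapping order, with per-stage mismatch budgets
STAGES = (
    ("tRNA", 1),
    ("miRNA", 0),
    ("rRNA", 1),
    ("mRNA", 1),
    ("other_sRNA", 1),
    ("genome", 1),
)

CATEGORIES = tuple(s for s, _ in STAGES) + ("unmapped",)

MAX_TAIL = 3


@dataclass(frozen=True)
class AnnotatedRead:
    """Final class assignment for one read.

    ``ref_start``/``ref_end`` are 0-based half-open on the reference and
    cover the templated part only; for a tailed miRNA read the insert length
    equals (ref_end - ref_start) + tail_len.
    """

    read_id: str
    category: str
    ref_name: str
    ref_start: int
    ref_end: int
    mismatches: int
    tail_len: int
    insert_len: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "unmapped") != (self.ref_name == ""):
            raise ValueError("unmapped iff ref_name empty")
        if self.category != "unmapped":
            if self.ref_end - self.ref_start != self.insert_len - self.tail_len:
                raise ValueError("reference span must cover the templated part")
        if self.tail_len and self.category != "miRNA":
            raise ValueError("untemplated tails only apply to miRNA hits")


@dataclass(frozen=True)
class ClassComposition:
    """Per-sample read counts and fractions by annotation category."""

    sample_id: str
    counts: dict[str, int]
    fractions: dict[str, float]

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit once ``limit`` is exceeded."""
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def match_substring(read_seq: str, ref_seq: str,
                    max_mismatch: int) -> tuple[int, int] | None:
    """Best ungapped end-to-end placement of the read inside the reference.

    Scans every offset; returns (start, mismatches) for the placement with
    the fewest mismatches (leftmost on ties) if that count is within
    ``max_mismatch``, else None.
    """
    if not read_seq:
        raise ValueError("empty read")
    n, m = len(read_seq), len(ref_seq)
    if n > m:
        return None
    best: tuple[int, int] | None = None
    limit = max_mismatch
    for start in range(m - n + 1):
        mm = _mismatches(read_seq, ref_seq[start:start + n], limit)
        if mm <= limit:
            if best is None or mm < best[1]:
                best = (start, mm)
                if mm == 0:
                    break
    return best


def match_mirna_with_tail(read_seq: str, mirna: MatureMiRNA,
                          max_tail: int = MAX_TAIL,
                          ) -> tuple[int, int, int] | None:
    """Match a read to a mature miRNA allowing an untemplated 3' A/T tail.

    Finds the smallest t in [0, max_tail] such that the read minus its last
    t bases (all of which must be A or T) occurs exactly inside the mature
    sequence.  Returns (tail_len, ref_start, ref_end) over the templated
    part, or None.  Minimising t means bases that are templated in the
    reference are never called tail.
    """
    if not read_seq:
        raise ValueError("empty read")
    for t in range(0, max_tail + 1):
        if t > 0 and read_seq[len(read_seq) - t] not in "AT":
            return None  # last t bases no longer all A/T; larger t cannot fix it
        core = read_seq[: len(read_seq) - t]
        if not core:
            return None
        hit = match_substring(core, mirna.sequence, 0)
        if hit is not None:
            return t, hit[0], hit[0] + len(core)
    return None


class _SeedIndex:
    """Seed-and-verify substring index over one reference class.

    Indexes all 7-mers of every reference; a read is looked up via two
    disjoint seeds (its first and last 7-mer), which by pigeonhole find
    every placement with <= 1 mismatch for reads of length >= 14.
    """

    K = 7

    def __init__(self, refs: list[tuple[str, str]]):
        self.refs = refs
        self.index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ri, (_, seq) in enumerate(refs):
            for off in range(len(seq) - self.K + 1):
                self.index[seq[off:off + self.K]].append((ri, off))

    def candidates(self, read_seq: str):
        n = len(read_seq)
        seen: set[tuple[int, int]] = set()
        for read_off in (0, n - self.K):
            if read_off < 0:
                continue
            seed = read_seq[read_off:read_off + self.K]
            for ri, off in self.index.get(seed, ()):
                start = off - read_off
                if start < 0 or start + n > len(self.refs[ri][1]):
                    continue
                if (ri, start) not in seen:
                    seen.add((ri, start))
                    yield ri, start

    def best_hit(self, read_seq: str,
                 max_mismatch: int) -> tuple[int, int, str] | None:
        """(start, mismatches, ref_name) winner under the stage tie rules."""
        if max_mismatch > 1:
            raise ValueError("seed index is complete only for <= 1 mismatch")
        best = None
        for ri, start in self.candidates(read_seq):
            ref_seq = self.refs[ri][1]
            mm = _mismatches(read_seq, ref_seq[start:start + len(read_seq)],
                             max_mismatch)
            if mm > max_mismatch:
                continue
            key = (mm, start, self.refs[ri][0])
            if best is None or key < best:
                best = key
        if best is None:
            return None
        return best[1], best[0], best[2]


class _CascadeEngine:
    """Reusable cascade over one reference set."""

    def __init__(self, refs: ReferenceSet, max_tail: int = MAX_TAIL,
                 trna_max_mismatch: int = 1):
        pools = {"genome": refs.by_class("genome_decoy")}
        for cls in ("tRNA", "miRNA", "rRNA", "mRNA", "other_sRNA"):
            pools[cls] = refs.by_class(cls)
        self.indexes = {cls: _SeedIndex(pools[cls]) for cls, _ in STAGES}
        self.stages = tuple(
            (s, trna_max_mismatch if s == "tRNA" else mm) for s, mm in STAGES)
        self.max_tail = max_tail

    def _mirna_hit(self, seq: str) -> tuple[int, int, int, str] | None:
        """(tail_len, ref_start, ref_end, name): smallest tail wins first."""
        idx = self.indexes["miRNA"]
        for t in range(0, self.max_tail + 1):
            if t > 0 and seq[len(seq) - t] not in "AT":
                return None
            core = seq[: len(seq) - t]
            if not core:
                return None
            hit = idx.best_hit(core, 0)
            if hit is not None:
                start, _, name = hit
                return t, start, start + len(core), name
        return None

    def annotate(self, read: CleanRead) -> AnnotatedRead:
        seq = read.sequence
        for stage, max_mm in self.stages:
            if stage == "miRNA":
                mhit = self._mirna_hit(seq)
                if mhit is not None:
                    t, start, end, name = mhit
                    return AnnotatedRead(read.read_id, "miRNA", name, start,
                                         end, 0, t, len(seq))
                continue
            hit = self.indexes[stage].best_hit(seq, max_mm)
            if hit is not None:
                start, mm, name = hit
                return AnnotatedRead(read.read_id, stage, name, start,
                                     start + len(seq), mm, 0, len(seq))
        return AnnotatedRead(read.read_id, "unmapped", "", 0, 0, 0, 0,
                             len(seq))


def cascade_annotate(reads: list[CleanRead], refs: ReferenceSet,
                     max_tail: int = MAX_TAIL,
                     trna_max_mismatch: int = 1) -> list[AnnotatedRead]:
    """Annotate clean reads through the full cascade, one record per read."""
    engine = _CascadeEngine(refs, max_tail=max_tail,
                            trna_max_mismatch=trna_max_mismatch)
    return [engine.annotate(r) for r in reads]


def composition(annotated: list[AnnotatedRead],
                sample_id: str) -> ClassComposition:
    """Per-category counts and fractions of all clean reads (unmapped included)."""
    if not annotated:
        raise ValueError("empty annotation list")
    counts = Counter(a.category for a in annotated)
    full = {c: counts.get(c, 0) for c in CATEGORIES}
    n = len(annotated)
    fractions = {c: full[c] / n for c in CATEGORIES}
    return ClassComposition(sample_id=sample_id, counts=full,
                            fractions=fractions)


def length_histogram(reads: list[CleanRead],
                     lo: int = 15, hi: int = 45) -> dict[int, int]:
    """Insert-length histogram over [lo, hi]; sums to the number of reads."""
    hist = {length: 0 for length in range(lo, hi + 1)}
    for r in reads:
        hist[len(r.sequence)] += 1
    return hist


ANNOTATION_COLUMNS = ["read_id", "category", "ref_name", "ref_start",
                      "ref_end", "mismatches", "tail_len", "insert_len"]


def write_annotation_tsv(annotated: list[AnnotatedRead],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for a in annotated:
            fh.write(f"{a.read_id}\t{a.category}\t{a.ref_name}\t"
                     f"{a.ref_start}\t{a.ref_end}\t{a.mismatches}\t"
                     f"{a.tail_len}\t{a.insert_len}\n")


def read_annotation_tsv(path: str | Path) -> list[AnnotatedRead]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ANNOTATION_COLUMNS:
            raise ValueError(f"unexpected annotation header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(AnnotatedRead(f[0], f[1], f[2], int(f[3]), int(f[4]),
                                     int(f[5]), int(f[6]), int(f[7])))
    return out
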