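"""Synthetic references and small-RNA read simulation with known ground truth.

This module builds a self-contained benchmark for the annotation cascade:
random mature-miRNA, mature-tRNA and background references that are screened
to be collision-free at the shortest simulated read length, plus a FASTQ
simulator that emits miRNA reads (optionally with untemplated 3' A/T tails),
5'/3' tRNA halves cut in the anticodon loop, shorter tRNA fragments, and
background reads, together with a per-read ground-truth table.

All sequences use the DNA alphabet (U -> T), matching sequencer output.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MatureTRNA",
    "MatureMiRNA",
    "ReferenceSet",
    "SimulatedRead",
    "SimulationConfig",
    "ISOACCEPTOR_LABELS",
    "TRUSEQ_SMALL_RNA_ADAPTER",
    "TRUTH_COLUMNS",
    "generate_references",
    "simulate_sample",
    "write_fastq",
    "write_truth",
    "write_reference_fastas",
]

#: Illumina TruSeq small-RNA 3' adapter.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Human tRNA isoacceptor labels (amino acid + anticodon, DNA alphabet).
ISOACCEPTOR_LABELS = [
    "Gly-GCC", "Val-AAC", "Val-CAC", "Glu-CTC", "Gly-CCC", "Lys-TTT",
    "His-GTG", "Ser-GCT", "Ser-ACT", "Phe-GAA", "Ile-AAT", "Leu-TAG",
    "Thr-CGT", "Arg-CCG", "Asn-GTT", "Ala-TGC", "Sup-TTA", "Glu-TTC",
    "Asp-GTC", "Cys-GCA", "Met-CAT", "Trp-CCA", "Gln-CTG", "Pro-AGG",
    "Arg-TCT", "Leu-CAG", "Tyr-GTA", "Lys-CTT", "Ala-AGC", "Thr-TGT",
]

BACKGROUND_CLASSES = ("rRNA", "mRNA", "other_sRNA", "genome_decoy")

TRUTH_COLUMNS = [
    "read_id", "class", "ref_name", "ref_start", "ref_end", "tail_seq",
    "tsrna_type",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: shortest simulated read; collision screening works at this k-mer size
_MIN_READ_LEN = 17


@dataclass(frozen=True)
class MatureTRNA:
    """A mature tRNA with its anticodon-loop coordinates.

    The anticodon loop is the 7-nt loop of the cloverleaf; the anticodon
    itself starts two bases into the loop.  Mature tRNAs end in the
    post-transcriptionally added 3' CCA.
    """

    name: str
    sequence: str
    anticodon_start: int
    anticodon_loop: tuple[int, int]  # 0-based half-open, length 7

    def __post_init__(self) -> None:
        lo, hi = self.anticodon_loop
        if not self.sequence.endswith("CCA"):
            raise ValueError(f"{self.name}: mature tRNA must end with CCA")
        if hi - lo != 7:
            raise ValueError(f"{self.name}: anticodon loop must span 7 nt")
        if self.anticodon_start - lo != 2:
            raise ValueError(f"{self.name}: anticodon must start 2 nt into loop")
        if not (0 <= lo < hi <= len(self.sequence)):
            raise ValueError(f"{self.name}: anticodon loop out of bounds")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA reference sequence (18-25 nt)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not 18 <= len(self.sequence) <= 25:
            raise ValueError(f"{self.name}: mature miRNA must be 18-25 nt")
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"{self.name}: alphabet restricted to ACGT")


@dataclass(frozen=True)
class ReferenceSet:
    """All reference sequences for one simulated experiment.

    ``background`` holds (name, class, sequence) triples with class one of
    rRNA / mRNA / other_sRNA / genome_decoy.  Generation guarantees that no
    17-mer is shared between any two records, so every simulated read of
    length >= 17 identifies its source unambiguously.
    """

    mirnas: list[MatureMiRNA]
    trnas: list[MatureTRNA]
    background: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        names = [m.name for m in self.mirnas] + [t.name for t in self.trnas]
        names += [b[0] for b in self.background]
        if len(names) != len(set(names)):
            raise ValueError("reference names must be unique across the set")
        trna_cat = "|".join(t.sequence for t in self.trnas)
        for m in self.mirnas:
            if m.sequence in trna_cat:
                raise ValueError(f"{m.name} is a substring of a tRNA reference")

    def by_class(self, cls: str) -> list[tuple[str, str]]:
        """(name, sequence) pairs for one annotation class."""
        if cls == "miRNA":
            return [(m.name, m.sequence) for m in self.mirnas]
        if cls == "tRNA":
            return [(t.name, t.sequence) for t in self.trnas]
        return [(n, s) for n, c, s in self.background if c == cls]

    def trna(self, name: str) -> MatureTRNA:
        for t in self.trnas:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class SimulatedRead:
    """One simulated read plus its ground truth.

    Coordinates are 0-based half-open on the named reference and describe the
    templated part only; ``tail_seq`` holds any untemplated 3' A/T addition.
    """

    read_id: str
    sequence: str
    quality: str
    truth_class: str
    ref_name: str
    ref_start: int
    ref_end: int
    tail_seq: str
    tsrna_type: str  # "" unless truth_class == "tRNA"

    def __post_init__(self) -> None:
        if set(self.tail_seq) - set("AT"):
            raise ValueError("untemplated tails contain only A/T")
        if (self.tsrna_type != "") != (self.truth_class == "tRNA"):
            raise ValueError("tsrna_type set iff the read is tRNA-derived")


@dataclass
class SimulationConfig:
    """Per-sample simulation parameters.

    ``composition`` maps class names (miRNA, tRNA, rRNA, mRNA, other_sRNA,
    genome) to proportions summing to 1.  tRNA reads are split into halves
    (30-40 nt, anchored at a mature end, produced by anticodon-loop cleavage)
    and fragments (17-26 nt, internal or end-proximal).
    """

    n_reads: int = 10_000
    composition: dict[str, float] = field(
        default_factory=lambda: {"miRNA": 0.5, "tRNA": 0.3, "rRNA": 0.1,
                                 "mRNA": 0.05, "other_sRNA": 0.03,
                                 "genome": 0.02})
    tail_prob: float = 0.25
    tail_length_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)  # 1,2,3 nt
    half_fraction: float = 0.7
    half_length_range: tuple[int, int] = (30, 40)
    fragment_length_range: tuple[int, int] = (17, 26)
    trna_weights: dict[str, float] | None = None  # isoacceptor usage; None = uniform
    error_rate: float = 0.0
    adapter: str = TRUSEQ_SMALL_RNA_ADAPTER
    read_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1, got {total}")
        if any(p < 0 for p in self.composition.values()):
            raise ValueError("composition proportions must be non-negative")
        for rng_ in (self.half_length_range, self.fragment_length_range):
            if not (15 <= rng_[0] <= rng_[1] <= 45):
                raise ValueError("length ranges must lie within [15, 45]")
        if not 0 <= self.error_rate < 0.05:
            raise ValueError("error_rate must be in [0, 0.05)")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _kmers(seq: str, k: int = _MIN_READ_LEN):
    return (seq[i:i + k] for i in range(len(seq) - k + 1))


def _screened_seq(rng: np.random.Generator, length: int,
                  seen: set[str], k: int = _MIN_READ_LEN) -> str:
    """Random sequence none of whose k-mers collides with ``seen``.

    Also rejects internal k-mer repeats so every read position is unique.
    Registers the accepted sequence's k-mers in ``seen``.
    """
    for _ in range(1000):
        seq = _random_seq(rng, length)
        mers = list(_kmers(seq, k)) if length >= k else [seq]
        if len(set(mers)) == len(mers) and not any(m in seen for m in mers):
            seen.update(mers)
            return seq
    raise RuntimeError("could not generate a collision-free sequence")


def generate_references(n_mirna: int, n_trna: int, n_background: int,
                        seed: int) -> ReferenceSet:
    """Generate a collision-free reference set.

    miRNAs are 20-24 nt (mode 22), tRNAs 70-90 nt ending in CCA with the
    anticodon triplet of their isoacceptor label embedded at the annotated
    position, and background records are longer transcripts cycling through
    rRNA / mRNA / other_sRNA / genome_decoy.  Deterministic for a fixed seed.
    """
    if n_mirna < 1 or n_trna < 1 or n_background < 0:
        raise ValueError("n_mirna and n_trna must be >= 1, n_background >= 0")
    if n_trna > len(ISOACCEPTOR_LABELS):
        raise ValueError(f"at most {len(ISOACCEPTOR_LABELS)} tRNA isoacceptors supported")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()

    trnas = []
    for label in ISOACCEPTOR_LABELS[:n_trna]:
        anticodon = label.split("-")[1]
        for _ in range(1000):
            length = int(rng.integers(70, 91))
            # loop placed so both cleavage halves can reach 30 nt
            loop_start = int(rng.integers(30, min(37, length - 37)))
            seq = _random_seq(rng, length - 3) + "CCA"
            seq = (seq[:loop_start + 2] + anticodon + seq[loop_start + 5:])
            mers = list(_kmers(seq))
            if len(set(mers)) == len(mers) and not any(m in seen for m in mers):
                seen.update(mers)
                break
        else:
            raise RuntimeError("could not place a collision-free tRNA")
        trnas.append(MatureTRNA(name=label, sequence=seq,
                                anticodon_start=loop_start + 2,
                                anticodon_loop=(loop_start, loop_start + 7)))

    mirnas = []
    mirna_lengths = rng.choice([20, 21, 22, 23, 24], size=n_mirna,
                               p=[0.10, 0.20, 0.40, 0.20, 0.10])
    for i, length in enumerate(mirna_lengths):
        seq = _screened_seq(rng, int(length), seen)
        mirnas.append(MatureMiRNA(name=f"sim-miR-{i + 1}", sequence=seq))

    background = []
    for i in range(n_background):
        cls = BACKGROUND_CLASSES[i % len(BACKGROUND_CLASSES)]
        length = int(rng.integers(100, 201))
        seq = _screened_seq(rng, length, seen)
        background.append((f"sim-{cls}-{i + 1}", cls, seq))

    return ReferenceSet(mirnas=mirnas, trnas=trnas, background=background)


def _phred(qualities: np.ndarray) -> str:
    return bytes((qualities + 33).astype(np.uint8)).decode()


def _apply_errors(rng: np.random.Generator, seq: str, qual: np.ndarray,
                  error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
        qual[i] = 12
    return bytes(arr).decode()


def simulate_sample(refs: ReferenceSet, cfg: SimulationConfig,
                    sample_id: str = "sample") -> list[SimulatedRead]:
    """Simulate one small-RNA library.

    Each read is an insert followed by adapter read-through, truncated to
    ``cfg.read_length``; base-call errors are substitutions whose quality is
    dropped from the Q36 baseline to Q12.  Returns reads in generation order;
    use :func:`write_fastq` / :func:`write_truth` to serialize.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    classes = sorted(cfg.composition)
    probs = np.array([cfg.composition[c] for c in classes])
    for cls, p in zip(classes, probs):
        pool = "genome_decoy" if cls == "genome" else cls
        if p > 0 and not refs.by_class(pool):
            raise ValueError(f"composition requests class {cls!r} but the "
                             "reference set has no such sequences")

    trna_names = [t.name for t in refs.trnas]
    if cfg.trna_weights:
        w = np.array([cfg.trna_weights.get(n, 0.0) for n in trna_names])
        if w.sum() <= 0:
            raise ValueError("trna_weights assigns no mass to any tRNA")
        trna_p = w / w.sum()
    else:
        trna_p = np.full(len(trna_names), 1 / max(len(trna_names), 1))

    draws = rng.choice(len(classes), size=cfg.n_reads, p=probs)
    tail_lens = np.array([1, 2, 3])
    reads: list[SimulatedRead] = []

    for i, ci in enumerate(draws):
        cls = classes[ci]
        tail = ""
        tsrna_type = ""
        if cls == "miRNA":
            m = refs.mirnas[rng.integers(len(refs.mirnas))]
            insert = m.sequence
            ref_name, start, end = m.name, 0, len(m.sequence)
            if rng.random() < cfg.tail_prob:
                t = int(rng.choice(tail_lens, p=cfg.tail_length_probs))
                tail = "".join("AT"[rng.integers(2)] for _ in range(t))
                insert = insert + tail
        elif cls == "tRNA":
            t_idx = rng.choice(len(trna_names), p=trna_p)
            trna = refs.trnas[t_idx]
            L = len(trna.sequence)
            if rng.random() < cfg.half_fraction:
                lo, hi = cfg.half_length_range
                cut = int(rng.integers(trna.anticodon_loop[0],
                                       trna.anticodon_loop[1] + 1))
                if rng.random() < 0.5:  # 5' half
                    length = int(np.clip(cut, lo, hi))
                    start, end = 0, length
                    tsrna_type = "half_5p"
                else:  # 3' half keeps the CCA end
                    length = int(np.clip(L - cut, lo, hi))
                    start, end = L - length, L
                    tsrna_type = "half_3p"
            else:
                lo, hi = cfg.fragment_length_range
                length = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, L - length + 1))
                end = start + length
                tsrna_type = "fragment"
            insert = trna.sequence[start:end]
            ref_name = trna.name
        else:
            pool = "genome_decoy" if cls == "genome" else cls
            recs = refs.by_class(pool)
            name, seq = recs[rng.integers(len(recs))]
            length = int(rng.integers(20, 36))
            start = int(rng.integers(0, len(seq) - length + 1))
            end = start + length
            insert = seq[start:end]
            ref_name = name

        full = (insert + cfg.adapter)[:cfg.read_length]
        qual = np.full(len(full), 36, dtype=np.int64)
        full = _apply_errors(rng, full, qual, cfg.error_rate)
        reads.append(SimulatedRead(
            read_id=f"{sample_id}:{i}", sequence=full, quality=_phred(qual),
            truth_class=cls, ref_name=ref_name, ref_start=start, ref_end=end,
            tail_seq=tail, tsrna_type=tsrna_type))
    return reads


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for r in reads:
            w.writerow([r.read_id, r.truth_class, r.ref_name, r.ref_start,
                        r.ref_end, r.tail_seq, r.tsrna_type])


def write_reference_fastas(refs: ReferenceSet, outdir: str | Path) -> dict[str, Path]:
    """Write one FASTA per annotation class (trna.fa, mirna.fa, ...)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    layout = {"trna.fa": refs.by_class("tRNA"),
              "mirna.fa": refs.by_class("miRNA"),
              "rrna.fa": refs.by_class("rRNA"),
              "mrna.fa": refs.by_class("mRNA"),
              "other.fa": refs.by_class("other_sRNA"),
              "genome.fa": refs.by_class("genome_decoy")}
    for fname, recs in layout.items():
        p = outdir / fname
        with open(p, "w") as fh:
            for name, seq in recs:
                fh.write(f">{name}\n{seq}\n")
        files[fname] = p
    return files
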