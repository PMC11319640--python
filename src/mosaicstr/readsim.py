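"""Stutter-aware simulation of raw sequencing reads around an STR.

Given a reference sequence and the coordinates of a target repeat
tract, this module enumerates the stuttered tract lengths each input
allele can produce, builds one haplotype sequence per (allele, stutter
variant), and draws reads (single- or paired-end) from those sequences
at rates proportional to haplotype fraction times stutter probability.
Reads carry uniform base-substitution errors and constant Q30 quality
strings; start positions are uniform within the configured window.
Output is FASTQ plus a truth table mapping every read to its source
allele and observed tract copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pyfaidx import Fasta

from .stutter import StutterParams, stutter_prob

__all__ = [
    "ReadSimConfig",
    "HaplotypeVariant",
    "build_haplotype_sequences",
    "simulate_reads",
    "write_fastq",
    "count_motif_copies",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_Q30 = "?"  # phred+33 symbol for Q30


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadSimConfig:
    """Configuration for stutter-aware read simulation at one STR locus.

    ``start``/``end`` delimit the repeat tract, 1-based inclusive.
    ``alleles`` lists (copy_number, haplotype_fraction) pairs whose
    fractions sum to 1. ``coverage`` is the target mean depth over the
    tract; ``window`` the flank (bp) on each side of the tract from
    which reads are drawn.
    """

    reference: str | Path
    chrom: str
    start: int
    end: int
    period: int
    motif: str
    alleles: Sequence[tuple[float, float]]
    theta: StutterParams
    coverage: int = 50
    read_length: int = 100
    paired: bool = False
    fragment_mean: float = 300.0
    fragment_sd: float = 30.0
    window: int = 500
    base_error_rate: float = 0.0
    seed: int = 0
    variant_floor: float = 1e-4

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        if self.window < self.read_length:
            raise ValueError("window must be >= read_length")
        if abs(sum(f for _, f in self.alleles) - 1.0) > 1e-9:
            raise ValueError("haplotype fractions must sum to 1")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if len(self.motif) != self.period:
            raise ValueError("motif length must equal period")


@dataclass(frozen=True)
class HaplotypeVariant:
    """One stutter variant of one input allele, with its full sequence."""

    source_allele: float
    observed_copies: float
    sequence: str
    proportion: float


def _tract_sequence(motif: str, copies: float) -> str:
    """Tract of ``copies`` motif units; fractional copies truncate in bp."""
    length_bp = int(round(copies * len(motif)))
    reps = -(-length_bp // len(motif))
    return (motif * reps)[:length_bp]


def build_haplotype_sequences(config: ReadSimConfig) -> list[HaplotypeVariant]:
    """Enumerate stuttered haplotype sequences with their proportions.

    For each input allele, stutter variants r with
    ``stutter_prob(r | allele) >= variant_floor`` are kept; each variant's
    raw weight is haplotype_fraction * stutter_prob, renormalized so all
    proportions sum to 1. The reference tract is replaced by the
    variant's tract; flanks of ``window`` bp are taken from the reference.
    """
    ref = Fasta(str(config.reference))
    if config.chrom not in ref:
        raise ValueError(f"chromosome {config.chrom!r} not in reference")
    chrom_seq = str(ref[config.chrom][:]).upper()
    t0, t1 = config.start - 1, config.end  # to 0-based half-open
    tract = chrom_seq[t0:t1]
    expected = _tract_sequence(config.motif.upper(), len(tract) / config.period)
    if tract != expected:
        raise ValueError(
            f"reference tract at {config.chrom}:{config.start}-{config.end} "
            f"does not match motif {config.motif!r}"
        )
    left = chrom_seq[max(0, t0 - config.window) : t0]
    right = chrom_seq[t1 : t1 + config.window]

    variants: list[HaplotypeVariant] = []
    for allele, frac in config.alleles:
        if frac <= 0:
            continue
        center = int(round(allele))
        offsets = range(-center, 200)  # r >= 0
        for off in offsets:
            r = center + off
            p = stutter_prob(float(r), float(allele), config.theta)
            if p < config.variant_floor:
                continue
            seq = left + _tract_sequence(config.motif.upper(), r) + right
            variants.append(HaplotypeVariant(allele, float(r), seq, frac * p))
    total = sum(v.proportion for v in variants)
    if total <= 0:
        raise ValueError("no haplotype variants above the proportion floor")
    return [
        HaplotypeVariant(v.source_allele, v.observed_copies, v.sequence, v.proportion / total)
        for v in variants
    ]


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    seq1: str
    seq2: str | None
    source_allele: float
    observed_copies: float
    variant_index: int = 0
    start: int = 0       # 0-based start of the read/fragment in its haplotype sequence
    frag_len: int = 0    # fragment length (== read length for single-end)


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(config: ReadSimConfig) -> tuple[list[SimulatedRead], list[HaplotypeVariant]]:
    """Draw reads from the stuttered haplotype sequences.

    The read count is chosen so the expected depth over the repeat tract
    matches ``config.coverage``. Each read (or fragment) picks a
    haplotype variant by its proportion, a uniform start position, and a
    strand with probability 1/2; base errors are applied uniformly.
    """
    rng = np.random.default_rng(config.seed)
    variants = build_haplotype_sequences(config)
    props = np.array([v.proportion for v in variants])
    L = config.read_length

    if config.paired and config.fragment_mean > min(len(v.sequence) for v in variants):
        raise ValueError("window too small for the configured fragment length")

    # expected depth at a tract base ~ n_units * L / n_start_positions
    mean_len = float(np.mean([len(v.sequence) for v in variants]))
    span = max(mean_len - L + 1.0, 1.0)
    per_unit = 2 if config.paired else 1
    n_frags = max(1, int(round(config.coverage * span / (L * per_unit))))

    reads: list[SimulatedRead] = []
    choices = rng.choice(len(variants), size=n_frags, p=props)
    for i, vi in enumerate(choices):
        v = variants[vi]
        seq = v.sequence
        if config.paired:
            flen = int(np.clip(rng.normal(config.fragment_mean, config.fragment_sd),
                               2 * L, len(seq)))
            start = rng.integers(0, len(seq) - flen + 1)
            frag = seq[start : start + flen]
            r1, r2 = frag[:L], _revcomp(frag[-L:])
            if rng.random() < 0.5:  # fragment orientation
                r1, r2 = r2, r1
            reads.append(SimulatedRead(
                f"sim_{i}", _apply_errors(r1, config.base_error_rate, rng),
                _apply_errors(r2, config.base_error_rate, rng),
                v.source_allele, v.observed_copies,
                variant_index=int(vi), start=int(start), frag_len=int(flen),
            ))
        else:
            start = rng.integers(0, len(seq) - L + 1)
            r1 = seq[start : start + L]
            if rng.random() < 0.5:
                r1 = _revcomp(r1)
            reads.append(SimulatedRead(
                f"sim_{i}", _apply_errors(r1, config.base_error_rate, rng), None,
                v.source_allele, v.observed_copies,
                variant_index=int(vi), start=int(start), frag_len=L,
            ))
    return reads, variants


def write_fastq(reads: list[SimulatedRead], prefix: str | Path, paired: bool) -> list[Path]:
    """Write reads to ``<prefix>.fastq`` or ``<prefix>_1/_2.fastq`` plus truth TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    if paired:
        p1, p2 = Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for r in reads:
                f1.write(f"@{r.name}/1\n{r.seq1}\n+\n{_Q30 * len(r.seq1)}\n")
                f2.write(f"@{r.name}/2\n{r.seq2}\n+\n{_Q30 * len(r.seq2)}\n")
        paths += [p1, p2]
    else:
        p = Path(f"{prefix}.fastq")
        with open(p, "w") as fh:
            for r in reads:
                fh.write(f"@{r.name}\n{r.seq1}\n+\n{_Q30 * len(r.seq1)}\n")
        paths.append(p)
    truth = Path(f"{prefix}.truth.tsv")
    with open(truth, "w") as fh:
        fh.write("read_id\tsource_allele\tobserved_copies\n")
        for r in reads:
            fh.write(f"{r.name}\t{r.source_allele}\t{r.observed_copies}\n")
    paths.append(truth)
    return paths


def count_motif_copies(seq: str, motif: str) -> int:
    """Length (in motif units) of the longest tandem run of ``motif`` in ``seq``."""
    seq = seq.upper()
    motif = motif.upper()
    best = run = 0
    i = 0
    while i <= len(seq) - len(motif):
        if seq[i : i + len(motif)] == motif:
            run += 1
            i += len(motif)
            best = max(best, run)
        else:
            run = 0
            i += 1
    return best
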