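"""Programmatic generation of small synthetic VCF fixtures.

Builds syntactically valid single- or multi-sample STR VCFs (GT, Q, DP,
MALLREADS FORMAT fields, INFO/PERIOD) with read vectors drawn from the
stutter-aware mixture simulator, so the VCF-driven pipeline can be
exercised end to end without external data. Deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .simulate import SimulationSpec, simulate_read_vector
from .stutter import StutterParams

__all__ = ["FixtureLocus", "make_fixture_vcf", "DEFAULT_MOTIFS"]

DEFAULT_MOTIFS = {1: "A", 2: "AC", 3: "ACG", 4: "ACGT", 5: "ACGTC", 6: "ACGTCA"}


@dataclass(frozen=True)
class FixtureLocus:
    """Specification for one synthetic VCF locus.

    ``mosaic`` optionally injects a mosaic allele (C, f) into the read
    mixture; ``mallreads_override`` bypasses simulation entirely (use for
    degenerate cases such as single-allele evidence).
    """

    chrom: str = "chr1"
    pos: int = 10000
    period: int = 3
    ref_copies: int = 10
    A: int = 10
    B: int = 12
    coverage: int = 50
    Q: float = 0.95
    theta: StutterParams = field(default_factory=lambda: StutterParams(0.005, 0.005, 0.9))
    mosaic: tuple[int, float] | None = None
    mallreads_override: str | None = None


def _mallreads_string(reads: np.ndarray, ref_copies: float, period: int) -> str:
    bp_diffs = np.rint((reads - ref_copies) * period).astype(int)
    vals, counts = np.unique(bp_diffs, return_counts=True)
    return ";".join(f"{v}|{c}" for v, c in zip(vals, counts))


def make_fixture_vcf(
    loci: Sequence[FixtureLocus],
    vcf_path: str | Path,
    sidecar_path: str | Path | None = None,
    seed: int = 0,
    samples: Sequence[str] = ("SAMPLE",),
) -> Path:
    """Write a synthetic STR VCF (and optional per-period stutter sidecar).

    Each locus/sample pair gets an independent simulated read vector
    honoring the locus's germline genotype, optional mosaic allele, and
    stutter model. Returns the VCF path.
    """
    vcf_path = Path(vcf_path)
    root = np.random.SeedSequence(seed)
    streams = iter(root.spawn(len(loci) * len(samples)))

    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=PERIOD,Number=1,Type=Integer,Description="Repeat unit length in bp">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=Q,Number=1,Type=Float,Description="Genotype quality in [0,1]">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=MALLREADS,Number=1,Type=String,'
        'Description="Semicolon-separated bpdiff|count read support">',
    ]
    chroms = []
    for lc in loci:
        if lc.chrom not in chroms:
            chroms.append(lc.chrom)
    for c in chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))

    for idx, lc in enumerate(sorted(loci, key=lambda l: (chroms.index(l.chrom), l.pos))):
        motif = DEFAULT_MOTIFS.get(lc.period, "A" * lc.period)
        copies = [lc.ref_copies]
        for g in (lc.A, lc.B):
            if g not in copies:
                copies.append(g)
        ref_seq = motif * lc.ref_copies
        alts = [motif * c for c in copies[1:]]
        gt_idx = {c: i for i, c in enumerate(copies)}
        fmt_cols = []
        for _s in samples:
            stream = next(streams)
            if lc.mallreads_override is not None:
                mall = lc.mallreads_override
                dp = sum(int(tok.split("|")[1]) for tok in mall.split(";")) if mall not in (".", "") else 0
            else:
                spec = SimulationSpec(
                    A=float(lc.A),
                    B=float(lc.B),
                    coverage=lc.coverage,
                    theta=lc.theta,
                    mosaic_alleles=[(float(lc.mosaic[0]), lc.mosaic[1])] if lc.mosaic else [],
                    seed=int(stream.generate_state(1)[0] % (2**31)),
                )
                reads = simulate_read_vector(spec, np.random.default_rng(stream))
                mall = _mallreads_string(reads, lc.ref_copies, lc.period)
                dp = reads.size
            fmt_cols.append(f"{gt_idx[lc.A]}/{gt_idx[lc.B]}:{lc.Q:.3f}:{dp}:{mall}")
        lines.append(
            f"{lc.chrom}\t{lc.pos}\tSTR_{idx}\t{ref_seq}\t{','.join(alts) or '.'}\t.\tPASS\t"
            f"PERIOD={lc.period}\tGT:Q:DP:MALLREADS\t" + "\t".join(fmt_cols)
        )

    vcf_path.parent.mkdir(parents=True, exist_ok=True)
    vcf_path.write_text("\n".join(lines) + "\n")

    if sidecar_path is not None:
        thetas: dict[int, StutterParams] = {}
        for lc in loci:
            thetas.setdefault(lc.period, lc.theta)
        with open(sidecar_path, "w") as fh:
            fh.write("period\tu\td\trho\n")
            for period, th in sorted(thetas.items()):
                fh.write(f"{period}\t{th.u}\t{th.d}\t{th.rho}\n")
    return vcf_path
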