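"""Reading STR genotyper VCFs and running per-sample mosaicism inference.

The expected input is the VCF output of a short-tandem-repeat genotyper
that reports, per sample, the diploid genotype (GT), a genotype quality
in [0, 1] (Q), read depth (DP), and a per-allele read-support string
(MALLREADS) listing ``bpdiff|count`` pairs relative to the reference
allele. Allele copy numbers are derived from REF/ALT sequence lengths
divided by the repeat period, so fractional copy numbers are possible
at impure repeats.

Stutter error parameters come from a tab-delimited sidecar, either one
row per locus (chrom, pos, end, period, u, d, rho) or one row per
repeat-unit length (period, u, d, rho) applied genome-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import pysam

from .inference import LocusReadData, estimate_mosaicism
from .stutter import StutterParams

__all__ = [
    "StrCall",
    "parse_mallreads",
    "exclude_call",
    "StutterCatalog",
    "load_stutter_sidecar",
    "run_sample",
    "run_vcf",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "chrom",
    "pos",
    "sample",
    "A",
    "B",
    "C_hat",
    "f_hat",
    "mosaic_support",
    "depth",
    "Q",
    "lambda_lr",
    "pvalue",
    "converged",
    "haplotype_case",
]

_COPY_TOL = 1e-6


@dataclass(frozen=True)
class StrCall:
    """One sample's call at one STR locus, parsed from a VCF record."""

    chrom: str
    pos: int  # 1-based, VCF convention
    period: int
    ref_copies: float
    sample: str
    A: float
    B: float
    Q: float
    depth: int
    mallreads: str
    theta: StutterParams | None = None


def parse_mallreads(mallreads: str | None, ref_copies: float, period: int) -> np.ndarray:
    """Expand a MALLREADS string into a vector of per-read copy numbers.

    Each ``bpdiff|count`` token contributes ``count`` reads at
    ``ref_copies + bpdiff / period`` copies. Empty or missing ("." )
    strings give an empty vector; a malformed token raises ValueError.
    """
    if mallreads is None or mallreads in ("", "."):
        return np.empty(0)
    reads: list[float] = []
    for token in mallreads.split(";"):
        try:
            bp_diff_s, count_s = token.split("|")
            bp_diff = int(bp_diff_s)
            count = int(count_s)
        except ValueError as exc:
            raise ValueError(f"malformed MALLREADS token {token!r}") from exc
        if count < 0:
            raise ValueError(f"negative read count in MALLREADS token {token!r}")
        reads.extend([ref_copies + bp_diff / period] * count)
    return np.asarray(reads, dtype=float)


def exclude_call(call: StrCall) -> tuple[bool, str]:
    """Decide whether a call enters mosaicism testing.

    Returns ``(keep, reason)``. Calls are dropped when they have no read
    support at all, a missing genotype, no read support for either
    called germline allele, or read evidence from only a single allele
    (mosaicism is untestable without a second observed allele).
    """
    reads = parse_mallreads(call.mallreads, call.ref_copies, call.period)
    if reads.size == 0:
        return False, "no_coverage"
    if not (np.isfinite(call.A) and np.isfinite(call.B)):
        return False, "missing_genotype"
    has_a = bool(np.any(np.abs(reads - call.A) < _COPY_TOL))
    has_b = bool(np.any(np.abs(reads - call.B) < _COPY_TOL))
    if not has_a and not has_b:
        return False, "no_genotype_support"
    if np.unique(np.round(reads / _COPY_TOL) * _COPY_TOL).size < 2:
        return False, "single_allele_evidence"
    return True, "ok"


class StutterCatalog:
    """Resolves stutter parameters per locus, per period, or both.

    Locus-specific rows take precedence over per-period rows; a default
    model (if configured) backstops both.
    """

    def __init__(
        self,
        per_locus: dict[tuple[str, int], StutterParams] | None = None,
        per_period: dict[int, StutterParams] | None = None,
        default: StutterParams | None = None,
    ):
        self.per_locus = per_locus or {}
        self.per_period = per_period or {}
        self.default = default

    def resolve(self, chrom: str, pos: int, period: int) -> StutterParams | None:
        hit = self.per_locus.get((chrom, pos))
        if hit is not None:
            return hit
        hit = self.per_period.get(period)
        if hit is not None:
            return hit
        return self.default


def load_stutter_sidecar(path, default: StutterParams | None = None) -> StutterCatalog:
    """Load the tab-delimited stutter sidecar (see module docstring)."""
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if {"chrom", "pos", "period", "u", "d", "rho"} <= cols:
        per_locus = {
            (str(row.chrom), int(row.pos)): StutterParams(
                u=float(row.u), d=float(row.d), rho=float(row.rho), period=int(row.period)
            )
            for row in df.itertuples()
        }
        return StutterCatalog(per_locus=per_locus, default=default)
    if {"period", "u", "d", "rho"} <= cols:
        per_period = {
            int(row.period): StutterParams(
                u=float(row.u), d=float(row.d), rho=float(row.rho), period=int(row.period)
            )
            for row in df.itertuples()
        }
        return StutterCatalog(per_period=per_period, default=default)
    raise ValueError(
        "stutter sidecar must have columns (chrom, pos, end, period, u, d, rho) "
        f"or (period, u, d, rho); got {sorted(cols)}"
    )


def _record_calls(
    rec: pysam.VariantRecord, samples: Sequence[str], catalog: StutterCatalog
) -> Iterator[StrCall]:
    period = rec.info.get("PERIOD")
    if period is None:
        raise ValueError(f"record {rec.chrom}:{rec.pos} lacks INFO/PERIOD")
    period = int(period)
    ref_copies = len(rec.ref) / period
    allele_copies = [len(a) / period if a not in (None, "*") else np.nan for a in rec.alleles]
    for name in samples:
        fmt = rec.samples[name]
        gt = fmt.get("GT")
        if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
            a = b = np.nan
        else:
            a, b = allele_copies[gt[0]], allele_copies[gt[1]]
        q = fmt.get("Q")
        dp = fmt.get("DP")
        mall = fmt.get("MALLREADS")
        yield StrCall(
            chrom=rec.chrom,
            pos=rec.pos,
            period=period,
            ref_copies=ref_copies,
            sample=name,
            A=float(a) if a is not None else np.nan,
            B=float(b) if b is not None else np.nan,
            Q=float(q) if q is not None else np.nan,
            depth=int(dp) if dp is not None else 0,
            mallreads=mall if mall is not None else ".",
            theta=catalog.resolve(rec.chrom, rec.pos, period),
        )


def run_vcf(
    vcf_path,
    catalog: StutterCatalog,
    samples: Sequence[str] | None = None,
    region: str | None = None,
    only_passing: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run mosaicism inference over all (locus, sample) pairs of a VCF.

    Returns ``(results, skipped)``: one result row per retained call
    (columns ``RESULT_COLUMNS``) and one skip row per excluded call with
    its reason code. Every input call appears in exactly one of the two.
    """
    required = {"GT", "Q", "DP", "MALLREADS"}
    rows: list[dict] = []
    skips: list[dict] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        missing = required - set(vcf.header.formats.keys())
        if missing:
            raise ValueError(f"VCF lacks required FORMAT fields: {sorted(missing)}")
        use_samples = list(samples) if samples else list(vcf.header.samples)
        unknown = set(use_samples) - set(vcf.header.samples)
        if unknown:
            raise ValueError(f"samples not in VCF: {sorted(unknown)}")
        records = vcf.fetch(region=region) if region else vcf
        for rec in records:
            if only_passing and rec.filter.keys() not in ([], ["PASS"]):
                for name in use_samples:
                    skips.append(
                        {"chrom": rec.chrom, "pos": rec.pos, "sample": name,
                         "reason": "upstream_filtered"}
                    )
                continue
            for call in _record_calls(rec, use_samples, catalog):
                if call.theta is None:
                    logger.warning(
                        "no stutter model for %s:%d (period %d); skipped",
                        call.chrom, call.pos, call.period,
                    )
                    skips.append(
                        {"chrom": call.chrom, "pos": call.pos, "sample": call.sample,
                         "reason": "no_stutter_model"}
                    )
                    continue
                try:
                    keep, reason = exclude_call(call)
                except ValueError as exc:
                    logger.warning("%s:%d %s: %s", call.chrom, call.pos, call.sample, exc)
                    keep, reason = False, "parse_error"
                if not keep:
                    skips.append(
                        {"chrom": call.chrom, "pos": call.pos, "sample": call.sample,
                         "reason": reason}
                    )
                    continue
                reads = parse_mallreads(call.mallreads, call.ref_copies, call.period)
                data = LocusReadData(A=call.A, B=call.B, reads=reads, theta=call.theta)
                est = estimate_mosaicism(data)
                rows.append(
                    {
                        "chrom": call.chrom,
                        "pos": call.pos,
                        "sample": call.sample,
                        "A": call.A,
                        "B": call.B,
                        "C_hat": est.C_hat,
                        "f_hat": est.f_hat,
                        "mosaic_support": est.mosaic_support,
                        "depth": call.depth,
                        "Q": call.Q,
                        "lambda_lr": est.lambda_lr,
                        "pvalue": est.pvalue,
                        "converged": est.converged,
                        "haplotype_case": est.haplotype_case,
                    }
                )
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    skipped = pd.DataFrame(skips, columns=["chrom", "pos", "sample", "reason"])
    return results, skipped


def run_sample(
    vcf_path,
    catalog: StutterCatalog,
    sample: str,
    region: str | None = None,
    only_passing: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-sample convenience wrapper around :func:`run_vcf`."""
    return run_vcf(
        vcf_path, catalog, samples=[sample], region=region, only_passing=only_passing
    )
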