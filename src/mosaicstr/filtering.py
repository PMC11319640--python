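"""Post-hoc candidate filters and multiple-testing correction.

Candidate mosaic calls from the per-locus test are screened with
Benjamini-Hochberg FDR adjustment plus hard thresholds on mosaic read
support, depth, mosaic fraction and genotype quality; loci recurrently
called across many cohort samples or falling in user-supplied excluded
regions (e.g. hard-to-map tracks) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterThresholds",
    "bh_adjust",
    "apply_candidate_filters",
    "recurrence_filter",
    "region_filter",
    "read_bed",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Hard thresholds for candidate mosaic calls (boundaries inclusive)."""

    min_support: int = 3      # reads supporting the mosaic allele
    min_depth: int = 10
    max_f: float = 0.3        # larger f indicates a likely heterozygous site
    min_quality: float = 0.8
    max_adjusted_p: float = 0.05  # strict: adjusted p must be < this


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def apply_candidate_filters(
    records: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Flag each call against the candidate thresholds.

    Expects columns ``mosaic_support``, ``depth``, ``f_hat``, ``Q`` and
    ``adjusted_pvalue`` (the latter is added from ``pvalue`` via
    :func:`bh_adjust` if absent). Adds one boolean ``fail_*`` column per
    criterion, a ``filter_flags`` summary string and a ``pass_filters``
    column true iff every criterion passes.
    """
    th = thresholds or FilterThresholds()
    out = records.copy()
    if "adjusted_pvalue" not in out.columns:
        out["adjusted_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
    checks = {
        "low_mosaic_support": out["mosaic_support"] < th.min_support,
        "low_depth": out["depth"] < th.min_depth,
        "high_f": out["f_hat"] > th.max_f,
        "low_quality": out["Q"] < th.min_quality,
        "high_adjusted_p": out["adjusted_pvalue"] >= th.max_adjusted_p,
    }
    flags = pd.Series([""] * len(out), index=out.index, dtype=object)
    for name, failed in checks.items():
        out[f"fail_{name}"] = failed.to_numpy()
        flags = flags.where(~failed, flags + np.where(flags != "", ";", "") + name)
    out["filter_flags"] = flags.replace("", "PASS")
    out["pass_filters"] = ~np.logical_or.reduce([c.to_numpy() for c in checks.values()])
    return out


def recurrence_filter(records: pd.DataFrame, max_samples: int = 10) -> pd.DataFrame:
    """Flag loci called as mosaic in more than ``max_samples`` cohort samples.

    Recurrence counts passing calls per (chrom, pos) locus across
    distinct samples; a locus exceeding the cap has all its records
    flagged ``recurrent`` and demoted from passing.
    """
    out = records.copy()
    passing = out[out.get("pass_filters", True) == True]  # noqa: E712
    counts = passing.groupby(["chrom", "pos"])["sample"].nunique()
    out["recurrence_count"] = [
        int(counts.get((c, p), 0)) for c, p in zip(out["chrom"], out["pos"])
    ]
    recurrent = out["recurrence_count"] > max_samples
    out["fail_recurrent"] = recurrent.to_numpy()
    if "filter_flags" in out.columns:
        out.loc[recurrent, "filter_flags"] = out.loc[recurrent, "filter_flags"].where(
            out.loc[recurrent, "filter_flags"] != "PASS", ""
        )
        nonempty = recurrent & (out["filter_flags"] != "")
        out.loc[nonempty, "filter_flags"] = out.loc[nonempty, "filter_flags"] + ";recurrent"
        out.loc[recurrent & (out["filter_flags"] == ""), "filter_flags"] = "recurrent"
    if "pass_filters" in out.columns:
        out.loc[recurrent, "pass_filters"] = False
    return out


def read_bed(path) -> list[tuple[str, int, int]]:
    """Parse a BED file into (chrom, start, end) 0-based half-open intervals."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {line!r}") from exc
            intervals.append((parts[0], start, end))
    return intervals


def region_filter(
    records: pd.DataFrame, bed_intervals: list[tuple[str, int, int]]
) -> pd.DataFrame:
    """Flag records whose locus falls inside an excluded region.

    Record positions are 1-based (VCF convention); BED intervals are
    0-based half-open, so position ``pos`` intersects ``[start, end)``
    iff ``start <= pos - 1 < end``.
    """
    out = records.copy()
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in bed_intervals:
        by_chrom.setdefault(chrom, []).append((start, end))
    hit = np.zeros(len(out), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(out["chrom"], out["pos"])):
        p0 = int(pos) - 1
        hit[i] = any(s <= p0 < e for s, e in by_chrom.get(str(chrom), ()))
    out["fail_excluded_region"] = hit
    if "filter_flags" in out.columns:
        cur = out.loc[hit, "filter_flags"].replace("PASS", "")
        out.loc[hit, "filter_flags"] = np.where(
            cur == "", "excluded_region", cur + ";excluded_region"
        )
    if "pass_filters" in out.columns:
        out.loc[hit, "pass_filters"] = False
    return out
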