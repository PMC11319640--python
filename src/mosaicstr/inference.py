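"""Per-locus maximum-likelihood inference of STR somatic mosaicism.

A locus in one sample is summarized by the diploid germline genotype
<A, B> (repeat copy numbers) and the vector R of per-read observed copy
numbers. If a fraction ``f`` of chromosome copies carries a mosaic
allele ``C`` that arose on the haplotype bearing B, each read is a draw
from the mixture

    1/2 * S(r|A) + (1/2 - f) * S(r|B) + f * S(r|C)

with ``S`` the stutter error model. Since short reads cannot reveal the
haplotype of origin, the likelihood is maximized over both cases
(mosaic on A's haplotype or on B's). The estimator alternates an
exhaustive scan over candidate integer-spaced C with a bounded scalar
maximization of f in [0, 0.5], then tests H0: f = 0 with a likelihood
ratio statistic. Because f = 0 lies on the parameter boundary, the null
distribution is a 50:50 mixture of a point mass at zero and chi-square
with 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .stutter import StutterParams, stutter_prob

__all__ = [
    "LocusReadData",
    "MosaicEstimate",
    "log_likelihood_case",
    "log_likelihood",
    "estimate_mosaicism",
    "mixture_null_pvalue",
]

# Per-read mixture probabilities are floored before taking logs so a
# misspecified stutter model cannot produce -inf log-likelihoods.
_PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class LocusReadData:
    """Germline genotype plus per-read repeat copy numbers for one locus.

    ``A`` and ``B`` are the two germline allele copy numbers (equal when
    homozygous); ``reads`` holds one observed copy number per spanning
    read; ``theta`` is the stutter model resolved for this locus.
    """

    A: float
    B: float
    reads: Sequence[float]
    theta: StutterParams

    def __post_init__(self) -> None:
        r = np.asarray(self.reads, dtype=float)
        if r.size < 1:
            raise ValueError("read vector must contain at least one read")
        if not (np.isfinite(self.A) and np.isfinite(self.B)):
            raise ValueError("germline alleles must be finite")
        object.__setattr__(self, "reads", r)

    @property
    def n(self) -> int:
        return int(np.asarray(self.reads).size)


@dataclass(frozen=True)
class MosaicEstimate:
    """Result of mosaicism inference at one locus in one sample."""

    C_hat: float
    f_hat: float
    loglik: float
    lambda_lr: float
    pvalue: float
    n_iter: int
    haplotype_case: str  # which germline allele's haplotype carries the mosaic
    converged: bool = True
    mosaic_support: int = 0  # reads exactly matching C_hat

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_hat <= 0.5):
            raise ValueError(f"f_hat out of [0, 0.5]: {self.f_hat}")
        if self.lambda_lr < 0:
            raise ValueError(f"lambda_lr must be >= 0: {self.lambda_lr}")


class _LocusWorkspace:
    """Compressed read vector with cached stutter probabilities.

    Reads are collapsed to unique values with counts; S(r|A) and S(r|B)
    are computed once, S(r|C) on demand per candidate C. All likelihood
    evaluations below run on this compressed representation.
    """

    def __init__(self, data: LocusReadData):
        self.vals, self.counts = np.unique(np.asarray(data.reads, dtype=float), return_counts=True)
        self.counts = self.counts.astype(float)
        self.theta = data.theta
        self.A = float(data.A)
        self.B = float(data.B)
        self.sA = np.asarray(stutter_prob(self.vals, self.A, self.theta))
        self.sB = np.asarray(stutter_prob(self.vals, self.B, self.theta))
        self._sC_cache: dict[float, np.ndarray] = {}

    def sC(self, C: float) -> np.ndarray:
        got = self._sC_cache.get(C)
        if got is None:
            got = np.asarray(stutter_prob(self.vals, C, self.theta))
            self._sC_cache[C] = got
        return got

    def loglik_case(self, C: float, f: float, mutated_allele: str) -> float:
        if mutated_allele == "B":
            mix = 0.5 * self.sA + (0.5 - f) * self.sB + f * self.sC(C)
        else:
            mix = 0.5 * self.sB + (0.5 - f) * self.sA + f * self.sC(C)
        return float(np.dot(self.counts, np.log(np.maximum(mix, _PROB_FLOOR))))

    def loglik(self, C: float, f: float) -> tuple[float, str]:
        la = self.loglik_case(C, f, "A")
        lb = self.loglik_case(C, f, "B")
        # ties resolve to B for determinism
        return (la, "A") if la > lb else (lb, "B")

    def candidate_C(self, margin: int) -> np.ndarray:
        """Integer-spaced lattice anchored on observed reads, excluding A and B."""
        lo = int(np.floor(self.vals.min())) - margin
        hi = int(np.ceil(self.vals.max())) + margin
        anchored = np.unique(np.concatenate([self.vals, np.arange(lo, hi + 1, dtype=float)]))
        keep = (anchored >= lo) & (anchored <= hi)
        anchored = anchored[keep]
        return anchored[(anchored != self.A) & (anchored != self.B)]


def log_likelihood_case(
    data: LocusReadData, C: float, f: float, mutated_allele: str = "B"
) -> float:
    """Mixture log-likelihood for one haplotype-of-origin case.

    With ``mutated_allele="B"`` the mosaic allele replaces part of B's
    haplotype, so reads come from A with weight 1/2, B with 1/2 - f and
    C with f; the roles of A and B swap for ``mutated_allele="A"``.
    """
    if mutated_allele not in ("A", "B"):
        raise ValueError("mutated_allele must be 'A' or 'B'")
    if not (0.0 <= f <= 0.5):
        raise ValueError(f"f out of [0, 0.5]: {f}")
    return _LocusWorkspace(data).loglik_case(float(C), float(f), mutated_allele)


def log_likelihood(data: LocusReadData, C: float, f: float) -> tuple[float, str]:
    """Maximum of the two haplotype-case log-likelihoods.

    Returns ``(loglik, case)`` where ``case`` names the germline allele
    whose haplotype hosts the mosaic in the winning branch (ties go to B).
    """
    if not (0.0 <= f <= 0.5):
        raise ValueError(f"f out of [0, 0.5]: {f}")
    return _LocusWorkspace(data).loglik(float(C), float(f))


def mixture_null_pvalue(lambda_lr: float) -> float:
    """P-value of the LRT statistic under the boundary-corrected null.

    The null distribution is a 50:50 mixture of a point mass at 0 and a
    chi-square distribution with 2 degrees of freedom, accounting for
    f = 0 lying on the boundary of the parameter space. Returns 1 when
    the statistic is 0 (the point-mass component), else
    0.5 * Pr(chi2_2 >= lambda).
    """
    if lambda_lr < -1e-8:
        raise ValueError(f"negative LRT statistic: {lambda_lr}")
    lam = max(float(lambda_lr), 0.0)
    if lam == 0.0:
        return 1.0
    return max(float(0.5 * chi2.sf(lam, df=2)), np.nextafter(0, 1))


def _best_f(ws: _LocusWorkspace, C: float, case: str) -> tuple[float, float]:
    """Bounded scalar maximization of f in [0, 0.5] at fixed C and case."""
    res = minimize_scalar(
        lambda f: -ws.loglik_case(C, f, case),
        bounds=(0.0, 0.5),
        method="bounded",
        options={"xatol": 1e-6},
    )
    f_star = float(np.clip(res.x, 0.0, 0.5))
    ll_star = -float(res.fun)
    # the bounded minimizer avoids the exact endpoints; check them
    for f_edge in (0.0, 0.5):
        ll_edge = ws.loglik_case(C, f_edge, case)
        if ll_edge > ll_star:
            f_star, ll_star = f_edge, ll_edge
    return f_star, ll_star


def _scan_C(ws: _LocusWorkspace, candidates: np.ndarray, f: float) -> tuple[float, float, str]:
    """Exhaustive scan over candidate C at fixed f; deterministic tie-break.

    Ties on log-likelihood (within 1e-12) resolve to the candidate
    closest to a germline allele, then to the smaller C.
    """
    best = None
    for C in candidates:
        ll, case = ws.loglik(float(C), f)
        key = (
            -ll,
            min(abs(C - ws.A), abs(C - ws.B)),
            C,
        )
        if best is None or key < best[0]:
            best = (key, float(C), ll, case)
    assert best is not None
    return best[1], best[2], best[3]


def estimate_mosaicism(
    data: LocusReadData,
    f_init: float = 0.01,
    c_margin: int = 3,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> MosaicEstimate:
    """Iterative maximum-likelihood estimation of the mosaic allele and fraction.

    Alternates (i) an exhaustive scan of integer-spaced candidate C over
    [min(R) - c_margin, max(R) + c_margin], excluding the germline
    alleles, at the current f; and (ii) bounded maximization of f in
    [0, 0.5] at the current C; until the log-likelihood improves by less
    than ``tol`` or ``max_iter`` is reached. A final polish sweep
    optimizes f for every candidate C and keeps the argmax, so
    coordinate descent cannot terminate at a joint local optimum.

    The likelihood-ratio statistic compares the constrained (f = 0) and
    unconstrained fits at the same C_hat, and the p-value uses the
    boundary-corrected 50:50 point-mass/chi-square(2) null.
    """
    ws = _LocusWorkspace(data)
    candidates = ws.candidate_C(c_margin)

    if candidates.size == 0:
        # degenerate: every lattice point is a germline allele (cannot happen
        # with margin >= 1, but guard anyway)
        ll0, case = ws.loglik(ws.A + 1.0, 0.0)
        return MosaicEstimate(ws.A + 1.0, 0.0, ll0, 0.0, 1.0, 0, case)

    f = float(f_init)
    C, ll, case = _scan_C(ws, candidates, f)
    prev_ll = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        C, ll, case = _scan_C(ws, candidates, f)
        f, ll = _best_f(ws, C, case)
        # the other haplotype case may now win at the refined f
        ll, case = ws.loglik(C, f)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll

    # polish: globally best (C, f) over the candidate lattice
    best_C, best_f, best_ll, best_case = C, f, ll, case
    for Cc in candidates:
        for cs in ("A", "B"):
            f_c, ll_c = _best_f(ws, float(Cc), cs)
            if ll_c > best_ll + 1e-12:
                best_C, best_f, best_ll, best_case = float(Cc), f_c, ll_c, cs
    C, f, ll, case = best_C, best_f, best_ll, best_case

    ll_null, _ = ws.loglik(C, 0.0)
    lam = -2.0 * (ll_null - ll)
    lam = max(lam, 0.0)  # clamp tiny negatives from numerics
    pval = mixture_null_pvalue(lam)
    support = int(np.sum(ws.counts[ws.vals == C]))
    return MosaicEstimate(
        C_hat=C,
        f_hat=f,
        loglik=ll,
        lambda_lr=lam,
        pvalue=pval,
        n_iter=n_iter,
        haplotype_case=case,
        converged=converged,
        mosaic_support=support,
    )
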