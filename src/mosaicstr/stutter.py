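"""PCR/sequencing stutter error model for short tandem repeats.

Stutter errors add or remove whole repeat units from the repeat tract
observed in a read. The model used throughout this package has three
parameters: ``u``, the per-read probability of an expansion error;
``d``, the per-read probability of a contraction error; and ``rho``,
the parameter of the geometric distribution governing the error step
size in repeat units. A read drawn from a true allele with ``G`` copies
therefore shows ``r`` copies with probability

    S(r | G) = 1 - u - d                     if r == G
             = u * rho * (1 - rho)^(r-G-1)   if r > G
             = d * rho * (1 - rho)^(G-r-1)   if r < G

This module provides the probability mass function, a sampler, and an
estimator of (u, d, rho) from confidently homozygous calls, where every
read not matching the called allele is attributed to stutter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StutterParams",
    "stutter_prob",
    "sample_read",
    "fit_stutter_params",
    "PCR_FREE",
    "PCR_PLUS",
]

# Floor used for rho when a fitted dataset contains no error reads at all:
# typical of low-error PCR-free libraries, where nearly all observed errors
# are single-unit steps.
RHO_FLOOR = 0.9


@dataclass(frozen=True)
class StutterParams:
    """Per-locus (or per-period) stutter error model parameters.

    Parameters
    ----------
    u : float
        Probability that a read carries a stutter expansion, in [0, 1).
    d : float
        Probability that a read carries a stutter contraction, in [0, 1).
    rho : float
        Geometric step-size parameter, in (0, 1]. ``rho = 1`` forces all
        stutter steps to be exactly one repeat unit.
    period : int
        Repeat-unit length in bp; used by I/O code for bp <-> copy-number
        conversion, not by the model itself.
    rho_floored : bool
        Set by :func:`fit_stutter_params` when no error reads were
        available and ``rho`` was set to the configured floor.
    """

    u: float
    d: float
    rho: float
    period: int = 1
    rho_floored: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.u < 0 or self.d < 0:
            raise ValueError(f"stutter probabilities must be >= 0 (u={self.u}, d={self.d})")
        if self.u + self.d >= 1:
            raise ValueError(f"u + d must be < 1 (got {self.u + self.d})")
        if not (0 < self.rho <= 1):
            raise ValueError(f"rho must be in (0, 1] (got {self.rho})")
        if self.period < 1:
            raise ValueError(f"period must be >= 1 bp (got {self.period})")


# Presets matching typical stutter-read fractions of PCR-free (~1% of
# reads) and PCR+ (~10% of reads) short-read libraries. These are
# defaults for simulation scenarios, not fitted constants.
PCR_FREE = StutterParams(u=0.005, d=0.005, rho=0.9)
PCR_PLUS = StutterParams(u=0.05, d=0.05, rho=0.8)


def _step_exponent(delta: np.ndarray) -> np.ndarray:
    """Geometric exponent for a (possibly fractional) step size.

    The model is defined on integer unit steps; impure repeats can yield
    fractional copy-number differences, which are rounded to the nearest
    integer step of at least 1.
    """
    return np.maximum(np.rint(np.abs(delta)), 1.0)


def stutter_prob(r, G: float, theta: StutterParams):
    """Probability of observing ``r`` repeat copies in a read from allele ``G``.

    Vectorized over ``r``. Scalar input returns a scalar.
    """
    r_arr = np.asarray(r, dtype=float)
    delta = r_arr - G
    match = delta == 0
    up = delta > 0
    k = _step_exponent(delta)
    tail = np.where(up, theta.u, theta.d) * theta.rho * (1.0 - theta.rho) ** (k - 1.0)
    out = np.where(match, 1.0 - theta.u - theta.d, tail)
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(out)
    return out


def sample_read(G: float, theta: StutterParams, rng: np.random.Generator, size: int | None = None):
    """Draw observed repeat copy numbers for reads from a true allele ``G``.

    With probability ``1 - u - d`` the read matches ``G``; with
    probability ``u`` (``d``) it gains (loses) ``k`` repeat units where
    ``k ~ Geometric(rho)`` on {1, 2, ...}. Draws landing below zero copy
    number are redrawn (physically impossible reads; negligible
    probability at realistic allele lengths).

    Returns a scalar when ``size`` is None, else an ndarray of length ``size``.
    """
    n = 1 if size is None else int(size)
    out = np.empty(n, dtype=float)
    todo = np.arange(n)
    while todo.size:
        uu = rng.random(todo.size)
        steps = rng.geometric(theta.rho, size=todo.size).astype(float)
        r = np.full(todo.size, float(G))
        r = np.where(uu < theta.u, G + steps, r)
        r = np.where((uu >= theta.u) & (uu < theta.u + theta.d), G - steps, r)
        out[todo] = r
        todo = todo[out[todo] < 0]
    if size is None:
        return float(out[0])
    return out


def fit_stutter_params(
    homozygous_calls: Iterable[tuple[float, Sequence[float]]],
    period: int = 1,
    max_step: int = 10,
    rho_floor: float = RHO_FLOOR,
) -> StutterParams:
    """Estimate (u, d, rho) from confidently homozygous STR calls.

    Every read at a homozygous locus that does not match the called
    allele is attributed to stutter error. Then

    * ``u`` = insertion reads / total reads,
    * ``d`` = deletion reads / total reads,
    * ``rho`` = fraction of error reads with a step size of exactly one
      repeat unit, after excluding error reads with extreme step sizes
      (``|step| > max_step``, unlikely to be stutter). The exclusion
      applies to the ``rho`` estimate only; ``u`` and ``d`` count all
      reads.

    Callers are responsible for selecting confident homozygous input
    (e.g. genotype quality > 0.9 and depth > 10).

    Parameters
    ----------
    homozygous_calls : iterable of (called_allele, read_vector)
        Read vectors in repeat-copy-number units on the same scale as
        the called allele.
    period : int
        Repeat-unit length the fitted model applies to.
    max_step : int
        Largest |step| (in repeat units) retained when estimating rho.
    rho_floor : float
        Value assigned to rho when no error reads are observed; the
        result is flagged via ``rho_floored``.
    """
    n_total = 0
    n_ins = 0
    n_del = 0
    n_step1 = 0
    n_rho_denom = 0
    for g, reads in homozygous_calls:
        reads = np.asarray(list(reads), dtype=float)
        if reads.size == 0:
            continue
        delta = reads - float(g)
        n_total += reads.size
        n_ins += int(np.sum(delta > 0))
        n_del += int(np.sum(delta < 0))
        err = delta[delta != 0]
        steps = _step_exponent(err)
        kept = steps[steps <= max_step]
        n_rho_denom += kept.size
        n_step1 += int(np.sum(kept == 1))
    if n_total == 0:
        raise ValueError("no reads supplied to fit_stutter_params")
    u = n_ins / n_total
    d = n_del / n_total
    if n_rho_denom == 0:
        return StutterParams(u=u, d=d, rho=rho_floor, period=period, rho_floored=True)
    return StutterParams(u=u, d=d, rho=n_step1 / n_rho_denom, period=period)
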