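"""Read-count-vector simulation and power / type-I-error estimation.

Each simulated read first draws its true source allele from the
categorical distribution {A: 1/2, B: 1/2 - sum(f_i), C_i: f_i} over the
two germline alleles and k >= 0 mosaic alleles, then passes through the
stutter error model to produce an observed repeat copy number. Power at
a setting is the fraction of simulation rounds whose mosaicism test
returns p below the significance threshold; with no mosaic alleles the
same fraction estimates the false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import LocusReadData, MosaicEstimate, estimate_mosaicism
from .stutter import StutterParams

__all__ = ["SimulationSpec", "simulate_read_vector", "estimate_power", "power_grid"]


@dataclass(frozen=True)
class SimulationSpec:
    """One simulation setting for read-count-vector generation.

    ``mosaic_alleles`` lists (C_i, f_i) pairs; allele B's frequency is
    0.5 - sum(f_i) so all frequencies sum to 1. ``n_reps`` simulation
    rounds are run, each producing ``coverage`` reads.
    """

    A: float
    B: float
    coverage: int
    theta: StutterParams
    mosaic_alleles: Sequence[tuple[float, float]] = field(default_factory=tuple)
    n_reps: int = 200
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "mosaic_alleles", tuple(self.mosaic_alleles))
        total_f = sum(f for _, f in self.mosaic_alleles)
        if any(f < 0 for _, f in self.mosaic_alleles):
            raise ValueError("mosaic fractions must be >= 0")
        if total_f > 0.5 + 1e-12:
            raise ValueError(f"sum of mosaic fractions must be <= 0.5 (got {total_f})")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def _geometric_from_uniform(w: np.ndarray, rho: float) -> np.ndarray:
    """Inverse-CDF Geometric(rho) on {1, 2, ...} from uniforms in [0, 1)."""
    if rho >= 1.0:
        return np.ones_like(w)
    k = np.ceil(np.log1p(-w) / np.log1p(-rho))
    return np.maximum(k, 1.0)


def simulate_read_vector(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one read-count vector of length ``spec.coverage``.

    Sampling is inverse-CDF throughout, consuming exactly three uniforms
    per read (source allele, error type, error step). Consequently, for
    a fixed generator state, read vectors at lower coverage are prefixes
    of those at higher coverage, and raising a mosaic fraction converts
    germline-B reads into mosaic reads read-by-read — useful for
    variance reduction when comparing settings under a common seed.
    """
    total_f = sum(f for _, f in spec.mosaic_alleles)
    alleles = np.array([spec.A, spec.B] + [c for c, _ in spec.mosaic_alleles])
    cum = np.cumsum([0.5, 0.5 - total_f] + [f for _, f in spec.mosaic_alleles])
    u3 = rng.random((spec.coverage, 3))
    sources = np.searchsorted(cum, u3[:, 0], side="right")
    sources = np.minimum(sources, len(alleles) - 1)
    true_g = alleles[sources]
    theta = spec.theta
    steps = _geometric_from_uniform(u3[:, 2], theta.rho)
    e = u3[:, 1]
    reads = np.where(e < theta.u, true_g + steps,
                     np.where(e < theta.u + theta.d, true_g - steps, true_g))
    # redraw physically impossible negative copy numbers (rare)
    bad = np.nonzero(reads < 0)[0]
    while bad.size:
        g = true_g[bad]
        w = rng.random((bad.size, 2))
        steps = _geometric_from_uniform(w[:, 1], theta.rho)
        e = w[:, 0]
        reads[bad] = np.where(e < theta.u, g + steps,
                              np.where(e < theta.u + theta.d, g - steps, g))
        bad = bad[reads[bad] < 0]
    return reads


def estimate_power(spec: SimulationSpec) -> dict:
    """Run ``n_reps`` simulate-then-infer rounds under one setting.

    The true germline genotype <A, B> is supplied to the estimator
    (genotype assumed known in this simulation strategy). Returns the
    fraction of rounds significant at ``spec.alpha`` plus estimate
    summaries and the per-rep estimates.
    """
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(spec.n_reps)
    estimates: list[MosaicEstimate] = []
    for child in streams:
        rng = np.random.default_rng(child)
        reads = simulate_read_vector(spec, rng)
        data = LocusReadData(A=spec.A, B=spec.B, reads=reads, theta=spec.theta)
        estimates.append(estimate_mosaicism(data))
    pvals = np.array([e.pvalue for e in estimates])
    f_hats = np.array([e.f_hat for e in estimates])
    c_hats = np.array([e.C_hat for e in estimates])
    c_vals, c_counts = np.unique(c_hats, return_counts=True)
    return {
        "power": float(np.mean(pvals < spec.alpha)),
        "mean_f_hat": float(f_hats.mean()),
        "mean_C_hat": float(c_hats.mean()),
        "modal_C_hat": float(c_vals[np.argmax(c_counts)]),
        "estimates": estimates,
    }


def power_grid(specs: Sequence[SimulationSpec]) -> pd.DataFrame:
    """Map :func:`estimate_power` over settings into a tidy table."""
    rows = []
    for spec in specs:
        res = estimate_power(spec)
        rows.append(
            {
                "A": spec.A,
                "B": spec.B,
                "mosaic_alleles": ";".join(f"{c}:{f}" for c, f in spec.mosaic_alleles),
                "true_f_total": sum(f for _, f in spec.mosaic_alleles),
                "coverage": spec.coverage,
                "u": spec.theta.u,
                "d": spec.theta.d,
                "rho": spec.theta.rho,
                "n_reps": spec.n_reps,
                "alpha": spec.alpha,
                "power": res["power"],
                "mean_f_hat": res["mean_f_hat"],
                "mean_C_hat": res["mean_C_hat"],
                "modal_C_hat": res["modal_C_hat"],
            }
        )
    return pd.DataFrame(rows)
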