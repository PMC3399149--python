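"""Domestication-bottleneck intensity by grid approximate likelihood.

The demographic model is an instantaneous reduction of effective population
size: an ancestral (wild) population of size ``N_a`` dropped to ``N_p`` at
``t`` generations in the past and stayed there.  The bottleneck intensity is
``alpha = N_a / N_p`` (alpha = 1 means no reduction).  With the calibration
``N_a = 30,000`` and ``t = 9,000`` generations, the size-change time in
units of ``2*N_p`` generations is ``tau = t/(2*N_p) = 0.15*alpha``;
equivalently it sits at a fixed ``t/(2*N_a) = 0.15`` in wild-scaled
coalescent units, which is the form the simulator consumes.

For each candidate alpha on a grid (default 19 values, 1 to 10 in steps of
0.5) and each locus, coalescent replicates of the model are drawn with the
locus's wild-estimated mutation parameter ``theta_wild`` and recombination
parameter ``rho``; the locus likelihood is the proportion of replicates
whose simulated diversity falls within a +/-20% band around the observed
per-locus pi (total over the locus).  The multilocus log-likelihood is the
sum of log proportions (floored at ``1/(2*reps)``); the estimate is the
grid argmax, with an interval from the 2-log-likelihood-unit drop rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coalescent
from .errors import EstimationError, InputError

DEFAULT_GRID = tuple(np.arange(1.0, 10.01, 0.5))  # 19 values
DEFAULT_NA = 30_000
DEFAULT_T = 9_000


@dataclass(frozen=True)
class BottleneckModel:
    """Five-parameter instantaneous-size-change model for one locus."""

    n: int                      # sample size of the domesticated group
    alpha: float                # bottleneck intensity N_a / N_p (>= 1)
    theta_wild: float           # ancestral diversity 4*N_a*mu*L, total over locus
    rho: float = 0.0            # population recombination 4*N*c*L for the locus
    L: int = 300                # effective sequence length, bp
    N_a: int = DEFAULT_NA       # ancestral effective size
    t: int = DEFAULT_T          # generations since the size change

    def __post_init__(self) -> None:
        if not all(
            np.isfinite(v) for v in (self.alpha, self.theta_wild, self.rho)
        ):
            raise InputError("model parameters must be finite")
        if self.alpha < 1 or self.theta_wild < 0 or self.rho < 0 or self.n < 2:
            raise InputError("require alpha >= 1, theta_wild >= 0, rho >= 0, n >= 2")

    @property
    def N_p(self) -> float:
        """Post-domestication effective size."""
        return self.N_a / self.alpha

    @property
    def tau(self) -> float:
        """Size-change time in units of 2*N_p generations (0.15*alpha default)."""
        return self.t / (2.0 * self.N_p)

    @property
    def change_time(self) -> float:
        """The same epoch boundary in wild-scaled units of 2*N_a generations."""
        return self.t / (2.0 * self.N_a)


def simulate_locus_pi(
    model: BottleneckModel,
    reps: int,
    seed: int | None = None,
) -> np.ndarray:
    """Simulated per-locus pi (average pairwise differences) per replicate.

    Seed-reproducible; uses the tree path when ``rho = 0`` and the
    ancestral-recombination-graph path otherwise.
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    if model.rho == 0.0:
        return coalescent.simulate_pi(
            model.n,
            model.theta_wild,
            reps,
            alpha=model.alpha,
            change_time=model.change_time,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    for r in range(reps):
        muts = coalescent.simulate_arg_mutations(
            model.n,
            model.theta_wild,
            model.rho,
            alpha=model.alpha,
            change_time=model.change_time,
            rng=rng,
        )
        out[r] = coalescent.pi_from_mutations(muts, model.n)
    return out


def locus_likelihood(
    observed_pi: float, sims: np.ndarray, band: float = 0.20
) -> float:
    """Proportion of simulated pi values within +/-band of the observed pi.

    The closed acceptance interval is ``[(1-band)*obs, (1+band)*obs]``; for
    an observed pi of 0 only exact zeros are accepted.  The proportion is
    floored at ``1/(2*reps)`` so its log is always finite.
    """
    sims = np.asarray(sims)
    if sims.size == 0:
        raise InputError("sims must be non-empty")
    if observed_pi < 0:
        raise InputError("observed_pi must be >= 0")
    lo, hi = (1.0 - band) * observed_pi, (1.0 + band) * observed_pi
    prop = float(np.mean((sims >= lo) & (sims <= hi)))
    floor = 1.0 / (2.0 * sims.size)
    return max(prop, floor)


@dataclass
class GridLikelihood:
    """Likelihood surface over the alpha grid."""

    alpha_grid: np.ndarray
    loglik: np.ndarray                       # multilocus log-likelihood per alpha
    per_locus_prop: pd.DataFrame             # rows: loci, cols: alpha values
    reps: int
    band: float


@dataclass
class BottleneckEstimate:
    alpha_hat: float
    ci95: tuple[float, float]
    at_floor: bool = False
    surface: GridLikelihood | None = field(default=None, repr=False)


def estimate_alpha(
    observed_pi: dict[str, float],
    wild_params: dict[str, dict],
    n: int,
    grid: tuple[float, ...] = DEFAULT_GRID,
    reps: int = 5000,
    band: float = 0.20,
    seed: int | None = None,
    N_a: int = DEFAULT_NA,
    t: int = DEFAULT_T,
) -> BottleneckEstimate:
    """Grid maximum-likelihood estimate of the bottleneck intensity.

    Parameters
    ----------
    observed_pi:
        Per-locus observed pi for the domesticated group, total over the
        locus (per-site pi times locus length).
    wild_params:
        Per-locus dict with keys ``theta_wild`` (total over locus), ``rho``
        and ``L``; locus ids must cover ``observed_pi``.
    n:
        Sample size of the domesticated group.
    reps:
        Coalescent replicates per (locus, alpha) point.
    seed:
        Master seed; per-(locus, alpha) substreams are spawned from it, so
        reruns are bit-reproducible and the result does not depend on locus
        ordering.

    Raises :class:`EstimationError` when every locus proportion sits at the
    floor across the entire grid (a flat, uninformative surface).
    """
    loci = list(observed_pi)
    if not loci:
        raise InputError("need at least one locus")
    missing = [l for l in loci if l not in wild_params]
    if missing:
        raise InputError(f"wild_params missing loci: {missing}")
    grid = tuple(grid)
    if sorted(grid) != list(grid):
        raise InputError("alpha grid must be sorted ascending")
    master = np.random.SeedSequence(seed)
    floor = 1.0 / (2.0 * reps)
    props = np.empty((len(loci), len(grid)))
    for li, locus in enumerate(sorted(loci)):  # sorted: order-invariant streams
        wp = wild_params[locus]
        row = loci.index(locus)
        for ai, alpha in enumerate(grid):
            child = np.random.SeedSequence(
                entropy=master.entropy, spawn_key=(li, ai)
            )
            sub_seed = int(child.generate_state(1)[0] % 2**31)
            model = BottleneckModel(
                n=n,
                alpha=float(alpha),
                theta_wild=float(wp["theta_wild"]),
                rho=float(wp.get("rho", 0.0)),
                L=int(wp.get("L", 300)),
                N_a=N_a,
                t=t,
            )
            sims = simulate_locus_pi(model, reps, seed=sub_seed)
            props[row, ai] = locus_likelihood(observed_pi[locus], sims, band)
    loglik = np.log(props).sum(axis=0)
    at_floor = bool(np.all(props <= floor + 1e-12))
    if at_floor:
        raise EstimationError(
            "likelihood surface is flat at the floor for every locus and alpha"
        )
    best = int(np.argmax(loglik))  # ties resolve to the smaller alpha
    inside = np.flatnonzero(loglik >= loglik[best] - 2.0)
    ci = (float(grid[inside[0]]), float(grid[inside[-1]]))
    surface = GridLikelihood(
        alpha_grid=np.asarray(grid),
        loglik=loglik,
        per_locus_prop=pd.DataFrame(props, index=loci, columns=list(grid)),
        reps=reps,
        band=band,
    )
    return BottleneckEstimate(
        alpha_hat=float(grid[best]), ci95=ci, at_floor=False, surface=surface
    )
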