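"""Coalescent simulation engine for the demographic model used throughout.

Model
-----
A single population whose relative size (in units of the ancestral/wild
effective size ``N_a``) is ``1/alpha`` at present and reverts instantaneously
to ``1`` at scaled time ``change_time`` in the past.  Time is measured in
units of ``2*N_a`` generations, so a pair of lineages coalesces at rate
``alpha`` during the reduced epoch and at rate ``1`` before it; ``alpha = 1``
is the standard neutral coalescent.  Mutations arrive on branches at rate
``theta/2`` per lineage per unit time (``theta = 4*N_a*mu*L``, total over the
locus) under the infinite-sites model; crossover recombination within the
locus occurs at total rate ``rho/2 = 2*N_a*c*L`` per lineage.

Two code paths are provided: a fast single-genealogy path for ``rho = 0``
(used by the likelihood grid and the neutrality nulls, where millions of
replicates are drawn) and a general ancestral-recombination-graph path for
``rho > 0``.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .errors import InputError

__all__ = [
    "expected_pairwise_time",
    "simulate_branches",
    "simulate_pi",
    "simulate_fixed_s",
    "simulate_mutations",
    "simulate_arg_mutations",
]


def expected_pairwise_time(alpha: float, change_time: float) -> float:
    """Closed-form E[pairwise coalescence time] under the size-change model.

    In units of ``2*N_a`` generations:
    ``(1 - exp(-alpha*t0))/alpha + exp(-alpha*t0)`` with ``t0 = change_time``.
    Equals 1 for ``alpha = 1``; decreases monotonically in ``alpha``.
    """
    t0 = change_time
    return (1.0 - math.exp(-alpha * t0)) / alpha + math.exp(-alpha * t0)


def _advance(t: float, rate_now: float, rate_past: float, t0: float, e: float) -> float:
    """Time of the next event given Exp(1) draw ``e`` and a piecewise rate."""
    if t < t0 and rate_now > 0:
        w = e / rate_now
        if t + w <= t0:
            return t + w
        e -= (t0 - t) * rate_now
        t = t0
    return t + e / rate_past


def simulate_branches(
    n: int,
    alpha: float,
    change_time: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one genealogy without recombination.

    Returns ``(blen, bsize)``: length and number of subtended samples for
    each of the ``2n - 2`` branches (the root lineage carries no branch).
    """
    if n < 2:
        raise InputError("need n >= 2 lineages")
    e = rng.exponential(size=n - 1)
    u = rng.random(size=2 * (n - 1))
    sizes = [1] * n
    births = [0.0] * n
    blen = np.empty(2 * n - 2)
    bsize = np.empty(2 * n - 2, dtype=np.int64)
    t = 0.0
    k = n
    bi = 0
    for step in range(n - 1):
        pair = k * (k - 1) / 2.0
        t = _advance(t, pair * alpha, pair, change_time, e[step])
        i = int(u[2 * step] * k)
        j = int(u[2 * step + 1] * (k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        blen[bi] = t - births[i]
        bsize[bi] = sizes[i]
        blen[bi + 1] = t - births[j]
        bsize[bi + 1] = sizes[j]
        bi += 2
        merged = sizes[i] + sizes[j]
        # remove j first (j > i) to keep index i valid
        del sizes[j], births[j]
        sizes[i] = merged
        births[i] = t
        k -= 1
    return blen, bsize


def simulate_pi(
    n: int,
    theta: float,
    reps: int,
    alpha: float = 1.0,
    change_time: float = 0.15,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Per-replicate average pairwise differences ``k`` (total over the locus).

    Mutation counts are Poisson given the genealogy's total branch length;
    each mutation lands on a branch with probability proportional to its
    length and contributes ``size*(n-size)/C(n,2)`` pairwise differences.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not (np.isfinite(theta) and np.isfinite(alpha) and np.isfinite(change_time)):
        raise InputError("model parameters must be finite")
    if theta < 0 or alpha < 1 or reps < 1:
        raise InputError("require theta >= 0, alpha >= 1, reps >= 1")
    npairs = n * (n - 1) / 2.0
    out = np.empty(reps)
    for r in range(reps):
        blen, bsize = simulate_branches(n, alpha, change_time, rng)
        total = blen.sum()
        m = rng.poisson(theta / 2.0 * total)
        if m == 0:
            out[r] = 0.0
            continue
        cum = np.cumsum(blen)
        picks = np.searchsorted(cum, rng.random(m) * total)
        s = bsize[picks]
        out[r] = float(np.sum(s * (n - s))) / npairs
    return out


def simulate_fixed_s(
    n: int,
    S: int,
    reps: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral genealogies with exactly ``S`` mutations placed on branches.

    Used for significance testing of summary statistics conditional on the
    observed number of segregating sites: ``S`` mutations are dropped on a
    standard-coalescent genealogy with probability proportional to branch
    length.  Returns per-replicate ``(k, eta_s)`` where ``k`` is the average
    pairwise difference count and ``eta_s`` the number of singleton
    mutations (subtending exactly 1 or exactly n-1 samples).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if S < 1:
        raise InputError("simulate_fixed_s requires S >= 1")
    npairs = n * (n - 1) / 2.0
    k_out = np.empty(reps)
    es_out = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        blen, bsize = simulate_branches(n, 1.0, 0.0, rng)
        cum = np.cumsum(blen)
        picks = np.searchsorted(cum, rng.random(S) * cum[-1])
        s = bsize[picks]
        k_out[r] = float(np.sum(s * (n - s))) / npairs
        es_out[r] = int(np.sum((s == 1) | (s == n - 1)))
    return k_out, es_out


def simulate_mutations(
    n: int,
    theta: float,
    alpha: float = 1.0,
    change_time: float = 0.15,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[frozenset[int]]:
    """One genealogy with Poisson mutations; returns carrier sets per mutation.

    Carrier sets index samples ``0..n-1``.  Used by the synthetic-data
    generator to build sequence alignments (``rho = 0``).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    e = rng.exponential(size=n - 1)
    u = rng.random(size=2 * (n - 1))
    lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    births = [0.0] * n
    branches: list[tuple[float, frozenset[int]]] = []
    t = 0.0
    k = n
    for step in range(n - 1):
        pair = k * (k - 1) / 2.0
        t = _advance(t, pair * alpha, pair, change_time, e[step])
        i = int(u[2 * step] * k)
        j = int(u[2 * step + 1] * (k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        branches.append((t - births[i], lineages[i]))
        branches.append((t - births[j], lineages[j]))
        merged = lineages[i] | lineages[j]
        del lineages[j], births[j]
        lineages[i] = merged
        births[i] = t
        k -= 1
    blen = np.array([b[0] for b in branches])
    total = blen.sum()
    m = rng.poisson(theta / 2.0 * total)
    if m == 0:
        return []
    cum = np.cumsum(blen)
    picks = np.searchsorted(cum, rng.random(m) * total)
    return [branches[p][1] for p in picks]


# --------------------------------------------------------------------------
# Ancestral recombination graph (rho > 0)
# --------------------------------------------------------------------------

Segment = tuple[float, float, frozenset]  # [left, right) in [0, 1), carriers


def _material(segs: list[Segment]) -> float:
    return sum(r - l for l, r, _ in segs)


def _span(segs: list[Segment]) -> float:
    return segs[-1][1] - segs[0][0]


def _merge_segments(a: list[Segment], b: list[Segment], full: frozenset) -> list[Segment]:
    """Union two segment maps; carrier sets union on overlap; drop MRCA regions."""
    bounds = sorted({x for l, r, _ in a + b for x in (l, r)})
    out: list[Segment] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = (lo + hi) / 2.0
        carriers: frozenset = frozenset()
        for l, r, c in a:
            if l <= mid < r:
                carriers |= c
                break
        for l, r, c in b:
            if l <= mid < r:
                carriers |= c
                break
        if carriers and carriers != full:
            if out and out[-1][1] == lo and out[-1][2] == carriers:
                out[-1] = (out[-1][0], hi, carriers)
            else:
                out.append((lo, hi, carriers))
    return out


def _split_segments(segs: list[Segment], x: float) -> tuple[list[Segment], list[Segment]]:
    left: list[Segment] = []
    right: list[Segment] = []
    for l, r, c in segs:
        if r <= x:
            left.append((l, r, c))
        elif l >= x:
            right.append((l, r, c))
        else:
            left.append((l, x, c))
            right.append((x, r, c))
    return left, right


def simulate_arg_mutations(
    n: int,
    theta: float,
    rho: float,
    alpha: float = 1.0,
    change_time: float = 0.15,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[tuple[float, frozenset[int]]]:
    """One ancestral-recombination-graph replicate with mutations.

    Returns a list of ``(position, carriers)`` mutations, position in
    ``[0, 1)`` along the locus.  Crossovers occur within the span of each
    lineage's ancestral material at total rate ``rho/2`` per unit span;
    mutations at rate ``theta/2`` per unit of ancestral material.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n < 2:
        raise InputError("need n >= 2 lineages")
    full = frozenset(range(n))
    lineages: list[list[Segment]] = [[(0.0, 1.0, frozenset([i]))] for i in range(n)]
    mutations: list[tuple[float, frozenset[int]]] = []
    t = 0.0
    # guard against pathological runaway recombination
    for _ in range(200_000):
        k = len(lineages)
        if k <= 1:
            break
        mat = [_material(s) for s in lineages]
        spans = [_span(s) for s in lineages]
        rec_rate = rho / 2.0 * sum(spans)
        pair = k * (k - 1) / 2.0
        e = rng.exponential()
        # piecewise-constant total rate across the epoch boundary
        if t < change_time:
            r1 = pair * alpha + rec_rate
            w = e / r1
            if t + w <= change_time:
                t_new = t + w
                coal_rate = pair * alpha
            else:
                e -= (change_time - t) * r1
                t_new = change_time + e / (pair + rec_rate)
                coal_rate = pair
        else:
            t_new = t + e / (pair + rec_rate)
            coal_rate = pair
        dt = t_new - t
        # mutations during (t, t_new]: lineage set was constant
        total_mat = sum(mat)
        m = rng.poisson(theta / 2.0 * dt * total_mat)
        if m:
            w = np.array(mat) / total_mat
            for li in rng.choice(len(lineages), size=m, p=w):
                segs = lineages[li]
                x = rng.random() * _material(segs)
                acc = 0.0
                for l, r, c in segs:
                    if acc + (r - l) >= x:
                        mutations.append((l + (x - acc), c))
                        break
                    acc += r - l
        t = t_new
        # event type
        if rng.random() < coal_rate / (coal_rate + rec_rate):
            i, j = rng.choice(k, size=2, replace=False)
            merged = _merge_segments(lineages[i], lineages[j], full)
            for idx in sorted((i, j), reverse=True):
                del lineages[idx]
            if merged:
                lineages.append(merged)
        else:
            w = np.array(spans) / sum(spans)
            li = int(rng.choice(k, p=w))
            segs = lineages[li]
            x = segs[0][0] + rng.random() * _span(segs)
            left, right = _split_segments(segs, x)
            if left and right:
                lineages[li] = left
                lineages.append(right)
    return mutations


def pi_from_mutations(mutations: list[tuple[float, frozenset]], n: int) -> float:
    """Average pairwise differences implied by a set of mutations."""
    npairs = n * (n - 1) / 2.0
    return sum(len(c) * (n - len(c)) for _, c in mutations) / npairs
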