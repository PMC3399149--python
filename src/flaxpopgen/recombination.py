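"""Minimum recombination events (four-gamete test) and a moment estimate of 4Nc.

Two biallelic sites displaying all four haplotypic combinations of their
alleles cannot descend from a single tree under infinite sites, so at least
one crossover occurred between them.  Rm is the Hudson-Kaplan lower bound on
the number of recombination events: the maximum number of pairwise-disjoint
open intervals selectable from the incompatible site pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .diversity import analysed_sites, nucleotide_diversity, segregating_sites
from .errors import InputError
from .seq_io import LocusAlignment


def biallelic_columns(aln: LocusAlignment, policy: str = "complete") -> np.ndarray:
    """Analysed column indices with exactly two distinct nucleotides."""
    cols = analysed_sites(aln, policy)
    mat = aln.matrix()[:, cols]
    keep = [j for j in range(mat.shape[1]) if len(np.unique(mat[:, j])) == 2]
    return cols[keep]


def four_gamete_pairs(
    aln: LocusAlignment, policy: str = "complete"
) -> set[tuple[int, int]]:
    """Site-index pairs (i < j) failing the four-gamete test.

    Only strictly biallelic analysed columns are scanned; indices refer to
    original alignment coordinates.
    """
    cols = biallelic_columns(aln, policy)
    mat = aln.matrix()
    out: set[tuple[int, int]] = set()
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            i, j = int(cols[a]), int(cols[b])
            gametes = {(x, y) for x, y in zip(mat[:, i], mat[:, j])}
            if len(gametes) == 4:
                out.add((i, j))
    return out


def rm_hudson_kaplan(pairs: set[tuple[int, int]]) -> int:
    """Minimum number of recombination events from incompatible site pairs.

    Standard interval logic: each incompatible pair (i, j) forces a
    recombination strictly inside the open interval (i, j); the bound is the
    maximum number of pairwise-disjoint such intervals, obtained by the
    greedy sweep over intervals sorted by right endpoint.
    """
    if any(i >= j for i, j in pairs):
        raise InputError("pairs must satisfy i < j")
    rm = 0
    last_right = -np.inf
    for i, j in sorted(pairs, key=lambda p: p[1]):
        if i >= last_right:  # open intervals (i, j): disjoint when i >= previous j
            rm += 1
            last_right = j
    return rm


@dataclass
class RecombinationResult:
    locus_id: str
    n_biallelic: int
    incompatible_pairs: set[tuple[int, int]] = field(repr=False)
    Rm: int = 0
    rho_hat: float | None = None


def analyse_locus(aln: LocusAlignment, policy: str = "complete") -> RecombinationResult:
    pairs = four_gamete_pairs(aln, policy)
    return RecombinationResult(
        locus_id=aln.locus_id,
        n_biallelic=len(biallelic_columns(aln, policy)),
        incompatible_pairs=pairs,
        Rm=rm_hudson_kaplan(pairs),
        rho_hat=estimate_rho_hudson87(aln, policy),
    )


def _pair_time_correlation(x: float) -> float:
    """Correlation of coalescence times at two sites a scaled distance x apart."""
    return (x + 18.0) / (x * x + 13.0 * x + 18.0)


def _avg_correlation(rho: float, npts: int = 200) -> float:
    """Mean correlation over site pairs in a locus of total map length rho.

    ``(2/rho^2) * Int_0^rho (rho - x) * g(x) dx`` evaluated numerically;
    equals 1 at rho = 0 and decays towards 0.
    """
    if rho <= 0:
        return 1.0
    x = np.linspace(0.0, rho, npts)
    w = (rho - x) * _pair_time_correlation(x)
    return float(2.0 / rho**2 * np.trapezoid(w, x))


def estimate_rho_hudson87(
    aln: LocusAlignment, policy: str = "complete"
) -> float | None:
    """Moment estimate of the per-locus population recombination rate 4Nc.

    Matches the observed variance of pairwise difference counts to its
    coalescent expectation for a pair of sequences,
    ``Var(d) = theta + theta^2 * h(rho)``, where ``theta`` is estimated by
    the mean pairwise difference count and ``h`` averages the classical
    two-site coalescence-time correlation ``(x+18)/(x^2+13x+18)`` over site
    pairs.  Larger rho shrinks the variance.  Returns ``None`` when fewer
    than two segregating sites exist or when the moment equation has no
    non-negative solution; a variance at or above the no-recombination
    expectation yields the boundary estimate 0.
    """
    if segregating_sites(aln, policy) < 2:
        return None
    cols = analysed_sites(aln, policy)
    mat = aln.matrix()[:, cols]
    n = aln.n
    codes = mat.view(np.uint32)
    diffs = []
    for i in range(n - 1):
        diffs.extend(int(np.sum(codes[j] != codes[i])) for j in range(i + 1, n))
    d = np.asarray(diffs, dtype=float)
    theta = d.mean()
    var = d.var(ddof=1)
    if theta <= 0:
        return None
    h_obs = (var - theta) / theta**2
    if h_obs >= 1.0:
        return 0.0
    if h_obs <= 0.0:
        return None  # variance below the Poisson floor: no solution
    f = lambda r: _avg_correlation(r) - h_obs
    hi = 1.0
    while f(hi) > 0 and hi < 1e7:
        hi *= 10.0
    if f(hi) > 0:
        return None
    return float(brentq(f, 0.0, hi, xtol=1e-8))
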