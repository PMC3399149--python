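"""Tajima's D and Fu & Li's D*/F* with coalescent-simulation significance.

Tajima's D contrasts the pairwise-difference estimator of theta with
Watterson's segregating-sites estimator; Fu & Li's outgroup-free D* and F*
contrast singleton mutations (variants carried by exactly one sequence)
with total mutations and with pairwise diversity respectively.  An excess
of rare variants drives all three negative.

Significance is assessed by simulating neutral standard-coalescent
genealogies conditional on the observed number of segregating sites and
placing exactly S mutations proportionally to branch length; p-values are
two-tailed with add-one smoothing, so the attainable floor is
``1/(reps + 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import coalescent
from .diversity import analysed_sites, harmonic, nucleotide_diversity, segregating_sites
from .errors import InputError
from .seq_io import LocusAlignment


@dataclass(frozen=True)
class TajimaConstants:
    """The n-dependent coefficients of Tajima's variance normalisation."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Coefficients a1..e2 for sample size ``n`` (requires n >= 4)."""
    if n < 4:
        raise InputError("tajima_constants requires n >= 4 (variance not estimable)")
    a1 = harmonic(n, 1)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d_from_summary(n: int, S: int, k_total: float) -> float | None:
    """Tajima's D from the summary triple (n, S, average pairwise differences).

    Returns ``None`` (undefined) when ``S = 0``; tables conventionally print
    'nd' in that case.
    """
    if S < 0:
        raise InputError("S must be non-negative")
    if S == 0:
        return None
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (k_total - S / c.a1) / math.sqrt(var)


def tajimas_d(aln: LocusAlignment, policy: str = "complete") -> float | None:
    """Tajima's D computed from an alignment (complete-deletion sites)."""
    S = segregating_sites(aln, policy)
    k, _ = nucleotide_diversity(aln, policy)
    if S == 0:
        return None
    return tajimas_d_from_summary(aln.n, S, k)


def _fu_li_coefficients(n: int) -> tuple[float, float, float, float]:
    """(u_D*, v_D*, u_F*, v_F*) with the corrected small-sample coefficients."""
    a_n = harmonic(n, 1)
    b_n = harmonic(n, 2)
    a_n1 = a_n + 1.0 / n  # a_{n+1}
    c_n = 2.0 * (n * a_n - 2 * (n - 1)) / ((n - 1) * (n - 2))
    d_n = c_n + (n - 2) / (n - 1) ** 2 + (2.0 / (n - 1)) * (
        1.5 - (2 * a_n1 - 3) / (n - 2) - 1.0 / n
    )
    denom = a_n**2 + b_n
    v_dstar = (
        (n / (n - 1.0)) ** 2 * b_n
        + a_n**2 * d_n
        - 2.0 * n * a_n * (a_n + 1) / (n - 1.0) ** 2
    ) / denom
    u_dstar = (n / (n - 1.0)) * (a_n - n / (n - 1.0)) - v_dstar
    v_fstar = (
        d_n
        + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        - (2.0 / (n - 1)) * (4 * b_n - 6 + 8.0 / n)
    ) / denom
    u_fstar = (
        (
            n / (n - 1.0)
            + (n + 1) / (3.0 * (n - 1))
            - 4.0 / (n * (n - 1))
            + 2.0 * (n + 1) / (n - 1.0) ** 2 * (a_n1 - 2.0 * n / (n + 1))
        )
        / a_n
        - v_fstar
    )
    return u_dstar, v_dstar, u_fstar, v_fstar


def fu_li_dstar_fstar(
    n: int, eta: int, eta_s: int, k_total: float
) -> tuple[float | None, float | None]:
    """Fu & Li's outgroup-free D* and F*.

    ``eta`` is the total number of mutations (sum over sites of distinct
    bases minus one), ``eta_s`` the number of singleton mutations (minor
    variant carried by exactly one sequence), ``k_total`` the average
    pairwise difference count.  Returns ``(None, None)`` when ``eta = 0``.
    """
    if n < 4:
        raise InputError("fu_li_dstar_fstar requires n >= 4")
    if eta_s > eta:
        raise InputError("eta_s cannot exceed eta")
    if eta == 0:
        return None, None
    a_n = harmonic(n, 1)
    u_d, v_d, u_f, v_f = _fu_li_coefficients(n)
    dstar = (n / (n - 1.0) * eta - a_n * eta_s) / math.sqrt(u_d * eta + v_d * eta**2)
    fstar = (k_total - (n - 1.0) / n * eta_s) / math.sqrt(u_f * eta + v_f * eta**2)
    return dstar, fstar


def mutation_counts(aln: LocusAlignment, policy: str = "complete") -> tuple[int, int]:
    """(eta, eta_s): total and singleton mutations over analysed columns.

    eta at a column is the number of distinct bases minus one (a strictly
    biallelic column contributes 1, tolerating rare triallelic columns);
    a singleton is a base observed in exactly one sequence at a polymorphic
    column.
    """
    cols = analysed_sites(aln, policy)
    mat = aln.matrix()[:, cols]
    eta = 0
    eta_s = 0
    for j in range(mat.shape[1]):
        bases, counts = np.unique(mat[:, j], return_counts=True)
        if len(bases) < 2:
            continue
        eta += len(bases) - 1
        eta_s += int(np.sum(counts == 1))
    return eta, eta_s


@dataclass(frozen=True)
class NeutralityResult:
    """Neutrality statistics for one alignment (None = undefined)."""

    n: int
    S: int
    eta: int
    eta_s: int
    k: float
    D: float | None
    Dstar: float | None
    Fstar: float | None
    p_D: float | None = None
    p_Dstar: float | None = None
    p_Fstar: float | None = None


def neutrality_tests(
    aln: LocusAlignment,
    policy: str = "complete",
    reps: int = 0,
    seed: int | None = None,
) -> NeutralityResult:
    """All three statistics for an alignment; p-values if ``reps >= 1000``."""
    S = segregating_sites(aln, policy)
    k, _ = nucleotide_diversity(aln, policy)
    eta, eta_s = mutation_counts(aln, policy)
    D = tajimas_d_from_summary(aln.n, S, k) if S > 0 else None
    Dstar, Fstar = fu_li_dstar_fstar(aln.n, eta, eta_s, k) if eta > 0 else (None, None)
    p_D = p_Ds = p_Fs = None
    if reps and S > 0:
        p_D = neutrality_pvalue("D", D, aln.n, S, reps, seed)
        p_Ds = neutrality_pvalue("Dstar", Dstar, aln.n, S, reps, seed)
        p_Fs = neutrality_pvalue("Fstar", Fstar, aln.n, S, reps, seed)
    return NeutralityResult(aln.n, S, eta, eta_s, k, D, Dstar, Fstar, p_D, p_Ds, p_Fs)


def _null_statistics(name: str, n: int, S: int, reps: int, seed) -> np.ndarray:
    k_arr, es_arr = coalescent.simulate_fixed_s(n, S, reps, seed=seed)
    if name == "D":
        c = tajima_constants(n)
        var = c.e1 * S + c.e2 * S * (S - 1)
        return (k_arr - S / c.a1) / math.sqrt(var)
    a_n = harmonic(n, 1)
    u_d, v_d, u_f, v_f = _fu_li_coefficients(n)
    if name == "Dstar":
        return (n / (n - 1.0) * S - a_n * es_arr) / math.sqrt(u_d * S + v_d * S**2)
    if name == "Fstar":
        return (k_arr - (n - 1.0) / n * es_arr) / math.sqrt(u_f * S + v_f * S**2)
    raise InputError(f"unknown statistic {name!r}")


def neutrality_pvalue(
    statistic_name: str,
    observed: float | None,
    n: int,
    S: int,
    reps: int = 1000,
    seed: int | None = None,
) -> float | None:
    """Two-tailed simulation p-value conditional on the observed S.

    The null statistics are computed on neutral genealogies carrying exactly
    S mutations.  Extremeness of a value x is its smaller empirical tail
    ``min(#{X <= x}, #{X >= x})``; the p-value is the add-one-smoothed
    fraction of replicates at least as extreme as the observation,
    ``(r + 1)/(reps + 1)``, which floors at ``1/(reps + 1)`` when the
    observation lies outside the whole null sample.
    """
    if observed is None:
        return None
    if reps < 1000:
        raise InputError("neutrality_pvalue requires reps >= 1000")
    null = np.sort(_null_statistics(statistic_name, n, S, reps, seed))
    e_obs = min(
        np.searchsorted(null, observed, side="right"),
        reps - np.searchsorted(null, observed, side="left"),
    )
    lo_all = np.searchsorted(null, null, side="right")
    hi_all = reps - np.searchsorted(null, null, side="left")
    e_null = np.minimum(lo_all, hi_all)
    r = int(np.sum(e_null <= e_obs))
    return (r + 1) / (reps + 1)
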