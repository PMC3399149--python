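"""Per-locus and concatenated polymorphism summaries.

The statistics follow the standard haploid-sequence definitions: segregating
sites S, haplotype count Nh, nucleotide diversity pi (average proportion of
pairwise differences per analysed site) and Watterson's theta (S divided by
the harmonic number a1 of n-1).  Columns containing a gap, an 'N' or an IUPAC
ambiguity code in any record are excluded under the default complete-deletion
policy before any statistic is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .seq_io import LocusAlignment, MultiLocusDataset, UNAMBIGUOUS

POLICIES = ("complete",)


def _check_policy(policy: str) -> None:
    if policy not in POLICIES:
        raise InputError(f"unknown site policy {policy!r}; expected one of {POLICIES}")


def harmonic(n: int, power: int = 1) -> float:
    """Sum of 1/i**power for i = 1..n-1 (a1 for power=1, a2 for power=2)."""
    return float(sum(1.0 / i**power for i in range(1, n)))


def analysed_sites(aln: LocusAlignment, policy: str = "complete") -> np.ndarray:
    """Indices of columns retained by the site-deletion policy.

    Under complete deletion a column survives only if every record carries an
    unambiguous nucleotide (A, C, G or T) there.  Indices are strictly
    increasing; the result may be empty.
    """
    _check_policy(policy)
    mat = aln.matrix()
    ok = np.all(np.isin(mat, list(UNAMBIGUOUS)), axis=0)
    return np.flatnonzero(ok)


def _analysed_matrix(aln: LocusAlignment, policy: str) -> np.ndarray:
    cols = analysed_sites(aln, policy)
    return aln.matrix()[:, cols]


def segregating_sites(aln: LocusAlignment, policy: str = "complete") -> int:
    """Number of analysed columns with at least two distinct nucleotides."""
    if aln.n < 2:
        raise InputError("segregating_sites requires at least 2 sequences")
    sub = _analysed_matrix(aln, policy)
    if sub.shape[1] == 0:
        return 0
    return int(np.sum(np.any(sub != sub[0], axis=0)))


def haplotype_count(aln: LocusAlignment, gap_mode: str = "exclude-gap-sites") -> int:
    """Number of distinct sequences (haplotypes) in the alignment.

    ``exclude-gap-sites`` compares sequences over complete-deletion columns
    only; ``include-gaps`` compares the raw residue strings, so sequences
    differing only by an indel count as distinct haplotypes.
    """
    if gap_mode == "include-gaps":
        return len({r.residues for r in aln.records})
    if gap_mode == "exclude-gap-sites":
        sub = _analysed_matrix(aln, "complete")
        return len({row.tobytes() for row in sub})
    raise InputError(f"unknown gap_mode {gap_mode!r}")


def nucleotide_diversity(
    aln: LocusAlignment, policy: str = "complete"
) -> tuple[float, float]:
    """Average pairwise differences ``k`` (per locus) and ``pi`` (per site).

    ``k`` is the unbiased all-pairs mean: the sum over the C(n, 2) sequence
    pairs of the count of mismatching analysed columns, divided by C(n, 2).
    ``pi = k / L_net``; NaN is returned for pi when no site survives the
    deletion policy (undefined, distinguishable from 0).
    """
    if aln.n < 2:
        raise InputError("nucleotide_diversity requires at least 2 sequences")
    sub = _analysed_matrix(aln, policy)
    n, l_net = sub.shape
    if l_net == 0:
        return 0.0, float("nan")
    codes = sub.view(np.uint32)  # U1 -> codepoint, mismatch comparison only
    total = 0
    for i in range(n - 1):
        total += int(np.sum(codes[i + 1 :] != codes[i]))
    k = total / (n * (n - 1) / 2)
    return k, k / l_net


def watterson_theta(S: int, n: int, L_net: int | None = None) -> tuple[float, float]:
    """Watterson's estimator: total ``S / a1`` and, if ``L_net`` given, per site."""
    if n < 2:
        raise InputError("watterson_theta requires n >= 2")
    a1 = harmonic(n)
    theta_total = S / a1
    theta_site = theta_total / L_net if L_net else float("nan")
    return theta_total, theta_site


@dataclass(frozen=True)
class LocusDiversity:
    """One row of a per-locus polymorphism table."""

    locus_id: str
    n: int
    L: int
    L_net: int
    S: int
    Nh: int
    k: float
    pi: float
    theta_w_total: float
    theta_w_site: float


def locus_diversity(aln: LocusAlignment, policy: str = "complete") -> LocusDiversity:
    """Compute the full per-locus summary for one alignment."""
    cols = analysed_sites(aln, policy)
    S = segregating_sites(aln, policy)
    Nh = haplotype_count(aln)
    k, pi = nucleotide_diversity(aln, policy)
    th_tot, th_site = watterson_theta(S, aln.n, len(cols) or None)
    return LocusDiversity(
        locus_id=aln.locus_id,
        n=aln.n,
        L=aln.length,
        L_net=len(cols),
        S=S,
        Nh=Nh,
        k=k,
        pi=pi,
        theta_w_total=th_tot,
        theta_w_site=th_site,
    )


def diversity_table(
    dataset: MultiLocusDataset, policy: str = "complete"
) -> pd.DataFrame:
    """Per-locus summary table plus a 'Total' row (length-weighted pi)."""
    rows = [locus_diversity(aln, policy) for aln in dataset.loci.values()]
    df = pd.DataFrame([r.__dict__ for r in rows])
    total_pi = concatenated_pi([(r.pi, r.L_net) for r in rows if r.L_net > 0])
    total = {
        "locus_id": "Total",
        "n": rows[0].n,
        "L": int(df["L"].sum()),
        "L_net": int(df["L_net"].sum()),
        "S": int(df["S"].sum()),
        "Nh": int(df["Nh"].sum()),
        "k": float(df["k"].sum()),
        "pi": total_pi,
        "theta_w_total": float(df["theta_w_total"].sum()),
        "theta_w_site": float(df["theta_w_total"].sum()) / max(int(df["L_net"].sum()), 1),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def concatenated_pi(per_locus: list[tuple[float, int]]) -> float:
    """Length-weighted mean of per-locus pi values.

    ``per_locus`` is a list of ``(pi_i, L_net_i)`` pairs.  Identical to the
    pi of the concatenated alignment when all loci share one site policy.
    """
    if not per_locus:
        raise InputError("concatenated_pi: empty per-locus list")
    if any(l < 1 for _, l in per_locus):
        raise InputError("concatenated_pi: every L_net must be >= 1")
    num = sum(pi * l for pi, l in per_locus)
    den = sum(l for _, l in per_locus)
    return num / den


def percent_reduction(pi_wild: float, pi_dom: float) -> int:
    """Diversity loss of a domesticated group relative to the wild group.

    Returns ``100 * (pi_wild - pi_dom) / pi_wild`` rounded to the nearest
    integer percent.
    """
    if not pi_wild > 0:
        raise InputError("percent_reduction requires pi_wild > 0")
    if math.isnan(pi_dom):
        raise InputError("pi_dom is undefined")
    return round(100.0 * (pi_wild - pi_dom) / pi_wild)
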