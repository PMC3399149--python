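"""Analysis of molecular variance on concatenated sequences.

Single-level AMOVA decomposes the sum of squared inter-individual distances
into among-group and within-group variance components; for haplotypic
sequence data the squared distance between two individuals is their count
of pairwise nucleotide differences (no distance correction).  Phi-st is the
proportion of molecular variance among groups; significance comes from
permuting individuals among groups (group sizes preserved) with add-one
smoothed p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import analysed_sites
from .errors import InputError
from .seq_io import GroupPanel, LocusAlignment


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal, pairwise difference counts

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise InputError("distance matrix must be symmetric, non-negative, zero-diagonal")
        self.d = d

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.d[np.ix_(idx, idx)])


@dataclass
class GroupingModel:
    """Named partition of (a subset of) the samples into >= 2 groups."""

    name: str
    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g, members in self.groups.items():
            if len(members) < 2:
                raise InputError(f"group {g!r} has fewer than 2 members")
            if seen & set(members):
                raise InputError("groups must be disjoint")
            seen |= set(members)

    @classmethod
    def from_panel(cls, panel: GroupPanel, name: str = "panel") -> "GroupingModel":
        return cls(name, {g: list(m) for g, m in panel.groups.items()})


@dataclass
class AmovaResult:
    model: str
    sigma_among: float
    sigma_within: float
    pct_among: float
    phi_st: float
    p_perm: float | None
    n_perm: int
    ssd_total: float
    ssd_among: float
    ssd_within: float


def pairwise_differences(
    concat: LocusAlignment, policy: str = "complete"
) -> DistanceMatrix:
    """Pairwise nucleotide difference counts over analysed columns."""
    if concat.n < 2:
        raise InputError("need at least 2 sequences")
    cols = analysed_sites(concat, policy)
    mat = concat.matrix()[:, cols].view(np.uint32)
    n = concat.n
    d = np.zeros((n, n))
    for i in range(n - 1):
        diff = np.sum(mat[i + 1 :] != mat[i], axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return DistanceMatrix(concat.sample_ids, d)


def _ssd(d: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squared deviations for one set of individuals: sum_{i<j} d_ij / n."""
    sub = d[np.ix_(idx, idx)]
    return float(sub.sum() / 2.0 / len(idx))


def _components(
    d: np.ndarray, group_idx: list[np.ndarray]
) -> tuple[float, float, float, float, float, float]:
    """(ssd_total, ssd_among, ssd_within, sigma_a, sigma_w, phi_st)."""
    all_idx = np.concatenate(group_idx)
    n_tot = len(all_idx)
    g = len(group_idx)
    ssd_total = _ssd(d, all_idx)
    ssd_within = sum(_ssd(d, idx) for idx in group_idx)
    ssd_among = ssd_total - ssd_within
    df_among = g - 1
    df_within = n_tot - g
    sigma_w = ssd_within / df_within
    n_prime = (n_tot - sum(len(i) ** 2 for i in group_idx) / n_tot) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    phi = sigma_a / denom if denom != 0 else 0.0
    return ssd_total, ssd_among, ssd_within, sigma_a, sigma_w, phi


def _group_indices(dist: DistanceMatrix, model: GroupingModel) -> list[np.ndarray]:
    pos = {l: i for i, l in enumerate(dist.labels)}
    missing = [m for members in model.groups.values() for m in members if m not in pos]
    if missing:
        raise InputError(f"samples missing from distance matrix: {missing[:5]}")
    return [np.array([pos[m] for m in members]) for members in model.groups.values()]


def amova_one_level(
    dist: DistanceMatrix,
    model: GroupingModel,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """Single-level AMOVA with a label-permutation test on Phi-st.

    ``p_perm`` is the add-one-smoothed fraction of permutations (individuals
    shuffled among groups, sizes preserved) with Phi-st at least the
    observed value.  Set ``n_perm = 0`` to skip the test.
    """
    if len(model.groups) < 2:
        raise InputError("AMOVA requires at least 2 groups")
    group_idx = _group_indices(dist, model)
    ssd_t, ssd_a, ssd_w, sig_a, sig_w, phi = _components(dist.d, group_idx)
    p = None
    if n_perm:
        if n_perm < 100:
            raise InputError("n_perm must be >= 100 (or 0 to skip)")
        rng = np.random.default_rng(seed)
        all_idx = np.concatenate(group_idx)
        sizes = [len(i) for i in group_idx]
        edges = np.cumsum([0] + sizes)
        r = 0
        for _ in range(n_perm):
            perm = rng.permutation(all_idx)
            gidx = [perm[edges[i] : edges[i + 1]] for i in range(len(sizes))]
            phi_p = _components(dist.d, gidx)[5]
            if phi_p >= phi:
                r += 1
        p = (r + 1) / (n_perm + 1)
    sig_a_c, sig_w_c = max(sig_a, 0.0), max(sig_w, 0.0)
    pct = 100.0 * sig_a_c / (sig_a_c + sig_w_c) if (sig_a_c + sig_w_c) > 0 else 0.0
    return AmovaResult(
        model=model.name,
        sigma_among=sig_a,
        sigma_within=sig_w,
        pct_among=pct,
        phi_st=phi,
        p_perm=p,
        n_perm=n_perm,
        ssd_total=ssd_t,
        ssd_among=ssd_a,
        ssd_within=ssd_w,
    )


def pairwise_group_fst(
    dist: DistanceMatrix,
    model: GroupingModel,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phi-st and permutation p for every group pair (two-group AMOVA each).

    Returns ``(fst, pvals)`` as symmetric DataFrames with NaN diagonals.
    """
    names = list(model.groups)
    if len(names) < 2:
        raise InputError("need at least 2 groups")
    fst = pd.DataFrame(np.nan, index=names, columns=names)
    pv = pd.DataFrame(np.nan, index=names, columns=names)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names) * len(names))
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            sub_model = GroupingModel(
                f"{names[a]}|{names[b]}",
                {names[a]: model.groups[names[a]], names[b]: model.groups[names[b]]},
            )
            child_seed = int(children[a * len(names) + b].generate_state(1)[0] % 2**31)
            res = amova_one_level(dist, sub_model, n_perm, child_seed)
            fst.iloc[a, b] = fst.iloc[b, a] = res.phi_st
            if res.p_perm is not None:
                pv.iloc[a, b] = pv.iloc[b, a] = res.p_perm
    return fst, pv


def group_specific_fst(dist: DistanceMatrix, model: GroupingModel) -> pd.Series:
    """Per-group differentiation: each group contrasted with the pooled rest.

    Implemented as the Phi-st of a two-group AMOVA of the group against all
    remaining samples; deterministic (no permutations).
    """
    names = list(model.groups)
    if len(names) < 2:
        raise InputError("need at least 2 groups")
    out = {}
    for g in names:
        rest = [m for h in names if h != g for m in model.groups[h]]
        sub = GroupingModel(f"{g}|rest", {g: model.groups[g], "rest": rest})
        out[g] = amova_one_level(dist, sub, n_perm=0).phi_st
    return pd.Series(out, name="group_specific_fst")
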