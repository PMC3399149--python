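"""Published per-locus summary statistics for the flax resequencing survey.

A population-resequencing survey of flax domestication sampled 48 *Linum*
accessions — 10 wild pale flax (*L. bienne*) and 38 cultivated flax
(*L. usitatissimum*) split into dehiscent, fiber, oil and winter groups —
at 24 unlinked genomic regions (184-441 bp, 6886 bp concatenated).  The
survey's per-locus summary tables are shipped here as model inputs and
worked-example data: contig lengths, segregating sites, haplotype counts
and nucleotide diversity overall and per group, plus Tajima's D and minimum
recombination events per group.  Per-site pi values are printed to 4
decimal places.
"""

from __future__ import annotations

import pandas as pd

LOCI = [
    "031B/A", "049B/A", "071B/A", "145B/A", "151B/A", "204B/A", "221B/A",
    "242B/A", "246B/A", "281B/A", "316B/A", "360B/A", "440B/A", "449B/A",
    "469B/A", "503B/A", "524B/A", "550B/A", "586B/A", "590B/A", "632B/A",
    "676B/A", "677B/A", "712B/A",
]

#: Contig length (bp) flanked by each primer set.
LOCUS_LENGTHS = dict(zip(LOCI, [
    346, 334, 283, 364, 363, 225, 370, 304, 259, 285, 227, 287,
    231, 248, 441, 313, 277, 330, 222, 231, 256, 257, 184, 249,
]))

#: All-sample (n=48) summary: segregating sites, haplotypes, per-site pi.
ALL_SAMPLES = pd.DataFrame(
    {
        "L": pd.Series(LOCUS_LENGTHS),
        "S": pd.Series(dict(zip(LOCI, [
            10, 13, 15, 3, 10, 4, 12, 4, 5, 7, 10, 8,
            27, 2, 15, 10, 4, 7, 1, 8, 6, 15, 5, 2,
        ]))),
        "Nh": pd.Series(dict(zip(LOCI, [
            5, 8, 17, 5, 5, 5, 8, 9, 5, 6, 7, 14,
            7, 3, 9, 17, 7, 5, 2, 9, 5, 10, 10, 3,
        ]))),
        "pi": pd.Series(dict(zip(LOCI, [
            0.0064, 0.0078, 0.0079, 0.0033, 0.0077, 0.0042, 0.0114, 0.0061,
            0.0029, 0.0060, 0.0129, 0.0068, 0.0411, 0.0018, 0.0078, 0.0062,
            0.0033, 0.0062, 0.0183, 0.0095, 0.0151, 0.0104, 0.0062, 0.0024,
        ]))),
    }
)

_GROUP_COLUMNS = ("S", "pi", "D", "Rm")

_PALE = [
    (9, 0.0102, 0.454, 0), (3, 0.0042, 1.152, 0), (10, 0.0104, -0.754, 4),
    (2, 0.0030, 1.642, 0), (9, 0.0167, 1.310, 0), (1, 0.0027, 1.303, 0),
    (11, 0.0099, -0.281, 1), (5, 0.0072, 0.931, 2), (4, 0.0041, -0.943, 0),
    (4, 0.0053, 0.264, 0), (9, 0.0251, 1.219, 0), (8, 0.0121, 0.026, 1),
    (25, 0.0603, 1.585, 0), (2, 0.0043, 1.642, 0), (6, 0.0065, 1.455, 0),
    (4, 0.0048, 0.204, 1), (2, 0.0027, 0.222, 0), (7, 0.0065, -0.584, 0),
    (2, 0.0136, -0.184, 0), (5, 0.0116, 0.981, 0), (7, 0.0096, -0.318, 0),
    (13, 0.0162, -0.458, 1), (4, 0.0087, 0.143, 1), (2, 0.0032, 0.120, 0),
]

_CULTIVATED = [
    (4, 0.0040, 1.126, 0), (14, 0.0089, -0.343, 1), (11, 0.0070, -0.739, 4),
    (4, 0.0049, 1.967, 1), (3, 0.0042, 0.959, 0), (6, 0.0056, -0.344, 0),
    (10, 0.0105, 1.458, 0), (4, 0.0056, 0.992, 2), (3, 0.0026, -0.158, 0),
    (7, 0.0063, 0.200, 0), (6, 0.0078, 0.627, 0), (7, 0.0055, -1.013, 3),
    (25, 0.0353, 0.503, 0), (2, 0.0008, -1.102, 0), (15, 0.0088, -0.202, 0),
    (9, 0.0063, -0.510, 3), (4, 0.0034, -0.041, 2), (5, 0.0051, 1.057, 0),
    (1, 0.0125, 0.976, 0), (7, 0.0068, -0.158, 1), (6, 0.0161, 2.778, 0),
    (8, 0.0081, -0.286, 0), (5, 0.0054, -0.605, 2), (1, 0.0023, 1.643, 0),
]

_DEHISCENT = [
    (0, 0.0000, None, None), (9, 0.0116, 0.545, 0), (10, 0.0140, 0.138, 0),
    (2, 0.0019, -0.448, 0), (3, 0.0053, 0.458, 0), (3, 0.0033, -1.448, 0),
    (7, 0.0101, 1.411, 0), (2, 0.0026, 0.069, 0), (2, 0.0026, -0.448, 0),
    (3, 0.0056, 1.601, 0), (0, 0.0000, None, None), (1, 0.0011, -1.055, 0),
    (25, 0.0522, 0.248, 0), (1, 0.0017, 0.334, 0), (8, 0.0074, 0.258, 0),
    (9, 0.0122, -0.060, 1), (3, 0.0027, -1.448, 0), (4, 0.0065, 1.697, 0),
    (4, 0.0108, 0.182, 1), (3, 0.0040, -0.813, 0), (1, 0.0025, 1.444, 0),
    (6, 0.0110, 1.022, 0), (4, 0.0094, 0.081, 1), (1, 0.0025, 1.444, 0),
]

_FIBER = [
    (0, 0.0000, None, None), (1, 0.0006, -1.112, 0), (2, 0.0027, 0.222, 0),
    (4, 0.0057, 1.7724, 0), (0, 0.0000, None, None), (3, 0.0042, -0.431, 0),
    (7, 0.0089, 0.900, 0), (6, 0.0064, -0.366, 1), (1, 0.0021, 1.303, 0),
    (3, 0.0037, 0.021, 0), (0, 0.0000, None, None), (4, 0.0033, -1.245, 0),
    (0, 0.0000, None, None), (0, 0.0000, None, None), (6, 0.0040, -1.103, 0),
    (5, 0.0046, -0.783, 1), (2, 0.0039, 1.743, 1), (0, 0.0000, None, None),
    (1, 0.0029, 0.820, 0), (0, 0.0000, None, None), (7, 0.0157, 2.383, 0),
    (5, 0.0063, -0.329, 0), (2, 0.0024, -1.401, 0), (1, 0.0021, 1.303, 0),
]

_OIL = [
    (0, 0.0000, None, None), (6, 0.0081, 1.108, 0), (3, 0.0032, -0.507, 0),
    (4, 0.0059, 1.953, 0), (1, 0.0008, -1.112, 0), (1, 0.0021, 0.820, 0),
    (7, 0.0068, 0.025, 0), (3, 0.0042, -0.130, 0), (1, 0.0021, 1.303, 0),
    (7, 0.0094, 0.329, 0), (1, 0.0009, -1.112, 0), (9, 0.0115, 0.026, 3),
    (22, 0.0217, -2.053, 0), (0, 0.0000, None, None), (8, 0.0100, 2.093, 0),
    (2, 0.0026, 0.526, 1), (2, 0.0020, -0.691, 0), (5, 0.0054, 0.024, 0),
    (0, 0.0000, None, None), (0, 0.0000, None, None), (7, 0.0154, 2.041, 0),
    (4, 0.0038, -1.667, 0), (2, 0.0040, -0.184, 0), (1, 0.0022, 1.464, 0),
]

_WINTER = [
    (1, 0.0006, -1.112, 0), (5, 0.0071, 1.334, 1), (3, 0.0039, 0.097, 0),
    (4, 0.0055, 1.591, 0), (1, 0.0019, 0.820, 0), (4, 0.0043, -1.245, 0),
    (7, 0.0089, 1.356, 0), (6, 0.0073, 0.198, 2), (1, 0.0018, 0.820, 0),
    (4, 0.0052, 0.143, 0), (0, 0.0000, None, None), (7, 0.0091, -0.348, 0),
    (22, 0.0578, 2.405, 0), (2, 0.0016, -1.401, 0), (11, 0.0089, -0.255, 0),
    (4, 0.0053, 0.686, 1), (4, 0.0044, -0.521, 0), (5, 0.0054, 0.024, 0),
    (0, 0.0000, None, None), (4, 0.0055, -0.400, 0), (6, 0.0175, 2.1482, 0),
    (4, 0.0037, -1.245, 0), (2, 0.0042, 0.019, 0), (1, 0.0021, 1.303, 0),
]


def _frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(_GROUP_COLUMNS), index=LOCI)
    df.insert(0, "L", pd.Series(LOCUS_LENGTHS))
    return df


#: Per-group per-locus tables: S, per-site pi, Tajima's D, Rm (None = 'nd').
GROUP_TABLES: dict[str, pd.DataFrame] = {
    "pale": _frame(_PALE),
    "cultivated": _frame(_CULTIVATED),
    "dehiscent": _frame(_DEHISCENT),
    "fiber": _frame(_FIBER),
    "oil": _frame(_OIL),
    "winter": _frame(_WINTER),
}

#: Printed per-group totals over the concatenated 24 loci.
GROUP_TOTALS = {
    "pale": {"S": 154, "pi": 0.0097, "Rm": 11, "n": 10},
    "cultivated": {"S": 167, "pi": 0.0071, "Rm": 19, "n": 38},
    "dehiscent": {"S": 111, "pi": 0.0071, "Rm": 3, "n": 8},
    "fiber": {"S": 60, "pi": 0.0034, "Rm": 3, "n": 10},
    "oil": {"S": 96, "pi": 0.0053, "Rm": 4, "n": 10},
    "winter": {"S": 108, "pi": 0.0069, "Rm": 4, "n": 10},
}

#: Reported bottleneck intensities (grid MLE) with 2-unit-drop intervals.
BOTTLENECK_INTENSITY = {
    "dehiscent": {"alpha": 1.5, "ci": (1.2, 1.7)},
    "fiber": {"alpha": 1.5, "ci": (1.2, 1.9)},
    "oil": {"alpha": 2.0, "ci": (1.1, 2.4)},
    "winter": {"alpha": 1.5, "ci": (1.0, 3.0)},
    "cultivated": {"alpha": 1.5, "ci": (1.0, 1.9)},
}

GROUP_SIZES = {"pale": 10, "dehiscent": 8, "fiber": 10, "oil": 10, "winter": 10}


def printed_wild_params(rho: float = 0.0) -> dict[str, dict]:
    """Per-locus bottleneck inputs derived from the printed wild-group table.

    theta_wild is Watterson's estimate from the pale-flax segregating sites
    (n = 10), total over the locus; per-locus 4Nc was never published, so
    ``rho`` defaults to 0 for table-driven runs.
    """
    a1 = sum(1.0 / i for i in range(1, 10))
    pale = GROUP_TABLES["pale"]
    return {
        lid: {
            "theta_wild": float(pale.loc[lid, "S"]) / a1,
            "rho": rho,
            "L": int(pale.loc[lid, "L"]),
        }
        for lid in LOCI
    }


def printed_observed_k(group: str) -> dict[str, float]:
    """Per-locus observed diversity (total over locus) for one group.

    The printed per-site pi is scaled by the contig length to the same
    total-pairwise-differences scale the simulator reports.
    """
    tab = GROUP_TABLES[group]
    return {lid: float(tab.loc[lid, "pi"]) * float(tab.loc[lid, "L"]) for lid in LOCI}
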