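"""Study-shaped synthetic datasets with known truth.

The generator emulates the structure of the flax resequencing survey: 24
unlinked loci (lengths taken from the published contig-length column), a
wild group of 10 samples drawn from the neutral coalescent at a configured
ancestral diversity, and four domesticated groups (8/10/10/10 samples)
drawn independently from the instantaneous-size-change bottleneck model at
per-group intensities alpha.  Mutations are placed on the genealogy under
an infinite-sites emulation: each mutation occupies a distinct column when
possible, drawn uniformly over the locus, and substitutes a uniformly
chosen alternative base on the carriers of the mutation.

Every group's genealogy is simulated independently per locus, so the
generator does not model shared wild/domesticated ancestry or migration;
see the methods note for what that implies for downstream tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import coalescent
from .datasets import LOCI, LOCUS_LENGTHS
from .errors import InputError
from .seq_io import (
    GroupPanel,
    LocusAlignment,
    MultiLocusDataset,
    SequenceRecord,
    write_fasta_alignment,
    write_sample_panel,
)

GENERATOR_VERSION = "1"

_BASES = np.array(list("ACGT"))


@dataclass
class StudyConfig:
    """Shape and truth parameters of a synthetic study."""

    locus_lengths: dict[str, int] = field(
        default_factory=lambda: dict(LOCUS_LENGTHS)
    )
    wild_size: int = 10
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"dehiscent": 8, "fiber": 10, "oil": 10, "winter": 10}
    )
    theta_wild_per_site: float = 0.01
    rho_per_locus: float = 0.0
    alpha_per_group: dict[str, float] = field(
        default_factory=lambda: {"dehiscent": 1.5, "fiber": 1.5, "oil": 2.0, "winter": 1.5}
    )
    N_a: int = 30_000
    t: int = 9_000
    gap_rate: float = 0.0     # per-column probability of planting a gap column
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wild_size < 4 or any(s < 4 for s in self.group_sizes.values()):
            raise InputError("all group sizes must be >= 4")
        if any(a < 1 for a in self.alpha_per_group.values()):
            raise InputError("alpha must be >= 1")
        if any(l < 1 for l in self.locus_lengths.values()):
            raise InputError("locus lengths must be >= 1")
        if set(self.alpha_per_group) != set(self.group_sizes):
            raise InputError("alpha_per_group and group_sizes must list the same groups")

    @property
    def change_time(self) -> float:
        return self.t / (2.0 * self.N_a)


def _simulate_group_alignment(
    locus_id: str,
    length: int,
    sample_ids: list[str],
    theta: float,
    alpha: float,
    change_time: float,
    rng: np.random.Generator,
    ancestral: np.ndarray,
) -> list[SequenceRecord]:
    """Sequences for one group at one locus from one genealogy.

    All groups at a locus substitute away from the same ancestral sequence,
    so cross-group differences reflect only each group's own mutations.
    """
    n = len(sample_ids)
    muts = coalescent.simulate_mutations(
        n, theta, alpha=alpha, change_time=change_time, rng=rng
    )
    seqs = np.tile(ancestral, (n, 1))
    used: set[int] = set()
    for carriers in muts:
        free = [c for c in range(length) if c not in used]
        if free:
            col = int(rng.choice(free))
            used.add(col)
        else:  # more mutations than columns: recurrent hit allowed
            col = int(rng.integers(length))
        alt = rng.choice([b for b in "ACGT" if b != ancestral[col]])
        for s in carriers:
            seqs[s, col] = alt
    return [
        SequenceRecord(sample_ids[i], "".join(seqs[i])) for i in range(n)
    ]


def generate_study(
    config: StudyConfig, out_dir: str | Path | None = None
) -> MultiLocusDataset:
    """Generate a full synthetic study; optionally write it to disk.

    Writes one FASTA per locus, a panel TSV and a flat-text truth manifest
    when ``out_dir`` is given.  The same config (including seed) regenerates
    byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    wild_ids = [f"P{i+1}" for i in range(config.wild_size)]
    group_ids = {
        g: [f"{g[:1].upper()}{i+1}" for i in range(sz)]
        for g, sz in config.group_sizes.items()
    }
    assignment: dict[str, str] = {s: "pale" for s in wild_ids}
    for g, ids in group_ids.items():
        assignment.update({s: g for s in ids})
    panel = GroupPanel(assignment)

    loci: dict[str, LocusAlignment] = {}
    for locus_id, length in config.locus_lengths.items():
        theta = config.theta_wild_per_site * length
        ancestral = rng.choice(_BASES, size=length)
        records = _simulate_group_alignment(
            locus_id, length, wild_ids, theta, 1.0, 0.0, rng, ancestral
        )
        for g, ids in group_ids.items():
            records.extend(
                _simulate_group_alignment(
                    locus_id,
                    length,
                    ids,
                    theta,
                    config.alpha_per_group[g],
                    config.change_time,
                    rng,
                    ancestral,
                )
            )
        if config.gap_rate > 0:
            records = _inject_gaps(records, length, config.gap_rate, rng)
        loci[locus_id] = LocusAlignment(locus_id, records)
    dataset = MultiLocusDataset(loci, panel)
    if out_dir is not None:
        _write_study(dataset, config, Path(out_dir))
    return dataset


def _inject_gaps(
    records: list[SequenceRecord],
    length: int,
    rate: float,
    rng: np.random.Generator,
) -> list[SequenceRecord]:
    """Plant whole-column gaps in one random record per selected column."""
    cols = np.flatnonzero(rng.random(length) < rate)
    if cols.size == 0:
        return records
    arr = np.array([list(r.residues) for r in records])
    for c in cols:
        arr[rng.integers(len(records)), c] = "-"
    return [
        SequenceRecord(r.sample_id, "".join(row)) for r, row in zip(records, arr)
    ]


def _write_study(dataset: MultiLocusDataset, config: StudyConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for locus_id, aln in dataset.loci.items():
        safe = locus_id.replace("/", "_")
        write_fasta_alignment(aln, out / f"{safe}.fasta")
    write_sample_panel(dataset.panel, out / "panel.tsv")
    lines = [
        f"generator_version\t{GENERATOR_VERSION}",
        f"seed\t{config.seed}",
        f"theta_wild_per_site\t{config.theta_wild_per_site}",
        f"rho_per_locus\t{config.rho_per_locus}",
        f"N_a\t{config.N_a}",
        f"t\t{config.t}",
        f"gap_rate\t{config.gap_rate}",
    ]
    for g in sorted(config.alpha_per_group):
        lines.append(f"alpha_{g}\t{config.alpha_per_group[g]}")
    for locus_id in config.locus_lengths:
        lines.append(f"length_{locus_id}\t{config.locus_lengths[locus_id]}")
    (out / "truth_manifest.tsv").write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Deterministic hand-crafted toy fixtures
# --------------------------------------------------------------------------

_TOYS: dict[str, list[tuple[str, str]]] = {
    # all four gametes at columns 0 and 1
    "four-gamete": [("s1", "AA"), ("s2", "AG"), ("s3", "TA"), ("s4", "TG")],
    "all-identical": [(f"s{i}", "ACGTACGT") for i in range(1, 6)],
    # four singleton variants on distinct sequences, one shared background
    "singleton-excess": [
        ("s1", "TCGTACGTAC"),
        ("s2", "AGGTACGTAC"),
        ("s3", "ACTTACGTAC"),
        ("s4", "ACGAACGTAC"),
        ("s5", "ACGTACGTAC"),
        ("s6", "ACGTACGTAC"),
    ],
    # two internally identical, mutually distant groups (phi_st = 1)
    "two-group-divergent": [
        ("a1", "AAAAAAAA"),
        ("a2", "AAAAAAAA"),
        ("a3", "AAAAAAAA"),
        ("b1", "GGGGGGGG"),
        ("b2", "GGGGGGGG"),
        ("b3", "GGGGGGGG"),
    ],
    # two sequences differing only at a gap-bearing column
    "gap-column": [("s1", "ACG-ACGT"), ("s2", "ACGTACGT"), ("s3", "ACGTACGT")],
}


def generate_toy(kind: str) -> LocusAlignment:
    """Return one of the named deterministic fixtures."""
    try:
        rows = _TOYS[kind]
    except KeyError:
        raise InputError(
            f"unknown toy {kind!r}; available: {sorted(_TOYS)}"
        ) from None
    return LocusAlignment(kind, [SequenceRecord(s, r) for s, r in rows])
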