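"""Aligned multi-FASTA loci, sample panels, and multilocus dataset assembly.

A study is organised as one aligned FASTA per locus (equal-length sequences,
one per accession) plus a tab-separated panel assigning every accession to a
group (e.g. the wild progenitor ``pale`` and the domesticated groups
``dehiscent``, ``fiber``, ``oil``, ``winter``).  All coordinates are 0-based,
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import AlignmentError, ConsistencyError, FormatError

#: Residues accepted in an alignment: the four nucleotides, IUPAC ambiguity
#: codes, alignment gap and missing data.
VALID_RESIDUES = frozenset("ACGTRYSWKMBDHVN-")
#: Residues treated as observed data by site-based statistics.
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence for one accession at one locus."""

    sample_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise FormatError("sample_id must be non-empty")
        if not self.residues:
            raise FormatError(f"empty sequence for sample {self.sample_id!r}")
        bad = set(self.residues.upper()) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"invalid residues {sorted(bad)} in sample {self.sample_id!r}"
            )
        object.__setattr__(self, "residues", self.residues.upper())


class LocusAlignment:
    """An equal-length set of aligned sequences for a single locus.

    Parameters
    ----------
    locus_id:
        Label for the locus (e.g. a primer-pair name).
    records:
        Sequence records; all must share the same length and have unique
        sample ids.  File order is preserved.
    """

    def __init__(self, locus_id: str, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise AlignmentError(f"locus {locus_id!r}: no records")
        length = len(records[0].residues)
        seen: set[str] = set()
        for rec in records:
            if len(rec.residues) != length:
                raise AlignmentError(
                    f"locus {locus_id!r}: sequence {rec.sample_id!r} has length "
                    f"{len(rec.residues)}, expected {length}"
                )
            if rec.sample_id in seen:
                raise FormatError(
                    f"locus {locus_id!r}: duplicate sample_id {rec.sample_id!r}"
                )
            seen.add(rec.sample_id)
        self.locus_id = locus_id
        self.records = records
        self.length = length

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def matrix(self) -> np.ndarray:
        """Return the alignment as an (n, L) array of single-byte strings."""
        return np.array([list(r.residues) for r in self.records], dtype="U1")

    def subset(self, sample_ids: Iterable[str]) -> "LocusAlignment":
        """Restrict to the given samples (order follows the argument)."""
        by_id = {r.sample_id: r for r in self.records}
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise ConsistencyError(
                f"locus {self.locus_id!r}: samples not present: {missing}"
            )
        return LocusAlignment(self.locus_id, [by_id[s] for s in sample_ids])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LocusAlignment({self.locus_id!r}, n={self.n}, L={self.length})"
        )


@dataclass
class GroupPanel:
    """Mapping of sample ids to group labels."""

    assignment: dict[str, str]

    @property
    def groups(self) -> dict[str, list[str]]:
        """Group label -> member sample ids, in panel order."""
        out: dict[str, list[str]] = {}
        for sid, grp in self.assignment.items():
            out.setdefault(grp, []).append(sid)
        return out

    @property
    def group_sizes(self) -> dict[str, int]:
        return {g: len(m) for g, m in self.groups.items()}

    def members(self, group: str) -> list[str]:
        try:
            return self.groups[group]
        except KeyError:
            raise ConsistencyError(f"unknown group {group!r}") from None


@dataclass
class MultiLocusDataset:
    """A collection of per-locus alignments sharing one sample set."""

    loci: dict[str, LocusAlignment]
    panel: GroupPanel = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ConsistencyError("dataset has no loci")
        ids0 = None
        for locus_id, aln in self.loci.items():
            ids = set(aln.sample_ids)
            if ids0 is None:
                ids0 = ids
            elif ids != ids0:
                raise ConsistencyError(
                    f"locus {locus_id!r} sample set differs from the rest"
                )
        if self.panel is not None:
            panel_ids = set(self.panel.assignment)
            if panel_ids != ids0:
                raise ConsistencyError(
                    "panel sample ids do not match dataset sample ids: "
                    f"panel-only={sorted(panel_ids - ids0)[:5]}, "
                    f"data-only={sorted(ids0 - panel_ids)[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        first = next(iter(self.loci.values()))
        return first.sample_ids

    @property
    def locus_ids(self) -> list[str]:
        return list(self.loci)

    def subset(self, sample_ids: Iterable[str]) -> "MultiLocusDataset":
        sample_ids = list(sample_ids)
        loci = {lid: aln.subset(sample_ids) for lid, aln in self.loci.items()}
        panel = None
        if self.panel is not None:
            panel = GroupPanel({s: self.panel.assignment[s] for s in sample_ids})
        return MultiLocusDataset(loci, panel)

    def group_dataset(self, group: str) -> "MultiLocusDataset":
        """Restrict the dataset to the members of one panel group."""
        if self.panel is None:
            raise ConsistencyError("dataset has no panel")
        return self.subset(self.panel.members(group))


def read_fasta_alignment(path: str | Path, locus_id: str) -> LocusAlignment:
    """Read one aligned FASTA file into a :class:`LocusAlignment`.

    The description after the first whitespace of each header is ignored;
    wrapped and unwrapped sequence lines are both accepted.  Residues are
    upper-cased on read.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return LocusAlignment(locus_id, records)


def write_fasta_alignment(aln: LocusAlignment, path: str | Path, wrap: int = 60) -> None:
    """Write an alignment as FASTA, wrapping sequence lines at ``wrap`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in aln.records:
            fh.write(f">{rec.sample_id}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


def load_sample_panel(path: str | Path) -> GroupPanel:
    """Load a tab-separated panel with header columns ``sample_id`` and ``group``."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty panel file")
    header = lines[0].rstrip("\n").split("\t")
    try:
        i_sid = header.index("sample_id")
        i_grp = header.index("group")
    except ValueError:
        raise FormatError(
            f"{path}: header must contain 'sample_id' and 'group', got {header}"
        ) from None
    assignment: dict[str, str] = {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) <= max(i_sid, i_grp):
            raise FormatError(f"{path}:{ln}: expected {len(header)} fields")
        sid, grp = parts[i_sid].strip(), parts[i_grp].strip()
        if not sid:
            raise FormatError(f"{path}:{ln}: empty sample_id")
        if not grp:
            raise FormatError(f"{path}:{ln}: empty group for sample {sid!r}")
        if sid in assignment:
            raise FormatError(f"{path}:{ln}: duplicate sample_id {sid!r}")
        assignment[sid] = grp
    if not assignment:
        raise FormatError(f"{path}: no samples in panel")
    return GroupPanel(assignment)


def write_sample_panel(panel: GroupPanel, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, grp in panel.assignment.items():
            fh.write(f"{sid}\t{grp}\n")


def load_dataset(
    fasta_dir: str | Path,
    panel_path: str | Path | None = None,
    pattern: str = "*.fasta",
) -> MultiLocusDataset:
    """Assemble a dataset from a directory of per-locus FASTA files.

    The locus id is the file stem.  Loci are ordered by file name.
    """
    fasta_dir = Path(fasta_dir)
    paths = sorted(fasta_dir.glob(pattern))
    if not paths:
        raise FormatError(f"no FASTA files matching {pattern!r} in {fasta_dir}")
    loci = {p.stem: read_fasta_alignment(p, p.stem) for p in paths}
    panel = load_sample_panel(panel_path) if panel_path is not None else None
    return MultiLocusDataset(loci, panel)


def concatenate(
    dataset: MultiLocusDataset,
    locus_order: Sequence[str] | None = None,
) -> tuple[LocusAlignment, dict[str, tuple[int, int]]]:
    """Concatenate per-locus alignments into one long alignment.

    Returns the concatenated alignment plus an offset table mapping each
    locus to its half-open ``[start, end)`` column interval.  Sample order
    follows the first locus; the concatenated length is exactly the sum of
    the locus lengths.
    """
    if locus_order is None:
        locus_order = dataset.locus_ids
    unknown = [l for l in locus_order if l not in dataset.loci]
    if unknown:
        raise ConsistencyError(f"unknown loci in locus_order: {unknown}")
    sample_ids = dataset.sample_ids
    parts: dict[str, list[str]] = {s: [] for s in sample_ids}
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for lid in locus_order:
        aln = dataset.loci[lid]
        by_id = {r.sample_id: r.residues for r in aln.records}
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise ConsistencyError(f"locus {lid!r} missing samples {missing}")
        for s in sample_ids:
            parts[s].append(by_id[s])
        offsets[lid] = (pos, pos + aln.length)
        pos += aln.length
    records = [SequenceRecord(s, "".join(parts[s])) for s in sample_ids]
    return LocusAlignment("concatenated", records), offsets


def to_biopython(aln: LocusAlignment) -> list[_BioSeqRecord]:
    """Convert to Biopython SeqRecords (for interoperability)."""
    return [
        _BioSeqRecord(Seq(r.residues), id=r.sample_id, description="")
        for r in aln.records
    ]
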