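"""Homopolymeric amino-acid repeat (AAR) scanning.

Proteins carrying a run of at least ``min_run_length`` identical residues
(default 4) of any one of the 20 standard amino acids form the "polyX"
group for that residue X.  A proteome therefore defines 20 (possibly
empty, possibly overlapping) protein groups, which are the unit of all
downstream connectivity and enrichment analyses.

Coordinates are 1-based inclusive throughout, matching the convention of
NCBI CDD domain tables so that repeat and domain intervals are directly
comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "STANDARD_RESIDUES",
    "ProteinRecord",
    "RepeatOccurrence",
    "PolyXGroup",
    "read_fasta",
    "uniprot_accession",
    "find_homopolymer_runs",
    "scan_proteome",
    "build_polyx_groups",
    "write_repeats_tsv",
    "write_groups_tsv",
]

#: The 20 standard amino acids, one-letter code, alphabetical.
STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_RESIDUES)


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: a unique identifier and its residue string."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class RepeatOccurrence:
    """One maximal homopolymer run: ``sequence[start..end]`` (1-based,
    inclusive) is ``residue`` repeated, and the flanking positions, where
    they exist, hold a different letter."""

    protein_id: str
    residue: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PolyXGroup:
    """The set of proteins containing at least one qualifying run of
    ``residue``."""

    residue: str
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


def uniprot_accession(header: str) -> str:
    """Extract the accession from a UniProt-style ``db|ACC|NAME`` header;
    fall back to the first whitespace-delimited token."""
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return token


def read_fasta(
    path: str | Path,
    id_extractor: Callable[[str], str] | None = None,
) -> list[ProteinRecord]:
    """Read a proteome FASTA into :class:`ProteinRecord` objects.

    Parameters
    ----------
    path
        FASTA file; multi-line sequences are concatenated and upper-cased.
    id_extractor
        Optional callable mapping the full header line (without ``>``) to
        the record id.  Default: the header token up to the first
        whitespace.  Use :func:`uniprot_accession` for ``sp|ACC|NAME``
        headers.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        On duplicate ids or an entry with an empty sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = id_extractor(rec.description) if id_extractor else rec.id
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA entry {name!r}")
        if name in seen:
            raise ValueError(f"duplicate protein id {name!r} in {path}")
        seen.add(name)
        records.append(ProteinRecord(id=name, sequence=seq))
    return records


def find_homopolymer_runs(
    sequence: str, min_run_length: int = 4
) -> list[tuple[str, int, int]]:
    """All maximal runs of identical standard residues with length >=
    ``min_run_length``, as ``(residue, start, end)`` with 1-based inclusive
    coordinates, ordered by start.

    Runs of non-standard letters (X, U, B, Z, ``*``, gaps, ...) are never
    reported, and a non-standard letter breaks any run it interrupts.
    """
    if min_run_length < 1:
        raise ValueError("min_run_length must be >= 1")
    runs: list[tuple[str, int, int]] = []
    pos = 1
    for ch, grp in itertools.groupby(sequence):
        n = sum(1 for _ in grp)
        if n >= min_run_length and ch in _STANDARD_SET:
            runs.append((ch, pos, pos + n - 1))
        pos += n
    return runs


def scan_proteome(
    proteome: Iterable[ProteinRecord], min_run_length: int = 4
) -> dict[str, list[RepeatOccurrence]]:
    """Map protein id -> all its qualifying runs (possibly empty list
    omitted: only proteins with at least one run appear)."""
    out: dict[str, list[RepeatOccurrence]] = {}
    for rec in proteome:
        runs = find_homopolymer_runs(rec.sequence, min_run_length)
        if runs:
            out[rec.id] = [
                RepeatOccurrence(rec.id, res, s, e) for res, s, e in runs
            ]
    return out


def build_polyx_groups(
    proteome: Sequence[ProteinRecord],
    min_run_length: int = 4,
    occurrences: Mapping[str, list[RepeatOccurrence]] | None = None,
) -> dict[str, PolyXGroup]:
    """Build the 20 polyX groups (every standard residue present as a key,
    possibly with an empty member set).

    A protein belongs to group X iff it has >= 1 maximal run of X of
    length >= ``min_run_length``; membership in several groups is allowed.
    Pass a precomputed ``occurrences`` map (from :func:`scan_proteome`) to
    avoid rescanning.
    """
    if not proteome:
        raise ValueError("proteome must be non-empty")
    if occurrences is None:
        occurrences = scan_proteome(proteome, min_run_length)
    members: dict[str, set[str]] = {res: set() for res in STANDARD_RESIDUES}
    for pid, occs in occurrences.items():
        for occ in occs:
            members[occ.residue].add(pid)
    return {
        res: PolyXGroup(residue=res, members=frozenset(ids))
        for res, ids in members.items()
    }


def write_repeats_tsv(
    occurrences: Mapping[str, list[RepeatOccurrence]], path: str | Path
) -> None:
    """Write one row per run: protein_id, residue, start, end, length
    (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tresidue\tstart\tend\tlength\n")
        for pid in sorted(occurrences):
            for occ in sorted(occurrences[pid]):
                fh.write(
                    f"{occ.protein_id}\t{occ.residue}\t{occ.start}\t"
                    f"{occ.end}\t{occ.length}\n"
                )


def write_groups_tsv(groups: Mapping[str, PolyXGroup], path: str | Path) -> None:
    """Write one row per residue: residue, n_proteins, comma-joined members."""
    with open(path, "w") as fh:
        fh.write("residue\tn_proteins\tmembers\n")
        for res in STANDARD_RESIDUES:
            grp = groups.get(res, PolyXGroup(res, frozenset()))
            fh.write(f"{res}\t{grp.size}\t{','.join(sorted(grp.members))}\n")
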