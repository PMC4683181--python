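"""Positional overlap of repeats and protein domains.

For a (repeat residue, domain) pair, each protein carrying both is
checked for any (run, domain-instance) pair whose 1-based inclusive
intervals share at least ``min_overlap`` residues (default 4).  The
summary is the fraction of such proteins, reported with the bands used
for qualitative description: no overlap at all, overlap in under a
quarter of the proteins, or in 25-100% of them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .enrichment import DomainAnnotation, EnrichmentRecord
from .repeats import RepeatOccurrence

__all__ = [
    "interval_overlap_length",
    "OverlapSummary",
    "overlap_summary",
    "overlap_all",
    "write_overlap_tsv",
]


def interval_overlap_length(
    a_start: int, a_end: int, b_start: int, b_end: int
) -> int:
    """Number of positions shared by two 1-based inclusive intervals:
    ``max(0, min(ends) - max(starts) + 1)``."""
    if a_start > a_end or b_start > b_end:
        raise ValueError("malformed interval (start > end)")
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


@dataclass(frozen=True)
class OverlapSummary:
    """Overlap outcome for one (residue, domain) pair.

    ``n_total`` proteins carry both the repeat and the domain;
    ``n_overlap`` of them have some run/domain-instance pair overlapping
    by at least the threshold.  ``fraction`` is None when no protein
    carries both (undefined)."""

    residue: str
    domain_id: str
    n_total: int
    n_overlap: int

    @property
    def fraction(self) -> float | None:
        if self.n_total == 0:
            return None
        return self.n_overlap / self.n_total

    @property
    def band(self) -> str:
        if self.n_total == 0:
            return "undefined"
        if self.n_overlap == 0:
            return "none"
        if self.fraction < 0.25:  # type: ignore[operator]
            return "partial(<25%)"
        return "25-100%"


def overlap_summary(
    residue: str,
    domain_id: str,
    repeats: Iterable[RepeatOccurrence],
    annotations: Iterable[DomainAnnotation],
    min_overlap: int = 4,
) -> OverlapSummary:
    """Per-protein yes/no overlap of the residue's runs with the domain's
    instances, aggregated over all proteins carrying both.

    A protein counts as overlapping if ANY single (run, instance) pair
    shares >= ``min_overlap`` positions; overlap is never summed across
    runs.  Annotations without coordinates are ignored (they cannot be
    positioned).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    runs_by_protein: dict[str, list[RepeatOccurrence]] = {}
    for occ in repeats:
        if occ.residue == residue:
            runs_by_protein.setdefault(occ.protein_id, []).append(occ)
    doms_by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        if ann.domain_id == domain_id and ann.has_coordinates:
            doms_by_protein.setdefault(ann.protein_id, []).append(ann)

    both = sorted(set(runs_by_protein) & set(doms_by_protein))
    n_overlap = 0
    for pid in both:
        hit = any(
            interval_overlap_length(occ.start, occ.end, ann.start, ann.end)
            >= min_overlap
            for occ in runs_by_protein[pid]
            for ann in doms_by_protein[pid]
        )
        if hit:
            n_overlap += 1
    return OverlapSummary(
        residue=residue, domain_id=domain_id,
        n_total=len(both), n_overlap=n_overlap,
    )


def overlap_all(
    pairs: Iterable[tuple[str, str]] | Sequence[EnrichmentRecord],
    repeats: Iterable[RepeatOccurrence],
    annotations: Sequence[DomainAnnotation],
    min_overlap: int = 4,
    significant_only: bool = True,
) -> list[OverlapSummary]:
    """Overlap summaries for a collection of (residue, domain) pairs.

    ``pairs`` may be explicit tuples or enrichment records; with records
    and ``significant_only`` (the default) only pairs flagged significant
    by the enrichment step are analyzed.
    """
    wanted: list[tuple[str, str]] = []
    for p in pairs:
        if isinstance(p, EnrichmentRecord):
            if significant_only and not p.significant:
                continue
            wanted.append((p.residue, p.domain_id))
        else:
            wanted.append(tuple(p))  # type: ignore[arg-type]
    repeats = list(repeats)
    seen: set[tuple[str, str]] = set()
    out: list[OverlapSummary] = []
    for residue, dom in wanted:
        if (residue, dom) in seen:
            continue
        seen.add((residue, dom))
        out.append(overlap_summary(residue, dom, repeats, annotations, min_overlap))
    return sorted(out, key=lambda s: (s.residue, s.domain_id))


def write_overlap_tsv(summaries: Sequence[OverlapSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tdomain_id\tn_total\tn_overlap\tfraction\tband\n")
        for s in summaries:
            frac = "NA" if s.fraction is None else f"{s.fraction:.10g}"
            fh.write(
                f"{s.residue}\t{s.domain_id}\t{s.n_total}\t{s.n_overlap}\t"
                f"{frac}\t{s.band}\n"
            )
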