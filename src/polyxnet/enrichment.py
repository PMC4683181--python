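"""Domain over-representation in polyX protein groups.

For every domain annotated on at least one group member, a one-sided
hypergeometric test asks whether the domain occurs in the group more
often than expected from its background frequency; p-values are adjusted
per group with Benjamini-Hochberg.  The conservative EASE variant
(observed overlap decremented by one before taking the tail, as popular
annotation servers do) is available as an option.

Coiled-coil status, when available, is supplied as an ordinary domain
annotation; no keyword system exists here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DomainAnnotation",
    "EnrichmentRecord",
    "read_domain_annotations",
    "hypergeom_tail",
    "hypergeom_enrichment",
    "bh_adjust",
    "enrich_all_groups",
    "write_enrichment_tsv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class DomainAnnotation:
    """One domain instance on one protein.  Coordinates are 1-based
    inclusive (CDD convention) and optional: enrichment needs only the
    (protein, domain) pair, the overlap analysis needs positions."""

    protein_id: str
    domain_id: str
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if (self.start is None) != (self.end is None):
            raise ValueError("start and end must be given together")
        if self.start is not None and self.start > self.end:  # type: ignore[operator]
            raise ValueError(
                f"start > end for {self.protein_id}/{self.domain_id}"
            )

    @property
    def has_coordinates(self) -> bool:
        return self.start is not None


@dataclass
class EnrichmentRecord:
    """One domain x one group: counts, fold enrichment, raw and
    BH-adjusted one-sided hypergeometric p."""

    residue: str
    domain_id: str
    k: int  # group proteins with the domain
    n: int  # group size within the background
    K: int  # background proteins with the domain
    N: int  # background size
    fold: float
    p_raw: float
    p_bh: float = float("nan")
    significant: bool = False


def read_domain_annotations(path: str | Path) -> list[DomainAnnotation]:
    """Read a TSV with required columns ``protein_id``, ``domain_id`` and
    optional ``start``, ``end`` (1-based inclusive).

    Rows with malformed coordinates (non-integer, or start > end) are
    rejected; the rejected count is logged.  Exact duplicates collapse to
    one record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "domain_id"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    has_coords = "start" in df.columns and "end" in df.columns
    records: set[DomainAnnotation] = set()
    n_rejected = 0
    for row in df.itertuples(index=False):
        pid = getattr(row, "protein_id")
        dom = getattr(row, "domain_id")
        if not isinstance(pid, str) or not isinstance(dom, str):
            n_rejected += 1
            continue
        start = end = None
        if has_coords:
            s_raw, e_raw = getattr(row, "start"), getattr(row, "end")
            if not (pd.isna(s_raw) and pd.isna(e_raw)):
                try:
                    start, end = int(s_raw), int(e_raw)
                except (TypeError, ValueError):
                    n_rejected += 1
                    continue
        try:
            records.add(DomainAnnotation(pid, dom, start, end))
        except ValueError:
            n_rejected += 1
    if n_rejected:
        logger.warning("%s: rejected %d malformed annotation rows", path, n_rejected)
    return sorted(records)


def hypergeom_tail(N: int, K: int, n: int, k: int, mode: str = "standard") -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``mode="ease"`` decrements k by one (never below 0) before taking the
    tail, the conservative variant used by popular annotation servers.
    ``k = 0`` (either mode) gives the whole tail, 1.
    """
    if mode not in ("standard", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    if not (0 <= k <= min(n, K) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError("inconsistent hypergeometric counts")
    k_eff = k if mode == "standard" else max(k - 1, 0)
    return float(min(stats.hypergeom.sf(k_eff - 1, N, K, n), 1.0))


def hypergeom_enrichment(
    group: Iterable[str],
    annotations: Sequence[DomainAnnotation],
    background: Iterable[str],
    mode: str = "standard",
) -> list[EnrichmentRecord]:
    """One-sided over-representation test for every domain present in the
    group.

    ``p_raw = P(X >= k)`` for X ~ Hypergeometric(N, K, n) with N the
    background size, K the background proteins carrying the domain, n the
    group size and k the group proteins carrying it.  ``mode="ease"``
    takes the tail from k - 1 (never below 0), the conservative variant.
    Domains annotated only outside the background are skipped with a
    warning.  Records are returned unadjusted (see :func:`bh_adjust`).
    """
    if mode not in ("standard", "ease"):
        raise ValueError(f"unknown mode {mode!r}")
    gset = frozenset(group)
    bset = frozenset(background)
    if not bset:
        raise ValueError("background must be non-empty")
    if not gset <= bset:
        raise ValueError("group must be a subset of the background")
    dom_background: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.protein_id in bset:
            dom_background.setdefault(ann.domain_id, set()).add(ann.protein_id)
    skipped = {
        ann.domain_id
        for ann in annotations
        if ann.domain_id not in dom_background
    }
    for dom in sorted(skipped):
        logger.warning("domain %s annotated only outside the background; skipped", dom)

    N, n = len(bset), len(gset)
    out: list[EnrichmentRecord] = []
    for dom in sorted(dom_background):
        carriers = dom_background[dom]
        k = len(carriers & gset)
        if k == 0:
            continue  # domain absent from the group: nothing to report
        K = len(carriers)
        p_raw = hypergeom_tail(N, K, n, k, mode=mode)
        fold = (k / n) / (K / N)
        out.append(
            EnrichmentRecord(
                residue="?", domain_id=dom, k=k, n=n, K=K, N=N,
                fold=fold, p_raw=p_raw,
            )
        )
    return out


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped
    at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(p, method="fdr_bh")[1]
    return [float(v) for v in adjusted]


def enrich_all_groups(
    groups: Mapping[str, Iterable[str]],
    annotations: Sequence[DomainAnnotation],
    background: Iterable[str],
    alpha: float = 0.05,
    mode: str = "standard",
) -> list[EnrichmentRecord]:
    """Per-group enrichment with per-group BH adjustment (each polyX
    group is its own BH family, mirroring one annotation-server run per
    protein list).  Returns records sorted by (residue, p_bh)."""
    bset = frozenset(background)
    out: list[EnrichmentRecord] = []
    for res in sorted(groups):
        members = frozenset(groups[res]) & bset
        if not members:
            continue
        records = hypergeom_enrichment(members, annotations, bset, mode=mode)
        if not records:
            continue
        adj = bh_adjust([r.p_raw for r in records])
        for rec, p_bh in zip(records, adj):
            rec.residue = res
            rec.p_bh = p_bh
            rec.significant = p_bh < alpha
        out.extend(sorted(records, key=lambda r: (r.p_bh, r.domain_id)))
    return out


def write_enrichment_tsv(
    records: Sequence[EnrichmentRecord],
    path: str | Path,
    category_map: Mapping[str, str] | None = None,
) -> None:
    """Write the enrichment table; an optional domain -> category map
    (e.g. protein/nucleic-acid/lipid binding) is echoed into a column."""
    with open(path, "w") as fh:
        cols = "residue\tdomain_id\tk\tn\tK\tN\tfold\tp_raw\tp_bh\tsignificant"
        if category_map is not None:
            cols += "\tcategory"
        fh.write(cols + "\n")
        for r in records:
            line = (
                f"{r.residue}\t{r.domain_id}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                f"{r.fold:.10g}\t{r.p_raw:.10g}\t{r.p_bh:.10g}\t{r.significant}"
            )
            if category_map is not None:
                line += f"\t{category_map.get(r.domain_id, '')}"
            fh.write(line + "\n")
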