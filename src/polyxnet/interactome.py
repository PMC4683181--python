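"""Binary protein-protein interaction networks and group-edge classification.

An :class:`Interactome` is an undirected simple graph read from a
tab-delimited edge list (plain two-column, or BioGRID TAB with named
interactor-symbol columns).  For a protein group (a polyX group or a
random control group) the incident edges split into:

* **type a** — both endpoints belong to the group;
* **type b** — exactly one endpoint belongs to the group.

Edges between two non-members are not retained in the group network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Interactome",
    "GroupNetwork",
    "read_interactions",
    "extract_group_network",
    "within_group_degrees",
]

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def _canon(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Interactome:
    """Undirected simple graph: unordered distinct id pairs, deduplicated
    regardless of input orientation; self-pairs filtered out (optionally
    retained separately in ``self_loops``)."""

    edges: frozenset[Edge]
    self_loops: frozenset[str] = frozenset()
    n_skipped: int = 0

    @property
    def nodes(self) -> frozenset[str]:
        out: set[str] = set()
        for u, v in self.edges:
            out.add(u)
            out.add(v)
        out.update(self.self_loops)
        return frozenset(out)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def read_interactions(
    path: str | Path,
    format: str = "two_column",
    col_a: str = "Official Symbol Interactor A",
    col_b: str = "Official Symbol Interactor B",
    keep_self_loops: bool = False,
) -> Interactome:
    """Read a tab-delimited binary-interaction file.

    Parameters
    ----------
    format
        ``"two_column"``: headerless, first two tab-separated fields per
        row are the interactors.  ``"biogrid_tab"``: a header row names
        the interactor columns (defaults match BioGRID TAB exports).
    keep_self_loops
        Self-interactions are dropped by default; when kept they are
        recorded per node and count as one type-a interaction in any
        group containing the node.

    Raises
    ------
    ValueError
        On an unknown format, a missing header column, or zero edges
        after filtering.  Unparseable rows are skipped; the skip count is
        logged and stored on the result.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "two_column":
        try:
            df = pd.read_csv(
                path, sep="\t", header=None, dtype=str, comment="#",
                on_bad_lines="skip", skip_blank_lines=True,
            )
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=[0, 1])
        if df.shape[1] < 2:
            df = pd.DataFrame(columns=[0, 1])
        pairs = df.iloc[:, :2]
    elif format == "biogrid_tab":
        df = pd.read_csv(path, sep="\t", dtype=str, on_bad_lines="skip")
        missing = [c for c in (col_a, col_b) if c not in df.columns]
        if missing:
            raise ValueError(f"missing interactor column(s) {missing} in {path}")
        pairs = df[[col_a, col_b]]
    else:
        raise ValueError(f"unknown interaction format {format!r}")

    edges: set[Edge] = set()
    loops: set[str] = set()
    n_skipped = 0
    for u, v in pairs.itertuples(index=False):
        if not isinstance(u, str) or not isinstance(v, str) or not u or not v:
            n_skipped += 1
            continue
        u, v = u.strip(), v.strip()
        if not u or not v:
            n_skipped += 1
            continue
        if u == v:
            if keep_self_loops:
                loops.add(u)
            continue
        edges.add(_canon(u, v))
    if n_skipped:
        logger.warning("%s: skipped %d unparseable interaction rows", path, n_skipped)
    if not edges and not loops:
        raise ValueError(f"zero edges after filtering in {path}")
    return Interactome(
        edges=frozenset(edges),
        self_loops=frozenset(loops),
        n_skipped=n_skipped,
    )


@dataclass(frozen=True)
class GroupNetwork:
    """A group's interaction neighbourhood with classified edges.

    ``type_a`` and ``type_b`` are disjoint; every interactome edge
    incident to a group member lands in exactly one of them.
    ``present_members`` is the subset of the group that appears in the
    interactome at all.
    """

    group: frozenset[str]
    type_a: frozenset[Edge]
    type_b: frozenset[Edge]
    present_members: frozenset[str]


def extract_group_network(interactome: Interactome, group: Iterable[str]) -> GroupNetwork:
    """Classify interactome edges incident to ``group`` into type a / b.

    Self-loops of the interactome (when retained at read time) on group
    members count as type-a interactions with multiplicity 1, encoded as
    the degenerate edge ``(n, n)``.
    """
    gset = frozenset(group)
    if not gset:
        raise ValueError("group must be non-empty")
    type_a: set[Edge] = set()
    type_b: set[Edge] = set()
    for u, v in interactome.edges:
        u_in = u in gset
        v_in = v in gset
        if u_in and v_in:
            type_a.add((u, v))
        elif u_in or v_in:
            type_b.add((u, v))
    for n in interactome.self_loops:
        if n in gset:
            type_a.add((n, n))
    return GroupNetwork(
        group=gset,
        type_a=frozenset(type_a),
        type_b=frozenset(type_b),
        present_members=gset & interactome.nodes,
    )


def within_group_degrees(gn: GroupNetwork) -> dict[str, int]:
    """Per present member, the number of incident type-a edges.

    Without self-loops the degree sum equals ``2 * |type_a|`` (handshake
    identity); a retained self-loop contributes 1.
    """
    deg = {m: 0 for m in gn.present_members}
    for u, v in gn.type_a:
        if u == v:
            deg[u] = deg.get(u, 0) + 1
        else:
            deg[u] = deg.get(u, 0) + 1
            deg[v] = deg.get(v, 0) + 1
    return deg
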