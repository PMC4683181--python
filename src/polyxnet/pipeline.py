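"""End-to-end orchestration: scan -> networks -> connectivity ->
enrichment -> overlap, from a config file or keyword parameters, with a
reproducibility manifest.

All randomness flows from the single manifest seed; rerunning a config
with the same seed produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import yaml

from . import __version__
from .connectivity import ConnectivityModel, ConnectivityResults
from .enrichment import (
    enrich_all_groups,
    read_domain_annotations,
    write_enrichment_tsv,
)
from .interactome import GroupNetwork, extract_group_network, read_interactions
from .overlap import overlap_all, write_overlap_tsv
from .repeats import (
    STANDARD_RESIDUES,
    build_polyx_groups,
    read_fasta,
    scan_proteome,
    write_groups_tsv,
    write_repeats_tsv,
)

__all__ = ["RunConfig", "PipelineError", "run_full_analysis", "write_network_export"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Paths and parameters of one full analysis run.

    Parameter defaults follow the reference analysis: runs of >= 4
    residues define a group, 5 random control groups, significance at
    alpha = 0.05, repeat/domain overlap threshold of 4 residues.
    """

    proteome: str = ""
    interactome: str = ""
    domains: str | None = None
    outdir: str = "polyxnet_out"
    min_run_length: int = 4
    n_controls: int = 5
    seed: int = 0
    alpha: float = 0.05
    chi2_controls: str = "mean"
    per_node_denominator: str = "present_members"
    enrichment_mode: str = "standard"
    background: str = "proteome"
    min_overlap: int = 4
    min_group_size: int = 2
    interaction_format: str = "two_column"
    export_graphml: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_network_export(
    gn: GroupNetwork, path: str | Path, format: str = "edge_tsv"
) -> None:
    """Export a group network with edge types for graph viewers.

    ``edge_tsv``: columns protein_a, protein_b, edge_type; round-trips
    through :func:`~polyxnet.interactome.read_interactions` when the type
    column is ignored.  ``graphml``: nodes carry an ``in_group`` flag,
    edges an ``edge_type`` in {a, b}.
    """
    if not gn.type_a and not gn.type_b:
        raise ValueError("refusing to export an empty network")
    path = Path(path)
    if format == "edge_tsv":
        with open(path, "w") as fh:
            # '#' header so the two-column reader round-trips the file
            fh.write("#protein_a\tprotein_b\tedge_type\n")
            for u, v in sorted(gn.type_a):
                fh.write(f"{u}\t{v}\ta\n")
            for u, v in sorted(gn.type_b):
                fh.write(f"{u}\t{v}\tb\n")
    elif format == "graphml":
        g = nx.Graph()
        for u, v in sorted(gn.type_a):
            g.add_edge(u, v, edge_type="a")
        for u, v in sorted(gn.type_b):
            g.add_edge(u, v, edge_type="b")
        for node in g.nodes:
            g.nodes[node]["in_group"] = node in gn.group
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def run_full_analysis(config: RunConfig) -> Path:
    """Run every stage and write all artifacts to ``config.outdir``.

    Artifacts: repeats.tsv, groups.tsv, networks/<X>_edges.tsv,
    connectivity.tsv, summary_stats.tsv, enrichment.tsv and overlap.tsv
    (when a domain table is given), and run_manifest.json recording every
    parameter, the seed and input checksums.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "scan"
    try:
        proteome = read_fasta(config.proteome)
        occurrences = scan_proteome(proteome, config.min_run_length)
        groups = build_polyx_groups(proteome, config.min_run_length, occurrences)
        write_repeats_tsv(occurrences, outdir / "repeats.tsv")
        write_groups_tsv(groups, outdir / "groups.tsv")

        stage = "networks"
        inter = read_interactions(config.interactome, format=config.interaction_format)
        proteome_ids = {p.id for p in proteome}
        node_overlap = (
            len(inter.nodes & proteome_ids) / len(inter.nodes) if inter.nodes else 0.0
        )
        if node_overlap < 0.5:
            logger.warning(
                "only %.0f%% of interactome nodes match proteome ids; "
                "check that both inputs share one id namespace",
                100 * node_overlap,
            )
        netdir = outdir / "networks"
        netdir.mkdir(exist_ok=True)
        for res in STANDARD_RESIDUES:
            grp = groups[res]
            if grp.size == 0:
                continue
            gn = extract_group_network(inter, grp.members)
            if gn.type_a or gn.type_b:
                write_network_export(gn, netdir / f"{res}_edges.tsv", "edge_tsv")
                if config.export_graphml:
                    write_network_export(gn, netdir / f"{res}.graphml", "graphml")

        stage = "connectivity"
        model = ConnectivityModel(
            groups,
            inter,
            universe=sorted(proteome_ids),
            n_controls=config.n_controls,
            min_group_size=config.min_group_size,
            chi2_controls=config.chi2_controls,
            per_node_denominator=config.per_node_denominator,
            alpha=config.alpha,
        )
        results: ConnectivityResults = model.fit(seed=config.seed)
        results.save(outdir)

        enrichment_records = None
        annotations = None
        if config.domains is not None:
            stage = "enrichment"
            annotations = read_domain_annotations(config.domains)
            if config.background == "proteome":
                background = proteome_ids
            elif config.background == "annotated":
                background = {a.protein_id for a in annotations} & proteome_ids
            else:
                raise ValueError(f"unknown background {config.background!r}")
            enrichment_records = enrich_all_groups(
                {res: g.members for res, g in groups.items()},
                annotations,
                background,
                alpha=config.alpha,
                mode=config.enrichment_mode,
            )
            write_enrichment_tsv(enrichment_records, outdir / "enrichment.tsv")

            stage = "overlap"
            all_occurrences = [o for occs in occurrences.values() for o in occs]
            summaries = overlap_all(
                enrichment_records,
                all_occurrences,
                annotations,
                min_overlap=config.min_overlap,
                significant_only=True,
            )
            write_overlap_tsv(summaries, outdir / "overlap.tsv")

        stage = "manifest"
        manifest: dict[str, object] = {
            "polyxnet_version": __version__,
            "parameters": dataclasses.asdict(config),
            "inputs": {
                "proteome_sha256": _sha256(Path(config.proteome)),
                "interactome_sha256": _sha256(Path(config.interactome)),
                "domains_sha256": (
                    _sha256(Path(config.domains)) if config.domains else None
                ),
            },
            "interactome_proteome_id_overlap": round(node_overlap, 6),
            "groups_analyzed": [r.residue for r in results.group_results],
            "groups_skipped": dict(results.skipped),
        }
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return outdir
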