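"""Synthetic proteome / interactome / domain-annotation generator.

Every pipeline stage is testable without downloads by planting known
structure:

* **proteome** — sequences drawn i.i.d. from a typical vertebrate
  amino-acid composition, with accidental homopolymer runs suppressed by
  resampling, and pure runs of chosen residues planted in a chosen
  fraction of proteins at recorded positions;
* **interactome** — a planted-partition graph: each within-group protein
  pair receives an edge with probability ``p_in``, every other pair with
  ``p_out``, so the expected within-group edge count is C(g, 2) * p_in
  and the per-node connectivity ratio recovers p_in / p_out;
* **domain annotations** — a planted domain assigned to group members
  with probability ``q_in`` and to outsiders with ``q_out``; with
  probability ``overlap_rate`` an instance on a member is positioned to
  overlap that member's planted run by at least 4 residues, otherwise it
  is placed disjoint from every planted run; decoy domains are assigned
  uniformly at random.

The defaults describe a polyQ-like study condition: a universe of 500
proteins, a planted group of 8% of them, a background edge probability
of 0.06 (mean degree about 30, comparable to curated human interactome
density) and a within-group elevation of 2.4x — the per-node connectivity
excess reported for polyglutamine proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .enrichment import DomainAnnotation
from .interactome import Interactome
from .repeats import (
    ProteinRecord,
    RepeatOccurrence,
    find_homopolymer_runs,
)

__all__ = [
    "AA_COMPOSITION",
    "PlantedRepeatSpec",
    "PlantedDomainSpec",
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate_proteome",
    "generate_interactome",
    "sample_domain_assignments",
    "generate_domain_annotations",
    "simulate_dataset",
    "write_fasta",
    "write_edge_list",
    "write_domain_tsv",
]

#: Typical vertebrate proteome amino-acid frequencies (UniProtKB global
#: statistics, normalized).
AA_COMPOSITION: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


@dataclass(frozen=True)
class PlantedRepeatSpec:
    """A residue to plant runs of: in ``fraction`` of the proteins, one
    pure run of length ``min_len`` plus a geometric tail with mean
    ``mean_extra`` (capped at ``max_len``)."""

    residue: str = "Q"
    fraction: float = 0.08
    min_len: int = 4
    mean_extra: float = 2.0
    max_len: int = 40


@dataclass(frozen=True)
class PlantedDomainSpec:
    """A domain enriched in one planted group: members carry it with
    probability ``q_in``, outsiders with ``q_out``; ``overlap_rate`` is
    the probability that a member's instance is positioned to overlap the
    planted run by >= 4 residues."""

    domain_id: str = "DOM_PLANTED"
    residue: str = "Q"
    q_in: float = 0.5
    q_out: float = 0.05
    overlap_rate: float = 0.5
    length: int = 30


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 500
    length_mean: float = 350.0
    length_min: int = 60
    length_max: int = 2000
    composition: Mapping[str, float] = field(
        default_factory=lambda: dict(AA_COMPOSITION)
    )
    repeats: tuple[PlantedRepeatSpec, ...] = (PlantedRepeatSpec(),)
    p_in: float = 0.144
    p_out: float = 0.06
    domains: tuple[PlantedDomainSpec, ...] = (PlantedDomainSpec(),)
    n_decoy_domains: int = 50
    decoy_rate: float = 0.05
    min_run_length: int = 4
    suppress_accidental: bool = True

    def validate(self) -> None:
        for p in (self.p_in, self.p_out, self.decoy_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for spec in self.repeats:
            if not 0.0 <= spec.fraction <= 1.0:
                raise ValueError("planted fraction must lie in [0, 1]")
            if spec.min_len > self.length_min:
                raise ValueError("planted run longer than the shortest sequence")
        for spec in self.domains:
            for q in (spec.q_in, spec.q_out, spec.overlap_rate):
                if not 0.0 <= q <= 1.0:
                    raise ValueError("domain probabilities must lie in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Planted structure, re-derivable from the emitted files."""

    groups: dict[str, list[str]] = field(default_factory=dict)
    repeats: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    p_in: float = 0.0
    p_out: float = 0.0
    n_within_edges: int = 0
    n_between_edges: int = 0
    enriched_domains: dict[str, str] = field(default_factory=dict)
    domain_members: dict[str, list[str]] = field(default_factory=dict)
    overlap_rates: dict[str, float] = field(default_factory=dict)
    realized_overlap: dict[str, float | None] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"SYN{i:0{width}d}" for i in range(1, n + 1)]


def _draw_lengths(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    # lognormal with median near length_mean and a modest right tail,
    # clipped to the configured range
    mu = np.log(cfg.length_mean)
    lengths = rng.lognormal(mean=mu, sigma=0.45, size=cfg.n_proteins)
    return np.clip(np.round(lengths), cfg.length_min, cfg.length_max).astype(int)


def generate_proteome(
    config: SyntheticConfig, seed: int = 0
) -> tuple[list[ProteinRecord], SyntheticGroundTruth]:
    """Generate sequences with planted homopolymer runs.

    With ``suppress_accidental`` (default) any background run reaching
    ``min_run_length`` is resampled away, so group membership in the
    ground truth is exact by construction.  With suppression off, the
    ground truth is recomputed post hoc by scanning the final sequences.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    letters = np.array(sorted(config.composition))
    probs = np.array([config.composition[a] for a in letters], dtype=float)
    probs = probs / probs.sum()
    ids = _protein_ids(config.n_proteins)
    lengths = _draw_lengths(rng, config)

    # choose planted members per spec
    planted_members: dict[str, list[str]] = {}
    for spec in config.repeats:
        size = int(round(spec.fraction * config.n_proteins))
        idx = rng.choice(config.n_proteins, size=size, replace=False)
        planted_members[spec.residue] = [ids[i] for i in sorted(idx)]

    specs_by_residue = {s.residue: s for s in config.repeats}
    member_lookup: dict[str, list[str]] = {}
    for res, mem in planted_members.items():
        for pid in mem:
            member_lookup.setdefault(pid, []).append(res)

    truth = SyntheticGroundTruth(p_in=config.p_in, p_out=config.p_out)
    records: list[ProteinRecord] = []
    for pid, L in zip(ids, lengths):
        seq = rng.choice(letters, size=L, p=probs)
        planted_here: list[tuple[str, int, int]] = []
        # forbidden[pos] holds a residue this position must never take
        # (the planted residue adjacent to a run flank), so redraws can
        # never extend a planted run past its recorded coordinates
        forbidden: dict[int, str] = {}
        occupied = np.zeros(L, dtype=bool)  # planted runs plus their flanks

        def draw_not(res: str) -> str:
            other = letters[letters != res]
            oprobs = probs[letters != res]
            return str(rng.choice(other, p=oprobs / oprobs.sum()))

        for res in member_lookup.get(pid, []):
            spec = specs_by_residue[res]
            extra = rng.geometric(1.0 / (spec.mean_extra + 1.0)) - 1
            run_len = min(spec.min_len + int(extra), spec.max_len, int(L))
            for _ in range(200):
                start0 = int(rng.integers(0, L - run_len + 1))  # 0-based
                lo = max(0, start0 - 1)
                hi = min(L, start0 + run_len + 1)
                if not occupied[lo:hi].any():
                    break
            else:  # pragma: no cover - only with absurdly dense planting
                raise ValueError(f"cannot place run of {res} in {pid}")
            seq[start0 : start0 + run_len] = res
            # force the flanks to differ from the run residue so the
            # planted run is maximal at exactly the recorded coordinates
            if start0 > 0:
                seq[start0 - 1] = draw_not(res)
                forbidden[start0 - 1] = res
            if start0 + run_len < L:
                seq[start0 + run_len] = draw_not(res)
                forbidden[start0 + run_len] = res
            occupied[lo:hi] = True
            planted_here.append((res, start0 + 1, start0 + run_len))
        planted_intervals = set(planted_here)
        protected = np.zeros(L, dtype=bool)
        for _, s, e in planted_here:
            protected[s - 1 : e] = True

        if config.suppress_accidental:
            for _ in range(200):
                runs = find_homopolymer_runs("".join(seq), config.min_run_length)
                extra_runs = [r for r in runs if r not in planted_intervals]
                if not extra_runs:
                    break
                for _, s, e in extra_runs:
                    for pos in range(s - 1, e):
                        if not protected[pos]:
                            seq[pos] = (
                                draw_not(forbidden[pos])
                                if pos in forbidden
                                else rng.choice(letters, p=probs)
                            )
            else:  # pragma: no cover - resampling converges in practice
                raise RuntimeError(f"run suppression did not converge for {pid}")

        records.append(ProteinRecord(id=pid, sequence="".join(seq)))
        if planted_here:
            truth.repeats[pid] = sorted(planted_here)

    if config.suppress_accidental:
        truth.groups = {res: list(mem) for res, mem in planted_members.items()}
    else:
        # recompute membership from the actual sequences
        groups: dict[str, set[str]] = {}
        truth.repeats = {}
        for rec in records:
            runs = find_homopolymer_runs(rec.sequence, config.min_run_length)
            if runs:
                truth.repeats[rec.id] = [(r, s, e) for r, s, e in runs]
            for res, _, _ in runs:
                groups.setdefault(res, set()).add(rec.id)
        truth.groups = {res: sorted(mem) for res, mem in groups.items()}
    return records, truth


def generate_interactome(
    groups: Mapping[str, Iterable[str]],
    p_in: float,
    p_out: float,
    universe: Sequence[str],
    seed: int = 0,
) -> tuple[Interactome, int, int]:
    """Planted-partition interactome over ``universe``.

    A pair sharing at least one group gets an edge with probability
    ``p_in``; every other pair with ``p_out``.  ``p_in < p_out`` is
    allowed (depleted, polyL-like fixtures).  Returns the interactome and
    the realized (within, between) edge counts.
    """
    ids = sorted(set(universe))
    n = len(ids)
    if n < 2:
        raise ValueError("universe too small for an interactome")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    index = {pid: i for i, pid in enumerate(ids)}
    member_masks = []
    for res in sorted(groups):
        mask = np.zeros(n, dtype=bool)
        for pid in groups[res]:
            if pid in index:
                mask[index[pid]] = True
        member_masks.append(mask)

    iu, ju = np.triu_indices(n, k=1)
    within = np.zeros(iu.size, dtype=bool)
    for mask in member_masks:
        within |= mask[iu] & mask[ju]
    p = np.where(within, p_in, p_out)
    drawn = rng.random(iu.size) < p
    n_within = int(np.count_nonzero(drawn & within))
    n_between = int(np.count_nonzero(drawn & ~within))
    edges = frozenset(
        (ids[a], ids[b]) if ids[a] <= ids[b] else (ids[b], ids[a])
        for a, b in zip(iu[drawn], ju[drawn])
    )
    if not edges:
        raise ValueError("planted-partition draw produced zero edges")
    return Interactome(edges=edges), n_within, n_between


def sample_domain_assignments(
    groups: Mapping[str, Iterable[str]],
    specs: Sequence[PlantedDomainSpec],
    universe: Sequence[str],
    n_decoys: int = 50,
    decoy_rate: float = 0.05,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Which proteins carry which domain (no coordinates yet): planted
    domains by q_in / q_out per group membership, decoys uniformly."""
    ids = sorted(set(universe))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    assignments: dict[str, list[str]] = {}
    for spec in specs:
        members = frozenset(groups.get(spec.residue, ()))
        carriers = [
            pid
            for pid in ids
            if rng.random() < (spec.q_in if pid in members else spec.q_out)
        ]
        assignments[spec.domain_id] = carriers
    width = max(3, len(str(n_decoys)))
    for d in range(1, n_decoys + 1):
        dom = f"DEC{d:0{width}d}"
        assignments[dom] = [pid for pid in ids if rng.random() < decoy_rate]
    return assignments


def generate_domain_annotations(
    proteome: Sequence[ProteinRecord],
    groups: Mapping[str, Iterable[str]],
    repeats: Mapping[str, Sequence[tuple[str, int, int]]],
    specs: Sequence[PlantedDomainSpec] = (PlantedDomainSpec(),),
    n_decoys: int = 50,
    decoy_rate: float = 0.05,
    seed: int = 0,
) -> tuple[list[DomainAnnotation], SyntheticGroundTruth]:
    """Domain annotations with planted enrichment and planted positional
    overlap.

    For a planted domain on a group member with a recorded run of the
    spec's residue: with probability ``overlap_rate`` the instance starts
    at the run start (guaranteeing >= 4 shared positions for runs of the
    default threshold length), otherwise it is placed with zero overlap
    with every recorded run of that protein.  Raises ``ValueError`` for a
    protein too short to hold any placement.
    """
    lengths = {rec.id: len(rec.sequence) for rec in proteome}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    assignments = sample_domain_assignments(
        groups, specs, list(lengths), n_decoys=n_decoys,
        decoy_rate=decoy_rate, seed=seed,
    )
    truth = SyntheticGroundTruth()
    annotations: list[DomainAnnotation] = []
    spec_by_dom = {s.domain_id: s for s in specs}

    def place_disjoint(pid: str, dlen: int) -> tuple[int, int]:
        L = lengths[pid]
        taken = [(s, e) for _, s, e in repeats.get(pid, ())]
        # shrink the instance if the sequence is too crowded for the
        # nominal domain length (never below 4 residues)
        for trial_len in (min(dlen, L), min(dlen, L) // 2, 8, 4):
            if trial_len < 4 or trial_len > L:
                continue
            for _ in range(200):
                start = int(rng.integers(1, L - trial_len + 2))
                end = start + trial_len - 1
                if all(min(end, e) - max(start, s) + 1 <= 0 for s, e in taken):
                    return start, end
        raise ValueError(f"protein {pid} too short to place a disjoint domain")

    for dom in sorted(assignments):
        carriers = assignments[dom]
        spec = spec_by_dom.get(dom)
        n_both = 0
        n_olap = 0
        for pid in carriers:
            if pid not in lengths:
                continue
            L = lengths[pid]
            if L < 4:
                raise ValueError(f"protein {pid} too short for any domain")
            dlen = min(spec.length if spec else 30, L)
            runs = [
                (s, e) for res, s, e in repeats.get(pid, ())
                if spec is not None and res == spec.residue
            ]
            if spec is not None and runs:
                n_both += 1
                if rng.random() < spec.overlap_rate:
                    s, e = runs[int(rng.integers(0, len(runs)))]
                    start = s
                    end = min(s + dlen - 1, L)
                    n_olap += 1
                else:
                    start, end = place_disjoint(pid, dlen)
            else:
                start, end = place_disjoint(pid, dlen)
            annotations.append(DomainAnnotation(pid, dom, start, end))
        truth.domain_members[dom] = sorted(carriers)
        if spec is not None:
            truth.enriched_domains[dom] = spec.residue
            truth.overlap_rates[dom] = spec.overlap_rate
            truth.realized_overlap[dom] = (n_olap / n_both) if n_both else None
    return sorted(annotations), truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_edge_list(interactome: Interactome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(interactome.edges):
            fh.write(f"{u}\t{v}\n")
        for n in sorted(interactome.self_loops):
            fh.write(f"{n}\t{n}\n")


def write_domain_tsv(annotations: Sequence[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain_id\tstart\tend\n")
        for ann in sorted(annotations):
            s = "" if ann.start is None else ann.start
            e = "" if ann.end is None else ann.end
            fh.write(f"{ann.protein_id}\t{ann.domain_id}\t{s}\t{e}\n")


def simulate_dataset(
    config: SyntheticConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[list[ProteinRecord], Interactome, list[DomainAnnotation], SyntheticGroundTruth]:
    """Generate a complete dataset (proteome, interactome, annotations,
    merged ground truth); optionally write ``proteome.fasta``,
    ``interactome.tsv``, ``domains.tsv`` and ``truth.json`` to
    ``outdir``."""
    config = config or SyntheticConfig()
    records, truth = generate_proteome(config, seed=seed)
    universe = [r.id for r in records]
    inter, n_within, n_between = generate_interactome(
        truth.groups, config.p_in, config.p_out, universe, seed=seed
    )
    truth.n_within_edges = n_within
    truth.n_between_edges = n_between
    annotations, dom_truth = generate_domain_annotations(
        records, truth.groups, truth.repeats, config.domains,
        n_decoys=config.n_decoy_domains, decoy_rate=config.decoy_rate,
        seed=seed,
    )
    truth.enriched_domains = dom_truth.enriched_domains
    truth.domain_members = dom_truth.domain_members
    truth.overlap_rates = dom_truth.overlap_rates
    truth.realized_overlap = dom_truth.realized_overlap
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, outdir / "proteome.fasta")
        write_edge_list(inter, outdir / "interactome.tsv")
        write_domain_tsv(annotations, outdir / "domains.tsv")
        truth.to_json(outdir / "truth.json")
    return records, inter, annotations, truth
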