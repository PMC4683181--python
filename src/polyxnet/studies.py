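"""Simulation studies: null calibration and planted-effect recovery.

These reusable studies characterize the behaviour of the connectivity,
enrichment and overlap analyses on synthetic data with known ground
truth:

* :func:`null_calibration` — groups drawn at random in an exchangeable
  (p_in = p_out) interactome; the normalized indexes should average 1 and
  the chi-square step should reject at roughly its nominal level.
* :func:`effect_recovery` — planted-partition interactomes with a known
  within-group elevation rho = p_in / p_out; the normalized per-node
  index should recover rho.
* :func:`enrichment_recovery` — a planted enriched domain among decoys;
  the enrichment step should detect it while rarely flagging decoys.
* :func:`overlap_recovery` — domain instances planted to overlap repeat
  runs at a known rate w; the overlap fraction should estimate w.

The chi-square step of the calibration uses the pooled control
construction: summing the 5 control count pairs yields a 2x2 table whose
independence-test variance matches the actual sampling variance of the
comparison, whereas dividing by an averaged control column does not (see
the methods note).
"""

from __future__ import annotations

import numpy as np

from .connectivity import connectivity_for_group
from .enrichment import DomainAnnotation, bh_adjust, hypergeom_enrichment
from .overlap import overlap_summary
from .repeats import RepeatOccurrence
from .simulate import (
    PlantedDomainSpec,
    PlantedRepeatSpec,
    SyntheticConfig,
    generate_domain_annotations,
    generate_interactome,
    generate_proteome,
    sample_domain_assignments,
)

__all__ = [
    "null_calibration",
    "effect_recovery",
    "enrichment_recovery",
    "overlap_recovery",
]


def _ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def null_calibration(
    n_datasets: int = 1000,
    universe_size: int = 500,
    group_size: int = 40,
    n_controls: int = 5,
    p: float = 0.06,
    alpha: float = 0.05,
    seed: int = 0,
    chi2_controls: str = "pooled",
) -> dict[str, float]:
    """Exchangeable null: the "polyX group" is itself a random draw.

    Returns the mean normalized proportion and per-node ratios over all
    datasets and the chi-square rejection rate at ``alpha``.
    """
    ids = _ids(universe_size)
    mean_props: list[float] = []
    mean_pns: list[float] = []
    n_reject = 0
    for ds in range(n_datasets):
        inter, _, _ = generate_interactome({}, p, p, ids, seed=int(seed) * 131071 + ds)
        grp_rng = np.random.default_rng(np.random.SeedSequence([seed, ds, 17]))
        group = frozenset(
            ids[i] for i in grp_rng.choice(universe_size, group_size, replace=False)
        )
        res = connectivity_for_group(
            inter, group, ids,
            n_controls=n_controls, seed=(seed, ds, 23),
            chi2_controls=chi2_controls, alpha=alpha,
        )
        mean_props.append(res.mean_norm_proportion)
        mean_pns.append(res.mean_norm_per_node)
        n_reject += int(res.significant)
    return {
        "n_datasets": n_datasets,
        "mean_norm_proportion": float(np.mean(mean_props)),
        "mean_norm_per_node": float(np.mean(mean_pns)),
        "chi2_rejection_rate": n_reject / n_datasets,
    }


def effect_recovery(
    rho: float,
    n_replicates: int = 200,
    universe_size: int = 600,
    group_size: int = 60,
    p_out: float = 0.01,
    n_controls: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Planted-partition recovery of a known connectivity elevation.

    The planted group's pairs receive edges at ``rho * p_out``; the mean
    normalized per-node index over replicates estimates rho (values below
    1 emulate depleted, polyL-like groups).
    """
    ids = _ids(universe_size)
    pns: list[float] = []
    props: list[float] = []
    for rep in range(n_replicates):
        grp_rng = np.random.default_rng(np.random.SeedSequence([seed, rep, 31]))
        group = frozenset(
            ids[i] for i in grp_rng.choice(universe_size, group_size, replace=False)
        )
        inter, _, _ = generate_interactome(
            {"G": group}, rho * p_out, p_out, ids, seed=int(seed) * 131071 + 7919 + rep
        )
        res = connectivity_for_group(
            inter, group, ids,
            n_controls=n_controls, seed=(seed, rep, 37),
            chi2_controls="pooled",
        )
        pns.append(res.mean_norm_per_node)
        props.append(res.mean_norm_proportion)
    return {
        "n_replicates": n_replicates,
        "rho": rho,
        "mean_norm_per_node": float(np.mean(pns)),
        "mean_norm_proportion": float(np.mean(props)),
    }


def enrichment_recovery(
    n_replicates: int = 100,
    background_size: int = 400,
    group_size: int = 40,
    q_in: float = 0.5,
    q_out: float = 0.05,
    n_decoys: int = 50,
    decoy_rate: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Detection of one planted enriched domain among uniform decoys.

    Per replicate: BH-adjust the group's domain family and record whether
    the planted domain is significant and whether any decoy is.
    """
    ids = _ids(background_size)
    spec = PlantedDomainSpec("DOM_PLANTED", "Q", q_in=q_in, q_out=q_out)
    n_detected = 0
    n_any_decoy = 0
    for rep in range(n_replicates):
        grp_rng = np.random.default_rng(np.random.SeedSequence([seed, rep, 41]))
        group = frozenset(
            ids[i] for i in grp_rng.choice(background_size, group_size, replace=False)
        )
        assignments = sample_domain_assignments(
            {"Q": group}, [spec], ids,
            n_decoys=n_decoys, decoy_rate=decoy_rate,
            seed=int(seed) * 131071 + 104729 + rep,
        )
        annotations = [
            DomainAnnotation(pid, dom)
            for dom, carriers in assignments.items()
            for pid in carriers
        ]
        records = hypergeom_enrichment(group, annotations, ids)
        if not records:
            continue
        adj = bh_adjust([r.p_raw for r in records])
        sig = {r.domain_id for r, p in zip(records, adj) if p < alpha}
        n_detected += int("DOM_PLANTED" in sig)
        n_any_decoy += int(any(d.startswith("DEC") for d in sig))
    return {
        "n_replicates": n_replicates,
        "detection_rate": n_detected / n_replicates,
        "decoy_false_positive_rate": n_any_decoy / n_replicates,
    }


def overlap_recovery(
    w: float,
    n_replicates: int = 10,
    n_proteins: int = 200,
    planted_fraction: float = 0.2,
    q_in: float = 0.7,
    q_out: float = 0.05,
    min_overlap: int = 4,
    seed: int = 0,
) -> dict[str, float]:
    """Estimate the planted repeat/domain overlap rate ``w``.

    Per replicate a proteome with a planted polyQ group is generated, a
    domain is planted with per-member overlap probability ``w``, and the
    overlap fraction is measured with the package's interval analysis,
    pooling counts across replicates.
    """
    spec = PlantedDomainSpec(
        "DOM_PLANTED", "Q", q_in=q_in, q_out=q_out, overlap_rate=w
    )
    cfg = SyntheticConfig(
        n_proteins=n_proteins,
        length_mean=250.0,
        length_min=60,
        length_max=800,
        repeats=(PlantedRepeatSpec("Q", fraction=planted_fraction),),
        domains=(spec,),
        n_decoy_domains=0,
    )
    n_total = 0
    n_overlap = 0
    for rep in range(n_replicates):
        records, truth = generate_proteome(cfg, seed=int(seed) * 131071 + 15485863 + rep)
        annotations, _ = generate_domain_annotations(
            records, truth.groups, truth.repeats, [spec],
            n_decoys=0, seed=int(seed) * 131071 + 32452843 + rep,
        )
        repeats = [
            RepeatOccurrence(pid, res, s, e)
            for pid, occs in truth.repeats.items()
            for res, s, e in occs
        ]
        summary = overlap_summary(
            "Q", "DOM_PLANTED", repeats, annotations, min_overlap=min_overlap
        )
        n_total += summary.n_total
        n_overlap += summary.n_overlap
    return {
        "n_replicates": n_replicates,
        "w": w,
        "n_total": n_total,
        "n_overlap": n_overlap,
        "fraction": (n_overlap / n_total) if n_total else float("nan"),
    }
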