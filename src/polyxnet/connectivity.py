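"""Connectivity indexes of polyX networks, normalized to random controls.

Two indexes quantify how strongly the proteins of a group interact among
themselves:

* **proportion index** — ``|type a| / (|type a| + |type b|)``, the share
  of a group's interactions that stay within the group;
* **per-node index** — ``2 |type a| / n``, the number of within-group
  interaction endpoints per group protein (``n`` is, by default, the
  group members present in the interactome).

Each raw index is divided by the same index computed on equinumerous
random control groups (5 by default) drawn from the proteome; the mean
and SEM of the resulting normalized ratios are reported.  A ratio of 1
means "no different from random"; the analysis across all 20 amino-acid
groups is summarized by a Yates-corrected chi-square per group, a one-way
ANOVA with Dunnett many-to-one comparisons across groups, and the Pearson
correlation between the two indexes.

:class:`ConnectivityModel` is the statsmodels-style entry point: build it
from the polyX groups and the interactome, call :meth:`fit`, and inspect
the returned :class:`ConnectivityResults` (``.frame``, ``.summary()``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interactome import GroupNetwork, Interactome, extract_group_network
from .repeats import STANDARD_RESIDUES, PolyXGroup

__all__ = [
    "UndefinedIndexError",
    "sample_control_groups",
    "proportion_index",
    "per_node_index",
    "normalize_against_controls",
    "yates_chi2_test",
    "one_way_anova",
    "dunnett_posthoc",
    "pearson_correlation",
    "ConnectivityResult",
    "connectivity_for_group",
    "ConnectivityModel",
    "ConnectivityResults",
    "analyze_all_groups",
]

logger = logging.getLogger(__name__)

DENOMINATORS = ("present_members", "typea_nodes", "all_members")
CHI2_MODES = ("mean", "pooled")


class UndefinedIndexError(ValueError):
    """An index has an empty denominator (no interactions, or no nodes)."""


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def sample_control_groups(
    universe: Sequence[str],
    size: int,
    n_controls: int = 5,
    seed: int = 0,
) -> list[frozenset[str]]:
    """Draw ``n_controls`` independent control groups of exactly ``size``
    distinct ids, without replacement within each replicate.

    Fully deterministic in ``(seed, replicate index)``; replicates may
    overlap each other.  Raises ``ValueError`` if ``size`` exceeds the
    universe.
    """
    ids = sorted(set(universe))
    if size > len(ids):
        raise ValueError(f"group size {size} exceeds universe of {len(ids)}")
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    out = []
    for rep in range(n_controls):
        rng = _rng(seed, rep, 0)
        idx = rng.choice(len(ids), size=size, replace=False)
        out.append(frozenset(ids[i] for i in idx))
    return out


def proportion_index(gn: GroupNetwork) -> float:
    """``|type a| / (|type a| + |type b|)``; undefined when the group has
    no interactions at all."""
    total = len(gn.type_a) + len(gn.type_b)
    if total == 0:
        raise UndefinedIndexError("group has no interactions")
    return len(gn.type_a) / total


def per_node_index(gn: GroupNetwork, denominator: str = "present_members") -> float:
    """Within-group interaction endpoints per group protein:
    ``2 |type a| / |denominator set|``.

    ``denominator`` selects the node count: group members present in the
    interactome (default), only the endpoints of type-a edges, or all
    group members regardless of interaction evidence.
    """
    if denominator == "present_members":
        nodes = gn.present_members
    elif denominator == "typea_nodes":
        nodes = {n for e in gn.type_a for n in e}
    elif denominator == "all_members":
        nodes = gn.group
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if not nodes:
        raise UndefinedIndexError(f"empty denominator set ({denominator})")
    # a self-loop edge (n, n) has 2 endpoints on paper but was recorded with
    # multiplicity 1; count it once
    endpoints = sum(1 if u == v else 2 for u, v in gn.type_a)
    return endpoints / len(nodes)


def normalize_against_controls(
    raw: float, controls: Sequence[float]
) -> tuple[list[float], float, float]:
    """Normalize a raw index by each control value.

    Returns ``(ratios, mean, sem)`` where ``ratios[i] = raw/controls[i]``
    and SEM is the sample standard deviation (ddof=1) over sqrt(n).
    Every control value must be > 0 (zeros are handled upstream by the
    resampling policy).
    """
    controls = list(controls)
    if not controls:
        raise ValueError("need at least one control value")
    if any(c <= 0 for c in controls):
        raise ValueError("control values must be positive to normalize")
    ratios = [raw / c for c in controls]
    mean = float(np.mean(ratios))
    sem = 0.0 if len(ratios) == 1 else float(np.std(ratios, ddof=1) / math.sqrt(len(ratios)))
    return ratios, mean, sem


def yates_chi2_test(a1: int, b1: int, a2: int, b2: int) -> tuple[float, float]:
    """Chi-square test with Yates' continuity correction on the 2x2 table
    ``[[a1, b1], [a2, b2]]`` (1 df).

    Closed form: ``N (max(0, |a1*b2 - b1*a2| - N/2))^2 /
    ((a1+b1)(a2+b2)(a1+a2)(b1+b2))``.  Raises ``ValueError`` when any
    marginal is zero (the statistic is undefined).
    """
    for c in (a1, b1, a2, b2):
        if c < 0:
            raise ValueError("counts must be non-negative")
    n = a1 + b1 + a2 + b2
    margins = [(a1 + b1), (a2 + b2), (a1 + a2), (b1 + b2)]
    if any(m == 0 for m in margins):
        raise ValueError("zero marginal: chi-square undefined")
    num = max(0.0, abs(a1 * b2 - b1 * a2) - n / 2.0) ** 2 * n
    stat = num / math.prod(margins)
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p


def one_way_anova(
    groups: Sequence[Sequence[float]],
) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA; returns ``(F, df_between, df_within, p)``.

    Zero within-group variance with distinct means is reported as
    ``F = inf, p = 0``.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs >= 2 values")
    df_between = len(arrays) - 1
    df_within = sum(a.size for a in arrays) - len(arrays)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    if ssw == 0.0:
        means = [a.mean() for a in arrays]
        if np.ptp(means) > 0:
            return float("inf"), df_between, df_within, 0.0
        return 0.0, df_between, df_within, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), df_between, df_within, float(p)


def dunnett_posthoc(
    groups: Sequence[Sequence[float]],
    control_index: int | str = "auto",
    seed: int = 0,
) -> tuple[int, list[float | None]]:
    """Dunnett many-to-one comparisons against a control group.

    ``control_index="auto"`` selects the group whose mean is closest
    to 1 — the natural reference for normalized connectivity ratios,
    where 1 means "indistinguishable from random".  Familywise-adjusted
    two-sided p-values come from the equicorrelated multivariate-t
    reference distribution (scipy's implementation, seeded for
    reproducibility).  Returns ``(control_index, p_values)`` with ``None``
    at the control's own position.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if control_index == "auto":
        ci = int(np.argmin([abs(float(a.mean()) - 1.0) for a in arrays]))
    else:
        ci = int(control_index)
    control = arrays[ci]
    if control.size < 2:
        raise ValueError("control group degenerate")
    others = [a for i, a in enumerate(arrays) if i != ci]
    res = stats.dunnett(
        *others, control=control, random_state=np.random.default_rng(seed)
    )
    pvals = iter(float(p) for p in np.atleast_1d(res.pvalue))
    out: list[float | None] = []
    for i in range(len(arrays)):
        out.append(None if i == ci else next(pvals))
    return ci, out


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided p-value from the t
    transform with n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# per-group orchestration
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityResult:
    """Both connectivity indexes for one group, with control normalization
    and the per-group chi-square."""

    residue: str
    group_size: int
    n_present: int
    type_a: int
    type_b: int
    raw_proportion: float
    raw_per_node: float
    control_type_a: list[int]
    control_type_b: list[int]
    control_proportions: list[float]
    control_per_node: list[float]
    norm_proportion_ratios: list[float]
    norm_per_node_ratios: list[float]
    mean_norm_proportion: float
    sem_norm_proportion: float
    mean_norm_per_node: float
    sem_norm_per_node: float
    chi2_stat: float
    chi2_p: float
    significant: bool
    n_resampled: int = 0


def _sample_one(ids: list[str], size: int, entropy: tuple[int, ...]) -> frozenset[str]:
    rng = _rng(*entropy)
    idx = rng.choice(len(ids), size=size, replace=False)
    return frozenset(ids[i] for i in idx)


def connectivity_for_group(
    interactome: Interactome,
    group: Iterable[str],
    universe: Sequence[str],
    n_controls: int = 5,
    seed: int | Sequence[int] = 0,
    chi2_controls: str = "mean",
    per_node_denominator: str = "present_members",
    alpha: float = 0.05,
    max_resample: int = 100,
    residue: str = "?",
) -> ConnectivityResult:
    """Full control-normalized connectivity analysis of one group.

    Controls are equinumerous id sets drawn without replacement from
    ``universe``.  A control replicate on which either index is zero or
    undefined (so the ratio could not be formed) is resampled with a
    fresh deterministic sub-seed, up to ``max_resample`` attempts; each
    resampling is logged and counted.

    ``chi2_controls`` picks the comparison column of the 2x2 table:
    ``"mean"`` rounds the mean of the control (a, b) counts, ``"pooled"``
    sums them.
    """
    if chi2_controls not in CHI2_MODES:
        raise ValueError(f"chi2_controls must be one of {CHI2_MODES}")
    if per_node_denominator not in DENOMINATORS:
        raise ValueError(f"per_node_denominator must be one of {DENOMINATORS}")
    entropy = tuple(seed) if isinstance(seed, (tuple, list)) else (seed,)
    gset = frozenset(group)
    gn = extract_group_network(interactome, gset)
    raw_prop = proportion_index(gn)  # raises UndefinedIndexError if isolated
    raw_pn = per_node_index(gn, per_node_denominator)

    ids = sorted(set(universe))
    if len(gset) > len(ids):
        raise ValueError("group larger than sampling universe")

    ctl_a: list[int] = []
    ctl_b: list[int] = []
    ctl_prop: list[float] = []
    ctl_pn: list[float] = []
    n_resampled = 0
    for rep in range(n_controls):
        ok = False
        for attempt in range(max_resample):
            members = _sample_one(ids, len(gset), entropy + (rep, attempt))
            cgn = extract_group_network(interactome, members)
            try:
                cp = proportion_index(cgn)
                cn = per_node_index(cgn, per_node_denominator)
            except UndefinedIndexError:
                cp = cn = 0.0
            if cp > 0 and cn > 0:
                ctl_a.append(len(cgn.type_a))
                ctl_b.append(len(cgn.type_b))
                ctl_prop.append(cp)
                ctl_pn.append(cn)
                ok = True
                break
            n_resampled += 1
            logger.info(
                "group %s control %d attempt %d: zero index, resampling",
                residue, rep, attempt,
            )
        if not ok:
            raise UndefinedIndexError(
                f"group {residue}: control replicate {rep} had zero indexes "
                f"after {max_resample} resampling attempts"
            )

    prop_ratios, prop_mean, prop_sem = normalize_against_controls(raw_prop, ctl_prop)
    pn_ratios, pn_mean, pn_sem = normalize_against_controls(raw_pn, ctl_pn)

    a1, b1 = len(gn.type_a), len(gn.type_b)
    if chi2_controls == "mean":
        a2 = int(round(float(np.mean(ctl_a))))
        b2 = int(round(float(np.mean(ctl_b))))
    else:
        a2 = int(np.sum(ctl_a))
        b2 = int(np.sum(ctl_b))
    try:
        chi2_stat, chi2_p = yates_chi2_test(a1, b1, a2, b2)
        significant = chi2_p < alpha
    except ValueError:
        chi2_stat, chi2_p, significant = float("nan"), float("nan"), False

    return ConnectivityResult(
        residue=residue,
        group_size=len(gset),
        n_present=len(gn.present_members),
        type_a=a1,
        type_b=b1,
        raw_proportion=raw_prop,
        raw_per_node=raw_pn,
        control_type_a=ctl_a,
        control_type_b=ctl_b,
        control_proportions=ctl_prop,
        control_per_node=ctl_pn,
        norm_proportion_ratios=prop_ratios,
        norm_per_node_ratios=pn_ratios,
        mean_norm_proportion=prop_mean,
        sem_norm_proportion=prop_sem,
        mean_norm_per_node=pn_mean,
        sem_norm_per_node=pn_sem,
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
        significant=significant,
        n_resampled=n_resampled,
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class ConnectivityModel:
    """Control-normalized connectivity analysis over all polyX groups.

    Parameters
    ----------
    groups
        Mapping residue -> :class:`~polyxnet.repeats.PolyXGroup` (or any
        mapping of residue to an id set).
    interactome
        The loaded :class:`~polyxnet.interactome.Interactome`.
    universe
        Id universe for control sampling; defaults to the union of all
        group members and interactome nodes, but the intended use is the
        full proteome id list.
    min_group_size
        Groups below this size are skipped (default 2: a one-protein
        group cannot have within-group interactions).
    """

    def __init__(
        self,
        groups: Mapping[str, PolyXGroup] | Mapping[str, Iterable[str]],
        interactome: Interactome,
        universe: Sequence[str] | None = None,
        n_controls: int = 5,
        min_group_size: int = 2,
        chi2_controls: str = "mean",
        per_node_denominator: str = "present_members",
        alpha: float = 0.05,
    ) -> None:
        self.groups = {
            res: (g.members if isinstance(g, PolyXGroup) else frozenset(g))
            for res, g in groups.items()
        }
        self.interactome = interactome
        if universe is None:
            universe = sorted(
                set().union(*self.groups.values(), interactome.nodes)
            )
        self.universe = sorted(set(universe))
        self.n_controls = n_controls
        self.min_group_size = min_group_size
        self.chi2_controls = chi2_controls
        self.per_node_denominator = per_node_denominator
        self.alpha = alpha

    def fit(self, seed: int = 0) -> "ConnectivityResults":
        """Run the per-group analyses and the cross-group statistical
        battery.  All randomness (control sampling, Dunnett reference
        quadrature) derives from ``seed``; groups get independent
        deterministic sub-seeds so adding or removing one group does not
        perturb the others."""
        results: list[ConnectivityResult] = []
        skipped: list[tuple[str, str]] = []
        for res in sorted(self.groups):
            members = self.groups[res]
            ordinal = STANDARD_RESIDUES.index(res) if res in STANDARD_RESIDUES else 99
            if len(members) < self.min_group_size:
                skipped.append((res, f"size {len(members)} < min_group_size"))
                continue
            try:
                results.append(
                    connectivity_for_group(
                        self.interactome,
                        members,
                        self.universe,
                        n_controls=self.n_controls,
                        seed=(seed, ordinal),
                        chi2_controls=self.chi2_controls,
                        per_node_denominator=self.per_node_denominator,
                        alpha=self.alpha,
                        residue=res,
                    )
                )
            except UndefinedIndexError as exc:
                skipped.append((res, str(exc)))
        return ConnectivityResults(self, results, skipped, seed)


class ConnectivityResults:
    """Fitted connectivity analysis: per-group results plus the ANOVA /
    Dunnett / Pearson summary."""

    def __init__(
        self,
        model: ConnectivityModel,
        group_results: list[ConnectivityResult],
        skipped: list[tuple[str, str]],
        seed: int,
    ) -> None:
        self.model = model
        self.group_results = group_results
        self.skipped = skipped
        self.seed = seed
        self.anova: tuple[float, int, int, float] | None = None
        self.dunnett_control: str | None = None
        self.dunnett_p: dict[str, float | None] = {}
        self.pearson: tuple[float, int, float] | None = None
        self._summarize()

    def _summarize(self) -> None:
        rs = self.group_results
        if len(rs) >= 2:
            samples = [r.norm_per_node_ratios for r in rs]
            self.anova = one_way_anova(samples)
            ci, pvals = dunnett_posthoc(samples, "auto", seed=self.seed)
            self.dunnett_control = rs[ci].residue
            self.dunnett_p = {r.residue: p for r, p in zip(rs, pvals)}
        if len(rs) >= 3:
            x = [r.mean_norm_proportion for r in rs]
            y = [r.mean_norm_per_node for r in rs]
            try:
                r_val, p_val = pearson_correlation(x, y)
                self.pearson = (r_val, len(rs), p_val)
            except ValueError:
                self.pearson = None

    @property
    def frame(self) -> pd.DataFrame:
        """One row per analyzed group, mirroring the connectivity table."""
        rows = []
        for r in self.group_results:
            row: dict[str, object] = {
                "residue": r.residue,
                "group_size": r.group_size,
                "n_present": r.n_present,
                "type_a": r.type_a,
                "type_b": r.type_b,
                "raw_proportion": r.raw_proportion,
                "raw_per_node": r.raw_per_node,
            }
            for i, (pr, nr) in enumerate(
                zip(r.norm_proportion_ratios, r.norm_per_node_ratios), 1
            ):
                row[f"prop_ratio_{i}"] = pr
                row[f"per_node_ratio_{i}"] = nr
            row.update(
                {
                    "mean_norm_proportion": r.mean_norm_proportion,
                    "sem_norm_proportion": r.sem_norm_proportion,
                    "mean_norm_per_node": r.mean_norm_per_node,
                    "sem_norm_per_node": r.sem_norm_per_node,
                    "chi2_stat": r.chi2_stat,
                    "chi2_p": r.chi2_p,
                    "significant": r.significant,
                    "dunnett_p": self.dunnett_p.get(r.residue),
                    "n_resampled": r.n_resampled,
                }
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table of the fitted analysis."""
        lines = ["Connectivity of polyX groups vs. equinumerous random controls"]
        lines.append(
            f"  controls per group: {self.model.n_controls}   seed: {self.seed}   "
            f"chi2 controls: {self.model.chi2_controls}   "
            f"per-node denominator: {self.model.per_node_denominator}"
        )
        lines.append(
            f"{'grp':>3} {'size':>6} {'a':>6} {'b':>7} "
            f"{'prop.norm':>12} {'pernode.norm':>14} {'chi2':>9} {'p':>9} {'sig':>4}"
        )
        for r in self.group_results:
            lines.append(
                f"{r.residue:>3} {r.group_size:>6} {r.type_a:>6} {r.type_b:>7} "
                f"{r.mean_norm_proportion:>6.3f}±{r.sem_norm_proportion:<5.3f} "
                f"{r.mean_norm_per_node:>7.3f}±{r.sem_norm_per_node:<5.3f} "
                f"{r.chi2_stat:>9.3f} {r.chi2_p:>9.3g} {'*' if r.significant else '':>4}"
            )
        empty = [res for res, why in self.skipped if why.startswith("size 0")]
        if empty:
            lines.append(f"empty groups (no repeat proteins): {', '.join(empty)}")
        for res, why in self.skipped:
            if res not in empty:
                lines.append(f"{res:>3} skipped: {why}")
        if self.anova:
            f, dfb, dfw, p = self.anova
            lines.append(
                f"One-way ANOVA on normalized per-node ratios: "
                f"F({dfb}, {dfw}) = {f:.2f}, p = {p:.3g}"
            )
        if self.dunnett_control is not None:
            lines.append(
                f"Dunnett post-hoc control group: poly{self.dunnett_control} "
                f"(mean ratio closest to 1)"
            )
        if self.pearson:
            r_val, n, p = self.pearson
            lines.append(
                f"Pearson correlation of the two indexes: r = {r_val:.2f}, "
                f"n = {n}, p = {p:.3g}"
            )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write ``connectivity.tsv`` and ``summary_stats.tsv``."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(
            outdir / "connectivity.tsv", sep="\t", index=False, float_format="%.10g"
        )
        rows = []
        if self.anova:
            f, dfb, dfw, p = self.anova
            rows.append(("anova_F", f))
            rows.append(("anova_df_between", dfb))
            rows.append(("anova_df_within", dfw))
            rows.append(("anova_p", p))
        if self.dunnett_control is not None:
            rows.append(("dunnett_control", self.dunnett_control))
            for res, p in sorted(self.dunnett_p.items()):
                if p is not None:
                    rows.append((f"dunnett_p_{res}", p))
        if self.pearson:
            r_val, n, p = self.pearson
            rows.append(("pearson_r", r_val))
            rows.append(("pearson_n", n))
            rows.append(("pearson_p", p))
        with open(outdir / "summary_stats.tsv", "w") as fh:
            fh.write("statistic\tvalue\n")
            for k, v in rows:
                fh.write(f"{k}\t{v:.10g}\n" if isinstance(v, float) else f"{k}\t{v}\n")


def analyze_all_groups(
    groups: Mapping[str, PolyXGroup],
    interactome: Interactome,
    universe: Sequence[str] | None = None,
    n_controls: int = 5,
    seed: int = 0,
    min_group_size: int = 2,
    **kwargs,
) -> ConnectivityResults:
    """Functional wrapper: build a :class:`ConnectivityModel` and fit it."""
    model = ConnectivityModel(
        groups,
        interactome,
        universe=universe,
        n_controls=n_controls,
        min_group_size=min_group_size,
        **kwargs,
    )
    return model.fit(seed=seed)
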