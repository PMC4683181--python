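# Methods

## Repeat scanning and group definition

A homopolymeric amino-acid repeat (AAR) is a maximal run of one of the 20
standard residues; a protein belongs to the polyX group when it carries at
least one run of X of length ≥ `min_run_length` (default 4). Runs are
pure: a single interrupting residue ends a run, and interruption-tolerant
variants are deliberately not implemented — the operational definition is
the uninterrupted run, and a fragmented-repeat notion would need a second
tolerance parameter with no principled default. Non-standard letters
(X, U, B, Z, `*`) break runs and never form them: only the 20 standard
residues define groups. All coordinates in files and APIs are 1-based
inclusive, the convention of NCBI CDD domain tables, so repeat and domain
intervals compare directly.

## Connectivity indexes and control normalization

For group G and an undirected simple interactome, edges incident to G
split into type a (both endpoints in G) and type b (exactly one). The
proportion index `a/(a+b)` measures how much of the group's interaction
activity stays internal; the per-node index `2a/n` measures internal
interaction density per protein. The per-node denominator `n` is, by
default, the group members present in the interactome (≥ 1 interaction of
any kind): group networks are built from proteins with interaction
evidence, and counting never-observed proteins would deflate the index by
a factor unrelated to within-group structure. `typea_nodes` (only
endpoints of type-a edges) and `all_members` are selectable alternatives,
because the denominator is a genuine modelling choice; with
`present_members` the planted-partition recovery studies return the
planted `p_in/p_out` ratio, which is the behaviour the normalization is
meant to have.

Controls are 5 equinumerous protein sets drawn uniformly without
replacement from the full proteome id universe (not only from interactome
nodes — random proteins without interaction evidence are part of the null
being emulated). Each raw index is divided by each control's index; the
mean and SEM (sample SD / √5) of the 5 ratios are reported. A control
replicate on which either index is 0 (so no ratio can be formed) is
resampled with a fresh deterministic sub-seed, up to 100 attempts, each
attempt logged; dropping such replicates instead would bias the effective
number of controls. On the group sizes the analysis targets this path is
essentially never taken.

Seeding: one master seed; per-(group, replicate, attempt) seeds derive
from it through `numpy.random.SeedSequence` entropy lists, so every group
is statistically independent and any subset of the analysis reproduces
exactly.

## The statistical battery

* **χ² with Yates' correction**, 1 df, on the 2×2 table of the group's
  (a, b) against a control column. Two constructions are provided: the
  default `mean` rounds the mean of the 5 control count pairs (one
  averaged "typical control network"); `pooled` sums them. The pooled
  table is the statistically calibrated one — the independence test's
  null variance `p(1−p)(1/n₁ + 1/n₂)` matches the actual sampling
  variance of a group-versus-5-pooled-controls comparison, while the
  `mean` construction treats a 5-replicate average as a single sample and
  is severely conservative. The simulation studies therefore use
  `pooled`; `mean` is retained as the default because it mirrors the
  verbal definition of comparing against the average control network.
* **One-way ANOVA** across groups on the 5 normalized per-node ratios
  each (19 analyzable groups on a real proteome ⇒ df 18, 76); zero
  within-group variance with distinct means reports F = ∞ explicitly.
* **Dunnett many-to-one comparisons** of every group against the group
  whose mean ratio is closest to 1 (the natural "indistinguishable from
  random" reference; an explicit control index can be forced). The
  familywise-adjusted p-values come from the equicorrelated
  multivariate-t distribution (scipy's implementation), with the
  quasi-Monte-Carlo integration seeded so results are reproducible.
* **Pearson correlation** between the two mean normalized indexes across
  groups, two-sided p from the t transform.

Groups below `min_group_size` (default 2) are skipped — a one-protein
group cannot have within-group interactions — as is any group with no
interactions at all; skips are reported with reasons, never silently.

## Domain enrichment

One-sided hypergeometric over-representation per (group, domain):
`p = P(X ≥ k)` with N the background size, K background carriers, n the
group size, k group carriers. The BH family is the set of domains tested
within one group, mirroring one annotation-server run per protein list.
The default background is the whole proteome; `annotated` (proteins with
≥ 1 annotation) approximates servers that silently drop unannotated
proteins. The EASE variant (tail from k − 1, never below 0) is opt-in:
it is the conservative choice of popular servers, but the plain
hypergeometric is the exact test for the stated null. Coiled-coil status
enters as an ordinary domain id; there is no keyword subsystem.

## Repeat–domain overlap

A protein carrying both a run of X and an instance of domain D counts as
overlapping when ANY single (run, instance) interval pair shares
≥ `min_overlap` positions (default 4). Overlap is never summed across
runs: the threshold expresses "the repeat lies within/across the domain",
which a union of sub-threshold fragments does not show. All domain
instances on a protein are considered (domain tables report repeated
hits). By default only enrichment-significant (group, domain) pairs are
summarized (`--all-pairs` overrides). Fractions are banded as none /
partial(<25%) / 25–100% for qualitative reporting.

## Synthetic data: what it emulates and what it does not

The generator plants known structure at the three levels the pipeline
consumes:

* **Proteome** — lengths lognormal (median ≈ 350, clipped to
  [60, 2000]); residues i.i.d. from UniProtKB's global amino-acid
  frequencies; accidental runs ≥ `min_run_length` are resampled away
  (with flank letters constrained so a planted run can never extend past
  its recorded coordinates), making planted group membership exact by
  construction. With suppression off, ground truth is recomputed by
  scanning the final sequences.
* **Interactome** — planted partition: within-group pairs get edges with
  probability `p_in`, all others `p_out`. Defaults `p_out = 0.06`
  (mean degree ≈ 30 at a 500-protein universe, comparable to curated
  human interactome density) and `p_in = 0.144`, i.e. a 2.4× elevation,
  the size of the strongest repeat-class effect the analysis is designed
  to detect. The density also serves a bias budget: the normalized index
  is a ratio with a noisy denominator, so its expectation exceeds the
  true ratio by roughly the denominator's squared coefficient of
  variation (≈ 2% at these counts); much sparser networks would inflate
  null ratios visibly.
* **Domains** — a planted domain hits group members with `q_in` and
  outsiders with `q_out`; with probability `w` a member's instance is
  anchored at the planted run start (guaranteeing ≥ 4 shared positions),
  otherwise placed disjoint from every recorded run; decoys are uniform.

Deliberately not emulated: scale-free degree distributions, repeat
length/composition correlations, shared-domain-driven edge correlations,
id-mapping noise between databases. Passing the recovery studies
therefore shows the estimators are unbiased and calibrated under
exchangeable-null and planted-partition conditions — not that any given
real proteome snapshot will reproduce a particular published effect size.

## Calibration and recovery studies

`polyxnet.studies` packages four studies (also driven by
`scripts/acceptance.py` and the acceptance tests):

* **Null calibration** (1000 datasets, universe 500, group 40,
  `p_in = p_out = 0.06`): both mean normalized ratios should sit within a
  few percent of 1 (the residual excess is the ratio-estimator bias
  above), and the pooled-χ² rejection rate near the nominal 5%. The
  Yates correction plus the membership overlap between a group and its
  controls leave the realized size slightly conservative (≈ 3–4%),
  never anti-conservative.
* **Effect recovery** (200 replicates, universe 600, group 60,
  `p_out = 0.01`): mean normalized per-node index ≈ 2.4 at ρ = 2.4 and
  ≈ 0.4 at ρ = 0.4 (a depleted, membrane-protein-like fixture).
* **Enrichment recovery** (100 replicates, group 40 of 400, `q_in` 0.5,
  `q_out` 0.05, 50 decoys): the planted domain is BH-significant
  essentially always; replicates flagging any decoy stay below 10%.
* **Overlap recovery**: pooled overlap fractions at planted
  w ∈ {0, 0.5, 1} fall within the binomial 95% CI of w (exactly 0 and 1
  at the extremes, by construction).

Study sizes were chosen to give sampling error well inside the effects
being measured while keeping a full run in the tens of seconds on one
CPU.

## Numerical and degenerate-input policy

Undefined quantities are never silently coerced: an index with an empty
denominator raises a typed error that the orchestration converts into an
explicit skip listing; a χ² with a zero marginal reports NaN and
non-significance; Pearson with zero variance is refused. SEM uses the
sample (ddof = 1) standard deviation. TSV floats are written with a fixed
`%.10g` format and sorted row order, making reruns byte-identical; the
run manifest records every parameter, the seed and SHA-256 checksums of
all inputs, so a run is reproducible from the manifest alone.

## Known limitations

* Interactome and proteome must share one id namespace; no id mapping is
  attempted (a warning reports the overlap rate). Real analyses need
  pre-mapped inputs.
* The χ² `mean` default mimics the verbal average-control comparison but
  is conservative; use `pooled` when calibrated size matters.
* Published repeat-class effect sizes depend on specific database
  snapshots (proteome, interactions, domain assignments) and on the exact
  enrichment backend a study used; this package recomputes the method,
  not any particular snapshot's numbers.
* Dunnett p-values use seeded quasi-Monte-Carlo integration and are
  reproducible at fixed seed but carry ~1e-3-level integration noise.
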