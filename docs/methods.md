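# Methods

This note documents the statistical model behind `dynsig`, the design
choices that were genuinely open, the simulator's assumptions, and the
limits of what the bundled benchmark can demonstrate.

## Regulatory states and discretization

All modeling happens on a tri-state alphabet per gene and sample:
downregulated (D), non-regulated (N), upregulated (U), stored
internally as codes 0/1/2 and on disk as −1/0/1. The alphabet order
D < N < U is part of the contract (tie-breaks and file encoding depend
on it).

Discretization reduces, for every supported rule, to a per-gene pair of
cut points `(lo, hi)` with `value < lo -> D`, `value > hi -> U`, else
N. Three rules are available:

- **zscore** (default for real data): cuts at `mean ± k·sd` per gene,
  `k = 1`, sample standard deviation (`ddof=1`). A zero-variance gene
  cannot be polarized and maps to all-N with a warning rather than an
  error.
- **fixed** (default for the simulation benchmark): global thresholds,
  default `(2, 4)` — the midpoints of the simulator's emission means
  1/3/5.
- **quantile**: per-gene cuts at the lower/upper quartiles by default.

Because every rule is thresholding, the state mapping is monotone in
expression, and re-applying derived thresholds is idempotent — both are
property-tested. Missing values are rejected at load time; imputation
is deliberately out of scope.

**Sensitivity.** Discretization is the single step this method is most
sensitive to. In the benchmark, fixed thresholds at (2, 4) separate the
extreme states well but confuse adjacent majors (the D/N and N/U
emission distributions, normals with sd 2 spaced 2 apart, overlap
heavily); supplying the generating states directly raises every
benchmark figure to its ceiling (see "What the benchmark shows").
Published figures obtained with other discretizers are therefore only
comparable to within the fidelity of the discretization step.

## The link model

A directed link `g1 -> g2` is a two-node Markov chain per class:
initial distribution `P0` (source-state frequencies) and transition
matrix `M` with `M[x, y]` the conditional frequency of the destination
state given the source state. A source state unobserved in training
yields an all-zero row (0/0 := 0) — the joint likelihood
`P0(x)·M[x, y]` of any pair through that state is 0, which is exactly
the count identity `P0(x)·M[x, y] = C[x, y]/n` (C the 3×3 pair-count
table). An optional Laplace pseudocount `alpha` (default 0) smooths TPM
rows for users who prefer positive transition estimates; `P0` is never
smoothed, so unseen source states still get zero likelihood.

## LOOCV link scoring

Each sample is held out of its own class's training set (the other
class stays complete), both class models are refitted, and the sample
is assigned to the class with the strictly larger joint likelihood.
Ties — including 0 vs 0 — count as incorrect: the rule is
deterministic, seed-free, and conservative. The link score `d` is the
fraction of correct assignments.

Two implementation routes exist and are cross-checked in the tests: a
literal per-sample refit (`loocv_link_score`) and a vectorized route
(`loocv_scores`) built on the count identity — the held-out likelihood
is `(C_own[x, y] − 1)/(n_own − 1)` against `C_other[x, y]/n_other`.
The vectorized route scores thousands of links per second, which is
what makes the permutation null affordable.

**Small-sample bias.** Under exchangeable labels `d` is not centered
exactly at 0.5: the two training sets have unequal sizes (n−1 vs n),
and equal training counts favor the own class (`k/(n−1) > k/n`). At
n = 60 per class the null mean of `d` is ≈ 0.53–0.55. The bias shifts
observed and null pathways alike, so the permutation test absorbs it;
`d` values should nevertheless be compared to an empirical null, never
to 0.5 literally.

**Degenerate inputs.** If both classes present identical state columns,
every comparison ties and `d = 0`. A fully deterministic dataset (e.g.
noise-free simulation of a non-differential pathway) therefore gives
`d = 0` for observed and null pathways alike and, under the strict
inequality below, `p = 0` — significance on such degenerate data is
meaningless and the benchmark keeps emission noise positive.

## Pathway statistic and permutation null

`DEP` is the arithmetic mean of the pathway's link scores over links
whose two genes are both present in the data; pathways with fewer than
two present links are dropped (with a warning). Significance comes from
`Z` random pathways (default 1000; the desk-scale benchmark uses 200),
each built on the pathway's own genes with the same number of links —
`L` distinct directed non-self pairs sampled uniformly — and scored
under a fresh random permutation of the class labels:

```
p = (1/Z) · Σ_i 1(DEP_obs < rDEP_i)
```

Strict inequality is used and `p = 0` is possible; a smoothed
`(1 + hits)/(1 + Z)` estimator is available behind `smoothed=True` for
workflows where downstream FDR control needs positive p-values.

**Why shuffle labels in the null.** Randomizing only the wiring over
the pathway's own genes leaves the class signal of those genes intact —
any ordered gene pair carries the same marginal information as a true
link — so that null has essentially no power against distributed
differential signal. Randomizing genes over the whole dataset imports
whatever differential genes the dataset contains into the null. Scoring
the random pathways under permuted labels removes class signal from the
null by construction, is calibrated on null pathways (empirically, the
type-I level at p < 0.05 sits at the nominal level within binomial
error), and retains power. Both alternative nulls remain available
(`gene_pool="genome"`, `shuffle_labels=False`) for studying topology
effects specifically.

Per-pathway randomness is seeded by `(run seed, crc32(pathway name))`,
so p-values are independent of the order pathways are supplied in and
the whole pipeline is bit-reproducible under a fixed seed.

Multiple testing uses Benjamini–Hochberg step-up adjustment
(statsmodels). The reporting cutoffs (p < 0.05, q < 0.1) are
configuration, not hard-coded.

## Principal signaling patterns

For an ordered chain `g1 -> … -> gk` and one class, each link gets its
fitted model and the pattern is assembled backward from the ending
link: the ending link contributes the most probable transition mode
(fixing the last two genes' states), then each earlier link contributes
the most probable source state given its destination's already-fixed
state. If no training sample reaches the required destination state,
the pattern is reported as undefined upstream of that point, with a
warning.

Two definitions of "most probable" are provided. The default,
`mode="joint"`, maximizes `P0(i)·M[i, j]` at the ending link and the
joint counts into the fixed state backward — every choice is weighted
by how often the source state actually occurs. `mode="conditional"`
maximizes raw TPM entries; it is scale-free in the source state, which
sounds attractive but lets a state observed in a handful of samples tie
or beat the dominant one on a noisy 0/small-denominator estimate — in
the parameter-recovery benchmark the conditional rule recovers the
generating patterns on 86% of differential pathways versus 100% for the
joint rule, which is why joint is the default. Argmax ties are broken
by the fixed order D < N < U, source state first.

## The simulator

Each dataset holds `n_pathways` pathways (default 200, first half
differential) over disjoint gene sets — disjointness keeps pathway
truth unambiguous — with balanced classes (default 60 samples each).
Topologies: a ten-gene cascade (nine links), or a bundled 15-gene,
20-link "complex" graph with two branch and two convergence points
standing in for a curated signaling map (users can substitute their own
edge list; the bundled one ships as `data/complex_topology.sif`).

Every gene has a per-class major state; in a differential pathway a
fraction `rho` of genes (at least one) redraw their case-class major
uniformly among the two other states, so the two classes carry
different principal patterns. Per sample, with probability `r` the
pathway exhibits its dominant pattern — every member gene in its major
state — and otherwise each gene independently falls to one of its two
minor states. Marginally each gene is in its major state with
probability `r` and in each minor state with probability `(1 − r)/2`;
jointly, genes of a pathway rise and fall together, which is what makes
link transition structure (and not just per-gene marginals)
class-informative. `correlated=False` selects fully independent
per-gene draws with the same marginals; this variant carries strictly
less topology-level signal and exists for sensitivity analysis.

Continuous emissions: a gene in its major state draws from a normal
with mean 1/3/5 (D/N/U) and variance 4; in a minor state, from a gamma
with shape 1/3/5 and scale 0.5. Both conventions are configurable
(`normal_sd`, `gamma_shapes`, `gamma_scale`) since the
variance-vs-sd and shape/scale-vs-rate readings of such shorthand
differ across the literature. Note the asymmetry this creates: all
three minor-state gammas have small means (0.5–2.5), so minor-state
emissions mostly discretize to D under the (2, 4) thresholds. That is
part of the intended noise structure, not a bug: off-pattern samples
become nearly uninformative, and detection must rest on the on-pattern
majority.

**What the simulator does not emulate:** shared genes between pathways,
background (non-pathway) genes, gene–gene correlation beyond the
pattern switch, batch effects, library-size or intensity
normalization issues, and missingness. Passing benchmarks here
demonstrates correctness of the machinery under the stated generative
model, not performance on any real platform.

## Benchmark protocol and problem sizes

The bundled study (`dynsig benchmark`, `scripts/acceptance.py`,
`tests/test_acceptance.py`) uses cascade structure, r = 0.5,
rho ∈ {0.3, 0.5, 0.7}, 60 samples per class, 200 pathways, five
replicate datasets per scenario and Z = 200 — a scale chosen so the
full grid completes in about two minutes on one CPU while keeping the
Monte-Carlo error of scenario means near one percentage point. Metrics:
ACC/TPR/FPR/PPV/FNR/MCC at the p < 0.05 cutoff (NA when a denominator
is zero, propagated through scenario means) and rank-based
(Mann–Whitney, ties = ½) ROC AUC computed on the DEP statistic
directly — the statistic is the natural continuous ranking score and
needs no permutation. Replicate seeds derive from the master seed and
the scenario parameters, so extending the grid never perturbs existing
scenarios.

With the generating states supplied in place of threshold-discretized
ones, the protocol reaches TPR ≈ 100% and AUC ≈ 1.0 at rho ≥ 0.5 —
the gap between that ceiling and the fixed-threshold figures is
entirely the discretization step (see "Sensitivity" above).

## Known limitations

- Links are modeled pairwise; chains of three or more genes as a single
  Markov process are not implemented.
- The LOOCV tie rule makes `d` conservative; alternative tie handling
  would shift levels (not orderings) of link scores.
- The permutation p-value is exactly zero for top-ranked pathways at
  finite Z; use `smoothed=True` when downstream tools require p > 0.
- Relation types on links (activation/inhibition) are parsed and stored
  but do not enter the statistic.
- Real-data preprocessing support is limited to probe collapsing
  (mean) and a coefficient-of-variation filter; identifier mapping and
  pathway-database retrieval are out of scope.
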