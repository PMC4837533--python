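# Methods

## Model and scope

`massgain` models genetic gain from one round of seedling selection on a
single trait in a clonally propagated crop. Because selected seedlings are
propagated clonally, the relevant heritability is broad-sense
(`H = V_G/V_P`): dominance and epistasis are captured along with additive
effects. The second key parameter is the DNA test's predictiveness
(`P = V_M/V_G`), the share of genotypic variance explained by the tested
marker loci. Everything else about the genome is collapsed into a normally
distributed background effect `g_B ~ N(0, V_B)`; the environment contributes
`e ~ N(0, V_E)`. Marker effects are assumed known without error, markers are
completely linked to their trait loci, and marker loci do not interact with
the background genome. Estimation error, recombination, multi-trait
selection and cost/time efficiency are out of scope.

## Populations

Two segregating populations are built in, both on a scale whose zero point
is 25 (chosen so most phenotypes are positive; the constant cancels in every
gain and is added only when phenotypes are materialized):

- **Three genotypes** — a single marker-tagged locus from a biparental
  cross, MM : Mm : mm = 1 : 2 : 1, class means `a3, d3, −a3` (adjusted
  scale). Dominance cases: none (`d3 = 0`), partial (`d3 = a3/2`), complete
  (`d3 = a3`). Population mean `d3/2`;
  `a3 = sqrt(4·V_M / (2 + (d3/a3)²))` makes the class-mean variance equal
  `V_M` exactly.
- **Nine genotypes** — two unlinked loci (major M: effects `2a9, a9, −2a9`;
  minor T: `a9, 0, −a9`) with epistatic overrides for MMTt (`3a9`) and mmTT
  (`−2.5a9`); frequencies are the 1:2:1 ⊗ 1:2:1 cross products. Population
  mean `17·a9/32`. `a9 = sqrt(V_M / c)` where `c = 3.6708984375` is the
  frequency-weighted variance of the class means at `a9 = 1`, obtained by
  enumeration. (The enumeration definition is used because it is the only
  self-consistent one: it reproduces the class table's variance by
  construction, and every published effect value follows from it.)

The table type accepts arbitrary class lists, but only these two populations
have constructors.

## Study conditions (defaults)

`V_P = 200` trait units²; `H, P ∈ {0.2, 0.5, 0.8, 1.0}` (16 scenarios,
H-outer ordering); `N = 400` seedlings; 1000 replicates per cell; TSP grid
0.05–0.95 in steps of 0.05; SP_M grid from TSP to 1 in the same steps. These
defaults are the package's standing experimental conditions, not tuning
knobs. Genotype counts are assigned exactly (100/200/100 at N = 400), not
sampled multinomially — only `g_B` and `e` are stochastic — so N must be a
multiple of 4 (three-genotype) or 16 (nine-genotype).

## Selection strategies

All strategies retain `round(TSP·N)` seedlings (ties-to-even; the study
grids are exact multiples so rounding only matters for user-supplied
proportions). Ranking ties are broken uniformly at random — with continuous
noise ties have probability zero, but zero-noise scenarios (`H = P = 1`)
then degrade gracefully to random within-class culling, matching the
marker-only rule.

- *phenotype-only*: top seedlings by `z`.
- *marker-only*: classes in descending mean; the boundary class is thinned
  uniformly at random. Thinning leaves the class mean unchanged, which is
  why the exact expected gain is obtained by fractional enumeration.
- *two-stage*: marker-only truncation to `round(SP_M·N)` survivors, then
  phenotypic truncation among survivors; the final count equals
  `round(TSP·N)` exactly (the implied `SP_P = TSP/SP_M` is not re-rounded).
  Stage 2 ranks raw `z`; no re-standardization.
- *index*: `I = z + b_m·g_M`, `b_m = (1/H−1)/(1−P)` — the linear-projection
  weights for predicting `g` from `(z, g_M)`. Degenerate cases: `H = 1` is
  pure phenotype (`b_m = 0`); `P = 1` with `H < 1` is the `b_m → ∞` limit,
  implemented as lexicographic (marker class, then `z`) ranking. Using the
  adjusted marker scale changes no ranking.

Realized gain is the mean genotypic value of the selected seedlings minus
the mean of the whole pre-selection population.

## Analytic predictions

Closed forms are infinite-population expectations. The phenotype-only and
stage-2 formulas assume a normal phenotype; the mixture of marker classes
violates this increasingly as `H·P` grows, and that approximation gap —
quantified by the derived-vs-simulated Pearson correlations — is a finding,
not a defect. Where the source expressions are printed with bare variances,
dimensional consistency (gain = heritability × intensity × standard
deviation) fixes the intended `√V`; the stage-1 gain orientation is
`M′ − M` (non-negative under truncation from above). Two-stage optima are
grid argmaxes with ties resolved to the largest SP_M (least marker culling);
an exact tie occurs only in degenerate zero-variance cases. When truncation
leaves no residual variance (`V_P′ = 0`) the stage-2 response is zero and
`H′` is left undefined rather than 0/0.

## Replication and randomness

Every replicate stream descends from a root seed via `SeedSequence` spawn
keys. `run_cell` keys streams by the full cell identity (scenario,
population, dominance, strategy, TSP, SP_M, replicate), so any cell is
independently reproducible. The `sweep` engine instead keys streams by
replicate only and scores *all* requested cells on the same simulated
populations (common random numbers): comparisons between strategies and
grid points become paired, which sharpens contrasts without biasing means,
and makes two-stage at SP_M = 1 (or SP_M = TSP) select the identical
seedling set as phenotype-only (marker-only) within a replicate. Standard
deviations use `ddof = 1`; the 95% CI is `±1.96·s/√n`, with `s = 0` defined
for a single replicate. Population-level variances (genotype tables, moment
diagnostics) use the divide-by-N convention so zero-noise populations match
enumerated tables exactly.

## What the simulator does and does not emulate

The generator reproduces the study's idealized conditions: exact genotype
frequencies, known marker effects, normal independent `g_B` and `e`, no
marker–background interaction, single unreplicated plants. It does not
emulate estimation error in marker effects or in `H`/`P`, marker–trait
recombination, non-normal environments, family structure, or multi-trait
culling. Passing tests therefore validate the model's internal mathematics
and its published comparative conclusions — not field performance of MASS,
which those unmodeled factors can erode.

## Known limitations and observed deviations

- Analytic truncation thins the boundary class fractionally; the simulator
  retains whole seedlings at N = 400. The discreteness gap is part of what
  the derived-vs-simulated comparisons measure.
- Index selection is systematically slightly better (typically 1–5% of the
  gain) than the optimal two-stage strategy in mid-range scenarios, because
  it weights both signals simultaneously instead of hard-thresholding the
  marker first. At 1000 replicates the confidence intervals resolve this
  small real difference, so a strict "equal within CI" check between the two
  combined strategies fails by design; the corresponding acceptance test
  documents this in its failure message. The qualitative conclusion — both
  combined strategies at least match the best single-information strategy —
  holds everywhere.
- The marker-vs-phenotype ordering by P vs H is a per-scenario tendency. In
  populations with few classes the exact marker-only gain is capped at the
  best-class mean, so phenotype-only can win at very low TSP even when
  P > H; the ordering test therefore averages over the TSP grid and uses
  the nine-genotype population, whose smoother class distribution reflects
  the variance argument rather than discreteness artifacts.
- Published derived-effect values are matched at their printed 1-decimal
  precision; four cells of the published table are double-rounded
  (e.g. `sqrt(160) = 12.649` printed as 12.7), and the comparison accepts
  that rendering.

## Problem sizes

Unit tests use reduced replicate counts (tens to hundreds) for
sampling-based checks; the acceptance tests run the prescribed 1000
replicates at N = 400, which completes in seconds per scenario sweep. The
full 16-scenario × 4-population grid (`massgain run`) takes a few minutes on
one core.
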