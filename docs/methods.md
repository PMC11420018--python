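# Methods

## Data model

The battery has 54 items: 38 emotion-regulation (ER) strategy items on a
1–5 Likert scale in six subscales — suppression, engagement, reappraisal
(8 items each; sum-scores 8–40), rumination (6 items; 6–30), arousal
control and distraction (4 items each; 4–20) — plus nine depression and
seven anxiety items on a 0–3 scale. The published instrument does not
print its item-to-subscale assignment; the layout here is fixed by the
subscale sum-score ranges, which determine the item counts uniquely, and
items carry synthetic ids (`sup1`…`sup8`, `rum1`…`rum6`, …). Responses are
complete by contract: readers reject missing cells and out-of-range codes
by row and column.

The network has 22 nodes: six continuous strategy sum-scores and sixteen
ordinal symptom items, grouped as ER / depression / anxiety.

## Synthetic data generator

Real participant data for this design are not publicly available, so the
generator emulates their documented structure from a 22-dimensional latent
Gaussian specified through its precision matrix:

* **Strategy block.** The six factors are equicorrelated at r = +0.3; the
  corresponding precision off-diagonal is p = r/(1+4r) (exact for the
  isolated block). Each of the 38 items loads 0.7 on its factor with
  independent Gaussian noise, then is thresholded to codes 1–5 at the
  standard-normal quantiles of cumulative probabilities
  (0.10, 0.35, 0.70, 0.90).
* **Symptom block.** Any two symptoms of the same instrument have latent
  partial correlation +0.08. Symptom latents are thresholded to 0–3 at
  cumulative probabilities (0.42, 0.75, 0.91), giving right-skewed
  marginals with expected item severity 0.92 — so the sum of the 16
  symptom means sits near 14.8, the neighbourhood a community sample of
  this kind reports.
* **Cross-links.** Fourteen signed strategy–symptom partial correlations
  of magnitude 0.25 encode the reported associations (rumination –
  uncontrollable worry +, suppression – low self-esteem +, three positive
  arousal-control links, five negative reappraisal links, engagement –
  fatigue −, two negative distraction links, rumination – restlessness −).
  0.25 on the latent scale attenuates to ≈ 0.2 after discretization —
  the size of a strong reported MGM edge — and keeps the precision matrix
  comfortably positive definite (smallest eigenvalue 0.09). The
  constructor rejects configurations whose precision is not positive
  definite rather than repairing them silently.

Default sample size is N = 376. All randomness flows from one integer
seed through a single `numpy` generator; identical seeds give identical
matrices.

What the generator does **not** emulate: item-level idiosyncrasies
(wording effects, reversed items), differential item difficulty within a
subscale, demographic covariates, and any non-Gaussian dependence such as
zero-inflation beyond what thresholding induces. Passing tests therefore
demonstrate that the estimators recover this class of factor-plus-partial-
correlation structure at the study's sample size — not that they would
recover every feature of the real data.

## Network estimation

**EGA route.** Pearson correlations of the raw item scores (the analysis
is defined on raw scores; polychoric correlation is available as an
option) feed a graphical-lasso path of 100 log-spaced penalties with
min/max ratio 0.01, upper anchor at the largest absolute off-diagonal
correlation. Each fit is scored with
`EBIC = −2ℓ + E log n + 4γ E log p`, E the number of nonzero edges,
γ = 0.5 (the standard EGA default; the count E is non-increasing in γ,
which the tests assert). The selected precision matrix is returned as a
partial-correlation network; entries below 1e−4 are treated as exact
zeros. Non-PSD input correlation matrices get an eigenvalue-clipping
nearest-PD repair, logged. Glasso iterations run at tolerance 1e−3
(max 100 iterations): on item-scale problems this reproduces the
selection of the high-precision setting at an order of magnitude less
time; penalties that fail to converge are skipped. Walktrap communities
(4-step walks) use absolute edge weights — sign carries no meaning for
walk probabilities — and the dendrogram is cut at maximum modularity;
isolated nodes form their own communities.

**Mixed graphical model.** All 22 columns are z-scored with training
statistics. Each node is regressed on the other 21 by lasso; the penalty
is chosen per node by 10-fold cross-validation over 60 candidate values
(folds shuffled with a fixed seed). Ordinal symptoms enter as their
integer codes, i.e. every conditional is linear-Gaussian. This is a
deliberate simplification relative to a categorical treatment: it
preserves a single sign per edge and makes the fitted model directly
usable as a Gibbs sampler, at the price of ignoring category-specific
effects. Directed coefficient pairs are aggregated by the AND rule
(mean if both nonzero with equal sign; zero otherwise; sign-conflicting
nonzero pairs are zeroed, counted and logged). The OR rule is available.
Exact duplicate columns (|r| > 0.999) are rejected up front.

Two cross-validation selection rules are provided. The default, `"min"`
(smallest CV error), matches the convention of mixed-model estimation
with CV-selected penalties and is what the planted-sign recovery
properties are stated for. It is *not* selection-consistent: on fully
independent columns it leaves a small number of spurious edges in a
minority of datasets. The `"1se"` rule (sparsest fit within one standard
error of the CV minimum) is null-consistent — independent columns yield
an empty network essentially always — but misses weaker true edges at
N = 376. The tests pin both behaviours.

## Centrality, global properties, stability

Strength is Σⱼ|wᵢⱼ|; bridge strength restricts the sum to neighbours in a
different group (ER / depression / anxiety). Edge counts, negative-edge
counts and density are computed on the signed weighted matrix; average
path length (over reachable ordered pairs, with a disconnectedness flag),
transitivity and mean local clustering are computed on the binarized
graph (edge present iff weight ≠ 0) — on a dense psychometric network the
binarized versions are the interpretable ones, and weighted variants can
be had from the underlying `networkx` graph.

The CS coefficient uses case-dropping subsampling (without replacement,
matching its definition; never resampling): for each drop proportion q in
0.10–0.75 (step 0.05), subsamples of ⌈(1−q)n⌉ rows are drawn, the full
estimator is refit from scratch, and the statistic vector is correlated
with the full-sample one. CS is the largest q whose replicate
correlations reach 0.7 in at least 95% of replicates (strictly), 0 if
none qualifies. The reference replicate count is 500 per proportion;
the analysis scripts and the acceptance script run 20–40 replicates on a
0.1-step grid, which resolves CS to one decimal at a desk-scale runtime
(each replicate refits 22 cross-validated lasso regressions).

## Expected symptom activity

The fitted MGM defines one linear-Gaussian conditional per node: mean
Σⱼ wᵢⱼ zⱼ on the standardized scale, standard deviation equal to the
node's regression residual SD. Strategy nodes are clamped on the raw
sum-score scale and standardized with the training statistics (the sweep
grid is the strategy's integer range; training statistics are reused, not
recomputed per clamp). Unclamped nodes are updated by systematic-scan
single-site Gibbs; an ordinal node's Gaussian draw is mapped to the raw
scale, rounded and clipped to 0–3, and that code is re-standardized
before other nodes see it, so the chain's ordinal states live on the
code grid. ESA is the sum over the 16 symptom nodes of their conditional
means on the 0–3 scale (bounded 0–48 by construction).

Because the ordinal states are finite and clamped strategies are fixed, a
fully conditioned network makes the scan an exactly analysable finite
Markov chain: `exact_symptom_means` assembles the scan kernel as a
product of single-site transition matrices (transition probabilities from
Gaussian CDFs over the rounding bins) and solves its stationary
distribution. This enumeration is the independent oracle for the sampler;
on 2–3-node networks the two agree to within 0.02 at 50,000 draws.

Sampler defaults: 20,000 retained draws, 2,000 burn-in scans, thinning 1,
split across 20 parallel chains (burn-in is the total across chains;
couplings in these networks are weak, so per-chain burn-in of 100 scans
is ample, and parallel chains vectorize the update). Seeds fan out per
grid point via `numpy.random.SeedSequence.spawn`.

Baseline symptom activity has two definitions, both reported: the
**observed** sum of sample symptom means (primary — sweeps and crossing
points are referenced to it) and the **model-implied** value from an
unclamped simulation. The model-implied value runs ≈ 1.8–2.3 above the
observed one on default synthetic data: a rounded-clipped Gaussian cannot
reproduce a right-skewed ordinal marginal, each conditional's mean is
biased upward by a few hundredths, and the network's positive
within-instrument couplings amplify the bias. This is a known cost of
keeping the conditionals linear-Gaussian; it cancels when comparing
sweeps to each other and is why the observed baseline is primary.

Scenario sweeps clamp one strategy at every integer in its range with the
other five at the scenario's background values — minimum (8/8/8/6/4/4),
median (24/24/24/18/12/12) or maximum (40/40/40/30/20/20) for
(suppression, engagement, reappraisal, rumination, arousal control,
distraction). The crossing point is the smallest clamped sum-score whose
ESA *strictly* exceeds baseline. On the default synthetic network the
minimum-background sweeps sit far above baseline: nine of the fourteen
planted links are negative, so clamping all strategies near their minima
is strongly symptom-activating; this is a property of the planted
structure, not of the sampler.

## Design choices that were genuinely open

* Ordinal symptoms as linear nodewise regressions (vs multinomial):
  chosen for sign-preserving edges and a generative model the sampler can
  use; flagged above.
* CV-min vs 1-SE penalty selection: both implemented; min is default
  (see above).
* Observed vs model-implied baseline: both computed; observed is primary.
* Walktrap on absolute weights with 4 steps: the canonical defaults.
* Table-style global properties on the binarized graph; weighted variants
  possible but non-standard for path/clustering summaries of
  partial-correlation networks.

## Limitations

* The ESA engine's discretization bias (above) makes absolute
  model-implied levels systematically high; only contrasts between clamp
  settings should be interpreted.
* The symmetrized-weight conditionals do not correspond to one exact
  joint distribution (the nodewise regressions are reconciled by
  averaging), so the Gibbs chain's stationary law is defined by the scan
  itself; the enumeration oracle shares this definition deliberately, and
  small asymmetries are absorbed into it.
* CV-min penalty selection admits occasional spurious edges; CS
  coefficients at 20–40 replicates resolve the drop grid coarsely.
* The generator's planted effects are stronger than typical published
  edge weights at the low end; recovery rates on real data with weaker
  effects would be lower.
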