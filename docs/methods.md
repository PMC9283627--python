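# Methods

`epinet` implements a quantitative genetic-interaction (GI) analysis for
arrayed bacterial double-mutant screens run in two growth conditions —
auxotrophic rich medium (RM) and prototrophic minimal medium (MM) — of the
kind produced by *E. coli* synthetic genetic array (eSGA) technology. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic data generator does and does not emulate.

## Scoring model

### Multiplicative expectation

Let `W_d` and `W_r` be the single-mutant relative fitnesses of a donor
(query) and recipient (array) gene, estimated as the gene's median
normalized colony size over all partners and replicates divided by the
condition-wide median colony size (`reference_size`). Under neutrality the
expected double-mutant colony size is multiplicative:

    E_dr = reference_size * W_d * W_r

The multiplicative S-score is a t-like statistic over the pair's replicate
colonies:

    S_mult = (mean(obs) - E_dr) / (max(s, s_floor) / sqrt(n))

with `s` the replicate sample SD and `s_floor` a variance floor at the 5th
percentile of all replicate SDs, preventing tiny-variance blowups. Missing
replicates are excluded; pairs with fewer than `min_replicates` (default 4)
observations are skipped.

### Gaussian-process score

A Gaussian-process (GP) regression of the pair-mean colony size on
`(W_d, W_r)` captures smooth departures from the multiplicative surface
(e.g., saturation at low fitness). Kernel: constant x anisotropic RBF plus a
learnable white-noise term, hyperparameters by marginal-likelihood
optimization with a fixed seed. Three numerical choices matter:

- **Robust two-pass fit.** True interactions are outliers relative to the
  neutral surface and would otherwise inflate the learned noise and bend
  the mean. After a first fit, training points with residuals beyond
  `trim_sigma = 3` robust SDs (1.4826 x MAD) are dropped and the model
  refit (skipped when fewer than 2% of points would be trimmed).
- **Noise from replicates, not from the optimizer.** The score denominator
  uses the pooled median of the per-pair replicate variances of the mean
  (`median(s^2/n)`) plus the GP's smooth-function posterior variance. The
  pooled estimator is identical in expectation across conditions, which
  keeps RM and MM scores on a common scale — essential for differencing
  (a per-fit learned noise level differing by a few percent between
  conditions shifts `S_DF` of every strong pair systematically). A relative
  variance floor (`1e-6 * var(y)`) keeps the denominator positive on
  noise-free input.
- **Subsampled fit.** Screens larger than `max_fit_points = 400` pairs are
  fitted on a fixed-seed subsample and predicted for all pairs; the neutral
  surface is a smooth two-dimensional function, so a few hundred points
  determine it.

If all fitnesses are identical the predictor matrix is degenerate and the
scorer falls back to the multiplicative score with a warning.

### Significance and the static network

Scores are standardized within a condition, `Z = (S - mean S)/sd S`, with
two-sided normal `P = 2(1 - Phi(|Z|))`; a robust (median/MAD) variant is
available. A pair is non-neutral under one model when its S lies outside
the neutral band for that condition and model **and** `|Z| >= 2.0` with
`P <= 0.05`. The default bands are the published cuts of the *E. coli* TF
screen (multiplicative RM (-0.3, 1.8), MM (-1.4, 3.0); GP RM (-0.9, 1.3),
MM (-2.3, 1.9)); all comparisons are inclusive. An edge enters the static
network only when **both** models call it with the same sign (sign
concordance is the stricter reading of dual-model agreement and is
configurable), and the GP score is carried as the edge weight.

## Differential network

The differential score is `S_DF = S_MM - S_RM` over the GP static scores;
pairs scored in one condition only are flagged and excluded from calling.
Significance uses an empirical null of score differences that carries
replicate noise but no condition effect: within each condition the
replicates are split in half, each half is rescored through the same
pipeline, and the half-A minus half-B differences are pooled over pairs,
splits and conditions. `P_DF` is the two-sided empirical tail with add-one
smoothing, so it is never 0. Calls use the published cuts: aggravating when
`S_DF <= -2.6`, alleviating when `S_DF >= 1.7`, both requiring
`P_DF <= 0.05` (inclusive).

Default `n_splits = 10` (4 in the large acceptance simulations): each split
costs four GP fits and even a handful of splits pools tens of thousands of
null values at typical screen sizes.

Gain/loss of interaction is assigned to pairs with `P_DF <= 0.05` and
`|S_DF| >= 5.0`: gain = neutral in the RM static network but significant in
MM, loss = the mirror case; pairs significant (or neutral) in both are
labeled by the dominant shift (gain iff `|S_MM| > |S_RM|` — the tie rule is
our choice). Records are ordered by average-linkage hierarchical clustering
on `(S_RM, S_MM)` with Euclidean distance; the leaf order is made
deterministic by visiting the smaller cluster first with a lexicographic
tie-break on the minimal pair id.

## Network statistics

- **Process crosstalk.** For every unordered bioprocess pair (self-pairs
  included), an exact hypergeometric upper tail with parameters
  k = significant GIs between the two processes, n = possible GIs between
  them, M = significant GIs in the network, N = possible GIs in the
  network, followed by Benjamini-Hochberg FDR across process pairs. Fuzzy
  membership counts a gene pair once per process pair it instantiates; M
  and N are plain pair counts on the same universe, so
  `k <= min(n, M)` and `n <= N` hold by construction. Aggravating and
  alleviating edges can be tested separately or pooled.
- **Module crosstalk.** Observed inter-module significant-GI counts per
  module pair against a null of shuffled gene-to-module labels (module
  sizes preserved; 1000 permutations by default);
  `Z = (obs - mean)/sd`, significant at `Z >= 1.65` (one-sided ~5%). A zero
  permutation SD yields a flagged missing Z, never infinity.
- **Profiles.** Pearson correlation of two genes' GI profiles over shared
  partners (>= 30 by default, the pair itself excluded); autocorrelation is
  the same quantity for one gene between RM and MM, with genes split at
  r = 0.25 (boundary to "high", with a 1e-9 tolerance against round-off at
  an exact threshold). Pearson is used throughout.
- **Degrees.** Degree over significant edges; hubs at >= 100 GIs;
  aggravating:alleviating ratio reported as missing when the denominator is
  zero; summaries by regulator scope (local/global) and orphan status.

## Evolution

Phylogenetic profiles are binary ortholog presence vectors over a phylum
panel (default 17 bacterial phyla; presence means >= 1 species in the
phylum). A GI pair is co-conserved only if both genes are present in
**all** phyla of the panel — the panel is a parameter, so restricting to,
say, gamma-Proteobacteria is a one-argument change. Conservation enrichment
per process pair uses the same permutation machinery with profile rows
shuffled across genes. Paralogs are pairs with an alignment hit satisfying
coverage >= 0.5, E-value <= 5e-2 and identity >= 0.30 (inclusive; one
qualifying direction suffices — reciprocity is not required). The
aggravating-GI bias of paralogs is assessed against equal-sized random sets
of non-paralog pairs.

## Synthetic screens

The generator emulates the screen's design: by default 278 donors x 300
recipients x 8 replicate colonies on 32 x 48 plates, a 4.6 Mbp circular
chromosome, and a 30 kbp linkage window. Colony sizes are
`baseline * W_d * W_r` plus a planted effect for interacting pairs, plus
additive per-plate row/column offsets and a border bonus, plus i.i.d.
Gaussian replicate noise truncated at zero. Single-mutant fitness W is
truncated normal, mean 0.95, SD 0.08 on (0.4, 1.2] — the real distribution
of TF-deletion fitnesses is not published, so this is a free choice meant
to give mild, realistic fitness spread. Planted effects are +/- 6 replicate
noise SDs on the expected size (negative = aggravating), 5% of pairs per
sign, with 30% of planted pairs rewired, i.e. present in exactly one
(randomly chosen) condition. Replicate pinnings go to separate plate sets
with a seeded random pair-to-well assignment, as in arrayed screens where
replicates are separate plates; this keeps plate geometry independent of
genotype (a layout that confounds plate rows with donors would let the
row/column correction absorb genetic signal). One root seed feeds
fixed-label child streams, so adding a generator never perturbs existing
outputs.

Annotations assign orphan (72/304), global-regulator (14/304) and hypomorph
(7/304) flags by deterministic quota, 1-3 fuzzy major bioprocesses from a
13-category panel, one of 41 minor processes, and a TF family. Profile and
alignment generators plant co-conserved pairs and paralogs with decoys that
fail at least one criterion.

What the generator does **not** emulate: conjugation/selection efficiency,
pinning robotics, image analysis, spatially correlated agar gradients
beyond row/column/edge offsets, batch effects between replicate screens,
and heteroscedastic or non-Gaussian colony noise. Passing recovery tests
therefore demonstrates correctness of the scoring and calling machinery
under the stated noise model, not performance on raw plate images or on
screens with unmodeled artifacts.

## Problem sizes and calibration checks

The statistical acceptance checks run on 50 x 60 x 8 screens — large
enough for stable Z-standardization (3000 pairs) while keeping a multi-seed
protocol fast: null calibration pools 10 seeds x 2 conditions (the |Z| >= 2
call rate should match the two-sided normal tail 0.0455), recovery pools 5
seeds (static sensitivity/FDP; rewired-pair recovery and stable-pair false
calls in the differential network), and the permutation type-I checks pool
20 seeds of label-shuffled fixtures (8 modules x 10 genes with 900 edges;
60 genes with ~30% fully conserved profiles). The hypergeometric tail is
compared with exhaustive enumeration for every parameter combination with
N <= 12, and BH with the step-up definition on 1000 random vectors.

## Known limitations

- The GP scorer assumes the neutral surface is smooth in `(W_d, W_r)`;
  gene-specific effects that are not a function of marginal fitness (e.g.,
  a recipient that is systematically mismeasured) are absorbed into scores.
- The split-half null captures within-condition scoring noise but not
  cross-condition systematic differences; the pooled-replicate noise
  estimator keeps those small but cannot remove, e.g., a real global
  difference in colony-size variance between media beyond its own sampling
  error.
- Empirical differential P-values are bounded below by `1/(m+1)`; with few
  splits on small screens, heavy multiple-testing correction of `P_DF` is
  not meaningful.
- The module permutation shuffles gene labels, preserving gene-level degree
  but not the joint degree sequence of the module graph.
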