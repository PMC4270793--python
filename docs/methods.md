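# Methods

This note records the models, numerical choices and limitations behind
`nichetropism`, in the package's own terms.

## Densitometry model

A measurement is a multi-channel Z-stack (channels `wolbachia`,
`hub_marker`, `dna`; arbitrary grayscale units) plus per-plane pixel masks
for the hub and for the surrounding soma/germline.  Per plane, density =
summed bacterial-channel intensity over the mask divided by mask area
(intensity per pixel).  Masks are *inputs*: the package does not segment the
hub (published masks of this kind are drawn manually), and the two masks
must be disjoint within each plane.

**Aggregation.**  One ratio per hub, computed as mean-of-plane-densities per
region, then hub/surrounding (ratio of means).  This matches a per-hub
single-ratio-column layout and is robust to near-zero single-plane
denominators.  The alternative — mean of per-plane ratios — is implemented
(`aggregation="mean_of_ratios"`) but not the default; with noiseless,
plane-stationary data the two coincide.

**Classification.**  Tropism iff ratio ≥ 1.5, boundary inclusive ("at least
1.5-fold increased").  The threshold is a parameter (`threshold`), default
1.5 everywhere.

**Degenerate inputs.**  A hub whose mean surrounding density is zero has an
undefined ratio; it is flagged (NaN ratio, `tropism=None`), excluded from
frequency numerators *and* denominators, and logged.  Fewer than 3 measured
planes raises a warning (not an error): three planes is the recommended
minimum, one plane the hard floor.  Negative densities and overlapping masks
are rejected outright.

**Intervals.**  Tropism frequencies use the Wilson score interval: unlike
the Wald interval it behaves correctly at 0% and 100%, both of which occur
in real cohorts.  Density means carry SEM = sd/√n (ddof = 1).

## Synthetic stacks

The generator emulates punctate intracellular fluorescence:

* geometry — hub = ellipsoid (default radii (5, 14, 14) voxels in a
  16×96×96 stack); surrounding tissue = concentric ellipsoidal shell
  (thickness 10) separated by a guard gap (6 voxels) so that PSF spill from
  one region cannot enter the other's mask;
* emission — per-voxel punctum counts ~ Poisson(λ_region); puncta are
  single-voxel point emitters of fixed amplitude (200), so ground truth
  (counts, coordinates, true ratio λ_hub/λ_surround) is exact;
* optics — Gaussian PSF (σ = 1 voxel per axis, kernel truncated at 3σ),
  constant background, then shot noise (Poisson of the blurred signal) and
  optional Gaussian read noise;
* defaults — λ = 0.25/voxel in both regions, giving ≥ 500 expected puncta
  per measured region, the regime in which the ratio-recovery guarantee
  (|error| < 10% in ≥ 95% of seeded replicates) is stated and tested.

**Measurement planes.**  The returned measurement masks cover only Z planes
whose hub cross-section is ≥ 90% of the maximal one (`mask_plane_fraction`).
Measuring the ellipsoid cap planes — where the 2-D cross-section is small
and the PSF has blurred much of the signal into neighbouring planes —
depresses the hub's per-plane mean by ~10% and would bias every recovered
ratio low.  An experimenter places masks on a few planes well within the
niche; the central-plane rule is the synthetic analogue.  Setting
`mask_plane_fraction=0` measures every plane; the full generating regions
are always available in the `GroundTruth`.

**What the generator does not emulate:** real hub morphology (the marker
channel is a flat region fill), autofluorescence structure, depth-dependent
attenuation, chromatic offsets, or hub bursting at extreme titers.  Passing
recovery tests therefore validate the estimator against the stated noise
model, not against every artefact of real acquisitions.

Density *tables* can also be simulated directly: per-hub true ratios drawn
from a normal (truncated at 0) or lognormal family, per-plane multiplicative
noise, with the ratio column recomputed from the planes by the same
aggregation rule the quantifier uses — table and planes are self-consistent
by construction.  Between-hub spread defaults are arbitrary (no published
value exists to match) and are stated per analysis.

## Discrete character and phylogenetic signal

Frequencies bin into three unordered states at 10% and 60% (low/no:
[0, 10), moderate: [10, 60), high: [60, 100]).  Tree length is Fitch
parsimony — the minimum number of unordered state changes — computed by a
single postorder pass using Hartigan's majority rule at each node, which
reduces to the Fitch intersection/union rule on binary nodes and is exact on
polytomies.  Correctness is tested exhaustively: for every rooted binary
topology with ≤ 6 leaves and every 3-state character, the pass equals
brute-force minimization over all internal labelings, plus a polytomy
battery and an independent-implementation cross-check.

**Null model.**  The randomization test permutes the observed tip states
uniformly (conserving the state multiset in every draw), and
p = #{null ≤ observed}/n_random with ties counting as "as good".  There is
no +1 pseudo-count, so a character that fits no better than any permutation
can return exactly 1.0.  A multinomial null (i.i.d. tips at the observed
state proportions) is available as an option.  n_random defaults to 1000.

**Mk simulator.**  For power/sanity studies the package simulates characters
under the symmetric k-state Markov model: uniform root state,
P(stay | t) = 1/k + (1−1/k)·exp(−k·r·t/(k−1)), branch length default 1.
Rate 0 gives a perfectly conserved character, rate → ∞ i.i.d. uniform tips
(verified to match the permutation null after conditioning on the multiset).

**Bundled fixtures.**  The two survey phylogenies are transcriptions, not
deposited data (the sources print them graphically); the strain tree follows
published supergroup A/B relationships, the host tree is the species
phylogeny with the *simulans* complex as a soft trichotomy, and two
moderate-band frequencies are stand-ins inside their stated band.  See
`src/nichetropism/data/README.md`.  On these fixtures the tropism character
needs 6 steps on the strain tree and 5 on the host tree, and both
randomization tests give p = 1.00 — in each case the observed length equals
the maximum attainable for the state multiset on that topology, so the
result is exact, not a sampling accident.

## Factor partitioning and group statistics

* **Two-proportion test** — pooled-variance z, two-sided, no continuity
  correction by default (a flag adds the Yates-style correction).  Type-I
  error is calibration-tested (4–7% at α = 0.05 under a p = 0.3 null).
* **Fisher exact** — two-sided by the probability-mass rule (sum of
  hypergeometric probabilities ≤ that of the observed table); verified
  against direct enumeration for all margins ≤ 15.
* **Partitioning** — treatment coding, reference level = alphabetically
  first (determinism).  Logistic fits use maximum likelihood with Wald
  per-factor p values.  Separation — any zero cell in a factor×outcome
  table, or a coefficient diverging past |β| > 10 — switches the result to
  the Fisher fallback: per-factor exact tests on collapsed 2×2 tables, with
  Haldane-corrected log odds ratios and Woolf standard errors, and the
  `separation` flag set.  Designs where the two factors are completely
  confounded (each strain seen in only one host) are rejected as
  unidentifiable rather than silently fitted.
* **Letter displays** — all pairwise tests, Bonferroni-adjusted over the
  number of pairs, then a Piepho-style insert-and-absorb compact letter
  display.  Two groups share a letter iff their adjusted p ≥ α; the
  partition is invariant to group ordering.  Density letters use Welch
  t-tests by default (`equal_var=True` restores pooled).
* **Chi-square** — Pearson, (k−1) df, no continuity correction (so the 2×2
  statistic equals the squared two-proportion z); a zero expected count is
  rejected with a pointer to the exact test.  Being asymptotic, it agrees
  with its exact permutation counterpart to ~0.02 at n = 300 (tested with
  mid-p against 10,000 permutations), not to Monte-Carlo precision at small
  n.
* **Presence correlation** — Pearson on paired frequencies with the t-based
  two-sided p; Spearman available.  Constant vectors are rejected.

## Pipeline and reproducibility

Every generator and test takes an explicit seed; one RNG stream per
operation, no global state; identical configuration ⇒ byte-identical
reports.  `run_pipeline` writes long and per-hub density CSVs, a per-line
summary, a JSON report with a schema tag, and a manifest (package version,
full config, SHA-256 config hash, seed) sufficient to reproduce the run.
Stage failures abort with the stage name.  Excluded hubs (undefined ratios)
are counted in the log and the report.

**Problem sizes.**  The shipped analyses use desk-scale sizes chosen to make
their statistical guarantees meaningful: 20 seeded replicates per recovery
condition, 1000 random characters per signal test, 5000 null simulations for
test calibration, 2000 draws per Mk comparison.

## Known limitations

* Masks are trusted inputs; no registration, bleed-through or flat-field
  correction is applied before densitometry.
* The 1.5-fold threshold is a fixed operational definition; the package
  sweeps it but offers no data-driven calibration.
* Parsimony only: no likelihood signal statistics (Pagel's λ, Blomberg's K),
  and unordered states only (no step matrices).
* The raw-workbook re-derivation of published per-strain tropism fractions
  requires the original supplementary workbook, which cannot be
  redistributed here.
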