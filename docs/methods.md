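# Methods

## Generative model

A locus of ploidy m in n individuals is modeled generatively.  Each
individual i carries dosage gᵢ ∈ {0, …, m} of the x-channel allele.  The
vector of dosage counts c = (c_0, …, c_m), Σ c_g = n, is multinomial with
probabilities F(θ), the theoretical dosage frequencies of the population
model.  Each intensity observation is reduced to its L1-normalized
coordinate r = x/(x+y) ∈ [0, 1] and modeled as N(g/m, σ²); replicates of an
individual are conditionally independent given its genotype, so replicate
log-densities add.  The total intensity x+y carries no genotype information
in this model and is treated as nuisance scale.

The normalized pair (r, 1−r) lives on the 1-simplex, so the likelihood is
written on the scalar r; a 2-D Gaussian on the pair differs only by a
constant and would change no argmax or posterior ratio.

Skewed assays — where the two alleles' proportionality constants differ and
clusters shift off the expected angles — are outside the model: no skew
latent variable is fitted, and loci with visible skew should not be called
with this package.

### Population models

* Hardy–Weinberg: F_g = C(m,g) p^g (1−p)^{m−g}.  p is given a uniform prior
  discretized to a grid of resolution δp = 0.01 (101 points).  At n ≈ 200
  the multinomial can discriminate p differences of order 1/√(n·m), well
  above 0.01, so the grid is not the limiting error.
* F1 cross: a parent of dosage d transmits j copies with hypergeometric
  probability C(d,j)·C(m−d, m/2−j)/C(m, m/2) (random bivalent pairing; no
  preferential pairing, no double reduction).  Offspring frequencies are the
  convolution of the two gamete distributions.  Without parental data the
  prior is uniform over the (m+1)(m+2)/2 unordered dosage pairs (repeats
  allowed — a simplex×simplex cross is a perfectly good hypothesis); with
  parental data the parents are distinguishable, the prior is uniform over
  the (m+1)² ordered pairs, and each parent's replicate log-likelihood at
  its candidate dosage is added to the pair's score.
* Custom: frequency vectors supplied as a TSV of (param_id, dosage,
  frequency), validated to be distributions.

Both built-in models produce unimodal (or flat) frequency vectors with no
internal zeros; this is what makes the ploidy identifiable whenever more
than one dosage class is populated (a larger ploidy reproducing the same
angles would need a nonzero–zero–nonzero weight pattern).  When the data
occupy a single cluster the ploidy is fundamentally unidentifiable and the
search reports the lowest ploidy considered (Occam tie-break).

## Inference

For fixed (m, σ, θ) the joint log-score of a configuration with counts c is

    log n! − Σ_g log c_g! + Σ_g c_g log F_g + Σ_i log L(dᵢ | gᵢ) + log P(θ).

All arithmetic is in natural-log space; factorials via log-gamma;
marginalizations via log-sum-exp.  F_g = 0 with c_g > 0 gives −∞ (validly
excluded).  Four engines compute the per-setting MAP:

* **greedy** — per-individual argmax of the likelihood (ties to the lower
  dosage), then scored jointly.  Not exact (the multinomial rewards spread
  configurations that single-individual maximization never finds) but an
  excellent incumbent.
* **naive** — vectorized enumeration of all (m+1)^n configurations, in
  lexicographic order so ties resolve to the lexicographically smallest
  assignment.  Guarded at 2·10⁶ configurations; used as the test oracle.
* **dp** — layered dynamic program over partial count vectors along the
  sorted individuals.  Prefixes with equal counts admit identical suffixes,
  so only the best prefix likelihood per count vector is kept.  The bound is
  deliberately conservative (prefix likelihood + best unconstrained suffix
  likelihood + 0 for the multinomial log-pmf), and the per-layer node count
  grows like C(i+m, m): the engine aborts with a diagnostic when a layer
  exceeds its node guard (default 200 000), which on a 180-individual
  decaploid locus at σ = 0.16 happens around depth 11.
* **geometric** (default) — branch and bound over genotype *distributions*.
  For fixed counts, the likelihood-optimal configuration assigns dosage
  classes as contiguous blocks of individuals sorted by mean normalized
  coordinate: any non-contiguous assignment with the same counts contains a
  pair whose swap does not increase total distance.  (With coincident
  coordinates the optimum is contiguous only up to likelihood-neutral
  permutations; the engine always returns the contiguous representative.)
  The search tree enumerates (c_0, …, c_m) depth-first, so its depth is
  m+1, not n.

### The geometric bound

A node fixes counts for the closed classes 0..k, covering the first
s = Σ_{g≤k} c_g sorted individuals.  Its upper bound is the sum of

1. the closed multinomial part: log n! + Σ_{g≤k} (c_g log F_g − log c_g!);
2. the open multinomial part: the exact maximum over allocations of the
   remaining R = n − s individuals to classes g > k of
   Σ (c_g log F_g − log c_g!).  The marginal gain of the c-th individual in
   class g is log F_g − log c, decreasing in c, so the maximum is the sum of
   the R largest gains — precomputed per (k, R) by sorting;
3. the prefix log-likelihood (O(1) from cached column cumsums);
4. the best suffix likelihood: Σ over unassigned individuals of
   max_{g>k} log L(dᵢ | g) (cached suffix maxima).

Each term upper-bounds the corresponding part of every completion, so the
bound is admissible and the returned optimum is exact; tightness only
affects node counts.  Children are explored with counts nearest the greedy
distribution first, which finds strong incumbents early.  Exactness is
validated against the naive oracle on hundreds of randomized instances, and
the incumbent provably never changes the returned optimum (pruning with
bound ≤ best cannot discard a strictly better completion).

### Ordering and replicates

Individuals are sorted once per locus by the mean of their replicate
coordinates (ties by id, stable); the sort is parameter-free and shared
across the whole (m, σ, θ) grid.  The mean is the Gaussian-sufficient
summary of an individual's replicates.  With unequal replicate counts the
contiguity guarantee is proven only for equal counts, so a warning is
logged; the engines still run.

### Outer search and posteriors

`fit` grids over ploidies (default even 2–16), σ (default 0.01·2^k,
k = 0..5 — a geometric ladder whose span covers both tight fluorescence
clusters and broad mass-spec clusters), and θ.  Uniform priors on m and σ;
θ priors per model as above.  Ploidy ties break toward the lowest m by
search order with strict improvement.

The posterior of the MAP configuration is approximated by normalizing the
per-setting MAP joints (each setting's neighborhood mass is assumed
proportional to its peak).  A slack factor τ = ε / (N−1), with N the number
of searched settings and ε the requested maximum absolute posterior error
(default 0.01), lets the branch and bound prune any subtree whose bound
falls below τ × (current best joint): each such setting's contribution to
the denominator is then its greedy lower bound rather than its exact MAP,
an error of at most τ × the best mass per setting, hence ≤ ε in total.
Using the greedy value instead of zero for pruned settings only tightens
the approximation.  To make the floor effective from the start, a first
cheap pass scores every setting's greedy configuration and seeds the
running best with the largest.

Per-individual dosage posteriors are relative likelihoods,
softmax over dosages of the cached log-likelihood row; calls below the
reporting threshold (default 0.8) are written but flagged excluded.  These
are not exact marginals — computing those would require a second search —
but they are the quantity practitioners use to filter unreliable points,
subsuming ad-hoc total-intensity cutoffs.

## Simulator

The simulator draws dosage counts from the model's multinomial (or i.i.d.
dosages on request, to emulate mixture-model assumptions), places each
replicate at r ~ N(g/m, σ²) truncated to [0, 1] by clipping (negligible for
σ ≤ 0.16 at interior angles), and emits (x, y) = (T·r, T·(1−r)) with T
log-normal around a nominal total intensity.  Because the likelihood is
ratio-invariant, the intensity-magnitude model is immaterial to inference;
it exists so simulated tables resemble assay output.  A raw-channel noise
option perturbs x and y directly instead, deliberately violating the
normalized-coordinate noise assumption for robustness studies.

What the simulator does *not* emulate: allele-specific skew, total-intensity
dependence of noise, aneuploid mixtures of ploidies within a locus, and
cluster-shape asymmetries of real assays.  Passing recovery tests on
simulated data therefore demonstrates correctness of the inference under
the model's own assumptions, not robustness to these real-data pathologies.

Canonical fixture specs include oracle-sized instances, recovery-study
instances, and a sugarcane-like benchmark locus (180 progeny of a decaploid
triplex × nulliplex cross, 12 replicates per parent) used for the
engine-feasibility comparison.

## Study conditions and test sizes

Engine equivalence is checked on 200 seeded instances with n ∈ {5..8} and
m ∈ {2, 4} — the largest sizes where the exhaustive oracle is comfortable —
across both population models and σ ∈ [0.03, 0.4].  Recovery studies use
n = 200 individuals and σ = 0.05: 20 Hardy–Weinberg loci with m ∈ {2, 4, 6}
and p ∈ [0.2, 0.8] for ploidy recovery, and 20 tetraploid F1 crosses over a
spread of parental pairs for pair recovery.  Dosage accuracy is asserted at
the tetraploid reference condition (m = 4, p = 0.5), where the 0.25 angle
spacing makes clusters resolvable at σ = 0.05; at m = 6 the spacing is
1/6 and adjacent clusters overlap enough that a few percent of individuals
are misassigned by any method — the per-individual posterior is exactly the
tool for flagging those.  At these settings the full suite runs in about
two minutes on one CPU.

## Numerical choices and edge cases

* Zero-total-intensity rows (x + y = 0) cannot be normalized; the reader
  rejects them by default (naming the row) or drops them with a logged
  warning — never silently keeps them.
* σ ≤ 0, p ∉ [0, 1], odd ploidy under the F1 model, and non-distribution
  custom tables are domain errors.  Odd ploidies are allowed for the HW
  model behind an explicit flag.
* Configuration ties: engines update on strict improvement only, so the
  first optimum in each engine's deterministic search order is returned
  (lexicographic for naive; greedy-proximal count order for geometric).
* The dp incumbent is applied with a 1e-9 slack so an incumbent equal to
  the optimum (greedy already MAP) is rediscovered rather than pruned.
* Everything downstream of the seed is deterministic: identical inputs and
  settings produce byte-identical call files.

## Known limitations

* No skew latent variable: loci where the two channels use different
  proportionality constants will be miscalled, and should be screened out
  upstream.
* The meiotic model is the simplest available (hypergeometric gametes);
  deviations such as preferential pairing or double reduction will surface
  as anomalous fits rather than being modeled.
* Per-individual posteriors are likelihood ratios at the MAP setting, not
  exact marginals over all settings and configurations.
* Model selection between adjacent even ploidies is genuinely ambiguous
  when σ is comparable to the angle spacing; the configuration posterior
  (not just the point estimate) should be consulted in that regime.
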