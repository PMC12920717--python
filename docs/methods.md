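# Methods

This note documents the models, numerical choices and limitations behind
`vfsage`. Everything quantitative stated here is computed by the test suite
or the example scripts; nothing is quoted from external analyses.

## Variant frequency spectra

A VFS is one individual's somatic variants with supporting counts. Two
count semantics coexist:

* **bulk reads** — VAF = alt/(alt+ref), in [0, 1].
* **colony cells** — VAF = ½·mutant/(mutant+non-mutant), in [0, 0.5]. The ½
  converts the fraction of cells carrying a heterozygous somatic variant
  into an allele fraction, putting colony-derived spectra on the bulk-seq
  VAF scale.

**Tip-variant threshold.** A variant private to one of *n* sampled lineages
has VAF ≈ 1/(2n); with hundreds of lineages that is below 1%. The default
threshold θ = 0.01 is applied *inclusively* (VAF ≥ θ kept): the filtering
rule discards variants with frequency *less than* 1%, and the boundary
reading follows that wording literally. Filtering is idempotent and
composes (θ₁ then θ₂ ≥ θ₁ equals θ₂ directly).

**Deterministic depth rescaling.** `rescale_counts_to_depth` divides the
mutant count by total/target (e.g. 300 reads → 30: divisor 10) and sets the
non-mutant count to the remainder, preserving the VAF exactly in real
arithmetic. Scaled counts stay real by default; an optional integer mode
rounds half-away-from-zero, because rounding only matters to integer-count
consumers. Upscaling (total < target) is undefined and rejected.

**Cohort germline filtering.** Without paired germline sequencing, somatic
calls that recur across unrelated individuals are overwhelmingly germline
leakage. A variant is removed if it appears in ≥ 2 (configurable) other
cohort members or in a supplied known-germline site set; removals are
logged, never silent. The rule is monotone: lowering the recurrence cutoff
removes a superset.

## Decay metrics

**λ** is the sum of post-threshold VAFs. It is additive and monotone: adding
a retained variant raises λ by exactly its VAF; for colony-derived spectra
0 ≤ λ ≤ 0.5 × (retained count).

**γ** is Σ cluster-mean-frequency × cluster-size over non-excluded clusters.
Cluster means are always recomputed as arithmetic means of member VAFs, so
with no exclusions the sum telescopes to λ exactly (the suite checks
agreement to 1e-9 on random spectra).

**Clustering stand-in.** Full Dirichlet-process subclonal reconstruction is
the computational bottleneck the VAF-sum metric exists to bypass, so the
clusterer here is a one-dimensional binomial mixture over (mutant count,
depth) pairs fitted by EM: k-means++-style seeded initialisation on VAFs,
components 1..k_max (default 20, capped at the number of distinct VAFs),
Bayesian information criterion with 2k−1 parameters per model and ties
broken toward fewer components, hard assignment by maximum posterior.
Real-valued (rescaled) counts are supported through a gammaln-based
binomial likelihood. Deterministic given the seed.

**Spurious-cluster rule.** Clustering colony-scale spectra tends to recover
one very large cluster of rare variants that are really unrelated
tip-lineage mutations. The default rule flags the single largest cluster by
member count iff its mean VAF < 4%; an `all_below` variant flags every
sub-4% cluster, and `none` disables flagging. The single-largest default
was chosen because the artefact to remove is one catch-all cluster; the
alternative reading is exposed as configuration.

## Comparison statistics

* **π** — summed per-site heterozygosity with the n/(n−1) correction. From a
  VFS the carrier fraction is taken as p = 2·VAF (heterozygous somatic
  variants); from a genotype matrix it is mean pairwise differences with
  per-site deletion of missing entries. The two routes agree exactly
  without missing data.
* **Tajima's D / Fay & Wu's H** — computed on binary lineage × variant
  alignments. The somatic convention fixes polarisation: the reference
  state is ancestral, every variant allele is derived, no outgroup logic.
  D uses the standard variance normalisation with the nominal lineage
  count; H = θ_π − θ_H is left unnormalised. Missing entries are handled by
  per-site deletion — justified because colony-seq missingness is low
  (fractions of a percent to a few percent of sites). Both match
  independent brute-force oracles to 1e-9 across a randomised sweep.
* **Hill numbers** — on cluster mean frequencies normalised to sum 1:
  richness (q=0), exp Shannon entropy (q=1), inverse Simpson (q=2); the
  family is non-increasing in q.
* **LTT Shannon diversity** — the lineages-through-time curve rises steeply
  during embryogenesis and then plateaus (typically by two to three years).
  The plateau changepoint is the most negative discrete second difference
  of log lineage count, evaluated on a uniform 512-point time grid rather
  than on raw split events (embryonic split spacings vary by orders of
  magnitude, making event-local differences unstable), restricted to the
  first 5 years (later decelerations are ends of clonal expansions, not of
  embryogenesis), with the cut placed one grid step after the bend, where
  the plateau begins. If no early deceleration exists the cut falls back to
  2.5 years. The tree is cut there and −Σ c_i ln c_i computed over clade
  tip fractions. Known limitation: if embryonic diversification were spread
  over years instead of a burst, the sharpest-bend criterion can fire
  mid-expansion; within the simulator's stated world (0.1-year window) the
  star-tree, late-burst and known-clade oracles are all recovered exactly.

## The decay–age model

log λ = a + b·age + ε with ε ~ N(0, σ²), fitted by maximum likelihood.
Unweighted Gaussian errors are the minimal assumption — no per-individual
variance estimates are available to weight with, and that choice is
recorded in the model's fit log. Profiling σ reduces the likelihood to
least squares; the optimizer (BFGS with analytic gradient) still runs from
the conventional initial values a = 0.001, b = 0.3, and its solution is
cross-checked against the closed-form OLS estimate. When the two agree
(< 1e-4, the normal case) the closed-form values are returned, which makes
leave-one-out refits bit-reproducible against a brute-force oracle; a
disagreement keeps the optimizer solution and warns.

* b ≤ 0 after fitting is an error: the model is only invertible when decay
  grows with age.
* λ ≤ 0 individuals carry no decay signal: excluded from training (with a
  warning under `drop_nonpositive`), and prediction raises an explicit
  below-model-support error rather than returning −∞.
* Negative predictions (very small λ) are returned as-is with a status
  flag, not clipped — over-estimates for the young are reported, not hidden.
* Natural logarithms throughout; (a, b) are internally consistent under any
  fixed base.

**Evaluation.** Leave-one-out refits on n−1 individuals and predicts the
held-out λ; per-fold failures are recorded, not fatal. Errors are
aggregated overall and over right-closed age bands 0–30, 31–45, 46–60,
61–75, 76–100 plus a <65/≥65 split. The calibration regression (predicted
on chronological age) reports intercept, slope and R² with seeded bootstrap
percentile intervals over individuals.

## Sequencing-design emulation

Per variant: depth r ~ Poisson(mean_depth), mutant reads
m ~ Binomial(r, VAF), observed VAF = m/r. Variants with r = 0 are
unobserved; variants with m below the detection floor (`min_alt_reads`,
default 2) are undetected; both are dropped, and distinctly logged states
are preserved in the implementation. The tip-variant threshold is then
re-applied to observed VAFs.

**Why a detection floor.** With a bare ratio rule (m/r ≥ θ), any single
supporting read passes the 1% threshold at depths up to 100×, so the
expected λ would *not* rise with depth — it would be flat and then fall.
Detectability of low-frequency variants is what actually improves with
coverage, and a floor of two supporting reads (the minimum any somatic
caller effectively requires) produces exactly the observed behaviour:
expected λ and expected retained-variant count both increase with mean
depth, and matched-depth training absorbs the coverage effect (matched-30×
physiological ages track full-depth estimates at R² ≈ 0.99 on synthetic
cohorts). Setting `min_alt_reads=0` recovers the bare rule.

**Random-number contract.** Each variant's draws come from a dedicated
Philox substream keyed by (seed, variant_id), so subsetting a spectrum
never shifts the draws of the remaining variants, and identical seeds give
identical resampling.

**Panels.** BED regions are 0-based half-open and matched against 1-based
variant positions; gene lists match gene annotations. Records lacking the
needed annotation raise an error naming the offending ids.

## The cohort simulator

The generator's stated world:

* **n_lineages = 300** sampled HSC tips (inside the 224–453 per-person range
  of published colony-seq cohorts). A warning fires below 50 lineages,
  where single-tip variants would no longer sit below the 1% threshold.
* **mutation_rate = 17** mutations per lineage-year (the somatic clock),
  applied as Poisson(rate × branch length) to *every* branch.
* **embryonic_window = 0.1 years**: the n lineages are established by a
  caterpillar of bifurcations at uniform random times inside the window —
  strictly binary with near-zero internal branches, so trees stay
  newick-portable. These short internal branches carry a Poisson-expected
  ~1.7 mutations, giving young individuals a small, realistic baseline of
  shared variants (λ of order 0.1–1).
* **CH founding process**: intensity ρ(t) = ch_rate·exp(ch_age_coeff·t)
  with ch_rate = 3e-4 /year and ch_age_coeff = 0.084 /year. The exponent
  mirrors the empirical exponential growth of decay with age; the base rate
  was chosen once so that cohort λ reaches the hundreds by the ninth decade
  while young adults usually carry no expansion. Both are artefact choices
  (no mechanistic CH onset model is established) and a constant-rate mode
  (ch_age_coeff = 0) exists.
* **Clade sizes**: Beta(1, 9) fractions of the lineage pool (mean 10%),
  minimum 2 tips; a draw exceeding the available primary lineages is
  resampled (logged), and events arriving after the pool is exhausted are
  skipped (logged). Each founding event converts one primary lineage into a
  clade and removes clade-size − 1 other primaries, so the sampled tip
  count is constant and diversity strictly decays.
* **clade_spread = 1 year**: a new clade's internal splits spread over the
  year after founding. Growth is otherwise instantaneous replacement — the
  decay metric depends only on founding-branch sharing, not intra-clade
  topology, and the spread exists so LTT-based statistics see a finite
  (not degenerate) expansion.

Every mutation on a branch subtending c of n tips appears at VAF = c/(2n);
the ground-truth decay is Σ over shared branches with VAF ≥ θ of VAF ×
(branch mutations), computed with the same floating-point expression as the
spectrum side so the identity λ = truth holds to machine precision.
`calibrated_cohort` bypasses trees entirely, drawing λ from
exp(a + b·age + noise) for fast model-fitting tests. Tip-variant emission
can be switched off (`tip_mutations=False`) for workflows that filter them
anyway; genotype matrices are built on demand below a 2-million-cell
auto-limit.

**What the simulator does not emulate** — and hence what a green test does
not establish: sequencing error and strand bias, copy-number alterations
distorting VAFs, driver-gene-specific selection, stem-cell exhaustion,
germline contamination, and real inter-individual variation in CH onset.
End-to-end fits on simulated cohorts recover a positive slope of the same
order as the generator's exponent (b ≈ 0.11–0.12 per year on the default
example cohort; `examples/04_depth_and_panels.py` prints it), but the
simulator's constants are validated through internal identities, not
against any empirical cohort.

## Degenerate inputs and tie-breaks

Zero total counts make a VAF undefined (error). Empty spectra give λ = 0,
an empty cluster set, and errors for statistics that need observations
(largest VAF, Hill numbers). Statistics on alignments require ≥ 4 lineages
and ≥ 1 segregating site. BIC ties prefer fewer mixture components. All
stochastic components (clustering initialisation, depth resampling,
simulation, bootstrap) take explicit seeds and are reproducible.
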