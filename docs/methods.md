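# Methods

## The deconvolution problem

Each L1000 bead color carries beads for two landmark genes at a roughly 2:1
ratio, so the bead-intensity distribution of a color in one well is a
two-component mixture. Peak calling must output the two component
locations *and* keep their gene assignment consistent: the gene pairs were
chosen so that one gene of a pair is expressed higher than the other, and
that order should not change between replicate wells of the same condition.
Per-sample methods (k-medians, naïve GMM) have no way to enforce this, so
in hard wells — overlapping peaks, stray beads — they produce order flips.

## Model

For the m replicate samples of one color, with bead vectors
x_i = {x_{i,1}, …, x_{i,n_i}}, the aggregate Gaussian mixture model (AGMM)
assumes every bead is drawn from one of two Gaussians with a **shared**
standard deviation σ (the bead count per color is too small to estimate two
variances stably) and a **shared** mixing proportion λ (the bead ratio is a
property of the color, not the well):

    L = Σ_i Σ_j log[ λ f(x_ij; μ_i + δ_i/2, σ) + (1−λ) f(x_ij; μ_i − δ_i/2, σ) ]

μ_i is the per-sample peak midpoint and δ_i = μ_{1,i} − μ_{2,i} the
per-sample separation. The (μ, δ) parametrization is exactly equivalent to
the component-mean parametrization and turns the order constraint into the
box δ_i ≥ 0, so the MLE is computed by L-BFGS-B with analytic gradients.
λ is the weight of the *higher* peak; with the 2:1 design, λ ≈ 2/3 means
the majority gene is the higher-expressed one.

Assumptions worth stating: Gaussian within-peak noise on the analysis
scale; a common σ across both peaks and all m samples of the color; one
shared λ; peak positions may vary per sample (μ_i, δ_i are free), only the
*order* is tied. Intensities are taken as already transformed to the scale
the caller wants to analyze on; the package applies no transformation.

## Fitting

* Initialization: per sample, deterministic 1-D 2-means seeded at the 25th
  and 75th percentiles gives centers c_lo ≤ c_hi; μ_i⁰ = (c_hi + c_lo)/2,
  δ_i⁰ = c_hi − c_lo; λ⁰ = pooled fraction of beads in the high clusters,
  clipped to [0.05, 0.95]; σ⁰ = pooled within-cluster SD, floored at 1e-3.
* Bounds: δ_i ∈ [0, ∞) (exactly 0 is allowed so one-peak colors stay
  representable; a fit with every δ_i < 0.02 is flagged "single-peak"),
  σ ∈ [1e-3, ∞), λ ∈ [0.01, 0.99]. Gradient tolerance 1e-8, one restart
  from a perturbed start (δ × 1.05, λ → 0.5) on optimizer failure.
* Mixture terms are evaluated in log space (log-sum-exp) so widely
  separated peaks cannot underflow.
* Standard errors: inverse observed information from a numerical Hessian at
  the optimum, reported as NaN for parameters sitting on an active bound.
* Samples retaining fewer than 4 beads after outlier removal (a
  two-component shared-σ mixture has 4 parameters and is unidentifiable
  below that) are dropped from the joint fit and reported.

## Outlier screen

Per sample: Gaussian-kernel KDE with the rule-of-thumb bandwidth
h = 0.9·min(sd, IQR/1.34)·n^(−1/5) (falling back to sd when ties zero the
IQR), evaluated on 512 equally spaced points spanning the data ± 3h and
renormalized to integrate to 1. Grid points with density < dy_thr
(default 1e-4) mark data-free gaps; two beads are in the same cluster iff
no sub-threshold grid point lies strictly between them (this form makes
the partition monotone in dy_thr). Clusters smaller than clustersize_thr
(default 3) are outliers. If *every* cluster is sub-threshold the largest
is kept, so downstream fitting always has data. The screen is deliberately
conservative: a stray bead closer than roughly 8 bandwidths to the main
mass does not open a gap at the default threshold and survives; such
mid-range strays are the main residual error source of the no-filter
ablation.

## Baselines

* **k-medians**: two-cluster 1-D Lloyd iteration — nearest-median (L1)
  assignment alternating with median updates — seeded deterministically at
  the data extremes (farthest-point seeding). Like any Lloyd-type local
  optimizer it can be captured by a far stray bead: when the midrange of
  the data falls outside the main bead mass, one cluster collapses onto
  the stray and a peak is reported at an outlier. This fragility is a
  property of the method class, it is what the outlier screen plus joint
  fitting are designed to remove, and the benchmark exhibits it. On
  clearly gapped two-cluster inputs the iteration recovers the globally
  optimal L1 cut (tested against exhaustive search); on ambiguous
  unimodal-ish inputs it may return a local optimum, as any seeding does.
  Reported λ is the bead fraction of the higher-median cluster.
* **Naïve GMM**: the same two-component shared-σ mixture fitted per sample
  by EM (closed-form M-steps, σ floored at 1e-3, stopping when the
  log-likelihood gain drops below 1e-8). It is initialized from the same
  quantile-seeded 2-means as the AGMM rather than from the k-medians
  solution, so the two baselines fail independently rather than sharing
  the extremes-seeded basin; with m = 1 the AGMM and this EM agree on
  well-separated data.

## Simulator

The generator reproduces the structure of replicate A375/luciferase panels:
per color, separation diff ~ Gamma(shape 4, rate 4) (mean 1.0, so
separation ≈ 5 bead-SDs typically, with a hard left tail of barely
separated colors) and midpoint avg ~ N(7, 1) on a log-intensity-like
scale; per sample, exactly 40 beads ~ N(avg + diff/2, 0.2) and 20 beads
~ N(avg − diff/2, 0.2). Stray beads are sparse *per color*: a Poisson(2)
total count scattered uniformly over the samples, drawn from
Uniform(low − diff − 2, high + diff + 2). This per-color rate is the
regime in which an unfiltered joint ML fit remains usable (the observed
~6–8% ablation cost); at several strays per sample per color the global
ML optimum of a shared-σ mixture degenerates into one wide component
absorbing the strays, and no likelihood-based method survives without
filtering. Optional generalizations: per-sample jitter of the true peak
means (default 0: truth common to all replicates) and Poisson jitter of
the 40/20 bead counts (default off: exact counts keep tests sharp).

All randomness derives from one seed through per-color child streams
(`SeedSequence(seed, spawn_key=(color,))`), so datasets are bit-reproducible
and enlarging the panel never perturbs earlier colors.

What the simulator does **not** emulate: Luminex optics and saturation,
plate/batch effects, bead-count censoring, non-Gaussian within-peak noise,
and the real (unpublished) hyperparameters of the empirical peak
distributions. Passing benchmarks here show the methods behave correctly
under the stated generative assumptions, not that the absolute accuracy
numbers transfer to any particular real dataset.

## Evaluation

Predictions are paired to truth **by rank** (high↔high, low↔low) for
correlation, true-prediction counts (|error| < 0.05, strict) and MAE, so a
flipped call appears as two large errors rather than being silently
repaired. Flip counting uses **gene identity**: the component holding the
majority bead share (λ ≥ 0.5) is the majority gene, each sample's order is
the sign of (majority mean − minority mean), and by default a sample
counts as flipped when its order disagrees with the majority order of its
color across replicates (`reference="within_color"`). Under this
definition the joint fit can never flip — one shared λ and δ ≥ 0 force
every sample of a color to the same order — which is the structural
guarantee the δ-constraint buys; `reference="truth"` instead scores each
sample against the true order and can charge a jointly fitted color all m
flips at once when a barely separated color (δ ≈ σ, where λ is weakly
identified) converges with λ < 0.5. Williams's t-test compares the pooled
truth-correlation of the joint fit with a baseline's, accounting for their
dependence through the truth variable, with n = the number of pooled
paired rows and df = n − 3.

## Problem sizes

The multi-seed acceptance checks run ten seeds of a 60-color × 10-sample
panel (the per-seed orderings are scale-free; 60 colors keep ten
independent replicates cheap), parameter recovery uses 200 colors with
separation ≥ 4 bead-SDs, and `scripts/acceptance.py` runs the full
500-color × 10-sample default once (~1 minute).

## Known limitations

* The shared-σ assumption biases fits on colors whose two genes have
  genuinely different dispersions.
* λ is near-unidentified when δ → 0; peak locations remain meaningful but
  majority-gene assignment does not, and against-truth flip counts for
  such colors are essentially coin flips for every method.
* The density-gap screen cannot remove strays embedded within ~8
  bandwidths of the bead mass; heavy per-sample contamination therefore
  still degrades all likelihood-based fits.
* Mapping the two peaks to named genes (via the known 2:1 bead ratio of
  specific LINCS gene pairs) is left to the caller; the package reports λ
  and the ordered peaks only.
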