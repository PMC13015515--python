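# Methods

## Replication-timing proxy from methylation

The proxy assumes the established inverse relation between normalized
methylation and replication timing: hypermethylated, heterochromatic
regions replicate late. Per sample, probe beta values (clipped to [0, 1]
on ingest) are assigned to uniform windows of L = 200,000 bp and
summarized by the window median; medians are smoothed within each
chromosome by a centered rolling mean (width 3, odd by construction,
truncated at chromosome ends), z-scored genome-wide with the population
(n) denominator, and sign-inverted. Windows without probes stay missing
and are excluded from every downstream sum. Domains are fixed 300,000 bp
spans whose RT is the ℓ(w)-weighted mean over non-missing member windows;
the per-sample summary reports the ℓ-weighted mean RT and frac_late.

Numerical conventions, all exposed in `RTConfig`:

* **Lateness sign** (`late_sign`, default `"negative"`): a window is late
  when its RT proxy is below average, i.e. methylation above average. The
  opposite indicator is selectable because both conventions appear in
  practice; the default is the one consistent with the proxy's own
  construction.
* **Smoothing operator**: the minimal smoother (rolling mean) rather than
  loess/kernel choices, with the width a parameter; width 1 disables
  smoothing.
* **z-scores** use the population denominator everywhere (window RT,
  promoter z-scores, edge-weight normalization, null Z) for determinism
  and exactness of small closed-form cases.
* **Pooling**: window z-scoring pools all chromosomes of a sample, keeping
  RT comparable across chromosomes; the formula is subscripted only by
  window.
* Degenerate inputs: zero variance across windows yields RT ≡ 0 with a
  warning; zero-variance promoter genes get z = 0 and the baseline state;
  all-missing domains carry missing RT and drop out of similarity.
* Promoter state thresholds default to z = ±1 (the thresholds are fixed
  but unspecified upstream, so they are configuration).

Gene-level RT is the RT of the domain containing the gene's most-5'
promoter probe (TSS200 / TSS1500 / 5'UTR / First Exon classes);
multi-gene probes contribute to every mapped gene.

## Edge weights, selection, individualization

`w_int = a·w_rna + b·(2 s_rt − 1) + γ·norm(w_rna)`. The absolute
correlation floor (default 0.5) applies to the *association* `w_rna`
before mixing, not to the composite; `norm` is the population z-score over
the pairs that survive the floor. Missing RT similarity is neutral
(s = 0.5, signed 0), so unlocatable genes are neither boosted nor
penalized. Thresholding at τ (default 0.5) precedes top-K selection
(default 5000 global / 500 for plotting); ties at the K-th weight break
lexicographically, and all orderings are deterministic. Partial
correlations come from the inverse covariance with an automatic ridge
(1e-4 · trace(Σ)/p) only when Σ is ill-conditioned, since p ≈ n cohorts
make plain inversion unstable.

LIONESS freezes the selected pair set before individualization: every
patient's vector spans the same edges, which is what makes module scores
comparable across patients. The leave-one-out networks are recomputed
exactly (N ≈ 100–200 patients by ≤ 10³ retained pairs is cheap). The
per-subset edge function recomputes the association, the RT similarity
(from the subset-mean gene RT) and the z-normalization *over the frozen
pair set*; the normalization therefore adapts to the subset rather than
reusing the full-cohort moments, keeping e(−q) a genuine function of the
reduced cohort. Genes dropping below the minimum sample count in a subset
yield missing edges for that patient, excluded from module means with a
coverage report.

A consequence worth knowing when reading module AUCs: the individualized
Pearson edge is, to first order, the product of the two genes'
standardized deviations in that patient. Mean-shifted programs therefore
produce *quadratic* score shifts — both subtypes move up, the class with
the larger deviation from the cohort mean moves up more — so a module can
legitimately discriminate with AUC < 0.5 in the basal-positive direction.
Both directions are reported (they sum to 1 exactly under midrank ties).

## Modules, subtype readout, morphology gate

Module detection is greedy modularity maximization on the retained graph
(weights floored at 0 for clustering only), chosen for determinism and
absence of extra hyperparameters; communities are size-ordered with
lexicographic tie-breaks and singletons are excluded from scoring. The
subtype readout is an L2-penalized logistic model on module scores
(weak penalty, C = 10) with stratified 5-fold CV; out-of-fold
probabilities pool into one AUC. Basal is the positive class by default.

The morphology gate multiplies each module score by σ(θᵀf̃(q)), with θ an
L2-penalized logistic fit of subtype on cohort-standardized embeddings
learned inside CV training folds (no leakage; one shared θ serves all
modules). The gate's penalty is deliberately strong (C = 0.1): with
uninformative embeddings the fit shrinks toward θ ≈ 0, the gate toward a
constant, and module scores are essentially unchanged — the behavior a
multiplicative gate must have for the no-signal case. Morphology never
becomes a node; it only reweights activation.

## Validation machinery

Null comparison permutes subtype labels (uniformly, seeded). Network
construction does not consume labels, so the graph is a fixed quantity
under the shuffle and the recomputation covers the label-dependent
metrics (the subtype AUC); the interface takes an arbitrary
labels→metrics closure, so callers can null out anything that re-enters
their metric. Z uses the population sd of the shuffle values; the
empirical p carries the +1 correction, so its floor is 1/(S+1).

Stability resamples ⌈0.8·N⌉ patients without replacement (a
with-replacement flag exists), rebuilds the network per subsample and
compares top-10000 edge sets pairwise by Jaccard on unordered gene-pair
identity, ignoring weights. The grid sweep enumerates the inclusive
ranges a ∈ 0.5:1.5, b ∈ 0:1, γ ∈ 0:1 in 0.25 steps (125 cells); cells
whose mixed weights all fall below τ yield no network and are recorded as
failed rather than aborting the sweep — the (a=1, b=0, γ=0) cell
reproduces the pure-RNA condition exactly and anchors the sweep.

## Synthetic cohort

The generator emulates a PDAC-like cohort at desk scale: a toy genome of
3 chromosomes × 6 Mb (30 windows of 200 kb each), 50 genes placed
round-robin along the chromosomes, 3 promoter probes per gene (classes
cycling through the four promoter annotations, 5% of them mapping to two
genes), one gene-body probe each, 6 per-window filler probes, 120
patients at a 60/40 basal/classical split (the floor-then-remainder rule
fixes counts), and 1300-dimensional embeddings whose first dimension
separates subtypes.

**Replication timing**: each chromosome carries one contiguous late block
anchored at the chromosome start and covering the planted fraction of its
windows (exact to one window per chromosome). Contiguity mirrors the
megabase scale of real replication domains and bounds the smoothing
distortion at the block boundary to about one window per chromosome, so
the recovered frac_late lands within a few hundredths of the planted
value. Probes in late windows draw beta 0.7, early 0.3, with sd 0.05
noise, clipped to [0.01, 0.99] before writing.

**Expression**: a Gaussian copula over a block covariance, exponentiated
(X = 100·exp(0.3·z)) so values resemble normalized expression while the
small latent scale keeps Pearson structure within a few hundredths of the
target. The first two modules are the anticorrelated basal and classical
programs. Their shared activity is the subtype shift itself — ±e/2 on the
unit latent scale of a background gene — plus a small subtype-independent
activity noise (sd 0.1, correlated across the two programs at
`between_program_corr`); idiosyncratic gene noise is then scaled so the
cohort-level within-module correlation hits its target. This
shift-dominated regime is deliberate: it is how strongly bimodal subtype
programs behave in real cohorts (the cohort-level correlation of program
genes is largely *created* by the subtype mixture), and it is the regime
in which single-sample network scores carry subtype information at all —
if the same correlation were carried by subtype-independent activity, the
quadratic individualized-edge channel would bury the shift (measured
top-module AUC ≈ 0.6 in that regime versus ≥ 0.9 here). When the shift
variance is too small to dominate (effect sizes near 0), programs degrade
continuously to ordinary correlated blocks. Remaining modules are
subtype-free blocks at the same correlation target; leftover genes are
independent noise.

What the generator does **not** emulate: real probe-density heterogeneity
and manifest errata, copy-number and purity confounding of beta values,
count-based expression noise, batch structure, and any real morphology
beyond a single informative embedding direction. Passing tests therefore
demonstrate correctness and calibration of the machinery on planted
structure, not performance on TCGA-scale data.

Generation is byte-deterministic in the seed (independent substreams per
data type), and methylation files alternate between two dialects
(comma+header / tab headerless) to keep the column auto-detection honest.

## Problem sizes in tests and the acceptance script

The shipped checks run the full pipeline at n = 120 (planted recovery,
acceptance script) and n = 40–60 elsewhere (grid sweep, null calibration
with 20 repeats × 50 shuffles), sizes at which every stage — including
exact leave-one-out recomputation and the 125-cell sweep — completes in
seconds to a couple of minutes on one core. These are the package's
reference conditions; all of them scale linearly in samples and
quadratically in retained genes.

## Known limitations

* Module detection is resolution-limited greedy modularity; very small or
  overlapping modules will not be resolved (a spectral alternative is the
  natural extension point in `detect_modules`).
* The RT-only condition frequently yields no edges above the correlation
  floor when RT profiles vary little across samples; this is reported as
  an empty-network run, not an error.
* Partial correlations are cohort-level only; they are not individualized.
* The morphology gate is the smallest mechanism that weights activation
  without creating morphology nodes; it does not let morphology influence
  module membership.
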