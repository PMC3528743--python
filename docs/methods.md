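# Methods

## Setting and notation

Each siRNA is its 19-nt antisense strand s (5′→3′, alphabet {A,C,G,U})
with a measured efficacy y ∈ [0,1]; lower y means stronger silencing
(y is residual target expression), and y < 0.3 marks an "active"
silencer.  A *domain* is one dataset — one target mRNA or one
experimental platform — represented as (X, y) with X the feature matrix
over the catalog below.  The *target* domain is scarce; *source*
domains are abundant but have heterogeneous output scales: the same
sequence-to-silencing biology read out through different assays yields
differently distributed y.

## Feature catalog

146 descriptors, addressed by name:

| family | count | examples | notes |
|---|---|---|---|
| positional base | 76 | `U @ NT1` | 1-based from the 5′ end of the antisense strand; closed windows |
| k-mer counts | 20 | `CC in NT[1..19]` | overlapping occurrences, k = 1–2 by default; any motif addable (`UCUG in NT[1..19]`) |
| GC content | 1 + 18 | `GC content <0.55` | real value plus strict `<`/`>` indicators on the 0.35…0.75 grid |
| thermodynamic | 10 | `dG in NT[1,2]`, `SUM of dG`, `dG(NT[1,2]) - dG(NT[18,19])` | nearest-neighbor stack sums; `SUM of dG4` sums all 16 tetramer windows |
| structural | 21 | `Folding in NT[1..19]`, `NT18 forms bond`, `G stretch of length >= 3` | from the self-folding structure |

Thermodynamics use the Xia et al. (1998) Watson–Crick ΔG°37 stack
table, keyed by the 5′→3′ dinucleotide of the antisense strand with the
complement implied (a step and its reverse complement share one
parameter, so 16 dinucleotides cover the table).  The table is
swappable behind `NNParameterTable`.

Self-folding is Nussinov base-pair maximization (Watson–Crick + G·U,
hairpin loops ≥ 3) — a deliberately simple, reproducible stand-in for a
full energy model; an energy-based folder can be substituted behind the
same contract.  The per-position `NTi forms bond` indicators come from
one deterministic traceback (pairing preferred over leaving a base
unpaired; among equal partners the 5′-most).  The dynamic program is
verified against exhaustive enumeration of all non-crossing structures
for lengths ≤ 12.

## Base learner

Linear ridge regression minimizing Σᵢ(yᵢ − w·xᵢ)² + λ‖w‖², solved in
closed form by a symmetric positive-definite solve.  The intercept is
fit unpenalized by centering y; features are z-scored on the training
set and the frozen transform applied at prediction time (constant
columns get unit scale).  A dual form α = (K + λI)⁻¹(y − ȳ) supports
arbitrary PSD kernels; a non-PSD kernel matrix raises rather than being
silently regularized.  With the linear kernel, dual and primal
predictions agree to machine precision (asserted at 1e−8 in tests).

**λ default (`DEFAULT_LAMBDA = 30`).**  All compared methods in one
experiment share one λ so comparisons isolate the data-integration
strategy, never the regularization.  The value sits in the flat region
of the held-out-error regularization path of the target-only fit on the
synthetic benchmark across training sizes 20–180.  With ~146
standardized columns, λ of order 1 leaves any fit with n ≲ p
effectively interpolating its training labels, which degrades every
method and nullifies comparisons; λ ≳ 100 over-shrinks the scarce-data
fits that the transfer method needs for its initial model.

## The transfer step (HEGS)

Inputs: target training set T (n_T samples), source tasks S₁…S_n,
shared λ, `TransferConfig`.

1. **Initial model** θ₀ = ridge fit on T alone.
2. **Per source task — distribution unification.**  Both sides are
   standardized with T's feature statistics (a common scale is what
   makes the geometry comparable).  k-means with
   k = min(10, ⌊(n_T + n_S)/5⌋) clusters the pooled samples (single
   seeded k-means++ initialization; deterministic).  For cluster c with
   source/target membership proportions P_S(c), P_T(c), the divergence
   term is P_S(c)·log(P_S(c)/P_T(c)), with 0·log 0 := 0, multiplied by
   (1 + d_c) where d_c is the distance between the within-cluster
   source and target centroids (the weighting is one flag away from
   off; both variants are reported in diagnostics).  A cluster with
   source members but no target members has an infinite term: it is a
   region of feature space the target never visits, and transferring
   from it risks negative transfer, so it is excluded outright.
   Remaining clusters are accepted in ascending term order while the
   term stays at or below the threshold (default: the median finite
   term) and the augmentation cap is not exceeded.
3. **Per source task — output-space unification.**  Selected samples
   get initial outputs ŷⱼ = θ₀(xⱼ).  They are then grouped by 1-D
   k-means on their *original source outputs* yⱼˢ — the grouping that
   survives any monotone distortion of the source scale — into g = 10
   groups, and re-labeled as α·c_g + (1−α)·ŷⱼ with α = 0.5, where c_g
   is the group's mean initial output.  Within a group this affine map
   preserves the ordering of outputs (α < 1) and collapses to the
   center at α = 1.  Labels are clipped to T's output range, so
   generated outputs always live inside the target label space.
4. **Augmented fit.**  Selected, re-labeled samples from all tasks are
   appended to T (the target training set is never reduced) and the
   ridge model is re-fit once on the pool.  A sequential mode re-fits
   the labeling model after each task instead.  With zero selected
   samples the returned model is the target-only fit, bit for bit.

**Why grouping uses source outputs.**  Re-labeling by θ₀ alone is
self-training: the pseudo-labels are a function of the model class and
carry no information the target data did not already contain (for a
linear learner the augmented optimum then barely moves).  The only
external information in the source task that survives scale
heterogeneity is the *ordering/grouping* of its outputs; routing it
into the labels through the group structure is what makes the transfer
a transfer.  When source outputs are unavailable the grouping falls
back to the predictions themselves.

**Why the augmentation cap is generous (10 × n_T).**  The augmented fit
only benefits from noisy pseudo-labels when it *averages* them.  If the
pool stays smaller than the feature count, the shared-λ ridge
interpolates each pseudo-label instead, injecting pseudo-label error
(~4× the assay noise on the benchmark) at full strength — measured on
the benchmark, a 3× cap makes transfer strictly harmful while 10×
(overdetermined) makes it beneficial in 9–10 of 10 seeds.  The cap is
shared across source tasks, earlier tasks drawing first.

## Comparison strategies

*Baseline*: ridge on the target training data alone.  *SCM*
(simply-combined model): min–max normalize each source domain's outputs
onto [0,1] and fit one ridge model on everything pooled.  The target
training outputs are left untouched — they already live on the scale
the evaluation uses, and rescaling them would distort the RMSE scale.
Min–max removes affine scale differences only; monotone *nonlinear*
distortions (see the generator) remain in the pooled labels as bias.

## Feature selection

Per feature: Pearson r against efficacy with its t-distributed
significance p_r, and a two-sample t-test p_group of feature values
between active (y < 0.3) and inactive siRNAs (NaN when a group is
empty; constant features get r = 0, p = 1).  Selection keeps
|r| ≥ 0.1 (inclusive) with significance < 0.05; the gate uses p_r by
default (p_group by switch).  Ranking is by |r| descending.  No
multiple-testing correction is applied; p-values are reported raw.

The *post-transfer* mode repeats the augmentation (fresh seeds per
repeat), reruns the identical scoring/selection on each augmented set,
and ranks features by selection frequency (ties by mean |r|).  Feature
identifiability has a structural limit worth knowing: the catalog
contains families of near-duplicates (the graded GC thresholds all
track GC content at |ρ| ≈ 0.8–0.9; the overlapping ΔG windows track one
another similarly), and no marginal-association ranking can decide
which member of such a family is causal.

## Evaluation harness

Paired design throughout: within one run, every method sees the same
seeded target train/test split, so per-run RMSE differences support the
(two-sided) paired t-test; zero-variance difference vectors are flagged
rather than tested.  Splits are uniform random without stratification.
Provided protocols: training-fraction sweeps with each domain rotated
through the target role; random source-accumulation trajectories
(sources added one at a time in reshuffled orders, with baseline and
single-source reference lines); repeated k-fold CV (10 × 10-fold by
default).

## Synthetic benchmark

The generator emulates the multi-domain regime: 5 domains × 200 siRNAs.
Sequences are drawn position-wise with domain-specific base composition
(mean GC 0.35 → 0.65 across domains: covariate shift).  A single latent
signal shared by all domains,

    z = 0.5 + Σ_f w_f · x̃_f + ε,   ε ~ N(0, 0.05²),  clipped to [0,1],

uses five planted features spanning the families of known efficacy
determinants — `U @ NT1` (+0.28), `A @ NT10` (−0.26), `C @ NT19`
(+0.26), `GC content in NT[1..19]` (−0.20), `Folding in NT[1..19]`
(−0.20) — where x̃ is the feature standardized against a fixed
reference pool at GC 0.5, so weights are per-SD effects regardless of a
feature's natural units.  The positional effects carry the largest
weights and the composite features moderate ones: composite features
drag their near-duplicate catalog families along, and a planted set
shadowed by such proxies would be unidentifiable by any marginal
ranking (see above).  Observed outputs are y = z^γ_d with
γ = (0.5, 1.0, 2.0, 1.0, 0.7): monotone power warps that preserve each
domain's ranking — a plausible cross-platform distortion — while
breaking the affine comparability min–max assumes.  The default target
is domain 2 (γ = 1), down-sampled to 20 training records in the
scarce-target experiments; feature-selection experiments use the full
200.  Ground truth (weights, warps, composition) is emitted as a
sidecar for oracle-based tests and never consumed by the pipeline under
test.

**What the benchmark does and does not show.**  It reproduces the
qualitative regime the method targets — shared signal, covariate shift,
non-affine output heterogeneity — so passing tests show the machinery
behaves as designed under that regime.  It does not emulate
domain-specific *signal* differences (different mRNAs plausibly weight
sequence features differently), mRNA-level system factors (abundance,
turnover, site accessibility), measurement-protocol artifacts beyond a
monotone warp, or chemically modified siRNAs; conclusions about real
cross-platform data require real data.  One honest negative result:
under these warps the pooled SCM model is *not* reliably worse than the
scarce baseline — two domains share the target's scale exactly and
power warps are near-affine over the mid-range, so pooling's variance
reduction usually wins.  Harsher, more idiosyncratic distortions than
power warps are needed before naive pooling collapses.

## Numerical and reproducibility choices

k-means: scikit-learn, k-means++ with one seeded initialization
everywhere (selection, output grouping).  Ridge: closed-form solves, no
iterative optimizer.  0·log 0 := 0; logs are natural.  Degenerate
cases: constant output vectors cannot be min–max normalized (error);
fewer selected samples than output groups reduces g with a warning;
empty selections are valid and collapse the transfer to the baseline
exactly.  Every stochastic step takes an explicit integer seed;
per-task and per-repeat seeds are derived from it by fixed offsets, so
a run's configuration reproduces its outputs bitwise (the CLI writes
the resolved config and seeds next to every output).
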