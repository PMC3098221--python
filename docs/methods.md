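# Methods

This note documents the models, estimators and numerical choices behind
`msuaflow`, and what the built-in simulator does and does not emulate.

## Rate estimation and epoch labeling

Spike trains are convolved with unit-area Gaussian kernels (SD σ, default
0.2 s, valid range 5–200 ms — discrimination results are insensitive across
this range) and averaged over half-open bins of width Δ = 0.2 s, computed
exactly from Gaussian CDF differences, so values are in spikes/s and
converge as Δ → 0. Gaussian mass outside the trial is truncated, not
reflected. An optional flag divides each unit's density by its integral over
the trial (a probability density over time); the default is unnormalized
spikes/s so that the quality-control rule "exclude units below 2% of the
most responsive unit's mean rate" remains meaningful.

Quality control runs in a fixed order: (1) the second spike of any pair with
inter-spike interval ≤ 10 ms is dropped; (2) of any unit pair whose zero-lag
1-ms-binned spike-indicator correlation exceeds 0.9 (configurable), the
lower-rate unit is dropped as a putative duplicate; (3) low-rate units are
excluded with rates computed after the first two steps.

Epoch windows come either from explicit (label, start, end) rows or from
point events: a food-cup event opens a 1 s reward window starting 0.2 s
before it; an arm-choice event opens a choice window from 1.5 s before until
0.5 s after it, clipped at the next reward window's start. Bins are labeled
by majority overlap (> Δ/2), with precedence reward > choice > delay when
windows of different kinds overlap; windows are clipped at trial boundaries.

## Delay coordinates

One lag per unit, chosen as the first interior local minimum of the unit's
average cross-correlation with all other units over lags up to 5% of the
shortest task *phase* (training / delay / test — epochs grouped by phase;
single 1-s epochs would cap lags below one bin). Without an interior
minimum the lag falls back to one bin. Rows lacking lag history at trial
starts are dropped; no row mixes bins across trials.

## Expansion and kernel

The order-O expansion space contains every monomial of total degree 1..O in
the 2n delay-coordinate variables. It is accessed through the inhomogeneous
polynomial kernel k(x, y) = (1 + x·y)^O − 1; the constant is removed so the
feature space is exactly the degree-1..O monomials, each weighted by
√(C(O,k)·multinomial). An explicit feature map (graded-lex monomial order)
is provided for problems with ≤ 12 base variables and O ≤ 4 and serves as
the oracle for kernel correctness; at O = 1 the kernel is the plain Gram
matrix, and all kernel methods reduce to their linear counterparts.

## Kernel Fisher discriminant and classification

The discriminant is solved in dual form: with centered kernel K and class
column means M_c, the within-class scatter operator is
N = Σ_c K_c (I − 1/m_c) K_cᵀ and the two-class solution is
α = (N + η I)⁻¹ (M₁ − M₂); with more classes or components, the generalized
symmetric eigenproblem M_b α = λ (N + η I) α. The kernel is normalized by
its mean value before centering (cross-kernels share the training factor):
raw O = 5 kernels span ~15 decades and would push the ridge below machine
precision relative to N; on the normalized scale η is directly the
regularization expressed as a fraction of the mean kernel value. Default
η = 0.05, inside the broad plateau (≈1–40%) where held-out discrimination
is insensitive to η; much smaller values overfit (in-sample SE → 0 with no
out-of-sample validity). Double centering makes projections invariant to
adding a constant to the kernel.

Projections on the axis are near-Gaussian (sums of very many expanded
coordinates), so each class gets a 1-D Gaussian with its own mean and SD,
and a Bayes classifier with priors fixed at 0.5 — results are then not
biased toward longer epochs, and chance level is exactly 50%. SE is the
fraction misclassified; SE_predic evaluates prediction-trial vectors with
the direction *and* the class Gaussians frozen from the reference trials
(reference and prediction sets must be disjoint; forward and backward
directions supported; per-epoch series truncated to equal length across the
two sets). The epoch KL divergence is computed between the two class
Gaussians discretized on a grid of 1000 cells spanning ±6 pooled SDs around
the grand mean, floored at 1e-12 and renormalized; the C₁→C₂ direction is
reported, with a symmetrized option.

For analyses that consume likelihood *magnitudes* (the convergence and
escape statistics below), the class Gaussians are calibrated on a held-out
trailing 30% of the reference vectors, with the direction fitted on the
leading 70%: in-sample projections shrink severely on strongly expanded
spaces (out-of-sample spread up to ~10× the in-sample SD at O = 5), so
uncalibrated tail likelihoods are meaningless. SE_predic itself keeps the
fully frozen in-sample Gaussians — classification only compares the two
class densities, which shrink together.

## Convergence statistics

Velocities are finite differences of 3-D kernel-PCA scores (basis frozen on
the reference trials; scores scaled so component variance equals
eigenvalue/m) — never of coordinates in the full expanded space, where
finite differences are unreliable. Cross-trial pairs are excluded. Speeds
are normalized by their 95th percentile and clipped to [0, 1] so a single
extreme jump cannot compress the axis; they are binned into 20 equal-width
bins, and an ordinary least-squares line through (bin center, mean
log-likelihood of correct classification) yields the convergence slope b.
Likelihoods are floored at 4 SDs from each class mean so a few off-manifold
vectors cannot dominate a bin's mean log. Epochs are balanced in the pooled
curve (cap per epoch) so the long delay period does not swamp the short
choice/reward epochs. A negative b means fast-moving states are unlikely to
be classified correctly — the flow decelerates near the epoch states.

The null for this statistic inverts the temporal order of the binned rates
within every epoch (an exact involution preserving epoch lengths and
marginals), re-embeds the inverted series, and evaluates its likelihoods
against the *same* empirical velocity field: the surrogate randomizes the
assignment of population vectors to positions in the flow while keeping the
flow itself, isolating the causal structure seen by the classifier.
(Differentiating the surrogate's own deliberately broken embedding injects
coordinate noise that can flip the comparison in either direction; the
underlying effect — the likelihood drop under inversion concentrates at low
speeds — is only visible on a shared speed axis.) Slopes are compared by
regressing the per-bin difference of mean log-likelihoods on the bin
centers; the t statistic of that slope (df = bins − 2) tests the contrast.

## Escape analysis

A trajectory is a maximal run of consecutive same-epoch bins within one
trial. Membership of bin t in its epoch state is decided by majority voting
of the frozen pairwise kernel-FDA Bayes classifiers (voting breaks
near-ties bin by bin; a one-vs-rest argmax was found to break them
systematically toward one class, which distorts trajectory-level counts).
Non-member stretches shorter than k = 2 bins count as membership noise.
Types: "a" confined throughout; "b" departs (≥ k consecutive non-member
bins) but re-enters before the run ends; "c" starts outside, converges, and
stays; "escaped" departs without re-entering within the run. The typing is
exhaustive and mutually exclusive. An escaped trajectory violates the
trapping region if any of its 3-D projection points lies farther from the
epoch's reference-set centroid than ρ = 1.5 × the reference set's maximum
member distance. k, ρ and the return horizon (the remainder of the run) are
configurable.

## Surrogates and bootstrap

- Epoch-block shuffle: the series is cut at epoch boundaries; block contents
  permute uniformly while the label timeline stays fixed. Blocks exchange
  only within ±10% length compatibility so labels stay aligned. With the
  `chunk_length` option every block is first cut into chunks of that length
  (the cross-trial-prediction null uses the shortest relevant epoch length):
  autocorrelations survive up to the chunk length and the vector-label
  relation is fully randomized — without chunking, a unique-length block
  such as a single 60 s delay can never move.
- Time inversion: bin order reversed within each epoch block, all units
  together; exact involution.
- Augmentation/decimation: within-epoch resampling with replacement (to a
  multiple of the original count) or uniform thinning; per-unit KS distances
  against the original marginals are checked and logged.
- Bootstrap test: one-sided exceedance with the add-one rule
  p = (1 + #extreme)/(n + 1), 100 replications by default (minimum
  attainable p = 1/101 ≈ 0.0099), all replication seeds derived from one
  seed.

## Correlation dimension

The correlation sum S(ε) is the fraction of point pairs within ε, excluding
pairs closer in time than a Theiler window (chosen where S(ε) varies by
< 5% across temporal separations, the space–time separation criterion).
d₂ is the slope of log S vs log ε over the longest contiguous window
spanning ≥ half a decade that maximizes the linear-fit R²; the Takens
maximum-likelihood estimator over distances below the window's upper edge
is the cross-check, and the minimum embedding dimension is reported as
2·d₂ + 1. Results are flagged unreliable when no well-fitting scaling
region exists.

## The simulator

The generator emulates one session of a delayed win-shift radial-arm-maze
task: per trial (~152 s) four training choice (2 s) / reward (1 s) passes,
a 60 s delay, eight test choice/reward passes, separated by unlabeled 4 s
locomotion periods. A latent state z(t) (3-D) follows
dz = λ(c(t) − z) dt + σ dW with λ = 2/s and σ = 0.25, where c(t) is the
active epoch's pull target. Each labeled epoch's target carries a
circulating component of radius 2 at ω = 2 rad/s in the plane of the first
two latent dimensions, with a random initial phase per epoch occurrence: the
population cycles through a sequence of sub-patterns within each state.
Epochs of the same kind in the training and test phases (the two choice
epochs; the two reward epochs) share their fixed point but circulate in
opposite directions — like their behavioral counterparts they share all
"sensory" features (identical marginal rate statistics) and differ only in
internal dynamics, so they are separable through interactions of current
and lagged rates but not through any linear readout. The circulation also
breaks time-reversibility inside the states; a pure OU pull is reversible
in stationarity and would make time-inversion nulls vacuous. Rates are
rect(10 + L z) spikes/s with loading L of SD 8/√3 per entry, and spikes are
inhomogeneous Poisson at 1 ms resolution (exact AR(1) discretization of the
latent; uniform spike jitter within steps). Everything is reproducible from
one seed.

Null variants: `single_center` (all epochs pull toward the mean fixed point
and circulate in the same direction — no epoch structure, matched
autocorrelations), `label_shuffle` (labels permuted over windows),
`time_invert` (spike times reflected within windows).

What the simulator does *not* emulate: non-Poisson spiking statistics
(bursting, refractoriness), slow drift and nonstationarity across trials,
behavioral variability in epoch timing, correlated noise across units
beyond the shared latent, and electrode artifacts. Passing the recovery
suite therefore shows that the pipeline detects attractor signatures when
they are present in this idealized form and not when they are absent — it
does not certify performance on real recordings.

## Validation problem sizes

The built-in validation battery runs at deliberately modest sizes chosen to
exercise every code path with stable statistics: chance-level control with
20 units × 800 vectors × 20 seeds; signature recovery with 20 units,
10 trials (5 reference / 5 prediction), 10 seeds, 100 bootstrap
replications, per-class caps of 120–160 vectors in kernel fits; dimension
oracles with 1000–2000 points. The convergence-slope contrast is assessed
on the curves pooled across the 10 seeds (per-bin means averaged, one
paired comparison across the 20 bins), the per-seed statistic being noisy
at these sample sizes.
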