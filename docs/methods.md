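# Methods

## The spatial information score

Given a cells-by-genes expression matrix with 2-D coordinates, the package
scores each gene's spatial coherence as a variational lower bound on the
Jensen-Shannon (JS) divergence between two distributions over expression
pairs:

* the **neighborhood distribution** p_N(x, x′): expression at the two ends of
  a k-step uniform random walk on a spatial neighborhood graph, started at a
  uniformly chosen cell;
* the **product of marginals** p(x) p(x′): the same walk indices applied
  after shuffling expression values across cells.

For a classifier f_θ producing a logit for a pair, the bound is

    E_near[ −softplus(−f) ] + E_far[ −softplus(f) ]  ≤  D_JS(p_N ‖ p·p),

maximized over θ by stochastic gradient ascent. The per-pair summand equals
log σ(f_near) + log σ(−f_far) — the log-probability of labelling both the
neighborhood pair and the shuffled pair correctly — so a random-guessing
classifier scores log(0.25) ≈ −1.386 per cell and a perfect one scores 0.
Because the bound decomposes over cells, the per-cell values are reported as
a **saliency** map after the affine rescaling

    saliency_j = clip( (s_j − log 0.25) / (−log 0.25), 0, 1 ),

and the gene's **normalized score** is the sum of saliencies, in [0, n].
A spatially coherent pattern involving more cells scores higher than the
same pattern involving fewer; divide by n when a per-cell rate is wanted.

### The classifier

The classifier is deliberately weak — a five-parameter family

    f(x, x′, d) = exp(−d/α) · ( w_s |x + x′ + shift| − w_d |x − x′| + b ),

with w_s, w_d > 0 enforced by a softplus parameterization and α > 0 by a log
parameterization. The −w_d |x − x′| term rewards similarity of the pair; the
w_s |x + x′ + shift| term rewards pairs that are jointly unusually high or
low; exp(−d/α) lets the model discount long walks when structure is very
local, with the decay length α learned per gene (coordinate units — this is
what makes the score insensitive to whether coordinates are pixels,
micrometers or grid indices). Positive weights restrict detection to
positive spatial association: two genes expressed in complementary regions
are invisible to this family, a documented trade (an option to drop the
constraint exists but is off by default).

### Training loop

Each iteration, per resolution level (see binning): resample expression from
the count posterior (below), standardize it across cells (zero mean, unit
variance — an affine change absorbed by the weights and shift, kept purely
for optimizer conditioning), draw one fresh k-step walk per cell, shuffle a
copy of the expression vector for the far pairs (reusing the walk indices
and distances), and take one Adam step (β1 = 0.9, β2 = 0.999, ε = 1e−8,
learning rate 0.01) on the gradient of the *summed* objective weighted by
the level weight. Sums rather than means keep levels comparable on total
evidence. Initialization: w_s = w_d = 0.1, b = shift = 0 (so training starts
essentially at the guessing baseline, which is why fitted scores do not fall
materially below log 0.25), α = the mean walk distance of a pilot batch.
Training runs at most 1,000 iterations, stopping early when the 100-iteration
moving average of the objective improves by less than a relative 1e−4
(disable with `early_stop=False` / `--no-early-stop`).

After training, parameters are frozen and E = 10 fresh evaluation rounds on
the unbinned level produce the reported per-cell scores (averaged over
rounds), the accuracy, and the p value. Reported quantities come from the
unbinned level only; binned levels are auxiliary training signal.

### Walks and graphs

The neighborhood graph is Delaunay triangulation by default (edges longer
than the 99th-percentile edge length are pruned, since hull-spanning edges
distort neighborhoods); radius, symmetrized k-NN, and lattice ("grid")
adjacency are alternatives. Isolated nodes are attached to their nearest
neighbor so walks are defined everywhere. Walks take k = 10 uniform-neighbor
steps by default: small k tunes the score to fine patterns, large k to broad
ones, and in the k → ∞ limit the endpoint distribution approaches the
degree-proportional stationary distribution and all spatial signal is lost.
The same k is used on binned levels.

### Count uncertainty

Counts are noisy measurements. Rather than training on a fixed transform,
expression is redrawn each iteration from a per-cell-gene posterior:

* **Gamma-Poisson** (default; counts as absolute expression):
  λ ~ Gamma(a₀ + x, b₀ + s_c) with weak priors a₀ = b₀ = 0.1 and size factor
  s_c = library size / median library size; trained on log λ.
* **Dirichlet-Multinomial** (counts as proportions): per-cell proportions
  ~ Dirichlet(a₀d + x), a₀d = 0.01, trained on log(10⁴·p). Per-gene draws
  use the exact Beta marginal of the Dirichlet.
* **Gaussian**: Normal(mean, sd) draws from externally supplied posterior
  summaries (e.g. the output of a probabilistic normalization method).
* **none**: deterministic log1p of the counts (makes the whole pipeline
  bit-reproducible for a given seed).

The log transform on posterior draws (safe, since draws are strictly
positive) and the per-draw standardization are choices the bound's optimum
is insensitive to; they matter only for conditioning.

### Binning

Sparse genes give little signal at single-cell resolution, so training also
runs on aggregated copies of the data with bin sizes k = 4, 8, 16, weighted
by k in the objective. Bins must have *exactly* k cells — unequal occupancy
leaks cell-count information that masquerades as spatial signal — so a
random n mod k cells are discarded and the rest are split recursively along
alternating axes (first axis = larger coordinate range, cuts at the multiple
of k nearest the median) down to blocks of k. Binned counts are sums, so the
Gamma-Poisson resampler applies to them unchanged; bin coordinates are
member centroids, and each level gets its own Delaunay graph.

### Significance

Under the null (no spatial structure) the classifier cannot distinguish a
true neighborhood pair from a shuffled one. Each evaluation round provides
one trial per cell: the trial is correct when f_near > f_far (ties count as
incorrect). With E rounds the correct count is Binomial(n·E, 1/2) under the
null, giving an upper-tail p value, adjusted across genes by
Benjamini-Hochberg. We deliberately do *not* count the near and the far
classification as two separate trials: both depend on the same fitted bias,
which moves them in opposite directions, so their sum is underdispersed
relative to a 2nE-trial binomial and the resulting p values are
miscalibrated (empirically: KS test against U(0,1) on 200 null genes rejects
at p ≈ 3·10⁻⁴ for the 2nE version and accepts, p ≈ 0.25, for the paired
version). The paired trial is a fair coin under the null by symmetry.
p values of strongly spatial genes saturate double precision; they are
floored at the smallest positive float, and ranking by the normalized score
is generally more informative than thresholding p.

### Pairwise information and clustering

The score generalizes to ordered gene pairs: near pairs take gene a at walk
starts and gene b at walk ends; far pairs apply one shared cell permutation
to both genes (destroying spatial structure while preserving within-cell
coupling). The matrix I is symmetrized as Ĩ = (I + Iᵀ)/2, transformed to a
distance D = (1 + Ĩ)^(−s) with s = 0.5, the diagonal forced to 0 (the
formula gives a positive self-distance, which linkage cannot accept), and
clustered with complete linkage. Because all pairs of g genes cost g²
trainings, genes are pre-filtered by auto-information (a threshold or the
top few dozen genes). With the default positivity constraint, anti-correlated
gene pairs score near zero — the same documented blind spot as in the
single-gene case.

## Synthetic data

### Cellular Potts simulator

Cell positions and shapes come from a cellular Potts model on an L×L square
lattice: cells are site sets; each Monte-Carlo sweep makes L² copy attempts
(source site copies its cell identity into a 4-neighbor), accepted by the
Metropolis rule at the configured temperature on the Hamiltonian

    H = Σ_{adjacent sites in different cells} J(type_i, type_j)
      + λ_area Σ_c (area_c − A)²  +  activity term,

with J a symmetric matrix drawn uniformly from the adhesion range per
simulation. The activity term implements actin-like protrusion: a site's
activity is set to max_act on a successful copy and decays by 1 per sweep;
copy attempts from high geometric-mean-activity regions into low ones
receive an energy bonus λ_act·(GM_a − GM_b)/max_act, producing persistent
migration. Copies that would erase a cell's last site are rejected, so the
cell count is conserved exactly.

Cells start as single sites on a jittered grid, typed by discretizing
sin(2πx/L) + sin(2πy/L) into equal-probability bands (one full sine period
per axis — this yields the intended highly ordered initial "blobs", with
Delaunay type-homophily ≈ 0.9 at iteration 0 on the default configuration),
then grow to the target area before the Metropolis phase. More sweeps make
the arrangement progressively less ordered while differential adhesion keeps
it patterned; homophily after 10 sweeps exceeds homophily after 1,000.

Defaults: L = 200, 2,000 cells, 4 types, target area 16, adhesion range
(5, 15), λ_area = 25, λ_act = 100, max_act = 20, temperature 15. The
adhesion/activity/temperature values are this package's own calibration
(chosen so default-config cells migrate visibly within 1,000 sweeps); they
are recorded in every simulation's params.json and carry no claim beyond
that qualitative behaviour.

Expression: per gene a baseline mean from a log-normal(0, 1), rescaled so
the expected library size is 200 counts/cell (a sparse, in-situ-like
regime); counts are NB(r) with r = 4 by default (variance μ + μ²/r). A
random 1,000 of the 8,000 genes are SVGs: their means are multiplied
per-type by exp(N(0, σ_e²)), σ_e = 0.5 by default, so their expression
tracks the spatially organized type layout.

### Streak / hotspot simulator

Cells uniform on the unit square; SVG genes have their NB mean multiplied by
a fold change inside either a vertical band of width = region_fraction or a
central disk of radius sqrt(region_fraction/π). fold_change = 1 is the
documented degenerate all-null case (labels present, no effect).

### What the simulators do and do not capture

They produce discrete cell types with multiplicative expression shifts,
homogeneous NB noise, and geometrically simple (geo) or adhesion-driven
(Potts) spatial arrangements. They do not model continuous expression
gradients, segmentation error, cell-density confounding, platform-specific
capture efficiency, or within-type covariance between genes. Tests passing
on them demonstrate the estimator's behaviour under its intended data model,
not performance on any particular real platform.

## Benchmarks and baselines

Moran's I and Geary's C are computed with binary weights on the same graph,
on log1p library-size-normalized counts; constant genes are flagged NA (and
rank last), not silently zeroed. Geary's C is ranked by 2 − C so "higher =
more spatial" holds for both statistics. Ranking quality is area under the
precision-recall curve (average precision with tied scores handled as
blocks), and Δ PR-AUC subtracts the Moran's I value. The bundled benchmark
test uses the Potts simulator scaled to 500 cells × 300 genes (38 SVGs,
σ_e = 0.5, r = 4, 100 sweeps, lattice 80, area 8) over 3 seeds — sizes
chosen so the whole suite runs comfortably on a laptop-class single core —
and checks the direction of the result (Δ PR-AUC > 0, PR-AUC ≥ 0.5 at
prevalence 0.125); observed values are typically Δ ≈ +0.1–0.2.

## Numerical and degenerate-input choices

* softplus/log-sigmoid evaluated via `logaddexp` / `log_expit`; the identity
  −softplus(−f) = log σ(f) holds to double precision and is asserted in tests.
* Constant genes skip training and return the baseline (score 0, p = 1,
  flagged `skipped`).
* Collinear coordinates make Delaunay triangulation degenerate; the graph
  falls back to k-NN with a warning. Duplicate coordinates are allowed
  (zero-length edges are legal).
* Binomial tail from the exact survival function; underflow floored at the
  smallest positive double so p ∈ (0, 1].
* Ties in the kd-binning coordinate sort break by cell index (stable sort);
  an exactly centered cut rounds to the nearest multiple of k.
* Seeds: the master seed spawns one child stream per gene (seed sequence of
  master + gene index), so per-gene results are independent of execution
  order and of which gene subset is scored; graph and binning randomness use
  a separate fixed-offset stream.

## Known limitations

* Anti-correlated spatial patterns (gene high where its partner is low, or a
  single gene with mirrored halves) are undetectable under the default
  positivity constraints.
* The score grows with the number of participating cells by design; compare
  scores across datasets of different size only after dividing by n.
* The optimizer is stochastic: scores carry Monte-Carlo noise of a few
  percent between seeds in the resampling modes.
* The five-parameter classifier detects joint high/low and similarity
  patterns; deliberately elaborate spatial relationships (e.g. periodic
  phase relations) are out of its hypothesis class.
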