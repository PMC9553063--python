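# Methods

## Model

`selexrbm` models a pool of fixed-length DNA sequences with a Restricted
Boltzmann Machine: L categorical visible units (one per nucleotide
position, alphabet A/C/G/T) coupled by weights w_μi(a) to M real hidden
units with double-ReLU potentials U(h) = ½γ₊h₊² + ½γ₋h₋² + θ₊h₊ + θ₋h₋
(γ± > 0). The hidden marginal is analytic: each unit contributes
Γ(I) = log ∫ dh e^(−U(h)+hI), a sum of two half-Gaussian integrals, so a
sequence's unnormalized log-likelihood
log p̃(s) = Σᵢ gᵢ(sᵢ) + Σ_μ Γ_μ(I_μ(s)) is exact and cheap. The dReLU
family interpolates between quadratic (Gaussian) units and
rectified units, letting single hidden units express motif presence
with bimodal activities while keeping the marginal closed-form.

Score *differences* between sequences never involve the partition
function; all ranking, enrichment and design operations use log p̃
directly. When an absolute scale is needed (held-out likelihoods), log Z
is estimated by annealed importance sampling along a weight-scaling path
from the fields-only model (whose Z is a product over sites), default
1000 temperatures × 100 chains, with a reported standard error. The
choice of normalization affects no ranking.

### Numerical details

- Γ(I) is computed via the scaled complementary error function erfcx
  with the two branches combined in the log domain; for arguments where
  erfcx overflows, log erfcx(z) = z² + log(2 − erfc(−z)) is used. The
  implementation is stable for |I| well beyond 10³ and matches adaptive
  quadrature to ~1e−15 (tested).
- Conditional hidden moments (⟨h±⟩, ⟨h±²⟩) use truncated-normal moment
  identities with the inverse Mills ratio expressed through erfcx.
- Sampling h|s draws the branch exactly from the two branch weights,
  then a truncated normal: plain rejection from the untruncated Gaussian
  where the acceptance region is wide, Robert's shifted-exponential
  rejection in the tail. s|h is per-site categorical via Gumbel-max.
- The duplication trick samples p(s)²: two independent hidden vectors
  conditioned on s, visible logits with doubled fields plus both hidden
  contributions. On enumerable models both samplers match the exact
  (squared-)distribution within total variation 0.02 at 10⁶ samples.

## Training

Persistent contrastive divergence maximizes the (optionally
count-weighted) mean log-likelihood minus the L12 penalty
λ Σ_μ (Σ_{i,a}|w_μi(a)|)². The positive phase uses exact conditional
hidden moments; the negative phase advances persistent Gibbs chains
(never reset) a few sweeps per update. Defaults: M = 70 for 20-nt loops
and 90 for 40-nt double loops, λ = 1e−3 — the reference configuration
for this data regime — and, as this package's own optimizer choices,
batch 100, learning rate 5e−3 with linear decay, 100 chains, 10 Gibbs
steps/update, γ± floored at 0.05, θ initialized at 0, γ at 1,
w ~ N(0, 0.01²), fields at log empirical site frequencies. The scaled
benchmark runs in the test-suite and acceptance script use fewer Gibbs
steps per update (2) and smaller M — PCD tolerates short chains because
persistence keeps the negative phase near the model distribution.

Count weighting draws minibatches uniformly over unique sequences and
weights per-example gradients by counts (normalized per batch), which
makes counts mode and unique mode *identical* when all counts are equal
(asserted in tests) and keeps memory independent of total reads.
Training stops after a fixed epoch budget with a divergence guard; no
early stopping. Oracle properties validated by enumeration: single-step
ascent of the exact regularized objective, site-marginal moment
matching, hidden units beating a fields-only fit on a correlated
target, and weight sparsity non-decreasing in λ.

## Selection-dynamics analysis

Exponential selection multiplies pool frequencies by e^{αF(s)} per
round. Because per-sequence enrichment ratios are destroyed by
subsampling, sequences are pooled into bins of similar model
log-likelihood; the regression of log[C_r(bin)/C_{r−1}(bin)] on bin
center estimates α_{r−1} when log p̃ tracks F. Defaults: 100 bins over
the pooled score range; the fit window excludes under-sampled tails
holding 0.5% of the count mass (both configurable — the reference
real-data analysis used a fixed window with a comparable exclusion).
Bin centers, not count-weighted means, serve as the regressor; the
difference vanishes as bins narrow (convergence asserted at three bin
widths). The Fisher-ratio estimator (Δmean/var of the score) divides by
the *pre-selection* round's variance by default — the choice consistent
with Fisher's theorem; the post-round variant is exposed via a flag
since the convention is not settled. Cumulative strengths β_r are
solved from pairwise cross-model slopes by least squares in the log
domain with the reference round anchored at 1.

Parasite detection (a low-scoring loop carried by a high-scoring
partner loop in a double-loop construct) thresholds at the 0.99
quantile of uniformly random 20-mer scores, 10⁵ random draws by
default.

## Sequencing-error estimation

Reads of a high-count "peak" sequence carrying exactly one sequencing
error appear as low-count one-mutant neighbours. The estimator solves
Σ_peaks C·L·ε(1−ε)^{L−1} = observed neighbour mass for ε on the
monotone branch ε ≤ 1/L, where the observed mass counts neighbours with
count ≤ a cutoff (default 10; peaks excluded — they may be genuinely
selected variants). Genuine low-fitness variants inflate the observed
mass, so ε̂ is an upper bound (asserted on simulations with planted
variants). Multi-error reads are neglected (O((Lε)²) at ε ≤ 1e−3).
Expected spurious uniques per table follow
Σ_s 3L·(1 − e^{−C_s L ε/(3L)}), counting each neighbour once. Defaults:
peak threshold 1000 counts, neighbour cutoff 10.

## Synthetic SELEX generator

The simulator is the ground truth for every recovery claim. It draws an
initial library i.i.d. uniform over sequence space (default 10⁶
distinct molecules — real libraries are ~10¹⁵; the scaled-down library
preserves the regime that matters, library ≫ sequencing depth, so that
most observed counts are 1), applies exact exponential reweighting per
round, optionally Poisson PCR resampling, then multinomial subsampling
at the sequencing depth (default 750,000 reads/round, matching the
data regime the package targets) with per-read per-nucleotide error
injection (default ε = 1e−3). Defaults: 8 rounds at constant α = 0.15,
the order of mid-round strengths inferred from real pools. An
infinite-depth mode returns the exact frequencies so tests can separate
sampling noise from dynamics (the reweighting law is formally an
infinite-population statement).

Fitness landscapes are additive fields plus windowed motif bonuses.
The named benchmarks: `additive_only` (fields only), `gquad_like`
(fields σ = 0.5 plus a G-rich GGTTGG motif with bonus 4 — the field
scale is chosen so that a few selection rounds spread scores over tens
of units, as real pool score histograms do), `two_family` (two disjoint
motifs), and `double_loop_additive` (the same single-loop landscape on
both halves of a 40-mer, so F is exactly additive and the two loops
have matching statistics, as real left/right loops do).

What the simulator does *not* emulate: washing/binding biophysics,
PCR sequence bias (foldable into F), position-dependent or
quality-correlated sequencing errors, secondary-structure effects, and
inter-loop epistasis. Passing recovery tests therefore demonstrates the
estimators are correct under the stated selection model, not that real
pools obey it.

## Scaled benchmark sizes

The test-suite and acceptance-script benchmarks use problem sizes
chosen to exercise the full pipelines at desk scale: selection-strength
recovery at depth 10⁵ over a 2×10⁵ library; fitness tracking on L = 10
(full 4¹⁰ enumeration) with M = 20 and 15 epochs; double-loop
additivity on L = 40 with a 2×10⁶ library, depth 1.5×10⁵, M = 20/15 and
8 epochs; error recovery on a 50-clone pool at depth 2×10⁵. Exactness
checks (marginals, samplers, partition functions) run on fully
enumerable models (L ≤ 4, M ≤ 3).

## Design layer

Threshold calibration minimizes misclassifications over all cuts of the
labelled scores; the minimizing cuts form intervals and the midpoint of
the lowest optimal interval is returned (deterministic; translation
equivariant). A score exactly at the threshold counts as a predicted
binder — boundary candidates in the packaged assay table sit slightly
above the threshold, so the inclusive rule is the safe one. Candidate
generation samples p or p² and filters by score and Hamming distance to
the dataset (distance annotations can be restricted to sequences above
a count floor). Critical-mutation search enumerates all ≤ k-site
mutants exhaustively under an optional per-mutation constraint (e.g.
never remove a G, preserving quadruplex-forming potential).
Count/likelihood mismatch mining uses default cutoffs of ≥ 139 counts
(high-count/low-score list) and ≤ 11 counts (low-count/high-score
list), the reference analysis values.

## Packaged fixture

`data/table1.tsv` reproduces the published table of 37 assayed 20-nt
thrombin-aptamer loops (27 designed candidates r1–r27, known binders
ThA–ThD, and the six ThA→r9 intermediates p1–p6) with both models'
scores, threshold predictions, gel-shift outcomes, exosites, and
distances to the round-8 pool. It is fixture data — the published
scores are inputs here, not retraining targets; the package recomputes
only derived statistics (AUC, agreement counts, distances) from it.

## Known limitations

- The absolute log-likelihood scale depends on the AIS normalization;
  only score differences are load-bearing.
- The L12 subgradient at exact zeros is taken as 0; weights can
  oscillate around zero at large λ instead of sticking exactly.
- The error-rate estimator assumes peaks are genuine (not themselves
  error-dominated) and ignores position-specific error profiles.
- Enrichment-slope estimates degrade when consecutive rounds share few
  occupied score bins (very strong selection or very shallow depth).
- The simulator's multinomial sequencing model has no read-quality
  structure; FASTQ quality integration is out of scope.
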