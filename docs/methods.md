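# Methods

`threatnet` implements a dynamic oscillatory-network analysis of
instructed-threat EEG experiments: band-limited power-envelope correlation
networks from epoched source time series, consensus Louvain community
dynamics with topology metrics over a proportional-density grid, and
time-resolved partial directed coherence (TPDC) with time-reversal surrogate
testing — together with a synthetic cohort generator that plants every
quantity the analysis is supposed to recover.

## Epochs and windows

Epochs span −0.25 s to 1.5 s around stimulus onset at 250 Hz.  Sample k sits
at t_k = −0.25 + k/250; window edges in milliseconds map to sample indices
by round-half-to-even of t·fs, half-open `[start, end)`.  This puts stimulus
onset at index 62, gives the epoch 438 samples, the 250 ms baseline samples
`[0, 62)`, and makes the six post-stimulus windows T1–T6 tile `[62, 437)`
without gaps.  Each 250 ms window divides into five 50 ms sub-windows
(12–13 samples each) that serve as community-detection layers.  The
convention must be fixed because neither 250 ms nor 50 ms is an integer
number of sample periods; any consistent convention would do, and this one
keeps windows contiguous by construction.

Preprocessing is a zero-phase (forward–backward) fourth-order Butterworth
band-pass, 3–45 Hz by default.  Zero-phase filtering is chosen because the
windowed connectivity downstream is phase-sensitive; the cost is
non-causality, which is irrelevant for windowed summaries.  An anti-aliasing
low-pass whose cutoff reaches Nyquist is a mathematical no-op at this rate
and is skipped with a warning rather than applied.  Inter-trial phase
coherence (ITPC) — the modulus of the mean unit phasor of band-filtered
analytic-signal phases across trials — is the phase-locking quality check;
for n independent trials its null expectation is ≈0.886/√n.

## Connectivity

An edge is the Pearson correlation of two ROIs' band power envelopes
(squared analytic-signal amplitude of the band-filtered series) over a
window's samples, rectified to `[0, 1]`.  Power envelopes are the standard
construction for source-level amplitude coupling, and zero-lag correlation
is the simplest symmetric reading of "power cross-correlation".  For the
50 ms sub-windows the per-trial sample count (12–13) is far too small, so
windowed samples are concatenated ("pooled") across trials before
correlating; trial-level envelope co-fluctuations are deliberately kept —
they carry most of the coupling signal at this window length.  Fisher-z
averaging of per-trial correlations is available as the alternative pooling
mode.  Binary graphs come from proportional thresholding: keep the
⌈d·N(N−1)/2⌉ strongest edges, ties broken lexicographically, so edge sets
are exactly nested along the 20-density grid spanning 0.1–0.6.

## Communities

Community structure is Newman–Girvan modularity maximisation (resolution γ)
by Louvain, repeated with randomized visitation (5000 iterations at full
scale; every function takes `n_iter`), and consolidated by consensus: runs
are aligned to the best-modularity run by Hungarian matching on the
contingency table, the consensus label is the per-node mode, per-node
stability the modal fraction, and the allegiance matrix the pairwise
co-assignment frequency.  Labels are renumbered by descending community
size for reproducibility.  A resolution sweep (γ = 1–2.5, step 0.05 by
default) with `select_gamma` supports choosing the resolution that yields a
target community count.

Dynamic assignments across layers use true multilayer modularity: each
layer contributes its own null term A_s − γ k_s k_sᵀ/2m_s, and inter-layer
identity coupling ω enters the quality matrix directly (categorical
coupling, all layer pairs).  A flat supra-adjacency under single-layer
modularity was evaluated and rejected: without layer-restricted null terms
the optimum degenerates to one community per layer.  The multilayer matrix
is optimized by a seeded greedy local-move routine (quality non-decreasing
per move), run `n_iter` times for consensus.  At ω = 0 the layers decouple
and per-layer consensus partitions are matched across consecutive layers by
maximal overlap.

ω trades temporal smoothness against sensitivity: in the strong-modularity
regime (planted block graphs) moderate ω (≈0.5) recovers planted
mid-sequence switches essentially perfectly, while large ω suppresses them.
For the dense, weakly contrasted envelope matrices of 50 ms sub-windows any
appreciable ω freezes the labels — the interlayer term dominates the small
intralayer modularity differences — so the cohort analysis runs its
flexibility layers at ω = 0.  The API default remains ω = 1, configurable.

Detected communities can be named (central executive, salience, default
mode, or one of six anatomical baseline communities) by Jaccard overlap
against fixed bilateral ROI membership lists shipped in `threatnet.atlas`.
The atlas fixture enumerates 56 bilateral region names (112 labels); the
default 90-channel source space uses the first 90.

## Topology metrics

Flexibility f_i is the fraction of consecutive-layer transitions at which a
node changes community label (0 = rigid, 1 = maximally flexible); F is the
node average.  The layers are the five 50 ms sub-windows of each 250 ms
window (T = 5).  Clustering, global efficiency (mean inverse shortest-path
length over ordered pairs, disconnected pairs contributing zero) and local
efficiency (global efficiency of each node's neighbour-induced subgraph)
are computed on the thresholded binary graphs at each of the 20 densities;
graphs whose largest component covers <90% of nodes are flagged fragmented
but never dropped.  Community detection itself runs on the weighted
matrices, so flexibility is density-independent; `metrics_over_densities`
accepts a per-density label supplier for the thresholded variant.

## Time-resolved effective connectivity

A time-varying MVAR model x_t = Σ_r A_r(t) x_{t−r} + w_t is estimated by a
dual Kalman scheme: a signal filter (scalar-covariance, measurement noise
`observation_noise`; with the default 0 it passes the observations through)
coupled to a weight filter that tracks the vectorised coefficients under
random-walk dynamics with process noise q.  The weight covariance is shared
across target channels — they regress on identical lagged predictors and
the gain uses the channel-mean innovation variance — which keeps the
recursion exactly decoupled per channel and cheap enough to batch across
trials and surrogates.  Innovation variances are tracked by an exponential
moving average (`sigma_forget`, default 0.02).  Estimates before a burn-in
of 5·order samples are excluded from summaries.

q sets the tracking/variance trade-off and should be matched to the
question: q ≈ 1e−3 tracks a coefficient step (crossing half the step within
200 samples and settling within ±0.15); q ≈ 1e−6 is the near-recursive-
least-squares regime for stationary data, where the time-averaged
coefficients agree with an ordinary-least-squares MVAR fit (PDC of the
averaged model within ~0.02 RMS of the OLS-based PDC over the 2–45 Hz
grid).  Model order defaults to 5 at 250 Hz with an information-criterion
helper (`select_order`); the validation studies use order 2, matching their
AR(2) generators.

PDC is evaluated per time point: Ā(f,t) = I − Σ_r A_r(t) e^{−i2πfr/fs},
π_{i←j} = |Ā_ij| / √(Σ_k |Ā_kj|²).  For every source channel the squared
outflows over all targets sum to one at each (f, t) — the normalization the
tests verify to 1e−10.  PDC columns become near-singular at the oscillator
resonance (|Ā_jj| small), which amplifies coefficient noise; this is why
stationary comparisons average coefficients before, not after, the PDC
transform.

Directed significance uses a time-reversal randomization test: each
surrogate time-reverses a random subset of trials and recomputes the
trial-averaged band-mean summary.  Reversal preserves each trial's spectrum
but flips its directed temporal structure; under the no-coupling null,
stationary Gaussian trials are time-reversible, so observed and surrogate
statistics are exchangeable and the test is calibrated by construction
(measured type-I ≈ 0.05–0.07 at nominal 0.05).  Because the summary is a
trial average, surrogates are averages of precomputed per-trial forward and
reversed statistics — two Kalman fits per trial regardless of surrogate
count.  A pair is significant when the observed summary exceeds the
(1−α) null quantile (α default 0.001 with 1000 surrogates; the validation
studies use 200 surrogates at α = 0.01); both directions combine into a
none / uni(i→j) / uni(j→i) / bi call.  At least two trials are required so
the randomization has support, and the test refuses α below the resolution
1/(n_surrogates+1).  Fitting all 90 ROIs jointly is out of scope; the
intended operating regime is the 4–5 node subsets of a named network.

## Statistics

Behavioural contrasts use two-sided paired t-tests (α = 0.01).  A
zero-variance difference is reported as a degenerate result rather than an
exception: t = 0, p = 1 when the difference is identically zero, t = ±∞,
p = 0 when it is a non-zero constant.  Network metrics enter a two-way
fully within-subject ANOVA (condition × window) computed by explicit
sums-of-squares decomposition, each factor tested against its own
subject-by-factor interaction; Mauchly's test runs on the window factor
(collapsed over condition) and a Greenhouse–Geisser correction is applied
to window-involving terms when sphericity is rejected at p < 0.05.  The
implementation agrees with pingouin's two-way repeated-measures ANOVA to
1e−10 and its condition-test type-I error is 0.02–0.09 at nominal 0.05 in
null simulations.  Metric values are averaged across the density grid per
cell before testing (density-as-replicate is available by passing the
unaveraged table).  Post hoc contrasts are paired t-tests over consecutive
window pairs or each window versus baseline, Bonferroni-corrected within
the contrast family; Shapiro–Wilk normality is reported but never gates.
Pearson correlations carry Bonferroni-adjusted p-values (multiplied by the
family size, capped at 1).

## Synthetic cohorts

Each ROI is a damped AR(2) oscillator: centre frequency and pole radius ρ
map to coefficients a₁ = 2ρcos(2πf/fs), a₂ = −ρ²; ROIs cycle through the
configured bands (theta 6 Hz and alpha 10 Hz by default, ρ = 0.95, i.e. an
autocorrelation time of ~20 samples).  Community structure is planted by a
hidden driver oscillator per community: every ROI receives a lag-1
coefficient (0.9 by default) from its current community's driver, so
members share band-limited input and their power envelopes correlate
strongly, while different communities stay uncorrelated.  Membership
follows a planted timeline over the 35 sub-window layers: layer one is the
base partition, and at each transition every node independently resamples
to a *different* community with the switching probability — making expected
nodal flexibility exactly equal the rate.  Default rates are 0.4 (CS+)
versus 0.2 (CS−) post-stimulus and 0.05 in the baseline window; the trial
counts (36 CS+, 24 CS−) mirror the instructed-threat design.

Directed ROI-to-ROI couplings are injected as lagged cross-terms with
optional activity windows; the stimulation stand-in multiplies the
configured coupling coefficients by a gain during its interval
(1000–1250 ms by default), only in its configured condition — exogenous
perturbation as a transient change in information flow.  Every distinct
coefficient regime is verified covariance-stationary (companion spectral
radius < 1) before simulation; drivers receive no input, so the check
reduces to the ROI block.  The process warms up for 200 samples before the
epoch.  Series are unitless at innovation scale σ = 1 and are *not*
z-scored by default: rescaling channels would bias recovered MVAR
coefficients away from their planted values (a `standardize` flag exists).

Behaviour: each subject has a latent switching deviation z (their rates
shift by 0.1·z, clipped to [0, 1]) and a latent affect factor u.  Ratings
load 0.6 on z (the planted behaviour–flexibility correlation) and share u
with heart rate so that corr(rating, heart rate) ≈ 0.5; condition shifts
are +2.0 rating points and +8 bpm for CS+ (SDs 1.0 and 4.0).  All
randomness flows through `numpy.random.SeedSequence`, so a fixed seed gives
bit-identical cohorts, on disk and in memory.

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes — band-limited
oscillations, envelope coupling with planted communities, Markov membership
switching, directed lagged coupling, behaviour tied to network parameters —
but not volume conduction or source leakage, 1/f background spectra,
non-stationary artefacts, or realistic stimulation waveforms.  Passing
recovery tests therefore demonstrates that the pipeline recovers the
structure it targets when that structure is present, not that real EEG
satisfies these assumptions.

## Validation studies and problem sizes

The studies in `threatnet.experiments` (rerun from scratch by
`scripts/acceptance.py`) use sizes chosen to finish in minutes on one CPU
while keeping Monte-Carlo error well below the effects measured:
planted-partition recovery on five 60-node 6-block graphs (p_in = 0.6,
p_out = 0.05) with 200-iteration consensus; flexibility calibration at
rates {0, 0.3, 1} over 500 timelines of 90 nodes × 6 layers; stationary
TPDC agreement on five 2000-sample bivariate AR(2) runs; step tracking
averaged over ten 1000-sample runs; surrogate calibration and power over
100 runs of 16 trials × 400 samples with 200 surrogates; and the
end-to-end study over 20 replicate cohorts of 20 subjects with 36 ROIs in
three communities, sub-window detection at γ = 1, ω = 0, 5-iteration
consensus.

In the end-to-end study the condition effect on flexibility is essentially
always detected (p < 0.01 in all 20 cohorts), but measured flexibility is
an attenuated estimate of the planted rate: the theta filter's impulse
response (~100 ms) outlasts the 50 ms layers, so membership switches blur
across layer boundaries and the measured-vs-planted slope is well below
one.  Correlation with the planted rate across subjects still averages
~0.75, and the recovered behaviour–flexibility correlation averages ~0.43
against a planted 0.6 — attenuation, not bias, which is exactly what this
window length permits.

## Known limitations

- The dual Kalman filter's shared weight covariance ignores cross-channel
  innovation correlation; strongly correlated innovations would make the
  decoupled update approximate.
- Multilayer coupling across subjects (as opposed to across time layers) is
  not implemented.
- Flexibility at 50 ms layers is attenuated by filter memory (above); band
  limits and window lengths are inherent to the design, not tunables that
  remove this.
- The local-move multilayer optimizer has no aggregation phase; for the
  layer sizes used here (≤ a few hundred supra-nodes) local moving reaches
  the planted optima, but very large supra-graphs would warrant a full
  Louvain-style aggregation.
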