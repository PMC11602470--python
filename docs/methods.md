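# Methods

`mwnetdyn` analyzes multichannel EEG as a sequence of two-layer multiplex
functional-connectivity networks and detects mind-wandering from the dynamics
of recurring network states. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic benchmarks do and
do not establish.

## Signal model and preprocessing

Inputs are 8-channel recordings (F3, F4, T3, C3, C4, T4, O1, O2) at 256 Hz,
assumed already resampled and notch-filtered. Each recording is restricted to
one of five canonical bands — delta (1–4 Hz), theta (4–8), alpha (8–13),
beta (13–30), gamma (30–80) — with a zero-phase windowed-Hamming FIR filter
(MNE's default design: transition bandwidths `min(max(0.25·f, 2 Hz), f)`
below and `min(max(0.25·f, 2 Hz), Nyquist − f)` above, order from the 3.3 /
transition-bandwidth rule). Two practical consequences are worth keeping in
mind: a "band-limited" signal holds roughly 5–20% of its power in the
filter's transition bands, and re-filtering band-limited noise removes that
transition energy (a 2–5% RMS change), so idempotence holds only for signals
inside the flat passband.

Artifact handling is a mask, not a cut: samples where any channel exceeds an
amplitude threshold (default 100 µV, a common convention — the threshold is
a parameter, not an estimate) are marked invalid together with 0.25 s of
padding on each side, and every later analysis window must lie entirely
inside a valid stretch. Masking rather than concatenating avoids
manufacturing connectivity across discontinuities.

## Connectivity and the multiplex network

For a data segment, two 8×8 matrices are computed from the Hilbert analytic
signal of each channel:

- **AEC** (layer 1): absolute Pearson correlation between amplitude
  envelopes. Absolute value, because sign has no interpretation in this
  analysis and cancellation during averaging is undesirable.
- **IPLV** (layer 2): `(1/N)·|Im Σ_n exp(i(φ_i(n) − φ_j(n)))|`. Using only
  the imaginary part of the phase-locking phasor makes the measure blind to
  zero-lag synchrony, the signature of volume conduction at the electrode
  level.

Each layer's off-diagonal weights are min-max normalized to [0, 1] so the two
layers share a scale. A layer whose edges are all equal is mapped to 1 (not
0): a zero weight means an absent edge and infinite distance downstream,
which would disconnect the graph for no physical reason. The Hilbert
transform is taken on the segment as given (no padding); the segmenter's
minimum segment length (0.5 s) keeps edge effects bounded. Envelopes are not
orthogonalized.

The two layers form a weighted multiplex network: interlayer edges connect a
node only to its own replica and carry no traversal cost.

## Centrality

Edge distance is the inverse of the normalized weight; zero-weight edges are
absent. Within a layer, closeness of node *i* is the inverse of its mean
shortest-path distance to all other nodes, and exactly 0 if any node is
unreachable (the limit of the formula, not a special case). The
**overlapping closeness** of a node is the mean of its per-layer closenesses.
Because the printed formula averages a per-layer quantity, the default
convention computes distances within each layer; an alternative in which
paths may hop between replicas at zero cost — equivalent, for two layers, to
shortest paths on the elementwise-maximum graph — is available via
`interlayer="zero-cost"` for sensitivity analysis. Inter-layer heterogeneity
is the Pearson correlation between the two layers' vectorized upper
triangles.

## Segmentation (EDMCC)

The recording is scanned at 0.25 s steps. At each candidate position the
multiplex networks of the trailing 2 s reference window and the advancing
2 s candidate window are built, and the Euclidean distance between their
layer-averaged closeness profiles (the centrality-matrix distance) is
computed. A Gaussian KDE (Scott bandwidth) is maintained over the distances
observed so far; once at least 30 are available, a position is an *outlier*
when its distance exceeds the KDE's 0.96 quantile.

A boundary is declared at the distance **peak of an outlier excursion that
persists for at least 1 s** (`min_persist_s`). The persistence rule is the
key discriminator: a genuine network change keeps reference and candidate
windows mismatched for about one window length, whereas isolated noise
outliers — which a per-step quantile rule necessarily produces at a rate of
1 − p_KDE — do not persist. Segments respect a minimum length of 0.5 s,
never span masked samples, and stretches longer than 10 s are force-split.
When states dwell for about one window length or less, both windows straddle
switches most of the time and few persistent excursions emerge, so the
maximum-length cap dominates segment sizes; for state-sequence analysis at
the 2 s dwell scale the pipeline therefore runs the segmenter with a 2.5 s
cap, which recovers the ~2 s segment granularity while still letting genuine
sustained changes place boundaries.
Segmentation quality is scored by `p_diff`: over adjacent segment pairs, the
fraction whose between-segment network distance strictly exceeds both
segments' first-half/second-half distances (chance level ≈ 1/3 under
exchangeability). The uniform 2 s sliding-window segmentation is the
comparison baseline.

## Recurring network states

Every segment is summarized by its overlapping-closeness vector. To remove
inter-individual scale differences, each participant's vectors are min-max
normalized per node component over all of that participant's segments and
trials. The normalized vectors from all participants are pooled into a
complete similarity graph whose edge weights are Spearman rank correlations;
negative correlations are clamped to 0 because modularity assumes
nonnegative weights. Louvain community detection (resolution 1.0, seeded)
partitions the segments; communities are the network states, labeled A, B,
C, … by descending time coverage, and communities holding under 1% of total
time are merged into their most-correlated neighbor so tiny clusters cannot
destabilize downstream observation alphabets. The state count is
data-driven, never forced. Per band the procedure is repeated independently;
state centroids can be correlated across bands and states.

## State-sequence dynamics

Adjacent same-state segments are consolidated into runs, so self-transitions
are impossible; an artifact gap breaks a run without creating a transition.
Per state: frequency (runs/s), mean run duration, and coverage. Observed
transition probabilities are joint frequencies over ordered state pairs. The
frequencies-only expectation is

    P*(X→Y) = P_Y · P_X / (1 − P_X),

whose off-diagonal total is exactly 1 — the unique memoryless benchmark for
consolidated sequences. Structure beyond frequencies is tested by the
chi-square distance `d = Σ (P − P*)² / P*` against a permutation null that
pools the off-diagonal cells of the observed and expected matrices and
randomly reassigns them to two pseudo-matrices (cells with zero
pseudo-expected value contribute nothing); `p = (m + 1)/(n + 1)`,
tie-inclusive, so that observed = expected yields p = 1.

**Known limitation.** This cell-pooling permutation is conservative by
construction: the actual distance pairs every observed cell with the
expectation computed from the same sequence, a pairing that any reassignment
breaks, so permuted distances are stochastically larger and the empirical
type-I error under a frequency-matched memoryless null is ≈ 0 rather than
the nominal 0.05. Power is excellent against alternatives whose observed
matrices contain structural zeros (e.g., a deterministic cycle) and weak
against diffuse alternatives. A small p from this test is therefore strong
evidence of transition structure, but a large p is uninformative.

## Group comparisons

The fixed cascade per metric: Tukey box-plot outlier removal per group
(linear-interpolation quartiles, 1.5 IQR fences), Shapiro–Wilk normality per
group at 0.05, then Levene's test choosing between pooled-variance and Welch
t-tests, or the two-sided rank-sum test if either group is non-normal. Raw
p-values at α = 0.05, no multiplicity correction, and every branch taken is
recorded in the result. Note that trimming before testing makes the cascade
mildly anticonservative at small n (measured ≈ 0.09 at n = 15 under a normal
null, ≈ 0.07 at n = 60).

## Mind-wandering classifier

Per participant and band, trials of one condition are concatenated into one
symbol sequence over the state alphabet. For each of k = 8 contiguous
cross-validation blocks: one discrete 2-hidden-state HMM is trained per
condition on the other k − 1 blocks with Baum–Welch; the frequency band is
chosen by inner 4-fold cross-validation on those training blocks only (ties
toward the lower band); each held-out block is split into 4 windows per
condition, and every window is scored by the posterior under equal priors,
`S_FL = P(Y|λ_FL) / (P(Y|λ_FL) + P(Y|λ_MW))`, computed stably from the
scaled-forward log-likelihood difference. Fold AUC is the rank (Mann–Whitney)
AUC of these scores; F1 uses the Youden threshold of the training-window
ROC. Nothing outside the training blocks touches band choice or threshold.

Numerical choices that matter, all of which were decisive in development:

- **Initialization.** Exactly uniform A, B, π are a fixed point of EM at
  which the hidden states never differentiate. Each row is therefore
  perturbed by seeded 10% jitter; smaller jitter leaves some runs inside the
  saddle's basin for hundreds of iterations. Three seeded restarts are run
  and the highest-likelihood solution kept.
- **Convergence.** Tolerance 1e-6 on the log-likelihood gain, at most 300
  iterations. Near the symmetric saddle EM progresses in steps far smaller
  than 1e-4, so a loose tolerance silently returns the degenerate solution.
- **Smoothing.** Transition and emission cells are floored at 1e-2 during
  the M-step. Training sequences here are short (order 10² symbols) and bare
  maximum likelihood drives unseen cells to exact zero, after which a single
  unseen pattern in a test window dominates its log-likelihood.
- **Window scoring.** Held-out windows are mid-sequence excerpts, so the
  hidden chain is scored from the stationary distribution of the trained
  transition matrix rather than from the trained initial distribution, which
  only describes recording starts.

## Synthetic benchmark data

The generator plants recurring coupling motifs in otherwise independent
narrowband noise. A motif (network state) is a phase-coupled module — a
clique of (by default 4) channels sharing a single source rendered with
incremental analytic phase lags of π/4, which loads on both the envelope and
the phase layer — plus one amplitude-only pair on channels outside the
module, whose shared source carries a slow common envelope (±30%
modulation). One source per module keeps pairwise coupling undiluted
regardless of module size. Mixing is power-preserving:
`x = √(1−a²)·noise + a·√snr·source` with coupling strength a = 0.9 and
snr = 1 by default. Motifs are drawn with tagged-edge Jaccard overlap < 0.5
and module channel-set Jaccard < 0.5; the second state's module avoids the
first's channels entirely so every library contains one fully disjoint pair.
All signals are white noise shaped by the pipeline's own FIR band-pass, so
generator and analyzer agree spectrally. A trial switches motifs along a
Markov chain with exponential dwell times (mean 2 s, matching the method's
operating segment scale); ground truth records the path and change points.

The benchmark conditions share all four motifs and differ only in switching:
focused learning favors A↔B exchanges, mind-wandering favors C↔D (and their
stationary occupancies differ accordingly).

Benchmarks run in the **gamma band**: a 2 s window of a 50 Hz-wide band
contains an order of magnitude more independent envelope and phase samples
than the same window of a 5 Hz-wide band, so window-level connectivity
estimates are usable at the method's native window scale. Benchmark problem
sizes (60 s trials for segmentation studies; four 300 s trials per
synthetic participant for classification, segmented with a 2.5 s maximum
segment length to approximate the ~2 s segment scale; 10–20 seeds; 500
permutation-test replicates) were chosen to leave clear statistical margins
while a study completes in minutes on one core.

What passing these benchmarks does **not** show: the generator has no
volume conduction, no 1/f background, no artifacts beyond amplitude spikes,
no inter-participant topography differences beyond scale, and stationary
within-state coupling. Recovery on this data establishes that the pipeline's
machinery is correct and self-consistent, not that real EEG carries signals
this clean; in narrow bands (delta–alpha) the window-level connectivity
estimates are substantially noisier and state separation degrades.

## Degenerate inputs and edge conventions

Constant channels: AEC/IPLV pairs set to 0 with a warning. Degenerate layer
normalization: all edges mapped to 1. Zero-variance components in
per-participant normalization: set to 0. Constant vectors in the similarity
graph: edges 0. Empty states: dropped from centroids. Single-state
sequences: expected transitions undefined (NaN). Fewer than 2 segments:
p_diff undefined (NaN). Insufficient group sizes after outlier removal:
missing comparison result. Cross-validation folds with insufficient data are
skipped with a warning; an error is raised only if every fold is skipped.
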