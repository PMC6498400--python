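# Methods

`jdnet` turns epoched multichannel EEG into a functional brain network and
compares network topology between two groups. This note records the model,
its conventions, the tunable parameters, and what the synthetic cohorts do
and do not establish.

## Signal model and preprocessing

A subject arrives as a tensor `u[channel, sample, epoch]` at sampling rate
`fs` (nominally 256 Hz), recorded around a stimulus. Processing order:

1. **Pre-stimulus trim.** The first `prestim_samples` samples of every epoch
   (0.2 s ≈ 51 samples at 256 Hz) are dropped so only task-elicited activity
   remains. With 1.40 s epochs (≈358 samples) this leaves N = 307 samples;
   durations that are non-integer in samples are rounded to the nearest
   sample.
2. **Epoch averaging.** `ū_c(i) = mean_e u[c, i, e]` isolates the
   stimulus-locked (evoked) component; non-locked activity and noise shrink
   as 1/√E.
3. **Zero-phase band-pass.** A Butterworth cascade — high-pass of design
   order 4 with half-power frequency 9 Hz, then low-pass of order 8 at
   34 Hz — is applied forward and backward per stage (`sosfiltfilt`). The
   two passes square each magnitude response and cancel phase exactly, so
   narrowband features keep zero lag. Edge transients are handled with
   odd-reflection padding longer than three times the filter order. The
   9–34 Hz band nominally targets beta activity though it also spans alpha;
   the cutoffs and orders are exposed in `FilterSpec`/`PipelineConfig`.
4. **Unit-range rescale.** Each channel is mapped affinely onto [0, 1] by
   `(u − min u)/(max u − min u)`. A constant channel cannot be rescaled and
   raises a structured error naming the channel; in a cohort run the
   subject is skipped and reported. Rescaling makes the coupling measure
   invariant to per-channel gain and offset.

## Joint-distribution entropy (JDistEn)

For each channel the rescaled series is delay-embedded with dimension
`m = 2` and delay `τ = 1` (the standard choice for short EEG records in
entropy-based analysis): columns `X(i) = [ū(i), ū(i+τ), …, ū(i+(m−1)τ)]`
for `i = 1 … N − n`, `n = mτ`. (With `m = 2, τ = 1` the index range leaves
one usable column unused; this follows the printed definition of the
method.)

The per-channel distance matrix uses the operational definition

    D(i, j) = max[ max X(i) − min X(j),  max X(j) − min X(i) ],

a comparison of column extrema. This is not the textbook Chebyshev maximum
norm (which is available via `EmbeddingConfig(norm="chebyshev")`); the two
differ, and the extrema form is the default because it is the method's
operational definition. Its diagonal equals each column's own range rather
than zero; the diagonal is excluded from everything downstream, so the
discrepancy is inert.

Two channels' distance matrices combine entrywise into the joint distance
matrix

    JD = 1 − sqrt((1 − D₁) ∘ (1 − D₂)),

which equals `D₁` exactly when `D₁ = D₂` (implemented as an exact fast path
— floating-point `sqrt(x²)` is otherwise off by an ulp). The off-diagonal
entries of `JD` — both triangles, `n_obv = (N−n)² − (N−n)` values — are
histogrammed with the bin count from Doane's rule,

    B = 1 + log₂ n_obv + log₂(1 + |g₁|/σ_g1),
    σ_g1 = sqrt(6(n_obv − 2) / ((n_obv + 1)(n_obv + 3))),

with `g₁` the population skewness (`m₃/m₂^1.5`; defined as 0 for constant
input), `B` rounded half-away-from-zero and floored at 2 bins. Bins are
equal-width over `[min, max]` with the rightmost bin closed. The coupling is
the normalized Shannon entropy

    JDistEn = (−1 / log₂ Bins) Σ_t ρ_t log₂ ρ_t ∈ [0, 1],

summing over non-empty bins. Identical dynamics preserve the full spread of
the single-channel distance distribution (entropy near 1 — fully coupled);
independent channels average each other's structure away, concentrating the
histogram (entropy toward 0). All pairwise values form a symmetric
channels × channels coupling matrix; the diagonal (self-coupling) is set to
0 and never enters thresholding. Per-channel distance matrices are computed
once and shared across the pairs.

## Binary networks and small-world metrics

Coupling matrices vary in range across subjects, so thresholding is by
**fixed density**: the strongest `E = round(0.10 · V(V−1)/2)` node pairs
become edges (813 edges at V = 128), giving every subject the same edge
count. Rounding is half-away-from-zero; ties at the threshold weight break
deterministically by lexicographic (row, column) order so quantized weights
reproduce exactly.

On the binary graph:

* **Clustering C** — mean over all nodes of the local clustering
  coefficient (degree < 2 contributes 0).
* **Characteristic path length L** — mean shortest-path length over ordered
  reachable pairs. Sparse graphs can disconnect; L is then computed on the
  largest connected component (ties broken toward the component containing
  the smallest node label), and the component size is reported per subject.
* **Eccentricity** — per node, the maximum shortest-path distance within
  its own component (0 for isolated nodes); the subject-level summary is
  the mean over the largest component's nodes, consistent with the L
  convention. The maximum (diameter) is available via configuration.
* **Small-world quotient** `Q = (C/C_random)/(L/L_random)`, with
  `C_random`, `L_random` the means over **ten** reference graphs, each a
  symmetric matrix of independent uniform weights thresholded at the same
  edge count — i.e. uniform-random E-edge (Erdős–Rényi-style) graphs, not
  degree-preserving rewires. References are reproducible from a per-subject
  substream of the master seed. A uniform-random graph self-normalizes to
  Q ≈ 1; Q ≫ 1 means high clustering at near-random path lengths.

Degenerate regime: at 16 nodes and 10% density (12 edges) a random
reference graph has no triangles with probability ≈ 0.57, so all ten
references can average to `C_random = 0` (≈0.4% of subjects). Q is then
undefined; the subject is skipped with a structured message rather than
assigned an arbitrary value. At the full 128-channel scale this does not
occur.

## Group comparison

Each metric (clustering, path length, eccentricity, Q) is compared between
groups with a normality-gated test at α = 0.05:

* **Gate.** Jarque–Bera on each group, `JB = n/6 (S² + (K−3)²/4)` against
  χ²(2). The χ² reference is asymptotic and anticonservative at n ≈ 13; the
  gate is a screen, not a calibrated test, and a zero-variance group simply
  fails it.
* **Both normal →** unpaired two-sample Student t-test (pooled variance;
  Welch via configuration).
* **Otherwise →** two-sided Wilcoxon rank-sum with an **exact** p-value:
  the null distribution of the rank sum over all group assignments,
  computed by the shift (convolution) algorithm on midranks — identical to
  full enumeration, which is infeasible directly at these sizes. The
  smaller tail is doubled and capped at 1. Beyond combined n = 30 the tie-
  and continuity-corrected normal approximation is used instead; at
  combined n = 20 the two already agree within 0.02. All values tied across
  both groups yields p = 1.
* The simulated type-I error of the whole gated procedure on normal data at
  n = 13/14 stays ≤ 7% at nominal 5% (the t-branch after a passed gate is
  slightly anticonservative).

Outliers are screened per metric and group by classical Chauvenet
(`n · P(|Z| ≥ |z_i|) < 1/2`, z-scores from the sample mean and SD with
ddof = 1) and the 1.5 × IQR fence rule with linearly interpolated
quartiles. Both rules are reported, not applied; a configuration flag can
exclude flagged subjects before testing. No multiple-testing correction is
applied across the four metrics — the comparison report notes this.

## Synthetic cohorts

Real task EEG of this kind is clinical and not redistributable, so every
cohort-level claim is established on synthetic data shaped like the study:
two groups (13 vs 14 subjects), 256 Hz, 1.40 s epochs with 0.2 s
pre-stimulus, 23–87 epochs per subject, 16 channels at test scale
(128-channel generation is a parameter away).

Channels are mixtures of band-limited oscillators plus white channel noise
(sd 1.0). Oscillators are **stimulus-locked**: frequency (centre ± 0.5 Hz)
and base phase are drawn per subject, and each epoch adds 0.5 rad Gaussian
phase jitter, so epoch averaging retains the locked component — the premise
of evoked-response analysis. (Fully random epoch phases would leave each
source a Rayleigh-distributed residual after averaging and scramble the
planted structure.)

Structure: adjacent channel pairs form *local modules*, each with a private
oscillator at mixing weight 0.25; one *integration-core* oscillator is
mixed, at the group's between-module weight, into the channels of the first
three modules. The groups differ only in that weight — default 0.0
(weak-core group) vs 0.6 (strong-core group). A strong core makes its six
channels mutually near-coherent, so the fixed-density threshold selects a
clustered, integrated subgraph; without the core only local dyads and noise
pairs reach the threshold and the graph looks random and fragmented. This
reproduces, by construction, an "integration loss" phenotype: lower
clustering, lower small-world quotient and higher eccentricity in the
weak-core group. Equal weights make the two groups exchangeable — the null
case used for calibration.

What the generator does **not** emulate: volume conduction and electrode
geometry, 1/f background spectra, artefacts (blinks, muscle), non-sinusoidal
or transient oscillations, and epoch rejection. Passing tests therefore
establish the pipeline's internal correctness and its behaviour under a
controlled coupling model — not performance on clinical recordings.

## Numerical and scale choices

* Cohort-level tests and the acceptance script run with 115-sample epochs
  (100 samples after the trim, so 98 embedded columns and 9,506 histogram
  observations per pair) and 16 channels, keeping a full 27-subject cohort
  under a second while preserving every pipeline stage; single-subject
  checks use even smaller toys. Graph-level contracts (edge count, ER
  self-normalization) run at the full V = 128.
* Tiny-graph tests threshold at densities above 10% because the ER
  reference clustering is degenerate (often exactly 0) below ~10 edges.
* Master seeds drive `numpy` `SeedSequence` substreams: one per subject for
  generation, one per subject for reference graphs, so cohorts and metrics
  are bit-reproducible end to end.
* Entropy values are clipped to [0, 1] against last-ulp excursions;
  histogram masses always sum to 1 by construction.

## Known limitations

* The extrema-based distance is a coarse summary at m = 2; it discards
  within-column ordering. The Chebyshev alternative is provided but changes
  values.
* The Jarque–Bera gate at n ≈ 13 has low power, so the t-branch is taken
  often; the gated procedure's type-I error is bounded empirically, not
  analytically.
* Largest-component conventions make L and eccentricity well defined on
  fragmented graphs but mean that badly fragmented subjects are summarized
  by a small subgraph; component size is reported so such subjects are
  visible.
* Fixed-density thresholding guarantees comparable edge counts, not
  comparable topology; parameters whose value is driven mainly by density
  should be interpreted relative to the random reference, as Q is.
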