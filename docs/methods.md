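# Methods

This note documents the models, estimators, parameter choices and
known limitations of the pipeline. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Preprocessing

The canonical order is band-pass filter → epoch + baseline →
variance-based rejection → neighbour interpolation → average
reference, and every step is appended to the recording's provenance
log.

* **Filtering.** Zero-phase FIR band-pass (0.5–45 Hz default). The
  kernel is a symmetric Hamming-window FIR with transition width 25%
  of each cutoff (length ≈ 3.3·fs/Δf taps) applied by centre-aligned
  FFT convolution; a symmetric kernel has a purely real frequency
  response, so a single pass is zero-phase. Phase linearity matters
  because the connectivity stage consumes phase lags.
* **Epoching.** Exactly the first `n_epochs × epoch_length` seconds
  (default 60 × 10 s) are cut; each epoch is baseline-corrected to
  zero mean per channel.
* **Rejection.** The per-channel and per-epoch log-variance is
  z-scored; entries above threshold (default z = 4 for both) are
  removed. The published procedure this emulates was quasi-automated
  with visual confirmation; a fixed threshold is used here because a
  visual step cannot be reproduced. Rejecting more than 50% of
  channels or epochs aborts with a diagnostic. Rejected channels are
  refilled by an inverse-distance-weighted average of their k = 4
  nearest neighbours — a deliberate simplification of spherical-spline
  interpolation, flagged in provenance; downstream metrics depend on
  phase relations among retained channels, for which the neighbour
  average is adequate.
* **EOG control.** Bipolar vertical EOG derivations (default channel
  pairs 25−127 and 8−126 of a 128-channel net) are filtered to 1–3 Hz;
  their SD in non-overlapping 1 s windows, averaged over the two
  derivations and normalized by its own mean, gives an eye-activity
  timecourse whose first-half/second-half means flag progressive sleep
  onset. All-zero derivations yield a zero timecourse flagged
  degenerate rather than a division by zero.

## Spectral power

Welch spectra use 4 s Hamming segments with 50% overlap per epoch,
zero-padded to 0.25 Hz bins, averaged over epochs. Band contributions
divide each channel's power in delta (0–4), theta (4–8), alpha (8–13),
beta (13–30) and gamma (30–40 Hz) by the total over the five bands;
edges are half-open [lo, hi) so abutting bands never share a bin.
Temporal variability recomputes the contributions per epoch (same
Welch settings) and takes the SD across epochs of the channel-averaged
percentages.

## dwPLI connectivity

Per channel, a short-time Fourier decomposition (Hann taper) gives
complex coefficients on a time–frequency grid; the default grid uses a
2 s window, 0.04 s hop and zero-padding to ≈0.49 Hz bins up to 45 Hz.
A coarse grid (2 s window, 0.5 s hop, 1 Hz bins) is provided for
desk-scale runs and is the grid the test suite and acceptance script
use for 91-channel cohorts; the window is kept at 2 s even on the
coarse grid so a source near a band edge cannot bleed its main lobe
into the neighbouring band.

For each pair and TF bin, with I_e the imaginary part of the
cross-spectrum in epoch e, the debiased weighted phase lag index is

    dwPLI = [ (Σ_e I_e)² − Σ_e I_e² ] / [ (Σ_e |I_e|)² − Σ_e I_e² ]

an (approximately unbiased) estimator of the squared weighted PLI. It
is zero in expectation for zero-lag (volume-conducted) coupling and
for independent noise, dimensionless, and invariant to rescaling
either channel. A vanishing denominator (no imaginary cross-spectral
mass at all) is defined as 0 and logged. The estimator requires ≥ 2
epochs.

Band connectivity takes the **peak** dwPLI across all TF bins in the
band (delta, theta, alpha by default; beta/gamma are excluded because
scalp EMG contaminates them in patients, and are available behind a
flag). The maximum over many near-null bins has a positive selection
bias — on the coarse grid with 60 epochs the all-pairs null matrix
peaks around 0.2 per pair — which is identical in both subject groups
and therefore cancels from contrasts; an unbiased mean-over-bins
aggregation is available (`aggregate="mean"`) and is what the
zero-lag robustness checks use.

## Graph metrics

Matrices are proportionally thresholded to retain the strongest
round(density × N(N−1)/2) edges at densities 0.50 … 0.10 in steps of
0.025 (17 graphs, nested edge sets); surviving edges keep their dwPLI
weights. Ties at the cutoff break by channel-pair lexicographic order
for determinism.

* **Clustering**: Onnela geometric-mean-of-triangles weighted form
  with per-graph max-weight normalization (the standard weighted
  generalization in the Brain Connectivity Toolbox). Note this makes C
  sensitive to the graph's peak weight: a few saturated edges lower
  the contribution of every other triangle.
* **Path length / efficiency**: edge length 1/w; L averages shortest
  paths over *connected* pairs only (fragment counts are recorded), E
  averages inverse shortest paths with disconnected pairs contributing
  0, so fragmentation lowers E without infinities.
* **Louvain**: igraph's C implementation, 50 repetitions per graph,
  each with a derived seed and a random node permutation (the greedy
  pass order is what makes runs differ); Q is Newman weighted
  modularity computed on the un-permuted adjacency. Per-repetition
  metrics are averaged — never a single "best" partition. Resolution
  is fixed at 1.
* **Participation SD**: P_i = 1 − Σ_m (k_im/k_i)² with weighted
  degrees (isolated nodes get 0); the SD across nodes indexes how
  unevenly hub-ness is distributed.
* **NMI**: mutual information of two label vectors normalized by the
  arithmetic mean of their entropies; two zero-entropy partitions give
  1 if identical else 0. The subjects × subjects matrix averages NMI
  over matched (density, repetition) pairs.
* **Modular span**: S(M) = (1/n_M) Σ_{(i,j)∈M} w_ij d_ij over retained
  intra-modular edges, d the montage's normalized distances
  (max = 1). Single-node modules are excluded; the largest module is
  chosen by node count, ties by intra-modular weight. The printed
  definition's "scaled by the size of the module" is read as division
  by n_M; the divisor is configurable since other readings (e.g.
  n_M(n_M−1)/2) exist.

All metrics are verified against naive-loop brute-force
implementations on random ≤ 20-node graphs to 1e-10, and all
density-swept metrics are averaged across the 17 densities with equal
weight.

## Group statistics

Welch unequal-variance t-tests with Satterthwaite degrees of freedom;
Holm step-down correction applied within each metric family across the
tested bands (never across metrics). Within-group NMI is compared
using one value per subject — the mean NMI to same-group peers —
rather than all pairwise values, which would pseudo-replicate.
Robust regression is IRLS with Tukey bisquare weights; R² is the
squared Pearson correlation between fitted and observed values and the
slope p-value uses the robust standard error with a normal
approximation (the cited analyses name "robust regression" and "R²"
without further definition; these are the documented choices).
Imagery-subgroup contrasts are reported uncorrected, as single
comparisons.

## Synthetic cohort

The generator plants the two phenotypes the pipeline must separate,
with all coupling expressed through *phase consistency* rather than
amplitude: a regime's κ ∈ [0, 1] jitters each member's phase offset
per epoch with SD (1 − κ)·π/2 radians. This choice matches what dwPLI
measures (it estimates squared wPLI, which saturates quickly with
amplitude SNR) and keeps band power and connectivity independently
controllable.

Control-like subjects (defaults): pink noise (1/f^0.8, 10 µV), an
ambient 10 Hz rhythm on every channel (15 µV, κ = 0.7) whose lag
follows the electrode azimuth around the cap — a travelling wave that
sums to zero across channels and therefore survives average
referencing — three long-range fronto-parietal alpha modules
(16 channels each, κ = 0.85, 30 µV; anterior and posterior halves
π/2 apart with a small within-half gradient), and small focal
frontal slow generators (5 channels, κ = 0.75, 12 µV at 2.5 and
6 Hz) emulating normal frontal-midline delta/theta. The focal
generators also equalize the max-weight normalization of the
clustering coefficient between groups; without them the group whose
planted edges saturate the estimator is systematically penalized.

Patient-like subjects: steeper pink noise (1/f^1.4), a **short-range
synchrony field** at 2.5 and 6 Hz (35/25 µV) — a fixed fast-rotating
lag map plus per-epoch phase jitter with a spatially smooth component
(SD 1.5 rad, correlation length 0.35) and a white component (SD
0.3 rad), so nearby electrodes stay consistently lagged while distant
ones decohere — tiled by compact delta/theta clusters (5×12 and 4×12
channels, κ = 0.5/0.45) whose full-circle balanced lags cancel in the
channel mean, a small spared focal occipital alpha generator
(5 channels, κ = 0.9, 12 µV, common to all patients — it pins every
patient's peak alpha weight so the clustering coefficient's
max-normalization is constant across the κ range), and a residual
long-range alpha system (2×18 channels, 25 µV) whose κ is drawn per
subject from U(0.05, 0.6). The synthetic
CRS-R is round(6.5 + 20·κ_alpha + N(0,1)) clipped to the integer range
7–19; patients scoring ≤ 8 are labelled VS, the rest MCS, and the
imagery flag is drawn with probability 0.15 (0.70 when κ_alpha > 0.33),
mirroring the observation that covert command-followers tend to have
preserved alpha networks. Volume conduction is a row-normalized
Gaussian kernel over normalized distance (σ = 0.05) applied
instantaneously to everything — the zero-lag confound the estimator
must reject (verified: with no planted coupling the mean band dwPLI of
mixed noise stays at the null level).

These defaults were designed, with the recoverability requirements in
view, before the validation suite was frozen; they are study
conditions, not estimates of patient physiology, and are all recorded
in provenance. What the generator does **not** emulate: realistic
head-model forward projection (the mixing kernel is generic), EMG/EOG
artifacts and their stereotyped topographies, non-sinusoidal or
cross-frequency-coupled rhythms, within-epoch phase drift, and any
real electrode layout (the montage is a Fibonacci lattice on a
spherical cap). Passing tests therefore show that the *estimator
chain* recovers planted spectral-network structure under realistic
noise, volume conduction and re-referencing — not that real VS/MCS
EEG behaves like the generator.

## Problem sizes and numerical choices

The validation cohort is 15 + 15 subjects × 91 channels × 60 × 10 s
epochs analysed on the coarse TF grid with the full 17-density sweep
and 50 Louvain repetitions; oracle suites use 100 seeds (coupled
pairs, partition recovery), 2000 draws (test calibration) and 50
random graphs (metric oracles). Reproducibility: every stochastic
stage takes an explicit seed; per-subject, per-band and per-repetition
seeds derive from the master seed via `SeedSequence`, igraph's RNG is
seeded through Python's `random`, and the whole pipeline is
byte-deterministic given (config, seed). Degenerate inputs are defined
rather than erroring where a convention exists (dwPLI 0/0 → 0,
isolated node P = 0, empty graph → trivial partition with Q = 0,
all-zero EOG → flagged zero timecourse).

## Known limitations

Sensor-space only (no source projection); the peak-over-bins
aggregation carries a null-level floor that makes absolute dwPLI
values grid-dependent (contrasts are not); the montage's retained-
channel set is an input, since the 91-of-128 selection used in the
clinical recordings is not published; the EDF writer is minimal
(16-bit, one record/s) and intended for interchange, not archival.
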