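# Methods

This note documents the models, parameters and numerical choices behind
`noisecat`, and what the synthetic-data validation does and does not show.

## Stimulus protocol and analysis windows

All analyses assume the recording protocol encoded in
`noisecat.StimulusProtocol`: four conspecific vocalizations (whistles)
presented in quiet and embedded in two frozen maskers — a vocalization-shaped
stationary noise and a chorus noise — at SNRs of +10, 0 and −10 dB, each
condition repeated 20 times; the two maskers alone; and 129 pure tones
(log-spaced over eight octaves, 0.14–36 kHz, 8 repetitions each) for the
time-frequency response profile (TFRP).

Times are seconds relative to trial start.  Defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `vocalization_durations` | 0.26–0.34 s | individual call durations; only their ~300 ms mean is constrained by the protocol, so four durations averaging 0.300 s were fixed |
| `spontaneous_window_s` | 0.200 s | pre-onset window for spontaneous rate; stimulus onset defaults to 0.200 s so the window exists inside the trial |
| `masker_analysis_period_s` | 0.564 s | masker-alone analysis period |
| `masker_initial_window_s` | 0.200 s | FRm200 window (initial masker rate) |
| `signal_onset_in_masker_s` | 0.200 s | where the signal would have occurred in the masker; start of the FRm300 window (exact placement depends on unpublished stimulus timing, so it is a protocol parameter) |
| `signal_window_in_masker_s` | 0.300 s | FRm300 window width (the mean call duration) |
| `edge_window_s` | 0.050 s | initial/final masker spike-count windows |
| `psth_bin_s` | 0.004 s | EI PSTH bin; 1–32 ms bins give qualitatively similar EIs, 4 ms is canonical |
| `corrcoef_kernel_s` | 0.010 s | Gaussian σ for the reliability index ("10-ms width" is read as σ = 10 ms) |

## Extraction index

`EI = (D_n − D_v)/(D_n + D_v)` with cosine distances between the
noisy-condition PSTH and the masker-alone / clean references, evoked window
only.  The sum in the denominator is the only form consistent with the
stated bound EI ∈ [−1, 1].  Conventions:

* **Per-vocalization aggregation.** EI is computed per vocalization (each
  against its own clean reference and the masker-alone PSTH clipped to that
  vocalization's duration) and averaged over the four calls, skipping
  undefined values.  A concatenated-PSTH alternative was considered and
  rejected: averaging keeps each call's own clean reference and degrades
  gracefully when one call evokes no response.
* **Zero vectors.** If exactly one PSTH is all-zero the cosine distance is 1
  (a silent noisy response is maximally dissimilar from a structured
  reference); if both are zero the distance, and hence the EI, is undefined.
* **Surrogates.** Each replicate replaces every condition's trains with
  homogeneous Poisson trains at that condition's measured evoked rate (same
  trial count and window).  Binned counts of a homogeneous Poisson process
  are independent Poisson draws per bin, so the surrogate PSTHs are sampled
  directly at the bin level — distributionally identical and ~100× faster.
  Thresholds are per (masker, SNR) — surrogate mean + 2 SD — because the
  null EI spread depends on the condition's firing rate.  On structureless
  (flat Poisson) recordings the any-of-six filter fires in ~13 % of cases
  (6 one-sided ~2.3 % comparisons), within its ≤ 20 % calibration bound.

## Response metrics

* **CorrCoef.** Mean Pearson correlation over all unordered trial pairs of
  1-ms-binned, Gaussian-smoothed (σ = 10 ms) spike trains.  The printed
  prefactor 1/(N(N−1)) with a sum over i<j pairs would score 0.5 for
  identical trains; the pairwise mean is used instead so the index spans
  [−1, 1] with identical trains at 1.  Pairs with a zero-variance trace are
  excluded; with no valid pair the index is undefined.
* **Evoked-response significance.** The comparison of per-trial evoked
  vs. spontaneous rates is a two-sided Wilcoxon signed-rank test (sign test
  below 6 nonzero differences): paired, rank-based, deterministic, and
  exact at n = 20.  Null calibration is verified empirically (false-positive
  fraction within the binomial 99 % interval of α over 1000 flat recordings).
* **TFRP.** 1-ms PSTH per frequency over 0–100 ms post-onset, a 50-ms
  pre-onset baseline strip prepended, 5×5 uniform smoothing with
  renormalized partial windows at the edges.  Baseline mean and per-bin SD
  are pooled over the raw (unsmoothed) baseline strip; since a smoothed bin
  averaging n raw bins has sampling SD `sd/√n`, each bin is compared against
  `mean + 6·sd/√n(bin)`.  A single pooled threshold on the smoothed map
  would be dominated by the edge bins (smaller n, heavier Poisson tails) and
  empirically fires on ~30 % of flat maps; the per-bin form keeps the
  false-positive rate ≤ 5 %.  The best frequency is the frequency whose
  0–100 ms evoked rate, smoothed over 5 neighboring frequencies, is highest
  (the per-frequency summed firing rate is far less variable than the
  2-D matrix maximum); bandwidth and response duration are the octave and
  time extents of the largest connected supra-threshold region.

## Categorization

K-means (scikit-learn, Euclidean, 50 restarts, seeded) on 3-value EI
profiles per masker; MSE is `(1/N) Σ‖centroid − profile‖²` and is
cross-checked against brute-force recomputation in the tests.  k = 5 is
canonical; `elbow_curve` provides the k = 1..10 MSE diagnostic.

Cluster naming is a deterministic rule on centroid features m = mean EI and
r = EI(+10 dB) − EI(−10 dB): masker-like = lowest m among all-negative
centroids (lowest m overall if none); balanced = largest r of the remainder
(provided it exceeds the remaining median r); signal-like = highest m;
insensitive = smallest |m|; signal-dominated = the rest; ties break by m
descending then cluster index.  The rule reproduces the canonical centroid
shapes of the five categories and is permutation-invariant.

Bootstrap stability resamples each condition's 20 trials with replacement
independently per condition (the joint-resampling alternative is not
distinguishable from the published procedure; independent resampling is the
more conservative null), recomputes the EI profile, and reallocates it to
the nearest original centroid; replicates with an undefined profile count
against stability.  Reliability requires the modal category in ≥ 95 of 100
replicates.

## Switching and mutual information

The 5×5 switching matrix (rows = stationary-noise category, columns =
chorus-noise category) uses the plug-in Shannon MI in bits with zero cells
contributing zero and no bias correction.  MI is bounded by the marginal
entropies and reaches log₂ 5 ≈ 2.32 bits for a diagonal equal-count matrix.

## Descriptors and classification

Twelve descriptors per masker: TFRP (BF firing rate, bandwidth in octaves,
response duration in ms), signal (firing rate, CorrCoef, averaged over the
four clean calls), masker (firing rate and CorrCoef over the 564-ms period,
FRm300/FRm200 adaptation ratio, spike counts in the first and last 50 ms),
and signal/masker (signal rate over FRm200 and over FRm300).  Ratios with a
zero denominator are flagged and imputed with the column median of defined
values; rows with more than 3 imputed entries are excluded.

The classifier is a linear discriminant (scikit-learn, lsqr solver) with the
shared covariance shrunk by 10⁻⁶ toward its diagonal so collinear
descriptors cannot break the fit.  Descriptors are standardized on each
training fold (never on test data).  The cost matrix — 0 diagonal, 1
off-diagonal, 2 for predicting *insensitive* on a non-insensitive truth —
is applied at the decision stage as minimum expected cost over the
posterior, not by reweighting training.  Cross-validation is stratified
5-fold, seeded; the combination sweep evaluates all 15 nonempty subsets of
the four descriptor groups on identical folds, numbered so that all-groups
is 1, TFRP-only 8, signal-only 12, masker-only 14 and signal/masker-only 15.
Label-shuffled accuracy is calibrated at the five-class chance level of 20 %.

## Synthetic-data generator

The generator's claim is statistical, not biophysical: it produces spike
trains whose PSTH geometry has the structure the analysis assumes.

* **Envelopes.** Clean-call envelopes are sums of 4–8 half-cosine bumps with
  widths 2–10 % of the call duration, normalized to unit mean — sparse,
  event-locked rate profiles like the multiunit PSTHs whistles evoke.  Dense
  low-contrast envelopes were tried first and rejected: with an additive
  baseline they make all PSTHs nearly parallel, so cosine distances shrink
  below the Poisson sampling noise floor and every EI collapses toward 0.
  The stationary masker envelope is near-flat (modulation depth 0.15), the
  chorus envelope call-like with depth 0.75 — deeply modulated, while
  keeping the five planted categories separable at 20 trials.
* **Archetypes.** Per masker, a recording follows one of five archetypes
  whose SNR-indexed weights mix the call envelope and the masker envelope
  (`rate = baseline + gain·(w_sig·e_v + w_mask·e_n)`), with trial-to-trial
  lognormal gain (CV 0.15), Gaussian spike-time jitter (3–10 ms), and
  optional exponential masker adaptation (τ = 160 ms) feeding the FRm
  descriptors.  The default weight tables are tuning knobs, documented in
  `default_archetypes()`, calibrated once so that the strong-separation
  preset has the properties its name promises: every archetype passes the
  surrogate filter (this requires the masker-like archetype to retain a
  modest signal component at +10 dB — a fully signal-free profile has no EI
  significantly *above* its surrogate threshold and would be excluded, so
  its centroid is mildly positive at the best SNR rather than negative at
  all three), and the full pipeline recovers ≥ 90 % of planted categories
  per masker.  The insensitive archetype's weights (0.42/0.58 rather than
  0.5/0.5) compensate for the cosine asymmetry between sparse call envelopes
  and flatter masker envelopes, centering its EI near 0.
* **Tones.** Each recording gets a Gaussian log-frequency tuning bump
  (random center, width 0.6–1.5 octaves) driving a 30-ms onset response.

What passing tests on this generator shows: the pipeline recovers planted
structure of realistic magnitude through every stage, its null calibrations
hold, and all bookkeeping (selection, labeling, bootstrap, switching,
classification) is correct.  What it does not show: performance on real
multiunit data with correlated noise across conditions, non-Poisson firing,
electrode drift, or category structure different from the planted archetypes.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; pipeline sub-seeds are derived
by hashing (global seed, stage, recording id), so adding recordings does not
perturb existing ones and a rerun is bit-identical.  The validation suite
uses cohorts of 10–250 recordings (five seeds of 50 recordings per category
for the recovery check, 200 replicates for false-positive calibrations,
1000 for the significance-test null), sizes at which every calibration
bound is resolvable in minutes on one CPU.
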