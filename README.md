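# noisecat

Noise-robustness categorization of auditory spike-train recordings.

Auditory neurons keep detecting communication sounds in levels of background
noise that would swamp any simple energy detector, and different neurons
solve the problem differently: some track the vocalization, some track the
noise, some flip between the two as the signal-to-noise ratio (SNR) changes.
`noisecat` implements, as a tested and reusable Python library, the analysis
chain used to characterize these behaviors in multiunit recordings from the
auditory pathway (cochlear nucleus to secondary cortex) when conspecific
vocalizations are masked by a vocalization-shaped stationary noise or a
naturalistic chorus noise at +10, 0 and −10 dB SNR:

1. **Extraction index (EI).** For each masker type and SNR, the 4-ms-bin
   PSTH of the noisy response `P_snr` is compared with the clean-vocalization
   PSTH `P_v` and the masker-alone PSTH `P_n` through normalized-inner-product
   distances `D(p, q) = 1 − p·q / (‖p‖‖q‖)`:

   `EI = (D_{n,snr} − D_{v,snr}) / (D_{n,snr} + D_{v,snr})  ∈ [−1, 1]`

   +1 means the noisy response is indistinguishable from the clean one,
   −1 that it tracks the masker.
2. **Surrogate selection.** Per recording, 100 rate-matched homogeneous
   Poisson surrogates give an EI null distribution; recordings need at least
   one of their six EI values above the surrogate mean + 2 SD.
3. **Five-category K-means.** 3-value EI profiles (one per SNR) are
   clustered per masker (k = 5, Euclidean); centroids are deterministically
   named signal-like, signal-dominated, balanced, insensitive, masker-like.
4. **Bootstrap stability.** Trials are resampled with replacement 100 times;
   a recording is *reliable* if ≥ 95 replicates land in the same category.
5. **Noise-type switching.** Per-masker categories populate a 5×5 switching
   matrix whose Shannon mutual information (plug-in, bits) quantifies how
   predictive one masker's category is of the other's (0 = independent,
   log₂5 ≈ 2.32 = perfectly preserved).
6. **Category prediction.** A cost-weighted linear discriminant (cost 2 for
   calling a non-insensitive recording insensitive) predicts the category
   from 12 descriptors in four groups — pure-tone TFRP, signal alone, masker
   alone, signal/masker ratios — over all 15 group combinations with
   stratified 5-fold cross-validation.

Because the original neural recordings are not publicly deposited, the
package ships a first-class synthetic spike-train generator
(`noisecat.synth`) that emulates the recording protocol (4 vocalizations ×
20 trials, 2 maskers × 3 SNRs, 129 pure tones × 8 trials) with planted
per-masker categories, so every stage can be validated against ground truth.

## Worked example

```python
import noisecat as nc

dataset = nc.make_dataset(nc.strong_separation_config(2, seed=1,
                                                      include_tones=False))
protocol = dataset.protocol
rec = dataset.recordings[0]
profile = nc.ei_profile(rec, protocol)
profile.surrogate_threshold = nc.surrogate_thresholds(rec, protocol,
                                                      n_surrogates=100, seed=7)
print(profile.ei[("stationary", 10.0)], profile.any_significant)
```

Running `python examples/02_extraction_index.py` (which does the above for
six recordings) prints:

```
rec0001 (signal-like      ) stationary: +10dB=+0.73 +0dB=+0.69 -10dB=+0.64 significant=True
rec0003 (signal-dominated ) stationary: +10dB=+0.57 +0dB=+0.38 -10dB=+0.22 significant=True
rec0005 (balanced         ) stationary: +10dB=+0.68 +0dB=+0.31 -10dB=-0.31 significant=True
```

A planted signal-like recording keeps EI ≈ +0.7 at every SNR (its noisy
responses stay vocalization-like), the signal-dominated one is an attenuated
version of that, and the balanced one sweeps from +0.68 at +10 dB to −0.31
at −10 dB — its representation flips from signal to masker as the noise
level rises.  `significant=True` means at least one EI exceeds the Poisson
surrogate threshold, so the recording would survive selection.

The remaining examples cover simulation (`01`), clustering and bootstrap
stability (`03`), switching matrices and mutual information (`04`), and the
descriptor-based classifier sweep (`05`).  A thin CLI wraps the same
pipeline: `noisecat simulate --out data/ --seed 1` then
`noisecat run-all --in data/ --out results/ --seed 1`.

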