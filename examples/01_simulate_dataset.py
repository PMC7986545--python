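"""Generate a synthetic recording cohort with planted response categories.

Builds ten multiunit recordings per category (signal-like, signal-dominated,
balanced, insensitive, masker-like), writes them as plain-text spike tables,
and prints the planted ground truth.
"""

import noisecat as nc

config = nc.strong_separation_config(n_per_category=10, seed=0,
                                     include_tones=True)
dataset = nc.make_dataset(config)
nc.write_spike_events(dataset, "scratch/example_data")

print(f"{len(dataset)} recordings written to scratch/example_data")
for rec in dataset.recordings[::10]:
    n_spikes = sum(t.n_spikes for b in rec.blocks.values() for t in b.trains)
    print(f"  {rec.recording_id} ({rec.structure}): "
          f"planted {rec.planted_category_by_noise['stationary']} / "
          f"{rec.planted_category_by_noise['chorus']}, {n_spikes} spikes")
# Each recording holds 20 trials for every vocalization condition (clean,
# 2 maskers x 3 SNRs) plus masker-alone and 129 x 8 pure-tone trials.
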