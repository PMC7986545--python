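"""PSTHs, firing rates, response significance, reliability, and TFRPs.

These are the per-condition response quantifications every later stage is
built on: the 4-ms-bin repetition-averaged PSTH feeding the extraction index,
the evoked/spontaneous firing rates and their paired significance test, the
trial-to-trial temporal reliability (CorrCoef), and the time-frequency
response profile (TFRP) with its best frequency, tuning bandwidth and
response duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

from .dataset import TrialBlock
from .protocol import StimulusProtocol

__all__ = [
    "PSTH", "ReliabilityResult", "TFRPResult",
    "compute_psth", "evoked_rate", "spontaneous_rate", "per_trial_rates",
    "response_significant", "corrcoef", "compute_tfrp",
]


@dataclass
class PSTH:
    """Repetition-averaged binned response (spikes/s per bin)."""

    values: np.ndarray
    bin_s: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("PSTH values must be nonnegative")

    @property
    def n_bins(self) -> int:
        return len(self.values)


@dataclass
class ReliabilityResult:
    corrcoef: float          # NaN when undefined
    n_trials: int
    kernel_s: float

    @property
    def defined(self) -> bool:
        return not np.isnan(self.corrcoef)


@dataclass
class TFRPResult:
    """Smoothed 100 x 129 time-frequency firing-rate map and its summary."""

    matrix: np.ndarray               # time (100 rows, 1 ms) x frequency (129)
    bf_hz: float
    bf_firing_rate_hz: float
    significant: bool
    bandwidth_octaves: float
    response_duration_ms: float
    baseline_mean: float
    baseline_sd: float


def _bin_counts(block: TrialBlock, bin_s: float,
                window: tuple[float, float]) -> np.ndarray:
    """Total spike counts per bin, pooled across trials."""
    start, end = window
    n_bins = int(np.floor((end - start) / bin_s + 1e-9))
    edges = start + np.arange(n_bins + 1) * bin_s
    spikes = np.concatenate([tr.spike_times for tr in block.trains])
    counts, _ = np.histogram(spikes, bins=edges)
    return counts.astype(float)


def compute_psth(block: TrialBlock, bin_s: float,
                 window: tuple[float, float] | None = None) -> PSTH:
    """PSTH in spikes/s: pooled bin counts / (n_trials * bin_s).

    ``window`` defaults to the block's evoked window [onset, offset]; it must
    lie within the trial bounds.
    """
    if window is None:
        window = (block.onset_s, block.offset_s)
    t0, t1 = block.trial_window
    if window[0] < t0 - 1e-9 or window[1] > t1 + 1e-9:
        raise ValueError(f"PSTH window {window} outside trial bounds {(t0, t1)}")
    counts = _bin_counts(block, bin_s, window)
    return PSTH(counts / (block.n_trials * bin_s), bin_s, window)


def per_trial_rates(block: TrialBlock, start: float, end: float) -> np.ndarray:
    """Firing rate (spikes/s) of each trial over [start, end)."""
    dur = end - start
    if dur <= 0:
        raise ValueError("window must have positive duration")
    return np.array([tr.count_in(start, end) / dur for tr in block.trains])


def evoked_rate(block: TrialBlock) -> float:
    """Trial-averaged firing rate over the evoked window [onset, offset]."""
    return float(per_trial_rates(block, block.onset_s, block.offset_s).mean())


def spontaneous_rate(block: TrialBlock,
                     window_s: float = 0.200) -> float:
    """Trial-averaged rate over the ``window_s`` seconds preceding onset."""
    start = block.onset_s - window_s
    if start < block.trial_window[0] - 1e-9:
        raise ValueError(
            f"no spontaneous window: onset {block.onset_s} is less than "
            f"{window_s} s into the trial")
    return float(per_trial_rates(block, start, block.onset_s).mean())


def response_significant(block: TrialBlock, alpha: float = 0.05,
                         spontaneous_window_s: float = 0.200
                         ) -> tuple[bool, float]:
    """Paired two-sided test of per-trial evoked vs. spontaneous rates.

    Wilcoxon signed-rank on the per-trial rate differences; with fewer than 6
    nonzero differences (where the rank test degenerates) a two-sided sign
    test is used instead.  All-zero differences give p = 1.
    """
    if block.n_trials < 2:
        raise ValueError("significance test requires >= 2 trials")
    ev = per_trial_rates(block, block.onset_s, block.offset_s)
    start = block.onset_s - spontaneous_window_s
    if start < block.trial_window[0] - 1e-9:
        raise ValueError("no spontaneous window before onset")
    sp = per_trial_rates(block, start, block.onset_s)
    diffs = ev - sp
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return False, 1.0
    if nonzero.size < 6:
        k = int((nonzero > 0).sum())
        p = float(stats.binomtest(k, nonzero.size, 0.5).pvalue)
    else:
        p = float(stats.wilcoxon(diffs, zero_method="wilcox",
                                 alternative="two-sided").pvalue)
    return p < alpha, p


def corrcoef(block: TrialBlock, kernel_s: float = 0.010,
             window: tuple[float, float] | None = None) -> ReliabilityResult:
    """Trial-to-trial temporal reliability (CorrCoef).

    Each train is binned at 1 ms over the evoked window and convolved with a
    Gaussian kernel of SD ``kernel_s``; CorrCoef is the mean over all
    unordered trial pairs of the Pearson correlation between the smoothed
    traces.  Pairs in which either trace has zero variance are excluded; with
    no valid pair the result is undefined (NaN).
    """
    if block.n_trials < 2:
        raise ValueError("CorrCoef requires >= 2 trials")
    if window is None:
        window = (block.onset_s, block.offset_s)
    start, end = window
    n_bins = int(np.floor((end - start) / 0.001 + 1e-9))
    edges = start + np.arange(n_bins + 1) * 0.001
    traces = np.stack([
        np.histogram(tr.spike_times, bins=edges)[0].astype(float)
        for tr in block.trains
    ])
    traces = ndimage.gaussian_filter1d(traces, sigma=kernel_s / 0.001, axis=1,
                                       mode="constant")
    sd = traces.std(axis=1)
    valid = sd > 0
    if valid.sum() < 2:
        return ReliabilityResult(float("nan"), block.n_trials, kernel_s)
    sub = traces[valid]
    corr = np.corrcoef(sub)
    iu = np.triu_indices(len(sub), k=1)
    return ReliabilityResult(float(corr[iu].mean()), block.n_trials, kernel_s)


def compute_tfrp(tone_blocks: dict[str, TrialBlock],
                 protocol: StimulusProtocol,
                 baseline_window_s: float = 0.050,
                 n_sd: float = 6.0) -> TFRPResult:
    """Time-frequency response profile from the 129-tone block.

    For each frequency a 1-ms-bin PSTH is computed from tone onset to 100 ms;
    stacking them gives a 100 x 129 firing-rate matrix.  A pre-onset baseline
    strip is prepended, the extended matrix is smoothed with a uniform 5 x 5
    window (renormalized at the edges so smoothed values remain true local
    means), and baseline mean and per-bin SD are pooled over all frequencies
    of the raw baseline strip.  A smoothed bin that averages n raw bins has
    sampling SD ``baseline_sd / sqrt(n)``, so the peak contour compares each
    smoothed bin against ``baseline_mean + n_sd * baseline_sd / sqrt(n)``;
    the response is significant when any bin exceeds its threshold.  The best
    frequency (BF) is the frequency whose evoked firing rate (0-100 ms spike
    count), smoothed over 5 neighboring frequencies, is highest; the
    bandwidth is the octave span of the largest significant region and the
    response duration its time extent in ms.
    """
    n_freq = len(protocol.tone_frequencies)
    missing = [protocol.tone_condition(i) for i in range(n_freq)
               if protocol.tone_condition(i) not in tone_blocks]
    if missing:
        raise ValueError(f"missing tone conditions: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    n_base = int(round(baseline_window_s / 0.001))
    cols = []
    freq_rate = np.empty(n_freq)
    for i in range(n_freq):
        block = tone_blocks[protocol.tone_condition(i)]
        window = (block.onset_s - baseline_window_s, block.onset_s + 0.100)
        counts = _bin_counts(block, 0.001, window)
        cols.append(counts / (block.n_trials * 0.001))
        freq_rate[i] = counts[n_base:].sum() / (block.n_trials * 0.100)
    ext = np.stack(cols, axis=1)            # (n_base + 100) x 129
    kernel = np.ones((5, 5))
    n_eff = signal.convolve2d(np.ones_like(ext), kernel, mode="same")
    smoothed = signal.convolve2d(ext, kernel, mode="same") / n_eff
    base_mean = float(ext[:n_base, :].mean())
    base_sd = float(ext[:n_base, :].std())
    resp = smoothed[n_base:, :]             # 100 x 129
    above = resp > base_mean + n_sd * base_sd / np.sqrt(n_eff[n_base:, :])
    significant = bool(above.any())
    freqs = np.asarray(protocol.tone_frequencies)
    prof = (np.convolve(freq_rate, np.ones(5), mode="same") /
            np.convolve(np.ones(n_freq), np.ones(5), mode="same"))
    bf_index = int(np.argmax(prof))
    bandwidth = 0.0
    duration = 0.0
    if significant:
        labels, n_lab = ndimage.label(above)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n_lab + 1))
        biggest = int(np.argmax(sizes)) + 1
        tt, ff = np.nonzero(labels == biggest)
        bandwidth = float(np.log2(freqs[ff.max()] / freqs[ff.min()]))
        duration = float(tt.max() - tt.min() + 1)
    return TFRPResult(resp, float(freqs[bf_index]), float(prof[bf_index]),
                      significant, bandwidth, duration, base_mean, base_sd)
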