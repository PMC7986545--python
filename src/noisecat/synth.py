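"""Synthetic spike-train generator with planted noise-robustness categories.

The generator emulates the statistical structure the downstream analysis
assumes: every recording belongs, per masker type, to one of five archetypes
(signal-like, signal-dominated, balanced, insensitive, masker-like) whose
mixing weights control how vocalization-like or masker-like the response to a
noisy vocalization is at each SNR.

Rates are piecewise-constant on a 1-ms grid.  For a recording with clean-voc
envelope ``e_v`` and masker envelope ``e_n`` (both in [0, 1], fixed per
recording), the firing-rate templates are

* clean vocalization:   ``baseline + gain * e_v(t)``
* masker alone:         ``baseline + gain * e_n(t) * adapt(t)``
* noisy vocalization:   ``baseline + gain * (w_sig(snr)*e_v(t) + w_mask(snr)*e_n(t))``

where ``adapt(t)`` is an optional exponential firing-rate adaptation during
the masker (the substrate of the FRm300/FRm200 descriptors) and the weights
``w_sig``, ``w_mask`` are the archetype's signature.  Trials are drawn as
inhomogeneous Poisson processes with a lognormal per-trial gain (unit mean,
configurable CV) and Gaussian spike-time jitter that controls the
trial-to-trial temporal reliability.

Vocalization envelopes are sums of 4-8 random half-cosine bumps, mimicking
whistle amplitude envelopes.  The two masker types differ by envelope
modulation depth: the vocalization-shaped stationary noise is near-flat, the
chorus noise (a superposition of conspecific calls) is deeply modulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .dataset import CATEGORIES, Dataset, Recording, SpikeTrain, TrialBlock
from .protocol import StimulusProtocol

DT = 0.001  # rate-template grid (s)

#: Post-stimulus tail kept in every trial (s).
TRIAL_TAIL_S = 0.05

#: Duration of the onset response to a pure tone (s).
TONE_RESPONSE_S = 0.030


@dataclass
class RateTemplate:
    """Piecewise-constant firing rate over one trial."""

    rates_hz: np.ndarray          # one value per DT bin
    trial_window: tuple[float, float]
    onset_s: float
    offset_s: float

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        idx = np.clip(((np.asarray(t) - self.trial_window[0]) / DT).astype(int),
                      0, len(self.rates_hz) - 1)
        return self.rates_hz[idx]


@dataclass
class CategoryArchetype:
    """Generative parameters of one noise-robustness category.

    ``signal_weight_by_snr`` / ``masker_weight_by_snr`` are indexed like the
    protocol's SNR levels (best SNR first).  ``masker_adaptation`` is the
    fractional firing-rate decline over the masker (0 = none) with time
    constant ``adaptation_tau_s``.
    """

    name: str
    signal_weight_by_snr: Sequence[float]
    masker_weight_by_snr: Sequence[float]
    baseline_rate_hz: float = 2.0
    response_gain_hz: float = 40.0
    trial_gain_cv: float = 0.15
    jitter_sd_s: float = 0.004
    masker_adaptation: float = 0.0
    adaptation_tau_s: float = 0.160

    def __post_init__(self) -> None:
        self.signal_weight_by_snr = tuple(float(w) for w in self.signal_weight_by_snr)
        self.masker_weight_by_snr = tuple(float(w) for w in self.masker_weight_by_snr)
        for w in (*self.signal_weight_by_snr, *self.masker_weight_by_snr):
            if not 0.0 <= w <= 1.0:
                raise ValueError("archetype weights must lie in [0, 1]")
        if self.baseline_rate_hz < 0 or self.response_gain_hz < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.masker_adaptation <= 1.0:
            raise ValueError("masker_adaptation must lie in [0, 1]")


def default_archetypes() -> dict[str, CategoryArchetype]:
    """The five category archetypes with their default mixing weights.

    The weights are the generative inverse of the mean EI profiles the five
    categories display: signal-like responses stay vocalization-dominated at
    every SNR, balanced responses sweep from signal- to masker-dominated as
    the SNR drops, and masker-like responses track the noise throughout.
    """
    return {
        "signal-like": CategoryArchetype(
            "signal-like", (1.0, 0.95, 0.80), (0.05, 0.10, 0.25),
            response_gain_hz=50.0, jitter_sd_s=0.003, masker_adaptation=0.6),
        "signal-dominated": CategoryArchetype(
            "signal-dominated", (0.66, 0.48, 0.28), (0.20, 0.32, 0.46),
            response_gain_hz=35.0, jitter_sd_s=0.005, masker_adaptation=0.5),
        "balanced": CategoryArchetype(
            "balanced", (1.0, 0.50, 0.05), (0.05, 0.50, 1.0),
            response_gain_hz=45.0, jitter_sd_s=0.004, masker_adaptation=0.2),
        "insensitive": CategoryArchetype(
            "insensitive", (0.42, 0.42, 0.42), (0.58, 0.58, 0.58),
            response_gain_hz=24.0, jitter_sd_s=0.008, masker_adaptation=0.1),
        "masker-like": CategoryArchetype(
            "masker-like", (0.45, 0.15, 0.0), (0.55, 0.85, 1.0),
            response_gain_hz=40.0, jitter_sd_s=0.005, masker_adaptation=0.0),
    }


@dataclass
class RecordingSpec:
    """How many recordings to generate for one structure/category cell."""

    structure: str
    category_stationary: str
    category_chorus: str
    n: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("count must be nonnegative")
        for cat in (self.category_stationary, self.category_chorus):
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")


@dataclass
class GeneratorConfig:
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    specs: list[RecordingSpec] = field(default_factory=list)
    archetypes: dict[str, CategoryArchetype] = field(default_factory=default_archetypes)
    include_tones: bool = True
    seed: int = 0


# ---------------------------------------------------------------------------
# Envelopes
# ---------------------------------------------------------------------------

def _unit_mean(env: np.ndarray) -> np.ndarray:
    m = env.mean()
    return env / m if m > 0 else env


def vocalization_envelope(duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Sum of 4-8 random half-cosine bumps, normalized to unit mean.

    Bumps are narrow (2-10% of the call duration), mimicking the sparse,
    event-locked PSTHs that whistle envelopes evoke in multiunit activity;
    unit-mean normalization makes the archetype gain the mean evoked rate
    and keeps equal mixing weights geometrically symmetric.
    """
    n_bins = int(round(duration_s / DT))
    t = (np.arange(n_bins) + 0.5) * DT
    env = np.zeros(n_bins)
    for _ in range(rng.integers(4, 9)):
        center = rng.uniform(0.05, 0.95) * duration_s
        width = rng.uniform(0.02, 0.10) * duration_s
        amp = rng.uniform(0.3, 1.0)
        x = (t - center) / width
        mask = np.abs(x) < 1
        env[mask] += amp * 0.5 * (1 + np.cos(np.pi * x[mask]))
    return _unit_mean(env)


def masker_envelope(duration_s: float, noise_type: str,
                    rng: np.random.Generator) -> np.ndarray:
    """Masker envelope (unit mean): near-flat for the vocalization-shaped
    stationary noise, deeply modulated for the call-like chorus noise."""
    depth = 0.15 if noise_type == "stationary" else 0.75
    bumpy = vocalization_envelope(duration_s, rng)
    flat = np.ones(int(round(duration_s / DT)))
    return _unit_mean((1 - depth) * flat + depth * bumpy)


# ---------------------------------------------------------------------------
# Rate templates
# ---------------------------------------------------------------------------

def _template(window_end: float, onset: float, offset: float,
              baseline: float) -> RateTemplate:
    n = int(round(window_end / DT))
    return RateTemplate(np.full(n, float(baseline)), (0.0, n * DT), onset, offset)


def clean_voc_template(envelope: np.ndarray, archetype: CategoryArchetype,
                       protocol: StimulusProtocol) -> RateTemplate:
    onset = protocol.spontaneous_window_s
    dur = len(envelope) * DT
    tpl = _template(onset + dur + TRIAL_TAIL_S, onset, onset + dur,
                    archetype.baseline_rate_hz)
    i0 = int(round(onset / DT))
    tpl.rates_hz[i0:i0 + len(envelope)] += archetype.response_gain_hz * envelope
    return tpl


def noise_alone_template(envelope: np.ndarray, archetype: CategoryArchetype,
                         protocol: StimulusProtocol) -> RateTemplate:
    onset = protocol.spontaneous_window_s
    dur = len(envelope) * DT
    tpl = _template(onset + dur + TRIAL_TAIL_S, onset, onset + dur,
                    archetype.baseline_rate_hz)
    t = (np.arange(len(envelope)) + 0.5) * DT
    adapt = 1.0 - archetype.masker_adaptation * (
        1.0 - np.exp(-t / archetype.adaptation_tau_s))
    i0 = int(round(onset / DT))
    tpl.rates_hz[i0:i0 + len(envelope)] += (
        archetype.response_gain_hz * envelope * adapt)
    return tpl


def noisy_voc_template(voc_envelope: np.ndarray, noise_envelope: np.ndarray,
                       snr_index: int, archetype: CategoryArchetype,
                       protocol: StimulusProtocol) -> RateTemplate:
    onset = protocol.spontaneous_window_s
    dur = len(voc_envelope) * DT
    tpl = _template(onset + dur + TRIAL_TAIL_S, onset, onset + dur,
                    archetype.baseline_rate_hz)
    w_sig = archetype.signal_weight_by_snr[snr_index]
    w_mask = archetype.masker_weight_by_snr[snr_index]
    e_n = noise_envelope[:len(voc_envelope)]
    if len(e_n) < len(voc_envelope):  # masker shorter than call: pad with last value
        e_n = np.pad(e_n, (0, len(voc_envelope) - len(e_n)), mode="edge")
    i0 = int(round(onset / DT))
    tpl.rates_hz[i0:i0 + len(voc_envelope)] += archetype.response_gain_hz * (
        w_sig * voc_envelope + w_mask * e_n)
    return tpl


def tone_template(freq_hz: float, tuning_center_hz: float,
                  tuning_width_oct: float, tone_gain_hz: float,
                  baseline_rate_hz: float) -> RateTemplate:
    """Onset response to a pure tone under a Gaussian log-frequency tuning bump."""
    onset = 0.050
    tpl = _template(onset + 0.100, onset, onset + 0.100, baseline_rate_hz)
    gain = tone_gain_hz * np.exp(
        -0.5 * (np.log2(freq_hz / tuning_center_hz) / tuning_width_oct) ** 2)
    i0 = int(round(onset / DT))
    i1 = i0 + int(round(TONE_RESPONSE_S / DT))
    tpl.rates_hz[i0:i1] += gain
    return tpl


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_trials(template: RateTemplate, n_trials: int, trial_gain_cv: float,
                  jitter_sd_s: float, rng: np.random.Generator,
                  condition_id: str = "block") -> TrialBlock:
    """Draw a trial block of inhomogeneous Poisson spike trains.

    Each trial i is a Poisson draw from ``gain_i * rate(t)`` with ``gain_i``
    lognormal (unit mean, CV ``trial_gain_cv``); spikes are then jittered by
    centered Gaussian noise of SD ``jitter_sd_s`` and clipped to the trial
    window.  Deterministic given the generator state.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    t0, t1 = template.trial_window
    lam = template.rates_hz * DT
    if trial_gain_cv > 0:
        sigma2 = np.log1p(trial_gain_cv ** 2)
        gains = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), n_trials)
    else:
        gains = np.ones(n_trials)
    counts = rng.poisson(gains[:, None] * lam[None, :])
    per_trial = counts.sum(axis=1)
    flat = counts.ravel()
    idx = np.repeat(np.arange(flat.size), flat)
    bins = idx % len(lam)
    times = t0 + (bins + rng.random(idx.size)) * DT
    if jitter_sd_s > 0:
        times = times + rng.normal(0.0, jitter_sd_s, idx.size)
    times = np.clip(times, t0, t1)
    trains = []
    start = 0
    for n in per_trial:
        trains.append(SpikeTrain(np.sort(times[start:start + n]), (t0, t1)))
        start += n
    return TrialBlock(condition_id, trains, template.onset_s, template.offset_s)


# ---------------------------------------------------------------------------
# Recording / dataset assembly
# ---------------------------------------------------------------------------

def recording_templates(archetype_by_noise: dict[str, CategoryArchetype],
                        protocol: StimulusProtocol,
                        rng: np.random.Generator,
                        include_tones: bool = True) -> dict[str, RateTemplate]:
    """Noise-free rate templates for every condition of one recording.

    Recording-wide response parameters (baseline, gain, jitter) are taken from
    the archetype of the first noise type; the per-noise archetypes supply the
    mixing weights and masker adaptation, so a recording can belong to
    different categories under the two maskers.
    """
    base = archetype_by_noise[protocol.noise_types[0]]
    voc_envs = {v: vocalization_envelope(protocol.voc_duration(v), rng)
                for v in protocol.vocalization_ids}
    noise_envs = {nt: masker_envelope(protocol.masker_analysis_period_s, nt, rng)
                  for nt in protocol.noise_types}
    templates: dict[str, RateTemplate] = {}
    for v in protocol.vocalization_ids:
        templates[protocol.clean_condition(v)] = clean_voc_template(
            voc_envs[v], base, protocol)
    for nt in protocol.noise_types:
        arch = replace(archetype_by_noise[nt],
                       baseline_rate_hz=base.baseline_rate_hz,
                       response_gain_hz=base.response_gain_hz)
        templates[protocol.noise_condition(nt)] = noise_alone_template(
            noise_envs[nt], arch, protocol)
        for v in protocol.vocalization_ids:
            for si, snr in enumerate(protocol.snr_levels_db):
                templates[protocol.noisy_condition(v, nt, snr)] = (
                    noisy_voc_template(voc_envs[v], noise_envs[nt], si, arch,
                                       protocol))
    if include_tones:
        freqs = np.asarray(protocol.tone_frequencies)
        center = float(np.exp(rng.uniform(np.log(freqs[30]), np.log(freqs[98]))))
        width = rng.uniform(0.6, 1.5)
        gain = rng.uniform(1.0, 1.5) * base.response_gain_hz
        for i, f in enumerate(freqs):
            templates[protocol.tone_condition(i)] = tone_template(
                f, center, width, gain, base.baseline_rate_hz)
    return templates


def make_recording(recording_id: str, structure: str,
                   archetype_by_noise: dict[str, CategoryArchetype],
                   protocol: StimulusProtocol, rng: np.random.Generator,
                   include_tones: bool = True) -> Recording:
    templates = recording_templates(archetype_by_noise, protocol, rng,
                                    include_tones)
    base = archetype_by_noise[protocol.noise_types[0]]
    blocks = {}
    for cid, tpl in templates.items():
        n = (protocol.n_trials_tone if cid.startswith("tone_")
             else protocol.n_trials_voc)
        blocks[cid] = sample_trials(tpl, n, base.trial_gain_cv,
                                    base.jitter_sd_s, rng, cid)
    planted = {nt: archetype_by_noise[nt].name for nt in protocol.noise_types}
    return Recording(recording_id, structure, blocks, planted)


def make_dataset(config: GeneratorConfig) -> Dataset:
    """Generate a dataset with planted per-noise categories.

    Deterministic given the config (including its seed): recording i always
    uses the generator seeded with ``[config.seed, i]``.
    """
    protocol = config.protocol
    recordings = []
    i = 0
    for spec in config.specs:
        for _ in range(spec.n):
            rng = np.random.default_rng([config.seed, i])
            arch = {"stationary": config.archetypes[spec.category_stationary],
                    "chorus": config.archetypes[spec.category_chorus]}
            by_noise = {nt: arch[nt] for nt in protocol.noise_types}
            recordings.append(make_recording(
                f"rec{i + 1:04d}", spec.structure, by_noise, protocol, rng,
                config.include_tones))
            i += 1
    ds = Dataset(protocol, recordings)
    ds.validate()
    return ds


def strong_separation_config(n_per_category: int, seed: int = 0,
                             include_tones: bool = True,
                             protocol: StimulusProtocol | None = None,
                             structure: str = "CNIC") -> GeneratorConfig:
    """Preset with the same well-separated category under both maskers."""
    return GeneratorConfig(
        protocol=protocol or StimulusProtocol(),
        specs=[RecordingSpec(structure, cat, cat, n_per_category)
               for cat in CATEGORIES],
        include_tones=include_tones,
        seed=seed,
    )


def switching_config(n_stay: int, n_switch: int, seed: int = 0,
                     include_tones: bool = False,
                     protocol: StimulusProtocol | None = None,
                     structure: str = "CNIC") -> GeneratorConfig:
    """Preset with a controlled fraction of noise-type switchers.

    Stayers keep their category in both maskers; switchers move to the next
    category (cyclically) in chorus noise.
    """
    specs = []
    cats = list(CATEGORIES)
    for ci, cat in enumerate(cats):
        specs.append(RecordingSpec(structure, cat, cat, n_stay))
        specs.append(RecordingSpec(structure, cat, cats[(ci + 1) % 5], n_switch))
    return GeneratorConfig(protocol=protocol or StimulusProtocol(), specs=specs,
                           include_tones=include_tones, seed=seed)
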