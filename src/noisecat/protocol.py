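"""Stimulus protocol: the experimental design all analyses assume.

The protocol describes a recording session in which four conspecific
vocalizations (whistles) are presented in quiet and embedded in two frozen
masking noises (a vocalization-shaped stationary noise and a naturalistic
chorus noise) at three signal-to-noise ratios (+10, 0, -10 dB), plus the two
maskers alone and a block of 129 pure tones used to map the time-frequency
response profile (TFRP).

All times are in seconds, relative to trial start (trial start = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

#: Canonical masker labels, in matrix order (rows of the switching matrix).
NOISE_TYPES = ("stationary", "chorus")

_NOISE_ABBREV = {"stationary": "stat", "chorus": "chor"}
_NOISE_FROM_ABBREV = {v: k for k, v in _NOISE_ABBREV.items()}


def snr_label(snr_db: float) -> str:
    """Condition-id token for an SNR level: +10 -> 'p10', 0 -> '0', -10 -> 'm10'."""
    i = int(round(snr_db))
    if i > 0:
        return f"p{i}"
    if i < 0:
        return f"m{-i}"
    return "0"


def _snr_from_label(tok: str) -> float:
    if tok.startswith("p"):
        return float(tok[1:])
    if tok.startswith("m"):
        return -float(tok[1:])
    return float(tok)


def default_tone_frequencies(n: int = 129, f_lo: float = 140.0, f_hi: float = 36_000.0) -> list[float]:
    """Log-spaced pure-tone frequencies covering eight octaves (0.14-36 kHz)."""
    return [float(f) for f in np.geomspace(f_lo, f_hi, n)]


@dataclass
class StimulusProtocol:
    """Parameters of the stimulation protocol and of the analysis windows.

    Attributes
    ----------
    vocalization_ids:
        Identifiers of the four whistles, e.g. ``["voc1", ..., "voc4"]``.
    vocalization_durations:
        Duration of each vocalization in seconds.  The paper's calls average
        300 ms; defaults spread around that mean.
    noise_types:
        The two masker labels, ``("stationary", "chorus")``.
    snr_levels_db:
        The three SNRs in strictly decreasing order, ``(+10, 0, -10)``.
    n_trials_voc:
        Repetitions per vocalization (and per masker-alone) condition; 20.
    tone_frequencies:
        129 strictly increasing tone frequencies (Hz) over eight octaves.
    n_trials_tone:
        Repetitions per tone frequency; 8.
    spontaneous_window_s:
        Pre-onset window used for spontaneous rate (0.200 s); also the default
        stimulus onset so the window exists inside the trial.
    masker_analysis_period_s:
        Analysis period of the masker-alone response (0.564 s).
    masker_initial_window_s:
        Initial masker window for FRm200 (0.200 s).
    signal_onset_in_masker_s:
        Time, from masker onset, at which the signal would have occurred;
        start of the FRm300 window.
    signal_window_in_masker_s:
        Width of the FRm300 window (0.300 s, the mean vocalization duration).
    edge_window_s:
        Width of the initial/final spike-count windows of the masker (0.050 s).
    psth_bin_s:
        PSTH bin width for the extraction index (0.004 s).
    corrcoef_kernel_s:
        Gaussian-kernel sigma for the trial-to-trial reliability (0.010 s).
    """

    vocalization_ids: Sequence[str] = ("voc1", "voc2", "voc3", "voc4")
    vocalization_durations: Sequence[float] = (0.26, 0.29, 0.31, 0.34)
    noise_types: Sequence[str] = NOISE_TYPES
    snr_levels_db: Sequence[float] = (10.0, 0.0, -10.0)
    n_trials_voc: int = 20
    tone_frequencies: Sequence[float] = field(default_factory=default_tone_frequencies)
    n_trials_tone: int = 8
    spontaneous_window_s: float = 0.200
    masker_analysis_period_s: float = 0.564
    masker_initial_window_s: float = 0.200
    signal_onset_in_masker_s: float = 0.200
    signal_window_in_masker_s: float = 0.300
    edge_window_s: float = 0.050
    psth_bin_s: float = 0.004
    corrcoef_kernel_s: float = 0.010

    def __post_init__(self) -> None:
        self.vocalization_ids = tuple(self.vocalization_ids)
        self.vocalization_durations = tuple(float(d) for d in self.vocalization_durations)
        self.noise_types = tuple(self.noise_types)
        self.snr_levels_db = tuple(float(s) for s in self.snr_levels_db)
        self.tone_frequencies = tuple(float(f) for f in self.tone_frequencies)
        self.validate()

    def validate(self) -> None:
        if len(self.snr_levels_db) != 3:
            raise ValueError("protocol requires exactly 3 SNR levels")
        if not all(a > b for a, b in zip(self.snr_levels_db, self.snr_levels_db[1:])):
            raise ValueError("SNR levels must be strictly decreasing")
        if len(self.noise_types) != 2:
            raise ValueError("protocol requires exactly 2 noise types")
        if len(self.vocalization_ids) != len(self.vocalization_durations):
            raise ValueError("one duration per vocalization required")
        if len(set(self.vocalization_ids)) != len(self.vocalization_ids):
            raise ValueError("vocalization ids must be unique")
        freqs = np.asarray(self.tone_frequencies)
        if len(freqs) != 129:
            raise ValueError("protocol requires 129 tone frequencies")
        if not np.all(np.diff(freqs) > 0):
            raise ValueError("tone frequencies must be strictly increasing")
        for name in (
            "spontaneous_window_s",
            "masker_analysis_period_s",
            "masker_initial_window_s",
            "signal_window_in_masker_s",
            "edge_window_s",
            "psth_bin_s",
            "corrcoef_kernel_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.signal_onset_in_masker_s < 0:
            raise ValueError("signal_onset_in_masker_s must be nonnegative")
        if self.n_trials_voc < 1 or self.n_trials_tone < 1:
            raise ValueError("trial counts must be >= 1")

    # ---- condition ids -------------------------------------------------

    def clean_condition(self, voc_id: str) -> str:
        self._check_voc(voc_id)
        return f"{voc_id}_clean"

    def noisy_condition(self, voc_id: str, noise_type: str, snr_db: float) -> str:
        self._check_voc(voc_id)
        self._check_noise(noise_type)
        return f"{voc_id}_{_NOISE_ABBREV[noise_type]}_{snr_label(snr_db)}"

    def noise_condition(self, noise_type: str) -> str:
        self._check_noise(noise_type)
        return f"noise_{_NOISE_ABBREV[noise_type]}"

    def tone_condition(self, freq_index: int) -> str:
        if not 0 <= freq_index < len(self.tone_frequencies):
            raise ValueError(f"tone index {freq_index} out of range")
        return f"tone_{freq_index + 1:04d}"

    def _check_voc(self, voc_id: str) -> None:
        if voc_id not in self.vocalization_ids:
            raise ValueError(f"unknown vocalization {voc_id!r}")

    def _check_noise(self, noise_type: str) -> None:
        if noise_type not in self.noise_types:
            raise ValueError(f"unknown noise type {noise_type!r}")

    def voc_duration(self, voc_id: str) -> float:
        self._check_voc(voc_id)
        return self.vocalization_durations[self.vocalization_ids.index(voc_id)]

    def condition_ids(self, include_tones: bool = True) -> list[str]:
        """All condition ids of the protocol, in canonical order."""
        ids = [self.clean_condition(v) for v in self.vocalization_ids]
        for v in self.vocalization_ids:
            for nt in self.noise_types:
                for snr in self.snr_levels_db:
                    ids.append(self.noisy_condition(v, nt, snr))
        ids += [self.noise_condition(nt) for nt in self.noise_types]
        if include_tones:
            ids += [self.tone_condition(i) for i in range(len(self.tone_frequencies))]
        return ids

    def parse_condition(self, condition_id: str) -> dict:
        """Decompose a condition id into its components.

        Returns a dict with key ``kind`` in {"clean", "noisy", "noise", "tone"}
        plus, as applicable, ``voc_id``, ``noise_type``, ``snr_db``,
        ``freq_index``, ``frequency_hz``.
        """
        if condition_id.startswith("tone_"):
            idx = int(condition_id.split("_", 1)[1]) - 1
            if not 0 <= idx < len(self.tone_frequencies):
                raise ValueError(f"bad tone condition {condition_id!r}")
            return {"kind": "tone", "freq_index": idx,
                    "frequency_hz": self.tone_frequencies[idx]}
        if condition_id.startswith("noise_"):
            abbrev = condition_id.split("_", 1)[1]
            if abbrev not in _NOISE_FROM_ABBREV:
                raise ValueError(f"bad noise condition {condition_id!r}")
            return {"kind": "noise", "noise_type": _NOISE_FROM_ABBREV[abbrev]}
        parts = condition_id.split("_")
        if len(parts) == 2 and parts[1] == "clean":
            self._check_voc(parts[0])
            return {"kind": "clean", "voc_id": parts[0]}
        if len(parts) == 3 and parts[1] in _NOISE_FROM_ABBREV:
            self._check_voc(parts[0])
            snr = _snr_from_label(parts[2])
            if snr not in self.snr_levels_db:
                raise ValueError(f"unknown SNR in {condition_id!r}")
            return {"kind": "noisy", "voc_id": parts[0],
                    "noise_type": _NOISE_FROM_ABBREV[parts[1]], "snr_db": snr}
        raise ValueError(f"unparseable condition id {condition_id!r}")

    # ---- serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["vocalization_ids"] = list(self.vocalization_ids)
        d["vocalization_durations"] = list(self.vocalization_durations)
        d["noise_types"] = list(self.noise_types)
        d["snr_levels_db"] = list(self.snr_levels_db)
        d["tone_frequencies"] = list(self.tone_frequencies)
        d["condition_ids"] = self.condition_ids()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d.pop("condition_ids", None)
        return cls(**d)
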