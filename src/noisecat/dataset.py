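"""Domain containers for multiunit spike recordings and their plain-text I/O.

A :class:`Recording` holds one multiunit site's trial blocks for every
condition of the stimulus protocol, together with the auditory structure it
was recorded in (CN, CNIC, MGv, A1 or VRB).  A :class:`Dataset` bundles a
protocol with a collection of recordings.

On disk a dataset is four diffable text files:

``spikes.csv``
    recording_id, condition_id, trial, spike_time_s (6 decimals).
``trials.csv``
    recording_id, condition_id, trial, t_start_s, t_end_s, onset_s, offset_s.
    Every trial is enumerated here, so empty trials are representable.
``recordings.csv``
    recording_id, structure, planted_category_stationary, planted_category_chorus.
``protocol.yaml``
    all :class:`~noisecat.protocol.StimulusProtocol` fields.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import StimulusProtocol

#: The five auditory structures sampled along the pathway.
STRUCTURES = ("CN", "CNIC", "MGv", "A1", "VRB")

#: The five noise-robustness categories, in signal-to-masker order.
CATEGORIES = (
    "signal-like",
    "signal-dominated",
    "balanced",
    "insensitive",
    "masker-like",
)

_TIME_DECIMALS = 6


class ValidationError(ValueError):
    """A domain invariant was violated."""


class FormatError(ValueError):
    """An input file does not follow the documented tabular format."""


@dataclass
class SpikeTrain:
    """Spike times (s, trial-relative, nondecreasing) within a trial window."""

    spike_times: np.ndarray
    trial_window: tuple[float, float]

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.trial_window = (float(self.trial_window[0]), float(self.trial_window[1]))
        self.validate()

    def validate(self) -> None:
        t0, t1 = self.trial_window
        if t1 <= t0:
            raise ValidationError(f"empty trial window {self.trial_window}")
        t = self.spike_times
        if t.ndim != 1:
            raise ValidationError("spike_times must be 1-D")
        if t.size and np.any(np.diff(t) < 0):
            raise ValidationError("spike times must be nondecreasing")
        if t.size and (t[0] < t0 or t[-1] > t1):
            raise ValidationError(
                f"spike times outside trial window {self.trial_window}"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def count_in(self, start: float, end: float) -> int:
        """Number of spikes with start <= t < end."""
        return int(np.searchsorted(self.spike_times, end) -
                   np.searchsorted(self.spike_times, start))


@dataclass
class TrialBlock:
    """All repetitions of one stimulus condition.

    ``onset_s``/``offset_s`` locate the stimulus within the trial; the evoked
    window of every analysis is ``[onset_s, offset_s]``.
    """

    condition_id: str
    trains: list[SpikeTrain]
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.trains:
            raise ValidationError(f"block {self.condition_id}: no trials")
        w0 = self.trains[0].trial_window
        for tr in self.trains:
            if tr.trial_window != w0:
                raise ValidationError(
                    f"block {self.condition_id}: trials do not share a window"
                )
        if not (w0[0] <= self.onset_s < self.offset_s <= w0[1] + 1e-9):
            raise ValidationError(
                f"block {self.condition_id}: stimulus window "
                f"[{self.onset_s}, {self.offset_s}] outside trial {w0}"
            )

    @property
    def n_trials(self) -> int:
        return len(self.trains)

    @property
    def trial_window(self) -> tuple[float, float]:
        return self.trains[0].trial_window


@dataclass
class Recording:
    """One multiunit site: a complete block map over the protocol."""

    recording_id: str
    structure: str
    blocks: dict[str, TrialBlock]
    planted_category_by_noise: dict[str, str] | None = None

    def validate(self, protocol: StimulusProtocol) -> None:
        if self.structure not in STRUCTURES:
            raise ValidationError(
                f"{self.recording_id}: unknown structure {self.structure!r}"
            )
        tone_ids = {protocol.tone_condition(i)
                    for i in range(len(protocol.tone_frequencies))}
        present_tones = tone_ids & self.blocks.keys()
        # Tone blocks are all-or-none: a vocalization-only dataset is legal,
        # a partial tone map is not.
        include_tones = bool(present_tones)
        if include_tones and present_tones != tone_ids:
            missing = sorted(tone_ids - present_tones)
            raise ValidationError(
                f"{self.recording_id}: incomplete tone block map, "
                f"missing {missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        required = protocol.condition_ids(include_tones=include_tones)
        missing = [c for c in required if c not in self.blocks]
        if missing:
            raise ValidationError(
                f"{self.recording_id}: missing conditions {missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}"
            )
        for cid, block in self.blocks.items():
            info = protocol.parse_condition(cid)
            expected = (protocol.n_trials_tone if info["kind"] == "tone"
                        else protocol.n_trials_voc)
            if block.n_trials != expected:
                raise ValidationError(
                    f"{self.recording_id}/{cid}: {block.n_trials} trials, "
                    f"expected {expected}"
                )
        if self.planted_category_by_noise is not None:
            for nt, cat in self.planted_category_by_noise.items():
                if nt not in protocol.noise_types:
                    raise ValidationError(f"planted category for unknown noise {nt!r}")
                if cat not in CATEGORIES:
                    raise ValidationError(f"unknown planted category {cat!r}")

    @property
    def has_tones(self) -> bool:
        return any(cid.startswith("tone_") for cid in self.blocks)


@dataclass
class Dataset:
    """A stimulus protocol plus a collection of recordings."""

    protocol: StimulusProtocol
    recordings: list[Recording] = field(default_factory=list)

    def validate(self) -> None:
        ids = [r.recording_id for r in self.recordings]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate recording ids {dupes}")
        for rec in self.recordings:
            rec.validate(self.protocol)

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    def get(self, recording_id: str) -> Recording:
        for rec in self.recordings:
            if rec.recording_id == recording_id:
                return rec
        raise KeyError(recording_id)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def write_spike_events(dataset: Dataset, out_dir) -> None:
    """Write a dataset as spikes/trials/recordings CSVs plus protocol YAML.

    Spike times are serialized at 6 decimals, so a write/read round trip is
    exact to 1 microsecond.
    """
    os.makedirs(out_dir, exist_ok=True)
    spike_rows: list[tuple] = []
    trial_rows: list[tuple] = []
    rec_rows: list[dict] = []
    for rec in dataset.recordings:
        planted = rec.planted_category_by_noise or {}
        rec_rows.append({
            "recording_id": rec.recording_id,
            "structure": rec.structure,
            "planted_category_stationary": planted.get("stationary", ""),
            "planted_category_chorus": planted.get("chorus", ""),
        })
        for cid in sorted(rec.blocks):
            block = rec.blocks[cid]
            t0, t1 = block.trial_window
            for trial, train in enumerate(block.trains):
                trial_rows.append((rec.recording_id, cid, trial, t0, t1,
                                   block.onset_s, block.offset_s))
                for t in train.spike_times:
                    spike_rows.append((rec.recording_id, cid, trial,
                                       round(float(t), _TIME_DECIMALS)))
    pd.DataFrame(
        spike_rows,
        columns=["recording_id", "condition_id", "trial", "spike_time_s"],
    ).to_csv(os.path.join(out_dir, "spikes.csv"), index=False,
             float_format=f"%.{_TIME_DECIMALS}f")
    pd.DataFrame(
        trial_rows,
        columns=["recording_id", "condition_id", "trial",
                 "t_start_s", "t_end_s", "onset_s", "offset_s"],
    ).to_csv(os.path.join(out_dir, "trials.csv"), index=False,
             float_format=f"%.{_TIME_DECIMALS}f")
    pd.DataFrame(
        rec_rows,
        columns=["recording_id", "structure",
                 "planted_category_stationary", "planted_category_chorus"],
    ).to_csv(os.path.join(out_dir, "recordings.csv"), index=False)
    dataset.protocol.to_yaml(os.path.join(out_dir, "protocol.yaml"))


def read_spike_events(in_dir) -> Dataset:
    """Read a dataset written by :func:`write_spike_events`.

    Raises
    ------
    FormatError
        On unknown condition labels (names the offending row).
    ValidationError
        On trial-count mismatches or invariant violations (names the block).
    """
    protocol = StimulusProtocol.from_yaml(os.path.join(in_dir, "protocol.yaml"))
    trials = pd.read_csv(os.path.join(in_dir, "trials.csv"))
    spikes = pd.read_csv(os.path.join(in_dir, "spikes.csv"))
    recs_meta = pd.read_csv(
        os.path.join(in_dir, "recordings.csv"),
        dtype={"planted_category_stationary": str, "planted_category_chorus": str},
        keep_default_na=False,
    )

    known = set(protocol.condition_ids())
    for df, fname in ((trials, "trials.csv"), (spikes, "spikes.csv")):
        bad = df.index[~df["condition_id"].isin(known)]
        if len(bad):
            row = int(bad[0])
            raise FormatError(
                f"{fname} row {row}: unknown condition "
                f"{df.loc[row, 'condition_id']!r}"
            )

    spike_groups = {
        key: np.sort(grp["spike_time_s"].to_numpy(dtype=float))
        for key, grp in spikes.groupby(
            ["recording_id", "condition_id", "trial"], sort=False)
    }

    recordings = []
    for _, meta in recs_meta.iterrows():
        rid = meta["recording_id"]
        rec_trials = trials[trials["recording_id"] == rid]
        blocks: dict[str, TrialBlock] = {}
        for cid, grp in rec_trials.groupby("condition_id", sort=False):
            grp = grp.sort_values("trial")
            expected = np.arange(len(grp))
            if not np.array_equal(grp["trial"].to_numpy(), expected):
                raise FormatError(
                    f"{rid}/{cid}: trial indices must be 0..n-1"
                )
            trains = [
                SpikeTrain(
                    spike_groups.get((rid, cid, int(row.trial)), np.empty(0)),
                    (row.t_start_s, row.t_end_s),
                )
                for row in grp.itertuples()
            ]
            first = grp.iloc[0]
            blocks[cid] = TrialBlock(cid, trains, float(first.onset_s),
                                     float(first.offset_s))
        planted = {}
        if meta["planted_category_stationary"]:
            planted["stationary"] = meta["planted_category_stationary"]
        if meta["planted_category_chorus"]:
            planted["chorus"] = meta["planted_category_chorus"]
        recordings.append(Recording(rid, meta["structure"], blocks,
                                    planted or None))
    dataset = Dataset(protocol, recordings)
    dataset.validate()
    return dataset
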