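"""The extraction index (EI): a noise-invariance statistic per SNR and masker.

For a noisy-vocalization PSTH ``P_snr``, its clean-vocalization reference
``P_v`` and the masker-alone reference ``P_n`` (all 4-ms-bin, evoked window
only), the EI is

    EI = (D_n-snr - D_v-snr) / (D_n-snr + D_v-snr)

with D the normalized-inner-product (cosine) distance.  EI is bounded in
[-1, 1]: positive means the noisy response is more vocalization-like,
negative more masker-like.  Per-recording significance is assessed against
surrogate EI distributions obtained by replacing every condition's spike
trains with homogeneous Poisson trains at the measured evoked rate
(threshold = surrogate mean + 2 SD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import Dataset, Recording, STRUCTURES
from .metrics import compute_psth, evoked_rate, PSTH
from .protocol import StimulusProtocol

__all__ = [
    "EIProfile", "SelectionReport",
    "cosine_distance", "extraction_index", "ei_profile",
    "surrogate_thresholds", "select_recordings",
]

Key = tuple[str, float]  # (noise_type, snr_db)


@dataclass
class EIProfile:
    """Six EI values (2 maskers x 3 SNRs) and their surrogate thresholds."""

    ei: dict[Key, float]                       # NaN = undefined
    surrogate_threshold: dict[Key, float] = field(default_factory=dict)
    per_vocalization_ei: dict[Key, dict[str, float]] = field(default_factory=dict)

    @property
    def all_defined(self) -> bool:
        return bool(self.ei) and not any(np.isnan(v) for v in self.ei.values())

    @property
    def any_significant(self) -> bool:
        """True iff at least one defined EI exceeds its surrogate threshold."""
        for key, v in self.ei.items():
            thr = self.surrogate_threshold.get(key, np.nan)
            if not np.isnan(v) and not np.isnan(thr) and v > thr:
                return True
        return False

    def values_for(self, noise_type: str,
                   snr_levels: tuple[float, ...]) -> np.ndarray:
        """3-vector of EI values for one masker, best SNR first."""
        return np.array([self.ei[(noise_type, snr)] for snr in snr_levels])


def cosine_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Normalized-inner-product distance: 1 - p.q / (|p||q|), in [0, 1].

    If exactly one vector is all-zero the distance is 1 (maximally
    dissimilar); if both are all-zero it is undefined (NaN).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    np_, nq = np.linalg.norm(p), np.linalg.norm(q)
    if np_ == 0 and nq == 0:
        return float("nan")
    if np_ == 0 or nq == 0:
        return 1.0
    return float(1.0 - np.dot(p, q) / (np_ * nq))


def _nanmean_cols(a: np.ndarray) -> np.ndarray:
    """Column means ignoring NaN; NaN where a column has no defined value."""
    mask = np.isnan(a)
    n = (~mask).sum(axis=0)
    s = np.where(mask, 0.0, a).sum(axis=0)
    return np.where(n > 0, s / np.maximum(n, 1), np.nan)


def _ei_from_distances(d_n: float, d_v: float) -> float:
    if np.isnan(d_n) or np.isnan(d_v) or (d_n + d_v) == 0:
        return float("nan")
    return (d_n - d_v) / (d_n + d_v)


def extraction_index(psth_snr: PSTH | np.ndarray, psth_v: PSTH | np.ndarray,
                     psth_n: PSTH | np.ndarray) -> float:
    """EI of one noisy-condition PSTH against its two references.

    Accepts raw vectors or :class:`~noisecat.metrics.PSTH` objects; PSTHs
    must share bin width and window length.
    """
    vecs = []
    meta = []
    for p in (psth_snr, psth_v, psth_n):
        if isinstance(p, PSTH):
            vecs.append(p.values)
            meta.append((p.bin_s, p.n_bins))
        else:
            vecs.append(np.asarray(p, dtype=float))
            meta.append(None)
    known = [m for m in meta if m is not None]
    if known and any(m != known[0] for m in known):
        raise ValueError("PSTHs must share bin width and bin count")
    d_n = cosine_distance(vecs[2], vecs[0])
    d_v = cosine_distance(vecs[1], vecs[0])
    return _ei_from_distances(d_n, d_v)


def _evoked_psth(recording: Recording, condition_id: str, bin_s: float,
                 duration: float) -> PSTH:
    """PSTH over [onset, onset + duration], the per-vocalization evoked window."""
    block = recording.blocks[condition_id]
    return compute_psth(block, bin_s,
                        (block.onset_s, block.onset_s + duration))


def ei_profile(recording: Recording, protocol: StimulusProtocol,
               bin_s: float | None = None) -> EIProfile:
    """EI per (masker, SNR), averaged over the four vocalizations.

    For each vocalization the noisy PSTH is compared with that vocalization's
    clean PSTH and with the masker-alone PSTH, all over an evoked window of
    the vocalization's duration at 4-ms bins; undefined per-vocalization
    values are skipped and the (masker, SNR) entry is undefined only when all
    four are.
    """
    bin_s = bin_s or protocol.psth_bin_s
    ei: dict[Key, float] = {}
    per_voc: dict[Key, dict[str, float]] = {}
    clean = {v: _evoked_psth(recording, protocol.clean_condition(v), bin_s,
                             protocol.voc_duration(v))
             for v in protocol.vocalization_ids}
    for nt in protocol.noise_types:
        noise_cid = protocol.noise_condition(nt)
        noise_by_voc = {
            v: _evoked_psth(recording, noise_cid, bin_s, protocol.voc_duration(v))
            for v in protocol.vocalization_ids}
        for snr in protocol.snr_levels_db:
            vals = {}
            for v in protocol.vocalization_ids:
                p_snr = _evoked_psth(
                    recording, protocol.noisy_condition(v, nt, snr), bin_s,
                    protocol.voc_duration(v))
                vals[v] = extraction_index(p_snr, clean[v], noise_by_voc[v])
            per_voc[(nt, snr)] = vals
            arr = np.array(list(vals.values()))
            ei[(nt, snr)] = (float(np.nanmean(arr))
                             if not np.all(np.isnan(arr)) else float("nan"))
    return EIProfile(ei, per_vocalization_ei=per_voc)


def surrogate_thresholds(recording: Recording, protocol: StimulusProtocol,
                         n_surrogates: int = 100, seed: int = 0,
                         bin_s: float | None = None) -> dict[Key, float]:
    """Per-(masker, SNR) significance thresholds from Poisson surrogates.

    In each surrogate replicate every condition's trains are replaced by
    homogeneous Poisson trains matched to that condition's measured evoked
    firing rate (same trial count and window) and the six EI values are
    recomputed; the threshold is the surrogate mean + 2 SD.  Binned counts of
    a homogeneous Poisson train are independent Poisson draws per bin, so the
    surrogate PSTHs are sampled directly at the bin level.

    Thresholds are NaN when the surrogate EI distribution is undefined (e.g.,
    zero firing rate in the conditions involved).
    """
    if n_surrogates < 2:
        raise ValueError("n_surrogates must be >= 2")
    bin_s = bin_s or protocol.psth_bin_s
    rng = np.random.default_rng(seed)
    n_trials = protocol.n_trials_voc

    def surrogate_psths(cid: str, duration: float) -> np.ndarray:
        """(n_surrogates x n_bins) surrogate PSTH matrix for one condition."""
        block = recording.blocks[cid]
        rate = evoked_rate(block)
        n_bins = int(np.floor(duration / bin_s + 1e-9))
        lam = rate * n_trials * bin_s
        counts = rng.poisson(lam, size=(n_surrogates, n_bins))
        return counts / (n_trials * bin_s)

    # Draw every condition once per replicate so the six EI values of a
    # replicate come from one coherent surrogate recording.
    clean = {v: surrogate_psths(protocol.clean_condition(v),
                                protocol.voc_duration(v))
             for v in protocol.vocalization_ids}
    noise = {}
    for nt in protocol.noise_types:
        for v in protocol.vocalization_ids:
            noise[(nt, v)] = surrogate_psths(protocol.noise_condition(nt),
                                             protocol.voc_duration(v))
    thresholds: dict[Key, float] = {}
    for nt in protocol.noise_types:
        for snr in protocol.snr_levels_db:
            per_voc = np.full((len(protocol.vocalization_ids), n_surrogates),
                              np.nan)
            for vi, v in enumerate(protocol.vocalization_ids):
                p_snr = surrogate_psths(protocol.noisy_condition(v, nt, snr),
                                        protocol.voc_duration(v))
                per_voc[vi] = _ei_matrix(p_snr, clean[v], noise[(nt, v)])
            ei_s = _nanmean_cols(per_voc)
            ei_s = ei_s[~np.isnan(ei_s)]
            if ei_s.size < 2:
                thresholds[(nt, snr)] = float("nan")
            else:
                thresholds[(nt, snr)] = float(ei_s.mean() + 2.0 * ei_s.std())
    return thresholds


def _ei_matrix(p_snr: np.ndarray, p_v: np.ndarray,
               p_n: np.ndarray) -> np.ndarray:
    """Row-wise EI for stacked surrogate PSTHs (NaN where undefined)."""
    def row_cos(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        denom = na * nb
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - np.einsum("ij,ij->i", a, b) / denom
        d[(na == 0) ^ (nb == 0)] = 1.0
        d[(na == 0) & (nb == 0)] = np.nan
        return d

    d_n = row_cos(p_n, p_snr)
    d_v = row_cos(p_v, p_snr)
    denom = d_n + d_v
    with np.errstate(invalid="ignore", divide="ignore"):
        ei = (d_n - d_v) / denom
    ei[denom == 0] = np.nan
    return ei


@dataclass
class SelectionReport:
    """Stagewise selection counts in the layout of a recording-count table."""

    counts: pd.DataFrame         # rows = stages, columns = structures + Total
    selected_ids: list[str]
    criterion: str


_STAGES = (
    "tested",
    "six EI defined",
    "EI significant vs surrogate",
    "(a) voc response or TFRP",
    "(b) voc response and TFRP",
)


def select_recordings(dataset: Dataset, profiles: dict[str, EIProfile],
                      voc_significant: dict[str, bool],
                      tfrp_significant: dict[str, bool] | None = None,
                      criterion: str = "b") -> SelectionReport:
    """Apply the recording-selection cascade and tabulate counts per structure.

    Stages, in order: all six EI values defined; at least one EI above its
    surrogate threshold; then criterion (a) significant vocalization response
    OR significant TFRP, or criterion (b) significant vocalization response
    AND significant TFRP.  With no TFRP information (``tfrp_significant``
    None) the TFRP clause is dropped from both criteria.
    """
    if criterion not in ("a", "b"):
        raise ValueError("criterion must be 'a' or 'b'")
    structures = [s for s in STRUCTURES
                  if any(r.structure == s for r in dataset)]
    counts = pd.DataFrame(0, index=list(_STAGES), columns=structures + ["Total"])
    survivors_a: list[str] = []
    survivors_b: list[str] = []
    for rec in dataset:
        rid = rec.recording_id
        col = rec.structure

        def bump(stage: str) -> None:
            counts.loc[stage, col] += 1
            counts.loc[stage, "Total"] += 1

        bump("tested")
        prof = profiles.get(rid)
        if prof is None or not prof.all_defined:
            continue
        bump("six EI defined")
        if not prof.any_significant:
            continue
        bump("EI significant vs surrogate")
        voc = bool(voc_significant.get(rid, False))
        if tfrp_significant is None:
            a = b = voc
        else:
            tfrp = bool(tfrp_significant.get(rid, False))
            a, b = voc or tfrp, voc and tfrp
        if a:
            bump("(a) voc response or TFRP")
            survivors_a.append(rid)
        if b:
            bump("(b) voc response and TFRP")
            survivors_b.append(rid)
    selected = survivors_a if criterion == "a" else survivors_b
    return SelectionReport(counts, selected, criterion)
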