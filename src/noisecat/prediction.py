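"""Predicting a recording's noise-robustness category from 12 descriptors.

Per masker type, twelve response descriptors are extracted in four groups:

* ``tfrp`` — BF firing rate (spikes/s), tuning bandwidth (octaves), response
  duration (ms), from the pure-tone map;
* ``signal`` — firing rate and CorrCoef of the responses to the clean
  vocalizations (averaged over the four calls);
* ``masker`` — firing rate and CorrCoef of the masker-alone response, the
  short-term adaptation ratio FRm300/FRm200 (rate at the time the signal
  would have occurred over the initial 200-ms rate), and the spike counts in
  the first and last 50 ms of the 564-ms masker period;
* ``signal_to_masker`` — signal rate / FRm200 and signal rate / FRm300.

A linear discriminant classifier with a cost-weighted decision rule (cost 2
for predicting "insensitive" on a non-insensitive truth, 1 for other errors)
is evaluated with stratified 5-fold cross-validation over the 15 nonempty
combinations of the four descriptor groups, and in a train-on-reliable /
test-on-rest generalization setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .dataset import CATEGORIES, Recording
from .metrics import TFRPResult, compute_tfrp, corrcoef, per_trial_rates
from .protocol import StimulusProtocol

__all__ = [
    "DESCRIPTOR_GROUPS", "ClassifierReport",
    "extract_descriptors", "descriptor_table", "impute_table",
    "default_cost_matrix", "train_eval_lda", "combo_sweep", "generalize",
    "combination_id", "combination_groups",
]

#: Descriptor columns by group; 3 + 2 + 5 + 2 = 12.
DESCRIPTOR_GROUPS: dict[str, tuple[str, ...]] = {
    "tfrp": ("tfrp_bf_rate_hz", "tfrp_bandwidth_oct", "tfrp_duration_ms"),
    "signal": ("signal_rate_hz", "signal_corrcoef"),
    "masker": ("masker_rate_hz", "masker_corrcoef", "masker_frm_ratio",
               "masker_initial_50ms_spikes", "masker_final_50ms_spikes"),
    "signal_to_masker": ("sig_over_frm200", "sig_over_frm300"),
}

GROUP_ORDER = tuple(DESCRIPTOR_GROUPS)
ALL_COLUMNS = tuple(c for g in GROUP_ORDER for c in DESCRIPTOR_GROUPS[g])


def combination_id(groups) -> int:
    """Combination numbering of the descriptor-group sweep.

    Groups are bits (tfrp=8, signal=4, masker=2, signal_to_masker=1) and the
    id is 16 minus the bit value, so the all-group combination is 1, TFRP
    alone is 8, and signal-to-masker alone is 15.
    """
    bits = {"tfrp": 8, "signal": 4, "masker": 2, "signal_to_masker": 1}
    value = sum(bits[g] for g in set(groups))
    if value == 0:
        raise ValueError("combination must be nonempty")
    return 16 - value


def combination_groups(cid: int) -> tuple[str, ...]:
    """Inverse of :func:`combination_id`."""
    if not 1 <= cid <= 15:
        raise ValueError("combination id must be in 1..15")
    value = 16 - cid
    bits = {"tfrp": 8, "signal": 4, "masker": 2, "signal_to_masker": 1}
    return tuple(g for g in GROUP_ORDER if value & bits[g])


def extract_descriptors(recording: Recording, noise_type: str,
                        protocol: StimulusProtocol,
                        tfrp: TFRPResult | None = None) -> dict[str, float]:
    """The 12 descriptors of one recording for one masker type.

    Signal descriptors are averaged over the four clean vocalizations; masker
    descriptors come from the masker-alone block over the 564-ms analysis
    period.  Ratios with zero denominators are returned as NaN (flagged for
    imputation downstream).  ``tfrp`` may be precomputed; otherwise it is
    derived from the recording's tone blocks.
    """
    noise_cid = protocol.noise_condition(noise_type)
    if noise_cid not in recording.blocks:
        raise ValueError(f"{recording.recording_id}: missing masker-alone block")
    if tfrp is None:
        if not recording.has_tones:
            raise ValueError(
                f"{recording.recording_id}: no tone blocks and no TFRP given")
        tfrp = compute_tfrp(
            {cid: b for cid, b in recording.blocks.items()
             if cid.startswith("tone_")}, protocol)

    sig_rates, sig_ccs = [], []
    for v in protocol.vocalization_ids:
        block = recording.blocks[protocol.clean_condition(v)]
        sig_rates.append(per_trial_rates(block, block.onset_s,
                                         block.offset_s).mean())
        cc = corrcoef(block, protocol.corrcoef_kernel_s)
        if cc.defined:
            sig_ccs.append(cc.corrcoef)
    sig_rate = float(np.mean(sig_rates))
    sig_cc = float(np.mean(sig_ccs)) if sig_ccs else float("nan")

    nb = recording.blocks[noise_cid]
    on = nb.onset_s
    period = protocol.masker_analysis_period_s
    edge = protocol.edge_window_s
    masker_rate = float(per_trial_rates(nb, on, on + period).mean())
    cc = corrcoef(nb, protocol.corrcoef_kernel_s, window=(on, on + period))
    masker_cc = cc.corrcoef if cc.defined else float("nan")
    frm200 = float(per_trial_rates(
        nb, on, on + protocol.masker_initial_window_s).mean())
    t_sig = on + protocol.signal_onset_in_masker_s
    frm300 = float(per_trial_rates(
        nb, t_sig, t_sig + protocol.signal_window_in_masker_s).mean())
    initial = float(np.mean([tr.count_in(on, on + edge) for tr in nb.trains]))
    final = float(np.mean([tr.count_in(on + period - edge, on + period)
                           for tr in nb.trains]))

    def ratio(a: float, b: float) -> float:
        return a / b if b > 0 else float("nan")

    return {
        "tfrp_bf_rate_hz": tfrp.bf_firing_rate_hz,
        "tfrp_bandwidth_oct": tfrp.bandwidth_octaves,
        "tfrp_duration_ms": tfrp.response_duration_ms,
        "signal_rate_hz": sig_rate,
        "signal_corrcoef": sig_cc,
        "masker_rate_hz": masker_rate,
        "masker_corrcoef": masker_cc,
        "masker_frm_ratio": ratio(frm300, frm200),
        "masker_initial_50ms_spikes": initial,
        "masker_final_50ms_spikes": final,
        "sig_over_frm200": ratio(sig_rate, frm200),
        "sig_over_frm300": ratio(sig_rate, frm300),
    }


def descriptor_table(recordings, noise_type: str, protocol: StimulusProtocol,
                     tfrps: dict[str, TFRPResult] | None = None) -> pd.DataFrame:
    """Descriptor rows (12 columns) indexed by recording id."""
    rows = {}
    for rec in recordings:
        tfrp = tfrps.get(rec.recording_id) if tfrps else None
        rows[rec.recording_id] = extract_descriptors(rec, noise_type, protocol,
                                                     tfrp)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(ALL_COLUMNS))


def impute_table(table: pd.DataFrame, max_imputed: int = 3
                 ) -> tuple[pd.DataFrame, list[str]]:
    """Replace non-finite descriptors with the column median of finite values.

    Rows with more than ``max_imputed`` imputed entries are excluded and
    their ids returned.
    """
    t = table.copy()
    bad = ~np.isfinite(t.to_numpy(dtype=float))
    n_bad = bad.sum(axis=1)
    excluded = [str(i) for i in t.index[n_bad > max_imputed]]
    t = t[n_bad <= max_imputed]
    bad = ~np.isfinite(t.to_numpy(dtype=float))
    medians = np.nanmedian(np.where(np.isfinite(table.to_numpy(dtype=float)),
                                    table.to_numpy(dtype=float), np.nan),
                           axis=0)
    vals = t.to_numpy(dtype=float)
    vals[bad] = np.take(np.where(np.isfinite(medians), medians, 0.0),
                        np.nonzero(bad)[1])
    return pd.DataFrame(vals, index=t.index, columns=t.columns), excluded


def default_cost_matrix() -> pd.DataFrame:
    """Misclassification costs: 0 on the diagonal, 1 elsewhere, except cost 2
    for predicting 'insensitive' on a non-insensitive truth."""
    C = pd.DataFrame(1.0, index=list(CATEGORIES), columns=list(CATEGORIES))
    np.fill_diagonal(C.values, 0.0)
    for cat in CATEGORIES:
        if cat != "insensitive":
            C.loc[cat, "insensitive"] = 2.0
    return C


@dataclass
class ClassifierReport:
    combination_id: int
    groups: tuple[str, ...]
    cv_accuracy_percent: float
    confusion_percent: pd.DataFrame       # rows = true, cols = predicted
    n_train: int
    n_test: int


def _columns_for(groups) -> list[str]:
    return [c for g in GROUP_ORDER if g in set(groups)
            for c in DESCRIPTOR_GROUPS[g]]


def _fit_predict_cost(X_train, y_train, X_test, cost: pd.DataFrame,
                      classes: list[str], shrinkage: float = 1e-6
                      ) -> np.ndarray:
    """Standardize on train, fit LDA, predict by minimum expected cost."""
    scaler = StandardScaler().fit(X_train)
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    lda.fit(scaler.transform(X_train), y_train)
    proba = lda.predict_proba(scaler.transform(X_test))
    present = list(lda.classes_)
    C = cost.loc[present, [c for c in classes if c in present]]
    expected = proba @ C.to_numpy()
    return np.asarray(C.columns)[np.argmin(expected, axis=1)]


def _confusion_percent(y_true, y_pred) -> pd.DataFrame:
    conf = pd.DataFrame(0.0, index=list(CATEGORIES), columns=list(CATEGORIES))
    for t, p in zip(y_true, y_pred):
        conf.loc[t, p] += 1
    sums = conf.sum(axis=1)
    nonempty = sums > 0
    conf.loc[nonempty] = 100.0 * conf.loc[nonempty].div(sums[nonempty], axis=0)
    return conf


def train_eval_lda(table: pd.DataFrame, labels: pd.Series,
                   combination=GROUP_ORDER,
                   cost_matrix: pd.DataFrame | None = None,
                   n_folds: int = 5, seed: int = 0) -> ClassifierReport:
    """Stratified k-fold cross-validated, cost-weighted LDA evaluation.

    Descriptors are standardized on each training fold; the discriminant uses
    a shared within-class covariance with a small ridge (shrinkage) so
    collinear descriptors do not break the fit; predictions minimize expected
    cost under ``cost_matrix`` (default: the insensitive-penalizing matrix).
    Accuracy is percent correct pooled over folds.
    """
    cost = cost_matrix if cost_matrix is not None else default_cost_matrix()
    cols = _columns_for(combination)
    if not cols:
        raise ValueError("combination must include at least one group")
    X = table[cols].to_numpy(dtype=float)
    y = labels.loc[table.index].to_numpy()
    class_counts = pd.Series(y).value_counts()
    if (class_counts < n_folds).any():
        raise ValueError(
            f"every class needs >= {n_folds} samples for {n_folds}-fold CV; "
            f"got {class_counts.to_dict()}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=object)
    for train_idx, test_idx in skf.split(X, y):
        y_pred[test_idx] = _fit_predict_cost(
            X[train_idx], y[train_idx], X[test_idx], cost, list(CATEGORIES))
    acc = 100.0 * float(np.mean(y_pred == y))
    return ClassifierReport(combination_id(combination), tuple(combination),
                            acc, _confusion_percent(y, y_pred),
                            n_train=len(y), n_test=len(y))


def combo_sweep(table: pd.DataFrame, labels: pd.Series,
                cost_matrix: pd.DataFrame | None = None,
                n_folds: int = 5, seed: int = 0) -> dict[int, ClassifierReport]:
    """All 15 nonempty descriptor-group combinations, identical folds."""
    reports = {}
    for r in range(len(GROUP_ORDER), 0, -1):
        for groups in _combinations(GROUP_ORDER, r):
            rep = train_eval_lda(table, labels, groups, cost_matrix,
                                 n_folds, seed)
            reports[rep.combination_id] = rep
    return dict(sorted(reports.items()))


def generalize(train_table: pd.DataFrame, train_labels: pd.Series,
               test_table: pd.DataFrame, test_labels: pd.Series,
               combination=GROUP_ORDER,
               cost_matrix: pd.DataFrame | None = None) -> ClassifierReport:
    """Fit on the reliable set, evaluate on the held-out rest (no CV)."""
    overlap = set(train_table.index) & set(test_table.index)
    if overlap:
        raise ValueError(f"train/test sets overlap: {sorted(overlap)[:5]}")
    if len(test_table) == 0:
        raise ValueError("empty test set")
    cost = cost_matrix if cost_matrix is not None else default_cost_matrix()
    cols = _columns_for(combination)
    y_pred = _fit_predict_cost(
        train_table[cols].to_numpy(dtype=float),
        train_labels.loc[train_table.index].to_numpy(),
        test_table[cols].to_numpy(dtype=float), cost, list(CATEGORIES))
    y_true = test_labels.loc[test_table.index].to_numpy()
    acc = 100.0 * float(np.mean(y_pred == y_true))
    return ClassifierReport(combination_id(combination), tuple(combination),
                            acc, _confusion_percent(y_true, y_pred),
                            n_train=len(train_table), n_test=len(test_table))
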