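"""End-to-end orchestration: simulate -> metrics -> EI/selection ->
categorization/bootstrap -> switching/MI -> descriptors/classification.

Every stage is seeded from the global seed via
:func:`derive_seed`, which hashes (global seed, stage name, recording id):
adding recordings to a dataset does not perturb the sub-seeds of existing
ones, and a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import categorize, extraction, metrics, prediction, switching
from .dataset import CATEGORIES, Dataset, read_spike_events, write_spike_events
from .protocol import StimulusProtocol
from .synth import GeneratorConfig, make_dataset

__all__ = ["PipelineConfig", "PipelineResult", "derive_seed", "run_pipeline"]


def derive_seed(global_seed: int, *tokens) -> int:
    """Deterministic sub-seed < 2^31 from the global seed and stage tokens."""
    h = hashlib.sha256(repr((int(global_seed),) + tuple(map(str, tokens)))
                       .encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


@dataclass
class PipelineConfig:
    seed: int = 0
    generator: GeneratorConfig | None = None   # simulate if set ...
    data_dir: str | None = None                # ... else load from here
    out_dir: str | None = None
    n_surrogates: int = 100
    n_boot: int = 100
    k: int = 5
    n_restarts: int = 50
    reliability_threshold: int = 95
    selection_criterion: str = "b"
    n_folds: int = 5
    min_per_class: int = 5

    def __post_init__(self) -> None:
        if self.generator is None and self.data_dir is None:
            raise ValueError("config needs either a generator or a data_dir")
        for name in ("n_boot", "k", "n_restarts", "n_folds"):
            if getattr(self, name) < 0 or (name != "n_boot" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    dataset: Dataset
    metrics_table: pd.DataFrame | None = None
    tfrp_table: pd.DataFrame | None = None
    tfrps: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    selection: extraction.SelectionReport | None = None
    clusterings: dict = field(default_factory=dict)     # noise_type -> ClusteringResult
    assignments: dict = field(default_factory=dict)     # noise_type -> {rid: CategoryAssignment}
    switching_all: switching.SwitchingMatrix | None = None
    switching_reliable: switching.SwitchingMatrix | None = None
    mi_bits: dict = field(default_factory=dict)
    classifier_reports: dict = field(default_factory=dict)  # noise_type -> {cid: report}
    summary: dict = field(default_factory=dict)


def _stage_metrics(ds: Dataset, result: PipelineResult) -> None:
    proto = ds.protocol
    rows = []
    tfrp_rows = []
    for rec in ds:
        for v in proto.vocalization_ids:
            cid = proto.clean_condition(v)
            block = rec.blocks[cid]
            sig, p = metrics.response_significant(block)
            cc = metrics.corrcoef(block, proto.corrcoef_kernel_s)
            rows.append({"recording_id": rec.recording_id, "condition_id": cid,
                         "evoked_rate_hz": metrics.evoked_rate(block),
                         "spontaneous_rate_hz": metrics.spontaneous_rate(block),
                         "significant": sig, "p_value": p,
                         "corrcoef": cc.corrcoef})
        for nt in proto.noise_types:
            cid = proto.noise_condition(nt)
            block = rec.blocks[cid]
            cc = metrics.corrcoef(block, proto.corrcoef_kernel_s)
            rows.append({"recording_id": rec.recording_id, "condition_id": cid,
                         "evoked_rate_hz": metrics.evoked_rate(block),
                         "spontaneous_rate_hz": metrics.spontaneous_rate(block),
                         "significant": np.nan, "p_value": np.nan,
                         "corrcoef": cc.corrcoef})
        if rec.has_tones:
            tfrp = metrics.compute_tfrp(
                {c: b for c, b in rec.blocks.items() if c.startswith("tone_")},
                proto)
            result.tfrps[rec.recording_id] = tfrp
            tfrp_rows.append({"recording_id": rec.recording_id,
                              "bf_hz": tfrp.bf_hz,
                              "bf_firing_rate_hz": tfrp.bf_firing_rate_hz,
                              "significant": tfrp.significant,
                              "bandwidth_octaves": tfrp.bandwidth_octaves,
                              "response_duration_ms": tfrp.response_duration_ms})
    result.metrics_table = pd.DataFrame(rows)
    result.tfrp_table = pd.DataFrame(tfrp_rows) if tfrp_rows else None


def _stage_ei(ds: Dataset, cfg: PipelineConfig, result: PipelineResult) -> None:
    proto = ds.protocol
    for rec in ds:
        prof = extraction.ei_profile(rec, proto)
        if cfg.n_surrogates >= 2:
            prof.surrogate_threshold = extraction.surrogate_thresholds(
                rec, proto, cfg.n_surrogates,
                derive_seed(cfg.seed, "surrogate", rec.recording_id))
        result.profiles[rec.recording_id] = prof
    mt = result.metrics_table
    voc_sig = {}
    for rec in ds:
        sub = mt[(mt.recording_id == rec.recording_id) &
                 mt.condition_id.str.endswith("_clean")]
        voc_sig[rec.recording_id] = bool(sub.significant.any())
    tfrp_sig = ({rid: t.significant for rid, t in result.tfrps.items()}
                if result.tfrps else None)
    result.selection = extraction.select_recordings(
        ds, result.profiles, voc_sig, tfrp_sig, cfg.selection_criterion)


def _stage_cluster(ds: Dataset, cfg: PipelineConfig,
                   result: PipelineResult) -> None:
    proto = ds.protocol
    snrs = proto.snr_levels_db
    selected = set(result.selection.selected_ids)
    for nt in proto.noise_types:
        vectors = {
            rid: prof.values_for(nt, snrs)
            for rid, prof in result.profiles.items()
            if rid in selected and prof.all_defined
        }
        if len(vectors) < cfg.k:
            result.clusterings[nt] = None
            result.assignments[nt] = {}
            continue
        clustering = categorize.kmeans_profiles(
            vectors, cfg.k, cfg.n_restarts, derive_seed(cfg.seed, "kmeans", nt))
        result.clusterings[nt] = clustering
        assigns = {}
        for rec in ds:
            rid = rec.recording_id
            if rid not in vectors:
                continue
            cluster = clustering.assignments[rid]
            _, dist = categorize.assign_to_centroids(
                vectors[rid], clustering.centroids)
            if cfg.n_boot > 0:
                boot = categorize.bootstrap_stability(
                    rec, nt, proto, clustering.centroids, clustering.label_map,
                    cfg.n_boot, derive_seed(cfg.seed, "boot", nt, rid))
                mode_count = boot.bootstrap_mode_count
                reliable = (boot.category == clustering.label_map[cluster]
                            and mode_count >= cfg.reliability_threshold
                            * cfg.n_boot // 100)
            else:
                mode_count, reliable = 0, False
            assigns[rid] = categorize.CategoryAssignment(
                rid, nt, clustering.label_map[cluster], dist, mode_count,
                reliable)
        result.assignments[nt] = assigns


def _stage_switch(ds: Dataset, cfg: PipelineConfig,
                  result: PipelineResult) -> None:
    a_st = result.assignments.get("stationary", {})
    a_ch = result.assignments.get("chorus", {})
    if not a_st or not a_ch:
        return
    result.switching_all = switching.switching_matrix(a_st, a_ch)
    result.mi_bits["all"] = switching.mutual_information(result.switching_all)
    if cfg.n_boot > 0:
        result.switching_reliable = switching.switching_matrix(
            a_st, a_ch, reliable_only=True)
        result.mi_bits["reliable"] = switching.mutual_information(
            result.switching_reliable)


def _stage_classify(ds: Dataset, cfg: PipelineConfig,
                    result: PipelineResult) -> None:
    proto = ds.protocol
    if not any(rec.has_tones for rec in ds):
        return
    for nt in proto.noise_types:
        assigns = result.assignments.get(nt, {})
        reliable = {rid for rid, a in assigns.items() if a.reliable}
        if cfg.n_boot == 0:
            reliable = set(assigns)
        recs = [ds.get(rid) for rid in sorted(reliable)]
        if not recs:
            continue
        table = prediction.descriptor_table(recs, nt, proto, result.tfrps)
        table, _excluded = prediction.impute_table(table)
        labels = pd.Series({rid: assigns[rid].category for rid in table.index})
        counts = labels.value_counts()
        if len(counts) < 2 or (counts < max(cfg.n_folds, cfg.min_per_class)).any():
            continue
        result.classifier_reports[nt] = prediction.combo_sweep(
            table, labels, n_folds=cfg.n_folds,
            seed=derive_seed(cfg.seed, "lda", nt))


def _write_outputs(cfg: PipelineConfig, result: PipelineResult) -> None:
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    if result.metrics_table is not None:
        result.metrics_table.to_csv(os.path.join(out, "metrics.csv"), index=False)
    if result.tfrp_table is not None:
        result.tfrp_table.to_csv(os.path.join(out, "tfrp.csv"), index=False)
    if result.profiles:
        rows = []
        for rid, prof in result.profiles.items():
            for (nt, snr), v in prof.ei.items():
                thr = prof.surrogate_threshold.get((nt, snr), np.nan)
                rows.append({"recording_id": rid, "noise_type": nt,
                             "snr_db": snr, "ei": v, "threshold": thr,
                             "significant": bool(v > thr) if not (
                                 np.isnan(v) or np.isnan(thr)) else False})
        pd.DataFrame(rows).to_csv(os.path.join(out, "ei.csv"), index=False)
    if result.selection is not None:
        result.selection.counts.to_csv(os.path.join(out, "selection.csv"))
    if result.assignments:
        rows = []
        for nt, assigns in result.assignments.items():
            for a in assigns.values():
                rows.append({"recording_id": a.recording_id, "noise_type": nt,
                             "category": a.category,
                             "centroid_distance": a.centroid_distance,
                             "bootstrap_mode_count": a.bootstrap_mode_count,
                             "reliable": a.reliable})
        pd.DataFrame(rows).to_csv(os.path.join(out, "categories.csv"), index=False)
        centroids = {nt: (c.centroids.tolist() if c else None)
                     for nt, c in result.clusterings.items()}
        label_maps = {nt: ({str(k): v for k, v in c.label_map.items()} if c else None)
                      for nt, c in result.clusterings.items()}
        with open(os.path.join(out, "centroids.json"), "w") as fh:
            json.dump({"centroids": centroids, "label_maps": label_maps}, fh,
                      indent=2)
    if result.switching_all is not None:
        result.switching_all.counts.to_csv(os.path.join(out, "switching.csv"))
        with open(os.path.join(out, "mi.json"), "w") as fh:
            json.dump(result.mi_bits, fh, indent=2)
    if result.classifier_reports:
        payload = {
            nt: {str(cid): {"groups": list(rep.groups),
                            "cv_accuracy_percent": rep.cv_accuracy_percent,
                            "confusion_percent": rep.confusion_percent
                            .round(2).to_dict()}
                 for cid, rep in reports.items()}
            for nt, reports in result.classifier_reports.items()}
        with open(os.path.join(out, "classifier_report.json"), "w") as fh:
            json.dump(payload, fh, indent=2)
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(result.summary, fh, indent=2)


def _summarize(cfg: PipelineConfig, result: PipelineResult) -> None:
    s: dict = {"seed": cfg.seed, "n_recordings": len(result.dataset)}
    if result.selection is not None:
        s["selection_counts"] = {
            stage: int(result.selection.counts.loc[stage, "Total"])
            for stage in result.selection.counts.index}
        s["n_selected"] = len(result.selection.selected_ids)
    for nt, assigns in result.assignments.items():
        if assigns:
            props = pd.Series([a.category for a in assigns.values()]) \
                .value_counts(normalize=True) * 100
            s[f"category_percent_{nt}"] = {c: round(float(props.get(c, 0.0)), 2)
                                           for c in CATEGORIES}
            s[f"n_reliable_{nt}"] = sum(a.reliable for a in assigns.values())
    if result.mi_bits:
        s["mi_bits"] = {k: round(float(v), 4) for k, v in result.mi_bits.items()}
    for nt, reports in result.classifier_reports.items():
        s[f"lda_accuracy_percent_{nt}"] = {
            cid: round(rep.cv_accuracy_percent, 2)
            for cid, rep in reports.items()}
    result.summary = s


_STAGE_ORDER = ("metrics", "ei", "cluster", "switch", "classify")


def run_pipeline(config: PipelineConfig,
                 through_stage: str = "classify") -> PipelineResult:
    """Run the analysis end to end (or up to ``through_stage``).

    Returns a :class:`PipelineResult`; when ``config.out_dir`` is set, all
    stage outputs (CSV/JSON) and a summary report are written there.
    """
    if through_stage not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {through_stage!r}")
    if config.generator is not None:
        ds = make_dataset(config.generator)
        if config.out_dir:
            write_spike_events(ds, os.path.join(config.out_dir, "data"))
    else:
        ds = read_spike_events(config.data_dir)
    result = PipelineResult(ds)
    last = _STAGE_ORDER.index(through_stage)
    stages = (_stage_metrics, _stage_ei, _stage_cluster, _stage_switch,
              _stage_classify)
    for stage_fn in stages[:last + 1]:
        if stage_fn is _stage_metrics:
            stage_fn(ds, result)
        else:
            stage_fn(ds, config, result)
    _summarize(config, result)
    if config.out_dir:
        _write_outputs(config, result)
    return result
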