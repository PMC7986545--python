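"""Extraction-index arithmetic, profiles, surrogates, and selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import noisecat as nc
from noisecat import synth

from conftest import flat_recording


class TestCosineDistance:
    def test_identity_and_orthogonality(self):
        assert nc.cosine_distance([2, 1, 3], [2, 1, 3]) == pytest.approx(0.0)
        assert nc.cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_known_value(self):
        assert nc.cosine_distance([1, 0], [1, 1]) == pytest.approx(
            1 - 1 / np.sqrt(2))

    def test_zero_vector_policy(self):
        assert nc.cosine_distance([0, 0], [1, 2]) == 1.0
        assert np.isnan(nc.cosine_distance([0, 0], [0, 0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nc.cosine_distance([1, 2], [1, 2, 3])


class TestExtractionIndex:
    def test_clean_match_gives_plus_one(self):
        assert nc.extraction_index([2, 1], [2, 1], [1, 3]) == pytest.approx(1.0)

    def test_noise_match_gives_minus_one(self):
        assert nc.extraction_index([1, 3], [2, 1], [1, 3]) == pytest.approx(-1.0)

    def test_known_mixture_value(self):
        # P_v=(1,0), P_n=(0,1), P_snr=(2,1):
        # D_n = 1 - 1/sqrt(5), D_v = 1 - 2/sqrt(5) -> EI ~ 0.679
        d_n = 1 - 1 / np.sqrt(5)
        d_v = 1 - 2 / np.sqrt(5)
        expected = (d_n - d_v) / (d_n + d_v)
        assert nc.extraction_index([2, 1], [1, 0], [0, 1]) == pytest.approx(expected)
        assert expected == pytest.approx(0.679, abs=5e-4)

    def test_bin_mismatch_rejected(self):
        a = nc.PSTH([1.0, 2.0], 0.004, (0.0, 0.008))
        b = nc.PSTH([1.0, 2.0], 0.008, (0.0, 0.016))
        with pytest.raises(ValueError):
            nc.extraction_index(a, a, b)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(deadline=None, max_examples=100)
    def test_antisymmetry_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        p_v, p_n, p_snr = rng.uniform(0.01, 1.0, (3, 16))
        ei = nc.extraction_index(p_snr, p_v, p_n)
        assert -1.0 <= ei <= 1.0
        assert nc.extraction_index(p_snr, p_n, p_v) == pytest.approx(-ei)
        for c in (0.5, 3.0):
            assert nc.extraction_index(c * p_snr, p_v, p_n) == pytest.approx(ei)
            assert nc.extraction_index(p_snr, c * p_v, p_n) == pytest.approx(ei)

    def test_monotone_in_mixing_weight(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p_v, p_n = rng.uniform(0.0, 1.0, (2, 12))
            lams = np.linspace(0.0, 1.0, 11)
            eis = [nc.extraction_index((1 - l) * p_n + l * p_v, p_v, p_n)
                   for l in lams]
            assert np.all(np.diff(eis) > 0)


class TestEIProfile:
    def test_pure_signal_recording_scores_high(self, protocol):
        arch = nc.CategoryArchetype("signal-like", (1.0,) * 3, (0.0,) * 3,
                                    response_gain_hz=80.0, trial_gain_cv=0.0,
                                    jitter_sd_s=0.0)
        rec = synth.make_recording("r", "CNIC",
                                   {nt: arch for nt in protocol.noise_types},
                                   protocol, np.random.default_rng(5), False)
        prof = nc.ei_profile(rec, protocol)
        assert all(v > 0.5 for v in prof.ei.values())

    def test_pure_masker_recording_scores_negative(self, protocol):
        arch = nc.CategoryArchetype("masker-like", (0.0,) * 3, (1.0,) * 3,
                                    response_gain_hz=80.0, trial_gain_cv=0.0,
                                    jitter_sd_s=0.0)
        rec = synth.make_recording("r", "CN",
                                   {nt: arch for nt in protocol.noise_types},
                                   protocol, np.random.default_rng(6), False)
        prof = nc.ei_profile(rec, protocol)
        assert all(v < 0 for v in prof.ei.values())

    def test_silent_recording_undefined_everywhere(self, protocol):
        arch = nc.CategoryArchetype("insensitive", (0.5,) * 3, (0.5,) * 3,
                                    baseline_rate_hz=0.0, response_gain_hz=0.0)
        rec = synth.make_recording("r", "CN",
                                   {nt: arch for nt in protocol.noise_types},
                                   protocol, np.random.default_rng(7), False)
        prof = nc.ei_profile(rec, protocol)
        assert all(np.isnan(v) for v in prof.ei.values())
        assert not prof.all_defined and not prof.any_significant


class TestSurrogates:
    def test_thresholds_deterministic_given_seed(self, protocol, voc_dataset):
        rec = voc_dataset.recordings[0]
        t1 = nc.surrogate_thresholds(rec, protocol, 20, seed=3)
        t2 = nc.surrogate_thresholds(rec, protocol, 20, seed=3)
        assert t1 == t2
        t3 = nc.surrogate_thresholds(rec, protocol, 20, seed=4)
        assert t1 != t3

    def test_minimum_surrogate_count_enforced(self, protocol, voc_dataset):
        with pytest.raises(ValueError):
            nc.surrogate_thresholds(voc_dataset.recordings[0], protocol, 1)

    def test_structured_recording_clears_threshold(self, protocol):
        hits = 0
        ds = nc.make_dataset(nc.GeneratorConfig(
            protocol=protocol,
            specs=[nc.RecordingSpec("CNIC", "signal-like", "signal-like", 10)],
            include_tones=False, seed=31))
        for i, rec in enumerate(ds):
            prof = nc.ei_profile(rec, protocol)
            prof.surrogate_threshold = nc.surrogate_thresholds(
                rec, protocol, 100, seed=i)
            hits += prof.any_significant
        assert hits >= 9  # ~95% power expected on strongly modulated responses

    def test_silent_recording_thresholds_undefined(self, protocol):
        arch = nc.CategoryArchetype("insensitive", (0.5,) * 3, (0.5,) * 3,
                                    baseline_rate_hz=0.0, response_gain_hz=0.0)
        rec = synth.make_recording("r", "CN",
                                   {nt: arch for nt in protocol.noise_types},
                                   protocol, np.random.default_rng(8), False)
        thr = nc.surrogate_thresholds(rec, protocol, 20, seed=0)
        assert all(np.isnan(v) for v in thr.values())


@pytest.fixture(scope="module")
def computed(voc_dataset):
    protocol = voc_dataset.protocol
    profiles, voc_sig = {}, {}
    rng = np.random.default_rng(0)
    for rec in voc_dataset:
        prof = nc.ei_profile(rec, protocol)
        prof.surrogate_threshold = nc.surrogate_thresholds(
            rec, protocol, 50, seed=int(rng.integers(2 ** 31)))
        profiles[rec.recording_id] = prof
        voc_sig[rec.recording_id] = any(
            nc.response_significant(rec.blocks[protocol.clean_condition(v)])[0]
            for v in protocol.vocalization_ids)
    tfrp_sig = {rec.recording_id: True for rec in voc_dataset}
    return profiles, voc_sig, tfrp_sig


class TestSelection:
    def test_criterion_a_superset_of_b(self, voc_dataset, computed):
        profiles, voc_sig, tfrp_sig = computed
        # make the two criteria differ for some recordings
        mixed = dict(tfrp_sig)
        for rid in list(mixed)[::3]:
            mixed[rid] = False
        a = nc.select_recordings(voc_dataset, profiles, voc_sig, mixed, "a")
        b = nc.select_recordings(voc_dataset, profiles, voc_sig, mixed, "b")
        assert set(b.selected_ids) <= set(a.selected_ids)

    def test_counts_table_layout(self, voc_dataset, computed):
        profiles, voc_sig, tfrp_sig = computed
        report = nc.select_recordings(voc_dataset, profiles, voc_sig, tfrp_sig)
        assert report.counts.loc["tested", "Total"] == len(voc_dataset)
        stage_totals = report.counts["Total"].to_numpy()
        assert np.all(np.diff(stage_totals[:3]) <= 0)  # cascade only removes

    def test_structureless_recordings_mostly_rejected(self, protocol):
        profiles, voc_sig = {}, {}
        recs = []
        for i in range(30):
            rec = flat_recording(protocol, seed=i)
            recs.append(rec)
            prof = nc.ei_profile(rec, protocol)
            prof.surrogate_threshold = nc.surrogate_thresholds(
                rec, protocol, 100, seed=i)
            profiles[rec.recording_id] = prof
            voc_sig[rec.recording_id] = True
        ds = nc.Dataset(protocol, recs)
        report = nc.select_recordings(ds, profiles, voc_sig, None, "a")
        frac = report.counts.loc["EI significant vs surrogate", "Total"] / 30
        assert frac <= 0.20
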