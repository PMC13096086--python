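import itertools

import numpy as np
import pytest

from freqstate import Recording, SyntheticSpec, sample_state_sequence, \
    spatial_correlation, synthesize_recording
from freqstate.backfit import (CanonicalTemplateSet, LabelSequence, UNASSIGNED,
                               backfit, canonical_templates, compute_iev,
                               compute_metrics, mean_maps, metrics_with_iev,
                               sort_by_template)
from freqstate.microstates import MicrostateModel, compute_gev
from freqstate.synthetic import _sequence_stats


def _model_from(maps, labels=()):
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps = maps / np.linalg.norm(maps, axis=1, keepdims=True)
    return MicrostateModel(maps=maps, labels=tuple(labels))


class TestCanonicalTemplates:
    def test_seven_labeled_unit_norm(self, layout60):
        tset = canonical_templates(layout60)
        assert tset.labels == ("A", "B", "C", "D", "E", "F", "G")
        np.testing.assert_allclose(np.linalg.norm(tset.maps, axis=1), 1,
                                   atol=1e-12)
        np.testing.assert_allclose(tset.maps.mean(axis=1), 0, atol=1e-12)

    def test_mutually_distinct(self, layout60):
        tset = canonical_templates(layout60)
        for i in range(7):
            for j in range(i + 1, 7):
                assert abs(spatial_correlation(tset.maps[i],
                                               tset.maps[j])) < 0.95


class TestMeanMaps:
    def test_idempotent_on_identical_inputs(self, layout20, templates4):
        m = _model_from(templates4)
        avg = mean_maps([m, m, m])
        for k in range(4):
            assert abs(avg.maps[k] @ m.maps[k]) > 1 - 1e-12

    def test_polarity_alignment(self, templates4):
        m1 = _model_from(templates4)
        m2 = _model_from(-templates4)
        avg = mean_maps([m1, m2])
        for k in range(4):
            assert abs(avg.maps[k] @ m1.maps[k]) > 1 - 1e-12

    def test_averaging_beats_individuals(self, templates4):
        # 21 noisy copies at SNR 10: the average correlates with truth
        # better than the median individual does
        rng = np.random.default_rng(0)
        models = []
        indiv_r = []
        for _ in range(21):
            noisy = templates4 + rng.normal(size=templates4.shape) / np.sqrt(10 * 20)
            m = _model_from(noisy)
            models.append(m)
            indiv_r.append(np.mean([abs(spatial_correlation(m.maps[k],
                                                            templates4[k]))
                                    for k in range(4)]))
        avg = mean_maps(models)
        avg_r = np.mean([abs(spatial_correlation(avg.maps[k], templates4[k]))
                         for k in range(4)])
        assert avg_r > np.median(indiv_r)

    def test_mismatched_k(self, templates4):
        with pytest.raises(ValueError):
            mean_maps([_model_from(templates4), _model_from(templates4[:3])])


class TestSortByTemplate:
    def test_permuted_templates_recovered(self, layout60):
        tset = canonical_templates(layout60)
        perm = [3, 0, 6, 2, 5, 1, 4]
        model = MicrostateModel(maps=tset.maps[perm])
        sorted_model, corr = sort_by_template(model, tset)
        assert sorted_model.labels == tset.labels
        np.testing.assert_allclose(corr, 1.0, atol=1e-9)
        np.testing.assert_allclose(sorted_model.maps, tset.maps, atol=1e-9)

    def test_sign_flips_corrected(self, layout60):
        tset = canonical_templates(layout60)
        flip = np.array([1, -1, 1, -1, -1, 1, -1])[:, None]
        model = MicrostateModel(maps=tset.maps * flip)
        sorted_model, corr = sort_by_template(model, tset)
        np.testing.assert_allclose(sorted_model.maps, tset.maps, atol=1e-9)

    def test_matches_factorial_enumeration(self, layout20):
        # brute force over all 4! pairings of |r| sums
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(4, 20))
        model = _model_from(raw)
        tmaps = _model_from(rng.normal(size=(4, 20))).maps
        tset = CanonicalTemplateSet(labels=("A", "B", "C", "D"), maps=tmaps,
                                    layout=layout20)
        corr = model.maps @ tmaps.T
        best_perm, best_sum = None, -np.inf
        for perm in itertools.permutations(range(4)):
            s = sum(abs(corr[r, c]) for r, c in enumerate(perm))
            if s > best_sum:
                best_sum, best_perm = s, perm
        sorted_model, scorr = sort_by_template(model, tset)
        assert scorr.sum() == pytest.approx(best_sum, abs=1e-12)

    def test_layout_mismatch(self, layout60, layout20):
        tset = canonical_templates(layout60)
        model = _model_from(np.random.default_rng(0).normal(size=(4, 20)))
        with pytest.raises(ValueError):
            sort_by_template(model, tset)


@pytest.fixture(scope="module")
def noise_free(templates4, layout20):
    spec = SyntheticSpec(n_subjects=1, n_templates=4, n_channels=20,
                         duration_s=30.0, snr=np.inf)
    labels = sample_state_sequence(spec, "wake", 5)
    rec = synthesize_recording(spec, labels, templates4, 6, layout=layout20)
    return rec, labels


class TestBackfit:

    def test_perfect_recovery_at_peaks(self, noise_free, templates4):
        rec, true_labels = noise_free
        model = _model_from(templates4, labels=("0", "1", "2", "3"))
        seq = backfit(rec, model)
        assigned = seq.labels != UNASSIGNED
        # midpoint interpolation smears boundaries between sparse peaks, so
        # sample-level agreement is high but not perfect
        agree = np.mean(seq.labels[assigned] == true_labels[assigned])
        assert agree > 0.8
        # and exactly at GFP peaks the label is always right
        from freqstate.microstates import compute_gfp
        peaks = compute_gfp(rec).peak_indices
        assert np.all(seq.labels[peaks] == true_labels[peaks])

    def test_midpoint_rule(self, layout20, templates4):
        # construct data with exactly two GFP peaks at samples 10 and 20
        T = 31
        data = np.zeros((20, T))
        # triangular envelope: unambiguous GFP maxima at samples 10 and 20
        t_ax = np.arange(T)
        env = 0.2 + np.maximum(1 - np.abs(t_ax - 10) / 5.0,
                               1 - np.abs(t_ax - 20) / 5.0).clip(0)
        lab = np.zeros(T, dtype=int)
        lab[16:] = 1
        for t in range(T):
            data[:, t] = env[t] * templates4[lab[t]]
        rec = Recording(data, 250.0, layout20)
        model = _model_from(templates4[:2])
        seq = backfit(rec, model)
        assert seq.labels[15] == seq.labels[10]
        assert seq.labels[16] == seq.labels[20]
        assert seq.labels[9] == UNASSIGNED
        assert seq.labels[21] == UNASSIGNED

    def test_polarity_inverted_recording(self, noise_free, templates4):
        rec, _ = noise_free
        model = _model_from(templates4)
        seq1 = backfit(rec, model)
        seq2 = backfit(rec.with_data(-rec.data), model)
        np.testing.assert_array_equal(seq1.labels, seq2.labels)

    def test_amplitude_scale_invariance(self, noise_free, templates4):
        rec, _ = noise_free
        model = _model_from(templates4)
        seq1 = backfit(rec, model)
        seq2 = backfit(rec.with_data(7.3 * rec.data), model)
        np.testing.assert_array_equal(seq1.labels, seq2.labels)

    def test_no_peaks_warns(self, layout20, templates4):
        rec = Recording(np.zeros((20, 100)), 250.0, layout20)
        model = _model_from(templates4)
        with pytest.warns(UserWarning):
            seq = backfit(rec, model)
        assert np.all(seq.labels == UNASSIGNED)


class TestComputeMetrics:
    def _alternating_sequence(self):
        # alternating 25-sample A/B segments over 10 s at 250 Hz
        rate = 250.0
        labels = np.tile(np.repeat([0, 1], 25), 50)
        from freqstate.backfit import _segment_runs
        segs = _segment_runs(labels, rate)
        return LabelSequence(labels=labels, rate=rate,
                             class_names=("A", "B"), segments=segs)

    def test_alternating_arithmetic(self):
        m = compute_metrics(self._alternating_sequence())
        np.testing.assert_allclose(m.duration_ms, [100.0, 100.0])
        np.testing.assert_allclose(m.occurrence_per_s, 5.0, rtol=0.03)
        np.testing.assert_allclose(m.coverage, 0.5, atol=0.01)

    def test_coverage_denominator_excludes_truncated(self):
        rate = 250.0
        labels = np.concatenate([np.full(100, 0), np.full(50, 2),
                                 np.full(850, 1)])
        from freqstate.backfit import _segment_runs
        segs = _segment_runs(labels, rate)
        seq = LabelSequence(labels=labels, rate=rate,
                            class_names=("A", "B", "C"), segments=segs)
        m = compute_metrics(seq)
        # only the class-C segment survives exclusion
        np.testing.assert_allclose(m.coverage, [0.0, 0.0, 1.0])
        np.testing.assert_allclose(m.duration_ms[2], 50 / rate * 1000)
        assert np.isnan(m.duration_ms[0])
        assert m.occurrence_per_s[0] == 0.0

    def test_coverage_sums_to_one(self, small_cohort, templates4):
        recs, _ = small_cohort
        model = _model_from(templates4)
        rec = recs[("S01", "wake")]
        seq = backfit(rec, model)
        m = compute_metrics(seq)
        np.testing.assert_allclose(m.coverage.sum(), 1.0, atol=1e-12)

    def test_coverage_occurrence_duration_identity(self, small_cohort,
                                                   templates4):
        recs, _ = small_cohort
        model = _model_from(templates4)
        seq = backfit(recs[("S02", "LOC")], model)
        m = compute_metrics(seq)
        est = m.occurrence_per_s * m.duration_ms / 1000.0
        np.testing.assert_allclose(est, m.coverage, atol=0.05)

    def test_recovers_generator_statistics(self, layout20, templates4):
        spec = SyntheticSpec(n_subjects=1, n_templates=4, n_channels=20,
                             duration_s=300.0, snr=np.inf)
        true = sample_state_sequence(spec, "wake", 2)
        rec = synthesize_recording(spec, true, templates4, 3, layout=layout20)
        model = _model_from(templates4)
        seq = backfit(rec, model)
        m = compute_metrics(seq)
        dwell, occ, cov = _sequence_stats(true, spec.rate, 4)
        np.testing.assert_allclose(m.coverage, cov, rtol=0.02, atol=0.005)
        # durations carry a small upward bias from midpoint interpolation
        np.testing.assert_allclose(m.duration_ms, dwell, rtol=0.10)


class TestIev:
    def test_partition_of_gev(self, small_cohort, templates4):
        recs, _ = small_cohort
        rec = recs[("S01", "wake")]
        model = _model_from(templates4)
        seq = backfit(rec, model)
        iev = compute_iev(rec, model, seq)
        from freqstate.microstates import compute_gfp
        data = rec.data - rec.data.mean(axis=0, keepdims=True)
        gfp = compute_gfp(rec)
        peak_maps = data[:, gfp.peak_indices].T
        gev, _ = compute_gev(model, peak_maps,
                             gfp_at_peaks=gfp.values[gfp.peak_indices],
                             assignment=seq.labels[gfp.peak_indices])
        assert iev.sum() == pytest.approx(gev, abs=1e-12)

    def test_single_class_gets_all(self, layout20):
        rng = np.random.default_rng(0)
        base = rng.normal(size=20)
        base -= base.mean()
        base /= np.linalg.norm(base)
        env = 1 + 0.5 * np.sin(2 * np.pi * 10 * np.arange(500) / 250)
        data = np.outer(base, env)
        rec = Recording(data, 250.0, layout20)
        other = rng.normal(size=20)
        other -= other.mean()
        other -= (other @ base) * base
        other /= np.linalg.norm(other)
        model = MicrostateModel(maps=np.vstack([base, other]))
        seq = backfit(rec, model)
        iev = compute_iev(rec, model, seq)
        assert iev[0] == pytest.approx(1.0, abs=1e-9)
        assert iev[1] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_classes_equal_iev(self, layout20, templates4):
        spec = SyntheticSpec(n_subjects=1, n_templates=2, n_channels=20,
                             duration_s=120.0, snr=6.0)
        labels = sample_state_sequence(spec, "wake", 4)
        rec = synthesize_recording(spec, labels, templates4[:2], 5,
                                   layout=layout20)
        model = _model_from(templates4[:2])
        seq = backfit(rec, model)
        iev = compute_iev(rec, model, seq)
        assert abs(iev[0] - iev[1]) < 0.1
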