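"""Detection/delineation scoring against brute-force enumeration, plus
observer-bias estimator checks."""

import numpy as np
import pytest

from ecgdelnet import (ECGRecord, FiducialSet, SimulationSpec, correspondence_matrix,
                       delineation_errors, detection_counts, dice_score, fuse_leads,
                       generate_record, interobserver_bias, intraobserver_bias)
from ecgdelnet.ecg_io import WaveFiducials
from ecgdelnet.evaluation import DetectionMetrics, WaveErrors
from ecgdelnet.mask_codec import SegmentationMask
from conftest import random_wave_list


def brute_force_H(true_waves, pred_waves):
    """Literal membership transcription: any fiducial of one wave inside the
    closed [on, off] interval of the other."""
    H = np.zeros((len(true_waves), len(pred_waves)), dtype=int)
    for i, t in enumerate(true_waves):
        for j, p in enumerate(pred_waves):
            hit = False
            for fid in (p.on, p.peak, p.off):
                if t.on <= fid <= t.off:
                    hit = True
            for fid in (t.on, t.peak, t.off):
                if p.on <= fid <= p.off:
                    hit = True
            H[i, j] = int(hit)
    return H


def brute_force_counts(H):
    matched_rows = {i for i, j in zip(*np.nonzero(H))}
    matched_cols = {j for i, j in zip(*np.nonzero(H))}
    return (len(matched_rows), H.shape[1] - len(matched_cols),
            H.shape[0] - len(matched_rows))


def brute_force_errors(per_lead, fs):
    """Per matched true wave, minimal-|.|(true - predicted) over leads and
    matched predictions, via full enumeration."""
    ms = 1000.0 / fs
    n = per_lead[0][2].shape[0]
    onsets, offsets = [], []
    for i in range(n):
        cand = []
        for true_w, pred_w, H in per_lead:
            for j in range(H.shape[1]):
                if H[i, j]:
                    cand.append(((true_w[i].on - pred_w[j].on) * ms,
                                 (true_w[i].off - pred_w[j].off) * ms))
        if cand:
            onsets.append(min((c[0] for c in cand), key=abs))
            offsets.append(min((c[1] for c in cand), key=abs))
    return onsets, offsets


class TestCorrespondence:
    def test_identity_on_equal_lists(self):
        waves = [WaveFiducials(10, 15, 20), WaveFiducials(40, 44, 50)]
        assert np.array_equal(correspondence_matrix(waves, waves), np.eye(2))

    def test_disjoint_intervals_do_not_match(self):
        t = [WaveFiducials(10, 15, 20)]
        p = [WaveFiducials(21, 25, 30)]
        assert correspondence_matrix(t, p).sum() == 0

    def test_unordered_input_rejected(self):
        waves = [WaveFiducials(40, 44, 50), WaveFiducials(10, 15, 20)]
        with pytest.raises(ValueError, match="ordered"):
            correspondence_matrix(waves, waves)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(60, 200))
            t = random_wave_list(rng, n)
            p = random_wave_list(rng, n)
            assert np.array_equal(correspondence_matrix(t, p), brute_force_H(t, p))


class TestFusion:
    def test_single_lead_identity(self):
        H = np.array([[1, 0], [0, 1]])
        assert np.array_equal(fuse_leads([H]), H)

    def test_or_semantics_rescues_missed_wave(self):
        a = np.array([[1, 0], [0, 0]])
        b = np.array([[0, 0], [0, 1]])
        fused = fuse_leads([a, b])
        assert detection_counts(fused).tp == 2

    def test_commutative_associative(self):
        rng = np.random.default_rng(1)
        ms = [rng.integers(0, 2, size=(3, 4)) for _ in range(3)]
        f1 = fuse_leads(ms)
        f2 = fuse_leads(ms[::-1])
        f3 = fuse_leads([fuse_leads(ms[:2]), ms[2]])
        assert np.array_equal(f1, f2) and np.array_equal(f1, f3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_leads([np.zeros((2, 2)), np.zeros((2, 3))])


class TestDetectionCounts:
    def test_perfect_prediction(self):
        m = detection_counts(np.eye(4, dtype=int))
        assert (m.tp, m.fp, m.fn) == (4, 0, 0)
        assert m.precision == m.recall == m.f1 == 1.0

    def test_partial_match_hand_case(self):
        H = np.array([[1, 0], [0, 1], [0, 0]])  # M=3 true, 2 predicted, 2 matched
        m = detection_counts(H)
        assert (m.tp, m.fp, m.fn) == (2, 0, 1)
        assert m.precision == 1.0 and m.recall == pytest.approx(2 / 3)

    def test_empty_prediction_convention(self):
        m = detection_counts(np.zeros((5, 0), dtype=int))
        assert (m.tp, m.fp, m.fn) == (0, 0, 5)
        assert m.precision == 1.0  # nothing predicted, nothing false
        assert m.recall == 0.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            H = (rng.random((rng.integers(0, 6), rng.integers(0, 6))) < 0.3).astype(int)
            m = detection_counts(H)
            assert (m.tp, m.fp, m.fn) == brute_force_counts(H)

    def test_fusion_monotonicity(self):
        """Adding a lead can never decrease TP nor increase FN."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = (rng.random((4, 4)) < 0.3).astype(int)
            b = (rng.random((4, 4)) < 0.3).astype(int)
            m_a = detection_counts(a)
            m_ab = detection_counts(fuse_leads([a, b]))
            assert m_ab.tp >= m_a.tp and m_ab.fn <= m_a.fn


class TestDelineationErrors:
    def test_identity_gives_zero_errors(self):
        waves = [WaveFiducials(10, 15, 20)]
        H = correspondence_matrix(waves, waves)
        e = delineation_errors([(waves, waves, H)], 250.0)
        assert e.onset_mean_ms == 0.0 and e.offset_sd_ms == 0.0

    def test_sign_convention_true_minus_predicted(self):
        t = [WaveFiducials(100, 105, 110)]
        p = [WaveFiducials(102, 107, 112)]  # predicted 2 samples late
        e = delineation_errors([(t, p, correspondence_matrix(t, p))], 250.0)
        assert e.onset_ms == [-8.0]
        assert e.offset_ms == [-8.0]

    def test_min_over_leads_picks_closer_lead(self):
        t = [WaveFiducials(100, 105, 110)]
        p_far = [WaveFiducials(95, 104, 109)]
        p_near = [WaveFiducials(99, 105, 110)]
        per_lead = [(t, p_far, correspondence_matrix(t, p_far)),
                    (t, p_near, correspondence_matrix(t, p_near))]
        e = delineation_errors(per_lead, 250.0)
        assert e.onset_ms == [4.0]

    def test_no_matches_yields_empty_report(self):
        t = [WaveFiducials(10, 15, 20)]
        p = [WaveFiducials(50, 55, 60)]
        e = delineation_errors([(t, p, correspondence_matrix(t, p))], 250.0)
        assert e.n == 0 and np.isnan(e.onset_mean_ms)

    def test_matches_brute_force_on_random_cases(self):
        rng = np.random.default_rng(4)
        fs = 250.0
        for _ in range(200):
            n = int(rng.integers(80, 200))
            t = random_wave_list(rng, n)
            if not t:
                continue
            per_lead = []
            for _ in range(int(rng.integers(1, 3))):
                p = random_wave_list(rng, n)
                per_lead.append((t, p, correspondence_matrix(t, p)))
            e = delineation_errors(per_lead, fs)
            on_bf, off_bf = brute_force_errors(per_lead, fs)
            assert e.onset_ms == on_bf and e.offset_ms == off_bf

    def test_errors_are_multiples_of_sample_period(self):
        rng = np.random.default_rng(5)
        t = random_wave_list(rng, 300)
        p = random_wave_list(rng, 300)
        e = delineation_errors([(t, p, correspondence_matrix(t, p))], 250.0)
        for v in e.onset_ms + e.offset_ms:
            assert v % 4.0 == 0.0


class TestDice:
    def test_identical_masks(self):
        v = (np.random.default_rng(0).random((50, 3)) > 0.5).astype(float)
        m = SegmentationMask(v, 250.0)
        assert np.allclose(dice_score(m, m), 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((20, 3))
        b = np.zeros((20, 3))
        a[:10] = 1.0
        b[10:] = 1.0
        d = dice_score(SegmentationMask(a, 250.0), SegmentationMask(b, 250.0))
        assert np.allclose(d, 0.0)

    def test_hand_counted_overlap(self):
        a = np.zeros((20, 3))
        b = np.zeros((20, 3))
        a[0:6, 1] = 1.0  # 6 samples
        b[2:8, 1] = 1.0  # 6 samples, 4 shared
        d = dice_score(SegmentationMask(a, 250.0), SegmentationMask(b, 250.0))
        assert d[1] == pytest.approx(2 * 4 / 12)
        assert d[0] == 1.0  # both empty

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_score(SegmentationMask(np.zeros((10, 3)), 250.0),
                       SegmentationMask(np.zeros((12, 3)), 250.0))


class TestInterObserver:
    def test_identical_observers_give_zero(self, small_record):
        _, fids = small_record
        report = interobserver_bias(fids, fids, 250.0)
        for wave, e in report.errors.items():
            assert e.onset_mean_ms == 0.0 and e.offset_sd_ms == 0.0

    def test_constant_shift_recovered(self, small_record):
        _, fids = small_record
        shifted = FiducialSet(record_id=fids.record_id, leads=[
            [{w: WaveFiducials(wf.on + 1, wf.peak + 1, wf.off + 1)
              for w, wf in beat.items()} for beat in beats]
            for beats in fids.leads])
        report = interobserver_bias(fids, shifted, 250.0)
        q = report.errors["QRS"]
        assert q.onset_mean_ms == pytest.approx(-4.0)
        assert q.onset_sd_ms == pytest.approx(0.0)

    def test_wave_missing_from_one_observer_is_skipped(self, small_record):
        _, fids = small_record
        no_p = FiducialSet(record_id=fids.record_id, leads=[
            [{w: wf for w, wf in beat.items() if w != "P"} for beat in beats]
            for beats in fids.leads])
        report = interobserver_bias(fids, no_p, 250.0)
        assert "P" not in report.errors
        assert "QRS" in report.errors

    def test_gaussian_jitter_parameters_recovered(self):
        """Injected N(delta, sigma^2) boundary jitter is recovered by the
        estimator within Monte-Carlo tolerance."""
        spec = SimulationSpec(n_subjects=1, duration=120.0, seed=31,
                              missing_p_probability=0.0)
        _, fids = generate_record(spec)
        rng = np.random.default_rng(7)
        delta, sigma = 2.0, 1.5  # samples
        leads = []
        for beats in fids.leads:
            out = []
            for beat in beats:
                nb = {}
                for w, wf in beat.items():
                    d_on = int(round(rng.normal(delta, sigma)))
                    d_off = int(round(rng.normal(delta, sigma)))
                    nb[w] = WaveFiducials(wf.on - d_on, wf.peak, max(wf.peak, wf.off - d_off))
                out.append(nb)
            leads.append(out)
        o2 = FiducialSet(record_id=fids.record_id, leads=leads)
        report = interobserver_bias(fids, o2, 250.0)
        ms = 4.0
        pooled_on = np.concatenate([report.errors[w].onset_ms for w in report.errors])
        assert abs(np.mean(pooled_on) - delta * ms) < 1.5
        assert abs(np.std(pooled_on) - sigma * ms) < 2.0


class TestIntraObserver:
    def test_duplicate_morphology_with_offset_shift(self):
        """Two copies of one wave whose annotated offsets differ by 8 ms are
        matched (correlation 1) and contribute an 8 ms offset difference."""
        fs = 250.0
        wave = np.exp(-0.5 * ((np.arange(40) - 20) / 4.0) ** 2)
        signal = np.zeros(600)
        signal[100:140] = wave
        signal[400:440] = wave
        record = ECGRecord("x", fs, signal[:, None])
        fids = FiducialSet("x", leads=[[
            {"QRS": WaveFiducials(110, 120, 130)},
            {"QRS": WaveFiducials(410, 420, 432)},  # offset 2 samples (8 ms) later
        ]])
        report = intraobserver_bias(fids, record)
        q = report.errors["QRS"]
        assert q.n == 1
        assert q.offset_ms == [-8.0]
        assert q.onset_ms == [0.0]

    def test_pure_noise_segments_rarely_match(self):
        rng = np.random.default_rng(0)
        fs = 250.0
        record = ECGRecord("x", fs, rng.normal(size=(4000, 1)))
        beats = []
        for start in range(100, 3800, 250):
            beats.append({"T": WaveFiducials(start, start + 10, start + 20)})
        fids = FiducialSet("x", leads=[beats])
        report = intraobserver_bias(fids, record)
        n_pairs = len(beats) * (len(beats) - 1) // 2
        matched = report.errors["T"].n if "T" in report.errors else 0
        assert matched / n_pairs < 0.05

    def test_wave_paired_with_itself_is_exact(self):
        fs = 250.0
        sig = np.sin(np.arange(300) / 5.0)
        record = ECGRecord("x", fs, sig[:, None])
        fids = FiducialSet("x", leads=[[
            {"T": WaveFiducials(50, 60, 70)}, {"T": WaveFiducials(50 + 157, 60 + 157, 70 + 157)}]])
        # sine has period 2*pi*5 ~ 31.4 samples: second wave placed 5 periods on
        report = intraobserver_bias(fids, record)
        if "T" in report.errors:
            assert max(abs(v) for v in report.errors["T"].onset_ms) <= 4.0


def test_report_identity_on_perfect_prediction(small_record):
    from ecgdelnet.evaluation import evaluate
    record, fids = small_record
    pred = [list(beats) for beats in fids.leads]
    report = evaluate(pred, fids, record)
    for wave in ("P", "QRS", "T"):
        m = report.detection[wave]
        assert m.precision == m.recall == 1.0
        assert report.errors[wave].onset_mean_ms == 0.0
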