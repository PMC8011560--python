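"""L2-norm target-peak selection, non-target screening and templates."""

import numpy as np
import pytest

from mrmscreen.annotate import (
    AnnotatedPeak,
    build_template,
    default_scaling,
    eq_l2_score,
    find_nontarget_peaks,
    select_target_peaks,
)
from mrmscreen.io_mrm import CalibrationTable
from mrmscreen.peakfit import FittedPeak


def peak(rt, height=100.0, width=0.03, channel=1, sample="S01"):
    return FittedPeak(
        amplitude=height, centroid=rt, width=width, channel_id=channel, sample_id=sample
    )


SCALING = (1000.0, 100.0)
EPS = 0.005


class TestScore:
    def test_closer_rt_scores_higher(self):
        near, far = peak(5.01), peak(5.20)
        assert eq_l2_score(near, 5.0, SCALING, EPS) > eq_l2_score(far, 5.0, SCALING, EPS)

    def test_larger_peak_scores_higher_at_equal_distance(self):
        small, big = peak(5.1, height=50.0), peak(5.1, height=500.0)
        assert eq_l2_score(big, 5.0, SCALING, EPS) > eq_l2_score(small, 5.0, SCALING, EPS)

    def test_monotonicity_on_random_triples(self, rng):
        for _ in range(200):
            rt = float(rng.uniform(4, 6))
            h = float(rng.uniform(10, 900))
            r_j = 5.0
            base = peak(rt, height=h)
            if abs(rt - r_j) > EPS:
                closer = peak(r_j + (rt - r_j) * 0.5, height=h)
                assert eq_l2_score(closer, r_j, SCALING, EPS) > eq_l2_score(base, r_j, SCALING, EPS)
            taller = peak(rt, height=h * 1.5)
            assert eq_l2_score(taller, r_j, SCALING, EPS) > eq_l2_score(base, r_j, SCALING, EPS)
            wider = peak(rt, height=h, width=0.06)  # larger area at equal height
            assert eq_l2_score(wider, r_j, SCALING, EPS) > eq_l2_score(base, r_j, SCALING, EPS)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            eq_l2_score(peak(5.0), 5.0, (0.0, 1.0), EPS)

    def test_default_scaling_uses_calibration_maxima(self):
        peaks = [peak(5.0, height=100.0), peak(6.0, height=300.0, width=0.06)]
        hs, as_ = default_scaling(peaks)
        assert hs == 300.0
        assert as_ == pytest.approx(max(p.area for p in peaks))


class TestSelectTargetPeaks:
    CALIB = CalibrationTable.from_rows([(1, "PCB 1", 1, 5.0), (2, "PCB 2", 1, 8.0)])

    def test_singleton_selected(self):
        p = peak(5.4)
        out = select_target_peaks([(p, 1)], self.CALIB, SCALING, EPS)
        assert len(out) == 1 and out[0].peak is p

    def test_empty_input(self):
        assert select_target_peaks([], self.CALIB, SCALING, EPS) == []

    def test_argmax_matches_exhaustive_scoring(self, rng):
        for _ in range(20):
            cands = [
                peak(float(rng.uniform(4.5, 5.5)), height=float(rng.uniform(10, 900)),
                     width=float(rng.uniform(0.01, 0.08)))
                for _ in range(20)
            ]
            out = select_target_peaks([(p, 1) for p in cands], self.CALIB, SCALING, EPS)
            scores = [eq_l2_score(p, 5.0, SCALING, EPS) for p in cands]
            assert out[0].score == pytest.approx(max(scores))

    def test_one_annotation_per_class(self, rng):
        classified = [
            (peak(float(rng.uniform(4, 9))), int(rng.integers(1, 3))) for _ in range(30)
        ]
        out = select_target_peaks(classified, self.CALIB, SCALING, EPS)
        keys = [(a.sample_id, a.class_id) for a in out]
        assert len(keys) == len(set(keys))

    def test_taller_nearer_true_target_wins_under_coelution(self, rng):
        wins = 0
        for s in range(100):
            r = np.random.default_rng(s)
            target = peak(5.0 + float(r.normal(0, 0.003)), height=500.0)
            shadow = peak(5.06 + float(r.normal(0, 0.003)), height=200.0)
            out = select_target_peaks(
                [(shadow, 1), (target, 1)], self.CALIB, SCALING, EPS
            )
            wins += out[0].peak is target
        assert wins >= 95

    def test_unknown_class_skipped(self):
        out = select_target_peaks([(peak(5.0), 99)], self.CALIB, SCALING, EPS)
        assert out == []


class TestFindNonTargets:
    CALIB = CalibrationTable.from_rows([(1, "PCB 1", 1, 5.0)])

    def _world(self, n_samples=10, interferent_in=9, interferent_rt=5.12):
        classified = {}
        annotated = []
        for i in range(n_samples):
            sid = f"S{i:02d}"
            target = peak(5.0, height=500.0, sample=sid)
            pairs = [(target, 1)]
            if i < interferent_in:
                pairs.append((peak(interferent_rt, height=150.0, sample=sid), 1))
            classified[sid] = pairs
            annotated.append(AnnotatedPeak(class_id=1, sample_id=sid, peak=target, score=1.0))
        return classified, annotated

    def test_no_residual_peaks(self):
        classified, annotated = self._world(interferent_in=0)
        assert find_nontarget_peaks(classified, annotated, 0.015, 0.5) == []

    def test_planted_interferent_reported(self):
        classified, annotated = self._world()
        out = find_nontarget_peaks(classified, annotated, 0.015, 0.5)
        assert len(out) == 1
        nt = out[0]
        assert nt.associated_class_id == 1
        assert nt.occurrence_fraction == pytest.approx(0.9)
        assert nt.mean_rt == pytest.approx(5.12, abs=0.015)

    def test_occurrence_threshold_excludes(self):
        classified, annotated = self._world()
        assert find_nontarget_peaks(classified, annotated, 0.015, 0.95) == []

    def test_clusters_never_contain_annotated_peaks(self):
        classified, annotated = self._world()
        selected = {a.peak for a in annotated}
        for nt in find_nontarget_peaks(classified, annotated, 0.015, 0.1):
            assert not selected & set(nt.member_peaks)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            find_nontarget_peaks({"S01": []}, [], 0.015, 0.5)


class TestTemplates:
    LOCS = {"S01": "A", "S02": "A", "S03": "B"}

    def _ann(self, sid, cid, height):
        return AnnotatedPeak(
            class_id=cid, sample_id=sid, peak=peak(5.0, height=height, sample=sid), score=1.0
        )

    def test_single_sample_template_is_its_heights(self):
        t = build_template([self._ann("S03", 1, 120.0)], "B", self.LOCS)
        assert t.n_samples == 1
        assert t.intensities == {1: 120.0}

    def test_identical_samples_idempotent(self):
        ann = [self._ann("S01", 1, 80.0), self._ann("S02", 1, 80.0)]
        t = build_template(ann, "A", self.LOCS)
        assert t.intensities[1] == pytest.approx(80.0)

    def test_mean_counts_absent_samples_as_zero(self):
        # class 1 present only in S01 of location A's two samples
        t = build_template([self._ann("S01", 1, 100.0)], "A", self.LOCS)
        assert t.intensities[1] == pytest.approx(50.0)

    def test_matches_brute_force_mean(self, rng):
        locs = {f"S{i:02d}": "A" for i in range(5)}
        ann, sums = [], {}
        for i in range(5):
            for cid in range(1, 4):
                if rng.uniform() < 0.7:
                    h = float(rng.uniform(10, 500))
                    ann.append(self._ann(f"S{i:02d}", cid, h))
                    sums[cid] = sums.get(cid, 0.0) + h
        t = build_template(ann, "A", locs)
        for cid, total in sums.items():
            assert t.intensities[cid] == pytest.approx(total / 5.0)

    def test_concatenation_is_weighted_mean(self, rng):
        locs1 = {f"X{i}": "A" for i in range(3)}
        locs2 = {f"Y{i}": "A" for i in range(2)}
        ann1 = [self._ann(f"X{i}", 1, float(rng.uniform(10, 100))) for i in range(3)]
        ann2 = [self._ann(f"Y{i}", 1, float(rng.uniform(10, 100))) for i in range(2)]
        t1 = build_template(ann1, "A", locs1)
        t2 = build_template(ann2, "A", locs2)
        t12 = build_template(ann1 + ann2, "A", {**locs1, **locs2})
        expected = (3 * t1.intensities[1] + 2 * t2.intensities[1]) / 5
        assert t12.intensities[1] == pytest.approx(expected)

    def test_unknown_location_raises(self):
        with pytest.raises(KeyError):
            build_template([], "nowhere", self.LOCS)
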