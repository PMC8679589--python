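import numpy as np
import pytest

import tmtvkit as tk
from tmtvkit.classify import SubjectContext, sphericity
from tmtvkit.errors import DegenerateDataError
from tmtvkit.mfs import CandidateROI


def make_roi(mask: tk.VoxelMask, roi_id=1, suvmax=8.0, suvpeak=7.0):
    voxels = np.argwhere(mask.data)
    centroid = tuple(np.asarray(mask.spacing) * voxels.mean(axis=0))
    return CandidateROI(roi_id, mask, suvmax, suvpeak, mask.volume_cm3, centroid)


@pytest.fixture
def phantom_with_lesion():
    spec = tk.PhantomSpec(
        seed=6, lesions=(tk.BlobSpec.sphere((100, 80, 250), 14.0, 9.0, blur_sigma_mm=0.0),)
    ).with_default_organs()
    return tk.generate_phantom(spec)


class TestOracleClassifier:
    def test_roi_inside_lesion_is_suspicious(self, phantom_with_lesion):
        vol, truth = phantom_with_lesion
        roi = make_roi(truth.lesion_masks[0])
        out = tk.OracleClassifier().classify([roi], SubjectContext(vol, truth=truth))
        assert out[0].is_suspicious and out[0].score == 1.0

    def test_roi_inside_bladder_is_physiologic_with_site(self, phantom_with_lesion):
        vol, truth = phantom_with_lesion
        bladder = next(m for s, m in truth.organ_masks if s == "bladder")
        roi = make_roi(bladder)
        out = tk.OracleClassifier().classify([roi], SubjectContext(vol, truth=truth))
        assert not out[0].is_suspicious
        assert out[0].site is tk.AnatomicalSite.BLADDER

    def test_exactly_half_overlap_counts_as_suspicious(self, phantom_with_lesion):
        vol, truth = phantom_with_lesion
        lesion_vox = np.argwhere(truth.lesion_masks[0].data)
        n = len(lesion_vox)
        half = lesion_vox[: n // 2]
        data = np.zeros(vol.shape, dtype=bool)
        data[tuple(half.T)] = True
        # pad with an equal number of background voxels -> overlap exactly 50%
        bg = np.argwhere(~truth.lesion_masks[0].data & truth.body_mask.data)[: len(half)]
        data[tuple(bg.T)] = True
        roi = make_roi(tk.VoxelMask(data, vol.spacing))
        out = tk.OracleClassifier(overlap_rule=0.5).classify([roi], SubjectContext(vol, truth=truth))
        assert out[0].is_suspicious  # inclusive "at least 50%" rule


class TestFeatures:
    def test_digital_sphere_sphericity_high(self):
        vol = tk.SUVVolume(np.zeros((40, 40, 40)), 2.0)
        mask, _ = tk.sphere_mask(vol, (40.0, 40.0, 40.0), 8.0)
        assert 0.8 <= sphericity(mask) <= 1.0

    def test_flat_slab_sphericity_low(self):
        data = np.zeros((40, 40, 40), dtype=bool)
        data[5:35, 5:35, 20] = True
        assert sphericity(tk.VoxelMask(data, 2.0)) < 0.5

    def test_features_deterministic_and_centered(self, phantom_with_lesion):
        vol, truth = phantom_with_lesion
        center = tuple(np.asarray(vol.shape) * np.asarray(vol.spacing) / 2)
        mask, _ = tk.sphere_mask(vol, center, 8.0)
        roi = make_roi(mask)
        f1 = tk.extract_features(roi, vol, truth.body_mask)
        f2 = tk.extract_features(roi, vol, truth.body_mask)
        assert np.array_equal(f1.to_array(), f2.to_array())
        assert np.allclose(f1.centroid_frac, 0.5, atol=0.08)


class TestBaseline:
    def test_separable_features_reach_full_accuracy(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(0.0, 0.3, (60, 4))
        x1 = rng.normal(5.0, 0.3, (60, 4))
        feats = np.vstack([x0, x1])
        labels = np.r_[np.zeros(60), np.ones(60)]
        clf = tk.train_baseline(feats, labels, seed=0)
        assert clf.holdout_accuracy == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(1)
        feats = rng.normal(size=(240, 5))
        labels = rng.integers(0, 2, 240)
        clf = tk.train_baseline(feats, labels, seed=1)
        assert abs(clf.holdout_accuracy - 0.5) <= 0.15

    def test_single_class_labels_rejected(self):
        with pytest.raises(DegenerateDataError):
            tk.train_baseline(np.random.default_rng(0).normal(size=(30, 3)), np.zeros(30))

    def test_baseline_learns_phantom_rois(self, small_cohort):
        """On oracle-labeled phantom candidates the feature-based classifier
        should be far better than chance (organs sit at canonical positions)."""
        cohort, results = small_cohort
        feats, labels = [], []
        for (vol, truth), res in zip(cohort, results):
            for c in res.rois:
                feats.append(tk.extract_features(c.roi, vol, truth.body_mask).to_array())
                labels.append(int(c.is_suspicious))
        clf = tk.train_baseline(np.stack(feats), labels, seed=0)
        assert clf.holdout_accuracy >= 0.90

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(3)
        feats = rng.normal(size=(80, len(tk.ROIFeatures.names())))
        labels = (feats[:, 0] > 0).astype(int)
        clf = tk.train_baseline(feats, labels, seed=0)
        back = tk.BaselineClassifier.from_dict(clf.to_dict())
        np.testing.assert_allclose(back.predict_score(feats), clf.predict_score(feats), rtol=1e-12)


class TestClassifySubject:
    def test_empty_candidate_list(self, phantom_with_lesion):
        vol, truth = phantom_with_lesion
        out = tk.classify_subject([], tk.OracleClassifier(), SubjectContext(vol, truth=truth))
        assert out == []

    def test_every_candidate_gets_exactly_one_class(self, small_cohort):
        _cohort, results = small_cohort
        for res in results:
            assert len(res.rois) == res.n_rois
            for c in res.rois:
                assert c.uptake_class in (tk.UptakeClass.SUSPICIOUS, tk.UptakeClass.PHYSIOLOGIC)
                assert 0.0 <= c.score <= 1.0

    def test_raising_threshold_never_adds_suspicious(self, small_cohort):
        cohort, results = small_cohort
        vol, truth = cohort[0]
        rois = [c.roi for c in results[0].rois]
        feats_ctx = SubjectContext(vol, truth=truth)
        counts = []
        for thr in (0.1, 0.5, 0.9):
            clf = tk.BaselineClassifier(decision_threshold=thr)
            # score with a fixed trained model: train once on oracle labels
            clf._pipe = _trained_pipe(cohort, results)
            out = clf.classify(rois, feats_ctx)
            counts.append(sum(c.is_suspicious for c in out))
        assert counts[0] >= counts[1] >= counts[2]

    def test_threshold_one_makes_everything_physiologic(self, small_cohort):
        cohort, results = small_cohort
        vol, truth = cohort[0]
        clf = tk.BaselineClassifier(decision_threshold=1.0)
        clf._pipe = _trained_pipe(cohort, results)
        out = clf.classify([c.roi for c in results[0].rois], SubjectContext(vol, truth=truth))
        assert all(not c.is_suspicious for c in out)


def _trained_pipe(cohort, results):
    feats, labels = [], []
    for (vol, truth), res in zip(cohort, results):
        for c in res.rois:
            feats.append(tk.extract_features(c.roi, vol, truth.body_mask).to_array())
            labels.append(int(c.is_suspicious))
    clf = tk.train_baseline(np.stack(feats), labels, seed=0)
    return clf._pipe
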