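"""Spherical neighborhoods, PCA feature reduction, CV-SVM accuracy, and
region constraining."""

import numpy as np
import pytest

from voxelight.containers import BrainMask, CohortVolumes, default_affine
from voxelight.searchlight import (
    SearchlightSpec,
    accuracy_map,
    constrain_regions,
    cv_accuracy,
    neighborhood_index,
    searchlight_features,
)


def _full_mask(dims=(5, 5, 5), voxel=1.5):
    return BrainMask(np.ones(dims, bool), default_affine(voxel))


class TestNeighborhoods:
    def test_2mm_radius_on_1p5mm_grid_is_seven_voxels(self):
        """Offsets with sqrt(sum (1.5 k)^2) <= 2: the center plus 6 face
        neighbors at 1.5 mm; edge neighbors at 2.12 mm are excluded."""
        mask = _full_mask()
        nb = neighborhood_index(mask, 2.0)
        coords = mask.indices
        interior = int(np.flatnonzero((coords == 2).all(axis=1))[0])
        assert len(nb[interior]) == 7
        # the brute-force offset enumeration agrees
        offsets = [
            (i, j, k)
            for i in range(-2, 3) for j in range(-2, 3) for k in range(-2, 3)
            if np.sqrt(((np.array([i, j, k]) * 1.5) ** 2).sum()) <= 2.0
        ]
        assert len(offsets) == 7

    def test_corner_voxel_is_clipped(self):
        mask = _full_mask()
        nb = neighborhood_index(mask, 2.0)
        corner = int(np.flatnonzero((mask.indices == 0).all(axis=1))[0])
        assert len(nb[corner]) == 4  # center + 3 in-bounds face neighbors
        assert len(nb[corner]) < 7

    def test_zero_radius_is_the_center_alone(self):
        mask = _full_mask()
        with pytest.warns(UserWarning, match="below the voxel size"):
            nb = neighborhood_index(mask, 0.0)
        assert all(len(x) == 1 for x in nb)

    def test_out_of_mask_voxels_never_appear(self):
        data = np.zeros((4, 4, 4), bool)
        data[:2] = True
        mask = BrainMask(data, default_affine(1.0))
        nb = neighborhood_index(mask, 1.0)
        n_in = mask.n_voxels
        assert all((x < n_in).all() and (x >= 0).all() for x in nb)


class TestFeatures:
    def test_single_voxel_neighborhood_is_centered_values(self, rng):
        col = rng.normal(size=(10, 1))
        feats, degenerate = searchlight_features(col, 0.8)
        assert not degenerate
        assert np.allclose(np.abs(feats[:, 0]), np.abs(col[:, 0] - col.mean()))

    def test_rank_one_matrix_needs_one_component(self, rng):
        base = rng.normal(size=(20, 1))
        block = base @ rng.normal(size=(1, 6))
        feats, _ = searchlight_features(block, 0.999)
        assert feats.shape[1] == 1

    def test_zero_variance_block_flagged(self):
        feats, degenerate = searchlight_features(np.ones((8, 3)), 0.8)
        assert degenerate
        assert np.allclose(feats, 0.0)

    def test_retained_count_matches_full_spectrum_oracle(self, rng):
        """Smallest k with cumulative eigenvalue fraction >= 0.8, against a
        long-hand eigendecomposition, on random 20 x 7 matrices."""
        for _ in range(25):
            block = rng.normal(size=(20, 7)) * rng.uniform(0.1, 3.0, size=7)
            feats, _ = searchlight_features(block, 0.8)
            Xc = block - block.mean(axis=0)
            evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
            frac = np.cumsum(evals) / evals.sum()
            k_oracle = int(np.argmax(frac >= 0.8 - 1e-12) + 1)
            assert feats.shape[1] == k_oracle
            assert frac[feats.shape[1] - 1] >= 0.8 - 1e-9
            if feats.shape[1] > 1:
                assert frac[feats.shape[1] - 2] < 0.8


def test_fast_svm_path_matches_svc_exactly(rng):
    """The low-level libsvm fold fit used in the hot loop predicts
    identically to a freshly constructed SVC on random data."""
    from sklearn.svm import SVC

    from voxelight.searchlight import _svm_fit_predict

    for _ in range(50):
        n = int(rng.integers(10, 60))
        k = int(rng.integers(1, 6))
        X = rng.normal(size=(n, k))
        y = rng.integers(0, 2, n).astype(float)
        if y.min() == y.max():
            continue
        Xt = rng.normal(size=(6, k))
        ref = SVC(kernel="linear", C=1.0).fit(X, y).predict(Xt)
        assert np.array_equal(_svm_fit_predict(X, y, Xt, 1.0), ref)


class TestCVAccuracy:
    def test_separable_features_are_perfect(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        x = np.where(y == 0, -10.0, 10.0)[:, None] + rng.normal(0, 0.1, (20, 1))
        assert cv_accuracy(x, y, folds=10) == 1.0

    def test_shuffled_labels_hover_at_chance(self, rng):
        """Mean accuracy over 50 label shuffles is 0.5 +- 0.03."""
        x = rng.normal(size=(40, 3))
        accs = []
        for i in range(50):
            y = rng.permutation(np.array([0] * 20 + [1] * 20))
            accs.append(cv_accuracy(x, y, folds=10, seed=i))
        assert abs(np.mean(accs) - 0.5) < 0.03

    def test_four_point_toy_matches_hand_run(self):
        """2/2 split, 2 folds: each fold trains on one +/- pair, and the
        midpoint rule of the maximal-margin separator classifies the held
        out pair correctly."""
        x = np.array([-2.0, -1.0, 1.0, 2.0])[:, None]
        y = np.array([0, 0, 1, 1])
        acc = cv_accuracy(x, y, folds=2, seed=0)
        # hand solve: any train fold holds one negative (x<0, class 0) and one
        # positive (x>0, class 1); the SVM boundary is their midpoint, so the
        # held-out pair is always classified correctly
        assert acc == 1.0

    def test_fold_missing_a_class_rejected(self):
        x = np.zeros((6, 1))
        y = np.array([0] * 5 + [1])
        with pytest.raises(ValueError, match="stratify"):
            cv_accuracy(x, y, folds=3)


def _planted_small(small_cohort):
    cfg, phen, vols, cog, truth = small_cohort
    from voxelight.voxelwise import build_mask

    mask = build_mask(vols)
    return cfg, phen, vols, truth, mask


class TestAccuracyMap:
    def test_planted_region_outscores_background(self, small_cohort):
        cfg, phen, vols, truth, mask = _planted_small(small_cohort)
        spec = SearchlightSpec(folds=5, seed=2)
        amap = accuracy_map(vols, mask, phen["group"].to_numpy(), spec)
        planted = truth.planted_masks["temporal"][mask.data]
        assert amap.accuracy[planted].mean() > amap.accuracy[~planted].mean() + 0.05
        assert (amap.accuracy >= 0).all() and (amap.accuracy <= 1).all()

    def test_determinism_under_fixed_seed(self, small_cohort):
        cfg, phen, vols, truth, mask = _planted_small(small_cohort)
        # tiny submask for speed
        sub = np.zeros_like(mask.data)
        coords = mask.indices[:40]
        sub[tuple(coords.T)] = True
        submask = BrainMask(sub, mask.affine)
        spec = SearchlightSpec(folds=5, seed=9)
        a1 = accuracy_map(vols, submask, phen["group"].to_numpy(), spec)
        a2 = accuracy_map(vols, submask, phen["group"].to_numpy(), spec)
        assert np.array_equal(a1.accuracy, a2.accuracy)

    def test_signal_monotone_in_effect_size(self):
        """Mean in-region accuracy never drops (beyond Monte-Carlo slack)
        as the planted effect grows, over 10 seeds per effect size."""
        from voxelight.synthetic import EffectRegion, SynthConfig, generate_cohort
        from voxelight.voxelwise import build_mask

        means = []
        for d in (0.0, 0.5, 1.0, 1.5):
            accs = []
            for seed in range(10):
                cfg = SynthConfig(
                    n_per_group=20,
                    effect_regions=[EffectRegion("r", (9, 9, 12), 4.5, d)],
                    cognitive_weights={}, seed=700 + seed,
                )
                phen, vols, _, truth = generate_cohort(cfg)
                mask = build_mask(vols)
                region = truth.planted_masks["r"]
                sub = np.zeros_like(mask.data)
                sub[region & mask.data] = True
                submask = BrainMask(sub, mask.affine)
                amap = accuracy_map(
                    vols, submask, phen["group"].to_numpy(),
                    SearchlightSpec(folds=5, seed=seed),
                )
                accs.append(amap.accuracy.mean())
            means.append(np.mean(accs))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]


class TestConstrainRegions:
    def _amap(self, mask, values):
        from voxelight.searchlight import AccuracyMap

        return AccuracyMap(values, np.ones(len(values)), mask, SearchlightSpec())

    def test_all_perfect_accuracy_excludes_nothing(self):
        mask = _full_mask((3, 3, 3))
        amap = self._amap(mask, np.ones(27))
        sig = np.ones((3, 3, 3), bool)
        part = constrain_regions(amap, sig)
        assert part.constrained.sum() == 27
        assert part.excluded.sum() == 0

    def test_threshold_one_constrains_nothing(self):
        mask = _full_mask((3, 3, 3))
        amap = self._amap(mask, np.ones(27))
        sig = np.ones((3, 3, 3), bool)
        with pytest.warns(UserWarning, match="empty"):
            part = constrain_regions(amap, sig, threshold=1.0)
        assert part.constrained.sum() == 0  # strict inequality
        assert part.excluded.sum() == 27

    def test_partition_tiles_significance_mask_exactly(self, rng):
        mask = _full_mask((4, 4, 4))
        amap = self._amap(mask, rng.uniform(size=64))
        sig = rng.random((4, 4, 4)) < 0.4
        part = constrain_regions(amap, sig)
        assert ((part.constrained | part.excluded) == sig).all()
        assert not (part.constrained & part.excluded).any()
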