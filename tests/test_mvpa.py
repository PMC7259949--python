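"""Scaling, voxel selection, cross-validated classification and
reinstatement evidence."""
import numpy as np
import pytest

from patcomp import mvpa
from patcomp.datatypes import Category, ClassifierSpec, PatternMatrix, Phase


def _pm(values, runs=None, phase=Phase.ENCODING):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    runs = np.ones(n, dtype=int) if runs is None else np.asarray(runs)
    ids = np.array([f"t{i}" for i in range(n)], dtype=object)
    return PatternMatrix(roi="VTC", phase=phase, values=values,
                         run_labels=runs, trial_ids=ids)


def _separable(rng, n_per_cat=12, n_runs=3, n_voxels=30, gain=5.0, noise=0.1):
    """Patterns with a planted category contrast; returns (pm, labels)."""
    t_face = np.zeros(n_voxels); t_face[: n_voxels // 2] = 1.0
    t_place = np.zeros(n_voxels); t_place[n_voxels // 2:] = 1.0
    vals, labels, runs = [], [], []
    for run in range(1, n_runs + 1):
        for cat, t in (("face", t_face), ("place", t_place)):
            for _ in range(n_per_cat):
                vals.append(gain * t + rng.normal(0, noise, n_voxels))
                labels.append(cat)
                runs.append(run)
    return _pm(np.array(vals), np.array(runs)), np.array(labels)


class TestScaleWithinRun:
    def test_two_point_column(self):
        pm = _pm([[1.0], [3.0]])
        out = mvpa.scale_within_run(pm)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 1.0])

    def test_idempotent_on_standardized_column(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((20, 4))
        x = (x - x.mean(0)) / x.std(0)
        out = mvpa.scale_within_run(_pm(x))
        np.testing.assert_allclose(out.values, x, atol=1e-12)

    def test_constant_column_zeroed_with_warning(self):
        vals = np.column_stack([np.full(4, 7.0), np.arange(4.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = mvpa.scale_within_run(_pm(vals))
        np.testing.assert_array_equal(out.values[:, 0], 0.0)
        assert out.values[:, 1].std() == pytest.approx(1.0)

    def test_scaling_is_per_run(self):
        vals = np.array([[0.0], [2.0], [10.0], [30.0]])
        out = mvpa.scale_within_run(_pm(vals, runs=[1, 1, 2, 2]))
        np.testing.assert_allclose(out.values[:, 0], [-1, 1, -1, 1])

    def test_single_trial_run_is_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            mvpa.scale_within_run(_pm([[1.0], [2.0], [3.0]], runs=[1, 1, 2]))


class TestVoxelSelection:
    def test_recovers_planted_voxels(self, rng):
        n_signal = 20
        n_voxels = 120
        labels = np.array(["face"] * 40 + ["place"] * 40)
        X = rng.standard_normal((80, n_voxels))
        X[:40, :n_signal] += 2.0     # face-preferring voxels
        X[40:, n_signal: 2 * n_signal] += 2.0  # place-preferring voxels
        sel = mvpa.select_category_voxels(X, labels, k=n_signal)
        planted = set(range(2 * n_signal))
        assert len(set(sel) & planted) >= int(0.95 * 2 * n_signal)

    def test_k_covering_all_voxels(self, rng):
        labels = np.array(["face"] * 10 + ["place"] * 10)
        X = rng.standard_normal((20, 8))
        sel = mvpa.select_category_voxels(X, labels, k=4)
        assert list(sel) == list(range(8))

    def test_label_swap_symmetry(self, rng):
        labels = np.array(["face"] * 15 + ["place"] * 15)
        X = rng.standard_normal((30, 40))
        a = mvpa.select_category_voxels(X, labels, k=10)
        swapped = np.where(labels == "face", "place", "face")
        b = mvpa.select_category_voxels(X, swapped, k=10)
        assert set(a) == set(b)

    def test_oversized_k_falls_back_to_all(self, rng):
        labels = np.array(["face"] * 6 + ["place"] * 6)
        X = rng.standard_normal((12, 10))
        with pytest.warns(UserWarning, match="using all"):
            sel = mvpa.select_category_voxels(X, labels, k=8)
        assert len(sel) == 10


class TestEncodingCV:
    def test_perfect_on_separable_patterns(self, rng):
        pm, labels = _separable(rng, noise=0.01)
        spec = ClassifierSpec(n_subsamples=2, n_features_per_category=10,
                              n_permutations=100)
        out = mvpa.encoding_cv(mvpa.scale_within_run(pm), labels, spec, seed=0)
        assert out["mean_accuracy"] == 1.0
        assert out["mean_logit"] > 0

    def test_chance_under_label_shuffle(self, rng):
        pm, labels = _separable(rng, n_per_cat=20, n_runs=4, noise=0.01)
        shuffled = rng.permutation(labels)
        # keep shuffling until it's balanced per run (it is, by symmetry of
        # permutation over the whole set; folds may be mildly unbalanced)
        spec = ClassifierSpec(n_subsamples=2, n_features_per_category=10,
                              n_permutations=100)
        out = mvpa.encoding_cv(mvpa.scale_within_run(pm), labels=shuffled,
                               spec=spec, seed=1)
        n = len(out["records"])
        se = 0.5 / np.sqrt(n)
        assert abs(out["mean_accuracy"] - 0.5) < 4 * se

    def test_accuracy_consistent_with_logit_sign(self, rng):
        pm, labels = _separable(rng, noise=1.0, gain=0.5)
        spec = ClassifierSpec(n_subsamples=3, n_features_per_category=10,
                              n_permutations=100)
        out = mvpa.encoding_cv(mvpa.scale_within_run(pm), labels, spec, seed=2)
        rec = out["records"]
        assert (rec["accuracy"] == (rec["logit"] > 0)).all()


class TestRetrievalEvidence:
    def test_logit_values(self):
        # the signed logit is log(p/(1-p)) of the correct-category probability
        assert np.log(0.73 / 0.27) == pytest.approx(0.9946, abs=1e-4)

    def test_sign_is_toward_correct_category(self, rng):
        pm, labels = _separable(rng, noise=0.05)
        spec = ClassifierSpec(n_subsamples=2, n_features_per_category=10,
                              n_permutations=100)
        enc = mvpa.scale_within_run(pm)
        # retrieval patterns identical to encoding: evidence positive for
        # both categories
        ev = mvpa.retrieval_evidence(enc, labels, enc, labels, spec, seed=0)
        assert (ev["logit"] > 0).all()
        # wrong correct-category assignment flips the sign
        flipped = np.where(labels == "face", "place", "face")
        ev2 = mvpa.retrieval_evidence(enc, labels, enc, flipped, spec, seed=0)
        assert (ev2["logit"] < 0).all()

    def test_foil_trials_excluded(self, rng):
        pm, labels = _separable(rng)
        enc = mvpa.scale_within_run(pm)
        correct = labels.copy().astype(object)
        correct[0] = "none"
        spec = ClassifierSpec(n_subsamples=1, n_features_per_category=10,
                              n_permutations=100)
        ev = mvpa.retrieval_evidence(enc, labels, enc, correct, spec, seed=0)
        assert len(ev) == len(labels) - 1

    def test_hits_exceed_misses_with_strong_signal(self, trialwise_table):
        hits = trialwise_table.loc[trialwise_table["condition"] == "associative_hit"]
        miss = trialwise_table.loc[trialwise_table["condition"] == "associative_miss"]
        assert hits["logit__VTC"].mean() > 0
        assert hits["logit__VTC"].mean() > miss["logit__VTC"].mean()

    def test_evidence_invariant_to_voxel_permutation(self, rng):
        pm, labels = _separable(rng, noise=0.5)
        spec = ClassifierSpec(n_subsamples=1, n_features_per_category=10,
                              n_permutations=100)
        enc = mvpa.scale_within_run(pm)
        ev1 = mvpa.retrieval_evidence(enc, labels, enc, labels, spec, seed=3)
        perm = rng.permutation(enc.n_voxels)
        pmp = _pm(enc.values[:, perm], enc.run_labels)
        ev2 = mvpa.retrieval_evidence(pmp, labels, pmp, labels, spec, seed=3)
        np.testing.assert_allclose(ev1["p_correct"], ev2["p_correct"], atol=1e-9)


class TestPermutation:
    def test_tie_with_all_permutations_gives_one(self, rng):
        """If the observed accuracy is met by every permutation (all-noise,
        observed at the null floor), p = 1."""
        pm, labels = _separable(rng, n_per_cat=6, n_runs=2, noise=5.0, gain=0.0)
        spec = ClassifierSpec(n_subsamples=1, n_features_per_category=5,
                              n_permutations=100)
        enc = mvpa.scale_within_run(pm)
        p = mvpa.permutation_pvalue(0.0, enc, labels, enc, labels, spec, seed=0)
        assert p == 1.0

    def test_real_signal_gives_small_p(self, rng):
        """Moderate category signal with an independent test set: the
        observed accuracy should beat essentially every permuted refit."""
        pm, labels = _separable(rng, n_per_cat=15, gain=0.8, noise=1.0)
        pm2, labels2 = _separable(rng, n_per_cat=15, gain=0.8, noise=1.0)
        spec = ClassifierSpec(n_subsamples=2, n_features_per_category=10,
                              n_permutations=199)
        enc = mvpa.scale_within_run(pm)
        test = mvpa.scale_within_run(pm2)
        ev = mvpa.retrieval_evidence(enc, labels, test, labels2, spec, seed=0)
        obs = float(ev["accuracy"].mean())
        assert obs > 0.8
        p = mvpa.permutation_pvalue(obs, enc, labels, test, labels2, spec, seed=1)
        assert p < 0.02

    def test_small_permutation_count_warns(self, rng):
        pm, labels = _separable(rng, n_per_cat=4, n_runs=2)
        spec = ClassifierSpec(n_subsamples=1, n_features_per_category=5,
                              n_permutations=99)
        enc = mvpa.scale_within_run(pm)
        with pytest.warns(UserWarning, match="unstable"):
            mvpa.permutation_pvalue(1.0, enc, labels, enc, labels, spec, seed=0)
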