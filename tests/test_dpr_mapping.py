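"""Epoching, rank-sum testing, FDR masking and frequency-map summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from passive_lp import dpr_mapping as dm
from passive_lp.io_formats import PhonemeAnnotation, Recording, default_class_map
from passive_lp.preprocess import apply_artifact_mask


def annotation_from_onsets(onsets_s, label="AA", dur_s=0.05):
    df = pd.DataFrame({
        "start_s": list(onsets_s),
        "end_s": [s + dur_s for s in onsets_s],
        "phoneme_label": [label] * len(onsets_s),
    })
    return PhonemeAnnotation(intervals=df, class_map=default_class_map())


def flat_recording(n_channels=1, duration_s=10.0, rate_hz=250.0):
    n = int(duration_s * rate_hz)
    data = np.tile(np.arange(n, dtype=float), (n_channels, 1))
    return Recording(channel_labels=[f"c{i}" for i in range(n_channels)],
                     rate_hz=rate_hz, data=data)


class TestExtractEpochs:
    def test_onset_sample_arithmetic(self):
        rec = flat_recording()
        sets = dm.extract_epochs(rec, annotation_from_onsets([0.1]))
        es = sets["V"]
        assert es.n_epochs == 1
        assert es.onset_samples[0] == 25
        np.testing.assert_array_equal(es.epochs[0, 0],
                                      np.arange(25, 150, dtype=float))

    def test_window_beyond_record_end_dropped(self):
        rec = flat_recording(duration_s=2.0)
        report = dm.EpochReport()
        sets = dm.extract_epochs(
            rec, annotation_from_onsets([0.5, 1.7]), report=report)
        assert sets["V"].n_epochs == 1
        assert report.boundary_dropped == 1

    def test_artifact_exclusion_fraction_matches_masked_onsets(self):
        # 413 of 10000 onsets fall in masked spans -> 4.13% excluded
        rate = 250.0
        onsets = 0.5 + 0.08 * np.arange(10000)
        rec = flat_recording(duration_s=onsets[-1] + 1.0)
        masked = onsets[:413]
        rec = apply_artifact_mask(rec, [(s, s + 0.004) for s in masked])
        report = dm.EpochReport()
        sets = dm.extract_epochs(rec, annotation_from_onsets(onsets),
                                 report=report)
        assert report.artifact_excluded / report.total_annotated == \
            pytest.approx(0.0413)
        assert sets["V"].n_epochs == 10000 - 413

    def test_unmapped_phonemes_counted_not_epoched(self):
        rec = flat_recording()
        df = pd.DataFrame({"start_s": [0.1, 0.3], "end_s": [0.2, 0.4],
                           "phoneme_label": ["AA", "CH"]})
        annot = PhonemeAnnotation(intervals=df, class_map=default_class_map())
        report = dm.EpochReport()
        sets = dm.extract_epochs(rec, annot, report=report)
        assert report.unmapped == 1
        assert sum(s.n_epochs for s in sets.values()) == 1


class TestRejectEpochs:
    def _sets(self, epochs):
        return {"V": dm.EpochSet(class_label="V", epochs=epochs,
                                 onset_samples=np.arange(len(epochs)))}

    def test_epoch_over_threshold_removed(self):
        epochs = np.zeros((2, 1, 125))
        epochs[1, 0, 60] = 11.0
        out = dm.reject_epochs(self._sets(epochs), sd_threshold=10.0)
        assert out["V"].n_epochs == 1

    def test_epoch_at_threshold_kept(self):
        epochs = np.full((3, 1, 125), 10.0)
        out = dm.reject_epochs(self._sets(epochs), sd_threshold=10.0)
        assert out["V"].n_epochs == 3

    def test_gaussian_rejection_fraction_below_one_percent(self, rng):
        epochs = rng.standard_normal((2000, 8, 125))
        out = dm.reject_epochs(self._sets(epochs), sd_threshold=10.0)
        assert 1 - out["V"].n_epochs / 2000 < 0.01


def ranksum_p_bruteforce(a, b):
    """Independent enumeration oracle: two-tailed permutation p of the
    rank-sum statistic over all reassignments of the pooled values."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1, N = len(a), len(pooled)
    mu = n1 * (N + 1) / 2
    w_obs = ranks[:n1].sum()
    hits = total = 0
    for combo in itertools.combinations(range(N), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


class TestRanksum:
    def test_fully_separated_small_groups(self):
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        b = np.array([4.0, 5.0, 6.0]).reshape(3, 1, 1)
        assert dm.ranksum_pvalues(a, b)[0, 0] == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        assert dm.ranksum_pvalues(a, a.copy())[0, 0] == pytest.approx(1.0)

    def test_degenerate_constant_data_gives_p_one(self):
        a = np.ones((20, 1, 1))
        b = np.ones((30, 1, 1))
        assert dm.ranksum_pvalues(a, b)[0, 0] == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (6, 4), (6, 6)])
    def test_exact_path_matches_enumeration_oracle(self, rng, n1, n2):
        for _ in range(12):
            a = rng.integers(0, 6, size=n1).astype(float)
            b = rng.integers(0, 6, size=n2).astype(float)
            got = dm.ranksum_pvalues(a.reshape(n1, 1, 1),
                                     b.reshape(n2, 1, 1))[0, 0]
            assert got == pytest.approx(ranksum_p_bruteforce(a, b))

    def test_normal_path_matches_scipy(self, rng):
        a = rng.standard_normal((20, 2, 6))
        b = rng.standard_normal((30, 2, 6))
        got = dm.ranksum_pvalues(a, b)
        ref = stats.mannwhitneyu(a, b, axis=0, method="asymptotic",
                                 use_continuity=True,
                                 alternative="two-sided").pvalue
        np.testing.assert_allclose(got, ref, atol=1e-12)

    def test_null_pvalues_uniform(self, rng):
        """Under no shift, the empirical CDF of p hugs the diagonal."""
        a = rng.standard_normal((40, 1, 10000))
        b = rng.standard_normal((40, 1, 10000))
        p = dm.ranksum_pvalues(a, b).ravel()
        grid = np.linspace(0.05, 0.95, 19)
        ecdf = (p[None, :] <= grid[:, None]).mean(axis=1)
        assert np.abs(ecdf - grid).max() < 0.02

    def test_too_few_epochs_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            dm.ranksum_pvalues(rng.standard_normal((1, 1, 5)),
                               rng.standard_normal((4, 1, 5)))


def bh_mask_bruteforce(p, alpha=0.05):
    """Literal step-up definition, independent of statsmodels."""
    m = len(p)
    order = np.argsort(p)
    sorted_p = p[order]
    below = np.flatnonzero(sorted_p <= (np.arange(1, m + 1) * alpha / m))
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask


class TestBHFDR:
    def test_step_up_worked_example(self):
        p = np.array([[0.01, 0.02, 0.04, 0.5]])
        np.testing.assert_array_equal(dm.bh_fdr_mask(p)[0],
                                      [True, True, False, False])

    def test_all_ones_rejects_nothing(self):
        assert not dm.bh_fdr_mask(np.ones((3, 10))).any()

    def test_single_pvalue_reduces_to_uncorrected(self):
        assert dm.bh_fdr_mask(np.array([[0.04]]))[0, 0]

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** float(rng.uniform(0.5, 3.0))
            got = dm.bh_fdr_mask(p[None, :])[0]
            np.testing.assert_array_equal(got, bh_mask_bruteforce(p))

    def test_within_channel_corrects_rows_independently(self, rng):
        p = np.vstack([np.full(50, 0.001), rng.uniform(0.5, 1.0, 50)])
        mask = dm.bh_fdr_mask(p, scope="within_channel")
        assert mask[0].all() and not mask[1].any()

    def test_global_not_more_permissive_under_null(self, rng):
        """In expectation on null data, one big family rejects no more
        cells than per-channel families."""
        tot_within = tot_global = 0
        for _ in range(200):
            p = rng.random((8, 125))
            tot_within += dm.bh_fdr_mask(p, scope="within_channel").sum()
            tot_global += dm.bh_fdr_mask(p, scope="global").sum()
        assert tot_global <= tot_within + 5

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            dm.bh_fdr_mask(np.array([[0.0, 0.5]]))


class TestPairMaps:
    def test_same_class_pair_rejected(self, vowel_epoch_sets):
        with pytest.raises(ValueError, match="differ"):
            dm.pair_result(vowel_epoch_sets, ("A", "A"))

    def test_average_requires_all_ten_pairs(self, rng):
        mask = rng.random((4, 125)) < 0.1
        results = [dm.PairResult(pair=p, p_values=np.full((4, 125), 0.5),
                                 mask=mask) for p in dm.ALL_PAIRS[:9]]
        with pytest.raises(ValueError, match="10 distinct"):
            dm.average_pair_maps(results)

    def test_average_is_fraction_of_pairs(self):
        results = []
        for k, pair in enumerate(dm.ALL_PAIRS):
            mask = np.zeros((2, 125), dtype=bool)
            mask[0, 0] = k < 3  # exactly 3 of 10 pairs significant there
            results.append(dm.PairResult(pair=pair, mask=mask,
                                         p_values=np.full((2, 125), 0.5)))
        fmap = dm.average_pair_maps(results)
        assert fmap.values[0, 0] == pytest.approx(0.3)
        assert fmap.values[1, 0] == 0.0
        assert fmap.level == "trial"
        assert fmap.chance_level == pytest.approx(0.0004)


class TestProfilesAndSubintervals:
    def _uniform_map(self, value, n_ch=4, n_pts=125):
        return dm.FrequencyMap(
            channel_labels=[f"c{i}" for i in range(n_ch)],
            points_ms=dm.time_axis_ms(), values=np.full((n_ch, n_pts), value))

    def test_uniform_map_profiles(self):
        fmap = self._uniform_map(0.2)
        np.testing.assert_allclose(dm.temporal_profile(fmap), 0.2)
        np.testing.assert_allclose(dm.spatial_profile(fmap), 0.2)

    def test_single_cell_temporal_profile(self):
        fmap = self._uniform_map(0.0, n_ch=37)
        fmap.values[5, 10] = 1.0
        profile = dm.temporal_profile(fmap)
        assert profile[10] == pytest.approx(1 / 37)
        assert profile[11] == 0.0

    def test_constant_map_subintervals(self):
        out = dm.subinterval_summary(self._uniform_map(0.5))
        np.testing.assert_allclose(out, 0.5)

    def test_first_bin_spans_21_timepoints(self):
        fmap = self._uniform_map(0.0)
        fmap.values[:, :21] = 1.0  # 0..80 ms inclusive on the 4 ms grid
        out = dm.subinterval_summary(fmap)
        np.testing.assert_allclose(out[:, 0], 1.0)
        assert (out[:, 1:] == 0.0).all()

    def test_off_grid_bin_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            dm.subinterval_summary(self._uniform_map(0.1),
                                   bins_ms=((0, 81), (85, 500)))


class TestRecovery:
    def test_vowel_effect_recovered_at_injected_locus(self, vowel_epoch_sets):
        """A 2 SD vowel bump at 120 ms on channels 2,3 lights up the
        84-148 ms bin of every vowel-containing pair at those channels."""
        tax = dm.time_axis_ms()
        in_bin = (tax >= 84) & (tax <= 148)
        for pair in dm.ALL_PAIRS:
            pr = dm.pair_result(vowel_epoch_sets, pair)
            if "V" in pair:
                assert pr.mask[2, in_bin].any(), pair
                assert pr.mask[3, in_bin].any(), pair

    def test_effect_free_channels_near_chance(self, vowel_epoch_sets):
        prs = [dm.pair_result(vowel_epoch_sets, p) for p in dm.ALL_PAIRS]
        fmap = dm.average_pair_maps(prs)
        # channels with zero effect weight: frequency near the 0.0004 chance
        assert fmap.values[[0, 1, 4, 5, 6, 7]].mean() < 0.01

    def test_early_effect_maximal_in_first_bin(self, rng):
        """A synthetic early (40 ms) effect dominates the 0-80 ms bin."""
        fmap = dm.FrequencyMap(
            channel_labels=["c0", "c1"], points_ms=dm.time_axis_ms(),
            values=np.zeros((2, 125)))
        tax = dm.time_axis_ms()
        fmap.values[0] = 0.02 + 0.5 * np.exp(-0.5 * ((tax - 40) / 15.0) ** 2)
        fmap.values = np.clip(fmap.values, 0, 1)
        out = dm.subinterval_summary(fmap)
        assert out[0].argmax() == 0
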