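"""Median normalization, control pooling and the log2-ratio signal."""

import numpy as np
import pandas as pd
import pytest

from wescnv.emrc import EMRCProfile
from wescnv.normalize import (compute_bin_table, median_normalize,
                              normalize_three_step, pool_controls, log2_ratio,
                              _bin_index)
from conftest import make_profile


def _bin_medians(profile, covariate):
    table = compute_bin_table(profile, covariate)
    return table.m_x, table.m


class TestMedianNormalize:
    def test_single_bin_is_identity(self, annotated_targets):
        targets = annotated_targets.copy()
        targets["gc_percent"] = 50
        rng = np.random.default_rng(0)
        profile = make_profile(targets, rng.uniform(1, 3, len(targets)))
        out = median_normalize(profile, "gc")
        np.testing.assert_allclose(out.emrc, profile.emrc)

    def test_two_bin_scale_factors(self, annotated_targets):
        targets = annotated_targets.copy()
        n = len(targets)
        targets["gc_percent"] = np.r_[np.full(n // 2, 30), np.full(n - n // 2, 60)]
        emrc = np.r_[np.full(n // 2, 10.0), np.full(n - n // 2, 20.0)]
        profile = make_profile(targets, emrc)
        out = median_normalize(profile, "gc")
        overall = np.median(emrc)  # 15 with equal halves
        np.testing.assert_allclose(out.emrc[:n // 2], 10.0 * overall / 10.0)
        np.testing.assert_allclose(out.emrc[n // 2:], 20.0 * overall / 20.0)
        m_x, m = _bin_medians(out, "gc")
        np.testing.assert_allclose(m_x, m)

    def test_gc_trend_equalized(self, annotated_targets):
        """After the pass every non-empty bin has the overall median."""
        rng = np.random.default_rng(3)
        gc = annotated_targets["gc_percent"].to_numpy()
        emrc = 2.0 + 0.05 * (gc - 50) + rng.normal(0, 0.05, len(gc))
        profile = make_profile(annotated_targets, np.abs(emrc))
        out = median_normalize(profile, "gc")
        m_x, m = _bin_medians(out, "gc")
        np.testing.assert_allclose(m_x, m, atol=1e-9)

    def test_overall_median_conserved(self, annotated_targets):
        rng = np.random.default_rng(4)
        profile = make_profile(annotated_targets, rng.uniform(0.5, 4, len(annotated_targets)))
        before = np.median(profile.emrc)
        for cov in ("gc", "mappability", "size"):
            out = median_normalize(profile, cov)
            # each bin maps its median onto m, so the overall median is m
            assert np.median(out.emrc[~out.mask]) == pytest.approx(before, rel=1e-9)

    def test_scale_equivariance(self, annotated_targets):
        rng = np.random.default_rng(5)
        emrc = rng.uniform(0.5, 4, len(annotated_targets))
        p1 = make_profile(annotated_targets, emrc)
        p2 = make_profile(annotated_targets, 7.0 * emrc)
        np.testing.assert_allclose(median_normalize(p2, "gc").emrc,
                                   7.0 * median_normalize(p1, "gc").emrc)

    def test_zero_median_bin_masked_not_scaled(self, annotated_targets):
        targets = annotated_targets.copy()
        targets.loc[targets.index[:5], "gc_percent"] = 10  # isolated zero bin
        emrc = np.full(len(targets), 2.0)
        emrc[:5] = 0.0
        profile = make_profile(targets, emrc)
        out = median_normalize(profile, "gc")
        assert out.mask[:5].all()
        np.testing.assert_allclose(out.emrc[:5], 0.0)

    def test_size_bins_are_10bp_and_capped(self):
        assert _bin_index(np.array([10, 19, 20, 999, 1000, 5000]), "size").tolist() == \
            [1, 1, 2, 99, 100, 100]

    def test_mappability_bins_are_tenths(self):
        assert _bin_index(np.array([0.0, 0.09, 0.1, 0.55, 1.0]), "mappability").tolist() == \
            [0, 0, 1, 5, 10]


class TestThreeStep:
    def test_flat_profile_unchanged(self, flat_profile):
        out = normalize_three_step(flat_profile)
        np.testing.assert_allclose(out.emrc, flat_profile.emrc)
        assert out.normalized

    def test_gc_only_bias_removed_and_preserved(self, annotated_targets):
        """A pure GC trend disappears at step 1 and stays gone after 2-3."""
        targets = annotated_targets.copy()
        targets["mappability"] = 0.85   # flat in the other covariates
        targets["size_bp"] = 200
        gc = targets["gc_percent"].to_numpy()
        emrc = 1.0 + 0.04 * (gc - gc.mean())
        profile = make_profile(targets, np.abs(emrc))
        out = normalize_three_step(profile)
        m_x, m = _bin_medians(out, "gc")
        np.testing.assert_allclose(m_x, m, atol=1e-9)

    def test_idempotent_once_bias_is_removed(self, annotated_targets):
        """Re-running the procedure on bias-free output changes nothing.

        With the bias confined to one covariate (the others flat), the
        first run removes it completely, so a second run finds every bin
        median already equal to the master median.
        """
        targets = annotated_targets.copy()
        targets["mappability"] = 0.85
        targets["size_bp"] = 200
        rng = np.random.default_rng(8)
        gc = targets["gc_percent"].to_numpy()
        emrc = np.abs(1.5 + 0.03 * (gc - 50) + rng.normal(0, 0.1, len(gc)))
        once = normalize_three_step(make_profile(targets, emrc))
        twice = normalize_three_step(once)
        keep = ~twice.mask
        np.testing.assert_allclose(twice.emrc[keep], once.emrc[keep], rtol=1e-6)


class TestPoolControls:
    def test_single_control_passthrough(self, annotated_targets):
        rng = np.random.default_rng(10)
        p = make_profile(annotated_targets, rng.uniform(1, 2, len(annotated_targets)))
        pooled = pool_controls([p])
        np.testing.assert_array_equal(pooled.rc, p.rc)

    def test_counts_sum_across_controls(self, annotated_targets):
        sizes = (annotated_targets["end"] - annotated_targets["start"]).to_numpy()
        a = EMRCProfile(targets=annotated_targets, rc=np.full(len(sizes), 3),
                        emrc=3 / sizes)
        b = EMRCProfile(targets=annotated_targets, rc=np.full(len(sizes), 5),
                        emrc=5 / sizes)
        pooled = pool_controls([a, b])
        assert (pooled.rc == 8).all()

    def test_matrix_sum_over_six_controls(self, annotated_targets):
        rng = np.random.default_rng(12)
        sizes = (annotated_targets["end"] - annotated_targets["start"]).to_numpy()
        rcs = rng.integers(10, 400, size=(6, len(sizes)))
        profiles = [EMRCProfile(targets=annotated_targets, rc=rc, emrc=rc / sizes)
                    for rc in rcs]
        pooled = pool_controls(profiles)
        np.testing.assert_array_equal(pooled.rc, rcs.sum(axis=0))

    def test_target_mismatch_rejected(self, annotated_targets):
        other = annotated_targets.copy()
        other.loc[other.index[0], "end"] += 1
        sizes = (annotated_targets["end"] - annotated_targets["start"]).to_numpy()
        a = EMRCProfile(targets=annotated_targets, rc=np.ones(len(sizes), int), emrc=1 / sizes)
        b = EMRCProfile(targets=other, rc=np.ones(len(sizes), int), emrc=1 / sizes)
        with pytest.raises(ValueError, match="mismatch"):
            pool_controls([a, b])


class TestLog2Ratio:
    def test_identical_samples_give_zero(self, flat_profile):
        ratio = log2_ratio(flat_profile, flat_profile, lowess=True)
        np.testing.assert_allclose(ratio.log2r[~ratio.mask], 0.0, atol=1e-9)

    def test_doubled_test_gives_one_before_recentering(self, annotated_targets):
        rng = np.random.default_rng(14)
        emrc = rng.uniform(1, 2, len(annotated_targets))
        test = make_profile(annotated_targets, 2 * emrc)
        control = make_profile(annotated_targets, emrc)
        ratio = log2_ratio(test, control, lowess=False)
        # a global factor 2 is removed by median re-centering; the raw
        # ratio is homogeneous, so the profile is exactly flat
        np.testing.assert_allclose(ratio.log2r[~ratio.mask], 0.0, atol=1e-12)
        raw = np.log2(test.emrc / control.emrc)
        np.testing.assert_allclose(raw, 1.0)

    def test_antisymmetry_without_lowess(self, annotated_targets):
        rng = np.random.default_rng(15)
        a = make_profile(annotated_targets, rng.uniform(1, 3, len(annotated_targets)))
        b = make_profile(annotated_targets, rng.uniform(1, 3, len(annotated_targets)))
        fwd = log2_ratio(a, b, lowess=False)
        rev = log2_ratio(b, a, lowess=False)
        keep = ~(fwd.mask | rev.mask)
        np.testing.assert_allclose(fwd.log2r[keep], -rev.log2r[keep], atol=1e-9)

    def test_low_control_coverage_masked(self, annotated_targets):
        emrc = np.full(len(annotated_targets), 2.0)
        control_emrc = emrc.copy()
        control_emrc[:4] = 0.01  # below the 0.1 reads/bp floor
        test = make_profile(annotated_targets, emrc)
        control = make_profile(annotated_targets, control_emrc)
        ratio = log2_ratio(test, control)
        assert ratio.mask[:4].all()
        assert not ratio.mask[4:].any()

    def test_all_masked_is_an_error(self, annotated_targets):
        test = make_profile(annotated_targets, np.full(len(annotated_targets), 1.0))
        control = make_profile(annotated_targets, np.full(len(annotated_targets), 0.001))
        with pytest.raises(ValueError, match="control coverage insufficient"):
            log2_ratio(test, control)

    def test_distances_positive_and_shift_invariant(self, annotated_targets):
        test = make_profile(annotated_targets, np.full(len(annotated_targets), 2.0))
        ratio = log2_ratio(test, test)
        d = ratio.distances["chr1"]
        assert (d > 0).all()
        shifted = annotated_targets.copy()
        shifted["start"] += 10_000
        shifted["end"] += 10_000
        shifted["midpoint"] += 10_000
        test2 = make_profile(shifted, np.full(len(shifted), 2.0))
        ratio2 = log2_ratio(test2, test2)
        np.testing.assert_array_equal(ratio2.distances["chr1"], d)

    def test_one_copy_region_sits_near_minus_one(self, annotated_targets):
        """A heterozygous deletion halves the test density: log2(1/2) = -1."""
        rng = np.random.default_rng(16)
        n = len(annotated_targets)
        base = rng.uniform(1.5, 2.5, n)
        test_emrc = base.copy()
        deleted = slice(20, 30)
        test_emrc[deleted] = base[deleted] / 2
        test = make_profile(annotated_targets, test_emrc)
        control = make_profile(annotated_targets, base)
        ratio = log2_ratio(test, control, lowess=False)
        assert np.median(ratio.log2r[deleted]) == pytest.approx(-1.0, abs=0.05)
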