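"""Pixel-wise permutation inference: scalar statistic, maps, enumeration,
cluster correction."""

from itertools import combinations

import numpy as np
import pytest

from bodymap import (
    cluster_correct,
    permutation_pmap,
    planted_effect_config,
    generate_cohort,
    region_mask,
    subject_concern_mask,
    two_proportion_z,
    z_map,
)
from bodymap.permstat import ProvenanceError

from conftest import random_masks


# --- scalar statistic -------------------------------------------------------

def test_degenerate_and_equal_proportions_give_zero():
    assert two_proportion_z(0, 10, 0, 7) == 0.0
    assert two_proportion_z(10, 10, 7, 7) == 0.0  # pooled proportion 1
    assert two_proportion_z(10, 20, 5, 10) == 0.0


def test_scalar_z_matches_direct_formula_and_reference_implementation():
    z = two_proportion_z(30, 65, 10, 38)
    assert z == pytest.approx(1.993, abs=5e-4)
    # independent cross-check: statsmodels' pooled two-proportion z test
    from statsmodels.stats.proportion import proportions_ztest

    z_ref, _ = proportions_ztest([30, 10], [65, 38])
    assert z == pytest.approx(z_ref, abs=1e-12)


def test_scalar_z_input_validation():
    with pytest.raises(ValueError):
        two_proportion_z(5, 4, 1, 10)
    with pytest.raises(ValueError):
        two_proportion_z(1, 0, 1, 10)
    with pytest.raises(ValueError):
        two_proportion_z(-1, 10, 1, 10)


# --- z map ------------------------------------------------------------------

def test_zmap_matches_scalar_on_toy_raster():
    a = [np.array([[1, 0], [1, 1]], np.uint8),
         np.array([[1, 0], [0, 1]], np.uint8),
         np.array([[1, 0], [0, 0]], np.uint8)]
    b = [np.array([[0, 0], [1, 0]], np.uint8),
         np.array([[1, 0], [0, 0]], np.uint8),
         np.array([[0, 0], [0, 0]], np.uint8)]
    zm = z_map(a, b)
    xa = np.sum(a, axis=0)
    xb = np.sum(b, axis=0)
    for r in range(2):
        for c in range(2):
            assert zm[r, c] == pytest.approx(
                two_proportion_z(xa[r, c], 3, xb[r, c], 3), abs=1e-12
            )


def test_zmap_antisymmetry_and_identical_groups(rng):
    a = random_masks(rng, 4, shape=(8, 8))
    b = random_masks(rng, 5, shape=(8, 8))
    assert np.allclose(z_map(a, b), -z_map(b, a), atol=1e-12)
    assert np.all(z_map(a, a) == 0.0)
    assert np.allclose(z_map(a, b, fwhm_px=2.0), -z_map(b, a, fwhm_px=2.0), atol=1e-12)


def test_zmap_rejects_empty_or_mismatched_groups(rng):
    a = random_masks(rng, 3, shape=(8, 8))
    with pytest.raises(ValueError):
        z_map(a, [])
    with pytest.raises(ValueError, match="mismatch"):
        z_map(a, random_masks(rng, 3, shape=(6, 8)))


# --- permutation p map ------------------------------------------------------

def _toy_six_masks():
    """Six 2x2 masks giving pixels with varied group counts and a
    constant-agreement pixel (all ones)."""
    patterns = [
        [[1, 1], [0, 1]],
        [[1, 0], [1, 1]],
        [[1, 1], [1, 0]],
        [[1, 0], [0, 0]],
        [[1, 1], [0, 0]],
        [[1, 0], [1, 0]],
    ]
    return [np.array(p, dtype=np.uint8) for p in patterns]


def _oracle_abs_z(stack, subset, n):
    """Direct two-proportion z on a relabeling, for exhaustive enumeration."""
    rest = [i for i in range(n) if i not in subset]
    p1 = stack[list(subset)].mean(axis=0)
    p2 = stack[rest].mean(axis=0)
    n1, n2 = len(subset), len(rest)
    pbar = (n1 * p1 + n2 * p2) / n
    var = pbar * (1 - pbar) * (1 / n1 + 1 / n2)
    z = np.where(var > 0, (p1 - p2) / np.sqrt(np.where(var > 0, var, 1)), 0.0)
    return np.abs(z)


def exact_exhaustive_pmap(masks, n1):
    """Exact permutation p over all C(n, n1) relabelings (oracle)."""
    stack = np.stack(masks).astype(float)
    n = len(masks)
    z_obs = _oracle_abs_z(stack, tuple(range(n1)), n)
    count = np.zeros_like(z_obs)
    total = 0
    for subset in combinations(range(n), n1):
        count += _oracle_abs_z(stack, subset, n) >= z_obs - 1e-9
        total += 1
    return count / total


def test_sampled_p_within_monte_carlo_error_of_exhaustive_enumeration():
    masks = _toy_six_masks()
    labels = ["x"] * 3 + ["y"] * 3
    B = 2000
    res = permutation_pmap(masks, labels, B=B, seed=7)
    exact = exact_exhaustive_pmap(masks, 3)
    sd = np.sqrt(exact * (1 - exact) / B)
    assert (np.abs(res.p_uncorrected - exact) <= 3 * sd + 1.0 / (B + 1)).all()


def test_agreement_pixel_has_p_one_and_p_floor_holds():
    masks = _toy_six_masks()  # pixel (0,0) is 1 for every subject
    res = permutation_pmap(masks, ["x"] * 3 + ["y"] * 3, B=200, seed=1)
    assert res.p_uncorrected[0, 0] == 1.0
    assert res.z[0, 0] == 0.0
    assert (res.p_uncorrected >= 1.0 / 201).all()
    assert (res.p_uncorrected <= 1.0).all()


def test_same_seed_reproduces_and_label_swap_is_invariant():
    masks = _toy_six_masks()
    labels = ["x"] * 3 + ["y"] * 3
    r1 = permutation_pmap(masks, labels, B=300, seed=42)
    r2 = permutation_pmap(masks, labels, B=300, seed=42)
    assert (r1.p_uncorrected == r2.p_uncorrected).all()
    swapped = ["y" if l == "x" else "x" for l in labels]
    r3 = permutation_pmap(masks, swapped, B=300, seed=42)
    assert (r1.p_uncorrected == r3.p_uncorrected).all()
    assert np.allclose(r1.z, -r3.z, atol=1e-12)


def test_permutation_rejects_bad_inputs():
    masks = _toy_six_masks()
    with pytest.raises(ValueError, match="two distinct"):
        permutation_pmap(masks, ["x"] * 6, B=10, seed=0)
    with pytest.raises(ValueError, match="two distinct"):
        permutation_pmap(masks, ["x", "y", "z", "x", "y", "z"], B=10, seed=0)
    with pytest.raises(ValueError, match="B"):
        permutation_pmap(masks, ["x"] * 3 + ["y"] * 3, B=0, seed=0)


# --- cluster correction -----------------------------------------------------

def test_no_supra_threshold_pixels_means_no_clusters():
    m = np.ones((6, 6), dtype=np.uint8)
    res = permutation_pmap([m] * 8, ["x"] * 4 + ["y"] * 4, B=100, seed=3)
    res = cluster_correct(res)
    assert res.clusters.max() == 0
    assert res.surviving.sum() == 0


def test_provenance_mismatch_rejected():
    masks = _toy_six_masks()
    res = permutation_pmap(masks, ["x"] * 3 + ["y"] * 3, B=100, seed=5)
    with pytest.raises(ProvenanceError, match="seed"):
        cluster_correct(res, seed=6)
    with pytest.raises(ProvenanceError, match="B"):
        cluster_correct(res, B=200)


def test_surviving_pixels_form_large_enough_supra_clusters():
    cfg = planted_effect_config(seed=1001)
    cohort = generate_cohort(cfg)
    masks = [subject_concern_mask(s.concerns, cohort.raster_dims) for s in cohort.subjects]
    labels = [s.group for s in cohort.subjects]
    res = cluster_correct(permutation_pmap(masks, labels, B=300, seed=9, fwhm_px=3.0))
    surv = res.surviving > 0
    # surviving pixels are a subset of labeled supra-threshold clusters
    assert not np.any(surv & (res.clusters == 0))
    # every surviving cluster meets the null max-extent critical size
    for lab in np.unique(res.clusters[surv]):
        assert (res.clusters == lab).sum() >= res.cluster_extent_threshold
    # the planted region is recovered for this strong effect
    planted = region_mask(cfg, "planted") > 0
    inter = (surv & planted).sum()
    union = (surv | planted).sum()
    assert inter / union > 0.3


def test_smoothed_and_unsmoothed_p_maps_are_valid_probabilities():
    cfg = planted_effect_config(n_a=8, n_b=8, seed=2)
    cohort = generate_cohort(cfg)
    masks = [subject_concern_mask(s.concerns, cohort.raster_dims) for s in cohort.subjects]
    labels = [s.group for s in cohort.subjects]
    for fwhm in (None, 3.0):
        res = permutation_pmap(masks, labels, B=99, seed=0, fwhm_px=fwhm)
        assert res.p_uncorrected.min() >= 1.0 / 100
        assert res.p_uncorrected.max() <= 1.0
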