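"""Cross-run RDMs, searchlights and sign-flip permutation inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from structbandit import rsa
from structbandit.rsa import (ConditionPatterns, ContrastSpec, cluster_mass_fwe,
                              contrast_value, cross_run_rdm, dendrogram_linkage,
                              leave_one_out, prewhiten, roi_test,
                              searchlight_map, searchlight_neighbors,
                              sign_flip_test, structure_contrast,
                              stimulus_contrast, whitening_matrix)


def _labels8():
    rows = []
    for sign, sset in [(-1, 1), (-1, 2), (1, 1), (1, 2)]:
        for stim in ("A", "B"):
            rows.append({"structure_sign": sign, "stimulus_set": sset,
                         "stimulus": stim})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# prewhitening

def test_prewhiten_diagonal_covariance_scaling():
    """A voxel with residual variance 4 has its betas halved; shrinkage to the
    diagonal leaves a diagonal covariance untouched."""
    a, b = np.sqrt(3), np.sqrt(3) / 2  # sample variances 4 and 1 (ddof=1)
    residuals = np.column_stack([a * np.array([1, -1, 1, -1.0]),
                                 b * np.array([1, 1, -1, -1.0])])
    betas = np.array([[2.0, 2.0], [4.0, -2.0]])
    white = prewhiten(betas, residuals, shrinkage=0.4)
    assert np.allclose(white, betas * [0.5, 1.0], atol=1e-10)


def test_prewhitening_decorrelates_residuals():
    rng = np.random.default_rng(0)
    v = 12
    mix = rng.normal(size=(v, v)) * 0.4 + np.eye(v)
    residuals = rng.normal(size=(400, v)) @ mix.T
    w = whitening_matrix(residuals, shrinkage=0.1)
    white = residuals @ w
    def mean_abs_offdiag(x):
        c = np.corrcoef(x.T)
        return np.abs(c[~np.eye(v, dtype=bool)]).mean()
    assert mean_abs_offdiag(white) < mean_abs_offdiag(residuals) / 2


def test_prewhiten_validates_voxel_dimension():
    with pytest.raises(ValueError):
        prewhiten(np.zeros((2, 3)), np.zeros((10, 4)))


# ---------------------------------------------------------------------------
# cross-run RDM

def test_cross_run_rdm_orthogonal_identical_runs():
    run = np.array([[1, -1, 1, -1.0], [1, 1, -1, -1.0], [1, -1, -1, 1.0]])
    rdm = cross_run_rdm(run, run)
    assert np.allclose(np.diag(rdm), 0.0, atol=1e-12)
    off = rdm[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 1.0, atol=1e-12)


def test_cross_run_rdm_anticorrelation_and_symmetry():
    rng = np.random.default_rng(1)
    run1 = rng.normal(size=(5, 30))
    run2 = rng.normal(size=(5, 30))
    run2[2] = -run1[2]
    rdm = cross_run_rdm(run1, run2)
    assert rdm[2, 2] == pytest.approx(2.0)
    assert np.allclose(rdm, rdm.T, atol=1e-14)
    assert np.all(rdm >= 0) and np.all(rdm <= 2)


def test_cross_run_rdm_zero_variance_flagged():
    run1 = np.ones((2, 5))
    run2 = np.random.default_rng(0).normal(size=(2, 5))
    with pytest.warns(UserWarning, match="zero-variance"):
        rdm = cross_run_rdm(run1, run2)
    assert np.isnan(rdm).all()


def test_contrast_scale_invariance():
    rng = np.random.default_rng(2)
    run1, run2 = rng.normal(size=(2, 8, 40))
    spec = structure_contrast(_labels8())
    v1 = contrast_value(cross_run_rdm(run1, run2), spec)
    v2 = contrast_value(cross_run_rdm(7.3 * run1, 7.3 * run2), spec)
    assert v1 == pytest.approx(v2, abs=1e-12)


# ---------------------------------------------------------------------------
# contrasts

def test_contrast_value_arithmetic():
    labels = _labels8()
    spec = structure_contrast(labels)
    rdm = np.where(spec.similar, 0.2, 0.6)
    assert contrast_value(rdm, spec) == pytest.approx(0.4)
    assert contrast_value(np.full((8, 8), 0.7), spec) == pytest.approx(0.0)


def test_contrast_spec_validation():
    labels = _labels8()
    sim = structure_contrast(labels).similar
    with pytest.raises(ValueError):
        ContrastSpec(similar=sim, dissimilar=sim, exclude=np.zeros_like(sim))
    with pytest.raises(ValueError):
        contrast_value(np.zeros((8, 8)),
                       ContrastSpec(similar=sim, dissimilar=~sim, exclude=np.ones_like(sim)))


def _planted_patterns(rng, labels, effect, noise=1.0, v=80, key="structure_sign"):
    protos = {k: rng.normal(size=v) for k in labels[key].unique()}
    runs = np.stack([
        np.stack([effect * protos[k] + noise * rng.normal(size=v)
                  for k in labels[key]]) for _ in range(2)])
    return runs


def test_planted_contrast_monotone_in_effect():
    labels = _labels8()
    spec = structure_contrast(labels)
    rng = np.random.default_rng(3)
    means = []
    for effect in (0.0, 0.1, 0.3):
        vals = []
        for _ in range(40):
            runs = _planted_patterns(rng, labels, effect)
            vals.append(contrast_value(cross_run_rdm(runs[0], runs[1]), spec))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_element_masking_controls_keep_planted_contrast_positive():
    """Excluding same-stimulus or same-set elements must not kill a true
    structure effect (the geometry lives in cross-set pairs too)."""
    labels = _labels8()
    rng = np.random.default_rng(4)
    for exclude in ("same_stim", "same_set"):
        spec = structure_contrast(labels, exclude=exclude)
        vals = [contrast_value(cross_run_rdm(*_planted_patterns(rng, labels, 0.5)), spec)
                for _ in range(30)]
        assert np.mean(vals) > 0.05


# ---------------------------------------------------------------------------
# searchlights

def test_searchlight_size_and_truncation():
    coords = np.argwhere(np.ones((6, 6, 6), dtype=bool)).astype(float)
    nbr = searchlight_neighbors(coords, 100)
    assert nbr.shape == (216, 100)
    with pytest.warns(UserWarning, match="truncating"):
        nbr_small = searchlight_neighbors(coords[:50], 100)
    assert nbr_small.shape == (50, 50)


def test_searchlight_null_map_mean_near_zero():
    rng = np.random.default_rng(5)
    labels = _labels8()
    v = 125
    coords = np.argwhere(np.ones((5, 5, 5), dtype=bool)).astype(float)
    cp = ConditionPatterns(patterns=rng.normal(size=(2, 8, v)), labels=labels)
    residuals = rng.normal(size=(300, v))
    maps, _ = searchlight_map(cp, residuals, coords, k=30,
                              specs=structure_contrast(labels))
    assert abs(maps.mean()) < 0.05


# ---------------------------------------------------------------------------
# sign-flip inference

def _enumeration_oracle(values):
    """Brute-force exhaustive sign-flip p for one voxel."""
    values = np.asarray(values, dtype=float)
    obs = values.mean()
    count = 0
    for signs in itertools.product([-1, 1], repeat=len(values)):
        if np.dot(signs, values) / len(values) >= obs - 1e-12:
            count += 1
    return count / 2 ** len(values)


def test_sign_flip_exact_matches_enumeration():
    rng = np.random.default_rng(6)
    maps = rng.normal(0.3, 1.0, size=(10, 6))
    res = sign_flip_test(maps, exact=True)
    oracle = [_enumeration_oracle(maps[:, v]) for v in range(maps.shape[1])]
    assert np.allclose(res.p, oracle)


def test_sign_flip_known_cases():
    # identical positive values: only the identity flip reaches the observed mean
    maps = np.tile([[1.0], [1.0]], (5, 3))[:10]
    maps = np.full((10, 3), 1.0) + np.random.default_rng(7).normal(0, 1e-3, (10, 3))
    res = sign_flip_test(maps, exact=True)
    assert np.allclose(res.p, 1.0 / 2 ** 10)
    # values symmetric around zero: p near one half
    sym = np.concatenate([np.full(5, 0.8), np.full(5, -0.8)])[:, None]
    res_sym = sign_flip_test(sym + np.random.default_rng(8).normal(0, 1e-4, (10, 1)),
                             exact=True)
    assert 0.3 < res_sym.p[0] < 0.7
    # all-zero maps: every permutation ties
    res0 = sign_flip_test(np.zeros((6, 2)), exact=True)
    assert np.all(res0.p == 1.0)


def test_sign_flip_random_approximates_exact():
    rng = np.random.default_rng(9)
    maps = rng.normal(0.5, 1.0, size=(9, 4))
    exact = sign_flip_test(maps, exact=True).p
    approx = sign_flip_test(maps, n_perm=4000, seed=1).p
    assert np.all(np.abs(exact - approx) < 0.03 + 2.0 / np.sqrt(4000))


def test_sign_flip_p_uniform_under_null():
    """Pooled exact sign-flip p values are approximately uniform under the null."""
    rng = np.random.default_rng(10)
    pooled = []
    for _ in range(150):
        maps = rng.normal(size=(10, 8))
        pooled.extend(sign_flip_test(maps, exact=True).p)
    ks = stats.kstest(pooled, "uniform")
    assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# cluster-mass FWE

def test_cluster_fwe_empty_when_nothing_suprathreshold():
    rng = np.random.default_rng(11)
    mask = np.ones((4, 4, 4), dtype=bool)
    maps = rng.normal(0, 0.01, size=(8, 64))
    table, details = cluster_mass_fwe(maps, mask, n_perm=200, seed=0)
    assert len(table) == 0
    assert details["null_max_mass"].shape == (200,)


def test_cluster_fwe_ranks_blobs_by_mass():
    rng = np.random.default_rng(12)
    mask = np.ones((8, 8, 4), dtype=bool)
    maps = rng.normal(0, 1.0, size=(12, mask.sum()))
    vol_strong = np.zeros(mask.shape)
    vol_strong[1:3, 1:3, 1:3] = 6.0   # 8-voxel strong blob
    vol_weak = np.zeros(mask.shape)
    vol_weak[6:8, 6:8, 1:2] = 4.0     # 4-voxel weaker blob
    maps = maps + (vol_strong + vol_weak)[mask][None, :]
    table, details = cluster_mass_fwe(maps, mask, n_perm=300, seed=2)
    assert len(table) >= 2
    table = table.sort_values("mass", ascending=False)
    assert table.iloc[0]["p_fwe"] <= table.iloc[1]["p_fwe"]
    assert table.iloc[0]["n_voxels"] == 8


def test_cluster_fwe_validation():
    mask = np.ones((3, 3, 3), dtype=bool)
    maps = np.zeros((5, 27))
    with pytest.raises(ValueError):
        cluster_mass_fwe(maps, mask, threshold_p=1.5)
    with pytest.raises(ValueError):
        cluster_mass_fwe(maps, mask, connectivity=10)
    with pytest.raises(ValueError):
        cluster_mass_fwe(maps[:1], mask)


def test_cluster_fwe_permutation_forming_agrees_at_high_nperm():
    """With enough permutations, permutation-p forming finds the same blob."""
    rng = np.random.default_rng(13)
    mask = np.ones((6, 6, 3), dtype=bool)
    maps = rng.normal(size=(10, mask.sum()))
    blob = np.zeros(mask.shape)
    blob[2:4, 2:4, :] = 5.0
    maps += blob[mask][None, :]
    t_par, _ = cluster_mass_fwe(maps, mask, n_perm=2000, seed=3, forming="parametric")
    t_perm, _ = cluster_mass_fwe(maps, mask, n_perm=2000, seed=3, forming="permutation")
    assert len(t_par) >= 1 and len(t_perm) >= 1
    assert t_par["mass"].max() == pytest.approx(t_perm["mass"].max(), rel=0.2)


# ---------------------------------------------------------------------------
# ROI tests and leave-one-out

def _labels4():
    return pd.DataFrame({"structure_sign": [-1, -1, 1, 1],
                         "stimulus_set": [1, 2, 1, 2],
                         "stimulus": ["AB"] * 4})


def test_roi_single_voxel_equals_direct_t_test():
    rng = np.random.default_rng(14)
    labels = _labels4()
    spec = structure_contrast(labels)
    rdms, vals = [], []
    for _ in range(9):
        runs = _planted_patterns(rng, labels, 0.4, v=50)
        rdm = cross_run_rdm(runs[0], runs[1])
        rdms.append(rdm[None])
        vals.append(contrast_value(rdm, spec))
    res = roi_test(rdms, spec)
    direct = stats.ttest_1samp(vals, 0.0, alternative="greater")
    assert res.statistic == pytest.approx(direct.statistic, abs=1e-10)
    assert res.p == pytest.approx(direct.pvalue, abs=1e-12)


def test_roi_test_calibration_and_power():
    rng = np.random.default_rng(15)
    labels = _labels4()
    spec = structure_contrast(labels)

    def cohort_p(effect, n_subj=20):
        rdms = []
        for _ in range(n_subj):
            runs = _planted_patterns(rng, labels, effect, noise=1.0, v=100)
            rdms.append(cross_run_rdm(runs[0], runs[1])[None])
        return roi_test(rdms, spec).p

    null_rej = np.mean([cohort_p(0.0, n_subj=10) < 0.05 for _ in range(120)])
    assert abs(null_rej - 0.05) < 0.07  # loose band at 120 repeats
    power = np.mean([cohort_p(0.3) < 0.05 for _ in range(60)])
    assert power > 0.8


def test_leave_one_out_behavior():
    mask = np.ones((5, 5, 3), dtype=bool)
    rng = np.random.default_rng(16)
    base = rng.normal(size=mask.sum())
    # identical subjects: every leave-one-out p is the same
    maps = np.tile(base, (6, 1)) + 3.0
    ps = leave_one_out(maps, mask, n_perm=100, seed=4)
    assert len(ps) == 6 and len(set(np.round(ps, 12))) == 1
    with pytest.raises(ValueError):
        leave_one_out(maps[:2], mask, n_perm=50, seed=0)
    # strong planted effect: robust to any single subject
    blob = np.zeros(mask.shape)
    blob[1:4, 1:4, :] = 4.0
    maps = rng.normal(size=(10, mask.sum())) + blob[mask][None, :]
    ps = leave_one_out(maps, mask, n_perm=300, seed=5)
    assert all(p < 0.05 for p in ps)


# ---------------------------------------------------------------------------
# dendrograms

def test_dendrogram_merges_well_separated_pairs_first():
    rdm = np.array([
        [0.0, 0.1, 1.0, 1.0],
        [0.1, 0.0, 1.0, 1.0],
        [1.0, 1.0, 0.0, 0.1],
        [1.0, 1.0, 0.1, 0.0],
    ])
    z = dendrogram_linkage(rdm)
    first_two = {frozenset(z[0, :2].astype(int)), frozenset(z[1, :2].astype(int))}
    assert first_two == {frozenset({0, 1}), frozenset({2, 3})}


def test_dendrogram_reproduces_ultrametric():
    from scipy.cluster.hierarchy import cophenet
    from scipy.spatial.distance import squareform
    rdm = np.array([
        [0.0, 0.2, 0.9, 0.9],
        [0.2, 0.0, 0.9, 0.9],
        [0.9, 0.9, 0.0, 0.4],
        [0.9, 0.9, 0.4, 0.0],
    ])
    z = dendrogram_linkage(rdm)
    coph = cophenet(z)
    assert np.allclose(coph, squareform(rdm), atol=1e-12)


def test_dendrogram_groups_by_structure_not_set():
    rng = np.random.default_rng(17)
    labels = _labels4()
    runs = _planted_patterns(rng, labels, 1.0, noise=0.3, v=60)
    z = dendrogram_linkage(cross_run_rdm(runs[0], runs[1]))
    merged = {frozenset(z[0, :2].astype(int)), frozenset(z[1, :2].astype(int))}
    # conditions 0,1 share -Corr, 2,3 share +Corr (different stimulus sets)
    assert merged == {frozenset({0, 1}), frozenset({2, 3})}
    with pytest.raises(ValueError):
        dendrogram_linkage(np.zeros((1, 1)))
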