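"""Representational similarity analysis with cross-run distances and
sign-flip permutation inference.

The unit of analysis is a pair of per-run condition patterns (spatially
prewhitened GLM coefficients over the voxels of a searchlight). The
cross-run correlation distance between conditions i and j is the mean of
the two between-run correlation distances, which makes the RDM symmetric by
construction and gives the diagonal a meaning: the consistency of a
condition's pattern across runs. Hypotheses about representational geometry
are contrasts between the mean of "dissimilar" and "similar" RDM elements
(optionally excluding same-stimulus or same-stimulus-set elements as
controls). Group inference sign-flips per-subject contrast maps to build
the null of the group mean, with max-cluster-mass FWE correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform


# ---------------------------------------------------------------------------
# condition patterns and distances

@dataclass
class ConditionPatterns:
    """Per-run condition patterns over a common voxel set.

    ``patterns`` has shape (2 runs, n_conditions, n_voxels); ``labels`` is a
    DataFrame with columns ``structure_sign``, ``stimulus_set`` and
    (optionally null) ``stimulus``.
    """

    patterns: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self):
        if self.patterns.ndim != 3 or self.patterns.shape[0] != 2:
            raise ValueError("patterns must be (2 runs, conditions, voxels)")
        if self.patterns.shape[2] < 2:
            raise ValueError("need at least 2 voxels")
        if len(self.labels) != self.patterns.shape[1]:
            raise ValueError("labels must match the condition count")


def shrunk_covariance(residuals: np.ndarray, shrinkage=0.4) -> np.ndarray:
    """Residual spatial covariance shrunk toward its diagonal.

    ``shrinkage`` is the fixed shrinkage intensity in [0, 1], or ``"auto"``
    for the analytic optimal intensity (Schafer-Strimmer style) targeting
    the diagonal.
    """
    r = residuals - residuals.mean(axis=0, keepdims=True)
    t = r.shape[0]
    if t < 2:
        raise ValueError("need at least 2 residual timepoints")
    s = r.T @ r / (t - 1)
    if shrinkage == "auto":
        r2 = r ** 2
        var_s = (r2.T @ r2 / t - (r.T @ r / t) ** 2) * t / (t - 1) ** 2
        off = ~np.eye(s.shape[0], dtype=bool)
        denom = (s[off] ** 2).sum()
        lam = 1.0 if denom == 0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))
    else:
        lam = float(shrinkage)
    return (1 - lam) * s + lam * np.diag(np.diag(s))


def whitening_matrix(residuals: np.ndarray, shrinkage=0.4) -> np.ndarray:
    """Inverse matrix square root of the shrunk residual covariance."""
    cov = shrunk_covariance(residuals, shrinkage)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, 1e-12 * evals.max())
    return (evecs * (evals ** -0.5)) @ evecs.T


def prewhiten(betas: np.ndarray, residuals: np.ndarray, shrinkage=0.4) -> np.ndarray:
    """Spatially prewhiten coefficient patterns with the residual covariance.

    ``betas`` is (..., n_voxels); ``residuals`` is (timepoints, n_voxels)
    from the same GLM.
    """
    if residuals.shape[1] != betas.shape[-1]:
        raise ValueError("betas and residuals must share the voxel dimension")
    return betas @ whitening_matrix(residuals, shrinkage)


def _row_normalize(x):
    z = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(z, axis=1, keepdims=True)
    bad = norm[:, 0] == 0
    norm[bad] = 1.0
    return z / norm, bad


def cross_run_rdm(run1: np.ndarray, run2: np.ndarray) -> np.ndarray:
    """Symmetric cross-run correlation-distance RDM with meaningful diagonal.

    ``d[i, j]`` is the mean of the correlation distances (1 - r) between
    condition i's run-1 pattern and condition j's run-2 pattern, and vice
    versa. The diagonal is the cross-run distance of a condition to itself.
    Conditions with zero-variance patterns yield NaN entries (flagged with a
    warning) rather than an arbitrary distance.
    """
    if run1.shape != run2.shape:
        raise ValueError("runs must share condition and voxel dimensions")
    z1, bad1 = _row_normalize(run1.astype(float))
    z2, bad2 = _row_normalize(run2.astype(float))
    d = 1.0 - z1 @ z2.T
    rdm = 0.5 * (d + d.T)
    bad = bad1 | bad2
    if bad.any():
        warnings.warn("zero-variance condition pattern; RDM entries set to NaN")
        rdm[bad, :] = np.nan
        rdm[:, bad] = np.nan
    return rdm


# ---------------------------------------------------------------------------
# model-RDM contrasts

@dataclass(frozen=True)
class ContrastSpec:
    """Element sets of an RDM hypothesis: dissimilar-mean minus similar-mean."""

    similar: np.ndarray
    dissimilar: np.ndarray
    exclude: np.ndarray
    name: str = ""

    def __post_init__(self):
        if (self.similar & self.dissimilar).any():
            raise ValueError("similar and dissimilar element sets must be disjoint")
        if not self.similar.any() or not self.dissimilar.any():
            raise ValueError("element sets must be non-empty")


def structure_contrast(labels: pd.DataFrame, exclude: str = "none") -> ContrastSpec:
    """Same-structure pairs similar, different-structure pairs dissimilar.

    ``exclude`` drops control elements: ``"same_stim"`` ignores same-stimulus
    pairs (including the diagonal), ``"same_set"`` ignores same-stimulus-set
    pairs.
    """
    sign = labels["structure_sign"].to_numpy()
    same_structure = sign[:, None] == sign[None, :]
    ex = _exclusion_mask(labels, exclude)
    return ContrastSpec(similar=same_structure, dissimilar=~same_structure,
                        exclude=ex, name=f"structure[{exclude}]")


def stimulus_contrast(labels: pd.DataFrame, exclude: str = "none") -> ContrastSpec:
    """Same-visual-stimulus pairs similar, all other pairs dissimilar."""
    ident = labels[["stimulus_set", "stimulus"]].astype(str).agg("/".join, axis=1).to_numpy()
    same = ident[:, None] == ident[None, :]
    return ContrastSpec(similar=same, dissimilar=~same,
                        exclude=_exclusion_mask(labels, exclude),
                        name=f"stimulus[{exclude}]")


def _exclusion_mask(labels, exclude):
    n = len(labels)
    if exclude == "none":
        return np.zeros((n, n), dtype=bool)
    sset = labels["stimulus_set"].to_numpy()
    if exclude == "same_set":
        return sset[:, None] == sset[None, :]
    if exclude == "same_stim":
        ident = labels[["stimulus_set", "stimulus"]].astype(str).agg("/".join, axis=1).to_numpy()
        return ident[:, None] == ident[None, :]
    raise ValueError("exclude must be 'none', 'same_stim' or 'same_set'")


def contrast_value(rdm: np.ndarray, spec: ContrastSpec) -> float:
    """Mean over "dissimilar" elements minus mean over "similar" elements."""
    sim = spec.similar & ~spec.exclude
    dis = spec.dissimilar & ~spec.exclude
    if not sim.any() or not dis.any():
        raise ValueError("contrast element sets are empty after exclusion")
    svals, dvals = rdm[sim], rdm[dis]
    if np.isnan(svals).any() or np.isnan(dvals).any():
        warnings.warn("NaN RDM entries excluded from contrast")
        if np.isnan(svals).all() or np.isnan(dvals).all():
            return np.nan
    return float(np.nanmean(dvals) - np.nanmean(svals))


# ---------------------------------------------------------------------------
# searchlights

def searchlight_neighbors(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest in-mask voxels (3-D Euclidean) per voxel."""
    n = coords.shape[0]
    if k > n:
        warnings.warn(f"mask has {n} voxels < searchlight size {k}; truncating")
        k = n
    tree = cKDTree(coords)
    _, nbr = tree.query(coords, k=k)
    return np.atleast_2d(nbr)


def searchlight_map(patterns: ConditionPatterns, residuals: np.ndarray,
                    coords: np.ndarray, k: int, specs,
                    shrinkage=0.4, resid_step: int = 1,
                    return_rdms: bool = False):
    """Searchlight contrast map(s) for one subject.

    For every in-mask voxel, the ``k`` nearest in-mask voxels form the
    searchlight; the condition patterns restricted to it are prewhitened
    with the local residual covariance, summarized as a cross-run RDM, and
    scored by each :class:`ContrastSpec`. ``resid_step`` thins the residual
    timepoints used for covariance estimation (every ``resid_step``-th
    frame).

    Returns ``(maps, rdms)`` where ``maps`` is (n_specs, n_voxels) and
    ``rdms`` is (n_voxels, C, C) when requested (else None).
    """
    single = isinstance(specs, ContrastSpec)
    spec_list = [specs] if single else list(specs)
    pats = patterns.patterns
    n_vox = pats.shape[2]
    if residuals.shape[1] != n_vox or coords.shape[0] != n_vox:
        raise ValueError("patterns, residuals and coords must share the voxel set")
    if k < 2:
        raise ValueError("searchlights need at least 2 voxels")
    nbr = searchlight_neighbors(coords, k)
    resid = np.ascontiguousarray(residuals[::max(resid_step, 1)], dtype=np.float32)
    pats32 = np.ascontiguousarray(pats, dtype=np.float32)
    maps = np.empty((len(spec_list), n_vox))
    rdms = np.empty((n_vox, pats.shape[1], pats.shape[1])) if return_rdms else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-voxel NaN warnings would flood
        for v in range(n_vox):
            idx = nbr[v]
            w = whitening_matrix(resid[:, idx], shrinkage)
            white = pats32[:, :, idx] @ w
            rdm = cross_run_rdm(white[0], white[1])
            if return_rdms:
                rdms[v] = rdm
            for s_i, spec in enumerate(spec_list):
                maps[s_i, v] = contrast_value(rdm, spec)
    return (maps[0] if single else maps), rdms


# ---------------------------------------------------------------------------
# group inference

@dataclass
class SignFlipResult:
    p: np.ndarray           # one-tailed p per voxel (positive tail)
    mean: np.ndarray        # observed group mean per voxel
    t: np.ndarray           # observed group t per voxel
    n_perm: int
    exact: bool


def _group_t(maps, flips):
    """t statistics of sign-flipped group means; flips is (n_perm, S)."""
    s = maps.shape[0]
    m = flips @ maps / s
    ss = (maps ** 2).sum(axis=0)
    var = np.maximum(ss - s * m ** 2, 0.0) / (s - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / np.sqrt(var / s)
    t[np.isnan(t)] = 0.0  # all-zero columns
    return m, t


def _enumerate_flips(n):
    bits = np.arange(2 ** n, dtype=np.int64)
    return 1 - 2 * ((bits[:, None] >> np.arange(n)) & 1).astype(np.int64)


def sign_flip_test(maps: np.ndarray, n_perm: int = 10000, seed: int = 0,
                   exact: bool = False) -> SignFlipResult:
    """One-tailed sign-flip permutation test of a positive group mean.

    Under the null the per-subject contrasts are symmetric around zero, so
    each subject's map is multiplied by a random sign (shared across voxels
    within a permutation). With random flips,
    ``p = (1 + #{permuted means >= observed}) / (1 + n_perm)``; with
    ``exact=True`` all 2^S flip patterns are enumerated and
    ``p = #{enumerated means >= observed} / 2^S`` (the identity pattern
    makes p exact and positive).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need a (subjects, voxels) array with >= 2 subjects")
    s = maps.shape[0]
    obs_mean, obs_t = _group_t(maps, np.ones((1, s)))
    obs_mean, obs_t = obs_mean[0], obs_t[0]
    if exact:
        if s > 16:
            raise ValueError("exact enumeration is limited to 16 subjects")
        flips = _enumerate_flips(s)
        means = flips @ maps / s
        p = (means >= obs_mean - 1e-12).sum(axis=0) / flips.shape[0]
        return SignFlipResult(p=p, mean=obs_mean, t=obs_t,
                              n_perm=flips.shape[0], exact=True)
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1, 1], size=(n_perm, s))
    means = flips @ maps / s
    p = (1 + (means >= obs_mean - 1e-12).sum(axis=0)) / (1 + n_perm)
    return SignFlipResult(p=p, mean=obs_mean, t=obs_t, n_perm=n_perm, exact=False)


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def cluster_mass_fwe(subject_maps: np.ndarray, mask: np.ndarray,
                     threshold_p: float = 0.001, connectivity: int = 6,
                     n_perm: int = 10000, seed: int = 0,
                     forming: str = "parametric"):
    """Max-cluster-mass FWE correction over sign-flip permutations.

    ``subject_maps`` is (subjects, n_mask_voxels) in the flat order of
    ``mask`` (C-order of ``np.where(mask)``). Voxels passing the
    cluster-forming threshold are grouped by face/edge/corner adjacency
    (``connectivity`` in {6, 18, 26}) and each cluster is scored by its mass
    — the sum of the group t statistic over member voxels. The null is the
    maximum cluster mass per permutation, with flips shared across voxels
    within a permutation.

    ``forming`` selects the cluster-forming rule: ``"parametric"``
    thresholds the t map at the one-tailed Student-t quantile for
    ``threshold_p`` (well defined at any permutation count);
    ``"permutation"`` thresholds the permutation p map (requires
    ``n_perm >= 1/threshold_p`` to be attainable).

    Returns ``(cluster_table, details)``; the table has one row per observed
    cluster with its size, mass and FWE-corrected p.
    """
    if not 0.0 < threshold_p < 1.0:
        raise ValueError("threshold_p must lie in (0, 1)")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    maps = np.asarray(subject_maps, dtype=float)
    s = maps.shape[0]
    if s < 2:
        raise ValueError("need >= 2 subjects")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() != maps.shape[1]:
        raise ValueError("subject_maps voxel count must match the mask")
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1, 1], size=(n_perm, s))
    _, obs_t = _group_t(maps, np.ones((1, s)))
    obs_t = obs_t[0]
    _, perm_t = _group_t(maps, flips)

    if forming == "parametric":
        t_thr = stats.t.ppf(1.0 - threshold_p, df=s - 1)
        obs_supra = obs_t > t_thr
        perm_supra = perm_t > t_thr
    elif forming == "permutation":
        ge = (perm_t >= obs_t[None, :] - 1e-12).sum(axis=0)
        obs_p = (1 + ge) / (1 + n_perm)
        obs_supra = obs_p < threshold_p
        # p of each permuted map against the same permutation family
        order = np.argsort(-perm_t, axis=0, kind="stable")
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(1, n_perm + 1)[:, None], axis=0)
        perm_p = (1 + ranks) / (1 + n_perm)
        perm_supra = perm_p < threshold_p
    else:
        raise ValueError("forming must be 'parametric' or 'permutation'")

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    flat_index = np.where(mask)

    def cluster_masses(supra_flat, t_flat):
        vol = np.zeros(mask.shape, dtype=bool)
        vol[flat_index] = supra_flat
        labels, n = ndimage.label(vol, structure=structure)
        if n == 0:
            return labels, np.array([])
        tvol = np.zeros(mask.shape)
        tvol[flat_index] = t_flat
        masses = ndimage.sum_labels(tvol, labels, index=np.arange(1, n + 1))
        return labels, masses

    obs_labels, obs_masses = cluster_masses(obs_supra, obs_t)
    null_max = np.zeros(n_perm)
    for kperm in range(n_perm):
        if perm_supra[kperm].any():
            _, masses = cluster_masses(perm_supra[kperm], perm_t[kperm])
            if masses.size:
                null_max[kperm] = masses.max()

    rows = []
    labels_in_mask = obs_labels[flat_index]
    for c, mass in enumerate(obs_masses, start=1):
        members = labels_in_mask == c
        p_fwe = (1 + (null_max >= mass - 1e-12).sum()) / (1 + n_perm)
        rows.append({"cluster": c, "n_voxels": int(members.sum()),
                     "mass": float(mass), "p_fwe": float(p_fwe),
                     "peak_t": float(obs_t[members].max())})
    table = pd.DataFrame(rows, columns=["cluster", "n_voxels", "mass", "p_fwe", "peak_t"])
    details = {"t_map": obs_t, "labels": obs_labels, "null_max_mass": null_max,
               "labels_in_mask": labels_in_mask}
    return table, details


def roi_test(rdms_per_subject, spec: ContrastSpec, roi_average: bool = True):
    """One-tailed group test of an RDM contrast within an ROI.

    ``rdms_per_subject`` is a list (or array) of per-subject stacks of
    searchlight RDMs over the ROI voxels, shape (n_roi_voxels, C, C). With
    ``roi_average`` the RDMs are first averaged across the ROI (the default,
    and the convention for a-priori ROIs); otherwise per-voxel contrasts are
    averaged instead.
    """
    from .comparison import _one_sample_t
    vals = []
    for rdms in rdms_per_subject:
        rdms = np.asarray(rdms, dtype=float)
        if rdms.ndim == 2:
            rdms = rdms[None]
        if rdms.shape[0] == 0:
            raise ValueError("empty ROI")
        if roi_average:
            vals.append(contrast_value(np.nanmean(rdms, axis=0), spec))
        else:
            vals.append(np.nanmean([contrast_value(r, spec) for r in rdms]))
    return _one_sample_t(np.array(vals), tail="greater")


def leave_one_out(subject_maps: np.ndarray, mask: np.ndarray, **fwe_kwargs):
    """Smallest FWE-corrected cluster p with each subject left out in turn.

    Reruns the sign-flip cluster-mass pipeline once per held-out subject and
    returns the list of minimal corrected p values (1.0 when no cluster
    forms), a robustness check that no single subject drives the effect.
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.shape[0] < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    out = []
    for held in range(maps.shape[0]):
        sub = np.delete(maps, held, axis=0)
        table, _ = cluster_mass_fwe(sub, mask, **fwe_kwargs)
        out.append(float(table["p_fwe"].min()) if len(table) else 1.0)
    return out


def dendrogram_linkage(rdm: np.ndarray, labels=None):
    """Average-linkage agglomerative tree over conditions.

    Uses the off-diagonal distances (self-distance set to 0 for the linkage
    algorithm; the meaningful diagonal plays no role in merging). Returns a
    scipy linkage matrix.
    """
    rdm = np.asarray(rdm, dtype=float)
    if rdm.shape[0] < 2:
        raise ValueError("need at least 2 conditions")
    d = 0.5 * (rdm + rdm.T)
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")
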