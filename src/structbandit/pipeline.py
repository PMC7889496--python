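"""End-to-end orchestration: behavior -> fits -> crossval -> phantom -> RSA.

A single :class:`RunConfig` seeds and parameterizes every stage. Each
stochastic stage receives a child seed derived deterministically from the
master seed, so a full run is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, glm, learning, phantom, rsa, task
from .learning import FitConfig, LearnerParams, NAIVE, STRUCT
from .task import BLOCK_TYPE_ORDER


@dataclass
class RunConfig:
    """All stage parameters of a pipeline run.

    Defaults mirror the scanner task and analysis conventions: per-trial
    switch probability 0.15, parameter bounds alpha in [0,1] / cross-terms
    in [-1,1] / beta in [0,8] (fixed in the learning module), 100-voxel
    searchlights, 10000 sign-flip permutations, cluster-forming p 0.001 and
    a 6 s HRF peak delay.
    """

    seed: int = 0
    out_dir: str = "pipeline_out"
    n_subjects: int = 12
    # simulated agent (correct structure knowledge)
    agent_alpha: float = 0.4
    agent_beta: float = 5.0
    agent_h_ab: float = 1.0     # magnitude; sign follows the block structure
    # fitting
    n_starts: int = 10
    fit_tol: float = 1e-6
    # phantom
    noise_sd: float = 1.0
    effect_structure: float = 1.0
    effect_stimulus: float = 1.0
    effect_pe: float = 1.0
    # rsa
    searchlight_k: int = 100
    shrinkage: float = 0.4
    resid_step: int = 4
    n_perm: int = 10000
    cluster_p: float = 0.001
    connectivity: int = 6
    hrf_delay: float = 6.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def child_seed(self, stage: str) -> int:
        import zlib
        ss = np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        return int(ss.generate_state(1)[0] % (2 ** 31))

    def agent_params(self) -> dict:
        """True per-structure learner params of the simulated cohort."""
        mk = lambda sgn: LearnerParams(alpha=self.agent_alpha, beta=self.agent_beta,
                                       h_ab=sgn * self.agent_h_ab, model_tag=STRUCT)
        return {+1: mk(+1), -1: mk(-1)}


# ---------------------------------------------------------------------------
# behavioral stages

def behavior_stage(config: RunConfig) -> pd.DataFrame:
    return task.simulate_cohort(config.n_subjects, config.child_seed("behavior"),
                                config.agent_params())


def fitting_stage(behavior: pd.DataFrame, config: RunConfig):
    """Pooled per-structure fits of both models for every subject."""
    fc = FitConfig(n_starts=config.n_starts, tol=config.fit_tol,
                   seed=config.child_seed("fit"))
    struct_fits, naive_fits = [], []
    for _, sub_df in behavior.groupby("subject", sort=True):
        struct_fits.append(learning.fit_by_structure(sub_df, STRUCT, fc))
        naive_fits.append(learning.fit_by_structure(sub_df, NAIVE, fc))
    return struct_fits, naive_fits


def crossval_stage(behavior: pd.DataFrame, config: RunConfig):
    """Per-subject 4x4 crossval matrices plus the group comparisons."""
    fc = FitConfig(n_starts=config.n_starts, tol=config.fit_tol,
                   seed=config.child_seed("crossval"))
    masks = comparison.crossval_masks()
    struct_mats, naive_mats = [], []
    for _, sub_df in behavior.groupby("subject", sort=True):
        m_s, _ = comparison.crossval_matrix(sub_df, STRUCT, fc)
        m_n, _ = comparison.crossval_matrix(sub_df, NAIVE, fc)
        struct_mats.append(m_s.to_numpy())
        naive_mats.append(m_n.to_numpy())
    tests = {
        "struct_within_vs_across": comparison.within_across_test(
            struct_mats, masks["within"], masks["across"], tail="two-sided"),
        "struct_within_vs_naive_diag": comparison.within_across_test(
            [(s, n) for s, n in zip(struct_mats, naive_mats)],
            masks["within"], masks["diag"], tail="two-sided"),
    }
    return struct_mats, naive_mats, tests


# ---------------------------------------------------------------------------
# imaging stages

def _condition_patterns(sub: phantom.SubjectPhantom, layout: str,
                        hrf_delay: float):
    """Fit a per-block GLM and collect RSA patterns and residuals.

    Returns ``(ConditionPatterns, residuals)``. Conditions are the four
    block types (x the two related stimuli for GLM2), with one pattern per
    run.
    """
    behavior = sub.behavior
    deriv = sub.derivatives
    if layout == "GLM2":
        cond_cols = [("A", "A_stim"), ("B", "B_stim")]
    elif layout == "GLM2a":
        cond_cols = [("AB", "AB_stim")]
    elif layout == "GLM3":
        cond_cols = [("AB", "pe_AB")]
    else:
        raise ValueError(f"no RSA pattern rule for layout {layout!r}")
    n_vox = next(iter(sub.bold_blocks.values())).shape[0]
    n_cond = 4 * len(cond_cols)
    patterns = np.zeros((2, n_cond, n_vox))
    rows = []
    for bt in BLOCK_TYPE_ORDER:
        sign = +1 if bt.startswith("+") else -1
        sset = int(bt[-1])
        for stim, _ in cond_cols:
            rows.append({"structure_sign": sign, "stimulus_set": sset,
                         "stimulus": stim, "block_type": bt})
    labels = pd.DataFrame(rows)
    resid_parts = []
    for block_id, bdf in behavior.groupby("block", sort=True):
        events = glm.build_canonical_glm(layout, bdf, derivatives=deriv)
        design = glm.build_design([events], tr=sub.spec.tr, hrf_delay=hrf_delay)
        fit = glm.fit_glm(sub.bold_blocks[int(block_id)].astype(float), design)
        resid_parts.append(fit.residuals.T)
        run = int(bdf["run"].iloc[0]) - 1
        bt = bdf["block_type"].iloc[0]
        for stim, col in cond_cols:
            cond = labels.index[(labels["block_type"] == bt)
                                & (labels["stimulus"] == stim)][0]
            patterns[run, cond] = fit.beta(f"b{block_id}:{col}")
    cp = rsa.ConditionPatterns(patterns=patterns,
                               labels=labels[["structure_sign", "stimulus_set",
                                              "stimulus"]])
    return cp, np.vstack(resid_parts)


def subject_contrast_maps(sub: phantom.SubjectPhantom, config: RunConfig,
                          return_rdms: bool = False, exclude: str = "none"):
    """Searchlight contrast maps for the three planted-geometry hypotheses.

    - ``structure``: same- vs different-structure contrast on the collapsed
      4-condition RDM (GLM2a patterns) — the default structure readout,
      since A/B identity cannot be aligned across stimulus sets;
    - ``stimulus``: visual-identity contrast on the 8-condition GLM2 RDM;
    - ``pe_by_structure``: structure contrast on the 4-condition RDM of
      prediction-error parametric patterns (GLM3).

    ``exclude`` applies the element-masking control (``"same_stim"`` or
    ``"same_set"``) to the structure contrast.
    """
    coords = sub.spec.mask_coords
    out, rdms_out = {}, {}

    cp2, resid2 = _condition_patterns(sub, "GLM2", config.hrf_delay)
    spec_stim = rsa.stimulus_contrast(cp2.labels)
    maps, rdms = rsa.searchlight_map(cp2, resid2, coords, config.searchlight_k,
                                     [spec_stim], shrinkage=config.shrinkage,
                                     resid_step=config.resid_step,
                                     return_rdms=return_rdms)
    out["stimulus"] = maps[0]
    rdms_out["stimulus"] = rdms

    cp2a, resid2a = _condition_patterns(sub, "GLM2a", config.hrf_delay)
    spec_struct = rsa.structure_contrast(cp2a.labels, exclude=exclude)
    maps, rdms = rsa.searchlight_map(cp2a, resid2a, coords, config.searchlight_k,
                                     [spec_struct], shrinkage=config.shrinkage,
                                     resid_step=config.resid_step,
                                     return_rdms=return_rdms)
    out["structure"] = maps[0]
    rdms_out["structure"] = rdms

    cp3, resid3 = _condition_patterns(sub, "GLM3", config.hrf_delay)
    spec_pe = rsa.structure_contrast(cp3.labels)
    maps, rdms = rsa.searchlight_map(cp3, resid3, coords, config.searchlight_k,
                                     [spec_pe], shrinkage=config.shrinkage,
                                     resid_step=config.resid_step,
                                     return_rdms=return_rdms)
    out["pe_by_structure"] = maps[0]
    rdms_out["pe_by_structure"] = rdms
    return (out, rdms_out) if return_rdms else out


def imaging_stage(behavior: pd.DataFrame, config: RunConfig, exclude: str = "none"):
    """Phantom generation + searchlight maps for the whole cohort."""
    spec = phantom.PhantomSpec(noise_sd=config.noise_sd, effects={
        "structure": config.effect_structure,
        "stimulus": config.effect_stimulus,
        "pe_by_structure": config.effect_pe,
    }, n_subjects=config.n_subjects)
    seed = config.child_seed("phantom")
    params = config.agent_params()
    maps = {name: [] for name in ("structure", "stimulus", "pe_by_structure")}
    for _, sub_df in behavior.groupby("subject", sort=True):
        scanner = sub_df[sub_df["run"] > 0]
        sub = phantom.generate_subject(spec, scanner, params, seed)
        sub_maps = subject_contrast_maps(sub, config, exclude=exclude)
        for name in maps:
            maps[name].append(sub_maps[name])
    maps = {name: np.stack(v) for name, v in maps.items()}
    return spec, maps


def inference_stage(spec: phantom.PhantomSpec, maps: dict, config: RunConfig):
    """Sign-flip + cluster-mass FWE per contrast and detection scoring."""
    truth = phantom.ground_truth(spec)
    results = {}
    for name, subject_maps in maps.items():
        sf = rsa.sign_flip_test(subject_maps, n_perm=config.n_perm,
                                seed=config.child_seed(f"flip-{name}"))
        table, details = rsa.cluster_mass_fwe(
            subject_maps, spec.mask, threshold_p=config.cluster_p,
            connectivity=config.connectivity, n_perm=config.n_perm,
            seed=config.child_seed(f"flip-{name}"))
        sig = table[table["p_fwe"] < 0.05]["cluster"].to_numpy()
        detected = np.isin(details["labels_in_mask"], sig)
        scores = {target: phantom.score_detection(detected, exp)
                  for target, exp in truth.expected.items()}
        results[name] = {"p_map": sf.p, "clusters": table, "detected": detected,
                         "scores": scores,
                         "labels_in_mask": details["labels_in_mask"]}
    return results


# ---------------------------------------------------------------------------
# full run

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, writing every intermediate artifact and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings, report = {}, {}

    def timed(stage, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:  # stage-tagged diagnostics
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        return result

    if config.n_subjects < 3:
        warnings.warn(f"group tests will run with dof={config.n_subjects - 1}")

    behavior = timed("simulate-behavior", behavior_stage, config)
    task.write_behavior(behavior, out / "behavior.tsv")

    struct_fits, naive_fits = timed("fit", fitting_stage, behavior, config)
    for tag, fits in (("struct", struct_fits), ("naive", naive_fits)):
        records = []
        for s, f in enumerate(fits):
            for sign, fr in f.items():
                rec = {"subject": s, "structure": sign}
                rec.update(fr.to_dict())
                records.append(rec)
        with open(out / f"fits_{tag}.json", "w") as fh:
            json.dump(records, fh, indent=2)

    struct_mats, naive_mats, group_tests = timed("crossval", crossval_stage,
                                                 behavior, config)
    cv_dir = out / "crossval"
    cv_dir.mkdir(exist_ok=True)
    for s, (ms, mn) in enumerate(zip(struct_mats, naive_mats)):
        pd.DataFrame(ms, index=BLOCK_TYPE_ORDER, columns=BLOCK_TYPE_ORDER).to_csv(
            cv_dir / f"sub-{s:02d}_STRUCT.tsv", sep="\t")
        pd.DataFrame(mn, index=BLOCK_TYPE_ORDER, columns=BLOCK_TYPE_ORDER).to_csv(
            cv_dir / f"sub-{s:02d}_NAIVE.tsv", sep="\t")
    # cohort-level exports of the matrices, both summed and averaged
    np.savetxt(cv_dir / "STRUCT_groupsum.tsv", np.sum(struct_mats, axis=0), delimiter="\t")
    np.savetxt(cv_dir / "STRUCT_groupmean.tsv", np.mean(struct_mats, axis=0), delimiter="\t")

    ct_test = comparison.cross_term_test(struct_fits)
    ic = comparison.information_criteria(struct_fits, naive_fits)
    ic.to_csv(out / "information_criteria.tsv", sep="\t", index=False)
    group_json = {name: {"t": res.statistic, "dof": res.dof, "p": res.p,
                         "tail": res.tail, "degenerate": res.degenerate}
                  for name, res in {**group_tests, "cross_terms": ct_test}.items()}
    with open(out / "group_tests.json", "w") as fh:
        json.dump(group_json, fh, indent=2)

    spec, maps = timed("simulate-fmri+glm+rsa", imaging_stage, behavior, config)
    results = timed("inference", inference_stage, spec, maps, config)
    rsa_dir = out / "rsa"
    rsa_dir.mkdir(exist_ok=True)
    detection = {}
    for name, res in results.items():
        res["clusters"].to_csv(rsa_dir / f"{name}_clusters.tsv", sep="\t", index=False)
        _save_map(rsa_dir / f"{name}_pmap.nii.gz", res["p_map"], spec)
        detection[name] = res["scores"]
    with open(rsa_dir / "detection.json", "w") as fh:
        json.dump(detection, fh, indent=2)

    report.update({"group_tests": group_json, "detection": detection,
                   "timings_s": timings})
    manifest = {"seed": config.seed, "config": asdict(config),
                "stage_seeds": {s: config.child_seed(s) for s in
                                ("behavior", "fit", "crossval", "phantom")},
                "timings_s": timings}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return {"behavior": behavior, "struct_fits": struct_fits,
            "naive_fits": naive_fits, "crossval": (struct_mats, naive_mats),
            "group_tests": group_json, "rsa": results, "phantom_spec": spec,
            "detection": detection, "manifest": manifest}


def _save_map(path, values, spec):
    import nibabel as nib
    vol = phantom.embed_in_volume(values, spec, fill=np.nan)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), np.diag([2., 2., 2., 1.])),
             path)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
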