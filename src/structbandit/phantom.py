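"""Synthetic multi-subject BOLD phantoms with known representational truth.

The phantom plants four disjoint voxel regions inside an analysis mask:

- ``structure``: stimulus-onset patterns shared by all conditions of the
  same relational structure (and differing across structures);
- ``stimulus``: stimulus-onset patterns keyed by visual stimulus identity;
- ``pe_by_structure``: prediction-error parametric patterns keyed by the
  relational structure;
- ``null``: no signal.

BOLD time series are the event design (stick + HRF, built from a simulated
subject's actual trial timings and model derivatives) times the planted
coefficient patterns, plus Gaussian noise (optionally AR(1)). A matching
ground-truth record lists the voxels each RSA contrast should detect, so
searchlight, permutation and FWE stages can be scored end to end without
any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import BlockEvents, Regressor, build_design, build_canonical_glm
from .learning import trial_derivatives

REGION_ROLES = ("structure", "stimulus", "pe_by_structure", "null")


@dataclass
class PhantomSpec:
    """Geometry, effect sizes and noise of the synthetic cohort."""

    shape: tuple = (20, 20, 20)
    tr: float = 1.235
    noise_sd: float = 1.0
    effects: dict = field(default_factory=lambda: {
        "structure": 1.0, "stimulus": 1.0, "pe_by_structure": 1.0})
    n_subjects: int = 12
    ar1: float = 0.0
    regions: dict = None          # role -> 3D bool mask
    mask: np.ndarray = None       # analysis mask, 3D bool

    def __post_init__(self):
        if self.regions is None or self.mask is None:
            regions, mask = default_geometry(self.shape)
            self.regions = self.regions or regions
            self.mask = self.mask if self.mask is not None else mask
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(e < 0 for e in self.effects.values()):
            raise ValueError("effect sizes must be non-negative")
        flat = [self.regions[r][self.mask] for r in self.regions]
        if (np.stack(flat).sum(0) > 1).any():
            raise ValueError("regions must be disjoint")
        for role, reg in self.regions.items():
            if reg.shape != tuple(self.shape):
                raise ValueError(f"region {role!r} does not match the grid")
            if (reg & ~self.mask).any():
                raise ValueError(f"region {role!r} leaves the analysis mask")

    @property
    def mask_coords(self) -> np.ndarray:
        return np.argwhere(self.mask).astype(float)

    def region_flat(self, role) -> np.ndarray:
        """Region membership in the flat in-mask voxel order."""
        return self.regions[role][self.mask]


def default_geometry(shape=(20, 20, 20)):
    """Central 16x16x16 analysis mask with four disjoint 150-voxel regions.

    Regions sit in the mask corners with pairwise gaps of at least 6 voxels:
    a 100-voxel nearest-neighbour searchlight centred at a mask corner can
    reach ~(3*8*100 / 4pi)^(1/3) ~ 5.8 voxels, so smaller gaps would let a
    searchlight centred in one region pick up another region's signal.
    """
    if min(shape) < 18:
        raise ValueError("default geometry needs a grid of at least 18 per axis")
    mask = np.zeros(shape, dtype=bool)
    mask[2:18, 2:18, 2:18] = True
    regions = {}
    slices = {
        "structure": (slice(2, 7), slice(2, 7), slice(2, 8)),
        "stimulus": (slice(13, 18), slice(2, 7), slice(2, 8)),
        "pe_by_structure": (slice(2, 7), slice(13, 18), slice(12, 18)),
        "null": (slice(13, 18), slice(13, 18), slice(12, 18)),
    }
    for role, sl in slices.items():
        m = np.zeros(shape, dtype=bool)
        m[sl] = True
        regions[role] = m
    return regions, mask


@dataclass
class SubjectPhantom:
    """One subject's synthetic acquisition: per-block BOLD over mask voxels."""

    subject: int
    bold_blocks: dict          # block id -> (n_mask_voxels, T) float32
    behavior: pd.DataFrame     # scanner behavior with choices
    derivatives: pd.DataFrame  # STRUCT derivatives aligned with behavior
    spec: PhantomSpec


@dataclass
class GroundTruth:
    """Expected-positive voxel sets (flat in-mask order) per contrast."""

    expected: dict             # contrast name -> bool (n_mask_voxels,)
    spec: PhantomSpec


def _generation_events(block_df, deriv) -> BlockEvents:
    """Events driving the synthetic BOLD: GLM2 mains plus a PE parametric."""
    ev = build_canonical_glm("GLM2", block_df, derivatives=None)
    ab = block_df["stimulus"].isin(["A", "B"])
    pe_vals = deriv.loc[block_df.index[ab], "correctness_pe"].to_numpy()
    ev.regressors.append(Regressor("pe_AB", block_df.loc[ab, "onset_outcome_s"].to_numpy(),
                                   modulator=pe_vals, role="parametric"))
    return ev


def generate_subject(spec: PhantomSpec, behavior: pd.DataFrame,
                     params_by_structure, seed: int) -> SubjectPhantom:
    """Synthesize one subject's BOLD from their behavior and planted geometry.

    Prototype patterns are drawn once per subject per region (standard
    normal over region voxels), keyed by relational structure for the
    ``structure`` and ``pe_by_structure`` regions and by stimulus identity
    for the ``stimulus`` region.
    """
    subject = int(behavior["subject"].iloc[0])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), subject, 99]))
    deriv = trial_derivatives(behavior, params_by_structure)
    n_vox = int(spec.mask.sum())

    def proto(region):
        return rng.standard_normal(int(spec.regions[region].sum()))

    proto_structure = {s: proto("structure") for s in (-1, +1)}
    proto_pe = {s: proto("pe_by_structure") for s in (-1, +1)}
    stim_keys = [(k, s) for k in (1, 2) for s in ("A", "B", "C")]
    proto_stimulus = {key: proto("stimulus") for key in stim_keys}

    in_structure = spec.region_flat("structure")
    in_stimulus = spec.region_flat("stimulus")
    in_pe = spec.region_flat("pe_by_structure")

    bold_blocks = {}
    for block_id, bdf in behavior.groupby("block", sort=True):
        sign = int(bdf["structure_sign"].iloc[0])
        sset = int(bdf["stimulus_set"].iloc[0])
        events = _generation_events(bdf, deriv)
        design = build_design([events], tr=spec.tr)
        betas = np.zeros((n_vox, len(design.names)))
        for col, name in enumerate(design.names):
            short = name.split(":", 1)[1]
            if short in ("A_stim", "B_stim", "C_stim"):
                stim = short[0]
                if stim in ("A", "B"):
                    betas[in_structure, col] = (spec.effects["structure"]
                                                * proto_structure[sign])
                betas[in_stimulus, col] = (spec.effects["stimulus"]
                                           * proto_stimulus[(sset, stim)])
            elif short == "pe_AB":
                betas[in_pe, col] = (spec.effects["pe_by_structure"]
                                     * proto_pe[sign])
        t = design.n_frames
        noise = rng.standard_normal((n_vox, t)) * spec.noise_sd
        if spec.ar1:
            for i in range(1, t):
                noise[:, i] += spec.ar1 * noise[:, i - 1]
        bold_blocks[int(block_id)] = (betas @ design.matrix.T + noise).astype(np.float32)
    return SubjectPhantom(subject=subject, bold_blocks=bold_blocks,
                          behavior=behavior, derivatives=deriv, spec=spec)


def generate_cohort(spec: PhantomSpec, behavior, params_by_structure, seed: int):
    """Synthesize every subject's acquisition plus the shared ground truth.

    ``behavior`` is a cohort table from the task simulator (choices filled);
    only scanner runs (run > 0) drive the acquisition. Returns
    ``(subjects, truth)`` where ``subjects`` is a list of
    :class:`SubjectPhantom`.
    """
    subjects = []
    for _, sub_df in behavior.groupby("subject", sort=True):
        scanner = sub_df[sub_df["run"] > 0]
        subjects.append(generate_subject(spec, scanner, params_by_structure, seed))
    return subjects, ground_truth(spec)


def ground_truth(spec: PhantomSpec) -> GroundTruth:
    return GroundTruth(expected={
        "structure": spec.region_flat("structure"),
        "stimulus": spec.region_flat("stimulus"),
        "pe_by_structure": spec.region_flat("pe_by_structure"),
    }, spec=spec)


def score_detection(detected: np.ndarray, expected: np.ndarray) -> dict:
    """Voxelwise sensitivity/specificity of a suprathreshold set."""
    detected = np.asarray(detected, dtype=bool)
    expected = np.asarray(expected, dtype=bool)
    if detected.shape != expected.shape:
        raise ValueError("detected and expected grids must match")
    pos = expected.sum()
    neg = (~expected).sum()
    tp = (detected & expected).sum()
    tn = (~detected & ~expected).sum()
    return {"sensitivity": float(tp / pos) if pos else np.nan,
            "specificity": float(tn / neg) if neg else np.nan,
            "n_detected": int(detected.sum())}


def embed_in_volume(values: np.ndarray, spec: PhantomSpec, fill=0.0) -> np.ndarray:
    """Scatter flat in-mask values back into the 3-D grid."""
    vol = np.full(spec.shape, fill, dtype=float)
    vol[spec.mask] = values
    return vol


def save_bold_nifti(subject_phantom: SubjectPhantom, out_dir) -> list:
    """Write per-block 4-D BOLD volumes (and the mask) as NIfTI files."""
    import nibabel as nib
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = subject_phantom.spec
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    paths = []
    for block_id, bold in subject_phantom.bold_blocks.items():
        vol = np.zeros(spec.shape + (bold.shape[1],), dtype=np.float32)
        vol[spec.mask] = bold
        p = out_dir / f"sub-{subject_phantom.subject:02d}_block-{block_id}_bold.nii.gz"
        nib.save(nib.Nifti1Image(vol, affine), p)
        paths.append(p)
    nib.save(nib.Nifti1Image(spec.mask.astype(np.uint8), affine),
             out_dir / "analysis_mask.nii.gz")
    return paths
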