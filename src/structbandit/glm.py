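"""Event-based GLMs: stick regressors, double-gamma HRF, least squares.

Regressors are delta functions at event onsets (optionally scaled by a
mean-centered parametric modulator), convolved with a double-gamma
hemodynamic response function whose peak delay is configurable (6 s default;
8.5 s for the slow medial-prefrontal response), and resampled to the TR
grid. Blocks are modeled separately: each block contributes its own set of
regressor columns plus an intercept, so a multi-block design matrix is
block-diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import gamma as gamma_dist

GLM_LAYOUTS = ("GLM1", "GLM2", "GLM2a", "GLM3")


def hrf_kernel(peak_delay: float = 6.0, dt: float = 0.1, duration: float = 32.0,
               undershoot_ratio: float = 1.0 / 6.0, dispersion: float = 1.0,
               undershoot_dispersion: float = 1.0) -> np.ndarray:
    """Double-gamma HRF sampled every ``dt`` seconds, normalized to unit peak.

    The undershoot delay scales proportionally with the peak delay (16 s at
    the canonical 6 s peak), so changing the delay to 8.5 s shifts the whole
    response rather than just the peak.
    """
    if peak_delay <= 0:
        raise ValueError("peak_delay must be positive")
    undershoot_delay = 16.0 * peak_delay / 6.0
    t = np.arange(0.0, duration, dt)
    # gamma(shape=a, scale=d) has its mode at (a - 1) d: put it at the delay
    h = (gamma_dist.pdf(t, peak_delay / dispersion + 1.0, scale=dispersion)
         - undershoot_ratio
         * gamma_dist.pdf(t, undershoot_delay / undershoot_dispersion + 1.0,
                          scale=undershoot_dispersion))
    return h / h.max()


@dataclass(frozen=True)
class Regressor:
    """Stick-event regressor: onsets in seconds, optional parametric modulator."""

    name: str
    onsets: np.ndarray
    modulator: np.ndarray | None = None
    role: str = "main"  # main | parametric | nuisance

    def __post_init__(self):
        object.__setattr__(self, "onsets", np.asarray(self.onsets, dtype=float))
        if self.modulator is not None:
            mod = np.asarray(self.modulator, dtype=float)
            if mod.shape != self.onsets.shape:
                raise ValueError("modulator must match onsets")
            object.__setattr__(self, "modulator", mod)


@dataclass
class BlockEvents:
    """Event regressors of one block plus optional TR-gridded nuisance columns."""

    regressors: list
    duration: float
    nuisance: np.ndarray | None = None  # (n_frames, n_nuisance)
    label: str | int = 0


@dataclass
class DesignMatrix:
    matrix: np.ndarray          # (T, P)
    names: list                 # column names, "b{block}:{regressor}"
    frame_times: np.ndarray     # (T,) seconds, restarting per block
    block_of_row: np.ndarray    # (T,)
    block_of_col: np.ndarray    # (P,)

    @property
    def n_frames(self):
        return self.matrix.shape[0]

    def column(self, name):
        return self.matrix[:, self.names.index(name)]


def _dct_drift_basis(n_frames, tr, cutoff_s):
    """Discrete-cosine high-pass drift basis (frequencies below 1/cutoff)."""
    order = int(np.floor(2 * n_frames * tr / cutoff_s))
    t = np.arange(n_frames)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_frames)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))


def _build_block(block: BlockEvents, tr, kernel, dt, drift_cutoff_s):
    n_frames = int(np.ceil(block.duration / tr))
    frame_times = np.arange(n_frames) * tr
    n_hi = int(np.ceil(block.duration / dt)) + kernel.size
    hi_times = np.arange(n_hi) * dt
    cols, names = [], []
    for reg in block.regressors:
        if np.any(reg.onsets >= block.duration):
            raise ValueError(f"regressor {reg.name!r} has onsets beyond block duration")
        if reg.onsets.size == 0:
            continue  # an event type absent from this block contributes no column
        sticks = np.zeros(n_hi)
        amp = reg.modulator
        if amp is not None:
            amp = amp - amp.mean()  # mean-center parametric modulators per block
        else:
            amp = np.ones(reg.onsets.size)
        idx = np.round(reg.onsets / dt).astype(int)
        np.add.at(sticks, idx, amp)
        conv = np.convolve(sticks, kernel)[:n_hi]
        cols.append(np.interp(frame_times, hi_times, conv))
        names.append(reg.name)
    if block.nuisance is not None:
        nuis = np.asarray(block.nuisance, dtype=float)
        if nuis.shape[0] != n_frames:
            raise ValueError("nuisance rows must match the block's TR frames")
        for k in range(nuis.shape[1]):
            cols.append(nuis[:, k])
            names.append(f"nuisance{k}")
    if drift_cutoff_s is not None:
        drift = _dct_drift_basis(n_frames, tr, drift_cutoff_s)
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            names.append(f"drift{k}")
    cols.append(np.ones(n_frames))
    names.append("intercept")
    return np.column_stack(cols), names, frame_times


def build_design(blocks, tr: float, hrf_delay: float = 6.0, dt: float = 0.1,
                 drift_cutoff_s: float | None = None) -> DesignMatrix:
    """Assemble a (block-diagonal) design matrix from per-block events."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    kernel = hrf_kernel(peak_delay=hrf_delay, dt=dt)
    mats, all_names, times, row_blk, col_blk = [], [], [], [], []
    for b, block in enumerate(blocks):
        x, names, ft = _build_block(block, tr, kernel, dt, drift_cutoff_s)
        mats.append(x)
        all_names.extend(f"b{block.label}:{n}" for n in names)
        times.append(ft)
        row_blk.append(np.full(x.shape[0], b))
        col_blk.append(np.full(x.shape[1], b))
    matrix = linalg.block_diag(*mats) if len(mats) > 1 else mats[0]
    return DesignMatrix(matrix=matrix, names=all_names,
                        frame_times=np.concatenate(times),
                        block_of_row=np.concatenate(row_blk),
                        block_of_col=np.concatenate(col_blk))


@dataclass
class GlmFit:
    betas: np.ndarray       # (V, P)
    residuals: np.ndarray   # (V, T)
    resid_var: np.ndarray   # (V,)
    design: DesignMatrix

    def beta(self, name):
        return self.betas[:, self.design.names.index(name)]


def fit_glm(bold: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Voxelwise ordinary least squares; ``bold`` is (voxels, time)."""
    x = design.matrix
    if bold.shape[1] != x.shape[0]:
        raise ValueError("bold time dimension must match the design")
    q, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    small = np.abs(np.diag(r)) < np.abs(r[0, 0]) * 1e-10
    if small.any():
        bad = [design.names[p] for p in piv[small]]
        raise ValueError(f"design is rank deficient; offending columns: {bad}")
    betas, *_ = np.linalg.lstsq(x, bold.T, rcond=None)
    betas = betas.T
    resid = bold - betas @ x.T
    dof = max(x.shape[0] - x.shape[1], 1)
    return GlmFit(betas=betas, residuals=resid,
                  resid_var=(resid ** 2).sum(axis=1) / dof, design=design)


def contrast_map(fit: GlmFit, weights) -> np.ndarray:
    """Weighted sum of coefficients per voxel.

    ``weights`` is either a full-length vector or a mapping from column
    name to weight (unnamed columns get 0).
    """
    if isinstance(weights, dict):
        w = np.zeros(len(fit.design.names))
        for name, val in weights.items():
            w[fit.design.names.index(name)] = val
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(fit.design.names):
            raise ValueError("weight length must equal the number of columns")
    return fit.betas @ w


def _onsets(block_df, stimuli, which):
    col = {"stim": "onset_stim_s", "outcome": "onset_outcome_s"}[which]
    m = block_df["stimulus"].isin(stimuli)
    return block_df.loc[m, col].to_numpy()


def build_canonical_glm(layout: str, block_df: pd.DataFrame, derivatives=None,
                    nuisance=None) -> BlockEvents:
    """Event set of one block in one of the four canonical GLM layouts.

    - ``GLM1``: [AB] stimulus/outcome mains; chosen-action-value parametric
      regressors from both STRUCT and NAIVE models at [AB] stimulus time
      (entered together, unorthogonalized); [C] mains; accept/reject button
      regressors.
    - ``GLM2``: per-stimulus mains (A, B, C) at stimulus and outcome times
      plus buttons — the per-stimulus pattern GLM for RSA.
    - ``GLM2a``: the related pair collapsed onto a single [AB] regressor.
    - ``GLM3``: [AB]/[C] outcome mains, a "correctness" prediction-error
      parametric regressor from the STRUCT model at [AB] outcome time,
      stimulus mains and buttons.

    ``derivatives`` carries per-trial model regressor values aligned with
    ``block_df``: a mapping with keys ``"STRUCT"``/``"NAIVE"`` for GLM1, or
    the STRUCT table (or same mapping) for GLM3.
    """
    if layout not in GLM_LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {GLM_LAYOUTS}")
    df = block_df
    label = df["block"].iloc[0]
    regs = []
    if layout == "GLM1":
        if not isinstance(derivatives, dict) or not {"STRUCT", "NAIVE"} <= set(derivatives):
            raise ValueError("GLM1 needs derivatives for both STRUCT and NAIVE")
        ab = df["stimulus"].isin(["A", "B"])
        regs += [Regressor("AB_stim", _onsets(df, ["A", "B"], "stim")),
                 Regressor("AB_outcome", _onsets(df, ["A", "B"], "outcome"))]
        for tag in ("STRUCT", "NAIVE"):
            vals = derivatives[tag].loc[df.index[ab], "chosen_action_value"].to_numpy()
            regs.append(Regressor(f"chosen_value_{tag}", _onsets(df, ["A", "B"], "stim"),
                                  modulator=vals, role="parametric"))
        regs += [Regressor("C_stim", _onsets(df, ["C"], "stim")),
                 Regressor("C_outcome", _onsets(df, ["C"], "outcome"))]
    elif layout == "GLM2":
        for s in ("A", "B", "C"):
            regs.append(Regressor(f"{s}_stim", _onsets(df, [s], "stim")))
        for s in ("A", "B", "C"):
            regs.append(Regressor(f"{s}_outcome", _onsets(df, [s], "outcome")))
    elif layout == "GLM2a":
        regs += [Regressor("AB_stim", _onsets(df, ["A", "B"], "stim")),
                 Regressor("C_stim", _onsets(df, ["C"], "stim")),
                 Regressor("AB_outcome", _onsets(df, ["A", "B"], "outcome")),
                 Regressor("C_outcome", _onsets(df, ["C"], "outcome"))]
    elif layout == "GLM3":
        deriv = derivatives["STRUCT"] if isinstance(derivatives, dict) else derivatives
        if deriv is None:
            raise ValueError("GLM3 needs STRUCT derivatives")
        ab = df["stimulus"].isin(["A", "B"])
        vals = deriv.loc[df.index[ab], "correctness_pe"].to_numpy()
        regs += [Regressor("AB_outcome", _onsets(df, ["A", "B"], "outcome")),
                 Regressor("C_outcome", _onsets(df, ["C"], "outcome")),
                 Regressor("pe_AB", _onsets(df, ["A", "B"], "outcome"),
                           modulator=vals, role="parametric"),
                 Regressor("AB_stim", _onsets(df, ["A", "B"], "stim")),
                 Regressor("C_stim", _onsets(df, ["C"], "stim"))]
    for ch in ("accept", "reject"):
        m = df["choice"] == ch
        regs.append(Regressor(ch, df.loc[m, "onset_choice_s"].to_numpy()))
    duration = float(df["onset_outcome_s"].max()) + 15.0
    return BlockEvents(regressors=regs, duration=duration, nuisance=nuisance,
                       label=label)


def smooth_nuisance(n_frames: int, rng, n_series: int = 6,
                    smooth_frames: float = 20.0) -> np.ndarray:
    """Six smooth random series standing in for motion parameters."""
    raw = rng.standard_normal((n_frames + 200, n_series))
    w = np.exp(-0.5 * (np.arange(-60, 61) / (smooth_frames / 2.355)) ** 2)
    w /= w.sum()
    sm = np.apply_along_axis(lambda c: np.convolve(c, w, mode="same"), 0, raw)
    sm = sm[100:100 + n_frames]
    return (sm - sm.mean(0)) / sm.std(0)
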