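"""Cross-term delta-rule learners, choice likelihood and constrained ML fitting.

The STRUCT learner tracks, for each of the three bandits, an estimate
``g`` in [-1, 1] of the (rescaled) probability of a good outcome. After an
outcome ``y`` in {-1, +1} on the presented stimulus X the estimates update as

    g_X <- (1 - alpha) g_X + alpha y
    g_Y <- (1 - alpha |H_XY|) g_Y + alpha H_XY y        (Y != X)

where ``H_XY`` in [-1, 1] is the cross-term coupling stimulus pair (X, Y):
+1 treats them as the same bandit, -1 as mirrored bandits, 0 as independent.
The NAIVE learner is the nested standard delta-rule model with all
cross-terms fixed at 0. Choices are generated by a sigmoid selector,
``P(accept) = 1 / (1 + exp(-beta g))``, beta in [0, 8].

Beliefs reset to 0 at the start of every block, and updates are skipped on
trials without outcome feedback (the choice itself still enters the
likelihood). Parameters are estimated by bound-constrained maximum
likelihood (L-BFGS-B, multi-start from a seeded Latin hypercube).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.stats import qmc

from .task import STIMULI

STRUCT = "STRUCT"
NAIVE = "NAIVE"

#: unordered stimulus pairs in canonical order; cross-term vector h = [H_AB, H_AC, H_BC]
PAIRS = (("A", "B"), ("A", "C"), ("B", "C"))

_PROB_FLOOR = 1e-12  # floor inside log, guards beta at its bound


@dataclass(frozen=True)
class LearnerParams:
    """Parameters of a cross-term learner for one relational structure."""

    alpha: float
    beta: float
    h_ab: float = 0.0
    h_ac: float = 0.0
    h_bc: float = 0.0
    model_tag: str = STRUCT

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.beta <= 8.0:
            raise ValueError("beta must lie in [0, 8]")
        for h in (self.h_ab, self.h_ac, self.h_bc):
            if not -1.0 <= h <= 1.0:
                raise ValueError("cross-terms must lie in [-1, 1]")
        if self.model_tag not in (STRUCT, NAIVE):
            raise ValueError("model_tag must be STRUCT or NAIVE")
        if self.model_tag == NAIVE and any(h != 0.0 for h in (self.h_ab, self.h_ac, self.h_bc)):
            raise ValueError("NAIVE model requires all cross-terms to be 0")

    @property
    def h(self) -> np.ndarray:
        return np.array([self.h_ab, self.h_ac, self.h_bc])

    @property
    def n_free_params(self) -> int:
        return 5 if self.model_tag == STRUCT else 2

    def cross_term_matrix(self) -> np.ndarray:
        """Symmetric 3x3 matrix M with M[x, y] = H_xy and zero diagonal."""
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = self.h_ab
        m[0, 2] = m[2, 0] = self.h_ac
        m[1, 2] = m[2, 1] = self.h_bc
        return m

    def to_dict(self) -> dict:
        return {"model": self.model_tag, "alpha": self.alpha, "beta": self.beta,
                "H_AB": self.h_ab, "H_AC": self.h_ac, "H_BC": self.h_bc}


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: LearnerParams
    nll: float
    n_trials: int
    n_free_params: int
    converged: bool
    starts_used: int

    def to_dict(self) -> dict:
        d = self.params.to_dict()
        d.update({"nll": self.nll, "n_trials": self.n_trials,
                  "n_free_params": self.n_free_params})
        return d


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings: start count, tolerance, seed."""

    n_starts: int = 10
    tol: float = 1e-6
    seed: int = 0


def update_beliefs(g, presented, y, params: LearnerParams) -> np.ndarray:
    """One cross-term delta-rule update; returns a new belief vector.

    ``g`` is the length-3 belief vector over (A, B, C); ``presented`` is a
    stimulus label or index; ``y`` is the outcome in {-1, +1}.
    """
    if y not in (-1, 1):
        raise ValueError("outcome y must be -1 or +1")
    s = STIMULI.index(presented) if isinstance(presented, str) else int(presented)
    g = np.asarray(g, dtype=float).copy()
    hmat = params.cross_term_matrix()
    for o in range(3):
        if o == s:
            g[o] = (1 - params.alpha) * g[o] + params.alpha * y
        else:
            h = hmat[s, o]
            g[o] = (1 - params.alpha * abs(h)) * g[o] + params.alpha * h * y
    return g


def p_accept(g, beta):
    """Sigmoid selector: probability of accepting given belief g."""
    return 1.0 / (1.0 + np.exp(-beta * np.asarray(g, dtype=float)))


@njit(cache=False)
def _nll_kernel(stim, y, feedback, accept, new_block, alpha, beta, h_ab, h_ac, h_bc):
    hmat = np.zeros((3, 3))
    hmat[0, 1] = hmat[1, 0] = h_ab
    hmat[0, 2] = hmat[2, 0] = h_ac
    hmat[1, 2] = hmat[2, 1] = h_bc
    g = np.zeros(3)
    nll = 0.0
    for t in range(stim.size):
        if new_block[t]:
            g[:] = 0.0
        s = stim[t]
        p = 1.0 / (1.0 + np.exp(-beta * g[s]))
        like = p if accept[t] else 1.0 - p
        if like < _PROB_FLOOR:
            like = _PROB_FLOOR
        nll -= np.log(like)
        if feedback[t]:
            yt = y[t]
            for o in range(3):
                if o == s:
                    g[o] = (1.0 - alpha) * g[o] + alpha * yt
                else:
                    hh = hmat[s, o]
                    g[o] = (1.0 - alpha * abs(hh)) * g[o] + alpha * hh * yt
    return nll


@njit(cache=False)
def _trajectory_kernel(stim, y, feedback, new_block, alpha, beta, h_ab, h_ac, h_bc):
    """Pre-update belief of the presented stimulus on every trial."""
    hmat = np.zeros((3, 3))
    hmat[0, 1] = hmat[1, 0] = h_ab
    hmat[0, 2] = hmat[2, 0] = h_ac
    hmat[1, 2] = hmat[2, 1] = h_bc
    g = np.zeros(3)
    g_pre = np.empty(stim.size)
    for t in range(stim.size):
        if new_block[t]:
            g[:] = 0.0
        s = stim[t]
        g_pre[t] = g[s]
        if feedback[t]:
            yt = y[t]
            for o in range(3):
                if o == s:
                    g[o] = (1.0 - alpha) * g[o] + alpha * yt
                else:
                    hh = hmat[s, o]
                    g[o] = (1.0 - alpha * abs(hh)) * g[o] + alpha * hh * yt
    return g_pre


def _encode(df: pd.DataFrame):
    """Behavior table -> flat arrays consumed by the numba kernels."""
    stim = df["stimulus"].map({s: i for i, s in enumerate(STIMULI)}).to_numpy(np.int64)
    y = df["outcome"].to_numpy(np.float64)
    feedback = df["feedback"].to_numpy(bool)
    block = df["block"].to_numpy()
    subject = df["subject"].to_numpy()
    new_block = np.ones(len(df), dtype=bool)
    if len(df) > 1:
        new_block[1:] = (block[1:] != block[:-1]) | (subject[1:] != subject[:-1])
    accept = None
    if df["choice"].notna().all():
        accept = (df["choice"] == "accept").to_numpy(bool)
    return stim, y, feedback, accept, new_block


def negative_log_likelihood(df: pd.DataFrame, params: LearnerParams) -> float:
    """Negative log likelihood of the observed choices under the learner.

    Beliefs reset to 0 at every block start; updates are skipped on
    no-feedback trials whose choices still contribute to the likelihood.
    """
    stim, y, feedback, accept, new_block = _encode(df)
    if accept is None:
        raise ValueError("behavior table has missing choices")
    return float(_nll_kernel(stim, y, feedback, accept, new_block,
                             params.alpha, params.beta,
                             params.h_ab, params.h_ac, params.h_bc))


_BOUNDS_STRUCT = [(0.0, 1.0), (0.0, 8.0), (-1.0, 1.0), (-1.0, 1.0), (-1.0, 1.0)]
_BOUNDS_NAIVE = [(0.0, 1.0), (0.0, 8.0)]


def _params_from_vector(x, model_tag):
    if model_tag == STRUCT:
        return LearnerParams(alpha=float(x[0]), beta=float(x[1]), h_ab=float(x[2]),
                             h_ac=float(x[3]), h_bc=float(x[4]), model_tag=STRUCT)
    return LearnerParams(alpha=float(x[0]), beta=float(x[1]), model_tag=NAIVE)


def fit(df: pd.DataFrame, model_tag: str = STRUCT,
        config: FitConfig = FitConfig()) -> FitResult:
    """Bound-constrained ML fit of the learner to observed choices.

    Runs L-BFGS-B from ``config.n_starts`` seeded Latin-hypercube starting
    points and keeps the best optimum. STRUCT fits 5 parameters (alpha, beta
    and the 3 cross-terms), NAIVE fits 2.
    """
    if len(df) == 0:
        raise ValueError("no trials to fit")
    if not df["feedback"].any():
        raise ValueError("all trials are feedback-less; parameters are unidentifiable")
    stim, y, feedback, accept, new_block = _encode(df)
    if accept is None:
        raise ValueError("behavior table has missing choices")
    bounds = _BOUNDS_STRUCT if model_tag == STRUCT else _BOUNDS_NAIVE
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(x):
        h = (x[2], x[3], x[4]) if model_tag == STRUCT else (0.0, 0.0, 0.0)
        return _nll_kernel(stim, y, feedback, accept, new_block, x[0], x[1], *h)

    sampler = qmc.LatinHypercube(d=len(bounds), seed=config.seed)
    starts = lo + sampler.random(config.n_starts) * (hi - lo)
    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": config.tol, "maxiter": 500})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    params = _params_from_vector(best.x, model_tag)
    return FitResult(params=params, nll=float(best.fun), n_trials=len(df),
                     n_free_params=params.n_free_params,
                     converged=any_converged, starts_used=config.n_starts)


def fit_by_structure(df: pd.DataFrame, model_tag: str = STRUCT,
                     config: FitConfig = FitConfig()) -> dict:
    """Pooled per-structure fits: one fit per structure sign over all its blocks."""
    return {int(s): fit(df[df["structure_sign"] == s], model_tag, config)
            for s in sorted(df["structure_sign"].unique())}


def fit_by_block_type(df: pd.DataFrame, model_tag: str = STRUCT,
                      config: FitConfig = FitConfig()) -> dict:
    """One fit per block type (the cross-validation training sets)."""
    return {bt: fit(df[df["block_type"] == bt], model_tag, config)
            for bt in sorted(df["block_type"].unique())}


def trial_derivatives(df: pd.DataFrame, params) -> pd.DataFrame:
    """Per-trial model quantities used as GLM regressors.

    Returns a table aligned with ``df`` containing:

    - ``stimulus_value``: pre-update belief g of the presented stimulus;
    - ``outcome_pe``: the outcome prediction error  eps = y - g;
    - ``chosen_action_value``: g on accepted trials, -g on rejections
      (a confident rejection is a high-value action);
    - ``correctness_pe``: |eps| signed positive when outcome and choice are
      congruent (accept-good or reject-bad), negative otherwise.

    ``params`` may be a single :class:`LearnerParams` or a mapping from
    structure sign to params (pooled per-structure fits).
    """
    if isinstance(params, LearnerParams):
        params = {s: params for s in df["structure_sign"].unique()}
    g_pre = np.empty(len(df))
    for sign, p in params.items():
        m = (df["structure_sign"] == sign).to_numpy()
        if not m.any():
            continue
        stim, y, feedback, _, new_block = _encode(df[m])
        g_pre[m] = _trajectory_kernel(stim, y, feedback, new_block,
                                      p.alpha, p.beta, p.h_ab, p.h_ac, p.h_bc)
    y = df["outcome"].to_numpy(float)
    accept = (df["choice"] == "accept").to_numpy(bool)
    eps = y - g_pre
    chosen = np.where(accept, g_pre, -g_pre)
    congruent = accept == (y > 0)
    correctness = np.where(congruent, np.abs(eps), -np.abs(eps))
    return pd.DataFrame({
        "stimulus_value": g_pre,
        "outcome_pe": eps,
        "chosen_action_value": chosen,
        "correctness_pe": correctness,
    }, index=df.index)


def save_fits(fits, path, subject=None) -> None:
    """Serialize per-structure fits as a JSON list of flat records."""
    import json
    records = []
    for key, fr in fits.items():
        rec = {"subject": subject, "structure": key}
        rec.update(fr.to_dict())
        records.append(rec)
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
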