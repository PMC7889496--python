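"""Cross-validated model comparison of STRUCT vs NAIVE learners.

Each subject's data splits into the four block types of the 2x2 design.
Fitting each model to each block type and evaluating its negative log
likelihood (NLL) on every block type yields a 4x4 cross-validation matrix
per model. Three element masks carry the hypotheses:

- ``within`` ("pink"): off-diagonal cells that train and test on different
  stimulus sets of the *same* relational structure;
- ``across`` ("green"): cells that cross the two structures;
- ``diag`` ("gray"): train = test cells.

A structure-sensitive learner should generalize within a structure but not
across, so for STRUCT the pink sum should undercut the green sum — and even
the NAIVE gray (same-data) sum, since the cross-terms carry genuinely
predictive information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .learning import (FitConfig, FitResult, LearnerParams, NAIVE, STRUCT,
                       fit_by_block_type, negative_log_likelihood,
                       trial_derivatives)
from .task import BLOCK_TYPE_ORDER


@dataclass(frozen=True)
class GroupTestResult:
    """A paired/one-sample t-test over per-subject contrast values."""

    statistic: float
    dof: int
    p: float
    tail: str
    contrasts: np.ndarray
    degenerate: bool = False


def _structure_of(block_type: str) -> int:
    return +1 if block_type.startswith("+") else -1


def crossval_masks(order=BLOCK_TYPE_ORDER):
    """Boolean 4x4 masks (within-structure off-diagonal, across, diagonal)."""
    signs = np.array([_structure_of(bt) for bt in order])
    same = signs[:, None] == signs[None, :]
    eye = np.eye(len(order), dtype=bool)
    return {"within": same & ~eye, "across": ~same, "diag": eye}


def crossval_matrix(behavior: pd.DataFrame, model_tag: str = STRUCT,
                    config: FitConfig = FitConfig(), fits: dict | None = None):
    """4x4 test-NLL matrix for one subject.

    Entry (i, j) is the NLL of the model fitted to block type i evaluated on
    the choices of block type j (beliefs reset per block). Returns
    ``(matrix, fits)`` where ``matrix`` is a DataFrame indexed by training
    block type.
    """
    missing = set(BLOCK_TYPE_ORDER) - set(behavior["block_type"].unique())
    if missing:
        raise ValueError(f"behavior table lacks block types: {sorted(missing)}")
    if fits is None:
        fits = fit_by_block_type(behavior, model_tag, config)
    mat = np.zeros((4, 4))
    for i, bt_train in enumerate(BLOCK_TYPE_ORDER):
        params = fits[bt_train].params
        for j, bt_test in enumerate(BLOCK_TYPE_ORDER):
            mat[i, j] = negative_log_likelihood(
                behavior[behavior["block_type"] == bt_test], params)
    return (pd.DataFrame(mat, index=BLOCK_TYPE_ORDER, columns=BLOCK_TYPE_ORDER),
            fits)


def _one_sample_t(values: np.ndarray, tail: str) -> GroupTestResult:
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("group tests need at least 2 subjects")
    sd = values.std(ddof=1)
    if sd == 0.0:
        # degenerate zero-variance contrast: report the limiting p
        mean = values.mean()
        if mean == 0.0:
            # an exactly-zero contrast carries no evidence either way
            p = 1.0 if tail == "two-sided" else 0.5
            t = 0.0
        else:
            t = np.inf * np.sign(mean)
            if tail == "two-sided":
                p = 0.0
            elif tail == "greater":
                p = 0.0 if mean > 0 else 1.0
            else:
                p = 0.0 if mean < 0 else 1.0
        return GroupTestResult(float(t), n - 1, float(p), tail, values, degenerate=True)
    res = stats.ttest_1samp(values, 0.0, alternative=tail)
    return GroupTestResult(float(res.statistic), n - 1, float(res.pvalue), tail, values)


def within_across_test(matrices, mask_a, mask_b, tail="two-sided") -> GroupTestResult:
    """Paired t-test of per-subject (sum over mask_a - sum over mask_b).

    ``matrices`` is a list with one 4x4 NLL array (or pairs of arrays: cell
    values are read off whichever array the mask indexes — pass tuples
    ``(mat_a, mat_b)`` to compare cells of two different models).
    """
    diffs = []
    for m in matrices:
        if isinstance(m, tuple):
            ma, mb = (np.asarray(x, dtype=float) for x in m)
        else:
            ma = mb = np.asarray(m, dtype=float)
        diffs.append(ma[mask_a].sum() - mb[mask_b].sum())
    return _one_sample_t(np.array(diffs), tail)


def divergent_trials(behavior: pd.DataFrame, params_1, params_2) -> pd.DataFrame:
    """Trials where the two models predict different choices.

    A model predicts "accept" iff its accept probability exceeds 0.5, i.e.
    iff its current belief g is positive; trials where either model sits
    exactly on the fence (g = 0) are excluded. Returns the behavior rows
    with the two models' beliefs appended — ready for histograms of g split
    by the subject's actual choice.
    """
    g1 = trial_derivatives(behavior, params_1)["stimulus_value"].to_numpy()
    g2 = trial_derivatives(behavior, params_2)["stimulus_value"].to_numpy()
    sel = (np.sign(g1) != np.sign(g2)) & (g1 != 0) & (g2 != 0)
    out = behavior.loc[sel, ["subject", "block", "block_type", "trial",
                             "stimulus", "choice", "outcome"]].copy()
    out["g_model1"] = g1[sel]
    out["g_model2"] = g2[sel]
    return out


def divergent_histograms(divergent: pd.DataFrame, bins=20):
    """Histogram tables of each model's beliefs split by actual choice."""
    edges = np.linspace(-1, 1, bins + 1)
    rows = []
    for model in ("g_model1", "g_model2"):
        for choice in ("accept", "reject"):
            counts, _ = np.histogram(
                divergent.loc[divergent["choice"] == choice, model], bins=edges)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                rows.append({"model": model, "choice": choice,
                             "bin_low": lo, "bin_high": hi, "count": int(c)})
    return pd.DataFrame(rows)


def cross_term_test(struct_fits_per_subject, tail="greater") -> GroupTestResult:
    """Do fitted related-pair cross-terms exceed the unrelated ones?

    For each subject, takes the mean over structures of |H_AB| minus the
    mean of (|H_AC| + |H_BC|)/2, then runs a one-tailed paired t-test of the
    differences against zero.
    """
    vals = []
    for fits in struct_fits_per_subject:
        per_structure = []
        for fr in fits.values():
            p = fr.params
            per_structure.append(abs(p.h_ab) - (abs(p.h_ac) + abs(p.h_bc)) / 2.0)
        vals.append(np.mean(per_structure))
    return _one_sample_t(np.array(vals), tail)


def information_criteria(struct_fits, naive_fits) -> pd.DataFrame:
    """AIC and BIC per subject for pooled STRUCT vs NAIVE fits.

    ``struct_fits`` / ``naive_fits`` are lists (one entry per subject) of
    per-structure fit dicts. Criteria per subject sum over structures:
    AIC = 2k + 2 NLL, BIC = k ln(n) + 2 NLL. A group-total row is appended.
    """
    rows = []
    for s, (sf, nf) in enumerate(zip(struct_fits, naive_fits)):
        nll_s = sum(fr.nll for fr in sf.values())
        nll_n = sum(fr.nll for fr in nf.values())
        k_s = sum(fr.n_free_params for fr in sf.values())
        k_n = sum(fr.n_free_params for fr in nf.values())
        n_s = sum(fr.n_trials for fr in sf.values())
        n_n = sum(fr.n_trials for fr in nf.values())
        if n_s != n_n:
            raise ValueError("STRUCT and NAIVE fits must cover identical data")
        rows.append({"subject": s, "n_trials": n_s,
                     "nll_struct": nll_s, "nll_naive": nll_n,
                     "aic_struct": 2 * k_s + 2 * nll_s,
                     "aic_naive": 2 * k_n + 2 * nll_n,
                     "bic_struct": k_s * np.log(n_s) + 2 * nll_s,
                     "bic_naive": k_n * np.log(n_n) + 2 * nll_n})
    df = pd.DataFrame(rows)
    total = df.drop(columns="subject").sum()
    total["subject"] = "total"
    return pd.concat([df, total.to_frame().T], ignore_index=True)
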