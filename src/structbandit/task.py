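"""Correlated-bandit task schedules and simulated agents.

Three one-armed bandits (A, B, C) are interleaved within a block. The latent
probability of a "good" outcome for each bandit switches between 0.9 and 0.1
with a fixed per-trial switch probability. Bandits A and B are yoked: in
+Corr blocks they share one latent process, in -Corr blocks their latent
probabilities are mirrored (p_A + p_B = 1). Bandit C evolves independently.
Blocks come in a 2x2 design of relational structure (+/-Corr) x stimulus set.

The subject predicts the binary outcome by accepting or rejecting the
presented stimulus: accepting a good outcome wins a point, accepting a bad
outcome loses one, and rejections never change the score although the outcome
card is still shown (full counterfactual feedback), except on the no-feedback
tail of some training blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STIMULI = ("A", "B", "C")

#: column order used for behavior tables written to TSV
BEHAVIOR_COLUMNS = [
    "subject", "run", "block", "block_type", "structure_sign", "stimulus_set",
    "trial", "stimulus", "p_good_A", "p_good_B", "p_good_C", "outcome",
    "feedback", "tail", "choice", "correct", "points",
    "onset_stim_s", "onset_choice_s", "onset_outcome_s",
]


@dataclass(frozen=True)
class BlockSpec:
    """Parameters of a single block of the 2x2 (structure x stimulus set) design.

    Parameters
    ----------
    structure_sign : {+1, -1}
        Sign of the correlation between the latent outcome probabilities of
        bandits A and B (+1: identical processes; -1: mirrored).
    stimulus_set_id : {1, 2}
        Which of the two stimulus triplets cues the bandits.
    trials_per_stimulus : int
        Presentations of each stimulus: 10 in the scanner, 14 pre-scan,
        20 in online training.
    switch_prob : float
        Per-trial probability that a latent process flips 0.9 <-> 0.1
        (0.15 scanner/pre-scan, 0.05 training).
    no_feedback_tail : int
        Number of final trials on which rejected choices get no outcome
        feedback (15 on training days 3-4, otherwise 0).
    background_color_id : str
        Label of the background colour cueing the block type.
    """

    structure_sign: int
    stimulus_set_id: int = 1
    trials_per_stimulus: int = 10
    switch_prob: float = 0.15
    no_feedback_tail: int = 0
    background_color_id: str | None = None

    def __post_init__(self):
        if self.structure_sign not in (+1, -1):
            raise ValueError("structure_sign must be +1 or -1")
        if self.stimulus_set_id not in (1, 2):
            raise ValueError("stimulus_set_id must be 1 or 2")
        if not (isinstance(self.trials_per_stimulus, (int, np.integer))
                and self.trials_per_stimulus >= 1):
            raise ValueError("trials_per_stimulus must be a positive integer")
        if not 0.0 < self.switch_prob < 1.0:
            raise ValueError("switch_prob must lie in (0, 1)")
        if self.no_feedback_tail < 0:
            raise ValueError("no_feedback_tail must be non-negative")

    @property
    def n_trials(self) -> int:
        return 3 * self.trials_per_stimulus

    @property
    def block_type(self) -> str:
        sign = "+" if self.structure_sign > 0 else "-"
        return f"{sign}Corr_set{self.stimulus_set_id}"


#: canonical ordering of the four block types (rows/columns of crossval matrices)
BLOCK_TYPE_ORDER = ["-Corr_set1", "-Corr_set2", "+Corr_set1", "+Corr_set2"]

# 4x4 Latin square used to counterbalance block order across simulated subjects
_LATIN = np.array([[0, 1, 2, 3], [1, 3, 0, 2], [2, 0, 3, 1], [3, 2, 1, 0]])


def _block_specs_for_types(order, **kwargs):
    types = [BlockSpec(structure_sign=s, stimulus_set_id=k, **kwargs)
             for s in (-1, +1) for k in (1, 2)]
    # types indexed in BLOCK_TYPE_ORDER
    return [types[i] for i in order]


def scanner_session_specs(subject: int = 0):
    """8 scanner blocks (two runs of the 4 block types, Latin-square ordered).

    Returns ``(specs, runs)`` where ``runs[i]`` is the run index (1 or 2) of
    block ``i``.
    """
    o1 = _LATIN[subject % 4]
    o2 = _LATIN[(subject + 2) % 4]
    specs = (_block_specs_for_types(o1, trials_per_stimulus=10, switch_prob=0.15)
             + _block_specs_for_types(o2, trials_per_stimulus=10, switch_prob=0.15))
    runs = [1] * 4 + [2] * 4
    return specs, runs


def prescan_session_specs(subject: int = 0):
    """4 pre-scan reminder blocks (42 trials each), one per block type."""
    order = _LATIN[(subject + 1) % 4]
    specs = _block_specs_for_types(order, trials_per_stimulus=14, switch_prob=0.15)
    return specs, [0] * 4


def training_session_specs(subject: int = 0, day: int = 4):
    """8 training blocks of 60 trials, switch probability 0.05.

    Days 3-4 withhold outcome feedback on rejected trials in the last 15
    trials of every block.
    """
    tail = 15 if day in (3, 4) else 0
    order = np.concatenate([_LATIN[subject % 4], _LATIN[(subject + 3) % 4]])
    specs = _block_specs_for_types(order, trials_per_stimulus=20,
                                   switch_prob=0.05, no_feedback_tail=tail)
    return specs, [0] * 8


def _truncated_exponential(rng, mean, lo, hi, size):
    """Exponential(mean) samples restricted to [lo, hi] by rejection sampling."""
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.exponential(mean, need.size)
        ok = (draw >= lo) & (draw <= hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def _latent_process(rng, n, switch_prob):
    """One seeded 0.9/0.1 latent process of length n (equiprobable start)."""
    start = rng.random() < 0.5
    flips = rng.random(n - 1) < switch_prob
    high = np.logical_xor.accumulate(np.concatenate([[start], flips]))
    return np.where(high, 0.9, 0.1)


def generate_schedule(specs, seed, subject: int = 0, runs=None) -> pd.DataFrame:
    """Generate a seeded reward schedule for an ordered list of blocks.

    Each block gets two latent processes (one shared by the related bandits
    A and B, one for the independent bandit C); each flips 0.9 <-> 0.1 with
    probability ``switch_prob`` on every trial. Stimulus order is a seeded
    permutation with exactly ``trials_per_stimulus`` presentations of each
    stimulus. Onset times follow the trial timing model (1.5 s pre-choice,
    lognormal RT, 0.5 s highlight, truncated-exponential choice-outcome delay,
    1 s outcome, truncated-exponential ITI); onsets are relative to block
    start, since downstream GLMs are estimated per block.

    Returns a trial table with one row per trial; choice columns are left
    empty until an agent is simulated.
    """
    specs = list(specs)
    if runs is None:
        runs = [1] * len(specs)
    if len(runs) != len(specs):
        raise ValueError("runs must match specs length")
    frames = []
    for b, spec in enumerate(specs):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(subject), b]))
        n = spec.n_trials
        shared = _latent_process(rng, n, spec.switch_prob)
        indep = _latent_process(rng, n, spec.switch_prob)
        p_a = shared
        p_b = shared if spec.structure_sign > 0 else 1.0 - shared
        p_c = indep
        stim = rng.permutation(np.repeat(np.arange(3), spec.trials_per_stimulus))
        p_all = np.stack([p_a, p_b, p_c], axis=1)
        p_shown = p_all[np.arange(n), stim]
        outcome = np.where(rng.random(n) < p_shown, 1, -1)
        tail = np.arange(n) >= n - spec.no_feedback_tail

        rt = rng.lognormal(mean=0.0, sigma=0.35, size=n)
        delay = _truncated_exponential(rng, 4.5, 3.5, 5.5, n)
        iti = _truncated_exponential(rng, 3.0, 2.5, 4.0, n)
        trial_len = 1.5 + rt + 0.5 + delay + 1.0 + iti
        onset_stim = np.concatenate([[0.0], np.cumsum(trial_len)[:-1]])
        onset_choice = onset_stim + 1.5 + rt
        onset_outcome = onset_choice + 0.5 + delay

        frames.append(pd.DataFrame({
            "subject": subject,
            "run": runs[b],
            "block": b,
            "block_type": spec.block_type,
            "structure_sign": spec.structure_sign,
            "stimulus_set": spec.stimulus_set_id,
            "trial": np.arange(n),
            "stimulus": np.array(STIMULI)[stim],
            "p_good_A": p_a,
            "p_good_B": p_b,
            "p_good_C": p_c,
            "outcome": outcome,
            "feedback": True,
            "tail": tail,
            "choice": pd.array([None] * n, dtype="string"),
            "correct": pd.array([None] * n, dtype="boolean"),
            "points": np.zeros(n, dtype=int),
            "onset_stim_s": onset_stim,
            "onset_choice_s": onset_choice,
            "onset_outcome_s": onset_outcome,
        }))
    return pd.concat(frames, ignore_index=True)[BEHAVIOR_COLUMNS]


def simulate_agent(schedule: pd.DataFrame, params_by_structure, seed) -> pd.DataFrame:
    """Simulate choices of a cross-term learner on a schedule.

    ``params_by_structure`` maps structure sign (+1/-1) to a
    :class:`~structbandit.learning.LearnerParams` (a single params object is
    also accepted and used for both structures). The agent accepts with
    probability ``sigmoid(beta * g)`` of its current belief about the
    presented stimulus; beliefs reset to 0 at every block start and are
    updated by the cross-term delta rule only on trials with outcome
    feedback. Rejected trials inside a block's no-feedback tail yield no
    feedback; the returned table has the resolved ``feedback`` column.
    """
    from .learning import LearnerParams  # local import to avoid cycle

    if isinstance(params_by_structure, LearnerParams):
        params_by_structure = {+1: params_by_structure, -1: params_by_structure}
    df = schedule.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    stim_idx = df["stimulus"].map({s: i for i, s in enumerate(STIMULI)}).to_numpy()
    outcome = df["outcome"].to_numpy(dtype=float)
    tail = df["tail"].to_numpy(dtype=bool)
    sign = df["structure_sign"].to_numpy()
    block = df["block"].to_numpy()
    n = len(df)
    choice = np.empty(n, dtype=object)
    correct = np.empty(n, dtype=bool)
    points = np.zeros(n, dtype=int)
    feedback = np.ones(n, dtype=bool)

    g = np.zeros(3)
    prev_block = None
    for t in range(n):
        if block[t] != prev_block:
            g[:] = 0.0
            prev_block = block[t]
            hmat = params_by_structure[sign[t]].cross_term_matrix()
            alpha = params_by_structure[sign[t]].alpha
            beta = params_by_structure[sign[t]].beta
        s = stim_idx[t]
        p = 1.0 / (1.0 + np.exp(-beta * g[s]))
        accept = rng.random() < p
        y = outcome[t]
        choice[t] = "accept" if accept else "reject"
        correct[t] = accept == (y > 0)
        points[t] = int(y) if accept else 0
        feedback[t] = not (tail[t] and not accept)
        if feedback[t]:
            for o in range(3):
                if o == s:
                    g[o] = (1 - alpha) * g[o] + alpha * y
                else:
                    h = hmat[s, o]
                    g[o] = (1 - alpha * abs(h)) * g[o] + alpha * h * y
    df["choice"] = choice
    df["correct"] = correct
    df["points"] = points
    df["feedback"] = feedback
    return df


def simulate_subject(subject, seed, params_by_structure, sessions=("prescan", "scanner")):
    """Schedule + choices for one subject over the requested sessions.

    Block indices are offset so they stay unique across sessions; pre-scan
    blocks carry run 0, scanner blocks runs 1 and 2.
    """
    frames = []
    offset = 0
    for sess_i, sess in enumerate(sessions):
        if sess == "prescan":
            specs, runs = prescan_session_specs(subject)
        elif sess == "scanner":
            specs, runs = scanner_session_specs(subject)
        elif sess == "training":
            specs, runs = training_session_specs(subject)
        else:
            raise ValueError(f"unknown session {sess!r}")
        sched = generate_schedule(specs, seed=int(seed) + 7919 * sess_i,
                                  subject=subject, runs=runs)
        sched["block"] = sched["block"] + offset
        offset = sched["block"].max() + 1
        frames.append(sched)
    sched = pd.concat(frames, ignore_index=True)
    return simulate_agent(sched, params_by_structure,
                          seed=np.random.SeedSequence([int(seed), subject, 13]).generate_state(1)[0] % (2**31))


def simulate_cohort(n_subjects, seed, params_by_structure, sessions=("prescan", "scanner")):
    """Concatenated behavior table for a cohort of simulated subjects."""
    return pd.concat(
        [simulate_subject(s, seed, params_by_structure, sessions) for s in range(n_subjects)],
        ignore_index=True,
    )


def write_behavior(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_behavior(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["choice"] = df["choice"].astype("string")
    return df
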