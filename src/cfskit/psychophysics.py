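"""Adaptive staircase psychophysics with simulated observers.

Contrast thresholds for detecting the suppressed target are measured with
a transformed up-down staircase: the level (log10 contrast) moves up one
step after every incorrect response and down one step after two
consecutive correct responses, which converges on the 70.71%-correct
point of the psychometric function (the level where p^2 = 1/2). Each
staircase starts in an *accelerated* one-up one-down regime — every
correct response lowers the level — until the first error, which switches
it permanently to the main one-up two-down regime.

Two staircases with different starting levels run per condition,
randomly interleaved within a session. The threshold of a staircase is
the mean level over its last 20 trials; condition thresholds average the
condition's staircases, and per-participant normalization divides each
condition threshold by the participant's mean threshold so the analysis
operates on dimensionless values with mean 1 per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONVERGENCE_P",
    "StaircaseState",
    "ObserverModel",
    "SessionPlan",
    "ThresholdEstimate",
    "staircase_update",
    "plan_session",
    "simulate_session",
    "estimate_threshold",
    "estimate_session_thresholds",
    "normalize_thresholds",
    "within_subject_ci",
    "measure_convergence",
]

#: Asymptotic percent-correct of the one-up two-down rule: sqrt(1/2).
CONVERGENCE_P = float(np.sqrt(0.5))

LEVEL_MIN = np.log10(1e-4)
LEVEL_MAX = np.log10(1.0)
DEFAULT_STEP = 0.05  # log10-contrast units


@dataclass
class StaircaseState:
    """State of one transformed up-down staircase (levels in log10 contrast)."""

    level: float
    step: float = DEFAULT_STEP
    phase: Literal["accelerated", "main"] = "accelerated"
    consecutive_correct: int = 0
    history: list[tuple[float, bool]] = field(default_factory=list)
    reversals: list[float] = field(default_factory=list)
    main_reversals: list[float] = field(default_factory=list)
    level_min: float = LEVEL_MIN
    level_max: float = LEVEL_MAX
    _last_move: int = 0  # -1 down, +1 up, 0 none yet

    @property
    def contrast(self) -> float:
        return float(10.0**self.level)


def _move(state: StaircaseState, direction: int) -> None:
    old = state.level
    state.level = float(np.clip(state.level + direction * state.step,
                                state.level_min, state.level_max))
    if state._last_move != 0 and direction != state._last_move:
        state.reversals.append(old)
        if state.phase == "main":
            state.main_reversals.append(old)
    state._last_move = direction


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Apply one response to the staircase (in place; also returned).

    Accelerated phase: one-up one-down; the first incorrect response ends
    acceleration for good. Main phase: one-up two-down. Levels are clamped
    to the displayable range; reversal levels are recorded whenever the
    direction of movement flips.
    """
    state.history.append((state.level, bool(correct)))
    if state.phase == "accelerated":
        if correct:
            _move(state, -1)
        else:
            state.phase = "main"
            state.consecutive_correct = 0
            _move(state, +1)
        return state
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= 2:
            state.consecutive_correct = 0
            _move(state, -1)
    else:
        state.consecutive_correct = 0
        _move(state, +1)
    return state


@dataclass
class ObserverModel:
    """Simulated observer with a cumulative-Weibull psychometric per condition.

    p(correct | contrast c, condition) =
        gamma + (1 - gamma - lapse) * (1 - exp(-(c / alpha)^beta))

    ``gamma = 0.5`` is the chance level of the two-alternative
    above/below-fixation judgement; ``alpha`` scales with suppression
    strength (stronger suppression -> higher threshold).
    """

    alpha: Mapping[str, float]
    beta: float = 3.5
    gamma: float = 0.5
    lapse: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0 or not 0.0 <= self.lapse < 0.5:
            raise ValueError("invalid gamma or lapse")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        for k, a in self.alpha.items():
            if a <= 0:
                raise ValueError(f"alpha for condition {k!r} must be positive")

    def p_correct(self, contrast: float, condition: str) -> float:
        a = self.alpha[condition]
        pf = 1.0 - np.exp(-((contrast / a) ** self.beta))
        return float(self.gamma + (1.0 - self.gamma - self.lapse) * pf)

    def level_at_p(self, p: float, condition: str) -> float:
        """Invert the psychometric: log10 contrast at probability ``p``."""
        a = self.alpha[condition]
        frac = (p - self.gamma) / (1.0 - self.gamma - self.lapse)
        if not 0.0 < frac < 1.0:
            raise ValueError("p outside the attainable range")
        return float(np.log10(a * (-np.log(1.0 - frac)) ** (1.0 / self.beta)))


@dataclass
class SessionPlan:
    """Randomly interleaved trial schedule for one participant session.

    ``trials`` is a DataFrame with columns (trial_index, staircase_id,
    condition, target_speed, target_path, block). Two staircases per
    condition start at distinct levels; target paths are balanced across
    each condition's trials.
    """

    trials: pd.DataFrame
    start_levels: dict[str, float]
    n_per_staircase: int
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def plan_session(conditions: Sequence[str],
                 n_per_staircase: int = 65,
                 seed: int = 0,
                 target_speeds: Sequence[float] = (3.0,),
                 blocked: bool | None = None,
                 start_levels: tuple[float, float] = (LEVEL_MAX, -2.0),
                 ) -> SessionPlan:
    """Build a session plan: 2 staircases x ``n_per_staircase`` trials per
    condition (per target speed), randomly interleaved.

    With one target speed (the single-target design) this yields
    n_conditions x 2 x 65 = 780 trials for the six standard conditions;
    with two blocked target speeds it yields 1,560. ``blocked`` defaults
    to True when more than one target speed is given: each target speed
    forms its own block with independent interleaving, and block order
    follows the given sequence (counterbalance at the experiment level by
    permuting ``target_speeds`` across participants).
    """
    if len(conditions) < 1:
        raise ValueError("at least one condition is required")
    if n_per_staircase < 21:
        raise ValueError("n_per_staircase must be >= 21 so the last-20 "
                         "threshold estimator is computable")
    if blocked is None:
        blocked = len(target_speeds) > 1
    rng = np.random.default_rng(seed)

    rows = []
    sc_starts: dict[str, float] = {}
    for block, tspeed in enumerate(target_speeds):
        block_rows = []
        for cond in conditions:
            for sc_num, lvl in enumerate(start_levels):
                sc_id = f"{cond}|t{tspeed:g}|s{sc_num}"
                sc_starts[sc_id] = float(lvl)
                # Balanced target paths within each staircase's trials.
                paths = np.tile(np.arange(1, 7),
                                int(np.ceil(n_per_staircase / 6)))[:n_per_staircase]
                paths = rng.permutation(paths)
                for k in range(n_per_staircase):
                    block_rows.append((sc_id, cond, tspeed, int(paths[k]), block))
        order = rng.permutation(len(block_rows))
        rows.extend(block_rows[i] for i in order)

    trials = pd.DataFrame(rows, columns=["staircase_id", "condition",
                                         "target_speed", "target_path",
                                         "block"])
    trials.insert(0, "trial_index", np.arange(len(trials)))
    return SessionPlan(trials=trials, start_levels=sc_starts,
                       n_per_staircase=n_per_staircase, seed=seed)


def simulate_session(plan: SessionPlan, observer: ObserverModel,
                     seed: int = 0,
                     step: float = DEFAULT_STEP,
                     ) -> tuple[pd.DataFrame, dict[str, StaircaseState]]:
    """Run every staircase in the plan against a simulated observer.

    Each trial draws a Bernoulli correctness at the staircase's current
    contrast from the observer's psychometric for that condition, then
    updates the staircase. Returns the trial table (with level, contrast
    and correctness columns added) and the final staircase states.
    """
    missing = set(plan.trials["condition"]) - set(observer.alpha)
    if missing:
        raise ValueError(f"observer lacks alpha for conditions: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    states = {sc: StaircaseState(level=lvl, step=step)
              for sc, lvl in plan.start_levels.items()}
    levels = np.empty(len(plan.trials))
    corrects = np.empty(len(plan.trials), dtype=bool)
    for i, row in enumerate(plan.trials.itertuples(index=False)):
        st = states[row.staircase_id]
        levels[i] = st.level
        p = observer.p_correct(st.contrast, row.condition)
        correct = bool(rng.random() < p)
        corrects[i] = correct
        staircase_update(st, correct)
    out = plan.trials.copy()
    out["level"] = levels
    out["contrast"] = 10.0**levels
    out["correct"] = corrects
    return out, states


def estimate_threshold(state: StaircaseState, n_last: int = 20,
                       space: Literal["linear", "log"] = "linear") -> float:
    """Threshold of one staircase: mean level over its final ``n_last`` trials.

    ``space='linear'`` (default) exponentiates levels to contrast before
    averaging; ``space='log'`` averages in log10 contrast and returns the
    exponentiated mean.
    """
    if len(state.history) < n_last:
        raise ValueError(f"staircase history has fewer than {n_last} trials")
    levels = np.array([lvl for lvl, _ in state.history[-n_last:]])
    if space == "linear":
        return float(np.mean(10.0**levels))
    if space == "log":
        return float(10.0 ** np.mean(levels))
    raise ValueError(f"unknown averaging space: {space!r}")


@dataclass
class ThresholdEstimate:
    """Threshold summary of one participant session.

    ``per_staircase`` maps staircase id to its last-20-trials threshold;
    ``table`` has one row per (condition, target_speed) with the mean over
    that condition's staircases and its per-participant normalized value
    (normalized values average to 1 within each target-speed block).
    """

    per_staircase: dict[str, float]
    table: pd.DataFrame


def estimate_session_thresholds(plan: SessionPlan,
                                states: Mapping[str, StaircaseState],
                                n_last: int = 20,
                                space: Literal["linear", "log"] = "linear",
                                ) -> ThresholdEstimate:
    """Per-condition thresholds for a completed session.

    Staircase thresholds (mean of the last ``n_last`` trials) are averaged
    over the staircases of each condition x target-speed cell, then
    normalized by the participant's mean threshold within each
    target-speed block.
    """
    per_sc = {sc: estimate_threshold(st, n_last=n_last, space=space)
              for sc, st in states.items()}
    meta = plan.trials.drop_duplicates("staircase_id")[
        ["staircase_id", "condition", "target_speed"]]
    rows = []
    for (cond, tspeed), grp in meta.groupby(["condition", "target_speed"],
                                            sort=False):
        thr = float(np.mean([per_sc[sc] for sc in grp["staircase_id"]]))
        rows.append({"condition": cond, "target_speed": tspeed,
                     "threshold": thr})
    table = pd.DataFrame(rows)
    table["normalized"] = np.nan
    for tspeed, grp in table.groupby("target_speed"):
        table.loc[grp.index, "normalized"] = normalize_thresholds(
            grp["threshold"].to_numpy())
    return ThresholdEstimate(per_staircase=per_sc, table=table)


def normalize_thresholds(per_condition: Sequence[float] | np.ndarray) -> np.ndarray:
    """Divide a participant's condition thresholds by their mean.

    The normalized vector has mean exactly 1, removing between-participant
    threshold scale differences before group analysis.
    """
    arr = np.asarray(per_condition, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("thresholds must be strictly positive")
    return arr / arr.mean()


def within_subject_ci(data: np.ndarray, prob: float = 0.95,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Within-subject confidence intervals for repeated-measures means.

    ``data`` is a participants x conditions matrix with no missing cells.
    Each value is centred by its participant's mean and shifted by the
    grand mean (Cousineau), the per-condition variance is inflated by
    J/(J-1) (Morey's bias correction), and a t-based interval at ``prob``
    is returned as (means, half_widths).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need a participants x conditions matrix, >= 2 each")
    if np.any(~np.isfinite(data)):
        raise ValueError("missing cells are not supported")
    n, j = data.shape
    centered = data - data.mean(axis=1, keepdims=True) + data.mean()
    var = centered.var(axis=0, ddof=1) * (j / (j - 1))
    tcrit = stats.t.ppf(0.5 + prob / 2.0, df=n - 1)
    half = tcrit * np.sqrt(var / n)
    return data.mean(axis=0), half


def measure_convergence(observer: ObserverModel, condition: str,
                        n_main_trials: int = 3000,
                        step: float = DEFAULT_STEP,
                        start_level: float = LEVEL_MAX,
                        space: Literal["linear", "log"] = "linear",
                        seed: int = 0) -> dict:
    """Empirically measure the staircase's convergence point.

    Runs one accelerated one-up two-down staircase against the observer
    until ``n_main_trials`` responses have been collected after the
    acceleration phase ends, averages the main-phase reversal levels, and
    evaluates the observer's psychometric at the averaged level. For any
    monotone psychometric the result should sit at ~70.71% correct.

    ``space`` selects the averaging space for the reversal levels and
    defaults to linear contrast, matching :func:`estimate_threshold`
    (the random walk's level distribution is skewed in log units, so the
    log average reads a slope-dependent 1-3 percentage points low; the
    linear average is nearly unbiased).
    """
    rng = np.random.default_rng(seed)
    st = StaircaseState(level=start_level, step=step)
    main_count = 0
    while main_count < n_main_trials:
        in_main = st.phase == "main"
        p = observer.p_correct(st.contrast, condition)
        staircase_update(st, bool(rng.random() < p))
        if in_main:
            main_count += 1
    if not st.main_reversals:
        raise RuntimeError("no main-phase reversals recorded")
    levels = np.asarray(st.main_reversals)
    if space == "linear":
        contrast = float(np.mean(10.0**levels))
    elif space == "log":
        contrast = float(10.0 ** np.mean(levels))
    else:
        raise ValueError(f"unknown averaging space: {space!r}")
    p_at = observer.p_correct(contrast, condition)
    return {
        "converged_level": float(np.log10(contrast)),
        "converged_contrast": contrast,
        "percent_correct": 100.0 * p_at,
        "n_reversals": len(st.main_reversals),
        "target_percent": 100.0 * CONVERGENCE_P,
    }
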