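"""Softmax choice model with fatigue and learning states.

The decision variable on each trial is the subjective-value difference
between the high-effort (HE) and low-effort (LE) option,

    dSV = kBias + benefit - cost

with benefit kR*dR on reward trials (kP*dP avoided on punishment
trials), and cost (kEp + kFp*F)*dE on physical trials or
max(kEm - kLm*L, 0)*dE on mental trials. Incentives and efforts enter
as design level codes. F is cumulative physical fatigue (exerted effort
normalized by the maximum effort level and the block length) and L is
mental learning / momentary efficiency (fraction of the block's mental
trials completed); both run on a [0, 1] scale within a block and reset
at block boundaries, keeping every sensitivity on a comparable O(1)
scale. Choice probability is the logistic
transform of dSV (softmax with unit temperature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import Block, PHYSICAL, MENTAL, REWARD, PUNISHMENT, Trial

PARAM_NAMES = ("kR", "kP", "kEp", "kEm", "kFp", "kLm", "kBias")
#: parameters constrained to be non-negative (all but the bias)
POSITIVE_PARAMS = PARAM_NAMES[:-1]


@dataclass(frozen=True)
class ModelParams:
    """Behavioral sensitivities of the choice model.

    kR/kP: reward and punishment sensitivity; kEp/kEm: physical and
    mental effort sensitivity; kFp: physical fatigue sensitivity; kLm:
    mental learning sensitivity; kBias: bias toward the HE option.
    """

    kR: float = 0.0
    kP: float = 0.0
    kEp: float = 0.0
    kEm: float = 0.0
    kFp: float = 0.0
    kLm: float = 0.0
    kBias: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        for name in POSITIVE_PARAMS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "ModelParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, values))))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class InternalState:
    """Within-block internal states: F = cumulative physical fatigue,
    L = cumulative mental learning. Both start at 0 at block onset."""

    F: float = 0.0
    L: float = 0.0


def delta_sv(trial: Trial, params: ModelParams, state: InternalState) -> float:
    """Subjective-value difference SV(HE) - SV(LE) for one trial."""
    d_inc = trial.he_incentive - trial.le_incentive
    d_eff = trial.he_effort - trial.le_effort
    if trial.valence == REWARD:
        benefit = params.kR * d_inc
    elif trial.valence == PUNISHMENT:
        # the HE option avoids the larger loss: benefit scales with the
        # punishment magnitude avoided, in level codes
        benefit = params.kP * d_inc
    else:
        raise ValueError(f"unknown valence {trial.valence!r}")
    if trial.domain == PHYSICAL:
        cost = (params.kEp + params.kFp * state.F) * d_eff
    elif trial.domain == MENTAL:
        cost = max(params.kEm - params.kLm * state.L, 0.0) * d_eff
    else:
        raise ValueError(f"unknown domain {trial.domain!r}")
    return params.kBias + benefit - cost


def p_high_effort(dsv) -> float:
    """Softmax (logistic) probability of choosing the high-effort option."""
    return expit(dsv)


def update_state(state: InternalState, trial: Trial, chosen: str,
                 he_effort_max: int, trials_per_block: int) -> InternalState:
    """Advance the internal state after one trial.

    Physical trials add the exerted effort (0 if LE was chosen),
    normalized by the maximum HE effort level and the block length, to
    F, so F runs from 0 to at most 1 over a block. Mental trials add
    1/trials_per_block to L regardless of the option chosen (the 2-back
    practice accrues either way), so L mirrors F's [0, 1] scale. The
    other domain's state is untouched.
    """
    if trial.domain == PHYSICAL:
        ech = trial.he_effort if chosen == "HE" else 0
        return replace(state,
                       F=state.F + ech / (he_effort_max * trials_per_block))
    return replace(state, L=state.L + 1.0 / trials_per_block)


def simulate_choices(session: list[Block], params: ModelParams,
                     rng: np.random.Generator,
                     dt_model=None) -> pd.DataFrame:
    """Forward-simulate choices for a whole session.

    For each trial the running internal state enters dSV, the choice is
    Bernoulli(p_he) (one uniform draw per trial, so simulations with the
    same rng state are coupled across parameter settings), and the state
    is updated with the exerted effort. States reset at block starts.
    ``dt_model(dsv, rng)`` optionally supplies a deliberation time.

    Returns one row per trial with the trial descriptors plus
    ``chosen``, ``choice`` (1 = HE), ``p_he``, ``delta_sv``, ``Ech``,
    ``SVch``, ``DT`` and a ``missed`` flag (always False here).
    """
    rows = []
    for block in session:
        state = InternalState()
        eff_max = max(t.he_effort for t in block.trials)
        n_trials = len(block.trials)
        for trial in block.trials:
            dsv = delta_sv(trial, params, state)
            p = float(p_high_effort(dsv))
            u = rng.random()
            chosen = "HE" if u < p else "LE"
            ech = trial.he_effort if chosen == "HE" else 0
            svch = dsv if chosen == "HE" else 0.0
            dt = float(dt_model(dsv, rng)) if dt_model is not None else np.nan
            rows.append({
                "block_index": trial.block_index,
                "trial_index": trial.trial_index,
                "domain": trial.domain,
                "valence": trial.valence,
                "he_incentive": trial.he_incentive,
                "he_effort": trial.he_effort,
                "chosen": chosen,
                "choice": 1 if chosen == "HE" else 0,
                "p_he": p,
                "delta_sv": dsv,
                "Ech": ech,
                "SVch": svch,
                "DT": dt,
                "missed": False,
            })
            state = update_state(state, trial, chosen, eff_max, n_trials)
    return pd.DataFrame(rows)


def parametric_modulators(records: pd.DataFrame,
                          columns: tuple[str, ...] = ("Ech", "SVch", "DT"),
                          by_block: bool = True) -> pd.DataFrame:
    """Z-score the trial-level fMRI parametric modulators per block.

    Within every block each modulator gets mean 0 and (sample) SD 1; a
    constant column degenerates to all zeros with a warning. Missed
    trials are excluded before z-scoring.
    """
    if "missed" in records.columns:
        records = records.loc[~records["missed"].astype(bool)]
    group_key = records["block_index"] if by_block else np.zeros(len(records))
    out = records[["block_index", "trial_index"]].copy()
    for col in columns:
        zs = np.empty(len(records))
        for _, idx in records.groupby(group_key).indices.items():
            if len(idx) == 0:
                raise ValueError("empty block")
            if len(idx) < 2:
                raise ValueError("need >=2 trials per block to z-score")
            vals = records[col].to_numpy()[idx]
            sd = np.std(vals, ddof=1)
            if sd == 0:
                warnings.warn(
                    f"modulator {col!r} constant within a block; set to 0",
                    stacklevel=2,
                )
                zs[idx] = 0.0
            else:
                zs[idx] = (vals - vals.mean()) / sd
        out[col] = zs
    return out
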