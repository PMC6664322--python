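"""Hybrid model-free / model-based reinforcement-learning model.

Stage-1 choice values are a weighted mixture of a SARSA(lambda) model-free
value and a model-based value that combines the (known, fixed) transition
structure with the current stage-2 values:

    Q_MB(a)  = sum_s P(s | a) * max_a' Q2(s, a')
    Q_net(a) = beta1 * [w * Q_MB(a) + (1 - w) * Q_MF(a)] + persev * rep(a)

with a softmax over Q_net at stage 1 and over beta2 * Q2(state, .) at
stage 2. After each valid trial the model-free values update with the
stage-2 prediction error propagated back by the eligibility parameter
lambda. ``w`` in [0, 1] is the weight of the model-based (goal-directed)
system and is the primary behavioural quantity of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import STATE_LABELS, SessionEnvironment, TransitionStructure

__all__ = [
    "ModelParams",
    "QState",
    "QUpdateTrace",
    "TrialRecord",
    "mb_stage1_values",
    "stage1_probs",
    "stage2_probs",
    "apply_updates",
    "session_loglik",
    "simulate_agent",
    "trials_to_frame",
    "trials_from_frame",
    "PROB_FLOOR",
    "CONDITION_LABELS",
]

#: Choice probabilities are floored at this value inside the log-likelihood
#: so the objective stays finite for extreme parameter values.
PROB_FLOOR = 1e-12

#: Fixed stimulation-condition labels used in all exported tables.
CONDITION_LABELS = ("control", "LPFC_to_IPS", "IPS_to_LPFC")

PARAM_NAMES = ("beta1", "beta2", "alpha1", "alpha2", "lam", "persev", "w")


@dataclass(frozen=True)
class ModelParams:
    """The seven bounded parameters of the hybrid model.

    beta1, beta2 : choice reliability (inverse temperature), stage 1 / 2, >= 0
    alpha1, alpha2 : learning rates, in [0, 1]
    lam : reinforcement eligibility (stage-2 error credited to stage 1), [0, 1]
    persev : perseveration (stage-1 choice stickiness), unbounded
    w : model-based weighting, in [0, 1]
    """

    beta1: float
    beta2: float
    alpha1: float
    alpha2: float
    lam: float
    persev: float
    w: float

    def __post_init__(self) -> None:
        vals = self.to_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("all parameters must be finite")
        if self.beta1 < 0 or self.beta2 < 0:
            raise ValueError("beta1 and beta2 must be >= 0")
        for name in ("alpha1", "alpha2", "lam", "w"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ModelParams":
        arr = np.asarray(arr, dtype=float)
        return cls(**dict(zip(PARAM_NAMES, arr)))

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class QState:
    """Learned action values: 2 stage-1 model-free values and 2x2 stage-2
    values (state x action). Model-based stage-1 values are derived, not
    stored."""

    q_mf: np.ndarray = field(default_factory=lambda: np.zeros(2))
    q2: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    @classmethod
    def initial(cls, q_init: float = 0.0) -> "QState":
        return cls(q_mf=np.full(2, float(q_init)), q2=np.full((2, 2), float(q_init)))

    def copy(self) -> "QState":
        return QState(q_mf=self.q_mf.copy(), q2=self.q2.copy())


@dataclass(frozen=True)
class QUpdateTrace:
    """Prediction errors produced by one trial's updates."""

    delta1: float | None = None
    delta2: float | None = None

    @property
    def empty(self) -> bool:
        return self.delta1 is None


@dataclass(frozen=True)
class TrialRecord:
    """One two-step trial.

    ``state2`` is 0 (state B) or 1 (state C); ``common`` records whether the
    transition was the modal one for the chosen action. Invalid trials
    (missed response deadline at either stage) carry no usable fields and are
    skipped by the likelihood.
    """

    choice1: int
    state2: int
    choice2: int
    reward: int
    common: bool
    rt2_ms: float = math.nan
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            for name in ("choice1", "choice2", "state2"):
                if getattr(self, name) not in (0, 1):
                    raise ValueError(f"{name} must be 0 or 1")
            if self.reward not in (0, 1):
                raise ValueError("reward must be 0 or 1")

    @property
    def transition(self) -> str:
        return "common" if self.common else "rare"


def mb_stage1_values(q2: np.ndarray, structure: TransitionStructure) -> np.ndarray:
    """Model-based stage-1 values: expected best stage-2 value under the
    fixed transition probabilities, Q_MB(a) = sum_s P(s|a) max_a' q2[s, a']."""
    best = np.max(np.asarray(q2, dtype=float), axis=1)
    return structure.matrix @ best


def _softmax2(v0: float, v1: float) -> np.ndarray:
    m = max(v0, v1)
    e0, e1 = math.exp(v0 - m), math.exp(v1 - m)
    z = e0 + e1
    return np.array([e0 / z, e1 / z])


def stage1_probs(
    params: ModelParams,
    q_mf: np.ndarray,
    q_mb: np.ndarray,
    prev_choice1: int | None,
) -> np.ndarray:
    """Stage-1 choice probabilities: softmax over the mixed value plus the
    perseveration bonus for repeating the previous valid stage-1 choice."""
    net = params.beta1 * (params.w * np.asarray(q_mb) + (1 - params.w) * np.asarray(q_mf))
    if prev_choice1 is not None:
        net = net.copy()
        net[prev_choice1] += params.persev
    return _softmax2(net[0], net[1])


def stage2_probs(params: ModelParams, q2: np.ndarray, state2: int) -> np.ndarray:
    """Stage-2 choice probabilities: softmax over beta2 * q2[state2, .]."""
    if state2 not in (0, 1):
        raise ValueError(f"state2 must be 0 or 1, got {state2!r}")
    v = params.beta2 * np.asarray(q2, dtype=float)[state2]
    return _softmax2(v[0], v[1])


def apply_updates(
    params: ModelParams, qstate: QState, trial: TrialRecord
) -> tuple[QState, QUpdateTrace]:
    """Apply one trial's SARSA(lambda)-style value updates.

    delta1 = q2(s2, c2) - q_mf(c1)       (stage-1 prediction error)
    delta2 = reward - q2(s2, c2)         (stage-2 reward prediction error)

    q_mf(c1) += alpha1 * delta1; q2(s2, c2) += alpha2 * delta2; and the
    stage-2 error is propagated back: q_mf(c1) += alpha1 * lam * delta2.
    Invalid trials return the state unchanged with an empty trace.
    """
    if not trial.valid:
        return qstate.copy(), QUpdateTrace()
    new = qstate.copy()
    c1, s2, c2 = trial.choice1, trial.state2, trial.choice2
    delta1 = new.q2[s2, c2] - new.q_mf[c1]
    new.q_mf[c1] += params.alpha1 * delta1
    delta2 = trial.reward - new.q2[s2, c2]
    new.q2[s2, c2] += params.alpha2 * delta2
    new.q_mf[c1] += params.alpha1 * params.lam * delta2
    return new, QUpdateTrace(delta1=float(delta1), delta2=float(delta2))


def session_loglik(
    params: ModelParams,
    trials,
    structure: TransitionStructure,
    q_init: float = 0.0,
) -> float:
    """Log-likelihood of a session of trials under the hybrid model.

    Invalid trials contribute nothing and trigger no update; the
    perseveration reference is the last *valid* trial's stage-1 choice.
    Choice probabilities are floored at ``PROB_FLOOR`` before the log.
    """
    if not np.all(np.isfinite(params.to_array())):
        raise ValueError("parameters must be finite")
    qstate = QState.initial(q_init)
    prev_choice1: int | None = None
    ll = 0.0
    for trial in trials:
        if not trial.valid:
            continue
        q_mb = mb_stage1_values(qstate.q2, structure)
        p1 = stage1_probs(params, qstate.q_mf, q_mb, prev_choice1)
        p2 = stage2_probs(params, qstate.q2, trial.state2)
        ll += math.log(max(p1[trial.choice1], PROB_FLOOR))
        ll += math.log(max(p2[trial.choice2], PROB_FLOOR))
        qstate, _ = apply_updates(params, qstate, trial)
        prev_choice1 = trial.choice1
    return ll


def simulate_agent(
    params: ModelParams,
    env: SessionEnvironment,
    seed: int,
    miss_rate: float = 0.0,
    q_init: float = 0.0,
) -> list[TrialRecord]:
    """Simulate a hybrid-model agent playing a session.

    Choices are sampled from the model's own probabilities, transitions from
    the session structure, and rewards Bernoulli(reward-walk probability).
    With ``miss_rate`` > 0 trials are independently marked invalid (missed
    deadline); invalid trials carry no choices and cause no learning.
    Reproducible given the seed. ``rt2_ms`` is left NaN — response times are
    a property of the cohort generator, not of the value model.
    """
    rng = np.random.default_rng(seed)
    qstate = QState.initial(q_init)
    prev_choice1: int | None = None
    records: list[TrialRecord] = []
    for t in range(env.n_trials):
        if miss_rate > 0 and rng.random() < miss_rate:
            records.append(
                TrialRecord(choice1=-1, state2=-1, choice2=-1, reward=-1,
                            common=False, valid=False)
            )
            continue
        q_mb = mb_stage1_values(qstate.q2, env.structure)
        p1 = stage1_probs(params, qstate.q_mf, q_mb, prev_choice1)
        c1 = int(rng.random() >= p1[0])
        row = env.structure.matrix[c1]
        s2 = int(rng.random() >= row[0])
        p2 = stage2_probs(params, qstate.q2, s2)
        c2 = int(rng.random() >= p2[0])
        reward = int(rng.random() < env.walks.prob(t, s2, c2))
        trial = TrialRecord(
            choice1=c1, state2=s2, choice2=c2, reward=reward,
            common=env.structure.is_common(c1, s2),
        )
        records.append(trial)
        qstate, _ = apply_updates(params, qstate, trial)
        prev_choice1 = c1
    return records


# ---------------------------------------------------------------------------
# tabular import/export of trial sequences


def trials_to_frame(trials, **keys) -> pd.DataFrame:
    """Convert TrialRecords to the on-disk schema (1-based trial index,
    state labels B/C, transition labels common/rare). Extra ``keys``
    (subject, condition, session_order, ...) become leading columns."""
    rows = []
    for i, tr in enumerate(trials, start=1):
        rows.append(
            {
                **keys,
                "trial": i,
                "choice1": float(tr.choice1) if tr.valid else math.nan,
                "state2": STATE_LABELS[tr.state2] if tr.valid else math.nan,
                "choice2": float(tr.choice2) if tr.valid else math.nan,
                "reward": float(tr.reward) if tr.valid else math.nan,
                "transition": tr.transition if tr.valid else math.nan,
                "rt2_ms": tr.rt2_ms,
                "valid": int(tr.valid),
            }
        )
    return pd.DataFrame(rows)


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame` for one session's rows."""
    out: list[TrialRecord] = []
    for _, row in df.sort_values("trial").iterrows():
        if int(row["valid"]) == 0:
            out.append(TrialRecord(-1, -1, -1, -1, False, valid=False))
            continue
        state = str(row["state2"]).strip()
        if state not in STATE_LABELS:
            raise ValueError(f"unknown stage-2 state label {state!r}")
        transition = str(row["transition"]).strip()
        if transition not in ("common", "rare"):
            raise ValueError(f"unknown transition label {transition!r}")
        out.append(
            TrialRecord(
                choice1=int(float(row["choice1"])),
                state2=STATE_LABELS.index(state),
                choice2=int(float(row["choice2"])),
                reward=int(float(row["reward"])),
                common=(transition == "common"),
                rt2_ms=float(row["rt2_ms"]) if pd.notna(row["rt2_ms"]) else math.nan,
            )
        )
    return out
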