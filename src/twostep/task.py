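"""Two-step task environment: transition structure, drifting rewards, timing.

The task has a stage-1 choice between two actions, a probabilistic transition
to one of two stage-2 states (each action has a "common" state it usually
leads to), a stage-2 choice, and a binary reward whose probability drifts
across trials as a bounded Gaussian random walk — so neither stage-2 option
stays best forever and subjects must keep learning.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TransitionStructure",
    "RewardWalkSet",
    "SessionEnvironment",
    "generate_reward_walks",
    "sample_transition",
    "sample_iti",
    "build_session",
]

#: Stage-2 state labels used in exported files; internally states are 0/1.
STATE_LABELS = ("B", "C")


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the two-step task environment.

    Defaults follow the canonical task design: 67 trials, a 0.7/0.3
    transition structure, and reward probabilities drifting as Gaussian
    random walks of step SD 0.025 reflected into [0.25, 0.75].
    """

    n_trials: int = 67
    common_prob: float = 0.7
    walk_sd: float = 0.025
    walk_bounds: tuple[float, float] = (0.25, 0.75)
    #: initial reward probabilities for the 4 stage-2 options, or "random"
    walk_init: tuple[float, float, float, float] | str = "random"
    n_walk_sets: int = 3
    stage_duration_s: float = 2.22
    outcome_duration_s: float = 1.11
    isi_s: float = 0.8
    iti_range_s: tuple[float, float] = (0.0, 3.6)

    def __post_init__(self) -> None:
        lo, hi = self.walk_bounds
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0.5 < self.common_prob <= 1.0:
            raise ValueError("common_prob must be in (0.5, 1]")
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"degenerate walk_bounds {self.walk_bounds}")
        if self.walk_sd < 0:
            raise ValueError("walk_sd must be >= 0")
        if self.n_walk_sets < 1:
            raise ValueError("n_walk_sets must be >= 1")
        for name in ("stage_duration_s", "outcome_duration_s", "isi_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        t0, t1 = self.iti_range_s
        if t0 < 0 or t1 < t0:
            raise ValueError("iti_range_s must satisfy 0 <= lo <= hi")
        if not isinstance(self.walk_init, str):
            init = np.asarray(self.walk_init, dtype=float)
            if init.shape != (4,):
                raise ValueError("walk_init must have 4 entries or be 'random'")
            if np.any(init < lo) or np.any(init > hi):
                raise ValueError("walk_init must lie within walk_bounds")
        elif self.walk_init != "random":
            raise ValueError("walk_init must be 4 probabilities or 'random'")

    def replace(self, **kwargs) -> "TaskConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TransitionStructure:
    """Fixed stage-1 action -> stage-2 state transition probabilities.

    Action ``a``'s common state is state ``a`` (action 0 usually leads to
    state B, action 1 to state C); ``matrix[a, s]`` is P(state s | action a).
    """

    common_prob: float = 0.7

    @property
    def matrix(self) -> np.ndarray:
        p = self.common_prob
        return np.array([[p, 1.0 - p], [1.0 - p, p]])

    def common_state(self, action: int) -> int:
        _check_action(action)
        return action

    def is_common(self, action: int, state: int) -> bool:
        return self.common_state(action) == state


@dataclass(frozen=True)
class RewardWalkSet:
    """Per-trial reward probabilities for the 4 stage-2 options.

    ``probs`` has shape (n_trials, 4) with columns ordered
    (state B, action 0), (B, 1), (C, 0), (C, 1).
    """

    probs: np.ndarray
    walk_id: int = 0
    bounds: tuple[float, float] = (0.25, 0.75)

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be (n_trials, 4)")
        lo, hi = self.bounds
        if p.min() < lo - 1e-12 or p.max() > hi + 1e-12:
            raise ValueError("reward probabilities escape walk_bounds")
        object.__setattr__(self, "probs", p)

    @property
    def n_trials(self) -> int:
        return self.probs.shape[0]

    def prob(self, trial: int, state: int, action: int) -> float:
        return float(self.probs[trial, 2 * state + action])


@dataclass(frozen=True)
class SessionEnvironment:
    """A playable session: transitions, reward walks, and trial timing."""

    config: TaskConfig
    structure: TransitionStructure
    walks: RewardWalkSet
    iti_s: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.config.n_trials

    def to_frame(self) -> pd.DataFrame:
        """Export as a table (1-based trial index, one row per trial)."""
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "pB0": self.walks.probs[:, 0],
                "pB1": self.walks.probs[:, 1],
                "pC0": self.walks.probs[:, 2],
                "pC1": self.walks.probs[:, 3],
                "iti_s": self.iti_s,
            }
        )

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    def plot_walks(self, ax=None):
        """Diagnostic plot of the four reward-probability trajectories."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = ("B/0", "B/1", "C/0", "C/1")
        for k, lab in enumerate(labels):
            ax.plot(self.walks.probs[:, k], label=f"state/action {lab}")
        lo, hi = self.config.walk_bounds
        ax.set(xlabel="trial", ylabel="P(reward)", ylim=(lo - 0.05, hi + 0.05))
        ax.legend(fontsize="small")
        return ax


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (repeatedly, for large excursions)."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def _check_action(action: int) -> None:
    if action not in (0, 1):
        raise ValueError(f"action must be 0 or 1, got {action!r}")


def generate_reward_walks(config: TaskConfig, seed: int) -> RewardWalkSet:
    """Generate 4 independent bounded Gaussian random walks of reward
    probability, one per stage-2 option, reflected at the bounds.

    Deterministic given (config, seed).
    """
    lo, hi = config.walk_bounds
    rng = np.random.default_rng(seed)
    if isinstance(config.walk_init, str):
        start = rng.uniform(lo, hi, size=4)
    else:
        start = np.asarray(config.walk_init, dtype=float)
    steps = rng.normal(0.0, config.walk_sd, size=(config.n_trials - 1, 4))
    # reflection must be applied step by step, not once at the end, or a
    # path that bounces twice comes back wrong
    probs = np.empty((config.n_trials, 4))
    probs[0] = _reflect(start, lo, hi)
    cur = probs[0].copy()
    for t in range(1, config.n_trials):
        cur = _reflect(cur + steps[t - 1], lo, hi)
        probs[t] = cur
    return RewardWalkSet(probs=probs, walk_id=0, bounds=config.walk_bounds)


def sample_transition(
    action: int, structure: TransitionStructure, rng: np.random.Generator
) -> tuple[int, bool]:
    """Draw the stage-2 state for a stage-1 action.

    Returns ``(state, is_common)`` where ``is_common`` is True iff the modal
    (common) state of the action was reached.
    """
    _check_action(action)
    row = structure.matrix[action]
    state = int(rng.random() >= row[0])  # state 1 with prob row[1]
    return state, structure.is_common(action, state)


def sample_iti(config: TaskConfig, rng: np.random.Generator) -> float:
    """Draw one inter-trial interval, uniform on the closed jitter range."""
    lo, hi = config.iti_range_s
    return float(rng.uniform(lo, hi))


def _walk_seed(seed: int, walk_id: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(walk_id)])
    return int(ss.generate_state(1)[0] % (2**31))


def build_session(config: TaskConfig, walk_id: int, seed: int) -> SessionEnvironment:
    """Assemble a playable session for one of the pre-generated walk sets.

    The reward walks depend on (seed, walk_id) so the ``n_walk_sets``
    sessions derived from one master seed carry different reward
    trajectories over the same transition structure.
    """
    if not 0 <= walk_id < config.n_walk_sets:
        raise ValueError(
            f"walk_id {walk_id} out of range [0, {config.n_walk_sets})"
        )
    walks = generate_reward_walks(config, seed=_walk_seed(seed, walk_id))
    walks = RewardWalkSet(probs=walks.probs, walk_id=walk_id, bounds=config.walk_bounds)
    iti_rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), int(walk_id), 7])
    )
    itis = np.array([sample_iti(config, iti_rng) for _ in range(config.n_trials)])
    return SessionEnvironment(
        config=config,
        structure=TransitionStructure(common_prob=config.common_prob),
        walks=walks,
        iti_s=itis,
    )
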