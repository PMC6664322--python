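"""Synthetic study cohorts with known ground truth.

Emulates the study design: ~29 subjects, three stimulation conditions
(control, LPFC->IPS, IPS->LPFC) with counterbalanced order, one 67-trial
two-step session and one 150-trial orientation working-memory session
(75 at load 3, 75 at load 6) per subject x condition. Subjects' hybrid-model
parameters are drawn once, the stimulation effect enters as a configurable
additive shift on the goal-directed weight w, and every generated quantity
is stored in a sealed ground-truth table so recovery can be scored.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

from .hybrid import (
    CONDITION_LABELS,
    ModelParams,
    simulate_agent,
    trials_to_frame,
)
from .task import TaskConfig, build_session

__all__ = [
    "CohortConfig",
    "CohortDataset",
    "generate_cohort",
    "export_cohort",
    "load_cohort",
    "kappa_for_sd",
    "sd_for_kappa",
]

TWOSTEP_COLUMNS = [
    "subject", "condition", "session_order", "trial", "choice1", "state2",
    "choice2", "reward", "transition", "rt2_ms", "valid",
]
WM_COLUMNS = [
    "subject", "condition", "session_order", "trial", "load", "target_deg",
    "response_deg",
]
QUESTIONNAIRE_COLUMNS = ["subject", "oci_r", "bdi", "stai", "mcq_log10k"]


def sd_for_kappa(kappa: float) -> float:
    """Circular SD (radians, orientation space) of von Mises noise with
    concentration kappa on the doubled circle."""
    r = special.i1e(kappa) / special.i0e(kappa)
    return math.sqrt(-2.0 * math.log(r)) / 2.0


def kappa_for_sd(sd: float) -> float:
    """Inverse of :func:`sd_for_kappa` (numerical)."""
    target_r = math.exp(-2.0 * sd * sd)
    return float(
        optimize.brentq(lambda k: special.i1e(k) / special.i0e(k) - target_r,
                        1e-6, 1e4)
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a synthetic cohort.

    Defaults reproduce the study's design counts and a plausible healthy
    cohort: control-condition w drawn Beta(1.3, 2.5) (right-skewed, mean
    ~0.34), an additive +0.15 shift of w under IPS->LPFC stimulation and no
    shift under LPFC->IPS, working-memory orientation noise with
    concentration 4.5 at load 3 and 2.0 at load 6 (circular SDs of roughly
    14 and 24 degrees), and second-stage RTs slowed after rare transitions
    in proportion to the subject's goal-directedness.
    """

    n_subjects: int = 29
    conditions: tuple[str, ...] = CONDITION_LABELS
    order_scheme: str = "counterbalanced"   # cycle the 6 condition orders
    control_w_beta_a: float = 1.3
    control_w_beta_b: float = 2.5
    w_shift_ips_lpfc: float = 0.15
    w_shift_lpfc_ips: float = 0.0
    shift_mechanism: str = "additive"        # or "multiplicative"
    beta_log_mu: float = math.log(4.0)
    beta_log_sd: float = 0.4
    alpha_beta_a: float = 2.0
    alpha_beta_b: float = 2.0
    lam_beta_a: float = 2.0
    lam_beta_b: float = 2.0
    persev_mu: float = 0.1
    persev_sd: float = 0.2
    n_wm_trials_per_load: int = 75
    wm_kappa_by_load: tuple[tuple[int, float], ...] = ((3, 4.5), (6, 2.0))
    wm_kappa_subject_log_sd: float = 0.3
    wm_precision_shift: tuple[tuple[str, float], ...] = (
        ("control", 1.0), ("LPFC_to_IPS", 1.0), ("IPS_to_LPFC", 1.0),
    )
    rt_base_ms: float = 700.0
    rt_base_subject_sd_ms: float = 80.0
    rt_rare_slowing_ms: float = 50.0
    rt_slowing_w_gain: float = 1.0
    rt_noise_sd_ms: float = 150.0
    miss_rate: float = 0.02
    drop_one_subject: bool = False
    task: TaskConfig = field(default_factory=TaskConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.miss_rate <= 0.2:
            raise ValueError("miss_rate must be in [0, 0.2]")
        if set(self.conditions) != set(CONDITION_LABELS):
            raise ValueError(f"conditions must be {CONDITION_LABELS}")
        n_orders = math.factorial(len(self.conditions))
        if self.order_scheme == "counterbalanced" and self.n_subjects < n_orders:
            raise ValueError(
                f"counterbalancing over {n_orders} condition orders needs at "
                f"least {n_orders} subjects (got {self.n_subjects})"
            )
        if self.shift_mechanism not in ("additive", "multiplicative"):
            raise ValueError("shift_mechanism must be additive|multiplicative")

    def replace(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)

    @property
    def kappa_by_load(self) -> dict[int, float]:
        return dict(self.wm_kappa_by_load)

    @property
    def precision_shift(self) -> dict[str, float]:
        return dict(self.wm_precision_shift)


@dataclass
class CohortDataset:
    """One synthetic study: observed tables plus sealed ground truth."""

    twostep: pd.DataFrame
    wm: pd.DataFrame
    questionnaires: pd.DataFrame
    ground_truth: pd.DataFrame
    config: CohortConfig

    def subjects(self) -> list[str]:
        return sorted(self.twostep["subject"].unique())


def _condition_orders(conditions: tuple[str, ...]) -> list[tuple[str, ...]]:
    return sorted(itertools.permutations(conditions))


def _shifted_w(cfg: CohortConfig, w0: float, condition: str) -> float:
    shift = {
        "control": 0.0,
        "IPS_to_LPFC": cfg.w_shift_ips_lpfc,
        "LPFC_to_IPS": cfg.w_shift_lpfc_ips,
    }[condition]
    if cfg.shift_mechanism == "additive":
        w = w0 + shift
    else:
        w = w0 * (1.0 + shift)
    return float(np.clip(w, 0.0, 1.0))


def generate_cohort(config: CohortConfig | None = None) -> CohortDataset:
    """Generate a full synthetic cohort, reproducible from ``master_seed``."""
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(cfg.master_seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    orders = _condition_orders(cfg.conditions)
    n = cfg.n_subjects
    subj_ids = [f"S{i + 1:02d}" for i in range(n)]
    if cfg.order_scheme == "counterbalanced":
        assigned = [orders[i % len(orders)] for i in range(n)]
    elif cfg.order_scheme == "random":
        assigned = [orders[rng.integers(len(orders))] for _ in range(n)]
    else:
        raise ValueError(f"unknown order_scheme {cfg.order_scheme!r}")

    two_rows, wm_rows, gt_rows, q_rows = [], [], [], []
    kappas = cfg.kappa_by_load
    pshift = cfg.precision_shift
    for i, (sid, order) in enumerate(zip(subj_ids, assigned)):
        srng = np.random.default_rng(np.random.SeedSequence([cfg.master_seed, 17, i]))
        # subject-level baseline parameters
        w0 = float(srng.beta(cfg.control_w_beta_a, cfg.control_w_beta_b))
        base = dict(
            beta1=float(np.exp(srng.normal(cfg.beta_log_mu, cfg.beta_log_sd))),
            beta2=float(np.exp(srng.normal(cfg.beta_log_mu, cfg.beta_log_sd))),
            alpha1=float(srng.beta(cfg.alpha_beta_a, cfg.alpha_beta_b)),
            alpha2=float(srng.beta(cfg.alpha_beta_a, cfg.alpha_beta_b)),
            lam=float(srng.beta(cfg.lam_beta_a, cfg.lam_beta_b)),
            persev=float(srng.normal(cfg.persev_mu, cfg.persev_sd)),
        )
        kappa_mult = float(np.exp(srng.normal(0.0, cfg.wm_kappa_subject_log_sd)))
        rt_base = float(srng.normal(cfg.rt_base_ms, cfg.rt_base_subject_sd_ms))
        q_rows.append(
            {
                "subject": sid,
                "oci_r": int(np.clip(round(srng.normal(12, 8)), 0, 72)),
                "bdi": int(np.clip(round(srng.normal(7, 6)), 0, 63)),
                "stai": int(np.clip(round(srng.normal(38, 9)), 20, 80)),
                "mcq_log10k": round(float(srng.normal(-1.8, 0.6)), 4),
            }
        )
        for day, condition in enumerate(order, start=1):
            j = cfg.conditions.index(condition)
            crng = np.random.default_rng(
                np.random.SeedSequence([cfg.master_seed, 23, i, j])
            )
            w = _shifted_w(cfg, w0, condition)
            params = ModelParams(w=w, **base)
            env = build_session(
                cfg.task,
                walk_id=int(crng.integers(cfg.task.n_walk_sets)),
                seed=int(crng.integers(2**31)),
            )
            trials = simulate_agent(
                params, env, seed=int(crng.integers(2**31)),
                miss_rate=cfg.miss_rate,
            )
            # second-stage RTs: base + rare-transition slowing scaled by
            # goal-directedness + trial noise
            rts = []
            for tr in trials:
                if not tr.valid:
                    rts.append(math.nan)
                    continue
                slow = 0.0
                if not tr.common:
                    slow = cfg.rt_rare_slowing_ms * (1.0 + cfg.rt_slowing_w_gain * w)
                rts.append(max(150.0, rt_base + slow + crng.normal(0, cfg.rt_noise_sd_ms)))
            frame = trials_to_frame(
                trials, subject=sid, condition=condition, session_order=day
            )
            frame["rt2_ms"] = np.round(rts, 1)
            two_rows.append(frame)

            # working-memory session: randomised interleaving of the loads
            loads = np.repeat(list(kappas), cfg.n_wm_trials_per_load)
            crng.shuffle(loads)
            for t_idx, load in enumerate(loads, start=1):
                kappa = kappas[int(load)] * kappa_mult
                sd_eff = sd_for_kappa(kappa) / pshift[condition]
                kappa_eff = kappa if pshift[condition] == 1.0 else kappa_for_sd(
                    min(sd_eff, 1.5)
                )
                target = float(crng.uniform(0, math.pi))
                err = float(crng.vonmises(0.0, kappa_eff)) / 2.0
                response = (target + err) % math.pi
                wm_rows.append(
                    {
                        "subject": sid,
                        "condition": condition,
                        "session_order": day,
                        "trial": t_idx,
                        "load": int(load),
                        "target_deg": round(math.degrees(target), 3),
                        "response_deg": round(math.degrees(response), 3),
                    }
                )
            gt_rows.append(
                {
                    "subject": sid,
                    "condition": condition,
                    "session_order": day,
                    "w_baseline": w0,
                    **{k: getattr(params, k) for k in
                       ("beta1", "beta2", "alpha1", "alpha2", "lam", "persev", "w")},
                    "wm_kappa_load3": kappas[3] * kappa_mult,
                    "wm_kappa_load6": kappas[6] * kappa_mult,
                    "rt_base_ms": rt_base,
                }
            )

    twostep = pd.concat(two_rows, ignore_index=True)[TWOSTEP_COLUMNS]
    wm = pd.DataFrame(wm_rows)[WM_COLUMNS]
    questionnaires = pd.DataFrame(q_rows)[QUESTIONNAIRE_COLUMNS]
    ground_truth = pd.DataFrame(gt_rows)
    if cfg.drop_one_subject:
        drop = subj_ids[int(rng.integers(n))]
        twostep = twostep[twostep["subject"] != drop].reset_index(drop=True)
        wm = wm[wm["subject"] != drop].reset_index(drop=True)
        questionnaires = questionnaires[questionnaires["subject"] != drop]
        ground_truth = ground_truth[ground_truth["subject"] != drop]
    return CohortDataset(
        twostep=twostep, wm=wm, questionnaires=questionnaires,
        ground_truth=ground_truth, config=cfg,
    )


# ---------------------------------------------------------------------------
# disk round-trip

_SCHEMAS = {
    "twostep.csv": TWOSTEP_COLUMNS,
    "wm.csv": WM_COLUMNS,
    "questionnaires.csv": QUESTIONNAIRE_COLUMNS,
}

_DIR_README = """\
Synthetic two-step / working-memory cohort
==========================================
twostep.csv        one row per two-step trial: subject, condition,
                   session_order, trial (1-based), choice1, state2 (B/C),
                   choice2, reward (0/1), transition (common/rare), rt2_ms,
                   valid (0/1; invalid rows have empty choice fields)
wm.csv             one row per working-memory trial: subject, condition,
                   session_order, trial, load (3/6), target_deg,
                   response_deg (orientations in degrees, [0, 180))
questionnaires.csv opaque per-subject totals: oci_r, bdi, stai, mcq_log10k
ground_truth.csv   sealed generating parameters per subject x condition
config.yaml        the generating configuration snapshot
Condition labels: control, LPFC_to_IPS, IPS_to_LPFC.
"""


def export_cohort(dataset: CohortDataset, directory) -> None:
    """Write the cohort tables, ground truth, and config snapshot."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    dataset.twostep.to_csv(d / "twostep.csv", index=False)
    dataset.wm.to_csv(d / "wm.csv", index=False)
    dataset.questionnaires.to_csv(d / "questionnaires.csv", index=False)
    dataset.ground_truth.to_csv(d / "ground_truth.csv", index=False)
    cfg = asdict(dataset.config)
    cfg["task"] = asdict(dataset.config.task)
    for key in ("wm_kappa_by_load", "wm_precision_shift"):
        cfg[key] = [list(t) for t in cfg[key]]
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    (d / "README.txt").write_text(_DIR_README)


def _read_checked(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing cohort file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    if "condition" in df.columns:
        bad = df.loc[~df["condition"].isin(CONDITION_LABELS)]
        if len(bad):
            row = int(bad.index[0]) + 2  # header + 1-based
            raise ValueError(
                f"{path.name} row {row}: unknown condition label "
                f"{bad['condition'].iloc[0]!r}"
            )
    return df


def load_cohort(directory) -> CohortDataset:
    """Read a cohort directory back; validates schemas and labels."""
    d = Path(directory)
    twostep = _read_checked(d / "twostep.csv", TWOSTEP_COLUMNS)
    wm = _read_checked(d / "wm.csv", WM_COLUMNS)
    questionnaires = _read_checked(d / "questionnaires.csv", QUESTIONNAIRE_COLUMNS)
    gt_path = d / "ground_truth.csv"
    ground_truth = pd.read_csv(gt_path) if gt_path.exists() else pd.DataFrame()
    cfg_path = d / "config.yaml"
    cfg = CohortConfig()
    if cfg_path.exists():
        with open(cfg_path) as fh:
            raw = yaml.safe_load(fh)
        raw["task"] = TaskConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw["task"].items()
        })
        raw["conditions"] = tuple(raw["conditions"])
        raw["wm_kappa_by_load"] = tuple(
            (int(k), float(v)) for k, v in raw["wm_kappa_by_load"]
        )
        raw["wm_precision_shift"] = tuple(
            (str(k), float(v)) for k, v in raw["wm_precision_shift"]
        )
        cfg = CohortConfig(**raw)
    return CohortDataset(
        twostep=twostep, wm=wm, questionnaires=questionnaires,
        ground_truth=ground_truth, config=cfg,
    )
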