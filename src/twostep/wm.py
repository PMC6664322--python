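"""Delayed-estimation working-memory analysis: angular error and precision.

Orientation stimuli are undirected lines, so the response space has period
pi. Errors are computed on the orientation circle, doubled onto the full
circle for circular statistics, and the circular SD is halved back. Recall
precision — the study's working-memory outcome — is the reciprocal of that
SD, computed separately for the low (3-item) and high (6-item) memory
loads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WMTrial",
    "PrecisionResult",
    "angular_error",
    "circular_sd",
    "precision_by_load",
    "log_transform_precision",
    "MAX_CIRCULAR_SD",
    "LOADS",
]

LOADS = (3, 6)

#: resultant lengths below this floor are treated as 0 (uniform errors);
#: the reported SD is then sqrt(-2 ln floor)/2, the documented maximum.
_R_FLOOR = 1e-12
MAX_CIRCULAR_SD = math.sqrt(-2.0 * math.log(_R_FLOOR)) / 2.0


@dataclass(frozen=True)
class WMTrial:
    """One orientation-report trial (angles in radians, [0, pi))."""

    target_theta: float
    response_theta: float
    load: int
    subject: str = ""
    condition: str = ""
    session_order: int = 0

    def __post_init__(self) -> None:
        if self.load not in LOADS:
            raise ValueError(f"load must be one of {LOADS}, got {self.load}")
        for name in ("target_theta", "response_theta"):
            v = getattr(self, name)
            if not 0.0 <= v < math.pi:
                raise ValueError(f"{name} must lie in [0, pi), got {v}")


@dataclass(frozen=True)
class PrecisionResult:
    """Recall precision for one load condition.

    ``precision`` is 1/SD (rad^-1); it is None (missing) when the SD is
    degenerate at 0, never infinity. ``at_max_sd`` flags a resultant length
    of ~0 (uniform responding), where the SD is reported at its documented
    maximum. ``chance_corrected`` records whether the permutation-based
    chance level was subtracted.
    """

    load: int
    n_trials: int
    circular_sd_rad: float
    precision: float | None
    log_precision: float | None
    chance_corrected: bool = False
    at_max_sd: bool = False


def angular_error(target_theta: float, response_theta: float) -> float:
    """Signed orientation error on the period-pi circle, in (-pi/2, pi/2].

    The wrap takes the short way around: a response of pi - 0.01 to a
    target of 0 is an error of -0.01, not +3.13.
    """
    for name, v in (("target_theta", target_theta), ("response_theta", response_theta)):
        if not 0.0 <= v < math.pi:
            raise ValueError(f"{name} must lie in [0, pi), got {v}")
    d = (response_theta - target_theta) % math.pi
    if d > math.pi / 2:
        d -= math.pi
    return d


def circular_sd(errors, method: str = "circular") -> tuple[float, bool]:
    """SD of signed orientation errors, in radians.

    The default ``circular`` estimator doubles the errors onto the full
    circle; SD = sqrt(-2 ln R) / 2 where R is the resultant length of the
    doubled angles. ``method="linear"`` returns the ordinary SD of the
    wrapped errors as a sensitivity check. Returns ``(sd, at_max)``;
    ``at_max`` is True when R underflows to 0 (uniform errors) and the SD is
    reported at :data:`MAX_CIRCULAR_SD`.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 errors for a circular SD")
    if method == "linear":
        return float(np.std(e, ddof=1)), False
    if method != "circular":
        raise ValueError("method must be 'circular' or 'linear'")
    z = np.exp(2j * e)
    r = float(np.abs(z.mean()))
    if r < _R_FLOOR:
        return MAX_CIRCULAR_SD, True
    r = min(r, 1.0)
    return math.sqrt(-2.0 * math.log(r)) / 2.0, False


def _chance_precision(errors: np.ndarray, targets: np.ndarray,
                      responses: np.ndarray, rng: np.random.Generator,
                      n_perm: int = 200) -> float:
    """Precision expected from random responding, estimated by permuting
    responses across trials (breaking the target-response pairing)."""
    vals = []
    for _ in range(n_perm):
        perm = rng.permutation(len(responses))
        err = np.array([angular_error(t, r) for t, r in zip(targets, responses[perm])])
        sd, at_max = circular_sd(err)
        if sd > 0:
            vals.append(1.0 / sd)
    return float(np.mean(vals)) if vals else 0.0


def precision_by_load(
    trials,
    chance_correct: bool = False,
    rng: np.random.Generator | None = None,
) -> dict[int, PrecisionResult]:
    """Recall precision per memory load for a sequence of :class:`WMTrial`.

    Requires >= 2 trials in every load that is present. When
    ``chance_correct`` is set, the precision expected under random
    responding (permutation estimate) is subtracted.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no working-memory trials supplied")
    rng = rng or np.random.default_rng(0)
    out: dict[int, PrecisionResult] = {}
    for load in sorted({t.load for t in trials}):
        grp = [t for t in trials if t.load == load]
        if len(grp) < 2:
            raise ValueError(f"load {load} has {len(grp)} trial(s); need >= 2")
        targets = np.array([t.target_theta for t in grp])
        responses = np.array([t.response_theta for t in grp])
        errors = np.array([angular_error(t, r) for t, r in zip(targets, responses)])
        sd, at_max = circular_sd(errors)
        if sd <= 0.0:
            prec: float | None = None
        else:
            prec = 1.0 / sd
            if chance_correct:
                prec -= _chance_precision(errors, targets, responses, rng)
        logp = math.log(prec) if prec is not None and prec > 0 else None
        out[load] = PrecisionResult(
            load=load,
            n_trials=len(grp),
            circular_sd_rad=sd,
            precision=prec,
            log_precision=logp,
            chance_corrected=chance_correct,
            at_max_sd=at_max,
        )
    return out


def log_transform_precision(values) -> np.ndarray:
    """Natural log of precision values; missing/non-positive propagate NaN."""
    v = pd.to_numeric(pd.Series(list(values)), errors="coerce").to_numpy(dtype=float)
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v) & (v > 0)
    out[ok] = np.log(v[ok])
    return out


def wm_trials_from_frame(df: pd.DataFrame) -> list[WMTrial]:
    """Build :class:`WMTrial` objects from the on-disk schema (degrees)."""
    out = []
    for _, row in df.iterrows():
        out.append(
            WMTrial(
                target_theta=math.radians(float(row["target_deg"])) % math.pi,
                response_theta=math.radians(float(row["response_deg"])) % math.pi,
                load=int(row["load"]),
                subject=str(row.get("subject", "")),
                condition=str(row.get("condition", "")),
                session_order=int(row.get("session_order", 0)),
            )
        )
    return out
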