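"""Maximum-likelihood fitting of the hybrid model, statsmodels-style.

:class:`HybridModel` wraps one subject-session of trials; ``fit()`` runs a
multi-start quasi-Newton search on an unconstrained reparameterisation
(logit for the [0,1] parameters, log for the inverse temperatures) and
returns a :class:`HybridResults` with back-transformed estimates,
approximate standard errors and a ``summary()`` table.

The likelihood inner loop is JIT-compiled with numba; a pure-Python
reference implementation lives in :mod:`twostep.hybrid` and the two are
held to agreement by the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .hybrid import (
    PARAM_NAMES,
    ModelParams,
    TrialRecord,
    simulate_agent,
    trials_from_frame,
)
from .task import TaskConfig, TransitionStructure, build_session

__all__ = [
    "HybridModel",
    "HybridResults",
    "FitConfig",
    "FitResult",
    "RecoveryReport",
    "to_unconstrained",
    "from_unconstrained",
    "fit_subject",
    "recovery_study",
    "BOUND_EPS",
]

#: parameters at a hard bound are pulled inside by this much before the
#: logit/log transform
BOUND_EPS = 1e-6

try:  # numba is optional at runtime; the pure-numpy loop below is exact
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _loglik_core(theta, choice1, state2, choice2, reward, valid, P, q_init):
    beta1, beta2, alpha1, alpha2, lam, persev, w = (
        theta[0], theta[1], theta[2], theta[3], theta[4], theta[5], theta[6],
    )
    q_mf = np.full(2, q_init)
    q2 = np.full((2, 2), q_init)
    prev = -1
    ll = 0.0
    for t in range(choice1.shape[0]):
        if valid[t] == 0:
            continue
        best0 = q2[0, 0] if q2[0, 0] > q2[0, 1] else q2[0, 1]
        best1 = q2[1, 0] if q2[1, 0] > q2[1, 1] else q2[1, 1]
        v0 = beta1 * (w * (P[0, 0] * best0 + P[0, 1] * best1) + (1 - w) * q_mf[0])
        v1 = beta1 * (w * (P[1, 0] * best0 + P[1, 1] * best1) + (1 - w) * q_mf[1])
        if prev == 0:
            v0 += persev
        elif prev == 1:
            v1 += persev
        m = v0 if v0 > v1 else v1
        e0 = math.exp(v0 - m)
        e1 = math.exp(v1 - m)
        p1 = e0 / (e0 + e1) if choice1[t] == 0 else e1 / (e0 + e1)
        s = state2[t]
        u0 = beta2 * q2[s, 0]
        u1 = beta2 * q2[s, 1]
        m2 = u0 if u0 > u1 else u1
        f0 = math.exp(u0 - m2)
        f1 = math.exp(u1 - m2)
        p2 = f0 / (f0 + f1) if choice2[t] == 0 else f1 / (f0 + f1)
        if p1 < 1e-12:
            p1 = 1e-12
        if p2 < 1e-12:
            p2 = 1e-12
        ll += math.log(p1) + math.log(p2)
        c1 = choice1[t]
        c2 = choice2[t]
        d1 = q2[s, c2] - q_mf[c1]
        q_mf[c1] += alpha1 * d1
        d2 = reward[t] - q2[s, c2]
        q2[s, c2] += alpha2 * d2
        q_mf[c1] += alpha1 * lam * d2
        prev = c1
    return ll


# ---------------------------------------------------------------------------
# parameter transforms


def to_unconstrained(params: ModelParams) -> np.ndarray:
    """Map bounded parameters to R^7: log(beta1), log(beta2),
    logit(alpha1), logit(alpha2), logit(lam), persev, logit(w).

    Values exactly at a bound are clipped inward by ``BOUND_EPS`` first.
    """
    arr = params.to_array()
    out = np.empty(7)
    out[0] = math.log(max(arr[0], BOUND_EPS))
    out[1] = math.log(max(arr[1], BOUND_EPS))
    for i in (2, 3, 4, 6):
        out[i] = logit(np.clip(arr[i], BOUND_EPS, 1 - BOUND_EPS))
    out[5] = arr[5]
    return out


def from_unconstrained(x) -> ModelParams:
    """Inverse of :func:`to_unconstrained`."""
    x = np.asarray(x, dtype=float)
    if x.shape != (7,) or not np.all(np.isfinite(x)):
        raise ValueError("expected 7 finite unconstrained values")
    arr = np.empty(7)
    arr[0] = math.exp(x[0])
    arr[1] = math.exp(x[1])
    for i in (2, 3, 4, 6):
        arr[i] = float(expit(x[i]))
    arr[5] = x[5]
    return ModelParams.from_array(arr)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for per-subject maximum likelihood."""

    n_restarts: int = 10
    maxiter: int = 500
    gtol: float = 1e-6
    #: uniform box in unconstrained space the random starts are drawn from:
    #: log-beta in [-1, 2.5], logits in [-2, 2], persev in [-1, 1]
    start_box_logbeta: tuple[float, float] = (-1.0, 2.5)
    start_box_logit: tuple[float, float] = (-2.0, 2.0)
    start_box_persev: tuple[float, float] = (-1.0, 1.0)
    compute_se: bool = True
    #: optional ridge-like MAP: Gaussian prior of this SD on each
    #: unconstrained parameter. None (default) is plain MLE.
    map_prior_sd: float | None = None


class HybridModel:
    """The hybrid RL model bound to one session of two-step trials.

    Parameters
    ----------
    trials : sequence of TrialRecord
    structure : TransitionStructure
    q_init : initial action value (0 by default; 0.5 available).
    """

    def __init__(self, trials, structure: TransitionStructure, q_init: float = 0.0):
        self.trials = list(trials)
        self.structure = structure
        self.q_init = float(q_init)
        valid = [t for t in self.trials if t.valid]
        self.n_valid_trials = len(valid)
        n = len(self.trials)
        self._c1 = np.array([t.choice1 if t.valid else -1 for t in self.trials], dtype=np.int64)
        self._s2 = np.array([t.state2 if t.valid else -1 for t in self.trials], dtype=np.int64)
        self._c2 = np.array([t.choice2 if t.valid else -1 for t in self.trials], dtype=np.int64)
        self._rw = np.array([t.reward if t.valid else 0 for t in self.trials], dtype=np.float64)
        self._ok = np.array([1 if t.valid else 0 for t in self.trials], dtype=np.int64)
        self._P = np.ascontiguousarray(structure.matrix, dtype=np.float64)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, structure: TransitionStructure | None = None,
        common_prob: float = 0.7, q_init: float = 0.0,
    ) -> "HybridModel":
        """Build from one session's rows of the trial-table schema."""
        if structure is None:
            structure = TransitionStructure(common_prob=common_prob)
        return cls(trials_from_frame(df), structure, q_init=q_init)

    def loglike(self, params: ModelParams | np.ndarray) -> float:
        """Session log-likelihood (fast array path)."""
        theta = params.to_array() if isinstance(params, ModelParams) else np.asarray(params, float)
        if not np.all(np.isfinite(theta)):
            raise ValueError("parameters must be finite")
        return float(
            _loglik_core(theta, self._c1, self._s2, self._c2, self._rw,
                         self._ok, self._P, self.q_init)
        )

    def _negll_unconstrained(self, x: np.ndarray) -> float:
        # hot path: transform without constructing ModelParams objects
        if not np.all(np.isfinite(x)):
            return 1e12
        theta = np.empty(7)
        theta[0] = math.exp(min(x[0], 30.0))
        theta[1] = math.exp(min(x[1], 30.0))
        theta[2] = expit(x[2])
        theta[3] = expit(x[3])
        theta[4] = expit(x[4])
        theta[5] = x[5]
        theta[6] = expit(x[6])
        ll = _loglik_core(theta, self._c1, self._s2, self._c2, self._rw,
                          self._ok, self._P, self.q_init)
        return -ll if math.isfinite(ll) else 1e12

    def fit(self, config: FitConfig | None = None, seed: int = 0) -> "HybridResults":
        """Maximize the session likelihood from multiple random starts.

        Deterministic given ``seed``. Raises ``ValueError`` when the session
        holds no valid trials.
        """
        if self.n_valid_trials == 0:
            raise ValueError("cannot fit a session with zero valid trials")
        cfg = config or FitConfig()
        rng = np.random.default_rng(seed)
        objective = self._negll_unconstrained
        if cfg.map_prior_sd is not None:
            inv_var = 1.0 / cfg.map_prior_sd**2

            def objective(x, _nll=self._negll_unconstrained):
                return _nll(x) + 0.5 * inv_var * float(np.dot(x, x))

        lo_b, hi_b = cfg.start_box_logbeta
        lo_l, hi_l = cfg.start_box_logit
        lo_p, hi_p = cfg.start_box_persev
        best = None
        best_idx = -1
        n_ok = 0
        for k in range(cfg.n_restarts):
            x0 = np.concatenate([
                rng.uniform(lo_b, hi_b, 2),
                rng.uniform(lo_l, hi_l, 3),
                rng.uniform(lo_p, hi_p, 1),
                rng.uniform(lo_l, hi_l, 1),
            ])
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B",
                options={"maxiter": cfg.maxiter, "gtol": cfg.gtol},
            )
            if np.isfinite(res.fun):
                n_ok += 1
                if best is None or res.fun < best.fun:
                    best = res
                    best_idx = k
        if best is None:
            raise RuntimeError("all optimizer restarts failed")
        se = None
        if cfg.compute_se:
            se = self._stderr(best.x, objective)
        # llf is always the plain log-likelihood at the optimum, even when a
        # MAP penalty shaped the search
        llf = -self._negll_unconstrained(best.x)
        return HybridResults(
            model=self,
            params=from_unconstrained(best.x),
            llf=float(llf),
            xopt=best.x.copy(),
            bse=se,
            n_restarts=cfg.n_restarts,
            best_restart=best_idx,
            converged=bool(n_ok > 0 and best.success),
            n_valid_trials=self.n_valid_trials,
        )

    def _stderr(self, xopt: np.ndarray, objective=None) -> dict[str, float] | None:
        """Delta-method SEs on the natural scale from the numerical Hessian
        of the unconstrained objective. NaN where singular."""
        from statsmodels.tools.numdiff import approx_hess1

        objective = objective or self._negll_unconstrained
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H = approx_hess1(xopt, objective)
                cov = np.linalg.pinv(H)
            var_u = np.clip(np.diag(cov), 0, np.inf)
            # d(natural)/d(unconstrained) for exp / expit / identity links
            p = from_unconstrained(xopt).to_array()
            jac = np.array([
                p[0], p[1],
                p[2] * (1 - p[2]), p[3] * (1 - p[3]), p[4] * (1 - p[4]),
                1.0,
                p[6] * (1 - p[6]),
            ])
            se = np.sqrt(var_u) * np.abs(jac)
            return dict(zip(PARAM_NAMES, se))
        except Exception:
            return None


@dataclass
class HybridResults:
    """Fit results for one session: estimates, uncertainty, diagnostics."""

    model: HybridModel
    params: ModelParams
    llf: float
    xopt: np.ndarray
    bse: dict[str, float] | None
    n_restarts: int
    best_restart: int
    converged: bool
    n_valid_trials: int

    @property
    def estimates(self) -> ModelParams:  # spec-facing alias
        return self.params

    @property
    def loglik(self) -> float:
        return self.llf

    def params_series(self) -> pd.Series:
        return pd.Series(self.params.to_array(), index=list(PARAM_NAMES))

    def simulate(self, env, seed: int, **kwargs):
        """Simulate a synthetic session from the fitted parameters."""
        return simulate_agent(self.params, env, seed, **kwargs)

    def summary(self) -> str:
        lines = [
            "Hybrid MF/MB model — maximum likelihood fit",
            "=" * 46,
            f"valid trials: {self.n_valid_trials:>5d}   log-likelihood: {self.llf:.3f}",
            f"restarts: {self.n_restarts} (best: {self.best_restart})   "
            f"converged: {self.converged}",
            "-" * 46,
            f"{'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for name in PARAM_NAMES:
            est = getattr(self.params, name)
            se = self.bse.get(name, math.nan) if self.bse else math.nan
            se_s = f"{se:>12.4f}" if np.isfinite(se) else f"{'—':>12}"
            lines.append(f"{name:<8}{est:>12.4f}{se_s}")
        lines.append("=" * 46)
        return "\n".join(lines)


#: spec-facing name for the per-session fit container
FitResult = HybridResults


def fit_subject(
    trials,
    structure: TransitionStructure,
    config: FitConfig | None = None,
    seed: int = 0,
    q_init: float = 0.0,
) -> HybridResults:
    """Fit the hybrid model to one subject-session of trials."""
    return HybridModel(trials, structure, q_init=q_init).fit(config=config, seed=seed)


@dataclass
class RecoveryReport:
    """True-vs-estimated parameters over a simulated cohort of agents."""

    table: pd.DataFrame          # columns true_<p>, est_<p> per agent
    summary: pd.DataFrame        # per-parameter correlation and bias
    degenerate: list[str] = field(default_factory=list)

    def correlation(self, name: str = "w") -> float:
        return float(self.summary.loc[name, "correlation"])

    def plot(self, name: str = "w", ax=None):
        """Scatter of true vs estimated values for one parameter."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table[f"true_{name}"]
        e = self.table[f"est_{name}"]
        ax.scatter(t, e, s=12, alpha=0.7)
        lims = (min(t.min(), e.min()), max(t.max(), e.max()))
        ax.plot(lims, lims, ls="--", c="grey", lw=1)
        ax.set(xlabel=f"true {name}", ylabel=f"estimated {name}")
        return ax


def recovery_study(
    param_sampler,
    n_agents: int,
    n_trials: int,
    seed: int,
    fit_config: FitConfig | None = None,
    task_config: TaskConfig | None = None,
) -> RecoveryReport:
    """Simulate ``n_agents`` hybrid agents, fit each, and tabulate recovery.

    ``param_sampler`` is a callable ``rng -> ModelParams``. Parameters whose
    true values are (numerically) constant across agents have undefined
    recovery correlation; they are reported as NaN and listed in
    ``degenerate`` rather than raising.
    """
    if n_agents < 2:
        raise ValueError("n_agents must be >= 2")
    task_config = task_config or TaskConfig(n_trials=n_trials)
    if task_config.n_trials != n_trials:
        task_config = task_config.replace(n_trials=n_trials)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_agents):
        true = param_sampler(rng)
        env = build_session(task_config, walk_id=i % task_config.n_walk_sets,
                            seed=int(rng.integers(2**31)))
        trials = simulate_agent(true, env, seed=int(rng.integers(2**31)))
        res = fit_subject(trials, env.structure, config=fit_config,
                          seed=int(rng.integers(2**31)))
        row = {f"true_{n}": getattr(true, n) for n in PARAM_NAMES}
        row.update({f"est_{n}": getattr(res.params, n) for n in PARAM_NAMES})
        row["loglik"] = res.llf
        row["converged"] = res.converged
        rows.append(row)
    table = pd.DataFrame(rows)
    summ = {}
    degenerate = []
    for name in PARAM_NAMES:
        t = table[f"true_{name}"].to_numpy()
        e = table[f"est_{name}"].to_numpy()
        if np.std(t) < 1e-12 or np.std(e) < 1e-12:
            corr = math.nan
            degenerate.append(name)
        else:
            corr = float(np.corrcoef(t, e)[0, 1])
        summ[name] = {"correlation": corr, "bias": float(np.mean(e - t))}
    return RecoveryReport(
        table=table,
        summary=pd.DataFrame(summ).T[["correlation", "bias"]],
        degenerate=degenerate,
    )
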