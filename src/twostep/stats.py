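"""The study's statistical battery.

Parametric repeated-measures tests with nonparametric fallbacks, exactly
the sequence applied to the fitted goal-directed weight w and to
working-memory precision: Lilliefors-corrected KS normality screening,
repeated-measures / mixed ANOVA, paired contrasts with dual-convention
effect sizes, an exact Wilcoxon signed-rank test, rank-transform ANCOVA,
two-way-mixed consistency ICC, a Bayesian Pearson-correlation test by
numerical integration, power analysis from the noncentral t, and the
two-step behavioural signatures (stay probabilities and RT-by-transition).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

__all__ = [
    "StatResult",
    "PowerSpec",
    "StayProbTable",
    "DeltaRatios",
    "ks_normality",
    "rm_anova",
    "paired_contrast",
    "wilcoxon_signed_rank",
    "rank_ancova",
    "icc_consistency_average",
    "bayes_cor_logbf",
    "paired_ttest_power",
    "solve_n",
    "stay_probability_table",
    "rt_by_transition",
    "delta_ratios",
    "CORRECTED_ALPHA_CONTRASTS",
]

#: Bonferroni-style alpha for the two planned stimulation-vs-control
#: contrasts, surfaced in reports alongside raw p-values.
CORRECTED_ALPHA_CONTRASTS = 0.025


@dataclass
class StatResult:
    """A single test outcome: statistic, df, p, effect sizes, method flags."""

    name: str
    statistic: float
    df: tuple | float | None
    pvalue: float
    effect_sizes: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": _jsonify(self.statistic),
            "df": _jsonify(self.df),
            "pvalue": _jsonify(self.pvalue),
            "effect_sizes": {k: _jsonify(v) for k, v in self.effect_sizes.items()},
            "flags": {k: _jsonify(v) for k, v in self.flags.items()},
        }
        if self.table is not None:
            d["table"] = self.table.round(6).to_dict(orient="records")
        return d


def _jsonify(v):
    if isinstance(v, (tuple, list)):
        return [_jsonify(x) for x in v]
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating, float)):
        f = float(v)
        return None if math.isnan(f) else f
    return v


# ---------------------------------------------------------------------------
# normality


def ks_normality(x) -> StatResult:
    """Kolmogorov-Smirnov test of normality with estimated mean/SD
    (Lilliefors correction)."""
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("normality test needs n >= 4")
    if np.std(x) == 0:
        raise ValueError("constant vector has no defined normality test")
    stat, p = lilliefors(x, dist="norm")
    return StatResult(
        name="ks_normality", statistic=float(stat), df=None, pvalue=float(p),
        flags={"correction": "lilliefors", "n": int(x.size)},
    )


# ---------------------------------------------------------------------------
# ANOVA family (pingouin behind the module surface)


def _check_complete(table: pd.DataFrame, within: list[str], subject: str, dv: str):
    counts = table.groupby([subject] + within, observed=True)[dv].count()
    missing = counts[counts != 1]
    n_cells = int(np.prod([table[w].nunique() for w in within]))
    per_subj = table.groupby(subject, observed=True)[dv].count()
    bad = per_subj[per_subj != n_cells]
    if len(bad) or len(missing):
        missing_pairs = []
        cells = set(
            itertools.product(*[sorted(table[w].unique()) for w in within])
        )
        for s, grp in table.groupby(subject, observed=True):
            have = set(map(tuple, grp[within].itertuples(index=False)))
            for cell in cells - have:
                missing_pairs.append((s, cell))
        raise ValueError(
            f"incomplete repeated-measures design; missing subject x cell "
            f"pairs: {missing_pairs[:10]}"
        )


def rm_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: list[str] | str = "condition",
    subject: str = "subject",
    between: str | None = None,
) -> StatResult:
    """Repeated-measures ANOVA (1 or 2 within factors), optionally with a
    between-subjects order factor (single within factor only), giving the
    order x condition interaction.

    Returns the first within factor's row as the headline statistic and the
    full ANOVA table in ``table``.
    """
    import pingouin as pg

    within = [within] if isinstance(within, str) else list(within)
    _check_complete(table, within, subject, dv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if between is not None:
            if len(within) != 1:
                raise ValueError(
                    "a between factor is supported with a single within factor"
                )
            aov = pg.mixed_anova(
                data=table, dv=dv, within=within[0], subject=subject,
                between=between,
            )
            aov = aov.rename(columns={"DF1": "ddof1", "DF2": "ddof2"})
        else:
            aov = pg.rm_anova(
                data=table, dv=dv, within=within if len(within) > 1 else within[0],
                subject=subject, detailed=True,
            )
            if "DF" in aov.columns:  # single-factor detailed output
                err = aov.loc[aov["Source"] == "Error", "DF"]
                aov = aov[aov["Source"] != "Error"].copy()
                aov["ddof1"] = aov["DF"]
                aov["ddof2"] = int(err.iloc[0])
            else:
                aov = aov.rename(columns={"DF": "ddof1"})
    head_src = within[0] if between is None else within[0]
    row = aov[aov["Source"] == head_src].iloc[0]
    keep = [c for c in ("Source", "ddof1", "ddof2", "F", "p_unc", "np2", "ng2")
            if c in aov.columns]
    return StatResult(
        name="rm_anova",
        statistic=float(row["F"]),
        df=(float(row["ddof1"]), float(row["ddof2"])),
        pvalue=float(row["p_unc"]),
        effect_sizes={k: float(row[k]) for k in ("np2", "ng2") if k in row.index
                      and pd.notna(row[k])},
        flags={"within": within, "between": between},
        table=aov[keep].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# paired contrasts


def paired_contrast(x, y) -> StatResult:
    """Paired t-test with both effect-size conventions.

    ``r_t = sqrt(t^2 / (t^2 + df))`` from the t statistic, and
    ``r_z = |Z| / sqrt(2n)`` from the matching Wilcoxon signed-rank normal
    approximation. The field is split on which of the two "r" conventions
    is meant by a reported medium effect, so both are carried.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired vectors of equal length n >= 2 required")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    n = d.size
    t, p = sps.ttest_rel(x, y)
    df = n - 1
    r_t = math.sqrt(t**2 / (t**2 + df))
    dz = float(np.mean(d) / np.std(d, ddof=1))
    try:
        wres = wilcoxon_signed_rank(x, y, exact_max_n=0)  # force approximation
        r_z = abs(wres.flags["z"]) / math.sqrt(2 * n)
    except ValueError:
        r_z = math.nan
    return StatResult(
        name="paired_t", statistic=float(t), df=float(df), pvalue=float(p),
        effect_sizes={"r_t": r_t, "r_z": r_z, "dz": dz},
        flags={"n": n, "corrected_alpha": CORRECTED_ALPHA_CONTRASTS},
    )


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    """Mid-ranks of |d| for the nonzero differences."""
    return sps.rankdata(np.abs(d))


def _exact_wplus_sf_cdf(ranks: np.ndarray, w: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) by full sign enumeration, computed as a
    polynomial convolution over the (doubled, integer) mid-ranks."""
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w))
    cdf = float(counts[: w2 + 1].sum())
    sf = float(counts[w2:].sum())
    return cdf, sf


def wilcoxon_signed_rank(x, y, exact_max_n: int = 20) -> StatResult:
    """Related-samples Wilcoxon signed-rank test.

    Zero differences are dropped and ties mid-ranked. The two-tailed p is
    exact (full 2^n sign enumeration, via rank convolution) when the number
    of nonzero differences is <= ``exact_max_n``, else a normal
    approximation with continuity and tie corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    mean_w = n * (n + 1) / 4.0
    # tie correction for the null variance
    _, t_counts = np.unique(np.abs(d), return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - (t_counts**3 - t_counts).sum() / 48.0
    if var_w > 0:
        cc = 0.5 * np.sign(w_plus - mean_w)
        z = (w_plus - mean_w - cc) / math.sqrt(var_w)
    else:
        z = 0.0
    if n <= exact_max_n:
        cdf, sf = _exact_wplus_sf_cdf(ranks, w_plus)
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "exact"
    else:
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "normal_approx"
    return StatResult(
        name="wilcoxon_signed_rank", statistic=w_plus, df=None, pvalue=float(p),
        effect_sizes={"r_z": abs(z) / math.sqrt(2 * x.size)},
        flags={"method": method, "n_nonzero": int(n), "z": float(z)},
    )


def rank_ancova(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    subject: str = "subject",
    covariate: str = "order",
    method: str = "rank_transform",
) -> StatResult:
    """Nonparametric condition test on a repeated-measures table.

    Default ``rank_transform``: the outcome is ranked across all
    observations, then the covariate-adjusted repeated-measures model
    (condition within, order between) is applied to the ranks; degrees of
    freedom follow that mixed-model decomposition. ``method="quade"`` runs
    Quade's blocked rank test instead (within-subject ranks weighted by
    ranked subject ranges; no covariate adjustment).
    """
    if method == "quade":
        return _quade(table, dv=dv, within=within, subject=subject)
    if method != "rank_transform":
        raise ValueError("method must be 'rank_transform' or 'quade'")
    t = table.copy()
    t["_rank"] = sps.rankdata(t[dv].to_numpy())
    res = rm_anova(t, dv="_rank", within=within, subject=subject, between=covariate)
    res.name = "rank_ancova"
    res.flags["procedure"] = "rank_transform"
    return res


def _quade(table: pd.DataFrame, dv: str, within: str, subject: str) -> StatResult:
    wide = table.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("Quade test needs a complete subject x condition table")
    m = wide.to_numpy(dtype=float)
    n, k = m.shape
    r = np.apply_along_axis(sps.rankdata, 1, m)            # within-block ranks
    q = sps.rankdata(m.max(axis=1) - m.min(axis=1))        # ranked block ranges
    s = q[:, None] * (r - (k + 1) / 2.0)
    s_j = s.sum(axis=0)
    a = float((s**2).sum())
    b = float((s_j**2).sum()) / n
    df1, df2 = k - 1, (n - 1) * (k - 1)
    if a == b:  # perfect ordering: F is infinite, p at machine floor
        f, p = math.inf, 0.0
    else:
        f = (n - 1) * b / (a - b)
        p = float(sps.f.sf(f, df1, df2))
    return StatResult(
        name="rank_ancova", statistic=float(f), df=(df1, df2), pvalue=p,
        flags={"procedure": "quade", "covariate_adjusted": False},
    )


# ---------------------------------------------------------------------------
# reliability


def icc_consistency_average(matrix) -> StatResult:
    """ICC(3,k): two-way mixed, consistency, average-measures reliability.

    ``matrix`` is subjects x sessions with no missing cells. Computed from
    the two-way ANOVA decomposition as (MS_subjects - MS_error)/MS_subjects
    with the F test on MS_subjects/MS_error.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 sessions")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing cells are not allowed in the ICC")
    n, k = m.shape
    grand = m.mean()
    ss_subj = k * ((m.mean(axis=1) - grand) ** 2).sum()
    ss_sess = n * ((m.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((m - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_sess
    df_subj, df_err = n - 1, (n - 1) * (k - 1)
    ms_subj = ss_subj / df_subj
    ms_err = ss_err / df_err
    icc = (ms_subj - ms_err) / ms_subj if ms_subj > 0 else math.nan
    f = ms_subj / ms_err if ms_err > 0 else math.inf
    p = float(sps.f.sf(f, df_subj, df_err)) if math.isfinite(f) else 0.0
    return StatResult(
        name="icc_3k", statistic=float(icc), df=(df_subj, df_err), pvalue=p,
        effect_sizes={"F": float(f)},
        flags={"model": "two-way mixed, consistency, average measures",
               "n_subjects": n, "n_sessions": k},
    )


# ---------------------------------------------------------------------------
# Bayesian correlation


def bayes_cor_logbf(x, y) -> StatResult:
    """log BF10 for a Pearson correlation, stretched-beta prior of width 1.

    The marginal likelihood is obtained by numerically integrating the
    exact sampling density of the observed correlation r over the uniform
    prior on rho in (-1, 1); negative values favour the null.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired vectors with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no defined correlation")
    n = int(x.size)
    r = float(np.corrcoef(x, y)[0, 1])

    def density_ratio(rho: float) -> float:
        # f(r | rho, n) / f(r | 0, n); the rho-free factors cancel
        a = (n - 1) / 2.0
        b = (3.0 - 2.0 * n) / 2.0
        hyp = special.hyp2f1(0.5, 0.5, (2.0 * n - 1.0) / 2.0, (rho * r + 1.0) / 2.0)
        hyp0 = special.hyp2f1(0.5, 0.5, (2.0 * n - 1.0) / 2.0, 0.5)
        return (1.0 - rho**2) ** a * (1.0 - rho * r) ** b * hyp / hyp0

    bf10, _ = integrate.quad(lambda rho: 0.5 * density_ratio(rho), -1.0, 1.0,
                             limit=200)
    logbf = math.log(max(bf10, 1e-300))
    return StatResult(
        name="bayes_pearson", statistic=logbf, df=None,
        pvalue=math.nan,
        effect_sizes={"r": r, "bf10": bf10},
        flags={"prior": "stretched beta, width 1 (uniform on rho)", "n": n},
    )


# ---------------------------------------------------------------------------
# power


@dataclass(frozen=True)
class PowerSpec:
    """Paired t-test power specification (two-tailed)."""

    dz: float
    alpha: float = 0.05
    power: float = 0.95
    n: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.n is not None and self.n < 2:
            raise ValueError("n must be >= 2")


def paired_ttest_power(spec: PowerSpec) -> float:
    """Achieved power of a two-tailed paired t-test at sample size spec.n,
    from the noncentral t distribution with ncp = dz * sqrt(n)."""
    if spec.n is None:
        raise ValueError("spec.n is required to compute power")
    df = spec.n - 1
    ncp = spec.dz * math.sqrt(spec.n)
    tcrit = sps.t.ppf(1 - spec.alpha / 2, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def solve_n(spec: PowerSpec, n_max: int = 100000) -> int:
    """Smallest n whose two-tailed paired t-test power reaches the target."""
    if spec.dz == 0 and spec.power > spec.alpha:
        raise ValueError("no finite n reaches the target power at dz = 0")
    for n in range(2, n_max + 1):
        if paired_ttest_power(PowerSpec(spec.dz, spec.alpha, spec.power, n)) >= spec.power:
            return n
    raise ValueError(f"target power not reached by n = {n_max}")


# ---------------------------------------------------------------------------
# two-step behavioural signatures


@dataclass
class StayProbTable:
    """Stay probabilities by previous (reward, transition) with the logistic
    signature coefficients (effect-coded reward, transition, interaction)."""

    probs: pd.DataFrame                 # index reward in {0,1}, cols common/rare
    coef: dict                           # reward, transition, interaction (or NaN)
    n_pairs: int
    empty_cells: list = field(default_factory=list)
    separation: bool = False


def stay_probability_table(trials) -> StayProbTable:
    """Tabulate stage-1 stay behaviour by the previous trial's outcome.

    Uses consecutive pairs of valid trials. A reward main effect is the
    habitual (model-free) signature; the reward x transition interaction is
    the goal-directed (model-based) signature. Coefficients come from a
    logistic regression with +/-1 effect coding; when the fit separates or a
    cell is empty the coefficients are reported as NaN and flagged.
    """
    import statsmodels.api as sm

    trials = list(trials)
    rows = []
    for prev, cur in zip(trials[:-1], trials[1:]):
        if not (prev.valid and cur.valid):
            continue
        rows.append(
            {
                "stay": int(cur.choice1 == prev.choice1),
                "reward": int(prev.reward),
                "common": int(prev.common),
            }
        )
    if len(rows) < 2:
        raise ValueError("need >= 2 valid consecutive-trial pairs")
    df = pd.DataFrame(rows)
    probs = (
        df.groupby(["reward", "common"])["stay"].mean().unstack("common")
        .reindex(index=[0, 1], columns=[0, 1])
    )
    probs.columns = ["rare", "common"]
    probs = probs[["common", "rare"]]
    empty = [
        (r, c) for r in (0, 1) for c in ("common", "rare")
        if pd.isna(probs.loc[r, c])
    ]
    coef = {"reward": math.nan, "transition": math.nan, "interaction": math.nan}
    separation = False
    if not empty:
        X = np.column_stack([
            np.ones(len(df)),
            2 * df["reward"] - 1,
            2 * df["common"] - 1,
            (2 * df["reward"] - 1) * (2 * df["common"] - 1),
        ])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(df["stay"], X).fit(disp=0, maxiter=200)
            if np.all(np.isfinite(fit.params)) and np.max(np.abs(fit.params)) < 20:
                coef = {
                    "reward": float(fit.params.iloc[1]),
                    "transition": float(fit.params.iloc[2]),
                    "interaction": float(fit.params.iloc[3]),
                }
            else:
                separation = True
        except Exception:
            separation = True
    return StayProbTable(
        probs=probs, coef=coef, n_pairs=len(df), empty_cells=empty,
        separation=separation,
    )


def rt_by_transition(trial_table: pd.DataFrame) -> StatResult:
    """Second-stage RT slowing after rare transitions.

    ``trial_table`` holds valid two-step trials with columns subject,
    transition, rt2_ms. Per-subject mean RTs by transition type feed a
    paired comparison (rare - common) across subjects; subjects lacking
    either transition type are excluded with a flag.
    """
    t = trial_table
    t = t[(t["valid"] == 1) & np.isfinite(pd.to_numeric(t["rt2_ms"], errors="coerce"))]
    means = (
        t.groupby(["subject", "transition"])["rt2_ms"].mean().unstack("transition")
    )
    excluded = means.index[means.isna().any(axis=1)].tolist()
    means = means.dropna()
    if len(means) < 2:
        raise ValueError("need >= 2 subjects with both transition types")
    res = paired_contrast(means["rare"].to_numpy(), means["common"].to_numpy())
    res.name = "rt_rare_minus_common"
    res.effect_sizes["mean_slowing_ms"] = float(
        (means["rare"] - means["common"]).mean()
    )
    res.flags["excluded_subjects"] = excluded
    res.table = means.reset_index()
    return res


@dataclass
class DeltaRatios:
    """Per-subject condition ratios relating the two outcomes:
    delta_w = w_control / w_IPS->LPFC and delta_p = p_IPS->LPFC / p_control."""

    delta_w: np.ndarray
    delta_p: np.ndarray
    flagged: np.ndarray  # True where a zero denominator made a ratio missing


def delta_ratios(w_ctrl, w_ips_lpfc, p_ctrl, p_ips_lpfc) -> DeltaRatios:
    w_ctrl, w_ips_lpfc, p_ctrl, p_ips_lpfc = map(
        lambda a: np.asarray(a, dtype=float), (w_ctrl, w_ips_lpfc, p_ctrl, p_ips_lpfc)
    )
    dw = np.where(w_ips_lpfc > 0, w_ctrl / np.where(w_ips_lpfc > 0, w_ips_lpfc, 1),
                  np.nan)
    dp = np.where(p_ctrl > 0, p_ips_lpfc / np.where(p_ctrl > 0, p_ctrl, 1), np.nan)
    flagged = ~(np.isfinite(dw) & np.isfinite(dp))
    return DeltaRatios(delta_w=dw, delta_p=dp, flagged=flagged)
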