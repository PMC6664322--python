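"""Pipeline orchestration: simulate -> fit -> analyse -> report.

Every number in the report is produced by a module operation; this layer
only sequences stages, derives per-stage sub-seeds from the master seed,
validates inputs, and serialises the report. Given the same inputs, config
and seed the report is byte-identical (no timestamps enter it).
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortConfig,
    export_cohort,
    load_cohort,
    _read_checked,
    TWOSTEP_COLUMNS,
    WM_COLUMNS,
)
from .fitting import FitConfig, HybridModel
from .hybrid import CONDITION_LABELS
from .task import TransitionStructure
from .stats import (
    CORRECTED_ALPHA_CONTRASTS,
    bayes_cor_logbf,
    delta_ratios,
    icc_consistency_average,
    ks_normality,
    paired_contrast,
    rank_ancova,
    rm_anova,
    rt_by_transition,
    wilcoxon_signed_rank,
)
from .wm import precision_by_load, wm_trials_from_frame

__all__ = ["RunConfig", "StudyReport", "run_pipeline", "validate_inputs"]

log = logging.getLogger("twostep")

FIT_COLUMNS = [
    "subject", "condition", "beta1", "beta2", "alpha1", "alpha2", "lam",
    "persev", "w", "loglik", "converged",
]


@dataclass(frozen=True)
class RunConfig:
    """Settings for one pipeline run."""

    mode: str = "full"               # simulate | fit | analyze | full
    in_dir: str | Path | None = None
    out_dir: str | Path = "twostep_run"
    seed: int = 0
    cohort: CohortConfig | None = None
    fit: FitConfig = field(default_factory=FitConfig)
    exact_wilcoxon_max_n: int = 20
    chance_correct_precision: bool = False
    effect_size: str = "t_based"     # t_based | z_based (headline convention)
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "fit", "analyze", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.effect_size not in ("t_based", "z_based"):
            raise ValueError("effect_size must be t_based|z_based")

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


@dataclass
class StudyReport:
    """The analysis report: nested dict payload plus provenance."""

    payload: dict

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=2, sort_keys=True,
                          allow_nan=False, default=_scrub) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _scrub(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        v = float(v)
    if isinstance(v, float) and not math.isfinite(v):
        return None
    if isinstance(v, float):
        return v
    raise TypeError(f"unserialisable {type(v)}")


def _clean(obj):
    """Recursively replace NaN with None so json stays strict."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not math.isfinite(f) else f
    return obj


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(directory) -> dict:
    """Schema / label / range / balance checks on a cohort directory.

    Returns ``{"errors": [...], "warnings": [...]}``; schema violations are
    errors, balance problems are warnings (they become fatal in analysis
    stages that need a complete design).
    """
    d = Path(directory)
    errors: list[str] = []
    warnings_: list[str] = []
    try:
        two = _read_checked(d / "twostep.csv", TWOSTEP_COLUMNS)
    except (FileNotFoundError, ValueError) as e:
        return {"errors": [str(e)], "warnings": []}
    try:
        wm = _read_checked(d / "wm.csv", WM_COLUMNS)
    except (FileNotFoundError, ValueError) as e:
        errors.append(str(e))
        wm = None

    valid = two[two["valid"] == 1]
    for col, allowed in (("choice1", {0, 1}), ("choice2", {0, 1}),
                         ("reward", {0, 1})):
        vals = set(pd.to_numeric(valid[col], errors="coerce").dropna().astype(int))
        if not vals <= allowed:
            errors.append(f"twostep.csv: {col} outside {allowed}: {vals - allowed}")
    if not set(valid["state2"].astype(str)) <= {"B", "C"}:
        errors.append("twostep.csv: state2 labels outside {B, C}")
    if wm is not None:
        for col in ("target_deg", "response_deg"):
            v = pd.to_numeric(wm[col], errors="coerce")
            bad = wm.index[(v < 0) | (v >= 180) | v.isna()]
            if len(bad):
                errors.append(
                    f"wm.csv row {int(bad[0]) + 2}: {col} outside [0, 180)"
                )
        if not set(wm["load"].astype(int)) <= {3, 6}:
            errors.append("wm.csv: load values outside {3, 6}")
    # balance: every subject has every condition
    for sid, grp in two.groupby("subject"):
        missing = set(CONDITION_LABELS) - set(grp["condition"])
        for cond in sorted(missing):
            warnings_.append(f"subject {sid} lacks condition {cond}")
    return {"errors": errors, "warnings": warnings_}


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, out: Path) -> Path:
    cohort_cfg = (cfg.cohort or CohortConfig()).replace(master_seed=cfg.seed)
    from .cohort import generate_cohort

    dataset = generate_cohort(cohort_cfg)
    data_dir = out / "data"
    export_cohort(dataset, data_dir)
    log.info("simulated cohort: %d subjects -> %s",
             cohort_cfg.n_subjects, data_dir)
    return data_dir


def _stage_fit(cfg: RunConfig, data_dir: Path, out: Path) -> pd.DataFrame:
    two = _read_checked(Path(data_dir) / "twostep.csv", TWOSTEP_COLUMNS)
    common_prob = (cfg.cohort or CohortConfig()).task.common_prob
    structure = TransitionStructure(common_prob=common_prob)
    import zlib

    rows = []
    for (sid, cond), grp in sorted(
        two.groupby(["subject", "condition"]), key=lambda kv: kv[0]
    ):
        # stable per-session sub-seed (crc32, not hash(): must survive
        # process restarts for reproducible re-runs)
        tag = zlib.crc32(f"{sid}|{cond}".encode())
        sub_seed = int(
            np.random.SeedSequence([cfg.seed, 101, tag]).generate_state(1)[0]
            % (2**31)
        )
        model = HybridModel.from_dataframe(grp, structure)
        res = model.fit(config=cfg.fit, seed=sub_seed)
        rows.append(
            {
                "subject": sid, "condition": cond,
                **{k: round(getattr(res.params, k), 6)
                   for k in ("beta1", "beta2", "alpha1", "alpha2",
                             "lam", "persev", "w")},
                "loglik": round(res.llf, 6),
                "converged": int(res.converged),
            }
        )
    fits = pd.DataFrame(rows)[FIT_COLUMNS]
    fits.to_csv(out / "fits.csv", index=False)
    log.info("fitted %d subject x condition sessions", len(fits))
    return fits


def _precision_table(cfg: RunConfig, wm: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (sid, cond, day), grp in wm.groupby(
        ["subject", "condition", "session_order"]
    ):
        trials = wm_trials_from_frame(grp)
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 301]))
        per_load = precision_by_load(
            trials, chance_correct=cfg.chance_correct_precision, rng=rng
        )
        for load, res in per_load.items():
            rows.append(
                {
                    "subject": sid, "condition": cond, "session_order": day,
                    "load": load, "n_trials": res.n_trials,
                    "circular_sd_rad": res.circular_sd_rad,
                    "precision": res.precision,
                    "log_precision": res.log_precision,
                    "chance_corrected": int(res.chance_corrected),
                }
            )
    return pd.DataFrame(rows)


def _stage_analyze(cfg: RunConfig, data_dir: Path, fits: pd.DataFrame,
                   out: Path) -> StudyReport:
    dataset = load_cohort(data_dir)
    two, wm = dataset.twostep, dataset.wm
    order_map = (
        two[two["condition"] == "control"]
        .groupby("subject")["session_order"].first()
    )
    fits = fits.copy()
    fits["order"] = fits["subject"].map(order_map)
    wide_w = fits.pivot(index="subject", columns="condition", values="w")

    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": cfg.seed,
            "mode": cfg.mode,
            "effect_size_convention": cfg.effect_size,
            "corrected_alpha_contrasts": CORRECTED_ALPHA_CONTRASTS,
            "chance_corrected_precision": cfg.chance_correct_precision,
        }
    }

    # --- goal-directed weight w ------------------------------------------
    w_sec: dict = {}
    w_sec["descriptives"] = {
        cond: {
            "mean": float(wide_w[cond].mean()),
            "median": float(wide_w[cond].median()),
            "sd": float(wide_w[cond].std(ddof=1)),
        }
        for cond in CONDITION_LABELS
    }
    from scipy import stats as sps

    w_sec["control_skewness"] = float(
        sps.skew(wide_w["control"].to_numpy(), bias=False)
    )
    w_sec["normality_control"] = ks_normality(wide_w["control"]).to_dict()
    long_w = fits.rename(columns={"w": "value"})[
        ["subject", "condition", "order", "value"]
    ]
    w_sec["rm_anova_condition"] = rm_anova(
        long_w, dv="value", within="condition", subject="subject"
    ).to_dict()
    w_sec["mixed_anova_condition_by_order"] = rm_anova(
        long_w, dv="value", within="condition", subject="subject", between="order"
    ).to_dict()
    w_sec["contrast_ips_lpfc_vs_control"] = paired_contrast(
        wide_w["IPS_to_LPFC"], wide_w["control"]
    ).to_dict()
    w_sec["contrast_lpfc_ips_vs_control"] = paired_contrast(
        wide_w["LPFC_to_IPS"], wide_w["control"]
    ).to_dict()
    w_sec["wilcoxon_ips_lpfc_vs_control"] = wilcoxon_signed_rank(
        wide_w["IPS_to_LPFC"], wide_w["control"],
        exact_max_n=cfg.exact_wilcoxon_max_n,
    ).to_dict()
    w_sec["rank_ancova_condition"] = rank_ancova(
        long_w, dv="value", within="condition", subject="subject",
        covariate="order",
    ).to_dict()
    w_sec["icc_w_across_sessions"] = icc_consistency_average(
        wide_w[list(CONDITION_LABELS)].to_numpy()
    ).to_dict()
    report["w"] = w_sec

    # --- reaction times ---------------------------------------------------
    report["rt"] = {
        "rare_vs_common": rt_by_transition(two).to_dict(),
    }

    # --- working memory ---------------------------------------------------
    prec = _precision_table(cfg, wm)
    prec.to_csv(out / "precision.csv", index=False)
    wm_sec: dict = {}
    prec_ok = prec.dropna(subset=["log_precision"])
    long_p = prec_ok.rename(columns={"log_precision": "value"})[
        ["subject", "condition", "load", "value"]
    ]
    wm_sec["rm_anova_load_by_condition"] = rm_anova(
        long_p, dv="value", within=["load", "condition"], subject="subject"
    ).to_dict()
    avg_p = prec_ok.groupby(["subject", "condition"])["precision"].mean().unstack()
    wm_sec["icc_precision_across_sessions"] = icc_consistency_average(
        avg_p[list(CONDITION_LABELS)].to_numpy()
    ).to_dict()
    report["wm"] = wm_sec

    # --- relating the two outcomes ---------------------------------------
    ratios = delta_ratios(
        wide_w["control"], wide_w["IPS_to_LPFC"],
        avg_p["control"], avg_p["IPS_to_LPFC"],
    )
    ok = ~ratios.flagged
    rel: dict = {
        "n_flagged_ratios": int(ratios.flagged.sum()),
    }
    if ok.sum() >= 4:
        r, p = sps.pearsonr(ratios.delta_w[ok], ratios.delta_p[ok])
        rel["pearson_dw_dp"] = {"r": float(r), "pvalue": float(p)}
        rel["bayes_dw_dp"] = bayes_cor_logbf(
            ratios.delta_w[ok], ratios.delta_p[ok]
        ).to_dict()
        base_p = avg_p["control"].to_numpy()
        r2, p2 = sps.pearsonr(base_p[ok], ratios.delta_w[ok])
        rel["pearson_baseline_precision_dw"] = {"r": float(r2), "pvalue": float(p2)}
    report["relation"] = rel

    # --- questionnaires (generic correlation stage) -----------------------
    qs = dataset.questionnaires.set_index("subject")
    qsec = {}
    dw_series = pd.Series(ratios.delta_w, index=wide_w.index)
    for col in ("oci_r", "bdi", "stai", "mcq_log10k"):
        joined = pd.concat([qs[col], dw_series.rename("dw")], axis=1).dropna()
        if len(joined) >= 4 and joined[col].std() > 0:
            r, p = sps.pearsonr(joined[col], joined["dw"])
            qsec[col] = {"r": float(r), "pvalue": float(p)}
    report["questionnaires_vs_dw"] = qsec

    # --- recovery diagnostics when ground truth is present ----------------
    if len(dataset.ground_truth):
        gt = dataset.ground_truth.set_index(["subject", "condition"])["w"]
        est = fits.set_index(["subject", "condition"])["w"]
        joined = pd.concat([gt.rename("true"), est.rename("est")], axis=1).dropna()
        if joined["true"].std() > 1e-12:
            report["recovery"] = {
                "pearson_true_vs_fitted_w": float(
                    np.corrcoef(joined["true"], joined["est"])[0, 1]
                ),
                "n": int(len(joined)),
            }
    return StudyReport(payload=_clean(report))


def _human_tables(report: StudyReport) -> str:
    """Plain-text rendering of the headline tests."""
    p = report.payload
    lines = ["Two-step / working-memory study report", "=" * 50]

    def fmt(test: dict, label: str) -> str:
        df = test.get("df")
        dfs = ""
        if isinstance(df, list):
            dfs = f"({df[0]:g}, {df[1]:g})"
        elif df is not None:
            dfs = f"({df:g})"
        pv = test.get("pvalue")
        pvs = f"p = {pv:.4f}" if pv is not None else ""
        return f"{label:<42} stat{dfs} = {test['statistic']:.3f}  {pvs}"

    for label, path in [
        ("w: RM-ANOVA condition", ("w", "rm_anova_condition")),
        ("w: mixed ANOVA condition (order between)",
         ("w", "mixed_anova_condition_by_order")),
        ("w: paired t IPS->LPFC vs control", ("w", "contrast_ips_lpfc_vs_control")),
        ("w: Wilcoxon IPS->LPFC vs control", ("w", "wilcoxon_ips_lpfc_vs_control")),
        ("w: rank ANCOVA", ("w", "rank_ancova_condition")),
        ("w: ICC(3,k) across sessions", ("w", "icc_w_across_sessions")),
        ("RT: rare - common slowing", ("rt", "rare_vs_common")),
        ("WM: load x condition ANOVA", ("wm", "rm_anova_load_by_condition")),
        ("WM: ICC(3,k) precision", ("wm", "icc_precision_across_sessions")),
    ]:
        node = p
        for key in path:
            node = node.get(key, {})
        if node:
            lines.append(fmt(node, label))
    bayes = p.get("relation", {}).get("bayes_dw_dp")
    if bayes:
        lines.append(f"{'dW vs dP: log BF10':<42} {bayes['statistic']:.3f}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> StudyReport | None:
    """Execute the requested stages; returns the report for analysis modes."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.verbosity:
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    try:
        t0 = time.time()
        data_dir = Path(cfg.in_dir) if cfg.in_dir else out / "data"
        if cfg.mode in ("simulate", "full"):
            data_dir = _stage_simulate(cfg, out)
            if cfg.mode == "simulate":
                return None
        fits = None
        if cfg.mode in ("fit", "full"):
            check = validate_inputs(data_dir)
            if check["errors"]:
                raise ValueError(
                    "input validation failed: " + "; ".join(check["errors"])
                )
            fits = _stage_fit(cfg, data_dir, out)
            if cfg.mode == "fit":
                return None
        if fits is None:
            fits_path = (
                out / "fits.csv" if (out / "fits.csv").exists()
                else Path(data_dir) / "fits.csv"
            )
            if not fits_path.exists():
                raise FileNotFoundError(
                    f"analyze mode needs a fitted-parameter table at {fits_path}"
                )
            fits = pd.read_csv(fits_path)
        report = _stage_analyze(cfg, data_dir, fits, out)
        report.write(out / "report.json")
        (out / "tables.txt").write_text(_human_tables(report))
        log.info("pipeline complete in %.1f s", time.time() - t0)
        return report
    finally:
        if cfg.verbosity:
            log.removeHandler(handler)
            handler.close()
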