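"""End-to-end study orchestration.

``run_study`` takes a long-format observation table (simulated from scenario
presets or read from CSV), fits the random-asymptote Gompertz model per
stand, derives the kinetic summary, detects per-tree phenology and seasonal
extrema, runs the age-trend and rate/duration statistics, and writes six
report tables mirroring the shapes such studies publish:

* ``table2.tsv`` — per-stand fixed effects with SEs, df, t values and R^2
* ``table3.tsv`` — per-stand seasonal extrema of each phase (DOY and cells)
* ``table4.tsv`` — per-stand kinetics plus onset/end/duration mean (SD)
* ``table5.tsv`` — age-trend ANOVA lines per characteristic
* ``table6.tsv`` — final-cell-number OLS on rate and duration
* ``importance.tsv`` — LMG shares of rate vs duration

plus ``manifest.json`` recording the seed, configuration and convergence,
so a rerun with the same inputs reproduces every byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import load_scenarios, preset_scenarios
from .gompertz import GompertzParams, kinetic_summary, max_rate, mean_rate
from .growth_stats import age_trend_anova, fit_rate_duration, lmg_importance
from .mixed import StandFit, fit_stand
from .phenology import (
    detect_onset_end,
    find_bimodal_extrema,
    smooth_series,
    stand_phenology,
)
from .simulate import COLUMNS, generate_study

log = logging.getLogger("xylokin")

__all__ = ["StudyConfig", "run_study", "validate_input", "load_observations"]

_COUNT_COLS = ["n_cambial", "n_enlarging", "n_thickening", "n_mature", "n_total"]
_MAX_GAP_DAYS = 21  # 3x the widest routine sampling interval


@dataclass
class StudyConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` (observation CSV) and ``preset``
    (scenario preset name or config file) must be set.
    """

    input_path: str | None = None
    preset: str | None = None
    span: float = 0.25
    min_prominence: float = 0.5
    method: str = "reml"
    rate_def: str = "mean"  # per-tree rate for the decomposition: mean|max
    out_dir: str = "xylokin_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("set exactly one of input_path / preset")
        if self.rate_def not in ("mean", "max"):
            raise ValueError("rate_def must be 'mean' or 'max'")


def validate_input(df: pd.DataFrame) -> list[str]:
    """Check an observation table; returns a list of issues (empty = clean).

    Verifies column presence, DOY range, non-negative integer counts, the
    total-equals-sum invariant, and per-tree sampling gaps no wider than
    three times the widest routine interval.  Reports, never raises.
    """
    issues: list[str] = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        issues.append(f"missing columns: {missing}")
        return issues
    if not df["doy"].between(1, 366).all():
        bad = df.loc[~df["doy"].between(1, 366), "doy"].unique()
        issues.append(f"DOY outside 1..366: {sorted(bad.tolist())}")
    for col in _COUNT_COLS:
        vals = df[col]
        if (vals < 0).any():
            issues.append(f"negative counts in {col}")
        if not np.array_equal(vals, vals.astype(int)):
            issues.append(f"non-integer counts in {col}")
    mismatch = df["n_total"] != df[_COUNT_COLS[:4]].sum(axis=1)
    for _, row in df.loc[mismatch].iterrows():
        issues.append(
            f"tree {row['tree_id']} DOY {row['doy']}: n_total {row['n_total']} "
            f"!= phase sum {int(sum(row[c] for c in _COUNT_COLS[:4]))}"
        )
    for tree, grp in df.groupby("tree_id"):
        gaps = np.diff(np.sort(grp["doy"].unique()))
        if gaps.size and gaps.max() > _MAX_GAP_DAYS:
            issues.append(f"tree {tree}: sampling gap of {int(gaps.max())} days")
    return issues


def load_observations(path: str | Path) -> pd.DataFrame:
    """Read and minimally type-check the long-format observation CSV."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message pass-through
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"{path}: no observation rows")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


# -- per-stand helpers -------------------------------------------------------

_EXTREMA_SPECS = [  # phase column, expected shape
    ("n_cambial", "bimodal"),
    ("n_enlarging", "bimodal"),
    ("n_thickening", "unimodal"),
]
_BIMODAL_KEYS = ["first_max", "first_min", "second_max", "second_min"]
_UNIMODAL_KEYS = ["unimodal_max", "unimodal_min"]


def _stand_extrema_rows(stand_id: str, obs: pd.DataFrame, span: float,
                        min_prominence: float) -> list[dict]:
    rows = []
    for col, shape in _EXTREMA_SPECS:
        keys = _BIMODAL_KEYS if shape == "bimodal" else _UNIMODAL_KEYS
        per_key: dict[str, list[tuple[float, float]]] = {k: [] for k in keys}
        for _, grp in obs.groupby("tree_id"):
            ser = grp.set_index("doy")[col].sort_index()
            ext = find_bimodal_extrema(
                smooth_series(ser, span=span), min_prominence=min_prominence,
                phase=col)
            for k in keys:
                val = getattr(ext, k)
                if val is None and k in ("first_max", "first_min") and not ext.is_bimodal:
                    # a unimodal trajectory still contributes its single peak
                    val = getattr(ext, "unimodal_max" if k == "first_max"
                                  else "unimodal_min")
                if val is not None:
                    per_key[k].append(val)
        for k in keys:
            pts = per_key[k]
            if not pts:
                continue
            doys = np.array([p[0] for p in pts])
            cells = np.array([p[1] for p in pts])
            sd = (lambda v: float(np.std(v, ddof=1)) if v.size > 1 else 0.0)
            rows.append({
                "stand_id": stand_id, "phase": col, "extremum": k,
                "n_trees": len(pts),
                "doy_mean": float(doys.mean()), "doy_sd": sd(doys),
                "cells_mean": float(cells.mean()), "cells_sd": sd(cells),
            })
    return rows


def _tree_level_frame(stand_id: str, obs: pd.DataFrame, fit: StandFit,
                      rate_def: str) -> pd.DataFrame:
    """Per-tree characteristics feeding the study-wide statistics."""
    rows = []
    t_p = fit.fixed.beta / fit.fixed.k
    for tree, grp in obs.groupby("tree_id"):
        rec = detect_onset_end(grp[["doy", "n_enlarging"]], tree_id=str(tree))
        a_i = fit.fixed.A + fit.tree_effects.get(tree, 0.0)
        r_max_i = max_rate(GompertzParams(A=max(a_i, 1e-9),
                                          beta=fit.fixed.beta, k=fit.fixed.k))
        r_m_i = mean_rate(r_max=r_max_i)
        rows.append({
            "tree_id": tree,
            "stand_id": stand_id,
            "planting_year": int(grp["planting_year"].iloc[0]),
            "n_cells": int(grp["n_total"].max()),
            "onset": rec.onset_doy,
            "end": rec.end_doy,
            "duration": rec.duration_days,
            "t_p": t_p,
            "r_max": r_max_i,
            "r_m": r_m_i,
            "rate": r_max_i if rate_def == "max" else r_m_i,
        })
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_study(config: StudyConfig) -> dict:
    """Run the full analysis; returns the report bundle as dataframes.

    Writes the six TSV reports and ``manifest.json`` to ``config.out_dir``.
    Deterministic given (input, config, seed).
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.input_path is not None:
        df = load_observations(config.input_path)
    else:
        preset = config.preset
        scenarios = (load_scenarios(preset) if Path(str(preset)).is_file()
                     else preset_scenarios(str(preset)))
        df = generate_study(scenarios, seed=config.seed)
    issues = validate_input(df)
    for issue in issues:
        log.warning("input issue: %s", issue)

    stands = list(dict.fromkeys(df["stand_id"]))
    ages = {s: int(df.loc[df["stand_id"] == s, "planting_year"].iloc[0])
            for s in stands}
    log.info("loaded %d observations, %d stands, %d trees",
             len(df), len(stands), df["tree_id"].nunique())

    t2_rows, t3_rows, t4_rows = [], [], []
    tree_frames = []
    convergence = {}
    for stand in stands:
        obs = df[df["stand_id"] == stand]
        fit = fit_stand(obs, response="total", method=config.method)
        convergence[stand] = fit.converged
        kin = kinetic_summary(fit.fixed)
        for pname, est in (("A", fit.fixed.A), ("beta", fit.fixed.beta),
                           ("k", fit.fixed.k)):
            t2_rows.append({
                "stand_id": stand, "parameter": pname, "estimate": est,
                "std_error": fit.std_errors.get(pname, float("nan")),
                "df": fit.df, "t_value": fit.t_values.get(pname, float("nan")),
                "r_squared": round(fit.r_squared, 6) if pname == "A" else "",
                "sigma_A": round(fit.sigma_A, 6) if pname == "A" else "",
                "sigma_e": round(fit.sigma_e, 6) if pname == "A" else "",
            })
        t3_rows.extend(_stand_extrema_rows(stand, obs, config.span,
                                           config.min_prominence))
        records = [detect_onset_end(g[["doy", "n_enlarging"]], tree_id=str(t))
                   for t, g in obs.groupby("tree_id")]
        pheno = stand_phenology(records)
        t4_rows.append({
            "stand_id": stand, "planting_year": ages[stand],
            "sample_size": fit.n_obs,
            "t_p": kin.t_p, "r_max": kin.r_max, "r_m": kin.r_m,
            "onset_mean": pheno.onset_mean, "onset_sd": pheno.onset_sd,
            "end_mean": pheno.end_mean, "end_sd": pheno.end_sd,
            "duration_mean": pheno.duration_mean,
            "duration_sd": pheno.duration_sd,
        })
        tree_frames.append(_tree_level_frame(stand, obs, fit, config.rate_def))
        log.info("stand %s: n=%d trees=%d converged=%s R2=%.3f",
                 stand, fit.n_obs, obs["tree_id"].nunique(), fit.converged,
                 fit.r_squared)

    trees = pd.concat(tree_frames, ignore_index=True)
    trees["age"] = 2019 - trees["planting_year"]
    live = trees.dropna(subset=["onset"])

    t5_rows = []
    for term, col in [("Number", "n_cells"), ("Onset", "onset"),
                      ("End", "end"), ("Duration", "duration"),
                      ("t-p", "t_p"), ("r-max", "r_max"), ("r-m", "r_m")]:
        try:
            res = age_trend_anova(live.set_index("tree_id")[col],
                                  live.set_index("tree_id")["age"], term=term)
            t5_rows.append({"term": term, "df": res.df, "sum_sq": res.sum_sq,
                            "mean_sq": res.mean_sq, "f_value": res.f_value,
                            "p_value": res.p_value})
        except ValueError as exc:
            log.warning("ANOVA for %s skipped: %s", term, exc)

    stats_notes = []
    t6_cols = ["term", "value", "t_value", "p_value"]
    try:
        rd = fit_rate_duration(live["n_cells"], live["rate"], live["duration"])
        t6 = pd.DataFrame([
            {"term": name, "value": val,
             "t_value": rd.t_values[name], "p_value": rd.p_values[name]}
            for name, val in (("intercept", rd.alpha0), ("rate", rd.alpha1),
                              ("duration", rd.alpha2))
        ], columns=t6_cols)
    except ValueError as exc:
        log.warning("rate+duration regression skipped: %s", exc)
        stats_notes.append(f"rate+duration regression skipped: {exc}")
        t6 = pd.DataFrame(columns=t6_cols)

    imp_cols = ["predictor", "lmg_share", "percent_of_r_squared"]
    total_r2 = None
    try:
        imp = lmg_importance(live["n_cells"].to_numpy(float),
                             {"rate": live["rate"].to_numpy(float),
                              "duration": live["duration"].to_numpy(float)})
        shares = imp.normalize().contributions
        total_r2 = imp.total_r_squared
        importance = pd.DataFrame([
            {"predictor": name, "lmg_share": imp.contributions[name],
             "percent_of_r_squared": 100.0 * shares[name]}
            for name in ("rate", "duration")
        ], columns=imp_cols)
    except ValueError as exc:
        log.warning("relative importance skipped: %s", exc)
        stats_notes.append(f"relative importance skipped: {exc}")
        importance = pd.DataFrame(columns=imp_cols)

    bundle = {
        "table2": pd.DataFrame(t2_rows),
        "table3": pd.DataFrame(t3_rows),
        "table4": pd.DataFrame(t4_rows),
        "table5": pd.DataFrame(t5_rows),
        "table6": t6,
        "importance": importance,
        "trees": trees,
    }
    for name in ("table2", "table3", "table4", "table5", "table6", "importance"):
        _write_tsv(bundle[name], out / f"{name}.tsv")

    manifest = {
        "package": "xylokin",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_observations": int(len(df)),
        "n_stands": len(stands),
        "n_trees": int(df["tree_id"].nunique()),
        "input_issues": issues,
        "converged": convergence,
        "rate_definition": config.rate_def,
        "full_model_r_squared": total_r2,
        "stats_notes": stats_notes,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    bundle["manifest"] = manifest
    return bundle
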