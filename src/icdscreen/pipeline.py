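"""End-to-end analysis pipeline over a respondent-level cohort table.

Runs the three-stage validation analysis on a cohort (real or synthetic):
(1) item distributions, descriptives, reliability and group comparisons;
(2) 1PL/2PL normal-ogive IRT on the binary endorsement recodes with a
likelihood-ratio model comparison, approximate fit indices and information
curves; (3) diagnostic prevalence with Wilson intervals, co-occurrence and
comparator (PHQ-9/GAD-7) cross-tabulations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import instruments as ins
from . import irt
from . import reliability as rel

logger = logging.getLogger("icdscreen")

__all__ = ["AnalysisReport", "read_cohort", "run_full_analysis", "write_report",
           "diagnose_cohort", "scale_columns", "COHORT_COLUMNS"]

COHORT_COLUMNS = (
    ["respondent_id"]
    + [f"idq{i}" for i in range(1, 10)]
    + [f"iaq{i}" for i in range(1, 9)]
    + ["idq_impair", "iaq_impair"]
    + [f"phq{i}" for i in range(1, 10)]
    + [f"gad{i}" for i in range(1, 8)]
    + ["sex", "age", "treatment_status"]
)

_RANGES = {"idq": (0, 4), "iaq": (0, 4), "phq": (0, 3), "gad": (0, 3)}


def scale_columns(prefix: str) -> list[str]:
    n = {"idq": 9, "iaq": 8, "phq": 9, "gad": 7}[prefix]
    return [f"{prefix}{i}" for i in range(1, n + 1)]


@dataclass
class AnalysisReport:
    n_respondents: int
    item_table: pd.DataFrame
    scale_descriptives: dict
    irt_table: Optional[pd.DataFrame]
    model_comparison: Optional[dict]
    fit_summary: Optional[dict]
    reliability: dict
    prevalence: dict
    associations: dict
    curves: Optional[pd.DataFrame] = None
    irt_skipped_reason: Optional[str] = None


def read_cohort(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Unknown columns raise; out-of-range item values are set to missing (the
    respondent then drops out of that scale's analyses under the
    complete-case policy) and counted in the log.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path} contains no rows")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown and strict:
        raise ValueError(f"unknown columns in {path.name}: {unknown}")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns in {path.name}: {missing}")
    if df["respondent_id"].duplicated().any():
        raise ValueError("duplicated respondent_id values")
    n_invalid = 0
    for prefix, (lo, hi) in _RANGES.items():
        for c in scale_columns(prefix):
            vals = pd.to_numeric(df[c], errors="coerce")
            bad = vals.notna() & ((vals < lo) | (vals > hi) | (vals % 1 != 0))
            n_invalid += int(bad.sum())
            df[c] = vals.mask(bad)
    for c in ("idq_impair", "iaq_impair"):
        ok = df[c].isin(["yes", "no"])
        n_invalid += int((~ok & df[c].notna()).sum())
        df[c] = df[c].where(ok)
    if n_invalid:
        logger.warning("%d out-of-range values set to missing", n_invalid)
    logger.info("read %d respondents from %s", len(df), path)
    return df


def _complete(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
    cols = scale_columns(prefix)
    sub = df.dropna(subset=cols)
    dropped = len(df) - len(sub)
    if dropped:
        logger.info("%s: %d respondents excluded (incomplete items)", prefix, dropped)
    return sub


def diagnose_cohort(df: pd.DataFrame, which: str) -> pd.Series:
    """Per-respondent caseness (True/False, NaN where undetermined or
    incomplete) under the instrument's diagnostic algorithm."""
    spec = ins.load_instrument(which)
    cols = scale_columns(which)
    out = pd.Series(np.nan, index=df.index, dtype=object)
    complete = df.dropna(subset=cols)
    for idx, row in complete.iterrows():
        imp = row[f"{which}_impair"]
        imp_val = None if pd.isna(imp) else (imp == "yes")
        rv = ins.ResponseVector(tuple(int(row[c]) for c in cols), imp_val)
        out.loc[idx] = ins.diagnose(rv, spec).case
    return out


def _item_table(df: pd.DataFrame, which: str) -> pd.DataFrame:
    spec = ins.load_instrument(which)
    cols = scale_columns(which)
    sub = _complete(df, which)
    x = sub[cols].to_numpy(dtype=float)
    it = rel.item_total_correlations(x)
    rows = []
    for j, c in enumerate(cols):
        v = x[:, j]
        cat_pct = [100.0 * np.mean(v == k) for k in range(5)]
        rows.append({
            "scale": spec.name, "item": j + 1, "text": spec.item_texts[j],
            **{f"pct_{k}": cat_pct[k] for k in range(5)},
            "pct_endorsed": 100.0 * np.mean(v >= spec.endorsement_threshold),
            "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
            "item_total_r": float(it["total"][j]),
            "item_rest_r": float(it["rest"][j]),
        })
    return pd.DataFrame(rows)


def _fit_scale_irt(df: pd.DataFrame, which: str, quadrature: int, seed: int):
    spec = ins.load_instrument(which)
    cols = scale_columns(which)
    sub = _complete(df, which)
    if len(sub) < 100:
        return None, None, None, None, "fewer than 100 complete cases"
    binary = (sub[cols].to_numpy(dtype=float) >= spec.endorsement_threshold).astype(int)
    if np.any(binary.mean(axis=0) == 0) or np.any(binary.mean(axis=0) == 1):
        return None, None, None, None, "zero-variance binary items"
    fit2 = irt.fit_2pl(binary, quadrature=quadrature, seed=seed)
    fit1 = irt.fit_1pl(binary, quadrature=quadrature, seed=seed)
    chi2, dfd, p = irt.lr_test(fit1, fit2)
    tet = irt.tetrachoric_matrix(binary)
    lam = fit2.loadings
    implied = np.outer(lam, lam)
    np.fill_diagonal(implied, 1.0)
    fi2 = irt.fit_indices(tet, implied, n=len(sub), df=irt.model_df(len(cols), "2PL"))
    lam1 = fit1.loadings
    implied1 = np.outer(lam1, lam1)
    np.fill_diagonal(implied1, 1.0)
    fi1 = irt.fit_indices(tet, implied1, n=len(sub), df=irt.model_df(len(cols), "1PL"))
    return fit1, fit2, (chi2, dfd, p), (fi1, fi2), None


def run_full_analysis(
    cohort: pd.DataFrame,
    quadrature: int = 61,
    seed: int = 0,
    conf_level: float = 0.95,
    theta_grid: Optional[np.ndarray] = None,
) -> AnalysisReport:
    """Run the full validation analysis and return a structured report."""
    df = cohort.copy()
    if df.empty:
        raise ValueError("cohort is empty")
    n_total = len(df)

    item_table = pd.concat(
        [_item_table(df, "idq"), _item_table(df, "iaq")], ignore_index=True)

    # scale scores (complete cases per scale)
    scores, descr, alpha = {}, {}, {}
    for which in ("idq", "iaq", "phq", "gad"):
        sub = _complete(df, which)
        s = sub[scale_columns(which)].sum(axis=1)
        scores[which] = s
        arr = s.to_numpy(dtype=float)
        if arr.size >= 3 and arr.std() > 0:
            d = rel.describe(arr)
            descr[which] = {"n": d.n, "mean": d.mean, "sd": d.sd,
                            "skewness": d.skewness, "skewness_se": d.skewness_se,
                            "min": d.min, "max": d.max}
        else:   # constant or tiny score vector: skewness undefined
            descr[which] = {"n": int(arr.size), "mean": float(arr.mean()),
                            "sd": float(arr.std(ddof=1)) if arr.size > 1 else None,
                            "skewness": None, "skewness_se": None,
                            "min": float(arr.min()), "max": float(arr.max())}
        try:
            alpha[which] = rel.cronbach_alpha(sub[scale_columns(which)].to_numpy())
        except ValueError:
            alpha[which] = None

    # IRT
    irt_rows, model_comparison, fit_summary, curves = [], {}, {}, []
    skipped = []
    for which in ("idq", "iaq"):
        fit1, fit2, lr, fis, reason = _fit_scale_irt(df, which, quadrature, seed)
        if reason is not None:
            skipped.append(f"{which}: {reason}")
            logger.warning("IRT skipped for %s: %s", which, reason)
            continue
        name = ins.load_instrument(which).name
        for j, p2 in enumerate(fit2.params):
            irt_rows.append({"scale": name, "item": j + 1,
                             "a": p2.a, "se_a": p2.se_a, "b": p2.b, "se_b": p2.se_b,
                             "a_1pl": fit1.params[j].a, "b_1pl": fit1.params[j].b})
        model_comparison[which] = {
            "loglik_1pl": fit1.loglik, "loglik_2pl": fit2.loglik,
            "chi2": lr[0], "df": lr[1], "p": lr[2],
            "preferred": "2PL" if lr[2] < 0.05 else "1PL",
        }
        fi1, fi2 = fis
        fit_summary[which] = {
            "1PL": fi1.__dict__, "2PL": fi2.__dict__,
            "converged_1pl": fit1.converged, "converged_2pl": fit2.converged,
        }
        grid = theta_grid if theta_grid is not None else np.linspace(-4, 4, 161)
        cur = irt.information_curves(fit2.params, grid)
        cd = pd.DataFrame({"scale": name, "theta": cur["theta"],
                           "total_info": cur["total_info"]})
        for j in range(len(fit2.params)):
            cd[f"icc_{j+1}"] = cur["icc"][j]
            cd[f"info_{j+1}"] = cur["item_info"][j]
        curves.append(cd)

    # reliability: omega from the 2PL loadings, alpha on raw items
    reliability = {}
    for which in ("idq", "iaq"):
        omega = None
        if which in model_comparison:
            name = ins.load_instrument(which).name
            lam = irt.loading_from_discrimination(
                np.array([r["a"] for r in irt_rows if r["scale"] == name]))
            omega = rel.omega_from_loadings(lam)
        reliability[which] = {"omega": omega, "alpha": alpha[which]}
    reliability["phq"] = {"alpha": alpha["phq"]}
    reliability["gad"] = {"alpha": alpha["gad"]}

    # prevalence + associations
    case_d = diagnose_cohort(df, "idq")
    case_a = diagnose_cohort(df, "iaq")
    det = case_d.isin([True, False]) & case_a.isin([True, False])
    cd_, ca_ = case_d[det].astype(bool), case_a[det].astype(bool)
    n_det = int(det.sum())
    prevalence = {}
    for label, mask in (
        ("depressive_episode", cd_), ("gad", ca_),
        ("either", cd_ | ca_), ("both", cd_ & ca_),
        ("depression_only", cd_ & ~ca_), ("anxiety_only", ~cd_ & ca_),
    ):
        pr = ins.prevalence_with_ci(int(mask.sum()), n_det, conf_level)
        prevalence[label] = {"n_cases": pr.n_cases, "n_total": pr.n_total,
                             "proportion": pr.proportion,
                             "ci_low": pr.ci_low, "ci_high": pr.ci_high}
    prevalence["n_undetermined"] = int(len(df) - n_det)

    associations = {}
    tab = pd.crosstab(cd_, ca_)
    if tab.shape == (2, 2):
        res = rel.chi_square_association(tab.to_numpy())
        associations["idq_iaq"] = {
            "chi2": res.statistic, "df": res.df[0], "p": res.p,
            "pct_dep_also_anx": 100.0 * float((cd_ & ca_).sum() / max(cd_.sum(), 1)),
            "pct_anx_also_dep": 100.0 * float((cd_ & ca_).sum() / max(ca_.sum(), 1)),
        }
    # comparator caseness
    for which, comp, cases in (("idq", "phq", cd_), ("iaq", "gad", ca_)):
        comp_scores = scores[comp].reindex(cases.index).dropna()
        common = cases.index.intersection(comp_scores.index)
        comp_case = comp_scores.loc[common] >= 10
        pr = ins.prevalence_with_ci(int(comp_case.sum()), len(common), conf_level)
        entry = {"prevalence": pr.proportion, "ci_low": pr.ci_low,
                 "ci_high": pr.ci_high}
        tabc = pd.crosstab(cases.loc[common], comp_case)
        if tabc.shape == (2, 2):
            res = rel.chi_square_association(tabc.to_numpy())
            entry.update({
                "chi2": res.statistic, "df": res.df[0], "p": res.p,
                "pct_comparator_cases_also_instrument": 100.0 * float(
                    (cases.loc[common] & comp_case).sum() / max(comp_case.sum(), 1)),
            })
        both_idx = scores[which].index.intersection(comp_scores.index)
        try:
            r, pv = rel.pearson_r(scores[which].loc[both_idx],
                                  comp_scores.loc[both_idx])
            entry["pearson_r"] = r
            entry["pearson_p"] = pv
        except ValueError:
            logger.warning("%s-%s correlation undefined (zero variance)",
                           which, comp)
        associations[f"{which}_{comp}"] = entry

    # sex / age / treatment
    for which, cases, sc in (("idq", cd_, scores["idq"]), ("iaq", ca_, scores["iaq"])):
        sex = df.loc[cases.index, "sex"]
        tab = pd.crosstab(sex, cases)
        if tab.shape == (2, 2):
            res = rel.chi_square_association(tab.to_numpy())
            associations[f"{which}_sex"] = {"chi2": res.statistic, "df": res.df[0],
                                            "p": res.p}
        age = df.loc[cases.index, "age"].astype(float)
        if cases.nunique() == 2 and cases.value_counts().min() >= 2:
            tt = rel.two_group_t(age.to_numpy(), cases.to_numpy())
            associations[f"{which}_age_case"] = {
                "t": tt.statistic, "df": tt.df[0], "p": tt.p, "d": tt.effect_size}
        sc_idx = sc.index
        try:
            r_age, p_age = rel.pearson_r(df.loc[sc_idx, "age"].astype(float), sc)
            associations[f"{which}_age_score_r"] = {"r": r_age, "p": p_age}
        except ValueError:
            logger.warning("%s age-score correlation undefined", which)
        trt = df.loc[sc_idx, "treatment_status"]
        valid = trt.isin(["never", "past", "current", "waiting"])
        if valid.sum() > 8 and trt[valid].nunique() >= 2:
            an = rel.oneway_anova(sc[valid].to_numpy(), trt[valid].to_numpy())
            associations[f"{which}_treatment_anova"] = {
                "F": an.statistic, "df": list(an.df), "p": an.p,
                "eta_squared": an.effect_size}
        sexsc = df.loc[sc_idx, "sex"]
        if sexsc.isin(["male", "female"]).all() and sexsc.nunique() == 2:
            tt = rel.two_group_t(sc.to_numpy(), sexsc.to_numpy())
            associations[f"{which}_sex_score_t"] = {
                "t": tt.statistic, "df": tt.df[0], "p": tt.p, "d": tt.effect_size}

    return AnalysisReport(
        n_respondents=n_total,
        item_table=item_table,
        scale_descriptives=descr,
        irt_table=pd.DataFrame(irt_rows) if irt_rows else None,
        model_comparison=model_comparison or None,
        fit_summary=fit_summary or None,
        reliability=reliability,
        prevalence=prevalence,
        associations=associations,
        curves=pd.concat(curves, ignore_index=True) if curves else None,
        irt_skipped_reason="; ".join(skipped) if skipped else None,
    )


def _round_df(df: pd.DataFrame, spec: dict[str, int]) -> pd.DataFrame:
    out = df.copy()
    for pat, nd in spec.items():
        for c in out.columns:
            if c.startswith(pat):
                out[c] = out[c].astype(float).round(nd)
    return out


def write_report(report: AnalysisReport, out_dir) -> list[Path]:
    """Write the report as JSON plus CSV tables; deterministic bytes for a
    fixed report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    payload = {
        "n_respondents": report.n_respondents,
        "scale_descriptives": report.scale_descriptives,
        "model_comparison": report.model_comparison,
        "fit_summary": report.fit_summary,
        "reliability": report.reliability,
        "prevalence": report.prevalence,
        "associations": report.associations,
        "irt_skipped_reason": report.irt_skipped_reason,
    }
    p = out / "report.json"
    p.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n")
    written.append(p)

    item = _round_df(report.item_table,
                     {"pct": 1, "mean": 2, "sd": 2, "item_": 2})
    p = out / "item_table.csv"
    item.to_csv(p, index=False)
    written.append(p)

    p = out / "irt_table.csv"
    if report.irt_table is not None:
        _round_df(report.irt_table, {"a": 3, "b": 3, "se": 3}).to_csv(p, index=False)
    else:
        p.write_text("skipped: " + (report.irt_skipped_reason or "unknown") + "\n")
    written.append(p)

    if report.curves is not None:
        p = out / "curves.csv"
        report.curves.round(6).to_csv(p, index=False)
        written.append(p)
    return written
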