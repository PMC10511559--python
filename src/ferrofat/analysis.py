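"""Orchestration: diagnostic flags per patient and the full cohort report.

``run_full_analysis`` walks the study's analysis chain in order —
regional comparison, demographic correlations, pancreatic iron vs fat,
HCV groups, regression for FF determinants, glucose metabolism, other
organs, cardiac function/fibrosis, cardiac complications — and returns a
machine-readable report.  Every stage is wrapped: a failing or
under-specified stage yields a ``not_computed`` block with a reason and
the rest of the report stays intact.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from .clinical_rules import GlucoseClass, classify_glucose, GlucoseThresholds, homa_ir
from .config import AnalysisConfig, default_config

__all__ = ["derive_flags", "run_full_analysis"]

log = logging.getLogger("ferrofat")

_ABNORMAL = ("IFG", "IGT", "DM")

_TRUE_TOKENS = {True, "True", "true", "1", 1, 1.0}
_FALSE_TOKENS = {False, "False", "false", "0", 0, 0.0, ""}


def _bool_series(s: pd.Series, default=None) -> pd.Series:
    """Coerce a bool-like column (bools or their CSV string forms)."""
    if s.dtype == bool:
        return s

    def conv(v):
        if isinstance(v, (bool,)):
            return v
        if pd.isna(v):
            return default
        if v in _TRUE_TOKENS:
            return True
        if v in _FALSE_TOKENS:
            return False
        return default

    return s.map(conv)


def derive_flags(df: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-patient diagnostic flags from a cohort table.

    Adds glucose class (recomputed from FPG/2h/known-diabetes when those
    columns exist, else taken from a provided ``glucose_class`` column),
    the organ iron/fat flags, and the cardiac-complication flag.
    """
    cfg = (config or default_config()).thresholds
    out = pd.DataFrame({"id": df["id"]})

    thr = GlucoseThresholds(
        fpg_ifg=cfg.fpg_ifg_mg_dl,
        fpg_dm=cfg.fpg_dm_mg_dl,
        g2h_igt=cfg.glucose2h_igt_mg_dl,
        g2h_dm=cfg.glucose2h_dm_mg_dl,
    )
    if "fpg_mg_dl" in df.columns:
        classes = []
        for _, row in df.iterrows():
            fpg = row.get("fpg_mg_dl")
            if fpg is None or (isinstance(fpg, float) and np.isnan(fpg)):
                classes.append(GlucoseClass.UNKNOWN.value)
                continue
            g2h = row.get("glucose_2h_mg_dl")
            if isinstance(g2h, float) and np.isnan(g2h):
                g2h = None
            known = row.get("known_diabetes", False)
            if known is None or (isinstance(known, float) and np.isnan(known)):
                known = False
            known = known in _TRUE_TOKENS
            classes.append(classify_glucose(fpg, g2h, known, thresholds=thr).value)
        out["glucose_class"] = classes
    elif "glucose_class" in df.columns:
        out["glucose_class"] = df["glucose_class"]

    if "pancreas_global_t2s_ms" in df.columns:
        out["pancreatic_iron_overload"] = df["pancreas_global_t2s_ms"] < cfg.pancreas_t2s_normal_ms
    if "pancreas_global_ff_pct" in df.columns:
        out["pancreatic_fatty_replacement"] = df["pancreas_global_ff_pct"] > cfg.ff_upper_limit_pct
    if "lic_mg_g_dw" in df.columns:
        out["significant_hepatic_iron"] = df["lic_mg_g_dw"] >= cfg.lic_significant_mg_g
    if "heart_global_t2s_ms" in df.columns:
        out["significant_mio"] = df["heart_global_t2s_ms"] <= cfg.heart_t2s_normal_ms

    hf = (
        _bool_series(df["heart_failure"], default=False).to_numpy(bool)
        if "heart_failure" in df.columns
        else np.zeros(len(df), bool)
    )
    arr = (
        _bool_series(df["arrhythmia"], default=False).to_numpy(bool)
        if "arrhythmia" in df.columns
        else np.zeros(len(df), bool)
    )
    if "jet_velocity_m_s" in df.columns:
        ph = pd.to_numeric(df["jet_velocity_m_s"], errors="coerce") > cfg.jet_velocity_ph_m_s
        out["cardiac_complication"] = hf | arr | ph.to_numpy(bool)
    elif "heart_failure" in df.columns or "arrhythmia" in df.columns:
        out["cardiac_complication"] = hf | arr
    return out


def _block(fn):
    """Run one report stage; convert failures into a not_computed block."""
    try:
        return fn()
    except Exception as exc:  # graceful degradation, never partial crashes
        log.warning("stage %s not computed: %s", fn.__name__, exc)
        return {"status": "not_computed", "reason": str(exc)}


def _median(x) -> float:
    x = pd.to_numeric(pd.Series(x), errors="coerce").dropna()
    return float(x.median()) if len(x) else float("nan")


def run_full_analysis(
    df: pd.DataFrame,
    config: AnalysisConfig | None = None,
    healthy: pd.DataFrame | None = None,
    seed: int | None = None,
) -> dict:
    """The full cohort report: nine analysis blocks plus provenance.

    Parameters
    ----------
    df
        Cohort table following the versioned column dictionary.
    config
        Effective configuration (defaults when omitted); its hash is
        recorded in the report.
    healthy
        Optional healthy-control table used to derive the normative FF
        limit; when omitted the configured limit is used directly.
    """
    cfg = config or default_config()
    thr = cfg.thresholds
    flags = derive_flags(df, cfg)
    ff = pd.to_numeric(df["pancreas_global_ff_pct"], errors="coerce")
    t2s = pd.to_numeric(df["pancreas_global_t2s_ms"], errors="coerce")

    ff_limit = thr.ff_upper_limit_pct
    normative = None
    if healthy is not None and "pancreas_global_ff_pct" in healthy.columns:
        normative = cs.derive_normative_limit(
            healthy["pancreas_global_ff_pct"].to_numpy(float),
            epsilon=cfg.stats.normative_epsilon_pct,
        )
    fatty = ff > ff_limit
    abnormal_glucose = flags["glucose_class"].isin(_ABNORMAL) if "glucose_class" in flags else None

    report: dict = {
        "meta": {
            "n_patients": int(len(df)),
            "config_sha256": cfg.sha256(),
            "seed": seed,
            "schema_version": "1.0",
            "ff_upper_limit_pct": ff_limit,
        }
    }
    if normative is not None:
        report["normative_limit"] = normative
    log.info("analysis start: %d patients, config %s", len(df), cfg.sha256()[:12])

    def regional_comparison():
        cols = [f"pancreas_{r}_ff_pct" for r in ("head", "body", "tail")]
        head, body, tail = (pd.to_numeric(df[c], errors="coerce") for c in cols)
        rep = cs.friedman_repeated(head, body, tail)
        return {
            "median_ff_pct": {"head": _median(head), "body": _median(body), "tail": _median(tail)},
            "friedman": rep,
        }

    def demographics():
        out = {
            "ff_vs_age": cs.spearman(ff, df["age_yr"]),
            "ff_vs_bmi": cs.spearman(ff, df["bmi_kg_m2"]),
        }
        if "sex" in df.columns:
            out["ff_by_sex"] = cs.compare_groups(
                {"M": ff[df["sex"] == "M"], "F": ff[df["sex"] == "F"]}
            )
        if "splenectomy" in df.columns:
            sp = _bool_series(df["splenectomy"], default=False).astype(bool)
            out["ff_by_splenectomy"] = cs.compare_groups(
                {"splenectomy": ff[sp], "spleen": ff[~sp]}
            )
        if "metabolic_syndrome" in df.columns:
            ms = _bool_series(df["metabolic_syndrome"])
            out["ff_by_metabolic_syndrome"] = cs.compare_groups(
                {"mets": ff[ms == True], "no_mets": ff[ms == False]}  # noqa: E712
            )
        return out

    def iron_and_fat():
        overload = t2s < thr.pancreas_t2s_normal_ms
        return {
            "ff_vs_pancreas_t2s": cs.spearman(ff, t2s),
            "ff_by_pancreatic_iron": cs.compare_groups(
                {"iron_overload": ff[overload], "normal_t2s": ff[~overload]}
            ),
            "fatty_replacement_prevalence_pct": float(100.0 * fatty.mean()),
            "pancreatic_iron_prevalence_pct": float(100.0 * overload.mean()),
            "roc_t2s_predicts_fatty_replacement": cs.roc_with_youden(
                t2s.to_numpy(float), fatty.to_numpy(bool), direction="less"
            ),
        }

    def hcv_groups():
        status = df["hcv_status"]
        groups = {s: ff[status == s] for s in ("negative", "eradicated", "chronic")}
        dm = flags["glucose_class"] == "DM"
        table = [
            [int((dm & (status == s)).sum()), int((~dm & (status == s)).sum())]
            for s in ("negative", "eradicated", "chronic")
        ]
        return {
            "ff_by_hcv_group": cs.compare_groups(groups),
            "diabetes_by_hcv_group": cs.chi_square(table),
        }

    def regression():
        data = pd.DataFrame(
            {
                "pancreas_global_ff_pct": ff,
                "female_sex": (df["sex"] == "F").astype(float),
                "age_yr": pd.to_numeric(df["age_yr"], errors="coerce"),
                "bmi_kg_m2": pd.to_numeric(df["bmi_kg_m2"], errors="coerce"),
                "metabolic_syndrome": pd.to_numeric(
                    _bool_series(df["metabolic_syndrome"]).map({True: 1.0, False: 0.0}),
                    errors="coerce",
                ),
                "splenectomy": _bool_series(df["splenectomy"], default=False).astype(float),
                "hcv_exposed": (df["hcv_status"] != "negative").astype(float),
                "ferritin_ng_ml": pd.to_numeric(df["ferritin_ng_ml"], errors="coerce"),
                "lic_mg_g_dw": pd.to_numeric(df["lic_mg_g_dw"], errors="coerce"),
                "pancreas_global_t2s_ms": t2s,
            }
        )
        candidates = [c for c in data.columns if c != "pancreas_global_ff_pct"]
        result = cs.stepwise_multivariate(
            data,
            outcome="pancreas_global_ff_pct",
            candidates=candidates,
            entry_p=cfg.stats.stepwise_entry_p,
            removal_p=cfg.stats.stepwise_removal_p,
            vif_max=cfg.stats.vif_max,
            tolerance_min=cfg.stats.tolerance_min,
        )
        return {"summary": result.summary(), "table": result.table(), "model_f": result.model_f,
                "model_p": result.model_p, "retained": result.retained}

    def glucose():
        gc = flags["glucose_class"]
        groups = {k: ff[gc == k] for k in ("NGT", "IFG", "IGT", "DM")}
        abnormal = abnormal_glucose.to_numpy(bool)
        known = gc.isin(("NGT", "IFG", "IGT", "DM")).to_numpy(bool)
        roc_ff = cs.roc_with_youden(ff.to_numpy(float)[known], abnormal[known], direction="greater")
        roc_t2s = cs.roc_with_youden(t2s.to_numpy(float)[known], abnormal[known], direction="less")
        # DeLong on a common "higher = more at risk" scale: FF vs -T2*
        delta, p = cs.delong_compare(
            ff.to_numpy(float)[known], -t2s.to_numpy(float)[known], abnormal[known]
        )
        out = {
            "median_ff_by_class": {k: _median(v) for k, v in groups.items()},
            "ff_by_glucose_class": cs.compare_groups(groups),
            "roc_ff_predicts_abnormal_glucose": roc_ff,
            "roc_t2s_predicts_abnormal_glucose": roc_t2s,
            "delong_ff_vs_t2s": {"delta_auc": delta, "p_value": p},
            "npv_normal_ff_for_abnormal_glucose": cs.predictive_values(
                fatty.to_numpy(bool)[known], abnormal[known]
            ),
        }
        nondm = ~gc.isin(("DM", "unknown"))
        out["ff_vs_fpg_nondiabetic"] = cs.spearman(ff[nondm], df["fpg_mg_dl"][nondm])
        if "glucose_2h_mg_dl" in df.columns:
            out["ff_vs_2h_nondiabetic"] = cs.spearman(ff[nondm], df["glucose_2h_mg_dl"][nondm])
        if "insulin_uu_ml" in df.columns:
            homa = [
                homa_ir(g, i) if np.isfinite(g) and np.isfinite(i) else float("nan")
                for g, i in zip(
                    pd.to_numeric(df["fpg_mg_dl"], errors="coerce"),
                    pd.to_numeric(df["insulin_uu_ml"], errors="coerce"),
                )
            ]
            out["ff_vs_homa_ir_nondiabetic"] = cs.spearman(
                ff[nondm], pd.Series(homa, index=df.index)[nondm]
            )
        else:
            out["ff_vs_homa_ir_nondiabetic"] = {
                "status": "not_computed",
                "reason": "insulin column absent",
            }
        return out

    def other_organs():
        out = {}
        if "lic_mg_g_dw" in df.columns:
            lic = pd.to_numeric(df["lic_mg_g_dw"], errors="coerce")
            hep = lic >= thr.lic_significant_mg_g
            out["ff_vs_lic"] = cs.spearman(ff, lic)
            out["ff_by_hepatic_iron"] = cs.compare_groups(
                {"hepatic_iron": ff[hep], "no_hepatic_iron": ff[~hep]}
            )
        if "heart_global_t2s_ms" in df.columns:
            heart = pd.to_numeric(df["heart_global_t2s_ms"], errors="coerce")
            mio = heart <= thr.heart_t2s_normal_ms
            out["ff_vs_heart_t2s"] = cs.spearman(ff, heart)
            if "n_pathological_segments" in df.columns:
                out["ff_vs_n_pathological_segments"] = cs.spearman(
                    ff, df["n_pathological_segments"]
                )
            out["mio_prevalence_pct"] = float(100.0 * mio.mean())
            out["ff_by_mio"] = cs.compare_groups({"mio": ff[mio], "no_mio": ff[~mio]})
            out["npv_normal_ff_for_mio"] = cs.predictive_values(
                fatty.to_numpy(bool), mio.to_numpy(bool)
            )
        return out

    def function_fibrosis():
        out = {}
        if "lvef_pct" in df.columns:
            out["ff_vs_lvef"] = cs.spearman(ff, df["lvef_pct"])
        if "rvef_pct" in df.columns:
            out["ff_vs_rvef"] = cs.spearman(ff, df["rvef_pct"])
        if "myocardial_fibrosis" in df.columns:
            fib = df["myocardial_fibrosis"]
            out["ff_by_fibrosis"] = cs.compare_groups(
                {"fibrosis": ff[fib == "present"], "no_fibrosis": ff[fib == "absent"]}
            )
            out["fibrosis_assessed_n"] = int((fib != "not_assessed").sum())
        return out

    def complications():
        comp = flags["cardiac_complication"].to_numpy(bool)
        return {
            "n_with_complication": int(comp.sum()),
            "ff_by_complication": cs.compare_groups(
                {"complication": ff[comp], "free": ff[~comp]}
            ),
            "roc_ff_predicts_complication": cs.roc_with_youden(
                ff.to_numpy(float), comp, direction="greater"
            ),
            "npv_normal_ff_for_complication": cs.predictive_values(
                fatty.to_numpy(bool), comp
            ),
        }

    stages = {
        "regional_comparison": regional_comparison,
        "demographics": demographics,
        "iron_and_fat": iron_and_fat,
        "hcv_groups": hcv_groups,
        "regression": regression,
        "glucose_metabolism": glucose,
        "other_organs": other_organs,
        "function_and_fibrosis": function_fibrosis,
        "cardiac_complications": complications,
    }
    for name, fn in stages.items():
        report[name] = _block(fn)
        log.info("stage %s done", name)
    return report
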