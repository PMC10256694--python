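"""End-to-end orchestration: simulate → z-score → diagnose → order → associate → VBM.

``run_pipeline`` executes the full analysis on a synthetic cohort (and
optionally a phantom-based VBM stage) from a single :class:`RunConfig`,
writing every intermediate table to the output directory so each report
cell is re-derivable. ``summarize_groups`` produces the group-comparison
table (mean (SD) / n (%) with ANOVA or chi-square, plus pairwise flags).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import associations, diagnostics, ordering, synth, vbm
from .normative import NormativeAgeModel, mean_striatal_zsbr
from .regions import REGIONS, GROUPS, PATIENT_GROUPS

__all__ = ["RunConfig", "run_pipeline", "summarize_groups",
           "fmt_mean_sd", "fmt_count_pct", "fmt_p"]


# ---------------------------------------------------------------------------
# formatting helpers (report conventions: % to 1 dp, z/AUC to 2, p to 3)
# ---------------------------------------------------------------------------

def fmt_mean_sd(values) -> str:
    v = np.asarray(values, dtype=float)
    return f"{v.mean():.1f} (± {v.std(ddof=1):.1f})"


def fmt_count_pct(count: int, total: int) -> str:
    if total <= 0:
        raise ValueError("total must be positive")
    return f"{count} ({100.0 * count / total:.1f})"


def fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# group summary
# ---------------------------------------------------------------------------

def summarize_groups(subjects: pd.DataFrame,
                     continuous=("age", "education"),
                     categorical=("sex",),
                     group_col: str = "group",
                     pairwise_alpha: float = 0.05) -> pd.DataFrame:
    """Group-comparison table in the clinical-paper style.

    Continuous variables: mean (SD) per group, one-way ANOVA p, pairwise
    Welch t-test flags. Categorical (0/1) variables: n (%), chi-square p,
    pairwise 2x2 chi-square flags. Groups with no rows are dropped with a
    warning column rather than an error.
    """
    groups = [g for g in GROUPS if (subjects[group_col] == g).any()]
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    rows = []
    for var in continuous:
        per = {g: subjects.loc[subjects[group_col] == g, var].dropna()
               for g in groups}
        p = float(stats.f_oneway(*[per[g] for g in groups]).pvalue)
        flags = []
        for a, b in pairs:
            tp = stats.ttest_ind(per[a], per[b], equal_var=False).pvalue
            if tp < pairwise_alpha:
                flags.append(f"{a} vs {b}")
        row = {"variable": var, "type": "continuous",
               "p": p, "p_str": fmt_p(p), "pairwise": "; ".join(flags)}
        for g in groups:
            row[g] = fmt_mean_sd(per[g])
        rows.append(row)
    for var in categorical:
        per = {g: subjects.loc[subjects[group_col] == g, var].dropna()
               for g in groups}
        table = np.array([[int(per[g].sum()), int(len(per[g]) - per[g].sum())]
                          for g in groups])
        with np.errstate(invalid="ignore"):
            p = float(stats.chi2_contingency(table, correction=False).pvalue) \
                if table.min() >= 0 and table.sum(axis=1).min() > 0 else np.nan
        flags = []
        for a, b in pairs:
            sub = np.array([[int(per[a].sum()), int(len(per[a]) - per[a].sum())],
                            [int(per[b].sum()), int(len(per[b]) - per[b].sum())]])
            if sub.sum(axis=0).min() == 0:
                continue
            pp = stats.chi2_contingency(sub, correction=False).pvalue
            if pp < pairwise_alpha:
                flags.append(f"{a} vs {b}")
        row = {"variable": var, "type": "categorical",
               "p": p, "p_str": fmt_p(p), "pairwise": "; ".join(flags)}
        for g in groups:
            row[g] = fmt_count_pct(int(per[g].sum()), len(per[g]))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One reproducible end-to-end run."""

    cohort: synth.CohortConfig
    out_dir: str | Path | None = None
    abnormality_threshold: float = ordering.DEFAULT_THRESHOLD  # z
    ordering_alpha: float = 0.01
    fdr_alpha: float = 0.05
    cluster_alpha: float = 0.05
    cluster_forming_p: float = 0.001
    operating_rule: str = "youden"
    run_vbm: bool = False
    phantom: synth.PhantomConfig | None = None
    vbm_n_perm: int = 500
    seed: int = 0

    def validate(self) -> None:
        for name, v in (("ordering_alpha", self.ordering_alpha),
                        ("fdr_alpha", self.fdr_alpha),
                        ("cluster_alpha", self.cluster_alpha),
                        ("cluster_forming_p", self.cluster_forming_p)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    def hash(self) -> str:
        blob = json.dumps({
            "cohort_seed": self.cohort.seed,
            "threshold": self.abnormality_threshold,
            "alphas": [self.ordering_alpha, self.fdr_alpha,
                       self.cluster_alpha, self.cluster_forming_p],
            "rule": self.operating_rule, "seed": self.seed,
            "vbm": self.run_vbm,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


BINARY_OUTCOMES = ("RBD", "CF", "VH", "parkinsonism_modest")
CONTINUOUS_OUTCOMES = ("UPDRS_III", "CDR_SOB", "K_MMSE")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the report dict and writes artifacts.

    Stages: cohort simulation, normative fit on HC + z-scoring, group
    summary, per-region ROC/logistic diagnostics for DLB-vs-HC and
    MCI-LB-vs-HC, conditional-probability ordering per patient group and
    pooled, covariate-adjusted association models with FDR, and (optional)
    a phantom VBM stage driven by the simulated nigral z-scores.
    """
    config.validate()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        return f"[stage {name}]"

    report: dict = {"config_hash": config.hash(), "seed": config.seed,
                    "cohort_seed": config.cohort.seed}

    # --- simulate ---------------------------------------------------------
    try:
        subjects, sbr = synth.simulate_cohort(config.cohort)
    except Exception as e:
        raise RuntimeError(f"{_stage('simulate')} {e}") from e

    # --- normative z-scoring ---------------------------------------------
    try:
        norm = NormativeAgeModel.from_dataframe(sbr).fit()
        ztable = norm.zscore_table(sbr, include_sides=True)
    except Exception as e:
        raise RuntimeError(f"{_stage('zscore')} {e}") from e

    # --- group summary ----------------------------------------------------
    cont = ["age", "education", "UPDRS_III", "K_MMSE", "CDR_SOB"]
    cont += list(REGIONS)
    cat = ["sex", "RBD", "CF", "VH", "parkinsonism"]
    merged = subjects.merge(sbr[["subject_id", *REGIONS]], on="subject_id")
    merged_z = subjects.merge(
        ztable[["subject_id", *REGIONS]], on="subject_id",
        suffixes=("", "_z"))
    summary = summarize_groups(merged, continuous=cont, categorical=cat)
    z_summary = summarize_groups(
        merged_z, continuous=list(REGIONS), categorical=())
    z_summary["variable"] = [f"{r}-zSBR" for r in REGIONS]
    report["group_summary"] = pd.concat([summary, z_summary],
                                        ignore_index=True)

    # --- diagnostics ------------------------------------------------------
    diag_rows = []
    hc = ztable[ztable["group"] == "HC"]
    for target in PATIENT_GROUPS:
        pat = ztable[ztable["group"] == target]
        labels = np.r_[np.ones(len(pat), int), np.zeros(len(hc), int)]
        for r in REGIONS:
            scores = np.r_[pat[r].to_numpy(), hc[r].to_numpy()]
            roc = diagnostics.roc_curve(labels, scores, direction="lower")
            thr, sens, spec = diagnostics.operating_point(
                roc, rule=config.operating_rule)
            logit = diagnostics.fit_univariate_logistic(labels, scores)
            diag_rows.append({
                "contrast": f"{target} vs HC", "region": r,
                "auc": roc.auc, "threshold": thr,
                "sensitivity_pct": sens, "specificity_pct": spec,
                "odds_ratio": logit.odds_ratio, "aic": logit.aic,
                "p": logit.p_value, "separation": logit.separation,
            })
        # paired AUC comparison SN vs PP, the headline contrast
        roc_sn = diagnostics.roc_curve(
            labels, np.r_[pat["SN"], hc["SN"]], direction="lower")
        roc_pp = diagnostics.roc_curve(
            labels, np.r_[pat["PP"], hc["PP"]], direction="lower")
        cmp = diagnostics.compare_auc(roc_sn, roc_pp)
        report[f"auc_sn_vs_pp_{target}"] = cmp
    report["diagnostics"] = pd.DataFrame(diag_rows)

    # --- ordering ---------------------------------------------------------
    order_results = {}
    for name, sel in (("DLB", ztable["group"] == "DLB"),
                      ("MCI-LB", ztable["group"] == "MCI-LB"),
                      ("pooled", ztable["group"].isin(PATIENT_GROUPS))):
        flags = ordering.flag_abnormal(ztable[sel],
                                       config.abnormality_threshold)
        res = ordering.conditional_matrix(flags)
        edges = ordering.infer_order(res, alpha=config.ordering_alpha)
        order_results[name] = {"result": res, "edges": edges}
    report["ordering"] = order_results

    # --- associations -----------------------------------------------------
    patients = merged_z[merged_z["group"].isin(PATIENT_GROUPS)].copy()
    patients["parkinsonism_modest"] = associations.parkinsonism_flag(
        patients["UPDRS_III"])
    binary = [b for b in BINARY_OUTCOMES
              if patients[b].nunique() == 2]
    assoc = associations.association_table(
        patients, binary_outcomes=binary,
        continuous_outcomes=CONTINUOUS_OUTCOMES,
        fdr_alpha=config.fdr_alpha)
    report["associations"] = assoc

    # --- vbm (optional) ---------------------------------------------------
    if config.run_vbm:
        ph = config.phantom or synth.reference_phantom_config(
            seed=config.seed)
        pat_z = patients.sort_values("subject_id")
        sn_z = pat_z["SN"].to_numpy()
        _, _, gm_maps, icv = synth.simulate_phantom(ph, sn_z)
        gm_arrays = [m.data for m in gm_maps]
        mask = vbm.build_gm_mask(gm_arrays)
        cov = pd.DataFrame({
            "age": pat_z["age"].to_numpy(),
            "sex": pat_z["sex"].to_numpy(),
            "education": pat_z["education"].to_numpy(),
            "icv": icv,
        })
        t_map, dof = vbm.voxelwise_glm(gm_arrays, sn_z, cov, mask)
        rep = vbm.cluster_correct(
            gm_arrays, sn_z, cov, mask,
            p_form=config.cluster_forming_p, n_perm=config.vbm_n_perm,
            alpha=config.cluster_alpha, seed=config.seed)
        report["vbm"] = {"report": rep, "dof": dof,
                         "r_map": vbm.effect_size_map(t_map, dof)}

    # --- artifacts --------------------------------------------------------
    if out:
        subjects.to_csv(out / "subjects.csv", index=False)
        sbr.to_csv(out / "sbr.csv", index=False)
        ztable.to_csv(out / "zsbr.csv", index=False)
        report["group_summary"].to_csv(out / "group_summary.csv", index=False)
        report["diagnostics"].to_csv(out / "diagnostics.csv", index=False)
        assoc.to_csv(out / "associations.csv", index=False)
        for name, d in order_results.items():
            d["result"].prob.to_csv(out / f"ordering_prob_{name}.csv")
            d["result"].p_value.to_csv(out / f"ordering_p_{name}.csv")
        edges_json = {
            name: [vars(e) for e in d["edges"]]
            for name, d in order_results.items()}
        (out / "ordering_edges.json").write_text(
            json.dumps(edges_json, indent=2))
        (out / "provenance.json").write_text(json.dumps({
            "config_hash": config.hash(), "seed": config.seed,
            "cohort_seed": config.cohort.seed,
            "abnormality_threshold": config.abnormality_threshold,
            "ordering_alpha": config.ordering_alpha,
            "fdr_alpha": config.fdr_alpha,
            "cluster_alpha": config.cluster_alpha,
            "cluster_forming_p": config.cluster_forming_p,
        }, indent=2))

    # derived convenience: mean striatal z
    report["mean_striatal_z"] = mean_striatal_zsbr(ztable)
    return report
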