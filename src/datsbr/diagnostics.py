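"""Diagnostic evaluation of regional zSBRs: logistic models, ROC, AUC.

Each regional zSBR is evaluated as a single-predictor classifier of
patients (MCI-LB or DLB) versus healthy controls. Lower z-scores indicate
disease, so scores are oriented before computing the empirical ROC curve;
the AUC equals the Mann–Whitney probability that a random case scores
lower than a random control (ties counted half). Operating points use
Youden's J (ties resolved toward the more specific threshold), and paired
AUC differences are tested with DeLong's method, with a seeded paired
bootstrap as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn import metrics as skmetrics

__all__ = [
    "LogisticFit",
    "ROCResult",
    "fit_univariate_logistic",
    "roc_curve",
    "operating_point",
    "compare_auc",
    "compare_auc_bootstrap",
]


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    """Single-predictor (optionally covariate-adjusted) logistic model."""

    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    aic: float
    n: int
    separation: bool = False
    covariate_coefs: dict = field(default_factory=dict)

    def summary(self) -> str:
        flag = "  [SEPARATION]" if self.separation else ""
        return (f"OR per z-unit {self.odds_ratio:.3f} "
                f"(95% CI {self.ci_low:.3f}-{self.ci_high:.3f}), "
                f"p = {self.p_value:.4g}, AIC = {self.aic:.2f}, "
                f"n = {self.n}{flag}")


def fit_univariate_logistic(labels, predictor, covariates=None,
                            alpha: float = 0.05) -> LogisticFit:
    """ML logistic fit of ``labels ~ predictor (+ covariates)``.

    ``labels`` are 0/1 (1 = case). Complete or quasi-separation is flagged
    (``separation=True``) rather than silently reporting an enormous odds
    ratio; the divergent estimate is still returned for inspection.
    """
    y = np.asarray(labels, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")

    cols = {"const": np.ones_like(x), "predictor": x}
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        if np.linalg.matrix_rank(np.column_stack([cols["predictor"],
                                                  cov.to_numpy(float)])) \
                < 1 + cov.shape[1]:
            raise ValueError("collinear covariates")
        for c in cov.columns:
            cols[str(c)] = cov[c].to_numpy(float)
    X = pd.DataFrame(cols)

    separation = False
    with np.errstate(all="ignore"):
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            separation = True
            res = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-8, maxiter=500)
    coef = float(res.params["predictor"])
    try:
        se = float(res.bse["predictor"])
    except Exception:
        se = float("nan")
    if not np.isfinite(se) or se > 50 or abs(coef) > 15:
        separation = True
    zq = stats.norm.ppf(1 - alpha / 2)
    aic = float(getattr(res, "aic", 2 * X.shape[1] - 2 * res.llf))
    return LogisticFit(
        coef=coef, se=se,
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - zq * se)),
        ci_high=float(np.exp(coef + zq * se)),
        p_value=float(res.pvalues["predictor"]) if np.isfinite(se) else float("nan"),
        aic=aic, n=len(y), separation=separation,
        covariate_coefs={c: float(res.params[c]) for c in X.columns
                         if c not in ("predictor",)},
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """Empirical ROC curve for one score.

    Thresholds are in the original score units; with ``direction="lower"``
    a subject is called a case when ``score <= threshold``.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int
    direction: str
    labels: np.ndarray
    scores: np.ndarray
    degenerate: bool = False

    def youden(self):
        return operating_point(self, rule="youden")


def roc_curve(labels, scores, direction: str = "lower") -> ROCResult:
    """Empirical ROC over all unique thresholds.

    ``direction="lower"`` (default) treats lower scores as disease-like,
    matching zSBR; ``"higher"`` is the conventional orientation. AUC is the
    trapezoidal area, identical to the Mann–Whitney estimator with ties
    counted half.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    oriented = -s if direction == "lower" else s
    fpr, tpr, thr = skmetrics.roc_curve(y, oriented, drop_intermediate=False)
    auc = float(skmetrics.roc_auc_score(y, oriented))
    thresholds = -thr if direction == "lower" else thr
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        n_cases=int((y == 1).sum()),
        n_controls=int((y == 0).sum()),
        direction=direction,
        labels=y, scores=s,
        degenerate=bool(np.ptp(s) == 0),
    )


def operating_point(roc: ROCResult, rule: str = "youden",
                    min_specificity: float | None = None):
    """Select an operating point on the ROC curve.

    ``rule="youden"`` maximises J = sensitivity + specificity - 1 (ties
    resolved toward the more specific threshold). With ``min_specificity``
    the point of maximal sensitivity subject to that specificity is
    returned instead.

    Returns ``(threshold, sensitivity_pct, specificity_pct)``.
    """
    sens, spec, thr = roc.sensitivity, roc.specificity, roc.thresholds
    if min_specificity is not None:
        ok = spec >= min_specificity
        if not ok.any():
            raise ValueError("no threshold attains the requested specificity")
        cand = np.flatnonzero(ok)
        best = cand[np.lexsort((spec[cand], sens[cand]))][-1]
    else:
        j = sens + spec - 1.0
        best_j = j.max()
        cand = np.flatnonzero(np.isclose(j, best_j))
        best = cand[np.argmax(spec[cand])]
    return float(thr[best]), float(100 * sens[best]), float(100 * spec[best])


# ---------------------------------------------------------------------------
# paired AUC comparison
# ---------------------------------------------------------------------------

def _midrank_placements(cases: np.ndarray, controls: np.ndarray):
    """DeLong structural components (placements) for one score."""
    v_cases = np.array([
        (np.sum(c > controls) + 0.5 * np.sum(c == controls)) / len(controls)
        for c in cases])
    v_controls = np.array([
        (np.sum(cases > c) + 0.5 * np.sum(cases == c)) / len(cases)
        for c in controls])
    return v_cases, v_controls


def compare_auc(roc1: ROCResult, roc2: ROCResult) -> dict:
    """DeLong test for the difference of two paired AUCs.

    Both ROCs must have been computed on the same subjects (labels equal,
    element-wise). Returns the two AUCs, their difference, the DeLong z
    statistic and two-sided p-value.
    """
    if len(roc1.labels) != len(roc2.labels) or \
            not np.array_equal(roc1.labels, roc2.labels):
        raise ValueError("paired AUC comparison requires identical subjects")
    y = roc1.labels
    aucs, v_cases, v_controls = [], [], []
    for roc in (roc1, roc2):
        s = -roc.scores if roc.direction == "lower" else roc.scores
        vc, vn = _midrank_placements(s[y == 1], s[y == 0])
        aucs.append(vc.mean())
        v_cases.append(vc)
        v_controls.append(vn)
    m, n = (y == 1).sum(), (y == 0).sum()
    s10 = np.cov(np.vstack(v_cases))      # 2x2 across scores, cases
    s01 = np.cov(np.vstack(v_controls))   # 2x2 across scores, controls
    var = s10 / m + s01 / n
    contrast = np.array([1.0, -1.0])
    denom = float(contrast @ var @ contrast)
    diff = float(aucs[0] - aucs[1])
    if denom <= 0:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(denom)
        p = float(2 * stats.norm.sf(abs(z)))
    return {"auc1": float(aucs[0]), "auc2": float(aucs[1]),
            "diff": diff, "z": float(z), "p_value": p}


def compare_auc_bootstrap(labels, scores1, scores2, direction: str = "lower",
                          n_boot: int = 2000, seed: int = 0) -> dict:
    """Paired-bootstrap test of AUC difference (two-sided, basic percentile)."""
    y = np.asarray(labels, dtype=int)
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    o1 = -s1 if direction == "lower" else s1
    o2 = -s2 if direction == "lower" else s2
    obs = skmetrics.roc_auc_score(y, o1) - skmetrics.roc_auc_score(y, o2)
    rng = np.random.default_rng(seed)
    idx_case = np.flatnonzero(y == 1)
    idx_ctrl = np.flatnonzero(y == 0)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        ic = rng.choice(idx_case, len(idx_case))
        ik = rng.choice(idx_ctrl, len(idx_ctrl))
        idx = np.concatenate([ic, ik])
        yb = y[idx]
        diffs[b] = (skmetrics.roc_auc_score(yb, o1[idx])
                    - skmetrics.roc_auc_score(yb, o2[idx]))
    centred = diffs - diffs.mean()
    p = (1 + np.sum(np.abs(centred) >= abs(obs))) / (1 + n_boot)
    return {"diff": float(obs), "p_value": float(p),
            "boot_mean": float(diffs.mean()), "n_boot": n_boot}
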