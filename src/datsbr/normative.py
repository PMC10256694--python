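"""Normative age modelling of regional SBRs and z-score (zSBR) computation.

For each region an ordinary least squares line ``SBR ~ age`` is fitted in
the healthy-control (HC) group. A subject's zSBR is the residual from the
HC-predicted mean divided by the HC residual standard error,

    z = (SBR - (intercept + slope * age)) / RSE,   RSE = sqrt(RSS / (n - 2)).

Scoring the HC training sample itself ("in-sample") therefore yields a mean
of exactly 0 per region and a sample standard deviation of
``sqrt((n - 2)/(n - 1))`` — 0.987 for n = 40, which prints as 1.0 at one
decimal. Patient z-scores are plain out-of-sample evaluations of the same
model.

Supplementary summaries: the mean striatal zSBR averages the four
caudate/putamen subregions, and the more-affected-side zSBR takes, per
region, the hemisphere with the lower z-score.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .regions import REGIONS, STRIATAL_REGIONS, SIDES

__all__ = [
    "RegionNormative",
    "NormativeAgeModel",
    "NormativeAgeResults",
    "fit_normative_model",
    "mean_striatal_zsbr",
    "more_affected_side_zsbr",
]


@dataclass(frozen=True)
class RegionNormative:
    """Fitted normative line for one region."""

    intercept: float   # SBR units at age 0
    slope: float       # SBR units per year
    resid_se: float    # sqrt(RSS / (n-2)), SBR units
    n: int
    dof: int

    def predict(self, age):
        return self.intercept + self.slope * np.asarray(age, dtype=float)

    def zscore(self, sbr, age):
        return (np.asarray(sbr, dtype=float) - self.predict(age)) / self.resid_se


def _fit_region(age: np.ndarray, sbr: np.ndarray, region: str) -> RegionNormative:
    age = np.asarray(age, dtype=float)
    sbr = np.asarray(sbr, dtype=float)
    n = len(age)
    if n < 3:
        raise ValueError(f"{region}: need >= 3 HC subjects, got {n}")
    if np.ptp(age) == 0:
        raise ValueError(f"{region}: constant age in HC sample")
    res = sm.OLS(sbr, sm.add_constant(age)).fit()
    rss = float(res.ssr)
    dof = n - 2
    tss = float(np.sum((sbr - sbr.mean()) ** 2))
    # RSS = 0 up to float roundoff: perfectly linear (or constant) SBR
    if not np.isfinite(rss) or rss <= max(1e-12 * max(tss, 1.0), 0.0) \
            or rss == 0.0:
        raise ValueError(f"{region}: degenerate normative variance (RSS = 0)")
    return RegionNormative(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        resid_se=float(np.sqrt(rss / dof)),
        n=n,
        dof=dof,
    )


class NormativeAgeModel:
    """Per-region OLS of SBR on age in healthy controls.

    Parameters
    ----------
    hc_sbr : DataFrame
        HC rows with an ``age`` column and one SBR column per region (and
        optionally per-hemisphere columns ``{region}_{L|R}``, which are
        fitted too when present so per-side z-scores can be produced).
    regions : sequence of str
        Region columns to fit (default: the five-ROI set).
    """

    def __init__(self, hc_sbr: pd.DataFrame, regions=REGIONS,
                 age_col: str = "age"):
        missing = [r for r in regions if r not in hc_sbr.columns]
        if missing:
            raise ValueError(f"missing region columns in HC table: {missing}")
        if age_col not in hc_sbr.columns:
            raise ValueError(f"missing '{age_col}' column")
        self.data = hc_sbr.reset_index(drop=True)
        self.regions = tuple(regions)
        self.age_col = age_col

    @classmethod
    def from_dataframe(cls, sbr: pd.DataFrame, group_col: str = "group",
                       hc_label: str = "HC", **kw) -> "NormativeAgeModel":
        """Build the model from a full cohort table, selecting HC rows."""
        return cls(sbr[sbr[group_col] == hc_label], **kw)

    def fit(self) -> "NormativeAgeResults":
        age = self.data[self.age_col].to_numpy(float)
        params = {r: _fit_region(age, self.data[r].to_numpy(float), r)
                  for r in self.regions}
        side_params = {}
        for r in self.regions:
            for s in SIDES:
                col = f"{r}_{s}"
                if col in self.data.columns:
                    side_params[col] = _fit_region(
                        age, self.data[col].to_numpy(float), col)
        return NormativeAgeResults(params, side_params, self.age_col)


class NormativeAgeResults:
    """Fitted normative model: predicted means, residual SEs, z-scoring."""

    def __init__(self, params: Mapping[str, RegionNormative],
                 side_params: Mapping[str, RegionNormative] | None = None,
                 age_col: str = "age"):
        self.params = dict(params)
        self.side_params = dict(side_params or {})
        self.age_col = age_col

    def _lookup(self, region: str) -> RegionNormative:
        if region in self.params:
            return self.params[region]
        if region in self.side_params:
            return self.side_params[region]
        raise KeyError(f"no normative model for region '{region}'")

    def zscore(self, region: str, sbr, age):
        """zSBR for one region: (sbr - predicted mean) / residual SE."""
        return self._lookup(region).zscore(sbr, age)

    def zscore_table(self, sbr: pd.DataFrame, include_sides: bool = False
                     ) -> pd.DataFrame:
        """Score every subject row; returns id/group/age plus z columns."""
        keep = [c for c in ("subject_id", "group", self.age_col)
                if c in sbr.columns]
        out = sbr[keep].copy()
        age = sbr[self.age_col].to_numpy(float)
        cols = list(self.params)
        if include_sides:
            cols += [c for c in self.side_params if c in sbr.columns]
        for c in cols:
            out[c] = self._lookup(c).zscore(sbr[c].to_numpy(float), age)
        return out

    def summary(self) -> str:
        lines = ["Normative age model (OLS of SBR on age in HC)",
                 f"{'region':>8} {'intercept':>10} {'slope/yr':>10} "
                 f"{'resid SE':>9} {'n':>4} {'dof':>4}"]
        for r, p in self.params.items():
            lines.append(f"{r:>8} {p.intercept:10.4f} {p.slope:10.5f} "
                         f"{p.resid_se:9.4f} {p.n:4d} {p.dof:4d}")
        return "\n".join(lines)

    def to_json(self, path) -> None:
        d = {"regions": {r: vars(p) for r, p in self.params.items()},
             "sides": {r: vars(p) for r, p in self.side_params.items()}}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "NormativeAgeResults":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls({r: RegionNormative(**p) for r, p in d["regions"].items()},
                   {r: RegionNormative(**p) for r, p in d.get("sides", {}).items()})


def fit_normative_model(hc_sbr: pd.DataFrame, regions=REGIONS,
                        age_col: str = "age") -> NormativeAgeResults:
    """Functional shortcut: ``NormativeAgeModel(...).fit()``."""
    return NormativeAgeModel(hc_sbr, regions=regions, age_col=age_col).fit()


def mean_striatal_zsbr(ztable: pd.DataFrame) -> pd.Series:
    """Unweighted mean zSBR over the four striatal subregions, per subject."""
    missing = [r for r in STRIATAL_REGIONS if r not in ztable.columns]
    if missing:
        raise ValueError(f"missing striatal region columns: {missing}")
    return ztable[list(STRIATAL_REGIONS)].mean(axis=1)


def more_affected_side_zsbr(ztable: pd.DataFrame, regions=REGIONS
                            ) -> pd.DataFrame:
    """Per region, the z-score of the hemisphere with the lower value."""
    out = {}
    for r in regions:
        cols = [f"{r}_L", f"{r}_R"]
        missing = [c for c in cols if c not in ztable.columns]
        if missing:
            raise ValueError(f"missing per-hemisphere columns: {missing}")
        out[r] = ztable[cols].min(axis=1)
    return pd.DataFrame(out, index=ztable.index)
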