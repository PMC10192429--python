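"""Survival estimation and testing: KM, log-rank, Cox, Lin's CCC, subgroups.

The Kaplan-Meier estimator and the two-group log-rank test are implemented
directly (short closed forms with the events-before-censorings tie
convention) and are cross-checked against lifelines in the test suite;
multivariable Cox fits delegate to lifelines' partial-likelihood Newton
solver with Efron tie handling.  Hazard-ratio confidence intervals are Wald
intervals on the log scale; all tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps


@dataclass
class KMCurve:
    """Product-limit estimate: S(t) evaluated at the ascending event times."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) at those times, non-increasing from 1
    at_risk: np.ndarray  # risk-set size just before each event time
    censor_times: np.ndarray  # censoring marks

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def _as_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("time and event must be equal-length 1-d arrays")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return t, e


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times, events are processed before censorings: a subject censored
    at t is still in the risk set for an event at t.
    """
    t, e = _as_arrays(time, event)
    if len(t) == 0:
        raise ValueError("empty sample")
    ev_times = np.unique(t[e == 1])
    surv, risks = [], []
    s = 1.0
    for tt in ev_times:
        n_at_risk = int(np.sum(t >= tt))
        d = int(np.sum((t == tt) & (e == 1)))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
        risks.append(n_at_risk)
    return KMCurve(times=ev_times, survival=np.array(surv),
                   at_risk=np.array(risks, dtype=int), censor_times=np.sort(t[e == 0]))


def logrank_chi2(time, event, group) -> float:
    """Two-group log-rank chi-square statistic (1 df)."""
    t, e = _as_arrays(time, event)
    g = np.asarray(group).astype(bool)
    o_minus_e = 0.0
    var = 0.0
    for tt in np.unique(t[e == 1]):
        at = t >= tt
        n = at.sum()
        n1 = (at & g).sum()
        d = int(np.sum((t == tt) & (e == 1)))
        d1 = int(np.sum((t == tt) & (e == 1) & g))
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0
    return float(o_minus_e ** 2 / var)


def logrank_test(time, event, group) -> dict[str, float]:
    """Two-sided two-group log-rank test; p from chi-square(1)."""
    g = np.asarray(group).astype(bool)
    if g.all() or (~g).all():
        raise ValueError("both groups must be non-empty")
    t, e = _as_arrays(time, event)
    if e.sum() < 1:
        raise ValueError("at least one event required")
    chi2 = logrank_chi2(t, e, g)
    return {"chi2": chi2, "p": float(sps.chi2.sf(chi2, df=1))}


def cox_fit(time, event, covariates: pd.DataFrame, multivariable: bool = True
            ) -> dict[str, HazardRatioResult]:
    """Cox proportional-hazards fit(s) with Wald 95% CIs and p-values.

    ``multivariable=True`` fits one joint model; otherwise each covariate is
    fitted in its own univariable model.  Complete-case rows only (per model).
    """
    t, e = _as_arrays(time, event)
    df = covariates.copy()
    df["_time"], df["_event"] = t, e

    def _one(cols: list[str]) -> dict[str, HazardRatioResult]:
        sub = df[cols + ["_time", "_event"]].dropna()
        n = len(sub)
        for c in cols:
            if sub[c].nunique() <= 1:
                raise ValueError(f"covariate {c!r} is constant (non-identifiable)")
        if sub["_event"].sum() < len(cols):
            raise ValueError("fewer events than coefficients")
        cph = CoxPHFitter()
        try:
            cph.fit(sub, duration_col="_time", event_col="_event")
        except ConvergenceError as err:
            raise RuntimeError(f"Cox fit did not converge for {cols}: {err}") from err
        out = {}
        for c in cols:
            beta = float(cph.params_[c])
            se = float(cph.standard_errors_[c])
            if not np.isfinite(se) or se > 50:
                raise RuntimeError(f"monotone likelihood / unstable fit for {c!r}")
            z = beta / se
            out[c] = HazardRatioResult(
                hr=float(np.exp(beta)),
                ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                p=float(2 * sps.norm.sf(abs(z))),
                n=n,
            )
        return out

    cols = list(covariates.columns)
    if multivariable:
        return _one(cols)
    results: dict[str, HazardRatioResult] = {}
    for c in cols:
        results.update(_one([c]))
    return results


def lin_ccc(x, y) -> dict[str, float]:
    """Lin's concordance correlation coefficient with a Fisher-z 95% CI.

    ccc = 2 cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2), population
    moments; the CI uses Lin's asymptotic variance of the z-transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length samples with n >= 3")
    vx, vy = np.var(x), np.var(y)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both inputs")
    mx, my = np.mean(x), np.mean(y)
    cov = float(np.mean((x - mx) * (y - my)))
    ccc = 2 * cov / (vx + vy + (mx - my) ** 2)
    r = cov / np.sqrt(vx * vy) if vx > 0 and vy > 0 else 0.0
    u = (mx - my) / (vx * vy) ** 0.25 if vx > 0 and vy > 0 else 0.0
    if abs(ccc) >= 1 or abs(r) < 1e-12:
        se_z = np.sqrt(1.0 / max(n - 3, 1))
    else:
        c2 = ccc ** 2
        se_z = np.sqrt(max(
            ((1 - r ** 2) * c2 / ((1 - c2) * r ** 2)
             + 2 * ccc ** 3 * (1 - ccc) * u ** 2 / (r * (1 - c2) ** 2)
             - c2 ** 2 * u ** 4 / (2 * r ** 2 * (1 - c2) ** 2)) / (n - 2), 1e-12))
    z = np.arctanh(np.clip(ccc, -1 + 1e-12, 1 - 1e-12))
    lo, hi = np.tanh(z - 1.959963984540054 * se_z), np.tanh(z + 1.959963984540054 * se_z)
    return {"ccc": float(ccc), "ci_low": float(lo), "ci_high": float(hi)}


def odx_categorize(score: int) -> str:
    """Traditional recurrence-score categories: <18 low, 18-30 intermediate, >30 high."""
    if score < 0:
        raise ValueError(f"recurrence score must be >= 0, got {score}")
    if score < 18:
        return "low"
    if score <= 30:
        return "intermediate"
    return "high"


@dataclass
class SubgroupResult:
    stratum: str
    n: int
    n_high: int
    n_low: int
    n_events: int
    evaluable: bool
    reason: str = ""
    km_high: KMCurve | None = None
    km_low: KMCurve | None = None
    logrank: dict[str, float] = field(default_factory=dict)
    hazard_ratio: HazardRatioResult | None = None


def _strata_labels(clinical: pd.DataFrame, by: str) -> pd.Series:
    if by == "odx_category":
        odx = pd.to_numeric(clinical.get("odx_score"), errors="coerce")
        return odx.map(lambda s: odx_categorize(int(s)) if pd.notna(s) else np.nan)
    if by == "grade":
        g = pd.to_numeric(clinical.get("grade"), errors="coerce")
        return g.map(lambda v: {1: "low", 2: "intermediate", 3: "high"}.get(int(v))
                     if pd.notna(v) else np.nan)
    if by == "her2_filter":
        return clinical["her2_status"].map(lambda s: "her2_neg" if s == "neg" else np.nan)
    raise ValueError(f"unknown stratifier {by!r}; use odx_category, grade or her2_filter")


def subgroup_analysis(predictions: pd.DataFrame, clinical: pd.DataFrame,
                      by: str) -> dict[str, SubgroupResult]:
    """High- vs low-risk survival comparison within each stratum.

    ``predictions`` needs patient_id and group ('high'/'low'); ``clinical``
    needs patient_id, dfs_time, event and the stratifier source column.
    Patients with a missing stratum are excluded; strata with fewer than two
    patients, no events, or a single risk group are reported non-evaluable.
    """
    merged = predictions.merge(clinical, on="patient_id", validate="one_to_one")
    merged["_stratum"] = _strata_labels(merged, by).to_numpy()
    out: dict[str, SubgroupResult] = {}
    for stratum, sub in merged.dropna(subset=["_stratum"]).groupby("_stratum"):
        hi = sub["group"] == "high"
        n_ev = int(sub["event"].sum())
        res = SubgroupResult(stratum=str(stratum), n=len(sub), n_high=int(hi.sum()),
                             n_low=int((~hi).sum()), n_events=n_ev, evaluable=True)
        if len(sub) < 2 or n_ev == 0 or hi.all() or (~hi).all():
            res.evaluable = False
            res.reason = ("fewer than 2 patients" if len(sub) < 2 else
                          "no events" if n_ev == 0 else "single risk group")
            out[res.stratum] = res
            continue
        res.km_high = km_estimate(sub.loc[hi, "dfs_time"], sub.loc[hi, "event"])
        res.km_low = km_estimate(sub.loc[~hi, "dfs_time"], sub.loc[~hi, "event"])
        res.logrank = logrank_test(sub["dfs_time"], sub["event"], hi)
        try:
            res.hazard_ratio = cox_fit(sub["dfs_time"], sub["event"],
                                       pd.DataFrame({"risk_high": hi.astype(float)})
                                       )["risk_high"]
        except (ValueError, RuntimeError):
            res.hazard_ratio = None
        out[res.stratum] = res
    return out


#: Table-style clinical covariate codings for uni/multivariable Cox analyses
def clinical_codings(clinical: pd.DataFrame) -> pd.DataFrame:
    """Binary/ordinal covariate codings used in the cohort Cox analyses.

    age >=50, tumor size >=20 mm, PR- vs PR+, HER2+ vs HER2-, grade as the
    3-level ordinal plus both merged 2-level variants, ODx category 3-level
    and merged variants.  Unknown levels become NaN (complete-case per model).
    """
    df = pd.DataFrame(index=clinical.index)
    df["age_ge50"] = (pd.to_numeric(clinical["age"], errors="coerce") >= 50).astype(float)
    size = pd.to_numeric(clinical["tumor_size_mm"], errors="coerce")
    df["size_ge20"] = (size >= 20).astype(float).where(size.notna())
    df["pr_neg"] = clinical["pr_status"].map({"neg": 1.0, "pos": 0.0})
    df["her2_pos"] = clinical["her2_status"].map({"pos": 1.0, "neg": 0.0})
    grade = pd.to_numeric(clinical["grade"], errors="coerce")
    df["grade_ordinal"] = grade
    df["grade_high_vs_rest"] = (grade == 3).astype(float).where(grade.notna())
    df["grade_rest_vs_low"] = (grade >= 2).astype(float).where(grade.notna())
    odx = pd.to_numeric(clinical.get("odx_score"), errors="coerce")
    ocat = odx.map(lambda s: {"low": 0, "intermediate": 1, "high": 2}[odx_categorize(int(s))]
                   if pd.notna(s) else np.nan)
    df["odx_ordinal"] = ocat
    df["odx_high_vs_rest"] = (ocat == 2).astype(float).where(ocat.notna())
    df["odx_rest_vs_low"] = (ocat >= 1).astype(float).where(ocat.notna())
    return df


def plot_km(curves: dict[str, KMCurve], ax=None, title: str = ""):
    """Step-plot KM curves with censor ticks (matplotlib axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, c in curves.items():
        t = np.concatenate([[0.0], c.times])
        s = np.concatenate([[1.0], c.survival])
        ax.step(t, s, where="post", label=label)
        if len(c.censor_times):
            sc = [c.survival_at(ct) for ct in c.censor_times]
            ax.plot(c.censor_times, sc, "|", color=ax.get_lines()[-1].get_color())
    ax.set_xlabel("months")
    ax.set_ylabel("DFS probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
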