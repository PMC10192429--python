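"""The image-based risk score (IbRiS) prognostic model.

Pipeline: (1) univariable Cox screening ranks every feature within each of
the three families by Wald p-value and keeps the top four per family (12
total, ~10% of the training-set size the design targets); (2) a LASSO-
regularized Cox model over the 12 z-scored features, with the penalty chosen
by 5-fold cross-validated partial likelihood, yields the linear risk score
(zero coefficients are retained in the locked model); (3) an optimal
cutpoint theta_opt — the candidate split maximizing the log-rank chi-square
within the 20th-80th percentile band of training scores — dichotomizes the
score into high (score > theta_opt) versus low (score <= theta_opt) risk.

Exposed both as module functions and as the ``IbrisModel`` / ``IbrisResults``
pair: the model is built from a feature matrix plus outcomes, ``fit()``
returns results carrying estimates, diagnostics and prediction methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .catalog import FeatureCatalog, default_catalog
from .datatypes import FeatureMatrix

_Z975 = 1.959963984540054


# ---------------------------------------------------------------------------
# vectorized univariable Cox screening (Breslow ties)

def univariable_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                    max_iter: int = 30, tol: float = 1e-9) -> dict[str, np.ndarray]:
    """Newton fit of a single-covariate Cox model for every column of X.

    Breslow tie handling; columns are used as given (z-score beforehand for
    comparable coefficients).  Returns beta, se, z and two-sided Wald p.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]
    n, p = X.shape
    # risk set of subject i = all j with t_j >= t_i: suffix sums anchored at
    # the first index of each tied block
    first_idx = np.searchsorted(t, t, side="left")
    ev = e == 1

    beta = np.zeros(p)
    for _ in range(max_iter):
        w = np.exp(X * beta)  # (n, p)
        sw = np.cumsum(w[::-1], axis=0)[::-1]
        swx = np.cumsum((w * X)[::-1], axis=0)[::-1]
        swx2 = np.cumsum((w * X * X)[::-1], axis=0)[::-1]
        rs_w = sw[first_idx]
        rs_wx = swx[first_idx]
        rs_wx2 = swx2[first_idx]
        mu = rs_wx / rs_w
        grad = (X[ev] - mu[ev]).sum(axis=0)
        info = (rs_wx2[ev] / rs_w[ev] - mu[ev] ** 2).sum(axis=0)
        info = np.maximum(info, 1e-12)
        step = np.clip(grad / info, -1.0, 1.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    w = np.exp(X * beta)
    sw = np.cumsum(w[::-1], axis=0)[::-1]
    swx = np.cumsum((w * X)[::-1], axis=0)[::-1]
    swx2 = np.cumsum((w * X * X)[::-1], axis=0)[::-1]
    mu = swx[first_idx] / sw[first_idx]
    info = (swx2[first_idx][ev] / sw[first_idx][ev] - mu[ev] ** 2).sum(axis=0)
    se = 1.0 / np.sqrt(np.maximum(info, 1e-12))
    z = beta / se
    return {"beta": beta, "se": se, "z": z, "p": 2 * sps.norm.sf(np.abs(z))}


def breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of a linear predictor."""
    order = np.argsort(time, kind="stable")
    t, e, lp = np.asarray(time)[order], np.asarray(event)[order], np.asarray(lp)[order]
    first_idx = np.searchsorted(t, t, side="left")
    w = np.exp(lp)
    sw = np.cumsum(w[::-1])[::-1]
    ev = e == 1
    return float(np.sum(lp[ev] - np.log(sw[first_idx][ev])))


def screen_top_features(fm: FeatureMatrix | pd.DataFrame, time, event,
                        family_names: list[str], k: int = 4) -> list[str]:
    """Top-k prognostic features of one family by univariable Cox Wald p.

    Constant (or all-NaN) features are skipped; ties broken by |z| descending
    then name.  Requires at least 10 events and k non-constant features.
    """
    df = fm.to_dataframe() if isinstance(fm, FeatureMatrix) else fm
    e = np.asarray(event, dtype=int)
    if e.sum() < 10:
        raise ValueError(f"screening requires >= 10 events, got {int(e.sum())}")
    cols = [c for c in family_names if c in df.columns]
    X = df[cols].to_numpy(dtype=float)
    # impute family-NA patients at the column mean so the fit stays defined
    col_mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
    X = np.where(np.isfinite(X), X, col_mean)
    sd = X.std(axis=0)
    usable = np.isfinite(col_mean) & (sd > 0)
    if usable.sum() < k:
        raise ValueError(
            f"fewer than {k} non-constant features in family ({int(usable.sum())})")
    Xu = (X[:, usable] - X[:, usable].mean(0)) / sd[usable]
    names = [c for c, u in zip(cols, usable) if u]
    res = univariable_cox(Xu, np.asarray(time, float), e)
    order = sorted(range(len(names)),
                   key=lambda i: (res["p"][i], -abs(res["z"][i]), names[i]))
    return [names[i] for i in order[:k]]


# ---------------------------------------------------------------------------
# optimal cutpoint

def find_theta_opt(scores, time, event) -> float:
    """Cutpoint maximizing the two-group log-rank chi-square.

    Candidates are midpoints of consecutive unique scores restricted to the
    [20th, 80th] percentile band; ties are resolved toward the more balanced
    split, then the smaller cutpoint.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct scores")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    lo, hi = np.percentile(s, [20, 80])
    cand = mids[(mids >= lo) & (mids <= hi)]
    if cand.size == 0:
        cand = mids

    order = np.argsort(t, kind="stable")
    t_s, e_s, s_s = t[order], e[order], s[order]
    first_idx = np.searchsorted(t_s, t_s, side="left")
    G = (s_s[None, :] > cand[:, None]).astype(float)  # (C, n)
    S = np.cumsum(G[:, ::-1], axis=1)[:, ::-1]  # suffix group counts
    n = len(t_s)
    o_minus_e = np.zeros(len(cand))
    var = np.zeros(len(cand))
    ev_high = (G * e_s[None, :]).sum(axis=1)
    ev_total = e_s.sum()
    for tt in np.unique(t_s[e_s == 1]):
        i0 = np.searchsorted(t_s, tt, side="left")
        i1 = np.searchsorted(t_s, tt, side="right")
        n_at = n - i0
        d = int(e_s[i0:i1].sum())
        n1 = S[:, i0]
        d1 = (G[:, i0:i1] * e_s[i0:i1][None, :]).sum(axis=1)
        o_minus_e += d1 - d * n1 / n_at
        if n_at > 1:
            var += d * (n1 / n_at) * (1 - n1 / n_at) * (n_at - d) / (n_at - 1)
    valid = var > 0
    if not np.any(np.minimum(ev_high, ev_total - ev_high)[valid] > 0):
        raise ValueError("every candidate cutpoint leaves all events on one side")
    chi2 = np.where(valid, o_minus_e ** 2 / np.where(valid, var, 1.0), 0.0)
    n_high = S[:, 0]
    balance = np.abs(n - 2 * n_high)
    best = sorted(range(len(cand)), key=lambda i: (-chi2[i], balance[i], cand[i]))[0]
    return float(cand[best])


# ---------------------------------------------------------------------------
# the locked risk model

@dataclass
class RiskModel:
    """Locked-down linear risk score: coefficients, scaling and cutpoint."""

    selected: list[str]  # 12 feature names, 4 per family
    beta: np.ndarray  # LASSO-Cox coefficients (zeros retained)
    means: np.ndarray  # training standardization means
    sds: np.ndarray  # training standardization SDs
    theta_opt: float
    catalog_hash: str
    metadata: dict = field(default_factory=dict)

    def score(self, features: FeatureMatrix | pd.DataFrame) -> pd.Series:
        df = features.to_dataframe() if isinstance(features, FeatureMatrix) else features
        missing = [c for c in self.selected if c not in df.columns]
        if missing:
            raise ValueError(f"feature matrix lacks selected features {missing}")
        X = df[self.selected].to_numpy(dtype=float)
        X = np.where(np.isfinite(X), X, self.means)  # family-NA -> neutral
        z = (X - self.means) / self.sds
        return pd.Series(z @ self.beta, index=df.index, name="score")

    def predict(self, features: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
        s = self.score(features)
        return pd.DataFrame({
            "patient_id": s.index.astype(str),
            "score": s.to_numpy(),
            "group": np.where(s.to_numpy() > self.theta_opt, "high", "low"),
        }).reset_index(drop=True)

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "beta": [float(b) for b in self.beta],
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "theta_opt": float(self.theta_opt),
            "catalog_hash": self.catalog_hash,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(selected=list(d["selected"]), beta=np.array(d["beta"], float),
                   means=np.array(d["means"], float), sds=np.array(d["sds"], float),
                   theta_opt=float(d["theta_opt"]), catalog_hash=d["catalog_hash"],
                   metadata=dict(d.get("metadata", {})))


def fit_ibris(features: FeatureMatrix | pd.DataFrame, time, event,
              selected: list[str], seed: int = 0, n_folds: int = 5,
              alphas=None, catalog: FeatureCatalog | None = None) -> RiskModel:
    """LASSO-Cox over the screened features with CV-chosen penalty + cutpoint.

    The penalty path comes from the full-data coxnet fit (or an explicit
    ``alphas`` grid); lambda maximizes the summed held-out Breslow partial
    likelihood over ``n_folds`` folds split by ``seed``, restricted to
    penalties that keep at least one coefficient non-zero so the locked model
    always yields a usable score.  Zero coefficients are retained in the
    model record.
    """
    catalog = catalog or default_catalog()
    df = features.to_dataframe() if isinstance(features, FeatureMatrix) else features
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if e.sum() < 10:
        raise ValueError(f"need >= 10 events to fit, got {int(e.sum())}")
    X = df[selected].to_numpy(dtype=float)
    col_mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
    X = np.where(np.isfinite(X), X, col_mean)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    if (sds == 0).any():
        bad = [s for s, sd in zip(selected, sds) if sd == 0]
        raise ValueError(f"constant selected features {bad}")
    Z = (X - means) / sds
    y = Surv.from_arrays(event=e.astype(bool), time=t)

    if alphas is None:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=40)
    else:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas))
    path.fit(Z, y)
    alphas = np.asarray(path.alphas_)
    nonempty = (path.coef_ != 0).any(axis=0)
    if not nonempty.any():
        raise ValueError(
            "all coefficients shrunk to zero along the whole penalty path; "
            "refit with smaller alphas")
    alphas = alphas[nonempty]

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_pl = np.zeros(len(alphas))
    for train, test in kf.split(Z):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        m.fit(Z[train], y[train])
        fitted = np.asarray(m.alphas_)
        coefs = m.coef_  # (p, n_fitted)
        for i, a in enumerate(alphas):
            j = int(np.argmin(np.abs(fitted - a)))
            lp = Z[test] @ coefs[:, j]
            if e[test].sum() > 0:
                cv_pl[i] += breslow_partial_loglik(lp, t[test], e[test])
    best_alpha = float(alphas[int(np.argmax(cv_pl))])

    final = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[best_alpha],
                                   fit_baseline_model=False)
    final.fit(Z, y)
    beta = final.coef_[:, 0].copy()
    if np.all(beta == 0):
        raise ValueError(
            f"all coefficients shrunk to zero at lambda={best_alpha:.4g}; "
            "refit with a smaller penalty (alphas)")
    scores = Z @ beta
    theta = find_theta_opt(scores, t, e)
    return RiskModel(
        selected=list(selected), beta=beta, means=means, sds=sds, theta_opt=theta,
        catalog_hash=catalog.version_hash(),
        metadata={"n": int(len(t)), "n_events": int(e.sum()), "seed": int(seed),
                  "lambda": best_alpha, "n_folds": int(n_folds)},
    )


# ---------------------------------------------------------------------------
# statsmodels-style front end

class IbrisModel:
    """Prognostic model specification: features + outcomes + catalog.

    Parameters
    ----------
    features : FeatureMatrix or DataFrame (patients x catalog features)
    time, event : disease-free survival outcome arrays aligned to features
    catalog : feature catalog (defaults to the shipped 343-entry catalog)
    """

    def __init__(self, features: FeatureMatrix | pd.DataFrame, time, event,
                 catalog: FeatureCatalog | None = None) -> None:
        self.catalog = catalog or default_catalog()
        self.features = (features.to_dataframe()
                         if isinstance(features, FeatureMatrix) else features.copy())
        self.time = np.asarray(time, dtype=float)
        self.event = np.asarray(event, dtype=int)
        if len(self.time) != len(self.features) or len(self.event) != len(self.features):
            raise ValueError("features and outcomes must be aligned")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, duration_col: str = "dfs_time",
                       event_col: str = "event",
                       catalog: FeatureCatalog | None = None) -> "IbrisModel":
        catalog = catalog or default_catalog()
        feats = df[[c for c in df.columns if c in set(catalog.names)]]
        return cls(feats, df[duration_col], df[event_col], catalog)

    def fit(self, k_per_family: int = 4, seed: int = 0, n_folds: int = 5
            ) -> "IbrisResults":
        screened: dict[str, list[str]] = {}
        for family in ("nuclear", "mitotic", "tubule"):
            screened[family] = screen_top_features(
                self.features, self.time, self.event,
                self.catalog.family_names(family), k=k_per_family)
        selected = [n for fam in ("nuclear", "mitotic", "tubule") for n in screened[fam]]
        risk_model = fit_ibris(self.features, self.time, self.event, selected,
                               seed=seed, n_folds=n_folds, catalog=self.catalog)
        return IbrisResults(self, risk_model, screened)


class IbrisResults:
    """Fitted risk model with coefficients, cutpoint and prediction methods."""

    def __init__(self, model: IbrisModel, risk_model: RiskModel,
                 screened: dict[str, list[str]]) -> None:
        self.model = model
        self.risk_model = risk_model
        self.screened = screened

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.risk_model.beta, index=self.risk_model.selected,
                         name="coef")

    @property
    def theta_opt(self) -> float:
        return self.risk_model.theta_opt

    def predict(self, features: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
        return self.risk_model.predict(features)

    def summary(self) -> str:
        md = self.risk_model.metadata
        lines = [
            "Image-based risk score (LASSO-Cox)",
            "=" * 58,
            f"n = {md.get('n')}    events = {md.get('n_events')}    "
            f"lambda = {md.get('lambda'):.4g}    folds = {md.get('n_folds')}",
            f"theta_opt = {self.risk_model.theta_opt:.4f}   "
            "(high risk iff score > theta_opt)",
            "-" * 58,
            f"{'feature':<38}{'family':<10}{'coef':>9}",
        ]
        for name, b in self.coefficients.items():
            lines.append(f"{name:<38}{self.model.catalog.family_of(name):<10}{b:>9.4f}")
        nz = int(np.sum(self.risk_model.beta != 0))
        lines.append("-" * 58)
        lines.append(f"{nz} non-zero of {len(self.risk_model.beta)} selected features")
        return "\n".join(lines)

    def save(self, path) -> None:
        from .io import save_model
        save_model(self.risk_model, path)
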