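"""End-to-end phantom validation harness.

Runs the whole pipeline — simulate a training phantom cohort, extract the
343 features, screen 4 per family, fit the LASSO-Cox score, lock theta_opt,
then score an independent phantom test cohort — and reports the held-out
risk-group separation.  Used by the parameter-recovery and null-calibration
studies; problem sizes are scaled to small tiles so replicated runs stay
cheap (see the methods note).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .aggregation import extract_features
from .datatypes import PatientCase
from .model import IbrisModel
from .phantom import PhantomConfig, simulate_cohort
from .survival import cox_fit, logrank_test

#: phantom settings for replicated Monte-Carlo validation runs: small tiles,
#: one tile per patient, ~25 nuclei per tile
MC_PHANTOM = dict(tiles_per_patient=1, tile_side_px=112, nuclei_density=25,
                  nucleus_radius_px=5.0)


def _outcomes(cohort: list[PatientCase]) -> tuple[np.ndarray, np.ndarray]:
    return (np.array([c.dfs_time for c in cohort]),
            np.array([c.event for c in cohort], dtype=int))


def phantom_validation_run(seed: int, planted_effect: dict | None = None,
                           n_train: int = 300, n_test: int = 150,
                           censor_rate: float = 0.2,
                           phantom_overrides: dict | None = None) -> dict:
    """One seeded train/validate cycle on independent phantom cohorts.

    Returns the held-out hazard ratio and log-rank p of the locked model's
    high- vs low-risk groups, plus the screened feature names.
    """
    planted_effect = dict(planted_effect or {})
    overrides = dict(MC_PHANTOM)
    overrides.update(phantom_overrides or {})
    train_cfg = PhantomConfig(n_patients=n_train, planted_effect=planted_effect,
                              censor_rate=censor_rate, seed=seed, **overrides)
    test_cfg = PhantomConfig(n_patients=n_test, planted_effect=planted_effect,
                             censor_rate=censor_rate, seed=seed + 1_000_003,
                             **overrides)
    train = simulate_cohort(train_cfg)
    fm_train = extract_features(train)
    t_tr, e_tr = _outcomes(train)
    results = IbrisModel(fm_train, t_tr, e_tr).fit(seed=seed)

    test = simulate_cohort(test_cfg)
    fm_test = extract_features(test)
    t_te, e_te = _outcomes(test)
    pred = results.predict(fm_test)
    hi = (pred["group"] == "high").to_numpy()

    out: dict = {
        "seed": seed,
        "screened": results.screened,
        "selected": results.risk_model.selected,
        "n_nonzero_coef": int(np.sum(results.risk_model.beta != 0)),
        "theta_opt": results.theta_opt,
        "n_train": n_train,
        "n_test": n_test,
        "n_test_high": int(hi.sum()),
        "train_censored_fraction": float(1.0 - e_tr.mean()),
    }
    if 0 < hi.sum() < len(hi) and e_te.sum() > 0:
        lr = logrank_test(t_te, e_te, hi)
        out["logrank_chi2"], out["logrank_p"] = lr["chi2"], lr["p"]
        try:
            hr = cox_fit(t_te, e_te, pd.DataFrame({"risk_high": hi.astype(float)})
                         )["risk_high"]
            out["hazard_ratio"] = dataclasses.asdict(hr)
        except (ValueError, RuntimeError):
            out["hazard_ratio"] = None
    else:
        out["logrank_chi2"] = out["logrank_p"] = None
        out["hazard_ratio"] = None
    return out


def recovery_study(seeds, planted_effect: dict | None = None, **kwargs) -> dict:
    """Replicate :func:`phantom_validation_run` and summarize the hit rate.

    A replicate is a success when the held-out high-risk group has hazard
    ratio > 1 and two-sided log-rank p < 0.05.
    """
    planted_effect = planted_effect if planted_effect is not None else {"mitotic": 1.0}
    runs = [phantom_validation_run(int(s), planted_effect, **kwargs) for s in seeds]
    hits = sum(1 for r in runs
               if r["hazard_ratio"] is not None and r["hazard_ratio"]["hr"] > 1
               and r["logrank_p"] is not None and r["logrank_p"] < 0.05)
    return {"runs": runs, "n_seeds": len(runs), "n_success": hits,
            "success_rate": hits / len(runs) if runs else float("nan")}
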