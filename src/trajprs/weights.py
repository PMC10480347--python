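"""Inverse-probability-of-response weights and posterior-probability weights.

Subjects with no post-deployment assessments cannot enter the trajectory
model; dropping them silently would bias downstream association estimates if
response is related to risk factors.  The remedy implemented here:

1. estimate each subject's probability of responding (completing at least one
   post-deployment assessment) from pre-deployment severity, exposure flags,
   polygenic scores and ancestry components, using a cross-fitted stacked
   ensemble (regularized logistic and gradient-boosted-tree base learners
   combined by a logistic meta-learner) so every subject gets an out-of-fold
   prediction;
2. weight responders by the inverse of that probability (optionally truncated
   at configurable quantiles to guard against unstable extremes);
3. multiply each responder's inverse probability weight by its posterior
   trajectory-class probabilities, yielding one record per class for the
   probability-weighted multinomial regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler


def _base_learners(seed: int, fast: bool):
    logit = make_pipeline(
        StandardScaler(),
        LogisticRegression(C=1.0, max_iter=2000, random_state=seed),
    )
    gbt = HistGradientBoostingClassifier(
        max_iter=40 if fast else 150,
        max_depth=3,
        learning_rate=0.15 if fast else 0.08,
        random_state=seed,
    )
    return [("logistic", logit), ("gbt", gbt)]


def estimate_response_propensity(
    features: pd.DataFrame,
    responded: np.ndarray,
    *,
    folds: int = 5,
    inner_folds: int = 5,
    seed: int = 0,
    method: str = "stack",
) -> np.ndarray:
    """Cross-fitted response propensities from a stacked ensemble.

    Each subject's prediction comes from models trained without that subject
    (outer K-fold).  Within each outer training set, the logistic meta-learner
    is trained on inner out-of-fold predictions of the base learners, then the
    base learners are refit on the full training set to score the held-out
    fold.  ``method='logistic'`` skips the ensemble and cross-fits a single
    regularized logistic model (useful for fast simulations).

    Raises if the response indicator is constant or ``folds < 2``.
    """
    X = np.asarray(features, dtype=float)
    r = np.asarray(responded).astype(int)
    if folds < 2 or inner_folds < 2:
        raise ValueError("folds must be >= 2")
    if len(np.unique(r)) < 2:
        raise ValueError("response indicator is constant; propensities are not estimable")
    if method not in {"stack", "logistic"}:
        raise ValueError("method must be 'stack' or 'logistic'")

    out = np.empty(len(r))
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold_id, (tr, te) in enumerate(outer.split(X, r)):
        Xtr, rtr = X[tr], r[tr]
        if method == "logistic":
            model = _base_learners(seed + fold_id, fast=True)[0][1]
            model.fit(Xtr, rtr)
            out[te] = model.predict_proba(X[te])[:, 1]
            continue
        bases = _base_learners(seed + fold_id, fast=True)
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                random_state=seed + 100 + fold_id)
        oof = np.zeros((len(tr), len(bases)))
        for itr, ite in inner.split(Xtr, rtr):
            for j, (_, mdl) in enumerate(bases):
                mdl.fit(Xtr[itr], rtr[itr])
                oof[ite, j] = mdl.predict_proba(Xtr[ite])[:, 1]
        meta = LogisticRegression(max_iter=2000, random_state=seed)
        meta.fit(oof, rtr)
        level1 = np.column_stack([
            mdl.fit(Xtr, rtr).predict_proba(X[te])[:, 1] for _, mdl in bases
        ])
        out[te] = meta.predict_proba(level1)[:, 1]
    return np.clip(out, 1e-6, 1.0 - 1e-6)


def ipw_from_propensity(
    propensities: np.ndarray,
    truncation_quantiles: tuple[float, float] | None = (0.01, 0.99),
) -> np.ndarray:
    """Inverse probability weights ``1 / p``, truncated at weight quantiles.

    Truncation (default 1st/99th percentile of the weights) caps unstable
    extremes; pass ``None`` to disable.
    """
    p = np.asarray(propensities, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("propensities must lie in (0, 1]")
    w = 1.0 / p
    if truncation_quantiles is not None:
        lo, hi = np.quantile(w, truncation_quantiles)
        w = np.clip(w, lo, hi)
    return w


def combine_weights(posterior: pd.DataFrame, ipw: pd.DataFrame) -> pd.DataFrame:
    """Expand responders to one record per class with weight ``p_ik * w_i``.

    ``posterior`` has a ``subject_id`` column plus ``class1..classK``; ``ipw``
    has ``subject_id`` and ``ipw``.  Per subject the combined weights sum to
    the subject's inverse probability weight, conserving total weight mass.
    """
    class_cols = [c for c in posterior.columns if c.startswith("class")]
    merged = posterior.merge(ipw[["subject_id", "ipw"]], on="subject_id",
                             how="inner", validate="one_to_one")
    if len(merged) != len(posterior):
        missing = set(posterior["subject_id"]) - set(merged["subject_id"])
        raise ValueError(f"no IPW for subjects {sorted(missing)[:5]}...")
    K = len(class_cols)
    rows = {
        "subject_id": np.repeat(merged["subject_id"].to_numpy(), K),
        "class_k": np.tile(np.arange(1, K + 1), len(merged)),
        "posterior": merged[class_cols].to_numpy().ravel(),
        "ipw": np.repeat(merged["ipw"].to_numpy(), K),
    }
    out = pd.DataFrame(rows)
    out["weight"] = out["posterior"] * out["ipw"]
    return out


def build_weight_set(
    cohort: pd.DataFrame,
    long: pd.DataFrame,
    posterior: pd.DataFrame,
    *,
    feature_columns: list[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    method: str = "stack",
    truncation_quantiles: tuple[float, float] | None = (0.01, 0.99),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end weighting: propensities, IPW and expanded combined weights.

    Returns ``(subject_table, expanded)`` where ``subject_table`` holds each
    subject's response indicator, propensity and (for responders) IPW, and
    ``expanded`` is the per-subject-by-class weight table for regression.
    """
    from .datagen import PRS_COLUMNS, PTE_COLUMNS  # default feature set

    post = long[long["wave"] >= 1]
    n_post = post.groupby("subject_id")["observed"].sum()
    responded = (
        n_post.reindex(cohort["subject_id"]).fillna(0).to_numpy() > 0
    ).astype(int)
    pre = (
        long[long["wave"] == 0]
        .set_index("subject_id")["harmonized"]
        .reindex(cohort["subject_id"])
        .to_numpy()
    )
    if feature_columns is None:
        feature_columns = list(PTE_COLUMNS) + list(PRS_COLUMNS) + [f"pc{j}" for j in range(1, 11)]
    feats = cohort[feature_columns].copy()
    feats.insert(0, "pre_severity", pre)
    prop = estimate_response_propensity(feats, responded, folds=folds,
                                        seed=seed, method=method)
    subject = pd.DataFrame({
        "subject_id": cohort["subject_id"],
        "responded": responded,
        "response_propensity": prop,
    })
    resp = subject[subject["responded"] == 1].copy()
    resp["ipw"] = ipw_from_propensity(
        resp["response_propensity"].to_numpy(), truncation_quantiles
    )
    subject = subject.merge(resp[["subject_id", "ipw"]], on="subject_id", how="left")
    expanded = combine_weights(posterior, resp)
    return subject, expanded
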