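"""Probability-weighted multinomial association analysis.

Each polygenic risk score (PRS) is tested against trajectory membership in a
weighted multinomial logistic regression: responders contribute one record
per trajectory class, weighted by posterior class probability times inverse
probability of response weight, adjusting for sex, age, eight exposure flags
and ten ancestry principal components.  The low-severity class is the
reference outcome.  Standard errors are cluster-robust by subject (each
subject appears in K records), which also guards against the tendency of
probability-weighted regression to understate uncertainty; per-PRS omnibus
Wald tests, pairwise adjusted odds ratios (AORs) with 95% confidence
intervals, quartile AORs and a Bonferroni threshold complete the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._multinomial import MultinomialFit, fit_multinomial
from .datagen import PTE_COLUMNS

#: default adjustment set for the association models
DEFAULT_COVARIATES: tuple[str, ...] = ("age", "male") + PTE_COLUMNS + tuple(
    f"pc{j}" for j in range(1, 11)
)

Z95 = stats.norm.ppf(0.975)


@dataclass
class AssocResult:
    """Fitted weighted multinomial model for one exposure of interest."""

    prs_name: str
    classes: int
    coef: np.ndarray            # (K-1, p); outcome reference = class 1
    cov: np.ndarray             # covariance of vec(coef), class-major
    column_names: list[str]
    exposure_cols: list[int]    # design column indices of the exposure terms
    fit: MultinomialFit
    robust: bool

    @property
    def n_coef_per_class(self) -> int:
        return self.coef.shape[1]

    def _flat_index(self, class_k: int, col: int) -> int:
        # class_k in 2..K maps to equation class_k - 2
        return (class_k - 2) * self.n_coef_per_class + col


def _design(records: pd.DataFrame, cohort: pd.DataFrame, exposure: list[str],
            covariates: list[str]) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    sub = cohort.set_index("subject_id")
    need = exposure + [c for c in covariates if c not in exposure]
    merged = records.merge(sub[need], left_on="subject_id", right_index=True, how="left")
    names = ["const"] + need
    X = np.column_stack([np.ones(len(merged))] + [merged[c].to_numpy(float) for c in need])
    return X, names, merged


def fit_weighted_multinomial(
    expanded: pd.DataFrame,
    cohort: pd.DataFrame,
    prs_name: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    *,
    robust: bool = True,
    min_weight: float = 1e-10,
    exposure_columns: list[str] | None = None,
) -> AssocResult:
    """Fit class membership on one PRS plus covariates with record weights.

    ``expanded`` must carry ``subject_id``, ``class_k`` (1..K) and ``weight``
    (posterior probability times IPW).  Records with negligible weight are
    dropped; clusters are subjects.
    """
    exposure = exposure_columns if exposure_columns is not None else [prs_name]
    rec = expanded[expanded["weight"] > min_weight].reset_index(drop=True)
    X, names, merged = _design(rec, cohort, exposure, list(covariates))
    y = merged["class_k"].to_numpy(int) - 1
    K = int(merged["class_k"].max())
    w = merged["weight"].to_numpy(float)
    fit = fit_multinomial(
        X, y, sample_weight=w, clusters=merged["subject_id"].to_numpy(),
        column_names=names,
    )
    if fit.separation:
        raise RuntimeError(f"separation detected fitting {prs_name}: unbounded coefficients")
    cov = fit.cov_robust if robust else fit.cov_model
    exp_cols = [names.index(c) for c in exposure]
    return AssocResult(prs_name=prs_name, classes=K, coef=fit.coef, cov=cov,
                       column_names=names, exposure_cols=exp_cols, fit=fit,
                       robust=robust)


def omnibus_test(result: AssocResult, column: int | None = None) -> dict:
    """Joint Wald chi-square of the exposure coefficients over the K-1
    non-reference equations (df = K-1)."""
    col = result.exposure_cols[0] if column is None else column
    idx = [result._flat_index(k, col) for k in range(2, result.classes + 1)]
    c = result.coef.ravel()[idx]
    V = result.cov[np.ix_(idx, idx)]
    try:
        stat = float(c @ np.linalg.solve(V, c))
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular covariance block in omnibus test")
    df = len(idx)
    return {"statistic": stat, "df": df, "p_value": float(stats.chi2.sf(stat, df))}


def pairwise_aor(result: AssocResult, class_a: int, class_b: int,
                 column: int | None = None) -> dict:
    """Adjusted odds ratio of membership in ``class_a`` vs ``class_b`` per
    unit (SD) of the exposure, with a delta-method 95% CI.

    The contrast is ``coef_a - coef_b`` with the reference class contributing
    zero, so AORs are consistent across reference choices and satisfy
    AOR(a,b) * AOR(b,a) = 1.
    """
    if class_a == class_b:
        raise ValueError("classes must differ")
    col = result.exposure_cols[0] if column is None else column
    v = np.zeros(result.cov.shape[0])
    if class_a != 1:
        v[result._flat_index(class_a, col)] += 1.0
    if class_b != 1:
        v[result._flat_index(class_b, col)] -= 1.0
    est = float(v @ result.coef.ravel())
    se = float(np.sqrt(v @ result.cov @ v))
    return {
        "log_aor": est,
        "aor": float(np.exp(est)),
        "ci_low": float(np.exp(est - Z95 * se)),
        "ci_high": float(np.exp(est + Z95 * se)),
        "se": se,
    }


def aor_table(result: AssocResult, class_labels: dict[int, str] | None = None) -> pd.DataFrame:
    """All pairwise AORs, higher-severity class first within each pair."""
    rows = []
    for b, a in combinations(range(1, result.classes + 1), 2):
        r = pairwise_aor(result, a, b)
        rows.append({
            "prs": result.prs_name,
            "class_a": class_labels.get(a, f"class{a}") if class_labels else f"class{a}",
            "class_b": class_labels.get(b, f"class{b}") if class_labels else f"class{b}",
            "aor": r["aor"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
            "excludes_1": bool(r["ci_low"] > 1.0 or r["ci_high"] < 1.0),
        })
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold ``alpha / m``, reported to 4 decimals."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return round(alpha / m, 4)


def quartile_bins(values: np.ndarray) -> np.ndarray:
    """Sample quartile labels 1..4 with ties broken by stable rank order."""
    n = len(values)
    ranks = np.empty(n, dtype=int)
    ranks[np.argsort(values, kind="stable")] = np.arange(n)
    return 1 + (4 * ranks) // n


def quartile_aor(
    expanded: pd.DataFrame,
    cohort: pd.DataFrame,
    prs_name: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    *,
    robust: bool = True,
) -> pd.DataFrame:
    """AORs of PRS quartiles 2-4 vs quartile 1 for every class pair.

    Refits the weighted multinomial with three quartile indicator columns in
    place of the continuous score.
    """
    work = cohort.copy()
    q = quartile_bins(work[prs_name].to_numpy(float))
    qcols = []
    for j in (2, 3, 4):
        cname = f"{prs_name}_q{j}"
        work[cname] = (q == j).astype(float)
        qcols.append(cname)
    res = fit_weighted_multinomial(
        expanded, work, prs_name, covariates, robust=robust, exposure_columns=qcols,
    )
    rows = []
    for b, a in combinations(range(1, res.classes + 1), 2):
        for j, cname in zip((2, 3, 4), qcols):
            col = res.column_names.index(cname)
            r = pairwise_aor(res, a, b, column=col)
            rows.append({
                "prs": prs_name, "quartile": j,
                "class_a": f"class{a}", "class_b": f"class{b}",
                "aor": r["aor"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
            })
    return pd.DataFrame(rows)


def compare_new_pte_rates(
    classified: pd.DataFrame,
    cohort: pd.DataFrame,
    *,
    correction: bool = False,
) -> pd.DataFrame:
    """Pairwise chi-square comparisons of new-exposure rates across classes.

    ``classified`` carries ``subject_id`` and ``assigned_class``; the binary
    ``new_pte`` flag comes from the cohort table.  No continuity correction by
    default (configurable).
    """
    merged = classified.merge(cohort[["subject_id", "new_pte"]], on="subject_id")
    rows = []
    for a, b in combinations(sorted(merged["assigned_class"].unique()), 2):
        sub = merged[merged["assigned_class"].isin([a, b])]
        table = pd.crosstab(sub["assigned_class"], sub["new_pte"])
        if table.shape != (2, 2) or (table.sum(axis=1) == 0).any():
            raise ValueError(f"empty class in pair ({a}, {b})")
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=correction)
        ra = merged.loc[merged["assigned_class"] == a, "new_pte"].mean()
        rb = merged.loc[merged["assigned_class"] == b, "new_pte"].mean()
        rows.append({"class_a": a, "class_b": b, "rate_a": ra, "rate_b": rb,
                     "chi2": float(chi2), "p_value": float(p)})
    return pd.DataFrame(rows)
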