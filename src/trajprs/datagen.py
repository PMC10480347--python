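"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a combat-deployed cohort assessed for
posttraumatic stress symptoms at four waves — pre-deployment, post-deployment
(time 0) and two follow-ups (~2.4 and ~11.8 months later) — with:

* four latent trajectory classes (low / increasing / decreasing / high
  severity) with configurable prevalences, linear within-class trajectories on
  the percent-of-maximum symptom scale, and a random intercept/slope
  covariance shared across classes;
* six standardized polygenic risk scores (PRS) whose effects on class
  membership are configurable per-SD log odds ratios against the low-severity
  reference class;
* demographic covariates, 10 ancestry principal components and 8 binary
  exposure flags with realistic marginal prevalences;
* wave-specific abbreviated instruments (6/5/17/17 items, each item rated
  0-4), so the raw totals live on different scales and must be harmonized;
* unit nonresponse (no post-deployment assessments at all) plus wave-level
  missingness at random (MAR) driven by pre-deployment severity, calibrated so
  the shares of responders observed at 3/2/1 post-deployment waves match
  configured targets.

All draws flow from a single integer seed; identical configurations produce
identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root
from scipy.special import expit, softmax

from .harmonize import ITEM_MAX, WAVE_ITEM_COUNTS

PRS_COLUMNS = ("prs_ptsd", "prs_mdd", "prs_scz", "prs_neu", "prs_aud", "prs_sa")
PTE_COLUMNS = (
    "pte_lifetime",
    "pte_prior_deploy",
    "pte_combat_patrol",
    "pte_take_fire",
    "pte_wounded",
    "pte_unit_casualty",
    "pte_saw_dead",
    "pte_other_stress",
)
#: marginal prevalences of the exposure flags, in PTE_COLUMNS order
PTE_PREVALENCES = (0.806, 0.473, 0.805, 0.730, 0.095, 0.709, 0.670, 0.837)

CLASS_LABELS = ("low", "increasing", "decreasing", "high")


class CalibrationError(RuntimeError):
    """A calibration root-solve did not converge; carries the residual."""

    def __init__(self, what: str, residual: float):
        super().__init__(f"{what} calibration failed; max residual {residual:.3g}")
        self.residual = residual


def _default_prs_logor() -> np.ndarray:
    """Per-SD log odds of membership in classes 2..4 vs the low class.

    Rows follow PRS_COLUMNS; columns are (increasing, decreasing, high).
    Defaults encode the reported significant per-SD odds ratios: PTSD-PRS
    1.12 (increasing) and 1.23 (high); MDD-PRS 1.16, 1.16 and 1.18.  The
    remaining scores have null effects.
    """
    lor = np.zeros((6, 3))
    lor[0] = [np.log(1.12), 0.0, np.log(1.23)]          # PTSD-PRS
    lor[1] = [np.log(1.16), np.log(1.16), np.log(1.18)]  # MDD-PRS
    return lor


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_subjects: int = 4900
    class_shares: tuple[float, ...] = (0.772, 0.105, 0.080, 0.043)
    # percent-of-maximum scale at time 0 (post-deployment)
    class_intercepts: tuple[float, ...] = (12.0, 18.0, 45.0, 55.0)
    # percent per month
    class_slopes: tuple[float, ...] = (-0.3, 2.5, -2.8, 0.0)
    # shared random intercept/slope covariance (percent, percent/month)
    re_cov: tuple[tuple[float, float], tuple[float, float]] = ((4.84, 0.0), (0.0, 0.0144))
    resid_sd: float = 2.2
    prs_class_logor: np.ndarray = field(default_factory=_default_prs_logor)
    # class-membership log odds for (age_z, male, 8 PTE flags); default null
    covariate_class_logor: np.ndarray = field(default_factory=lambda: np.zeros((10, 3)))
    # follow-up assessment months after post-deployment: mean, sd
    followup_times: tuple[tuple[float, float], ...] = ((2.38, 0.62), (11.76, 1.74))
    pre_time_months: float = -9.0
    wave_item_counts: tuple[int, ...] = WAVE_ITEM_COUNTS
    # MAR slope on pre-deployment harmonized score (logit of missingness
    # per percent point) and target responder shares
    mar_coef: float = 0.03
    target_complete_share: float = 0.594
    target_one_missing_share: float = 0.295
    target_post_only_share: float = 0.035
    unit_nonresponse_rate: float = 0.1114
    # optional severity dependence of unit nonresponse (logit slope per
    # percent point of pre-deployment score; 0 = nonresponse independent)
    unit_mar_coef: float = 0.0
    # class-conditional probability of reporting a new exposure during
    # follow-up (low, increasing, decreasing, high)
    new_pte_rates: tuple[float, ...] = (0.348, 0.636, 0.506, 0.638)
    age_mean: float = 25.9
    age_sd: float = 5.9
    male_share: float = 0.945
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return len(self.class_shares)

    def validate(self) -> None:
        shares = np.asarray(self.class_shares, dtype=float)
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if abs(shares.sum() - 1.0) > 1e-12 or (shares <= 0).any():
            raise ValueError("class_shares must be positive and sum to 1")
        K = self.n_classes
        if not (len(self.class_intercepts) == len(self.class_slopes) == K):
            raise ValueError("class parameter vectors must match class_shares length")
        cov = np.asarray(self.re_cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T):
            raise ValueError("re_cov must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError("re_cov must be positive semi-definite")
        if self.resid_sd <= 0:
            raise ValueError("resid_sd must be positive")
        lor = np.asarray(self.prs_class_logor, dtype=float)
        if lor.shape != (len(PRS_COLUMNS), K - 1):
            raise ValueError(f"prs_class_logor must be {len(PRS_COLUMNS)}x{K - 1}")
        if not 0.0 <= self.unit_nonresponse_rate < 1.0:
            raise ValueError("unit_nonresponse_rate must be in [0, 1)")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def _membership_design(cohort: pd.DataFrame) -> np.ndarray:
    """Covariate matrix whose columns pair with covariate_class_logor rows."""
    age_z = (cohort["age"].to_numpy() - cohort["age"].mean()) / max(cohort["age"].std(), 1e-12)
    cols = [age_z, cohort["male"].to_numpy(dtype=float)]
    cols += [cohort[c].to_numpy(dtype=float) for c in PTE_COLUMNS]
    return np.column_stack(cols)


def assign_classes(cohort: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample a latent trajectory class per subject from a multinomial logit.

    Class 1 (low severity) is the reference.  The intercepts of the
    non-reference classes are calibrated by root-solving so the cohort-average
    class probabilities equal ``class_shares`` exactly; the configured per-SD
    PRS log odds then hold conditionally on the covariates.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    K = config.n_classes
    shares = np.asarray(config.class_shares, dtype=float)
    if K == 1:
        out = cohort.copy()
        out["true_class"] = 1
        out["new_pte"] = (rng.random(len(cohort))
                          < config.new_pte_rates[0]).astype(int)
        return out
    Xp = cohort[list(PRS_COLUMNS)].to_numpy(dtype=float)
    Xc = _membership_design(cohort)
    base = Xp @ np.asarray(config.prs_class_logor, float) + Xc @ np.asarray(config.covariate_class_logor, float)

    def mean_probs(alpha: np.ndarray) -> np.ndarray:
        eta = np.column_stack([np.zeros(len(cohort)), base + alpha])
        return softmax(eta, axis=1).mean(axis=0)

    def residual(alpha: np.ndarray) -> np.ndarray:
        return mean_probs(alpha)[1:] - shares[1:]

    alpha0 = np.log(shares[1:] / shares[0])
    sol = root(residual, alpha0, method="hybr", tol=1e-12)
    resid = float(np.abs(residual(sol.x)).max())
    if resid > 1e-8:
        raise CalibrationError("class-share", resid)
    eta = np.column_stack([np.zeros(len(cohort)), base + sol.x])
    probs = softmax(eta, axis=1)
    u = rng.random(len(cohort))
    true_class = 1 + (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    out = cohort.copy()
    out["true_class"] = np.minimum(true_class, K).astype(int)
    rates = np.asarray(config.new_pte_rates, dtype=float)
    out["new_pte"] = (rng.random(len(cohort)) < rates[out["true_class"] - 1]).astype(int)
    return out


def draw_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the subject-level table: demographics, exposures, PCs, PRS, class."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cohort = pd.DataFrame({"subject_id": np.arange(1, n + 1)})
    cohort["age"] = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, None)
    cohort["male"] = (rng.random(n) < config.male_share).astype(int)
    for j in range(1, 11):
        cohort[f"pc{j}"] = rng.normal(size=n)
    for col, prev in zip(PTE_COLUMNS, PTE_PREVALENCES):
        cohort[col] = (rng.random(n) < prev).astype(int)
    for col in PRS_COLUMNS:
        z = rng.normal(size=n)
        cohort[col] = (z - z.mean()) / z.std()  # standardized within sample
    return assign_classes(cohort, config, rng=np.random.default_rng(config.seed + 1))


def simulate_trajectories(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Generate the long-format measurement table (all waves observed).

    Each subject's harmonized trajectory is the class line plus a subject
    random intercept/slope deviation plus residual noise, clipped to the
    attainable [0, 100] range; raw totals are back-computed on each wave's
    instrument scale.  The pre-deployment score evaluates the same subject
    line at a pseudo-time before deployment, giving the missingness mechanism
    a real predictor.
    """
    config.validate()
    if "true_class" not in cohort.columns:
        raise ValueError("cohort must have true_class; run assign_classes first")
    rng = np.random.default_rng(config.seed + 2)
    n = len(cohort)
    k = cohort["true_class"].to_numpy(dtype=int) - 1
    icpt = np.asarray(config.class_intercepts, float)[k]
    slope = np.asarray(config.class_slopes, float)[k]

    # eigen square root handles semi-definite covariances (e.g. no random slope)
    evals, evecs = np.linalg.eigh(np.asarray(config.re_cov, float))
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))
    b = rng.normal(size=(n, 2)) @ L.T  # (b0, b1)

    n_waves = len(config.wave_item_counts)
    times = np.empty((n, n_waves))
    times[:, 0] = config.pre_time_months
    times[:, 1] = 0.0
    prev = np.zeros(n)
    for w, (mu, sd) in enumerate(config.followup_times, start=2):
        t = rng.normal(mu, sd, n)
        prev = np.maximum(t, prev + 0.25)  # keep follow-ups strictly increasing
        times[:, w] = prev

    eps = rng.normal(0.0, config.resid_sd, size=(n, n_waves))
    mean = (icpt + b[:, 0])[:, None] + (slope + b[:, 1])[:, None] * times
    harmonized = np.clip(mean + eps, 0.0, 100.0)

    items = np.asarray(config.wave_item_counts, float)
    rows = {
        "subject_id": np.repeat(cohort["subject_id"].to_numpy(), n_waves),
        "wave": np.tile(np.arange(n_waves), n),
        "time_months": times.ravel(),
        "raw_total": (harmonized * ITEM_MAX * items / 100.0).ravel(),
        "n_items": np.tile(items, n).astype(int),
        "harmonized": harmonized.ravel(),
        "observed": np.ones(n * n_waves, dtype=int),
    }
    return pd.DataFrame(rows)


def _pattern_table() -> np.ndarray:
    """The 8 observation patterns over the three post-deployment waves."""
    return np.array([[(i >> w) & 1 for w in range(3)] for i in range(8)], dtype=float)


def _pattern_probs_given_miss(miss: np.ndarray) -> np.ndarray:
    """Pattern probabilities from (n, 3) per-wave missingness probabilities."""
    pat = _pattern_table()
    obs_p = np.where(pat[None, :, :] == 1, 1.0 - miss[:, None, :], miss[:, None, :])
    return obs_p.prod(axis=2)  # (n, 8)


def _conditional_pattern_probs(x: np.ndarray, a_post: float, a_fu: float, tau: float,
                               n_quad: int = 21) -> np.ndarray:
    """Per-subject pattern probabilities, given >=1 wave observed.

    Wave-level missingness follows ``logit m_iw = a_w + x_i + u_i`` with a
    shared normal frailty ``u_i ~ N(0, tau^2)`` inducing the within-subject
    correlation seen in real attrition; the frailty is integrated out by
    Gauss-Hermite quadrature.  ``x`` is the (centered, scaled) severity term.
    """
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_quad)
    wts = wts / wts.sum()
    a = np.array([a_post, a_fu, a_fu])
    probs = np.zeros((len(x), 8))
    for z, w in zip(nodes, wts):
        miss = expit(a[None, :] + x[:, None] + tau * z)
        probs += w * _pattern_probs_given_miss(miss)
    probs[:, 0] = 0.0  # condition on responding at least once
    probs /= probs.sum(axis=1, keepdims=True)
    return probs


def apply_missingness(long: pd.DataFrame, cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Impose unit nonresponse and MAR wave-level dropout on the long table.

    A fraction ``unit_nonresponse_rate`` of subjects loses all three
    post-deployment waves.  The remaining responders keep at least one wave;
    each wave's missingness follows a logit linear in the pre-deployment
    harmonized score with slope ``mar_coef`` and wave intercepts calibrated so
    the expected responder shares with 3, 2 and 1 observed waves — and the
    share observed at post-deployment only — match the configured targets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    n = len(cohort)
    pre = (
        long.loc[long["wave"] == 0]
        .set_index("subject_id")["harmonized"]
        .reindex(cohort["subject_id"])
        .to_numpy()
    )
    x = config.mar_coef * (pre - pre.mean())

    t3 = config.target_complete_share
    t2 = config.target_one_missing_share
    tpost = config.target_post_only_share
    pat = _pattern_table()
    n_obs = pat.sum(axis=1)
    post_only = np.all(pat == np.array([1.0, 0.0, 0.0]), axis=1)

    if config.unit_mar_coef != 0.0 and config.unit_nonresponse_rate > 0.0:
        xu = config.unit_mar_coef * (pre - pre.mean())
        sol_u = root(lambda a: expit(a + xu).mean() - config.unit_nonresponse_rate,
                     np.log(config.unit_nonresponse_rate / (1 - config.unit_nonresponse_rate)),
                     method="hybr", tol=1e-12)
        p_unit = expit(sol_u.x[0] + xu)
    else:
        p_unit = np.full(n, config.unit_nonresponse_rate)
    unit = rng.random(n) < p_unit
    if t3 >= 1.0:
        # completer share target of 1 switches wave-level dropout off
        observed_waves = np.ones((n, 3), dtype=bool)
    else:
        def shares(theta: np.ndarray) -> np.ndarray:
            probs = _conditional_pattern_probs(x, theta[0], theta[1], np.exp(theta[2]))
            m = probs.mean(axis=0)
            return np.array([m[n_obs == 3].sum(), m[n_obs == 2].sum(), m[post_only].sum()])

        target = np.array([t3, t2, tpost])
        sol = root(lambda th: shares(th) - target, np.array([-2.0, -1.5, 0.0]),
                   method="hybr", tol=1e-13)
        resid = float(np.abs(shares(sol.x) - target).max())
        if resid > 1e-6:
            raise CalibrationError("missingness", resid)
        probs = _conditional_pattern_probs(x, sol.x[0], sol.x[1], np.exp(sol.x[2]))
        u = rng.random(n)
        pattern_idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        observed_waves = pat[pattern_idx].astype(bool)  # (n, 3), waves 1..3
    observed_waves[unit] = False

    out = long.copy()
    sid_pos = pd.Series(np.arange(n), index=cohort["subject_id"])
    pos = sid_pos.loc[out["subject_id"]].to_numpy()
    wave = out["wave"].to_numpy()
    keep = np.ones(len(out), dtype=bool)
    post = wave >= 1
    keep[post] = observed_waves[pos[post], wave[post] - 1]
    out["observed"] = keep.astype(int)
    out.loc[~keep, ["raw_total", "harmonized"]] = np.nan
    return out


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full generator: cohort table plus long measurements with missingness."""
    cohort = draw_cohort(config)
    long = simulate_trajectories(cohort, config)
    long = apply_missingness(long, cohort, config)
    return cohort, long


def clipped_fraction(cohort: pd.DataFrame, config: GeneratorConfig) -> float:
    """Fraction of observed post-deployment scores clipped at 0 or 100.

    Diagnostic for the linear-scale simulation: large values would distort the
    within-class linear structure the trajectory model assumes.
    """
    long = simulate_trajectories(cohort, config)
    post = long[long["wave"] >= 1]
    h = post["harmonized"].to_numpy()
    return float(np.mean((h <= 0.0) | (h >= 100.0)))
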