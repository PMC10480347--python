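"""Latent growth mixture models for linear symptom trajectories.

A cohort's post-deployment symptom course is modeled as a finite mixture of
linear growth curves.  For subject *i* with harmonized scores ``y_i`` observed
at times ``t_i`` (post-deployment coded 0, follow-ups in months), class *k*
implies

    y_i | class k  ~  N( X_i beta_k,  Z_i Psi Z_i' + sigma^2 I )

where ``X_i = [1, t_i]`` carries the class intercept and slope, ``Z_i`` the
subject-level random effects (none for latent class growth analysis, a random
intercept, or a random intercept and slope) with covariance ``Psi`` shared
across classes, and class membership follows a multinomial logit on
subject-level covariates (by default the pre-deployment severity score):

    P(class k | w_i) = softmax_k( gamma_k' w_i ),   gamma_1 = 0.

Estimation is EM with the latent class indicators and random effects as
missing data (closed-form M-steps, monotone in the marginal likelihood), run
from multiple perturbed starts built off the one-class solution, with an
optional quasi-Newton polish of the best start on the marginal likelihood
under a log-Cholesky parameterization of ``Psi``.  Classes are canonically
ordered by model-implied mean at the final follow-up time so labels are
reproducible across runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._multinomial import _probs, fit_multinomial

RE_STRUCTURES = {"none": 0, "intercept": 1, "intercept+slope": 2}
_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LGMMSpec:
    """Specification of one mixture fit."""

    n_classes: int = 4
    random_effects: str = "intercept+slope"   # "none" => latent class growth analysis
    covariance_equal_across_classes: bool = True
    classmb_covariates: tuple[str, ...] = ("pre_severity",)
    multistart: tuple[int, int] = (100, 100)  # (repetitions, max EM iters per start)
    tol: float = 1e-6                         # relative log-likelihood change
    max_iter: int = 500
    polish: bool = True
    polish_maxiter: int = 60
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_classes <= 5:
            raise ValueError("n_classes must be between 1 and 5")
        if self.random_effects not in RE_STRUCTURES:
            raise ValueError(f"random_effects must be one of {sorted(RE_STRUCTURES)}")
        if not self.covariance_equal_across_classes:
            raise ValueError("only a covariance shared across classes is supported")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    @property
    def re_dim(self) -> int:
        return RE_STRUCTURES[self.random_effects]


class MixtureData:
    """Post-deployment observations grouped by per-subject wave pattern.

    Subjects with zero observed post-deployment waves are excluded (they are
    handled by the response-weighting stage, not the trajectory model).
    """

    def __init__(self, long: pd.DataFrame, cohort: pd.DataFrame,
                 classmb_covariates: tuple[str, ...] = ("pre_severity",)):
        post = long[(long["wave"] >= 1) & (long["observed"] == 1)].copy()
        if post["harmonized"].isna().any():
            raise ValueError("observed rows must have harmonized scores")
        counts = post.groupby("subject_id").size()
        ids = counts.index.to_numpy()
        self.subject_ids = ids
        self.n_subjects = len(ids)
        if self.n_subjects == 0:
            raise ValueError("no subjects with observed post-deployment data")
        order = {s: j for j, s in enumerate(ids)}

        # subject-level class-membership design: intercept + covariates
        sub = cohort.set_index("subject_id")
        pre = (
            long[long["wave"] == 0]
            .set_index("subject_id")["harmonized"]
        )
        cols = [np.ones(self.n_subjects)]
        self.classmb_names = ("const",) + tuple(classmb_covariates)
        self.classmb_scale: list[tuple[float, float]] = []
        for name in classmb_covariates:
            if name == "pre_severity":
                v = pre.reindex(ids).to_numpy(dtype=float)
            elif name in sub.columns:
                v = sub[name].reindex(ids).to_numpy(dtype=float)
            else:
                raise KeyError(f"unknown class-membership covariate {name!r}")
            mu, sd = float(np.nanmean(v)), float(np.nanstd(v))
            sd = sd if sd > 0 else 1.0
            self.classmb_scale.append((mu, sd))
            cols.append((v - mu) / sd)
        self.W = np.column_stack(cols)

        self.groups: list[dict] = []
        post = post.sort_values(["subject_id", "wave"])
        g = post.groupby("subject_id")
        y_by = {s: v["harmonized"].to_numpy() for s, v in g}
        t_by = {s: v["time_months"].to_numpy() for s, v in g}
        for ni in sorted(counts.unique()):
            members = counts.index[counts == ni].to_numpy()
            idx = np.array([order[s] for s in members])
            Y = np.stack([y_by[s] for s in members])
            T = np.stack([t_by[s] for s in members])
            self.groups.append({"ni": int(ni), "idx": idx, "Y": Y, "T": T})
        self.n_obs = int(counts.sum())
        # final-time anchor for canonical class ordering
        self.t_final = float(np.mean([t_by[s].max() for s in ids]))

    def simulate_like(self, beta, psi, sigma2, gamma, rng) -> "MixtureData":
        """Resimulate outcomes at this design under given mixture parameters
        (used by the parametric-bootstrap likelihood ratio test)."""
        new = object.__new__(MixtureData)
        new.subject_ids = self.subject_ids
        new.n_subjects = self.n_subjects
        new.W = self.W
        new.classmb_names = self.classmb_names
        new.classmb_scale = self.classmb_scale
        new.n_obs = self.n_obs
        new.t_final = self.t_final
        K = beta.shape[0]
        pi = _probs(self.W, gamma) if K > 1 else np.ones((self.n_subjects, 1))
        cls = (pi.cumsum(axis=1) < rng.random((self.n_subjects, 1))).sum(axis=1)
        q = psi.shape[0] if psi is not None and psi.size else 0
        b = rng.multivariate_normal(np.zeros(q), psi, size=self.n_subjects) if q else None
        new.groups = []
        for grp in self.groups:
            T = grp["T"]
            idx = grp["idx"]
            mean = beta[cls[idx], 0][:, None] + beta[cls[idx], 1][:, None] * T
            if q:
                Z = _z_design(T, q)
                mean = mean + np.einsum("mij,mj->mi", Z, b[idx])
            Y = mean + rng.normal(0.0, np.sqrt(sigma2), size=T.shape)
            new.groups.append({"ni": grp["ni"], "idx": idx, "Y": Y, "T": T})
        return new


@dataclass
class LGMMFit:
    """A fitted growth mixture: parameters, likelihood and posteriors."""

    spec: LGMMSpec
    beta: np.ndarray          # (K, 2) class (intercept, slope)
    psi: np.ndarray           # (re_dim, re_dim) shared random-effect covariance
    sigma2: float
    gamma: np.ndarray         # (K-1, q) class-membership coefficients, ref class 1
    loglik: float
    n_params: int
    posterior: np.ndarray     # (n, K)
    converged: bool
    n_subjects: int
    subject_ids: np.ndarray
    classmb_names: tuple[str, ...]
    class_shares: np.ndarray = field(default=None)
    start_logliks: np.ndarray = field(default=None)

    @property
    def n_classes(self) -> int:
        return self.beta.shape[0]


def _z_design(T: np.ndarray, re_dim: int) -> np.ndarray:
    """Random-effect design (m, ni, re_dim) from a time matrix (m, ni)."""
    m, ni = T.shape
    Z = np.empty((m, ni, re_dim))
    if re_dim >= 1:
        Z[:, :, 0] = 1.0
    if re_dim >= 2:
        Z[:, :, 1] = T
    return Z


def _group_cov_terms(grp: dict, psi: np.ndarray, sigma2: float, re_dim: int):
    """V^{-1} and log|V| per subject of a pattern group."""
    T = grp["T"]
    m, ni = T.shape
    if re_dim == 0:
        Vinv = np.broadcast_to(np.eye(ni) / sigma2, (m, ni, ni))
        logdet = np.full(m, ni * np.log(sigma2))
        return Vinv, logdet, None
    Z = _z_design(T, re_dim)
    V = sigma2 * np.eye(ni)[None, :, :] + np.einsum("mia,ab,mjb->mij", Z, psi, Z)
    Vinv = np.linalg.inv(V)
    _, logdet = np.linalg.slogdet(V)
    return Vinv, logdet, Z


def class_log_densities(data: MixtureData, beta: np.ndarray, psi: np.ndarray,
                        sigma2: float, re_dim: int) -> np.ndarray:
    """(n, K) matrix of per-class Gaussian marginal log densities."""
    K = beta.shape[0]
    out = np.empty((data.n_subjects, K))
    for grp in data.groups:
        Vinv, logdet, _ = _group_cov_terms(grp, psi, sigma2, re_dim)
        Y, T = grp["Y"], grp["T"]
        ni = grp["ni"]
        for k in range(K):
            r = Y - (beta[k, 0] + beta[k, 1] * T)
            quad = np.einsum("mi,mij,mj->m", r, Vinv, r)
            out[grp["idx"], k] = -0.5 * (ni * _LOG2PI + logdet + quad)
    return out


def marginal_loglik(data: MixtureData, beta: np.ndarray, psi: np.ndarray,
                    sigma2: float, gamma: np.ndarray, re_dim: int) -> float:
    """Observed-data log-likelihood of the mixture of linear mixed models."""
    if sigma2 <= 0:
        return -np.inf
    logdens = class_log_densities(data, beta, psi, sigma2, re_dim)
    K = beta.shape[0]
    if K == 1:
        return float(logdens.sum())
    logpi = np.log(np.maximum(_probs(data.W, gamma), 1e-300))
    return float(logsumexp(logdens + logpi, axis=1).sum())


def _posteriors(data: MixtureData, beta, psi, sigma2, gamma, re_dim):
    logdens = class_log_densities(data, beta, psi, sigma2, re_dim)
    K = beta.shape[0]
    if K == 1:
        return np.ones((data.n_subjects, 1)), float(logdens.sum())
    logpi = np.log(np.maximum(_probs(data.W, gamma), 1e-300))
    joint = logdens + logpi
    lse = logsumexp(joint, axis=1)
    return np.exp(joint - lse[:, None]), float(lse.sum())


def _em_iterate(data: MixtureData, beta, psi, sigma2, gamma, re_dim, *,
                max_iter: int, tol: float, trace: list | None = None):
    """Run EM until relative log-likelihood change < tol or max_iter."""
    K = beta.shape[0]
    ll_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        P, ll = _posteriors(data, beta, psi, sigma2, gamma, re_dim)
        if trace is not None:
            trace.append(ll)
        if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_prev = ll

        # M-step: class-membership multinomial on posterior responsibilities
        if K > 1:
            mfit = fit_multinomial(data.W, P, tol=1e-9, max_iter=50,
                                   check_rank=False, start=gamma)
            gamma = mfit.coef

        # M-step: growth parameters and variance components
        beta_new = np.zeros_like(beta)
        A = np.zeros((K, 2, 2))
        c = np.zeros((K, 2))
        bhat_store = []
        for grp in data.groups:
            Vinv, _, Z = _group_cov_terms(grp, psi, sigma2, re_dim)
            Y, T = grp["Y"], grp["T"]
            X = _z_design(T, 2)
            p_g = P[grp["idx"]]                      # (m, K)
            if re_dim:
                PsiZt = np.einsum("ab,mib->mai", psi, Z)          # Psi Z'
                Gain = np.einsum("mai,mij->maj", PsiZt, Vinv)      # Psi Z' Vinv
                C = psi - np.einsum("mai,mib,bc->mac", Gain, Z, psi)
            bhats = np.zeros((len(Y), K, re_dim)) if re_dim else None
            for k in range(K):
                r = Y - (beta[k, 0] + beta[k, 1] * T)
                if re_dim:
                    bhat = np.einsum("mai,mi->ma", Gain, r)
                    bhats[:, k, :] = bhat
                    resid_target = Y - np.einsum("mia,ma->mi", Z, bhat)
                else:
                    resid_target = Y
                w = p_g[:, k]
                A[k] += np.einsum("m,mia,mib->ab", w, X, X)
                c[k] += np.einsum("m,mia,mi->a", w, X, resid_target)
            bhat_store.append((grp, bhats, C if re_dim else None, Vinv, Z))
        for k in range(K):
            beta_new[k] = np.linalg.solve(A[k], c[k])

        if re_dim:
            psi_acc = np.zeros((re_dim, re_dim))
        sse = 0.0
        trace_acc = 0.0
        for grp, bhats, C, Vinv, Z in bhat_store:
            Y, T = grp["Y"], grp["T"]
            p_g = P[grp["idx"]]
            for k in range(K):
                r = Y - (beta_new[k, 0] + beta_new[k, 1] * T)
                if re_dim:
                    r = r - np.einsum("mia,ma->mi", Z, bhats[:, k, :])
                sse += float(np.einsum("m,mi->", p_g[:, k], r * r))
                if re_dim:
                    psi_acc += np.einsum("m,ma,mb->ab", p_g[:, k],
                                         bhats[:, k, :], bhats[:, k, :])
            if re_dim:
                psi_acc += C.sum(axis=0)
                trace_acc += float(np.einsum("mia,mab,mib->", Z, C, Z))
        beta = beta_new
        if re_dim:
            psi = psi_acc / data.n_subjects
            psi = 0.5 * (psi + psi.T)
        sigma2 = (sse + trace_acc) / data.n_obs
        sigma2 = max(sigma2, 1e-10)
    return beta, psi, sigma2, gamma, ll_prev if not converged else ll, converged


# --- packed parameterization for the quasi-Newton polish -------------------

def _pack(beta, psi, sigma2, gamma, re_dim):
    parts = [beta.ravel()]
    if re_dim:
        L = np.linalg.cholesky(psi + 1e-12 * np.eye(re_dim))
        if re_dim == 1:
            parts.append([np.log(L[0, 0])])
        else:
            parts.append([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])
    parts.append([0.5 * np.log(sigma2)])
    if gamma.size:
        parts.append(gamma.ravel())
    return np.concatenate([np.asarray(p, dtype=float) for p in parts])


def _unpack(theta, K, re_dim, q):
    pos = 0
    beta = theta[pos:pos + 2 * K].reshape(K, 2); pos += 2 * K
    if re_dim == 0:
        psi = np.zeros((0, 0))
    elif re_dim == 1:
        psi = np.array([[np.exp(2 * theta[pos])]]); pos += 1
    else:
        L = np.array([[np.exp(theta[pos]), 0.0],
                      [theta[pos + 1], np.exp(theta[pos + 2])]])
        psi = L @ L.T; pos += 3
    sigma2 = float(np.exp(2 * theta[pos])); pos += 1
    gamma = theta[pos:].reshape(K - 1, q) if K > 1 else np.zeros((0, q))
    return beta, psi, sigma2, gamma


def _n_params(K: int, re_dim: int, q: int) -> int:
    return 2 * K + {0: 0, 1: 1, 2: 3}[re_dim] + 1 + (K - 1) * q


def _canonical_order(beta: np.ndarray, t_final: float) -> np.ndarray:
    """Class permutation: ascending model-implied mean at the final time."""
    return np.argsort(beta[:, 0] + beta[:, 1] * t_final, kind="stable")


def _apply_order(order, beta, gamma, posterior):
    beta = beta[order]
    posterior = posterior[:, order]
    K = beta.shape[0]
    if K > 1:
        full = np.vstack([np.zeros((1, gamma.shape[1])), gamma])[order]
        gamma = full[1:] - full[0]
    return beta, gamma, posterior


def _kmeans_start(data: MixtureData, K: int) -> np.ndarray:
    """Deterministic data-driven start: k-means on per-subject crude level and
    slope summaries, complementing the random perturbation starts."""
    from sklearn.cluster import KMeans

    summ = np.zeros((data.n_subjects, 2))
    for grp in data.groups:
        Y, T = grp["Y"], grp["T"]
        if grp["ni"] >= 2:
            tbar = T.mean(axis=1, keepdims=True)
            ybar = Y.mean(axis=1, keepdims=True)
            denom = ((T - tbar) ** 2).sum(axis=1)
            slope = ((T - tbar) * (Y - ybar)).sum(axis=1) / np.maximum(denom, 1e-12)
            icpt = ybar[:, 0] - slope * tbar[:, 0]
        else:
            icpt = Y[:, 0]
            slope = np.zeros(len(Y))
        summ[grp["idx"], 0] = icpt
        summ[grp["idx"], 1] = slope
    sd = summ.std(axis=0)
    sd[sd == 0] = 1.0
    km = KMeans(n_clusters=K, n_init=4, random_state=0).fit(summ / sd)
    beta0 = np.zeros((K, 2))
    for k in range(K):
        members = km.labels_ == k
        beta0[k] = summ[members].mean(axis=0) if members.any() else summ.mean(axis=0)
    return beta0


def fit_lgmm(long: pd.DataFrame, cohort: pd.DataFrame, spec: LGMMSpec) -> LGMMFit:
    """Fit a K-class growth mixture by multistart EM with quasi-Newton polish.

    Starts are random perturbations of the one-class solution (class
    intercepts and slopes jittered on the scale of the between-subject spread
    of per-subject means and crude slopes); each start runs a capped number of
    EM iterations and the best is refined to convergence.
    """
    spec.validate()
    data = MixtureData(long, cohort, spec.classmb_covariates)
    return _fit_on_data(data, spec)


def _fit_on_data(data: MixtureData, spec: LGMMSpec) -> LGMMFit:
    K = spec.n_classes
    re_dim = spec.re_dim
    q = data.W.shape[1]
    rng = np.random.default_rng(spec.seed)

    # one-class base fit (closed-form-ish EM on the linear mixed model)
    y_all = np.concatenate([g["Y"].ravel() for g in data.groups])
    t_all = np.concatenate([g["T"].ravel() for g in data.groups])
    X1 = np.column_stack([np.ones_like(t_all), t_all])
    b_ols, *_ = np.linalg.lstsq(X1, y_all, rcond=None)
    resid_var = float(np.var(y_all - X1 @ b_ols))
    beta1 = np.array([b_ols])
    psi1 = 0.25 * resid_var * np.eye(re_dim) if re_dim else np.zeros((0, 0))
    if re_dim == 2:
        psi1[1, 1] = max(0.01 * resid_var, 1e-4)
    g1 = np.zeros((0, q))
    beta1, psi1, s2_1, g1, ll1, _ = _em_iterate(
        data, beta1, psi1, max(resid_var, 1e-6), g1, re_dim,
        max_iter=200, tol=spec.tol)
    if K == 1:
        if spec.polish and re_dim:
            theta0 = _pack(beta1, psi1, s2_1, g1, re_dim)

            def nll1(th):
                b, p_, s2, g_ = _unpack(th, 1, re_dim, q)
                return -marginal_loglik(data, b, p_, s2, g_, re_dim)

            res = minimize(nll1, theta0, method="L-BFGS-B",
                           options={"maxiter": spec.polish_maxiter, "ftol": 1e-13})
            if np.isfinite(res.fun) and -res.fun > ll1:
                beta1, psi1, s2_1, g1 = _unpack(res.x, 1, re_dim, q)
                ll1 = -res.fun
        posterior = np.ones((data.n_subjects, 1))
        return LGMMFit(spec=spec, beta=beta1, psi=psi1, sigma2=s2_1,
                       gamma=g1, loglik=ll1, n_params=_n_params(1, re_dim, q),
                       posterior=posterior, converged=True,
                       n_subjects=data.n_subjects, subject_ids=data.subject_ids,
                       classmb_names=data.classmb_names,
                       class_shares=np.ones(1),
                       start_logliks=np.array([ll1]))

    # spread scales for perturbed starts
    means = np.concatenate([g["Y"].mean(axis=1) for g in data.groups])
    scale0 = max(float(np.std(means)), 1e-3)
    tspan = max(float(t_all.max() - t_all.min()), 1.0)
    scale1 = 2.0 * scale0 / tspan

    reps, iters_per_start = spec.multistart
    starts = [_kmeans_start(data, K)]
    for _rep in range(max(reps, 1)):
        beta0 = np.repeat(beta1, K, axis=0)
        beta0[:, 0] += rng.normal(0.0, scale0, K)
        beta0[:, 1] += rng.normal(0.0, scale1, K)
        starts.append(beta0)
    best = None
    start_lls = []
    for beta0 in starts:
        state = _em_iterate(data, beta0, psi1.copy(), s2_1, np.zeros((K - 1, q)),
                            re_dim, max_iter=iters_per_start, tol=spec.tol)
        start_lls.append(state[4])
        if best is None or state[4] > best[4]:
            best = state
    beta, psi, sigma2, gamma, ll, conv = best
    if not conv:
        beta, psi, sigma2, gamma, ll, conv = _em_iterate(
            data, beta, psi, sigma2, gamma, re_dim,
            max_iter=spec.max_iter, tol=spec.tol)

    if spec.polish:
        theta0 = _pack(beta, psi, sigma2, gamma, re_dim)

        def nll(th):
            b, p_, s2, g_ = _unpack(th, K, re_dim, q)
            return -marginal_loglik(data, b, p_, s2, g_, re_dim)

        res = minimize(nll, theta0, method="L-BFGS-B",
                       options={"maxiter": spec.polish_maxiter, "ftol": 1e-12})
        if np.isfinite(res.fun) and -res.fun > ll:
            beta, psi, sigma2, gamma = _unpack(res.x, K, re_dim, q)
            ll = -res.fun

    posterior, ll = _posteriors(data, beta, psi, sigma2, gamma, re_dim)
    order = _canonical_order(beta, data.t_final)
    beta, gamma, posterior = _apply_order(order, beta, gamma, posterior)
    return LGMMFit(spec=spec, beta=beta, psi=psi, sigma2=sigma2, gamma=gamma,
                   loglik=ll, n_params=_n_params(K, re_dim, q),
                   posterior=posterior, converged=bool(conv),
                   n_subjects=data.n_subjects, subject_ids=data.subject_ids,
                   classmb_names=data.classmb_names,
                   class_shares=posterior.mean(axis=0),
                   start_logliks=np.asarray(start_lls))


def posterior_probs(fit: LGMMFit, long: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Posterior class membership probabilities by Bayes rule at the fitted
    parameters, for the subjects in ``long`` with post-deployment data."""
    data = MixtureData(long, cohort, fit.spec.classmb_covariates)
    P, _ = _posteriors(data, fit.beta, fit.psi, fit.sigma2, fit.gamma, fit.spec.re_dim)
    cols = {f"class{k + 1}": P[:, k] for k in range(P.shape[1])}
    return pd.DataFrame({"subject_id": data.subject_ids, **cols})


def entropy(fit: LGMMFit) -> float:
    """Relative entropy 1 - sum(-p log p) / (n log K); 1 = perfect separation."""
    K = fit.n_classes
    if K < 2:
        raise ValueError("entropy is undefined for a one-class model")
    P = np.clip(fit.posterior, 1e-300, 1.0)
    H = float(-(fit.posterior * np.log(P)).sum())
    return 1.0 - H / (fit.n_subjects * np.log(K))


def ssa_bic(fit: LGMMFit) -> float:
    """Sample-size-adjusted BIC: -2 loglik + n_params * log((n + 2) / 24),
    with n the number of subjects (Sclove adjustment)."""
    return -2.0 * fit.loglik + fit.n_params * np.log((fit.n_subjects + 2) / 24.0)


def classify(fit: LGMMFit) -> tuple[pd.DataFrame, float]:
    """Most-likely class per subject (ties to the lower class index) and the
    mean of the per-subject maximum posterior probabilities."""
    assigned = fit.posterior.argmax(axis=1) + 1  # argmax takes the first max
    mean_max = float(fit.posterior.max(axis=1).mean())
    table = pd.DataFrame({"subject_id": fit.subject_ids, "assigned_class": assigned})
    return table, mean_max


def label_classes(fit: LGMMFit, t_final: float = 11.76) -> dict[int, str]:
    """Descriptive labels for a four-class fit.

    With classes canonically ordered, the class with the lowest (highest)
    average of its post-deployment and final-time means is labeled
    ``low`` (``high``); of the remaining two, the steeper-rising class is
    ``increasing`` and the other ``decreasing``.  Other K fall back to
    ``class{k}`` names.
    """
    K = fit.n_classes
    if K != 4:
        return {k: f"class{k}" for k in range(1, K + 1)}
    level = fit.beta[:, 0] + 0.5 * fit.beta[:, 1] * t_final  # midpoint severity
    order = np.argsort(level)
    labels = {}
    labels[int(order[0]) + 1] = "low"
    labels[int(order[-1]) + 1] = "high"
    mid = [int(order[1]), int(order[2])]
    if fit.beta[mid[0], 1] >= fit.beta[mid[1], 1]:
        inc, dec = mid[0], mid[1]
    else:
        inc, dec = mid[1], mid[0]
    labels[inc + 1] = "increasing"
    labels[dec + 1] = "decreasing"
    return labels


def lmr_lrt(fit_k: LGMMFit, fit_km1: LGMMFit, *, mode: str = "analytic",
            data: MixtureData | None = None, n_boot: int = 99,
            boot_spec_overrides: dict | None = None,
            seed: int = 0) -> dict:
    """Likelihood ratio test of K classes against K-1.

    ``analytic`` mode uses an adjusted likelihood-ratio statistic: the raw
    2*(LL_K - LL_{K-1}) is scaled by the small-sample factor
    (n - 1 - (p_K + p_{K-1}) / 2) / n and referred to a chi-square with
    p_K - p_{K-1} degrees of freedom.  This is an approximation to the
    corrected mixture LRT reference distribution; the exact variant differs
    across software, so a parametric ``bootstrap`` mode is provided as a
    cross-check: data are resimulated under the fitted K-1 model, both models
    are refit, and the p-value is the empirical exceedance of the statistic.
    """
    if fit_k.n_classes != fit_km1.n_classes + 1:
        raise ValueError("fits must differ by exactly one class")
    if fit_k.spec.random_effects != fit_km1.spec.random_effects:
        raise ValueError("fits must share the random-effects family")
    stat = max(2.0 * (fit_k.loglik - fit_km1.loglik), 0.0)
    df = fit_k.n_params - fit_km1.n_params
    n = fit_k.n_subjects
    if mode == "analytic":
        pbar = 0.5 * (fit_k.n_params + fit_km1.n_params)
        adj = max((n - 1.0 - pbar) / n, 1e-6)
        p = float(stats.chi2.sf(stat * adj, df)) if stat > 0 else 1.0
        return {"statistic": stat, "df": df, "p_value": p, "mode": "analytic"}
    if mode != "bootstrap":
        raise ValueError("mode must be 'analytic' or 'bootstrap'")
    if data is None:
        raise ValueError("bootstrap mode needs the MixtureData used for fitting")
    rng = np.random.default_rng(seed)
    overrides = {"multistart": (2, 30), "polish": False}
    overrides.update(boot_spec_overrides or {})
    exceed = 0
    for b in range(n_boot):
        sim = data.simulate_like(fit_km1.beta, fit_km1.psi, fit_km1.sigma2,
                                 fit_km1.gamma, rng)
        s_small = dataclasses.replace(fit_km1.spec, seed=int(rng.integers(2**31)), **overrides)
        s_big = dataclasses.replace(fit_k.spec, seed=int(rng.integers(2**31)), **overrides)
        f_small = _fit_on_data(sim, s_small)
        f_big = _fit_on_data(sim, s_big)
        if 2.0 * (f_big.loglik - f_small.loglik) >= stat:
            exceed += 1
    p = (1.0 + exceed) / (n_boot + 1.0)
    return {"statistic": stat, "df": df, "p_value": p, "mode": "bootstrap"}


def comparison_table(fits: dict[tuple[str, int], LGMMFit]) -> pd.DataFrame:
    """Model comparison rows (family, K, loglik, SSA-BIC, entropy, LMR-LRT p,
    smallest class share) for a grid of fits keyed by (family, K)."""
    rows = []
    for (family, K), fit in sorted(fits.items()):
        prev = fits.get((family, K - 1))
        p_lmr = lmr_lrt(fit, prev)["p_value"] if prev is not None else np.nan
        rows.append({
            "family": family,
            "n_classes": K,
            "loglik": fit.loglik,
            "ssa_bic": ssa_bic(fit),
            "entropy": entropy(fit) if K > 1 else np.nan,
            "lmr_lrt_p": p_lmr,
            "smallest_class_share": float(fit.class_shares.min()),
            "n_params": fit.n_params,
        })
    return pd.DataFrame(rows)


def select_model(comparison: pd.DataFrame, *, min_class_share: float = 0.03,
                 max_entropy_drop: float = 0.05) -> tuple[str, int]:
    """Deterministic model selection over a comparison table.

    Candidates whose smallest class falls below ``min_class_share``, or whose
    entropy drops by more than ``max_entropy_drop`` relative to the same
    family's K-1 model, are excluded; among the rest the lowest SSA-BIC wins,
    with ties broken toward fewer classes.  This encodes the reported
    preference for parsimonious models over ones that add a sparse,
    indistinct trajectory.
    """
    if len(comparison) == 0:
        raise ValueError("empty comparison table")
    df = comparison.copy()
    ok = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        if row["n_classes"] > 1 and row["smallest_class_share"] < min_class_share:
            ok[df.index.get_loc(i)] = False
        prev = df[(df["family"] == row["family"]) & (df["n_classes"] == row["n_classes"] - 1)]
        if len(prev) and np.isfinite(row.get("entropy", np.nan)) and np.isfinite(prev["entropy"].iloc[0]):
            if prev["entropy"].iloc[0] - row["entropy"] > max_entropy_drop:
                ok[df.index.get_loc(i)] = False
    cand = df[ok] if ok.any() else df
    cand = cand.sort_values(["ssa_bic", "n_classes"], kind="stable")
    top = cand.iloc[0]
    return str(top["family"]), int(top["n_classes"])
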