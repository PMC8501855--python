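"""Parametric empirical Bayes over subjects, Bayesian model reduction and
Bayesian model averaging.

The second level is a linear-Gaussian hierarchical model: each subject's
connectivity parameters are modeled as a design-weighted sum of group
effects plus between-subject variation,

    theta_i = (x_i^T kron I_p) beta + eps_i,    eps_i ~ N(0, Sigma(gamma)),

where x_i is the subject's row of the design matrix (group mean first, then
mean-centered severity and age, +/-0.5-coded sex and optionally treatment),
beta holds one effect per (covariate, parameter) pair, and Sigma(gamma) is a
single shared random-effects component scaled by a log-precision gamma.

Each subject enters through the *likelihood* implied by their first-level
posterior and prior (precision difference), never through point estimates,
so uncertain subjects are automatically down-weighted.  Because everything
is Gaussian, the evidence is available in closed form given gamma; gamma is
optimized by bounded scalar search.

Model comparison over reduced priors (pruning effects to zero) uses the
analytic Bayesian-model-reduction identity, which is exact at this level;
the greedy search prunes while evidence improves, then enumerates the 2^k
neighborhood of the least decisive pruning decisions, and Bayesian model
averaging weights the surviving models by their evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .inversion import GaussianDensity, SubjectDCM, ParameterPacking

__all__ = [
    "DesignMatrix",
    "PEBModel",
    "ReducedModel",
    "BMAResult",
    "MissingCovariateError",
    "build_design",
    "fit_peb",
    "bmr",
    "greedy_search",
    "bma",
    "extract_likelihood",
]

GROUP_EFFECT_PRIOR_VAR = 1.0 / 16.0
PRUNED_PRIOR_VAR = 1e-8
GAMMA_PRIOR_SD = 2.0          # broad hyperprior on the random-effects log-precision
DEFAULT_PP_THRESHOLD = 0.95


class MissingCovariateError(ValueError):
    def __init__(self, excluded, message):
        super().__init__(message)
        self.excluded = list(excluded)


@dataclass(frozen=True)
class DesignMatrix:
    """Second-level design: subjects x covariates, group mean first."""

    subject_ids: tuple
    column_names: tuple
    values: np.ndarray
    centered: tuple  # per-column flag

    def __post_init__(self):
        X = np.array(self.values, dtype=float)
        ids = tuple(self.subject_ids)
        cols = tuple(self.column_names)
        if X.shape != (len(ids), len(cols)):
            raise ValueError("design shape must be subjects x covariates")
        if not np.allclose(X[:, 0], 1.0):
            raise ValueError("first design column must be the constant group mean")
        cent = tuple(bool(c) for c in self.centered)
        for k, is_c in enumerate(cent):
            if is_c and abs(X[:, k].sum()) > 1e-10 * max(1.0, np.abs(X[:, k]).max()) * len(ids):
                raise ValueError(f"column '{cols[k]}' flagged centered but does not sum to 0")
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "column_names", cols)
        object.__setattr__(self, "values", X)
        object.__setattr__(self, "centered", cent)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_covariates(self) -> int:
        return len(self.column_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.column_names.index(name)]


def _code_binary(x: np.ndarray, name: str) -> np.ndarray:
    """Code a binary covariate as +/-0.5 (keeps the mean column interpretable)."""
    vals = np.asarray(x)
    if vals.dtype.kind in "OU":
        mapping = {"f": 0.5, "female": 0.5, "m": -0.5, "male": -0.5, "1": 0.5, "0": -0.5}
        try:
            return np.array([mapping[str(v).strip().lower()] for v in vals])
        except KeyError as exc:
            raise ValueError(f"cannot code column '{name}' as binary: unknown value {exc}")
    return np.where(np.asarray(vals, float) > 0, 0.5, -0.5)


def build_design(
    covariates: pd.DataFrame,
    severity_column: str = "bdi",
    with_treatment: bool = False,
) -> DesignMatrix:
    """Design with columns [mean, severity, age, sex(, treatment)].

    Severity and age are mean-centered across subjects so the first
    regressor is interpretable as the group mean; sex and treatment are
    coded +/-0.5.  Subjects with missing values are reported in the raised
    error so the caller can exclude them explicitly.
    """
    needed = [severity_column, "age", "sex"] + (["treatment"] if with_treatment else [])
    if "subject_id" not in covariates.columns:
        raise ValueError("covariates table needs a subject_id column")
    for c in needed:
        if c not in covariates.columns:
            raise ValueError(f"covariates table is missing required column '{c}'")
    missing_mask = covariates[needed].isna().any(axis=1)
    if missing_mask.any():
        excluded = covariates.loc[missing_mask, "subject_id"].tolist()
        raise MissingCovariateError(
            excluded,
            f"missing covariate values for subjects {excluded}; exclude them before building the design",
        )
    n = len(covariates)
    sev = covariates[severity_column].to_numpy(float)
    age = covariates["age"].to_numpy(float)
    sex = _code_binary(covariates["sex"].to_numpy(), "sex")
    cols = [np.ones(n), sev - sev.mean(), age - age.mean(), sex]
    names = ["mean", severity_column, "age", "sex"]
    centered = [False, True, True, False]
    if with_treatment:
        cols.append(_code_binary(covariates["treatment"].to_numpy(), "treatment"))
        names.append("treatment")
        centered.append(False)
    X = np.column_stack(cols)
    for k, nm in enumerate(names[1:], start=1):
        if np.ptp(X[:, k]) == 0:
            warnings.warn(f"design column '{nm}' is constant: rank-deficient design", UserWarning)
    return DesignMatrix(tuple(covariates["subject_id"]), tuple(names), X, tuple(centered))


# ---------------------------------------------------------------------------
# Likelihood extraction and Bayesian model reduction
# ---------------------------------------------------------------------------

def _clip_psd(M: np.ndarray, floor: float = 0.0) -> np.ndarray:
    M = 0.5 * (M + M.T)
    ev, U = np.linalg.eigh(M)
    return (U * np.clip(ev, floor, None)) @ U.T


def extract_likelihood(posterior: GaussianDensity, prior: GaussianDensity):
    """Precision-form likelihood implied by a Gaussian posterior/prior pair:
    returns (eta, L) with L = post_prec - prior_prec and
    eta = post_prec @ post_mean - prior_prec @ prior_mean, so that
    p(data | theta) prop-to exp(eta^T theta - theta^T L theta / 2).

    Directions in which the posterior is no tighter than the prior (possible
    in flat directions of an approximate first-level fit) carry no data
    information: their precision is clipped to zero and eta is projected
    onto the informative subspace so the likelihood stays normalizable."""
    Pp = np.linalg.inv(posterior.cov)
    P0 = np.linalg.inv(prior.cov)
    D = 0.5 * ((Pp - P0) + (Pp - P0).T)
    ev, U = np.linalg.eigh(D)
    keep = ev > 1e-12 * max(1.0, ev.max())
    L = (U[:, keep] * ev[keep]) @ U[:, keep].T
    eta_raw = Pp @ posterior.mean - P0 @ prior.mean
    eta = U[:, keep] @ (U[:, keep].T @ eta_raw)
    return eta, L


def _log_evidence_terms(eta, L, mu, Sigma_inv, logdet_Sigma):
    """Log of the Gaussian-prior evidence integral (up to the likelihood
    normalization constant, which cancels in evidence differences):
    log int exp(eta'th - th'L th/2) N(th; mu, Sigma) dth + const."""
    P = L + Sigma_inv
    b = eta + Sigma_inv @ mu
    sign, logdet_P = np.linalg.slogdet(P)
    if sign <= 0:
        raise ValueError("non-PSD precision in evidence computation")
    m = np.linalg.solve(P, b)
    val = 0.5 * (b @ m) - 0.5 * (mu @ (Sigma_inv @ mu)) - 0.5 * logdet_Sigma - 0.5 * logdet_P
    return val, m, P


def bmr(
    full_posterior: GaussianDensity,
    full_prior: GaussianDensity,
    reduced_prior: GaussianDensity,
):
    """Bayesian model reduction: evidence change and implied posterior when
    the prior is changed (typically: variances shrunk to prune parameters).

    Exact for linear-Gaussian models; the likelihood is recovered from the
    (posterior, prior) pair and re-combined with the reduced prior.
    """
    d = full_posterior.dim
    if full_prior.dim != d or reduced_prior.dim != d:
        raise ValueError("all densities must share a dimension")
    for dens in (full_posterior, full_prior, reduced_prior):
        dens.validate_psd(tol=1e-8)
    eta, L = extract_likelihood(full_posterior, full_prior)
    Sf_inv = np.linalg.inv(full_prior.cov)
    Sr_inv = np.linalg.inv(reduced_prior.cov)
    _, ldf = np.linalg.slogdet(full_prior.cov)
    _, ldr = np.linalg.slogdet(reduced_prior.cov)
    zf, _, _ = _log_evidence_terms(eta, L, full_prior.mean, Sf_inv, ldf)
    zr, m_r, P_r = _log_evidence_terms(eta, L, reduced_prior.mean, Sr_inv, ldr)
    delta_f = float(zr - zf)
    reduced_posterior = GaussianDensity(m_r, np.linalg.inv(P_r), full_posterior.names)
    return delta_f, reduced_posterior


# ---------------------------------------------------------------------------
# PEB fit
# ---------------------------------------------------------------------------

@dataclass
class PEBModel:
    design: DesignMatrix
    parameter_names: tuple          # selected first-level parameters
    effect_names: tuple             # covariate:parameter, covariate-major
    posterior: GaussianDensity      # over group effects beta
    prior: GaussianDensity
    gamma: float                    # random-effects log-precision (MAP)
    gamma_var: float
    random_effects_var: np.ndarray  # diagonal of Sigma(gamma)
    free_energy: float

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    @property
    def n_covariates(self) -> int:
        return self.design.n_covariates


def _subject_blocks(subject_dcms, selection):
    """Per-subject likelihoods (eta_i, L_i) on the selected parameter block."""
    names0 = subject_dcms[0].posterior.names
    for d in subject_dcms:
        if d.posterior.names != names0:
            raise ValueError("subjects have mismatched parameter packings")
    idx = [list(names0).index(nm) for nm in selection]
    etas, Ls = [], []
    for d in subject_dcms:
        eta, L = extract_likelihood(d.posterior.marginal(idx), d.prior.marginal(idx))
        etas.append(eta)
        Ls.append(L)
    return etas, Ls


def fit_peb(
    subject_dcms: list,
    design: DesignMatrix,
    selection: list | None = None,
) -> PEBModel:
    """Fit the group-level model over the selected first-level parameters.

    Subject posteriors enter via their full covariance on the selected
    block.  The random-effects log-precision gamma is optimized by bounded
    scalar search on the (closed-form) free energy; the posterior over
    group effects is Gaussian given the optimal gamma.
    """
    if len(subject_dcms) != design.n_subjects:
        raise ValueError("design rows must match the number of subjects")
    if design.n_subjects < design.n_covariates:
        raise ValueError(
            f"rank error: {design.n_subjects} subjects < {design.n_covariates} covariates"
        )
    if selection is None:
        packing = ParameterPacking(subject_dcms[0].region_names)
        selection = packing.coupling_names(include_self=True)
    selection = list(selection)
    p = len(selection)
    c = design.n_covariates
    etas, Ls = _subject_blocks(subject_dcms, selection)
    X = design.values
    beta_prior_var = np.full(c * p, GROUP_EFFECT_PRIOR_VAR)
    Sb_inv_diag = 1.0 / beta_prior_var

    def evidence(gamma):
        # single shared random-effects component: Sigma(gamma) = exp(-gamma) I
        Sg_inv = np.exp(gamma) * np.eye(p)
        logdet_Sg = -gamma * p
        A = np.diag(Sb_inv_diag).astype(float)
        bvec = np.zeros(c * p)
        total = 0.0
        for x_i, eta_i, L_i in zip(X, etas, Ls):
            P_i = L_i + Sg_inv
            ch = np.linalg.cholesky(P_i)
            logdet_P = 2.0 * np.sum(np.log(np.diag(ch)))
            Pinv_eta = np.linalg.solve(P_i, eta_i)
            total += 0.5 * (eta_i @ Pinv_eta) - 0.5 * logdet_Sg - 0.5 * logdet_P
            # C_i^-1 = Sg_inv - Sg_inv P_i^-1 Sg_inv  (Woodbury)
            Ci_inv = Sg_inv - Sg_inv @ np.linalg.solve(P_i, Sg_inv)
            Ci_inv = 0.5 * (Ci_inv + Ci_inv.T)
            A += np.kron(np.outer(x_i, x_i), Ci_inv)
            bvec += np.kron(x_i, Sg_inv @ Pinv_eta)
        chA = np.linalg.cholesky(A)
        logdet_A = 2.0 * np.sum(np.log(np.diag(chA)))
        mu = np.linalg.solve(A, bvec)
        total += 0.5 * (bvec @ mu) - 0.5 * float(np.sum(np.log(beta_prior_var))) - 0.5 * logdet_A
        total += -0.5 * (gamma / GAMMA_PRIOR_SD) ** 2
        return total, mu, A

    res = minimize_scalar(lambda g: -evidence(g)[0], bounds=(-8.0, 8.0), method="bounded", options={"xatol": 1e-3})
    gamma = float(res.x)
    F, mu, A = evidence(gamma)
    h = 1e-3
    d2 = (evidence(gamma + h)[0] - 2 * F + evidence(gamma - h)[0]) / h**2
    gamma_var = float(-1.0 / d2) if d2 < 0 else 1.0

    effect_names = tuple(f"{cov}:{par}" for cov in design.column_names for par in selection)
    posterior = GaussianDensity(mu, np.linalg.inv(A), effect_names)
    prior = GaussianDensity(np.zeros(c * p), np.diag(beta_prior_var), effect_names)
    return PEBModel(
        design=design,
        parameter_names=tuple(selection),
        effect_names=effect_names,
        posterior=posterior,
        prior=prior,
        gamma=gamma,
        gamma_var=gamma_var,
        random_effects_var=np.full(p, np.exp(-gamma)),
        free_energy=float(F),
    )


# ---------------------------------------------------------------------------
# Greedy search over reduced models and Bayesian model averaging
# ---------------------------------------------------------------------------

@dataclass
class ReducedModel:
    free_mask: np.ndarray    # True = effect retained (broad prior)
    delta_f: float           # evidence relative to the full model
    posterior: GaussianDensity


def _prior_for_mask(prior: GaussianDensity, mask: np.ndarray) -> GaussianDensity:
    var = np.diag(prior.cov).copy()
    var[~mask] = PRUNED_PRIOR_VAR
    return GaussianDensity(prior.mean, np.diag(var), prior.names)


def greedy_search(peb: PEBModel, max_k: int = 8) -> list:
    """Greedy pruning of group effects by Bayesian model reduction.

    Repeatedly prunes the effect whose removal most improves the evidence,
    until no single pruning improves it; then enumerates all 2^k prior
    combinations over the k (<= ``max_k``) effects whose final pruning
    decisions were least decisive.  Deterministic: ties break on the lowest
    effect index (packing order).
    """
    n_eff = len(peb.effect_names)
    full_post, full_prior = peb.posterior, peb.prior
    mask = np.ones(n_eff, dtype=bool)
    current_df = 0.0
    last_score = np.zeros(n_eff)
    while True:
        best_gain, best_idx = 0.0, -1
        for e in range(n_eff):
            if not mask[e]:
                continue
            cand = mask.copy()
            cand[e] = False
            df, _ = bmr(full_post, full_prior, _prior_for_mask(full_prior, cand))
            gain = df - current_df
            last_score[e] = gain
            if gain > best_gain + 1e-12:
                best_gain, best_idx = gain, e
        if best_idx < 0:
            break
        mask[best_idx] = False
        current_df += best_gain
    # decisiveness of each effect's final decision: |evidence change| of
    # flipping it, evaluated at the terminal model
    flip_scores = np.empty(n_eff)
    for e in range(n_eff):
        cand = mask.copy()
        cand[e] = not cand[e]
        df, _ = bmr(full_post, full_prior, _prior_for_mask(full_prior, cand))
        flip_scores[e] = abs(df - current_df)
    k = min(max_k, n_eff)
    undecided = np.argsort(flip_scores, kind="stable")[:k]
    models = []
    for bits in range(2**k):
        cand = mask.copy()
        for pos, e in enumerate(undecided):
            cand[e] = bool((bits >> pos) & 1)
        df, post = bmr(full_post, full_prior, _prior_for_mask(full_prior, cand))
        models.append(ReducedModel(free_mask=cand, delta_f=float(df), posterior=post))
    return models


@dataclass
class BMAResult:
    effect_names: tuple
    mean: np.ndarray
    variance: np.ndarray
    pp: np.ndarray               # posterior probability that the effect is nonzero
    threshold: float
    weights: np.ndarray

    @property
    def retained(self) -> np.ndarray:
        return self.pp > self.threshold

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, name in enumerate(self.effect_names):
            cov, par = name.split(":", 1)
            if par.startswith("self_"):
                tgt = src = par[len("self_"):]
            else:
                tgt, src = par[len("a_"):].split("<-")
            rows.append(
                {
                    "covariate": cov,
                    "source_region": src,
                    "target_region": tgt,
                    "mean": self.mean[k],
                    "variance": self.variance[k],
                    "Pp": self.pp[k],
                    "retained": bool(self.retained[k]),
                }
            )
        return pd.DataFrame(rows)


def bma(models: list, threshold: float = DEFAULT_PP_THRESHOLD) -> BMAResult:
    """Average candidate models weighted by their evidence (softmax of the
    free energies); per-effect Pp is the total weight of models in which the
    effect is free, and moments are weight-mixtures of per-model posteriors."""
    if not models:
        raise ValueError("need at least one model")
    F = np.array([m.delta_f for m in models], float)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite free energy among candidate models")
    w = np.exp(F - F.max())
    w /= w.sum()
    n_eff = len(models[0].free_mask)
    names = models[0].posterior.names
    if len(names) != n_eff:
        names = tuple(f"effect_{k}" for k in range(n_eff))
    mean = np.zeros(n_eff)
    second = np.zeros(n_eff)
    pp = np.zeros(n_eff)
    for wm, m in zip(w, models):
        mu = m.posterior.mean
        var = np.diag(m.posterior.cov)
        mean += wm * mu
        second += wm * (var + mu**2)
        pp += wm * m.free_mask
    return BMAResult(
        effect_names=names,
        mean=mean,
        variance=second - mean**2,
        pp=pp,
        threshold=threshold,
        weights=w,
    )
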