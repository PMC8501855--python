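"""Leave-one-out cross-validation: out-of-sample prediction of a covariate
(severity) from effective connectivity.

For each subject in turn, the group model is refitted on the remaining
subjects and the held-out subject's (centered) severity score is treated as
a latent variable with the training subjects' empirical score distribution
as its prior.  Because the second level is linear-Gaussian, conditioning on
the held-out subject's connectivity likelihood gives the score posterior in
closed form.  Predictive validity is summarized by the Pearson correlation
between predicted and actual scores, with a one-tailed p-value (the
prediction is only meaningful if positively correlated with the truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inversion import SubjectDCM
from .peb import PEBModel, build_design, extract_likelihood, fit_peb

__all__ = ["LOOCVResult", "predict_left_out", "loo_crossval"]


@dataclass
class LOOCVResult:
    subject_ids: tuple
    predicted: np.ndarray
    predicted_var: np.ndarray
    actual: np.ndarray
    pearson_r: float
    p_value: float
    connections: tuple
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "predicted": self.predicted,
                "predicted_var": self.predicted_var,
                "actual": self.actual,
            }
        )


def predict_left_out(
    group: PEBModel,
    left_out: SubjectDCM,
    target_column: str,
    score_prior: tuple,
    known_covariates: dict | None = None,
    propagate_effect_uncertainty: bool = False,
) -> tuple[float, float]:
    """Posterior (mean, variance) of a held-out subject's centered score.

    The subject's connectivity enters via the likelihood implied by their
    first-level posterior; the group effects enter via their posterior
    means (set ``propagate_effect_uncertainty`` to marginalize over the
    group-effect posterior as well).  With a zero group effect on every
    selected connection the prediction collapses to the score prior.
    """
    cols = list(group.design.column_names)
    if target_column not in cols:
        raise ValueError(f"target column '{target_column}' not in the design")
    t = cols.index(target_column)
    p = group.n_params
    c = group.n_covariates
    names0 = list(left_out.posterior.names)
    idx = [names0.index(nm) for nm in group.parameter_names]
    eta, L = extract_likelihood(left_out.posterior.marginal(idx), left_out.prior.marginal(idx))

    B = group.posterior.mean.reshape(c, p)  # covariate-major blocks
    known = dict(known_covariates or {})
    x_known = np.zeros(c)
    x_known[0] = 1.0
    for k, nm in enumerate(cols):
        if k == t:
            continue
        if k > 0:
            if nm not in known:
                raise ValueError(f"known covariate '{nm}' required for prediction")
            x_known[k] = known[nm]
    mu_known = x_known @ B          # p-vector, target contribution excluded
    b = B[t]                        # effect of the target covariate per parameter

    # subject-level covariance: C = L^-1 + Sigma(gamma); use Woodbury so a
    # singular L (uninformative directions) never needs inversion:
    # C^-1 = Sg_inv - Sg_inv P^-1 Sg_inv with P = L + Sg_inv,
    # C^-1 m_L = eta - L P^-1 eta.
    Sg_inv = np.diag(1.0 / group.random_effects_var)
    P = L + Sg_inv
    Ci = Sg_inv - Sg_inv @ np.linalg.solve(P, Sg_inv)
    Ci = 0.5 * (Ci + Ci.T)
    Ci_mL = eta - L @ np.linalg.solve(P, eta)

    m0, v0 = score_prior
    if v0 <= 0:
        raise ValueError("score prior variance must be positive")
    if propagate_effect_uncertainty:
        # moment-matched Gaussian marginalization over the group-effect
        # posterior: inflate the quadratic term by the effect covariance and
        # add the known-covariate uncertainty to the subject-level noise
        Sb = group.posterior.cov.reshape(c, p, c, p)
        quad = b @ Ci @ b + float(np.trace(Ci @ Sb[t, :, t, :]))
        cross = b @ (Ci_mL - Ci @ mu_known)
    else:
        quad = b @ Ci @ b
        cross = b @ (Ci_mL - Ci @ mu_known)
    post_prec = 1.0 / v0 + quad
    post_var = 1.0 / post_prec
    post_mean = post_var * (m0 / v0 + cross)
    return float(post_mean), float(post_var)


def loo_crossval(
    subject_dcms: list,
    covariates: pd.DataFrame,
    target_column: str,
    connections: list,
    with_treatment: bool = False,
    propagate_effect_uncertainty: bool = False,
) -> LOOCVResult:
    """n-fold leave-one-out prediction of ``target_column`` from the
    selected connections; one PEB fit per held-out subject."""
    n = len(subject_dcms)
    if n < 10:
        raise ValueError("need at least 10 subjects for leave-one-out validation")
    if not connections:
        raise ValueError("need a nonempty set of selected connections")
    if len(covariates) != n:
        raise ValueError("covariate rows must match subjects")
    covariates = covariates.reset_index(drop=True)

    predicted = np.empty(n)
    predicted_var = np.empty(n)
    actual = covariates[target_column].to_numpy(float)
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        train_cov = covariates.iloc[train_idx]
        design = build_design(train_cov, severity_column=target_column, with_treatment=with_treatment)
        train_dcms = [subject_dcms[j] for j in train_idx]
        peb = fit_peb(train_dcms, design, selection=connections)
        # center/code the held-out subject with the training conventions
        known = {}
        row = covariates.iloc[i]
        known["age"] = float(row["age"]) - train_cov["age"].mean()
        known["sex"] = 0.5 if float(row["sex"]) > 0 else -0.5
        if with_treatment:
            known["treatment"] = 0.5 if float(row["treatment"]) > 0 else -0.5
        train_scores = train_cov[target_column].to_numpy(float)
        v0 = float(np.var(train_scores, ddof=1))
        if v0 <= 0:
            # degenerate: no score variability to learn from
            predicted[i] = train_scores.mean()
            predicted_var[i] = 0.0
            continue
        mean_c, var_c = predict_left_out(
            peb,
            subject_dcms[i],
            target_column,
            score_prior=(0.0, v0),
            known_covariates=known,
            propagate_effect_uncertainty=propagate_effect_uncertainty,
        )
        predicted[i] = train_scores.mean() + mean_c
        predicted_var[i] = var_c

    if np.ptp(predicted) == 0 or np.ptp(actual) == 0:
        return LOOCVResult(
            tuple(covariates["subject_id"]), predicted, predicted_var, actual,
            pearson_r=0.0, p_value=1.0, connections=tuple(connections), degenerate=True,
        )
    r = float(np.corrcoef(predicted, actual)[0, 1])
    tstat = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r**2))
    p = float(stats.t.sf(tstat, df=n - 2))  # one-tailed: validity means r > 0
    return LOOCVResult(
        tuple(covariates["subject_id"]), predicted, predicted_var, actual,
        pearson_r=r, p_value=p, connections=tuple(connections),
    )
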