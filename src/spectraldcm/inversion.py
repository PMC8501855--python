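"""Variational-Laplace inversion of one subject's cross-spectral data.

A Gaussian posterior q(theta) = N(m, S) over the generative parameters is
optimized by maximizing the free energy

    F = E_q[log p(data | theta)] - KL(q || prior)
      = accuracy - complexity,

a lower bound on the log model evidence.  The likelihood treats the
vectorized real and imaginary parts of the CSD residuals as Gaussian with
one precision hyperparameter per part (real / imaginary), updated in closed
form between damped Gauss-Newton (Levenberg-Marquardt) steps on the mean.
Proposals that lower F are rejected with increased damping (step-halving),
so the free-energy trace over accepted iterations is nondecreasing.

Gradients and curvatures use central finite differences in the packed
parameter space; with at most a few dozen parameters this is cheap and
avoids hand-derived gradients of the rational spectral model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .generative import (
    CANONICAL_ALPHA_E,
    CANONICAL_ALPHA_V,
    CANONICAL_BETA,
    ConnectivityMatrix,
    CrossSpectra,
    FluctuationParams,
    FrequencyGrid,
    HemodynamicParams,
    StabilityError,
    predicted_csd,
)

__all__ = [
    "ParameterPacking",
    "GaussianDensity",
    "SubjectDCM",
    "InversionConfig",
    "default_priors",
    "free_energy",
    "laplace_free_energy",
    "gaussian_kl",
    "invert_subject",
    "variance_explained",
    "csd_features",
]

# Prior variances (diagonal), per parameter class
PRIOR_VAR_COUPLING = 1.0 / 64.0
PRIOR_VAR_SELF = 1.0 / 256.0
PRIOR_VAR_LOG_AMP = 1.0 / 64.0
PRIOR_VAR_EXPONENT = 1.0 / 64.0
PRIOR_VAR_HEMO = 1.0 / 256.0


class ParameterPacking:
    """Deterministic packing of model parameters into a named flat vector.

    Order: off-diagonal couplings (row-major, skipping the diagonal), then
    self-connection log-scalings, then per-region log neural-fluctuation
    amplitudes (as deviations from the canonical scale), the shared neural
    exponent deviation, per-region log observation-noise amplitudes, the
    shared observation exponent deviation, and per-region hemodynamic decay
    and transit log-deviations.
    """

    def __init__(self, region_names):
        names = tuple(region_names)
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        self.region_names = names
        n = len(names)
        self.n_regions = n
        labels = []
        self._coupling_idx = []
        for i in range(n):
            for j in range(n):
                if i != j:
                    labels.append(f"a_{names[i]}<-{names[j]}")
                    self._coupling_idx.append((i, j))
        for r in names:
            labels.append(f"self_{r}")
        for r in names:
            labels.append(f"log_alpha_v_{r}")
        labels.append("beta_v_dev")
        for r in names:
            labels.append(f"log_alpha_e_{r}")
        labels.append("beta_e_dev")
        for r in names:
            labels.append(f"decay_ls_{r}")
        for r in names:
            labels.append(f"transit_ls_{r}")
        assert len(labels) == n * n + 4 * n + 2  # (n^2 - n) + n + (2n + 2) + 2n
        self.names = tuple(labels)
        self.size = len(labels)
        self._index = {nm: k for k, nm in enumerate(labels)}

    def index(self, name: str) -> int:
        return self._index[name]

    def coupling_names(self, include_self: bool = True):
        """Names of connectivity parameters (the ones that ascend to the group level)."""
        out = [f"a_{t}<-{s}" for (i, j) in self._coupling_idx for t, s in [(self.region_names[i], self.region_names[j])]]
        if include_self:
            out += [f"self_{r}" for r in self.region_names]
        return out

    def coupling_name(self, target: str, source: str) -> str:
        if target == source:
            return f"self_{target}"
        return f"a_{target}<-{source}"

    def pack(self, A: ConnectivityMatrix, fluct: FluctuationParams, hemo: HemodynamicParams) -> np.ndarray:
        n = self.n_regions
        v = np.empty(self.size)
        k = 0
        for (i, j) in self._coupling_idx:
            v[k] = A.couplings[i, j]
            k += 1
        v[k : k + n] = A.self_log_scale
        k += n
        v[k : k + n] = np.log(fluct.alpha_v / CANONICAL_ALPHA_V)
        k += n
        v[k] = fluct.beta_v - CANONICAL_BETA
        k += 1
        v[k : k + n] = np.log(fluct.alpha_e / CANONICAL_ALPHA_E)
        k += n
        v[k] = fluct.beta_e - CANONICAL_BETA
        k += 1
        v[k : k + n] = hemo.decay_log_scale
        k += n
        v[k : k + n] = hemo.transit_log_scale
        return v

    def unpack(self, v: np.ndarray):
        n = self.n_regions
        v = np.asarray(v, float)
        if v.shape != (self.size,):
            raise ValueError(f"expected vector of length {self.size}")
        A = np.zeros((n, n))
        k = 0
        for (i, j) in self._coupling_idx:
            A[i, j] = v[k]
            k += 1
        s = v[k : k + n]
        k += n
        alpha_v = CANONICAL_ALPHA_V * np.exp(v[k : k + n])
        k += n
        beta_v = CANONICAL_BETA + v[k]
        k += 1
        alpha_e = CANONICAL_ALPHA_E * np.exp(v[k : k + n])
        k += n
        beta_e = CANONICAL_BETA + v[k]
        k += 1
        decay = v[k : k + n]
        k += n
        transit = v[k : k + n]
        return (
            ConnectivityMatrix(self.region_names, A, s.copy()),
            FluctuationParams(alpha_v, beta_v, alpha_e, beta_e),
            HemodynamicParams(decay.copy(), transit.copy()),
        )


@dataclass(frozen=True)
class GaussianDensity:
    """Multivariate Gaussian with named dimensions (mean + covariance)."""

    mean: np.ndarray
    cov: np.ndarray
    names: tuple = ()

    def __post_init__(self):
        m = np.atleast_1d(np.array(self.mean, dtype=float))
        C = np.atleast_2d(np.array(self.cov, dtype=float))
        if C.shape != (m.size, m.size):
            raise ValueError("covariance shape must match mean length")
        if np.max(np.abs(C - C.T)) > 1e-10 * max(1.0, np.max(np.abs(C))):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", 0.5 * (C + C.T))
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def dim(self) -> int:
        return self.mean.size

    def validate_psd(self, tol: float = 1e-10) -> None:
        ev = np.linalg.eigvalsh(self.cov)
        if ev.min() < -tol * max(1.0, ev.max()):
            raise ValueError(f"covariance not PSD (min eigenvalue {ev.min():.3g})")

    def marginal(self, idx) -> "GaussianDensity":
        idx = np.asarray(idx, int)
        names = tuple(self.names[i] for i in idx) if self.names else ()
        return GaussianDensity(self.mean[idx], self.cov[np.ix_(idx, idx)], names)


@dataclass
class SubjectDCM:
    """One subject's inversion result for one network."""

    region_names: tuple
    prior: GaussianDensity
    posterior: GaussianDensity
    free_energy: float
    variance_explained_pct: float
    f_trace: list = field(default_factory=list)
    converged: bool = True
    subject_id: str = ""
    noise_log_precisions: tuple = (0.0, 0.0)

    def to_json(self) -> str:
        return json.dumps(
            {
                "subject_id": self.subject_id,
                "region_names": list(self.region_names),
                "parameter_names": list(self.posterior.names),
                "prior_mean": self.prior.mean.tolist(),
                "prior_cov": self.prior.cov.tolist(),
                "posterior_mean": self.posterior.mean.tolist(),
                "posterior_cov": self.posterior.cov.tolist(),
                "free_energy": self.free_energy,
                "variance_explained_pct": self.variance_explained_pct,
                "f_trace": list(map(float, self.f_trace)),
                "converged": self.converged,
                "noise_log_precisions": list(self.noise_log_precisions),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SubjectDCM":
        d = json.loads(text)
        names = tuple(d["parameter_names"])
        return cls(
            region_names=tuple(d["region_names"]),
            prior=GaussianDensity(np.array(d["prior_mean"]), np.array(d["prior_cov"]), names),
            posterior=GaussianDensity(np.array(d["posterior_mean"]), np.array(d["posterior_cov"]), names),
            free_energy=float(d["free_energy"]),
            variance_explained_pct=float(d["variance_explained_pct"]),
            f_trace=list(d["f_trace"]),
            converged=bool(d["converged"]),
            subject_id=d.get("subject_id", ""),
            noise_log_precisions=tuple(d.get("noise_log_precisions", (0.0, 0.0))),
        )


@dataclass(frozen=True)
class InversionConfig:
    max_iter: int = 128
    f_tol: float = 0.01
    n_converged: int = 3
    fd_step: float = 1e-4
    max_step_halvings: int = 8
    init_damping: float = 1.0
    psd_clip: float = 1e-8


def default_priors(region_names) -> GaussianDensity:
    """Shrinkage priors over the packed parameter vector: zero-centered,
    diagonal, tighter on self-connections and hemodynamics than on
    between-region couplings and noise parameters."""
    packing = ParameterPacking(region_names)
    if packing.n_regions < 2:
        raise ValueError("need at least 2 regions")
    var = np.empty(packing.size)
    for k, name in enumerate(packing.names):
        if name.startswith("a_"):
            var[k] = PRIOR_VAR_COUPLING
        elif name.startswith("self_"):
            var[k] = PRIOR_VAR_SELF
        elif name.startswith("log_alpha"):
            var[k] = PRIOR_VAR_LOG_AMP
        elif name.startswith("beta_"):
            var[k] = PRIOR_VAR_EXPONENT
        else:
            var[k] = PRIOR_VAR_HEMO
    return GaussianDensity(np.zeros(packing.size), np.diag(var), packing.names)


# ---------------------------------------------------------------------------
# Data features and free energy
# ---------------------------------------------------------------------------

def _feature_masks(n: int):
    iu_r = np.triu_indices(n, k=0)   # real part: upper triangle incl. diagonal
    iu_i = np.triu_indices(n, k=1)   # imaginary part: strict upper triangle
    return iu_r, iu_i


def csd_features(G: CrossSpectra) -> tuple[np.ndarray, np.ndarray]:
    """Vectorize a CrossSpectra into (real, imag) feature vectors without the
    redundant Hermitian copies (real: upper triangle incl. diagonal; imag:
    strict upper triangle), concatenated over frequencies."""
    n = G.n_regions
    iu_r, iu_i = _feature_masks(n)
    re = G.values[:, iu_r[0], iu_r[1]].real.ravel()
    im = G.values[:, iu_i[0], iu_i[1]].imag.ravel()
    return re, im


def gaussian_kl(q: GaussianDensity, p: GaussianDensity) -> float:
    """KL(q || p) between multivariate Gaussians (complexity term)."""
    d = q.dim
    if p.dim != d:
        raise ValueError("dimension mismatch")
    sign, logdet_p = np.linalg.slogdet(p.cov)
    if sign <= 0:
        raise ValueError("prior covariance is singular")
    sign_q, logdet_q = np.linalg.slogdet(q.cov)
    if sign_q <= 0:
        # allow degenerate q by clipping tiny eigenvalues
        ev, U = np.linalg.eigh(q.cov)
        ev = np.clip(ev, 1e-12 * max(1.0, ev.max()), None)
        logdet_q = float(np.sum(np.log(ev)))
    Pinv = np.linalg.inv(p.cov)
    dm = q.mean - p.mean
    return 0.5 * (np.trace(Pinv @ q.cov) + dm @ Pinv @ dm - d + logdet_p - logdet_q)


def laplace_free_energy(residual, jacobian, q, prior, lam, group_slices, scale: float = 1.0) -> float:
    """Laplace free energy for a Gaussian observation model.

    residual: data - prediction evaluated at q.mean (length N)
    jacobian: d(prediction)/d(theta) at q.mean (N x d)
    lam: precision per residual group; group_slices: slice per group
    scale: likelihood tempering in (0, 1] -- the weight of the accuracy
    term, used to discount smooth spectral features whose effective degrees
    of freedom are below their raw count
    """
    residual = np.asarray(residual, float)
    jacobian = np.asarray(jacobian, float)
    acc = 0.0
    for lam_g, sl in zip(lam, group_slices):
        e_g = residual[sl]
        J_g = jacobian[sl]
        n_g = e_g.size
        acc += -0.5 * lam_g * (e_g @ e_g) + 0.5 * n_g * np.log(lam_g) - 0.5 * n_g * np.log(2 * np.pi)
        acc += -0.5 * lam_g * np.trace(q.cov @ (J_g.T @ J_g))
    return float(scale * acc - gaussian_kl(q, prior))


class _CsdModel:
    """Forward map from packed parameters to the CSD feature vector."""

    def __init__(self, data: CrossSpectra):
        self.packing = ParameterPacking(data.region_names)
        self.grid = data.grid
        re, im = csd_features(data)
        self.y = np.concatenate([re, im])
        self.slice_r = slice(0, re.size)
        self.slice_i = slice(re.size, re.size + im.size)
        self.n_r, self.n_i = re.size, im.size
        # likelihood tempering: an estimated CSD is a smooth function of a
        # limited number of statistics; weight the accuracy term so those
        # statistics are not counted more than once
        if data.effective_dof is not None:
            self.temper = float(min(1.0, data.effective_dof / self.y.size))
        else:
            self.temper = 1.0

    def predict(self, theta: np.ndarray) -> np.ndarray:
        A, fl, hm = self.packing.unpack(theta)
        G = predicted_csd(A, fl, hm, self.grid)
        re, im = csd_features(G)
        return np.concatenate([re, im])

    def jacobian(self, theta: np.ndarray, step: float) -> np.ndarray:
        d = theta.size
        J = np.empty((self.y.size, d))
        for k in range(d):
            tp = theta.copy()
            tm = theta.copy()
            tp[k] += step
            tm[k] -= step
            try:
                fp = self.predict(tp)
            except StabilityError:
                fp = None
            try:
                fm = self.predict(tm)
            except StabilityError:
                fm = None
            if fp is not None and fm is not None:
                J[:, k] = (fp - fm) / (2 * step)
            elif fp is not None:
                J[:, k] = (fp - self.predict(theta)) / step
            elif fm is not None:
                J[:, k] = (self.predict(theta) - fm) / step
            else:
                J[:, k] = 0.0
        return J


def _closed_form_precisions(model: _CsdModel, e, J, S):
    """M-step: per-group residual precisions maximizing F, with a weak
    upper bound to keep the noiseless self-consistency case finite."""
    lams = []
    for sl in (model.slice_r, model.slice_i):
        e_g = e[sl]
        J_g = J[sl]
        n_g = max(e_g.size, 1)
        sse = float(e_g @ e_g) + float(np.trace(S @ (J_g.T @ J_g)))
        lam = n_g / max(sse, 1e-12)
        lams.append(min(lam, 1e10))
    return tuple(lams)


def free_energy(q: GaussianDensity, data: CrossSpectra, prior: GaussianDensity, lam=None) -> float:
    """Free energy of a Gaussian posterior against cross-spectral data.

    If ``lam`` (per-group residual precisions) is omitted it is set to its
    closed-form optimum given q.
    """
    model = _CsdModel(data)
    if q.dim != model.packing.size or prior.dim != model.packing.size:
        raise ValueError("density dimension does not match the network parameterization")
    prior.validate_psd()
    e = model.y - model.predict(q.mean)
    J = model.jacobian(q.mean, InversionConfig().fd_step)
    if lam is None:
        lam = _closed_form_precisions(model, e, J, q.cov)
    return laplace_free_energy(e, J, q, prior, lam, (model.slice_r, model.slice_i), scale=model.temper)


def variance_explained(model_csd: CrossSpectra, data_csd: CrossSpectra) -> float:
    """Percent variance of the data CSD explained by the model CSD:
    100*(1 - SS_res/SS_tot) over real and imaginary parts of all entries."""
    if len(model_csd.grid) != len(data_csd.grid) or not np.allclose(
        model_csd.grid.freqs_hz, data_csd.grid.freqs_hz
    ):
        raise ValueError("model and data must share the frequency grid")
    if model_csd.region_names != data_csd.region_names:
        raise ValueError("model and data must share regions")
    y = np.concatenate([data_csd.values.real.ravel(), data_csd.values.imag.ravel()])
    yh = np.concatenate([model_csd.values.real.ravel(), model_csd.values.imag.ravel()])
    ss_tot = float(y @ y)
    if ss_tot == 0:
        raise ValueError("data cross-spectra are identically zero")
    ss_res = float((y - yh) @ (y - yh))
    return 100.0 * (1.0 - ss_res / ss_tot)


def _psd_project(C: np.ndarray, clip: float) -> np.ndarray:
    C = 0.5 * (C + C.T)
    ev, U = np.linalg.eigh(C)
    ev = np.clip(ev, clip, None)
    return (U * ev) @ U.T


def invert_subject(
    data: CrossSpectra,
    prior: GaussianDensity | None = None,
    config: InversionConfig = InversionConfig(),
    subject_id: str = "",
) -> SubjectDCM:
    """Fit the spectral model to one subject's estimated cross-spectra.

    Damped Gauss-Newton ascent on the free energy, initialized at the prior
    mean, with closed-form precision updates between steps.  Deterministic:
    identical inputs and config give an identical result.
    """
    model = _CsdModel(data)
    packing = model.packing
    if prior is None:
        prior = default_priors(data.region_names)
    if prior.dim != packing.size:
        raise ValueError("prior dimension does not match network parameterization")
    prior.validate_psd()
    P0 = np.linalg.inv(prior.cov)
    m0 = prior.mean

    def full_state(m):
        """(F, e, J, S, lam) at mean m, or None if the model is unstable there."""
        try:
            pred = model.predict(m)
        except StabilityError:
            return None
        e = model.y - pred
        J = model.jacobian(m, config.fd_step)
        H_like = None
        # iterate S <-> lam once (S depends on lam and vice versa); a single
        # pass is enough for a monotone trace in practice
        lam = _closed_form_precisions(model, e, J, np.zeros((packing.size, packing.size)))
        for _ in range(2):
            Lam_JtJ = lam[0] * (J[model.slice_r].T @ J[model.slice_r]) + lam[1] * (
                J[model.slice_i].T @ J[model.slice_i]
            )
            S = np.linalg.inv(model.temper * Lam_JtJ + P0)
            lam = _closed_form_precisions(model, e, J, S)
        q = GaussianDensity(m, _psd_project(S, config.psd_clip), packing.names)
        F = laplace_free_energy(e, J, q, prior, lam, (model.slice_r, model.slice_i), scale=model.temper)
        return F, e, J, q.cov, lam

    state = full_state(m0.copy())
    if state is None or not np.isfinite(state[0]):
        raise ValueError("free energy is not finite at the prior mean (initialization failure)")
    F, e, J, S, lam = state
    m = m0.copy()
    trace = [F]
    damping = config.init_damping
    n_small = 0
    converged = False

    for _ in range(config.max_iter):
        # gradient and curvature of F with respect to the mean
        g = model.temper * (
            lam[0] * (J[model.slice_r].T @ e[model.slice_r])
            + lam[1] * (J[model.slice_i].T @ e[model.slice_i])
        ) - P0 @ (m - m0)
        H = model.temper * (
            lam[0] * (J[model.slice_r].T @ J[model.slice_r])
            + lam[1] * (J[model.slice_i].T @ J[model.slice_i])
        ) + P0
        accepted = False
        for _half in range(config.max_step_halvings):
            Hd = H + damping * np.diag(np.diag(H))
            try:
                step = np.linalg.solve(Hd, g)
            except np.linalg.LinAlgError:
                damping *= 4.0
                continue
            cand = full_state(m + step)
            if cand is not None and np.isfinite(cand[0]) and cand[0] >= F:
                dF = cand[0] - F
                m = m + step
                F, e, J, S, lam = cand
                trace.append(F)
                damping = max(damping / 2.0, 1e-8)
                accepted = True
                break
            damping *= 4.0
        if not accepted:
            # no admissible uphill step: treat as converged at current m
            converged = True
            break
        if dF < config.f_tol:
            n_small += 1
            if n_small >= config.n_converged:
                converged = True
                break
        else:
            n_small = 0

    posterior = GaussianDensity(m, _psd_project(S, config.psd_clip), packing.names)
    A, fl, hm = packing.unpack(m)
    ve = variance_explained(predicted_csd(A, fl, hm, model.grid), data)
    return SubjectDCM(
        region_names=data.region_names,
        prior=GaussianDensity(prior.mean, prior.cov, packing.names),
        posterior=posterior,
        free_energy=float(F),
        variance_explained_pct=float(ve),
        f_trace=trace,
        converged=converged,
        subject_id=subject_id,
        noise_log_precisions=(float(np.log(lam[0])), float(np.log(lam[1]))),
    )
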