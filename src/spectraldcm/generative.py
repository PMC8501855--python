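"""Forward model: from neuronal coupling parameters to predicted BOLD cross-spectra.

The resting-state network is modeled as a linear stochastic system

    dx/dt = J x(t) + v(t)

where ``J`` is the effective-connectivity Jacobian (off-diagonal entries are
directed coupling rates in Hz, column -> row; diagonal entries are
self-inhibition rates ``-0.5 * exp(s)`` with ``s`` a unitless log-scaling) and
``v(t)`` are endogenous neural fluctuations with scale-free (power-law)
spectral density ``g_v(f) = alpha_v * f**(-beta_v)``.  Neuronal activity is
observed through a linearized hemodynamic kernel (one complex gain per region
per frequency) plus additive measurement noise with its own power-law
spectrum ``g_e(f) = alpha_e * f**(-beta_e)``.

Because the dynamics are linear, the cross-spectral density of the observed
BOLD signal has the closed form

    G_y(f) = D(f) H(f) G_v(f) H(f)^H D(f)^H + G_e(f)

with ``H(f) = (2*pi*i*f*I - J)^-1`` the neuronal transfer function and
``D(f)`` the diagonal matrix of hemodynamic gains.  This module evaluates that
expression; inversion of the map is done in :mod:`spectraldcm.inversion`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StabilityError",
    "FrequencyGrid",
    "ConnectivityMatrix",
    "FluctuationParams",
    "HemodynamicParams",
    "CrossSpectra",
    "default_grid",
    "transfer_function",
    "power_law_spectrum",
    "hrf_transfer",
    "predicted_csd",
    "CANONICAL_DECAY_HZ",
    "CANONICAL_TRANSIT_HZ",
    "CANONICAL_ALPHA_V",
    "CANONICAL_ALPHA_E",
    "CANONICAL_BETA",
]

# Canonical hemodynamic rate constants (per second).  The per-region free
# parameters are multiplicative log-deviations from these.
CANONICAL_DECAY_HZ = 0.64
CANONICAL_TRANSIT_HZ = 0.5

# Canonical fluctuation/noise scales.  Chosen so that, at the prior mean
# (all log-deviations zero, self-decay 0.5 Hz), the modeled region variance
# over the default band is approximately 1 -- matching time series that have
# been standardized to unit grand variance -- with a neural:observation
# variance ratio of about 4:1.  See docs/methods.md.
CANONICAL_ALPHA_V = 0.06
CANONICAL_ALPHA_E = 0.03
CANONICAL_BETA = 1.0


class StabilityError(ValueError):
    """Raised when the effective Jacobian has an eigenvalue with Re >= 0."""


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing, strictly positive frequencies in Hz."""

    freqs_hz: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs_hz, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a nonempty 1-D array")
        if np.any(f <= 0):
            raise ValueError("all frequencies must be > 0 (power-law spectra diverge at 0)")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "freqs_hz", f)

    def __len__(self):
        return self.freqs_hz.size


def default_grid(f_min: float = 1.0 / 128.0, f_max: float = 0.2, n: int = 32) -> FrequencyGrid:
    """Default analysis band: 32 log-spaced points from the high-pass cutoff
    (1/128 Hz) to the Nyquist frequency of a 2.5 s sampling interval (0.2 Hz)."""
    return FrequencyGrid(np.geomspace(f_min, f_max, n))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Directed effective connectivity among named regions.

    ``couplings[i, j]`` (i != j) is the rate (Hz) at which activity in region
    ``j`` drives region ``i`` (column -> row).  The diagonal of ``couplings``
    is ignored; effective self-connections are ``-0.5 * exp(self_log_scale)``,
    which keeps them strictly negative (self-inhibition) for any real value
    of the log-scaling.
    """

    region_names: tuple
    couplings: np.ndarray
    self_log_scale: np.ndarray

    def __post_init__(self):
        names = tuple(self.region_names)
        n = len(names)
        if len(set(names)) != n:
            raise ValueError("region names must be unique")
        A = np.array(self.couplings, dtype=float)
        s = np.array(self.self_log_scale, dtype=float)
        if A.shape != (n, n):
            raise ValueError(f"couplings must be {n}x{n}, got {A.shape}")
        if s.shape != (n,):
            raise ValueError(f"self_log_scale must have length {n}")
        object.__setattr__(self, "region_names", names)
        object.__setattr__(self, "couplings", A)
        object.__setattr__(self, "self_log_scale", s)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def jacobian(self) -> np.ndarray:
        """Effective Jacobian: off-diagonal couplings with the scaled
        self-inhibition -0.5*exp(s) on the diagonal."""
        J = self.couplings.copy()
        np.fill_diagonal(J, -0.5 * np.exp(self.self_log_scale))
        return J

    def is_stable(self) -> bool:
        return bool(np.all(np.linalg.eigvals(self.jacobian()).real < 0))


@dataclass(frozen=True)
class FluctuationParams:
    """Power-law spectral parameters of neural fluctuations (v) and
    observation noise (e): amplitudes are per-region, exponents shared."""

    alpha_v: np.ndarray
    beta_v: float
    alpha_e: np.ndarray
    beta_e: float

    def __post_init__(self):
        av = np.atleast_1d(np.array(self.alpha_v, dtype=float))
        ae = np.atleast_1d(np.array(self.alpha_e, dtype=float))
        if np.any(av <= 0) or np.any(ae <= 0):
            raise ValueError("fluctuation amplitudes must be strictly positive")
        if not (np.isfinite(self.beta_v) and np.isfinite(self.beta_e)):
            raise ValueError("spectral exponents must be finite")
        object.__setattr__(self, "alpha_v", av)
        object.__setattr__(self, "alpha_e", ae)
        object.__setattr__(self, "beta_v", float(self.beta_v))
        object.__setattr__(self, "beta_e", float(self.beta_e))

    @classmethod
    def canonical(cls, n_regions: int) -> "FluctuationParams":
        return cls(
            alpha_v=np.full(n_regions, CANONICAL_ALPHA_V),
            beta_v=CANONICAL_BETA,
            alpha_e=np.full(n_regions, CANONICAL_ALPHA_E),
            beta_e=CANONICAL_BETA,
        )


@dataclass(frozen=True)
class HemodynamicParams:
    """Per-region log-deviations of the two hemodynamic rate constants from
    their canonical values; zeros give the canonical kernel exactly."""

    decay_log_scale: np.ndarray
    transit_log_scale: np.ndarray

    def __post_init__(self):
        d = np.atleast_1d(np.array(self.decay_log_scale, dtype=float))
        t = np.atleast_1d(np.array(self.transit_log_scale, dtype=float))
        if d.shape != t.shape:
            raise ValueError("decay and transit log-scales must have the same length")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(t))):
            raise ValueError("hemodynamic log-deviations must be finite")
        object.__setattr__(self, "decay_log_scale", d)
        object.__setattr__(self, "transit_log_scale", t)

    @classmethod
    def canonical(cls, n_regions: int) -> "HemodynamicParams":
        return cls(np.zeros(n_regions), np.zeros(n_regions))

    def rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(decay, transit) rates in Hz after applying the log-deviations."""
        kappa = CANONICAL_DECAY_HZ * np.exp(self.decay_log_scale)
        gamma = CANONICAL_TRANSIT_HZ * np.exp(self.transit_log_scale)
        return kappa, gamma


@dataclass(frozen=True)
class CrossSpectra:
    """Complex cross-spectral density matrices on a frequency grid.

    ``values[k]`` is the n x n (two-sided, per-Hz) CSD matrix at
    ``grid.freqs_hz[k]``; Hermitian and positive semidefinite at every
    frequency.
    """

    grid: FrequencyGrid
    region_names: tuple
    values: np.ndarray
    # number of independent statistics behind an *estimated* CSD (e.g. the
    # parameter count of the spectral estimator); None for model-implied
    # spectra.  Consumers can use it to temper likelihoods so that smooth,
    # highly correlated frequency samples are not over-counted as data.
    effective_dof: float | None = None

    def __post_init__(self):
        names = tuple(self.region_names)
        V = np.array(self.values, dtype=complex)
        n = len(names)
        if V.shape != (len(self.grid), n, n):
            raise ValueError(f"values must have shape ({len(self.grid)}, {n}, {n}), got {V.shape}")
        object.__setattr__(self, "region_names", names)
        object.__setattr__(self, "values", V)

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def max_hermitian_error(self) -> float:
        return float(np.max(np.abs(self.values - np.conj(np.swapaxes(self.values, 1, 2)))))

    def min_eigenvalue(self) -> float:
        return float(np.min(np.linalg.eigvalsh(0.5 * (self.values + np.conj(np.swapaxes(self.values, 1, 2))))))

    def validate(self, tol: float = 1e-8) -> None:
        if self.max_hermitian_error() > tol:
            raise ValueError("cross-spectra are not Hermitian")
        if self.min_eigenvalue() < -tol:
            raise ValueError("cross-spectra are not positive semidefinite")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _check_stable(J: np.ndarray) -> None:
    ev = np.linalg.eigvals(J)
    worst = ev[np.argmax(ev.real)]
    if worst.real >= 0:
        raise StabilityError(
            f"effective Jacobian is unstable: eigenvalue {worst:.6g} has nonnegative real part"
        )


def transfer_function(A: ConnectivityMatrix, grid: FrequencyGrid) -> np.ndarray:
    """Neuronal transfer function H(f) = (2*pi*i*f*I - J)^-1, shape (F, n, n)."""
    J = A.jacobian()
    _check_stable(J)
    n = J.shape[0]
    omega = 2j * np.pi * grid.freqs_hz
    # batched solve: (i*omega*I - J) H = I for each frequency
    M = omega[:, None, None] * np.eye(n)[None] - J[None]
    H = np.linalg.solve(M, np.broadcast_to(np.eye(n, dtype=complex), M.shape))
    if not np.all(np.isfinite(H)):
        raise FloatingPointError("non-finite entries in transfer function")
    return H


def power_law_spectrum(alpha: float, beta: float, grid: FrequencyGrid) -> np.ndarray:
    """Scale-free spectral density g(f) = alpha * f**(-beta) on the grid."""
    if alpha <= 0:
        raise ValueError("amplitude must be strictly positive")
    f = grid.freqs_hz
    if np.any(f <= 0):
        raise ValueError("power-law spectrum requires strictly positive frequencies")
    return alpha * f ** (-beta)


def hrf_transfer(hemo: HemodynamicParams, grid: FrequencyGrid) -> np.ndarray:
    """Linearized hemodynamic transfer per region per frequency, shape (F, n).

    The kernel is a difference of exponentials with rates kappa (signal
    decay) and gamma (transit), normalized to unit gain at f -> 0:

        h(t) = kappa*gamma/(kappa - gamma) * (exp(-gamma t) - exp(-kappa t))
        H(f) = kappa*gamma / ((kappa + 2*pi*i*f) * (gamma + 2*pi*i*f))

    Smooth, low-pass, and exactly canonical when both log-deviations are 0.
    """
    kappa, gamma = hemo.rates()
    w = 2j * np.pi * grid.freqs_hz
    return (kappa * gamma)[None, :] / ((kappa[None, :] + w[:, None]) * (gamma[None, :] + w[:, None]))


def hrf_kernel(hemo: HemodynamicParams, t: np.ndarray) -> np.ndarray:
    """Time-domain hemodynamic kernel sampled at times ``t`` (s), shape (nt, n)."""
    kappa, gamma = hemo.rates()
    t = np.asarray(t, dtype=float)[:, None]
    denom = kappa - gamma
    # kappa == gamma degenerates to a gamma-density kernel; perturb slightly
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    c = kappa * gamma / denom
    return c[None, :] * (np.exp(-gamma[None, :] * t) - np.exp(-kappa[None, :] * t))


def predicted_csd(
    A: ConnectivityMatrix,
    fluct: FluctuationParams,
    hemo: HemodynamicParams,
    grid: FrequencyGrid,
) -> CrossSpectra:
    """Predicted BOLD cross-spectral density G_y(f) (closed form).

    G_y = D H G_v H^H D^H + G_e with D the diagonal hemodynamic gain, G_v and
    G_e diagonal power-law spectra of neural fluctuations and observation
    noise.  The returned matrices are exactly Hermitian (symmetrized) and PSD
    by construction.
    """
    n = A.n_regions
    if fluct.alpha_v.shape != (n,) or fluct.alpha_e.shape != (n,):
        raise ValueError("fluctuation amplitudes must be per-region")
    if hemo.decay_log_scale.shape != (n,):
        raise ValueError("hemodynamic parameters must be per-region")
    H = transfer_function(A, grid)                      # (F, n, n)
    D = hrf_transfer(hemo, grid)                        # (F, n)
    f = grid.freqs_hz
    gv = fluct.alpha_v[None, :] * f[:, None] ** (-fluct.beta_v)   # (F, n)
    ge = fluct.alpha_e[None, :] * f[:, None] ** (-fluct.beta_e)
    DH = D[:, :, None] * H                              # row-scale H by hemodynamic gain
    G = np.einsum("fik,fk,fjk->fij", DH, gv, np.conj(DH))
    G[:, np.arange(n), np.arange(n)] += ge
    G = 0.5 * (G + np.conj(np.swapaxes(G, 1, 2)))
    return CrossSpectra(grid=grid, region_names=A.region_names, values=G)
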