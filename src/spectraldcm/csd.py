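"""Data features: cross-spectral density estimation from BOLD time series.

The model is fitted to second-order statistics of the observed signal, not
to the time series themselves.  At the short run lengths typical of
resting-state studies (~90 scans) raw periodograms are far too noisy, so the
estimator here is parametric: a multivariate autoregressive (MAR) model is
fitted by ridge-regularized least squares and its rational spectrum is
evaluated on the analysis frequency grid.  MAR spectra are smooth in
frequency and Hermitian/PSD by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .generative import CrossSpectra, FrequencyGrid

__all__ = [
    "RegionTimeSeries",
    "DegenerateInputError",
    "ConditioningError",
    "standardize",
    "estimate_csd",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
]

DEFAULT_MAR_ORDER = 8


class DegenerateInputError(ValueError):
    """Raised for inputs with no usable variance (e.g. a constant column)."""


class ConditioningError(ValueError):
    """Raised when the autoregression is numerically ill-conditioned."""


@dataclass(frozen=True)
class RegionTimeSeries:
    """Multi-region BOLD time series: scans x regions, sampled every TR seconds."""

    region_names: tuple
    sampling_interval_s: float
    values: np.ndarray

    def __post_init__(self):
        names = tuple(self.region_names)
        X = np.array(self.values, dtype=float)
        if len(names) < 2:
            raise ValueError("need at least 2 regions")
        if X.ndim != 2 or X.shape[1] != len(names):
            raise ValueError("values must be scans x regions matching region_names")
        if X.shape[0] < 32:
            raise ValueError("need at least 32 scans")
        if not np.all(np.isfinite(X)):
            raise ValueError("time series contain missing/non-finite values")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be positive")
        object.__setattr__(self, "region_names", names)
        object.__setattr__(self, "values", X)

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


def standardize(ts: RegionTimeSeries) -> RegionTimeSeries:
    """Center each region and divide by the grand standard deviation.

    Using one shared scale (the SD pooled over all regions after centering)
    preserves the relative amplitudes between regions, which carry
    information about region-specific fluctuation amplitudes.
    """
    X = ts.values
    if np.any(np.std(X, axis=0) == 0):
        bad = [ts.region_names[i] for i in np.flatnonzero(np.std(X, axis=0) == 0)]
        raise DegenerateInputError(f"constant region time series: {bad}")
    Xc = X - X.mean(axis=0, keepdims=True)
    grand_sd = np.sqrt(np.mean(Xc**2))
    return RegionTimeSeries(ts.region_names, ts.sampling_interval_s, Xc / grand_sd)


def estimate_csd(
    ts: RegionTimeSeries,
    grid: FrequencyGrid,
    order: int = DEFAULT_MAR_ORDER,
) -> CrossSpectra:
    """MAR(order) cross-spectral density of ``ts`` on ``grid``.

    Fits x_t = sum_k A_k x_{t-k} + eps by least squares with a small ridge
    (1e-6 of the mean predictor variance) and evaluates

        S(f) = TR * Abar(f)^-1 Sigma Abar(f)^-H,
        Abar(f) = I - sum_k A_k exp(-2*pi*i*f*k*TR)

    which is the two-sided per-Hz spectral density of the fitted process.
    """
    X = ts.values
    N, n = X.shape
    if N <= order * n + 1:
        raise ValueError(f"need more than order*regions+1 = {order * n + 1} scans, have {N}")
    fmax = float(grid.freqs_hz[-1])
    nyquist = 0.5 / ts.sampling_interval_s
    if fmax > nyquist * (1 + 1e-9):
        raise ValueError(f"grid extends beyond the Nyquist frequency {nyquist:.4g} Hz")

    Xc = X - X.mean(axis=0, keepdims=True)
    Y = Xc[order:]
    Z = np.hstack([Xc[order - k : N - k] for k in range(1, order + 1)])  # lags 1..p
    ZtZ = Z.T @ Z
    ridge = 1e-6 * np.trace(ZtZ) / ZtZ.shape[0]
    M = ZtZ + ridge * np.eye(ZtZ.shape[0])
    cond = np.linalg.cond(M)
    if cond > 1e12:
        raise ConditioningError(
            f"autoregression ill-conditioned (cond={cond:.2g}); try a lower order than {order}"
        )
    B = np.linalg.solve(M, Z.T @ Y)  # (p*n, n); block k rows give A_k^T
    resid = Y - Z @ B
    Sigma = resid.T @ resid / Y.shape[0]
    Sigma = 0.5 * (Sigma + Sigma.T)

    tr = ts.sampling_interval_s
    f = grid.freqs_hz
    A_k = np.stack([B[(k - 1) * n : k * n].T for k in range(1, order + 1)])  # (p, n, n)
    phase = np.exp(-2j * np.pi * np.outer(f, np.arange(1, order + 1)) * tr)  # (F, p)
    Abar = np.eye(n)[None] - np.einsum("fk,kij->fij", phase, A_k)
    Ainv = np.linalg.inv(Abar)
    S = tr * np.einsum("fik,kl,fjl->fij", Ainv, Sigma, np.conj(Ainv))
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))
    # the smooth MAR spectrum carries at most as much information as the
    # statistics it was computed from: order*n^2 coefficients plus the
    # residual covariance (capped by the number of scans)
    dof = min(order * n * n + n * (n + 1) / 2, N * n)
    return CrossSpectra(grid=grid, region_names=ts.region_names, values=S, effective_dof=float(dof))


# ---------------------------------------------------------------------------
# Text I/O: TSV with header row of region names; optional "# tr_s=" comment
# ---------------------------------------------------------------------------

def write_timeseries_tsv(ts: RegionTimeSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tr_s={ts.sampling_interval_s}\n")
        fh.write("\t".join(ts.region_names) + "\n")
        np.savetxt(fh, ts.values, delimiter="\t", fmt="%.10g")


def read_timeseries_tsv(path, tr_s: float | None = None) -> RegionTimeSeries:
    """Read a region x scan table; TR from a '# tr_s=' header line or argument."""
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    idx = 0
    for line in lines:
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.startswith("tr_s="):
                tr_s = float(stripped.split("=", 1)[1])
            idx += 1
        else:
            break
    if tr_s is None:
        raise ValueError(f"{path}: sampling interval not given ('# tr_s=' line or tr_s argument)")
    names = tuple(lines[idx].split("\t"))
    data = np.loadtxt(io.StringIO("\n".join(lines[idx + 1 :])), delimiter="\t", ndmin=2)
    return RegionTimeSeries(names, tr_s, data)
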