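"""Synthetic-cohort generator: resting-state BOLD with known ground truth.

Emulates small sensorimotor networks (2-4 regions) sampled at TR = 2.5 s in
~4-minute runs: each subject's effective connectivity is the group mean plus
covariate-linked effects plus between-subject variation; neuronal dynamics
are integrated by Euler-Maruyama with power-law (1/f-like) fluctuations,
passed through the hemodynamic kernel, downsampled to TR and corrupted with
power-law observation noise.  Ground truth is retained alongside the data so
that every stage of the analysis chain can be scored against it.

Also provides the first-principal-component extraction used to summarize a
region's voxels as a single representative time series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .csd import RegionTimeSeries, write_timeseries_tsv
from .generative import (
    ConnectivityMatrix,
    FluctuationParams,
    HemodynamicParams,
    StabilityError,
    hrf_kernel,
)
from .inversion import GaussianDensity, ParameterPacking, SubjectDCM, default_priors

__all__ = [
    "NETWORKS",
    "CohortConfig",
    "SyntheticSubject",
    "SyntheticCohort",
    "default_group_mean",
    "sample_cohort",
    "simulate_bold",
    "pca_extract",
    "emulate_first_level",
    "write_cohort",
]

# Region sets of the six sensorimotor networks plus the auditory-language
# probe network.  Motor: supplementary motor area above primary motor cortex;
# exteroceptive: three primary sensory cortices below the lateral frontal
# pole; interoceptive: posterior below anterior insula; auditory-language:
# thalamus -> A1 -> Broca -> frontal pole.
NETWORKS = {
    "left_motor": ("SMA", "MC"),
    "right_motor": ("SMA", "MC"),
    "left_exteroceptive": ("V1", "A1", "SSC", "FP1"),
    "right_exteroceptive": ("V1", "A1", "SSC", "FP1"),
    "left_interoceptive": ("AI", "PI"),
    "right_interoceptive": ("AI", "PI"),
    "left_auditory_language": ("Thal", "A1", "Bro", "FP1"),
}

# Hierarchical level of each region within its network (higher = more
# associative).  Used to orient forward (low->high) vs backward (high->low)
# connections when building default group means.
_HIERARCHY = {
    "left_motor": {"SMA": 1, "MC": 0},
    "right_motor": {"SMA": 1, "MC": 0},
    "left_exteroceptive": {"V1": 0, "A1": 0, "SSC": 0, "FP1": 1},
    "right_exteroceptive": {"V1": 0, "A1": 0, "SSC": 0, "FP1": 1},
    "left_interoceptive": {"PI": 0, "AI": 1},
    "right_interoceptive": {"PI": 0, "AI": 1},
    "left_auditory_language": {"Thal": 0, "A1": 1, "Bro": 2, "FP1": 3},
}

_MOTOR_NETWORKS = {"left_motor", "right_motor"}

DEFAULT_FORWARD = 0.2
DEFAULT_BACKWARD = -0.2


def default_group_mean(network: str) -> ConnectivityMatrix:
    """Qualitative group-mean pattern used as a test fixture: sensory
    networks get excitatory forward / inhibitory backward couplings between
    adjacent hierarchical levels; motor networks the reverse."""
    regions = NETWORKS[network]
    levels = _HIERARCHY[network]
    n = len(regions)
    A = np.zeros((n, n))
    fwd, bwd = DEFAULT_FORWARD, DEFAULT_BACKWARD
    if network in _MOTOR_NETWORKS:
        fwd, bwd = -DEFAULT_FORWARD, -DEFAULT_BACKWARD
    for i, tgt in enumerate(regions):
        for j, src in enumerate(regions):
            if i == j:
                continue
            if levels[tgt] - levels[src] == 1:
                A[i, j] = fwd
            elif levels[src] - levels[tgt] == 1:
                A[i, j] = bwd
    return ConnectivityMatrix(regions, A, np.zeros(n))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``effects`` maps covariate name -> {(target, source): slope}; slopes are
    per unit of the centered covariate (severity: per BDI point; sex and
    treatment are coded +/-0.5, so their slope is the full group difference).
    ``between_sd`` is the SD of subject-level variation added to every
    coupling (off-diagonal rates, in Hz) and self log-scaling.
    """

    network: str = "left_exteroceptive"
    n_subjects: int = 40
    scans: int = 91          # 4-min run at TR 2.5 s minus 5 discarded scans
    tr_s: float = 2.5
    seed: int = 0
    effects: dict = field(default_factory=dict)
    between_sd: float = 0.1
    patient_fraction: float = 0.7
    bdi_patient_range: tuple = (10, 30)   # mild-to-moderate severity
    bdi_control_range: tuple = (0, 9)
    age_mean: float = 33.0
    age_sd: float = 9.0
    female_fraction: float = 0.73
    with_treatment: bool = False
    generate_bold: bool = True
    dt_s: float = 0.1
    burn_in_s: float = 60.0
    max_stability_tries: int = 100


@dataclass
class SyntheticSubject:
    subject_id: str
    covariates: dict
    true_connectivity: ConnectivityMatrix
    timeseries: RegionTimeSeries | None = None


@dataclass
class SyntheticCohort:
    config: CohortConfig
    region_names: tuple
    group_mean: ConnectivityMatrix
    effects: dict
    subjects: list

    def covariates_df(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id}
            row.update(s.covariates)
            rows.append(row)
        return pd.DataFrame(rows)

    def true_coupling(self, subject_idx: int, target: str, source: str) -> float:
        A = self.subjects[subject_idx].true_connectivity
        i = A.region_names.index(target)
        if target == source:
            return float(A.self_log_scale[i])
        j = A.region_names.index(source)
        return float(A.couplings[i, j])


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def _power_law_noise(alpha, beta, nt: int, dt: float, rng) -> np.ndarray:
    """Real time series (nt, n) whose expected two-sided PSD is
    alpha * f**(-beta); synthesized by frequency-domain shaping of white
    Gaussian noise.  The DC component is excluded (unmodeled drift)."""
    alpha = np.atleast_1d(np.asarray(alpha, float))
    n = alpha.size
    freqs = np.fft.rfftfreq(nt, dt)
    amp = np.zeros((freqs.size, n))
    amp[1:] = np.sqrt(alpha[None, :] * freqs[1:, None] ** (-beta) * nt / dt)
    X = np.zeros((freqs.size, n), dtype=complex)
    z = rng.standard_normal((freqs.size, n, 2))
    X[1:-1] = amp[1:-1] * (z[1:-1, :, 0] + 1j * z[1:-1, :, 1]) / np.sqrt(2.0)
    if nt % 2 == 0:
        X[-1] = amp[-1] * z[-1, :, 0]
    else:
        X[-1] = amp[-1] * (z[-1, :, 0] + 1j * z[-1, :, 1]) / np.sqrt(2.0)
    return np.fft.irfft(X, n=nt, axis=0)


def _integrate_linear(J: np.ndarray, v: np.ndarray, dt: float) -> np.ndarray:
    """Euler-Maruyama recursion x_{k+1} = x_k + dt*(J x_k + v_k), evaluated
    exactly via eigenmode filtering (falls back to stepping if J is close to
    defective)."""
    n = J.shape[0]
    ev, Q = np.linalg.eig(J)
    if np.linalg.cond(Q) < 1e8:
        y = v @ np.linalg.inv(Q).T  # modal noise
        out = np.empty_like(y)
        for k in range(n):
            out[:, k] = sps.lfilter([dt], [1.0, -(1.0 + dt * ev[k])], y[:, k])
        return (out @ Q.T).real
    x = np.zeros(n)
    out = np.empty_like(v)
    M = np.eye(n) + dt * J
    for t in range(v.shape[0]):
        x = M @ x + dt * v[t]
        out[t] = x
    return out


def simulate_bold(
    A: ConnectivityMatrix,
    fluct: FluctuationParams,
    hemo: HemodynamicParams,
    scans: int,
    tr_s: float,
    seed: int,
    dt_s: float = 0.1,
    burn_in_s: float = 60.0,
) -> RegionTimeSeries:
    """Forward-simulate one subject's BOLD run from the stochastic model."""
    J = A.jacobian()
    if np.any(np.linalg.eigvals(J).real >= 0):
        raise StabilityError("cannot simulate an unstable system")
    n = A.n_regions
    rng = np.random.default_rng(seed)
    stride = int(round(tr_s / dt_s))
    if abs(stride * dt_s - tr_s) > 1e-9:
        raise ValueError("tr_s must be an integer multiple of dt_s")
    i0 = int(round(burn_in_s / dt_s))
    nt = i0 + stride * scans
    v = _power_law_noise(fluct.alpha_v, fluct.beta_v, nt, dt_s, rng)
    x = _integrate_linear(J, v, dt_s)
    # hemodynamic convolution (causal kernel, 32 s support)
    tk = np.arange(0, 32.0, dt_s)
    h = hrf_kernel(hemo, tk)
    y = np.empty_like(x)
    for r in range(n):
        y[:, r] = sps.fftconvolve(x[:, r], h[:, r] * dt_s, mode="full")[:nt]
    idx = i0 + stride * np.arange(scans)
    y_tr = y[idx]
    e = _power_law_noise(fluct.alpha_e, fluct.beta_e, scans, tr_s, rng)
    return RegionTimeSeries(A.region_names, tr_s, y_tr + e)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _sample_covariates(cfg: CohortConfig, rng) -> pd.DataFrame:
    n = cfg.n_subjects
    is_patient = rng.random(n) < cfg.patient_fraction
    lo_p, hi_p = cfg.bdi_patient_range
    lo_c, hi_c = cfg.bdi_control_range
    bdi = np.where(
        is_patient,
        rng.integers(lo_p, hi_p + 1, n),
        rng.integers(lo_c, hi_c + 1, n),
    ).astype(int)
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18, 55).round(1)
    sex = (rng.random(n) < cfg.female_fraction).astype(int)  # 1 = female
    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "bdi": bdi,
            "age": age,
            "sex": sex,
        }
    )
    if cfg.with_treatment:
        df["treatment"] = (rng.random(n) < 0.5).astype(int)
    return df


def _centered_covariate_values(df: pd.DataFrame, name: str) -> np.ndarray:
    x = df[name].to_numpy(dtype=float)
    if name in ("sex", "treatment"):
        x = np.where(x > 0, 0.5, -0.5)
    return x - x.mean()


def sample_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a cohort: covariates, per-subject true connectivity (group mean
    + centered-covariate effects + between-subject noise, resampled until
    stable), and optionally the BOLD runs."""
    rng = np.random.default_rng(config.seed)
    regions = NETWORKS[config.network]
    n = len(regions)
    group = default_group_mean(config.network)
    df = _sample_covariates(config, rng)
    for cov in config.effects:
        if cov not in df.columns:
            raise ValueError(f"effect on unknown covariate '{cov}'")
    centered = {cov: _centered_covariate_values(df, cov) for cov in config.effects}

    subjects = []
    for i in range(config.n_subjects):
        sid = df["subject_id"].iloc[i]
        base_A = group.couplings.copy()
        base_s = group.self_log_scale.copy()
        for cov, conn_effects in config.effects.items():
            for (target, source), slope in conn_effects.items():
                ti = regions.index(target)
                if target == source:
                    base_s[ti] += slope * centered[cov][i]
                else:
                    base_A[ti, regions.index(source)] += slope * centered[cov][i]
        conn = None
        for _try in range(config.max_stability_tries):
            A = base_A + rng.normal(0, config.between_sd, (n, n))
            s = base_s + rng.normal(0, config.between_sd, n)
            cand = ConnectivityMatrix(regions, A, s)
            if cand.is_stable():
                conn = cand
                break
        if conn is None:
            raise StabilityError(
                f"no stable connectivity draw for subject {sid} "
                f"after {config.max_stability_tries} tries"
            )
        ts = None
        if config.generate_bold:
            ts = simulate_bold(
                conn,
                FluctuationParams.canonical(n),
                HemodynamicParams.canonical(n),
                config.scans,
                config.tr_s,
                seed=int(rng.integers(0, 2**31 - 1)),
                dt_s=config.dt_s,
                burn_in_s=config.burn_in_s,
            )
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                covariates=df.iloc[i].drop("subject_id").to_dict(),
                true_connectivity=conn,
                timeseries=ts,
            )
        )
    return SyntheticCohort(
        config=config,
        region_names=regions,
        group_mean=group,
        effects=config.effects,
        subjects=subjects,
    )


# ---------------------------------------------------------------------------
# Region extraction (first principal component over voxels)
# ---------------------------------------------------------------------------

def pca_extract(voxel_matrix: np.ndarray, n_components: int = 1) -> np.ndarray:
    """Representative time series of a region: the first principal-component
    score series of its voxels, sign-aligned to the voxel average, with unit
    variance."""
    X = np.asarray(voxel_matrix, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a scans x voxels matrix with at least 2 voxels")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("rank-0 input: all voxels constant")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * S[:n_components]
    mean_series = Xc.mean(axis=1)
    for k in range(n_components):
        c = float(scores[:, k] @ mean_series)
        if c < 0:
            scores[:, k] = -scores[:, k]
        sd = scores[:, k].std()
        if sd > 0:
            scores[:, k] = scores[:, k] / sd
    return scores[:, 0] if n_components == 1 else scores


# ---------------------------------------------------------------------------
# Synthetic first-level posteriors (fast stand-in for full inversion when
# testing the group-level machinery)
# ---------------------------------------------------------------------------

def emulate_first_level(
    cohort: SyntheticCohort,
    posterior_sd: float = 0.05,
    seed: int = 0,
) -> list:
    """Build synthetic SubjectDCM objects directly from the cohort's true
    connectivity, emulating the information content of a converged
    first-level inversion: the data are taken to measure each coupling with
    Gaussian error of SD ``posterior_sd``, and the stored posterior is the
    coherent Bayesian update of the first-level prior with that likelihood
    (so downstream likelihood extraction recovers exactly what was put in).
    Lets group-level operations be exercised at scale without paying for
    per-subject optimization."""
    rng = np.random.default_rng(seed)
    packing = ParameterPacking(cohort.region_names)
    prior = default_priors(cohort.region_names)
    n = packing.n_regions
    dcms = []
    coupling_idx = [packing.index(nm) for nm in packing.coupling_names(include_self=True)]
    for s in cohort.subjects:
        theta = packing.pack(
            s.true_connectivity,
            FluctuationParams.canonical(n),
            HemodynamicParams.canonical(n),
        )
        prior_var = np.diag(prior.cov)
        like_prec = np.zeros(packing.size)
        like_mean = np.zeros(packing.size)
        like_prec[coupling_idx] = 1.0 / posterior_sd**2
        like_mean[coupling_idx] = theta[coupling_idx] + rng.normal(0, posterior_sd, len(coupling_idx))
        post_prec = like_prec + 1.0 / prior_var
        mean = (like_prec * like_mean + prior.mean / prior_var) / post_prec
        post = GaussianDensity(mean, np.diag(1.0 / post_prec), packing.names)
        dcms.append(
            SubjectDCM(
                region_names=cohort.region_names,
                prior=GaussianDensity(prior.mean, prior.cov, packing.names),
                posterior=post,
                free_energy=0.0,
                variance_explained_pct=90.0,
                f_trace=[0.0],
                converged=True,
                subject_id=s.subject_id,
            )
        )
    return dcms


# ---------------------------------------------------------------------------
# Disk interface
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write per-subject TSV time series, the covariate CSV and a manifest
    JSON recording the generating configuration."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        if s.timeseries is not None:
            write_timeseries_tsv(s.timeseries, out / f"{s.subject_id}_{cohort.config.network}.tsv")
    cohort.covariates_df().to_csv(out / "covariates.csv", index=False)
    cfg = cohort.config
    manifest = {
        "network": cfg.network,
        "regions": list(cohort.region_names),
        "n_subjects": cfg.n_subjects,
        "scans": cfg.scans,
        "tr_s": cfg.tr_s,
        "seed": cfg.seed,
        "between_sd": cfg.between_sd,
        "effects": {
            cov: {f"{t}<-{s_}": v for (t, s_), v in conns.items()}
            for cov, conns in cfg.effects.items()
        },
        "with_treatment": cfg.with_treatment,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
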