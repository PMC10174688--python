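"""Synthetic longitudinal cohorts with an age-drifting connectome.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without access to restricted
trial data:

* a latent "brain age" per subject that tracks chronological age with
  Gaussian noise;
* 100-node (configurable) ROI time series whose correlation structure
  interpolates between a "young" and an "old" correlation matrix as a
  function of the latent brain age;
* two ~7-minute runs per session with slow motion drift and occasional
  motion spikes, exercising the scrubbing/retention gate;
* a follow-up session ~21.36 months later in which percent weight change
  couples to a slowing of latent brain aging (months of attenuation per
  1% of body-weight loss), plus clinical deltas and ordinal
  food-frequency items correlated with weight change.

All randomness flows from one master seed through per-subject
``numpy.random.SeedSequence`` substreams, so enlarging a cohort never
perturbs already-generated subjects.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .connectivity import ROITimeSeries

__all__ = [
    "AgingCovarianceModel",
    "SyntheticSubject",
    "SyntheticCohort",
    "make_aging_covariance_pair",
    "covariance_at_age",
    "simulate_timeseries",
    "simulate_motion",
    "simulate_cohort_t0",
    "simulate_followup",
    "DEFAULT_CLINICAL_COUPLING",
]

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class AgingCovarianceModel:
    """Endpoint correlation matrices of the aging connectome.

    The connectome at latent brain age *a* is the convex combination
    ``(1 - lam) * sigma_young + lam * sigma_old`` with
    ``lam = clip((a - age_min) / (age_max - age_min), 0, 1)``.
    """

    n_nodes: int
    sigma_young: np.ndarray
    sigma_old: np.ndarray
    age_min: float
    age_max: float

    def __post_init__(self) -> None:
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")
        for name in ("sigma_young", "sigma_old"):
            s = np.asarray(getattr(self, name), dtype=float)
            if s.shape != (self.n_nodes, self.n_nodes):
                raise ValueError(f"{name} must be n_nodes x n_nodes")
            if not np.allclose(s, s.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if not np.allclose(np.diag(s), 1.0, atol=1e-10):
                raise ValueError(f"{name} must have unit diagonal")
            if np.linalg.eigvalsh(s).min() < -_PSD_TOL:
                raise ValueError(f"{name} is not positive semidefinite")
            object.__setattr__(self, name, s)


@dataclass
class SyntheticSubject:
    subject_id: str
    chronological_age_t0: float
    latent_brain_age_t0: float
    sex: int  # 0 = female, 1 = male
    runs_t0: list[ROITimeSeries]
    motion_t0: list[np.ndarray]
    # follow-up fields, populated by simulate_followup
    dt_months: Optional[float] = None
    weight_change_pct: Optional[float] = None
    latent_brain_age_t18: Optional[float] = None
    runs_t18: Optional[list[ROITimeSeries]] = None
    motion_t18: Optional[list[np.ndarray]] = None
    clinical_deltas: dict = field(default_factory=dict)
    ffq_items: dict = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    model: AgingCovarianceModel
    params: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def has_followup(self) -> bool:
        return all(s.runs_t18 is not None for s in self.subjects)


def _renormalize_to_correlation(c: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(c))
    corr = c / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def make_aging_covariance_pair(
    n_nodes: int = 100,
    n_factors: int = 5,
    similarity: float = 0.5,
    age_min: float = 25.0,
    age_max: float = 90.0,
    seed: int = 0,
) -> AgingCovarianceModel:
    """Build a (sigma_young, sigma_old) correlation pair.

    Both matrices come from a shared low-rank factor loading; each endpoint
    adds an independent loading perturbation scaled by ``1 - similarity``,
    and the resulting factor covariance (plus a shared unique-variance
    diagonal) is renormalized to unit diagonal.  ``similarity=1`` makes the
    two endpoints identical; smaller values make the connectome drift more
    with age.  The default age range extends past the sampled
    chronological range so that follow-up latent ages do not saturate the
    clipped interpolation.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if not 1 <= n_factors < n_nodes:
        raise ValueError("need 1 <= n_factors < n_nodes")
    if not 0.0 <= similarity <= 1.0:
        raise ValueError("similarity must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    shared = rng.normal(size=(n_nodes, n_factors))
    pert_young = rng.normal(size=(n_nodes, n_factors))
    pert_old = rng.normal(size=(n_nodes, n_factors))
    uniq = rng.uniform(0.5, 1.5, size=n_nodes)  # shared unique variances
    mats = []
    for pert in (pert_young, pert_old):
        loading = shared + (1.0 - similarity) * pert
        c = loading @ loading.T + np.diag(uniq)
        mats.append(_renormalize_to_correlation(c))
    return AgingCovarianceModel(
        n_nodes=n_nodes,
        sigma_young=mats[0],
        sigma_old=mats[1],
        age_min=age_min,
        age_max=age_max,
    )


def covariance_at_age(
    model: AgingCovarianceModel, brain_age: float
) -> np.ndarray:
    """Correlation matrix at a latent brain age (linear interpolation,
    clipped to the model's age range).  Convex combinations of correlation
    matrices are again valid correlation matrices."""
    if not np.isfinite(brain_age):
        raise ValueError("brain_age must be finite")
    lam = np.clip(
        (brain_age - model.age_min) / (model.age_max - model.age_min),
        0.0,
        1.0,
    )
    return (1.0 - lam) * model.sigma_young + lam * model.sigma_old


def _draw_timeseries(
    cov: np.ndarray,
    n_frames: int,
    rng: np.random.Generator,
    **ts_kwargs,
) -> ROITimeSeries:
    cov = np.asarray(cov, dtype=float)
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8:
        raise ValueError("covariance is not positive semidefinite")
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal(size=(n_frames, cov.shape[0]))
    values = z @ (v * np.sqrt(w)).T
    return ROITimeSeries(values=values, **ts_kwargs)


def simulate_timeseries(
    cov: np.ndarray,
    n_frames: int,
    seed: int = 0,
    **ts_kwargs,
) -> ROITimeSeries:
    """Independent zero-mean multivariate-normal frames with covariance
    ``cov`` (eigendecomposition sampler; reproducible given ``seed``)."""
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return _draw_timeseries(cov, n_frames, rng, **ts_kwargs)


def _draw_motion(
    n_frames: int,
    spike_prob: float,
    spike_amp_mm: float,
    rng: np.random.Generator,
    drift_sd_mm: float = 0.002,
) -> np.ndarray:
    # slow random-walk drift; rotations scaled so their FD contribution on a
    # 50 mm sphere matches the translation drift
    steps = np.zeros((n_frames, 6))
    steps[1:, :3] = rng.normal(0.0, drift_sd_mm, size=(n_frames - 1, 3))
    steps[1:, 3:] = rng.normal(0.0, drift_sd_mm / 50.0, size=(n_frames - 1, 3))
    motion = np.cumsum(steps, axis=0)
    spikes = rng.random(n_frames) < spike_prob
    spikes[0] = False  # a step needs a preceding frame
    # persistent translation step: FD exceeds the threshold at the spike
    # frame only, exercising the 1-before/2-after censoring window
    motion[:, 0] += spike_amp_mm * np.cumsum(spikes)
    return motion


def simulate_motion(
    n_frames: int,
    spike_prob: float = 0.02,
    spike_amp_mm: float = 1.0,
    seed: int = 0,
    drift_sd_mm: float = 0.002,
) -> np.ndarray:
    """frames x 6 motion table (tx ty tz in mm, rx ry rz in radians).

    Baseline drift keeps FD well below 0.5 mm; Bernoulli(spike_prob) frames
    receive a persistent translation step of ``spike_amp_mm``.
    """
    if not 0.0 <= spike_prob <= 1.0:
        raise ValueError("spike_prob must lie in [0, 1]")
    if spike_amp_mm < 0:
        raise ValueError("spike amplitude must be nonnegative")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return _draw_motion(n_frames, spike_prob, spike_amp_mm, rng, drift_sd_mm)


def _subject_streams(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def _simulate_session(
    subject_id: str,
    session: str,
    brain_age: float,
    model: AgingCovarianceModel,
    n_runs: int,
    frames_per_run: int,
    spike_prob: float,
    spike_amp_mm: float,
    tr_seconds: float,
    rng: np.random.Generator,
) -> tuple[list[ROITimeSeries], list[np.ndarray]]:
    cov = covariance_at_age(model, brain_age)
    runs, motions = [], []
    for r in range(n_runs):
        runs.append(
            _draw_timeseries(
                cov,
                frames_per_run,
                rng,
                tr_seconds=tr_seconds,
                subject_id=subject_id,
                session=session,
                run=f"run-{r + 1}",
            )
        )
        motions.append(
            _draw_motion(frames_per_run, spike_prob, spike_amp_mm, rng)
        )
    return runs, motions


def simulate_cohort_t0(
    n_subjects: int,
    age_low: float = 35.0,
    age_high: float = 75.0,
    brain_age_noise_sd: float = 2.0,
    n_runs: int = 2,
    frames_per_run: int = 191,
    model: AgingCovarianceModel | None = None,
    seed: int = 0,
    spike_prob: float = 0.02,
    spike_amp_mm: float = 1.0,
    tr_seconds: float = 2.2,
) -> SyntheticCohort:
    """Baseline (T0) cohort.

    Chronological ages are uniform on [age_low, age_high]; the latent brain
    age adds Normal(0, brain_age_noise_sd) years; each subject's runs are
    drawn from the connectome at their latent brain age.  The default
    191 frames per run corresponds to a 7-minute run at TR = 2.2 s.
    """
    if age_low >= age_high:
        raise ValueError("age_low must be < age_high")
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    if brain_age_noise_sd < 0:
        raise ValueError("brain_age_noise_sd must be nonnegative")
    if model is None:
        model = make_aging_covariance_pair(seed=seed)
    subjects = []
    for i, child in enumerate(_subject_streams(seed, n_subjects)):
        rng = np.random.default_rng(child)
        sid = f"sub-{i + 1:04d}"
        age = rng.uniform(age_low, age_high)
        latent = age + rng.normal(0.0, brain_age_noise_sd)
        sex = int(rng.random() < 0.5)
        runs, motions = _simulate_session(
            sid, "T0", latent, model, n_runs, frames_per_run,
            spike_prob, spike_amp_mm, tr_seconds, rng,
        )
        subjects.append(
            SyntheticSubject(
                subject_id=sid,
                chronological_age_t0=float(age),
                latent_brain_age_t0=float(latent),
                sex=sex,
                runs_t0=runs,
                motion_t0=motions,
            )
        )
    params = dict(
        n_subjects=n_subjects, age_low=age_low, age_high=age_high,
        brain_age_noise_sd=brain_age_noise_sd, n_runs=n_runs,
        frames_per_run=frames_per_run, seed=seed, spike_prob=spike_prob,
        spike_amp_mm=spike_amp_mm, tr_seconds=tr_seconds,
    )
    return SyntheticCohort(subjects=subjects, model=model, params=params)


#: clinical delta couplings: name -> (slope per percent weight change,
#: residual sd in native units, biomarker category).  Deltas follow the
#: trial convention delta = T0 - T18, so weight LOSS (negative percent
#: change) gives positive anthropometric deltas via the negative slopes.
DEFAULT_CLINICAL_COUPLING: dict[str, tuple[float, float, str]] = {
    "delta_bmi": (-0.175, 0.9, "anthropometry"),
    "delta_weight_kg": (-0.531, 2.0, "anthropometry"),
    "delta_wc_cm": (-1.239, 3.0, "anthropometry"),
    "delta_alt_u_l": (-0.9, 4.0, "liver"),
    "delta_hba1c_pct": (-0.02, 0.12, "glycemic"),
    "delta_hdl_mg_dl": (0.4, 2.5, "lipids"),
    "delta_liver_fat_pct": (-0.5, 2.0, "imaging"),
}


def simulate_followup(
    cohort: SyntheticCohort,
    residual_sd: float,
    dt_mean_months: float = 21.36,
    dt_sd_months: float = 1.68,
    gamma_months_per_pct: float = 8.9,
    weight_change_mean_pct: float = -4.35,
    weight_change_sd_pct: float = 5.86,
    clinical_coupling: dict[str, tuple[float, float, str]] | None = None,
    seed: int = 1,
) -> SyntheticCohort:
    """Add a follow-up (T18) session to a baseline cohort.

    The latent brain age advances by the inter-scan interval and is slowed
    by ``gamma_months_per_pct / 12`` years per percent of weight LOST
    (weight change is signed, negative = loss), plus Normal(0, residual_sd)
    noise:

        latent_t18 = latent_t0 + dt_years
                     - (gamma / 12) * (-weight_change_pct)
                     + Normal(0, residual_sd)

    ``residual_sd`` (years) sets the within-subject reliability of the
    latent trajectory and has no data-anchored default, so it must be
    given explicitly.  Negative inter-scan-interval draws are redrawn, not
    clamped (redraw count recorded in ``params['followup']``).
    """
    if not cohort.subjects or cohort.subjects[0].runs_t0 is None:
        raise ValueError("cohort must have baseline (T0) fields")
    if dt_sd_months < 0:
        raise ValueError("dt_sd_months must be nonnegative")
    if residual_sd < 0:
        raise ValueError("residual_sd must be nonnegative")
    if clinical_coupling is None:
        clinical_coupling = DEFAULT_CLINICAL_COUPLING
    p = cohort.params
    out = SyntheticCohort(
        subjects=copy.deepcopy(cohort.subjects),
        model=cohort.model,
        params=dict(p),
    )
    n_redraws = 0
    for subj, child in zip(
        out.subjects, _subject_streams(seed, len(out.subjects))
    ):
        rng = np.random.default_rng(child)
        dt = rng.normal(dt_mean_months, dt_sd_months)
        while dt <= 0:
            n_redraws += 1
            dt = rng.normal(dt_mean_months, dt_sd_months)
        wc = rng.normal(weight_change_mean_pct, weight_change_sd_pct)
        latent_t18 = (
            subj.latent_brain_age_t0
            + dt / 12.0
            - (gamma_months_per_pct / 12.0) * (-wc)
            + rng.normal(0.0, residual_sd)
        )
        runs, motions = _simulate_session(
            subj.subject_id, "T18", latent_t18, out.model,
            p.get("n_runs", 2), p.get("frames_per_run", 191),
            p.get("spike_prob", 0.02), p.get("spike_amp_mm", 1.0),
            p.get("tr_seconds", 2.2), rng,
        )
        subj.dt_months = float(dt)
        subj.weight_change_pct = float(wc)
        subj.latent_brain_age_t18 = float(latent_t18)
        subj.runs_t18 = runs
        subj.motion_t18 = motions
        subj.clinical_deltas = {
            name: float(slope * wc + rng.normal(0.0, sd))
            for name, (slope, sd, _cat) in clinical_coupling.items()
        }
        # ordinal food-frequency change items (-1 less, 0 same, +1 more),
        # loosely tracking weight change; one two-level item for the t-test
        latent_ffq = wc / max(weight_change_sd_pct, 1e-9)
        items = {}
        for item in ("ffq_processed", "ffq_sweets", "ffq_beverages"):
            u = latent_ffq + rng.normal(0.0, 1.0)
            items[item] = int(-1 if u < -0.6 else (1 if u > 0.6 else 0))
        items["processed_t18_level"] = int(
            latent_ffq + rng.normal(0.0, 1.0) > 0
        )  # 0 = less consumption, 1 = same consumption
        subj.ffq_items = items
    out.params["followup"] = dict(
        dt_mean_months=dt_mean_months, dt_sd_months=dt_sd_months,
        gamma_months_per_pct=gamma_months_per_pct,
        weight_change_mean_pct=weight_change_mean_pct,
        weight_change_sd_pct=weight_change_sd_pct,
        residual_sd=residual_sd, seed=seed, n_dt_redraws=n_redraws,
    )
    return out
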