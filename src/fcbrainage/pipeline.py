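"""End-to-end orchestration: cohort -> features -> model -> attenuation.

Mirrors the study design: the age model is trained on a separate
cross-sectional cohort, then applied unchanged to both sessions of the
longitudinal trial cohort.  Subjects failing the motion-retention gate are
excluded with a per-subject reason in the inclusion ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import attenuation as att
from . import model as mdl
from .connectivity import (
    check_retention,
    concat_runs,
    connectivity_matrix,
    edge_vector,
    framewise_displacement,
    scrub_mask,
)
from .synthetic import SyntheticCohort

__all__ = [
    "QualityParams",
    "session_edge_features",
    "cohort_feature_table",
    "AttenuationAnalysis",
    "run_attenuation_analysis",
    "run_synthetic_study",
]


@dataclass(frozen=True)
class QualityParams:
    """Motion-scrubbing and retention thresholds."""

    fd_threshold_mm: float = 0.5
    n_before: int = 1
    n_after: int = 2
    min_retention: float = 0.7
    head_radius_mm: float = 50.0


def session_edge_features(runs, motions, qp: QualityParams = QualityParams()):
    """Scrub, gate, concatenate and vectorize one session.

    Returns ``(edge_values | None, retention_check)``; the edge values are
    None when the session fails the retention gate.
    """
    masks = []
    for mot in motions:
        fd = framewise_displacement(mot, head_radius_mm=qp.head_radius_mm)
        masks.append(
            scrub_mask(fd, qp.fd_threshold_mm, qp.n_before, qp.n_after)
        )
    retention = check_retention(masks, min_fraction=qp.min_retention)
    if not retention.include:
        return None, retention
    ts = concat_runs(list(runs), masks)
    ev = edge_vector(connectivity_matrix(ts))
    return ev, retention


def cohort_feature_table(
    cohort: SyntheticCohort,
    session: str = "t0",
    qp: QualityParams = QualityParams(),
):
    """Edge features for every includable subject of one session.

    Returns ``(features df, ledger df, edge_index)``.  The ledger has one
    row per input subject with the retained fraction, the inclusion flag
    and the exclusion reason, so n_input = n_included + n_excluded.
    """
    feats, index, ledger = [], [], []
    edge_index = None
    for subj in cohort.subjects:
        runs = getattr(subj, f"runs_{session}")
        motions = getattr(subj, f"motion_{session}")
        ev, retention = session_edge_features(runs, motions, qp)
        included = ev is not None
        ledger.append({
            "subject_id": subj.subject_id,
            "session": session,
            "retained_fraction": retention.retained_fraction,
            "included": included,
            "reason": "" if included else "retention_below_threshold",
        })
        if included:
            feats.append(ev.values)
            index.append(subj.subject_id)
            edge_index = ev.edge_index
    features = pd.DataFrame(np.array(feats), index=index)
    return features, pd.DataFrame(ledger), edge_index


@dataclass
class AttenuationAnalysis:
    """Everything the longitudinal analysis produces."""

    records: list
    trajectory: att.TrajectoryFit
    slope: att.SlopeEstimate | None
    train_report: mdl.PredictionReport
    model: mdl.BrainAgeModel
    ledger: pd.DataFrame
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    trial_cohort: SyntheticCohort | None = None

    @property
    def n_attenuated(self) -> int:
        return int(sum(r.attenuation_years > 0 for r in self.records))


def run_attenuation_analysis(
    train_cohort: SyntheticCohort,
    trial_cohort: SyntheticCohort,
    k: int = 5,
    seed: int = 0,
    qp: QualityParams = QualityParams(),
    **fit_kwargs,
) -> AttenuationAnalysis:
    """Full chain on synthetic cohorts.

    1. Edge features for the training cohort (T0); fit the age model and
       report its cross-validated accuracy.
    2. Edge features for the trial cohort at T0 and T18 (subjects must
       pass the retention gate at both sessions).
    3. Baseline trajectory fit, expected T18 ages, per-subject attenuation
       and corrected gaps.
    4. OLS of attenuation (months) on percent weight lost, with 95% CI.
    """
    if not trial_cohort.has_followup:
        raise ValueError("trial cohort has no follow-up session")
    Xtr, ledger_tr, edge_index = cohort_feature_table(train_cohort, "t0", qp)
    ages_tr = np.array([
        s.chronological_age_t0 for s in train_cohort.subjects
        if s.subject_id in set(Xtr.index)
    ])
    report = mdl.prediction_report(
        Xtr.to_numpy(), ages_tr, k=k, seed=seed, **fit_kwargs
    )
    model = mdl.fit_brainage(
        Xtr.to_numpy(), ages_tr, edge_index=edge_index, seed=seed,
        **fit_kwargs,
    )

    X0, ledger0, _ = cohort_feature_table(trial_cohort, "t0", qp)
    X18, ledger18, _ = cohort_feature_table(trial_cohort, "t18", qp)
    keep = [sid for sid in X0.index if sid in set(X18.index)]
    by_id = {s.subject_id: s for s in trial_cohort.subjects}
    pred0 = mdl.predict_age(model, X0.loc[keep].to_numpy())
    pred18 = mdl.predict_age(model, X18.loc[keep].to_numpy())
    chron0 = np.array([by_id[s].chronological_age_t0 for s in keep])
    dt = np.array([by_id[s].dt_months for s in keep])
    wc = np.array([by_id[s].weight_change_pct for s in keep])

    traj = att.fit_trajectory(chron0, pred0)
    records = att.attenuation_records(keep, chron0, pred0, pred18, dt,
                                      fit=traj)
    att_months = np.array([r.attenuation_months for r in records])
    slope = None
    if np.ptp(wc) > 0:
        slope = att.months_per_percent(att_months, wc)

    table = pd.DataFrame({
        "subject_id": keep,
        "chronological_t0": chron0,
        "predicted_t0": pred0,
        "predicted_t18": pred18,
        "dt_months": dt,
        "expected_t18": [r.expected_t18 for r in records],
        "attenuation_years": [r.attenuation_years for r in records],
        "attenuation_months": att_months,
        "weight_change_pct": wc,
    })
    ledger = pd.concat([ledger_tr, ledger0, ledger18], ignore_index=True)
    return AttenuationAnalysis(
        records=records, trajectory=traj, slope=slope,
        train_report=report, model=model, ledger=ledger, table=table,
    )


def run_synthetic_study(
    seed: int,
    gamma_months_per_pct: float = 8.9,
    n_train: int = 120,
    n_trial: int = 80,
    n_nodes: int = 20,
    n_factors: int = 5,
    similarity: float = 0.1,
    frames_per_run: int = 250,
    brain_age_noise_sd: float = 1.5,
    residual_sd: float = 3.0,
    k: int = 5,
) -> AttenuationAnalysis:
    """One complete synthetic study at the package's reference conditions.

    Simulates a cross-sectional training cohort and a longitudinal trial
    cohort from a shared aging connectome, then runs the full analysis
    chain.  The default sizes (20 nodes, 120 training / 80 trial subjects,
    two 250-frame runs) are a scaled-down but statistically faithful
    version of a real study: the connectome drift across the age range is
    strong (similarity 0.1) so the age model is accurate, and the
    within-subject trajectory noise (residual_sd 3.0 years over the
    inter-scan interval) dominates the uncertainty of the
    attenuation-vs-weight-loss slope, as it would in practice.
    """
    from .synthetic import (
        make_aging_covariance_pair,
        simulate_cohort_t0,
        simulate_followup,
    )

    model = make_aging_covariance_pair(
        n_nodes=n_nodes, n_factors=n_factors, similarity=similarity,
        age_min=25.0, age_max=90.0, seed=seed,
    )
    train = simulate_cohort_t0(
        n_train, model=model, seed=seed + 1,
        frames_per_run=frames_per_run,
        brain_age_noise_sd=brain_age_noise_sd,
    )
    trial_t0 = simulate_cohort_t0(
        n_trial, model=model, seed=seed + 2,
        frames_per_run=frames_per_run,
        brain_age_noise_sd=brain_age_noise_sd,
    )
    trial = simulate_followup(
        trial_t0, residual_sd=residual_sd,
        gamma_months_per_pct=gamma_months_per_pct, seed=seed + 3,
    )
    analysis = run_attenuation_analysis(train, trial, k=k, seed=seed)
    analysis.trial_cohort = trial
    return analysis
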