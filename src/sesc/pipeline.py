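"""End-to-end trials: simulate a subject, identify, estimate, score.

One ``run_trial`` call reproduces a full experimental session for one
synthetic subject: sample static postures, synthesize noisy CoP and joint
readings, split 75/25 into identification and evaluation sets, solve for the
subject-specific serial-chain vector, and score both the serial-chain and the
table-driven segmental estimator against the held-out CoP references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import build_regressor_row, estimate_com
from .evaluation import RmseResult, rmse_per_axis
from .identification import (
    IdentificationResult,
    identify_from_observations,
    minimum_postures,
    split_postures,
)
from .segmental import AnthropometricTable, measurements_from_parameters, segmental_com
from .synthetic import (
    NoiseModel,
    SyntheticSubject,
    baseline_fit_table,
    make_subject,
    sample_static_postures,
    simulate_trial,
)

__all__ = ["TrialEvaluation", "run_trial", "sub_seeds"]


def sub_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


@dataclass(frozen=True)
class TrialEvaluation:
    """Held-out scores of one simulated identification session."""

    subject: SyntheticSubject
    identification: IdentificationResult
    sesc_rmse: RmseResult  # mm, vs CoP on the evaluation set
    segmental_rmse: RmseResult
    sesc_bias_mm: np.ndarray  # (AP, ML) mean of estimate - reference
    segmental_bias_mm: np.ndarray
    sesc_estimates_mm: np.ndarray  # (n_eval, 2)
    segmental_estimates_mm: np.ndarray
    references_mm: np.ndarray
    truth_rmse_mm: RmseResult  # vs the exact CoM, diagnostics only
    n_identify: int
    n_evaluate: int

    @property
    def sesc_bias_norm_mm(self) -> float:
        return float(np.linalg.norm(self.sesc_bias_mm))

    @property
    def segmental_bias_norm_mm(self) -> float:
        return float(np.linalg.norm(self.segmental_bias_mm))


def run_trial(
    preset: str,
    seed: int,
    n_postures: int = 120,
    cop_sd_mm: float = 2.0,
    angle_sd_deg: float = 0.5,
    fraction_identify: float = 0.75,
    table: AnthropometricTable | None = None,
) -> TrialEvaluation:
    """Simulate and score one subject's full identification session.

    ``table`` is the anthropometric table handed to the segmental comparator;
    by default the fit-population baseline, i.e. deliberately mismatched when
    ``preset='obese'``.
    """
    s_subj, s_post, s_noise, s_split = sub_seeds(seed, 4)
    subject = make_subject(preset, s_subj)
    postures = sample_static_postures(subject, n_postures, s_post)
    noise = NoiseModel(cop_sd_mm, angle_sd_deg, s_noise)
    observations, truth = simulate_trial(subject, postures, noise)

    min_m = minimum_postures(subject.tree.n_bodies)
    idx_id, idx_ev = split_postures(
        list(range(n_postures)), fraction_identify, s_split, min_identify=min_m
    )
    obs_id = [observations[i] for i in idx_id]
    obs_ev = [observations[i] for i in idx_ev]
    truth_ev = np.asarray([truth[i] for i in idx_ev])

    ident = identify_from_observations(subject.tree, obs_id)

    if table is None:
        table = baseline_fit_table()
    meas = measurements_from_parameters(subject.tree, subject.params)

    sesc_est, seg_est, refs = [], [], []
    for obs in obs_ev:
        row = build_regressor_row(subject.tree, obs.posture)
        com = estimate_com(row, obs.posture.root_position, ident.V)
        sesc_est.append(com[:2])
        seg = segmental_com(subject.tree, table, meas, obs.posture)
        seg_est.append(seg[:2])
        refs.append(obs.cop)
    sesc_est = np.asarray(sesc_est) * 1000.0
    seg_est = np.asarray(seg_est) * 1000.0
    refs = np.asarray(refs) * 1000.0
    truth_mm = truth_ev[:, :2] * 1000.0

    return TrialEvaluation(
        subject=subject,
        identification=ident,
        sesc_rmse=rmse_per_axis(sesc_est, refs),
        segmental_rmse=rmse_per_axis(seg_est, refs),
        sesc_bias_mm=np.mean(sesc_est - refs, axis=0),
        segmental_bias_mm=np.mean(seg_est - refs, axis=0),
        sesc_estimates_mm=sesc_est,
        segmental_estimates_mm=seg_est,
        references_mm=refs,
        truth_rmse_mm=rmse_per_axis(sesc_est, truth_mm),
        n_identify=len(obs_id),
        n_evaluate=len(obs_ev),
    )
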