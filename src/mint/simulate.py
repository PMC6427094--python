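"""Simulated responders: psychometrically structured synthetic subjects.

Lets every downstream stage — scoring, norms, reliability — be exercised
end-to-end without human data.  A responder is described on the accuracy
scale: an asymptotic sensitivity, per-condition offsets, a linear
accuracy-per-dB SNR slope, and a lapse rate that mixes in guessing.
Chance is 0.5 (two-alternative match/mismatch judgement).

A cohort draws per-subject ability (the subject's average probability
correct) from a normal distribution, so the generating mean and SD are
known exactly and parameter-recovery tests have an analytic target.
Because observed scores add binomial trial noise on top of the ability
distribution, the cohort fitter removes the mean within-subject binomial
variance when estimating the ability SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .scoring import ResponseRecord, item_score_matrix
from .trials import CONTROL, NOISE_CONDITIONS, SessionVersion

__all__ = [
    "ResponderModel",
    "CohortSpec",
    "CohortResult",
    "trial_accuracy",
    "simulate_responses",
    "simulate_cohort",
    "fit_score_distribution",
]

CHANCE = 0.5
_EPS = 1e-9


@dataclass(frozen=True)
class ResponderModel:
    """One simulated subject on the accuracy scale.

    p(correct) = clip(base + offset[cond] + slope * snr, 0.5, 1) * (1 - lapse)
                 + 0.5 * lapse
    """

    base_sensitivity: float = 0.8
    snr_slope: float = 0.0  # accuracy per dB; snr is <= 0, so positive slope
    lapse_rate: float = 0.0
    condition_offsets: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise InputError("lapse_rate must be in [0, 0.5]")
        if not CHANCE - _EPS <= self.base_sensitivity <= 1.0 + _EPS:
            raise InputError("base_sensitivity must be in [0.5, 1]")


def trial_accuracy(model: ResponderModel, condition: str, snr_db: float | None) -> float:
    """Deterministic probability of a correct response on one trial."""
    known = set(NOISE_CONDITIONS) | {CONTROL} | set(model.condition_offsets)
    if condition not in known:
        raise InputError(f"unknown condition {condition!r}")
    snr = 0.0 if snr_db is None else snr_db  # control trials have no masker
    p = model.base_sensitivity + model.condition_offsets.get(condition, 0.0)
    p += model.snr_slope * snr
    p = float(np.clip(p, CHANCE, 1.0))
    return p * (1.0 - model.lapse_rate) + CHANCE * model.lapse_rate


def simulate_responses(
    model: ResponderModel,
    session: SessionVersion,
    subject_id: str = "s0",
    include_familiarization: bool = False,
) -> list[ResponseRecord]:
    """Emit one response per trial, correct with ``trial_accuracy`` probability.

    Deterministic in ``model.seed`` and the session's trial order.
    """
    rng = np.random.default_rng(model.seed)
    records = []
    for t in session.all_trials():
        if t.familiarization and not include_familiarization:
            continue
        p = trial_accuracy(model, t.condition, t.snr_db)
        correct = bool(rng.random() < p)
        truth = "match" if t.is_match else "mismatch"
        flipped = "mismatch" if t.is_match else "match"
        records.append(
            ResponseRecord(
                trial_id=t.trial_id,
                response=truth if correct else flipped,
                subject_id=subject_id,
            )
        )
    return records


@dataclass(frozen=True)
class CohortSpec:
    """A population of responders with normally distributed ability."""

    n_subjects: int = 67
    ability_mean: float = 0.78
    ability_sd: float = 0.09
    snr_slope: float = 0.0
    lapse_rate: float = 0.0
    condition_offsets: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise InputError("n_subjects must be >= 1")
        if self.ability_sd < 0:
            raise InputError("ability_sd must be >= 0")


@dataclass
class CohortResult:
    responses: dict[str, list[ResponseRecord]]
    item_scores: dict[str, np.ndarray]  # condition -> subjects x items
    scores: np.ndarray  # per-subject MINT average (noise conditions)
    true_abilities: np.ndarray
    spec: CohortSpec


def simulate_cohort(spec: CohortSpec, session: SessionVersion) -> CohortResult:
    """Simulate a cohort on a session; returns data plus generating truth.

    Each subject's ability (mean trial-level probability correct) is drawn
    from Normal(ability_mean, ability_sd) truncated to [0.5, 1]; with the
    default zero SNR slope the ability is exactly the per-trial p(correct),
    keeping recovery math closed-form.
    """
    rng = np.random.default_rng(spec.seed)
    abilities = np.clip(
        rng.normal(spec.ability_mean, spec.ability_sd, size=spec.n_subjects),
        CHANCE,
        1.0,
    )
    responses: dict[str, list[ResponseRecord]] = {}
    for i, ability in enumerate(abilities):
        subj = f"s{i:03d}"
        model = ResponderModel(
            base_sensitivity=float(ability),
            snr_slope=spec.snr_slope,
            lapse_rate=spec.lapse_rate,
            condition_offsets=dict(spec.condition_offsets),
            seed=int(rng.integers(0, 2**31)),
        )
        responses[subj] = simulate_responses(model, session, subject_id=subj)
    item_scores = {
        cond: item_score_matrix(responses, session, cond) for cond in NOISE_CONDITIONS
    }
    scores = np.mean([m.mean(axis=1) for m in item_scores.values()], axis=0)
    return CohortResult(
        responses=responses,
        item_scores=item_scores,
        scores=np.asarray(scores),
        true_abilities=abilities,
        spec=spec,
    )


def fit_score_distribution(
    scores: np.ndarray, n_items: int | None = None
) -> dict[str, float]:
    """Estimate the ability distribution from observed average scores.

    Returns the sample mean and SD; when ``n_items`` (trials contributing
    to each score) is given, also a debiased ability SD that subtracts the
    expected within-subject binomial variance mean(p(1-p))/n_items from the
    observed score variance (floored at zero).
    """
    x = np.asarray(scores, dtype=float)
    out = {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
    if n_items:
        binom = float(np.mean(x * (1.0 - x)) / n_items)
        out["sd_ability"] = float(np.sqrt(max(np.var(x, ddof=1) - binom, 0.0)))
    return out
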