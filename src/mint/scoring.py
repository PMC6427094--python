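"""Scoring and psychometrics for MINT sessions.

Covers the statistics used to characterize the task: accuracy breakdowns
per condition and SNR, percentile norms against the published table,
split-half reliability with the Spearman-Brown correction (averaged over
many random item splits), distributional checks, rank/product-moment
correlations, and Steiger's z for comparing two dependent correlations
that share a variable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ManifestError, MintError
from .trials import CONTROL, NOISE_CONDITIONS, SessionVersion

__all__ = [
    "ResponseRecord",
    "ScoreReport",
    "ReliabilityResult",
    "NormsTable",
    "load_norms",
    "score_session",
    "percentile_lookup",
    "split_half_reliability",
    "spearman_brown",
    "overall_reliability",
    "check_normality",
    "correlate_measures",
    "compare_dependent_correlations",
    "item_score_matrix",
    "read_responses_csv",
]


@dataclass(frozen=True)
class ResponseRecord:
    """One keypress: which trial, 'match' or 'mismatch', optional latency."""

    trial_id: str
    response: str
    subject_id: str = "s0"
    latency: float | None = None

    def __post_init__(self) -> None:
        if self.response not in ("match", "mismatch"):
            raise InputError(f"response must be match/mismatch, got {self.response!r}")


@dataclass
class ScoreReport:
    by_condition: dict[str, float]
    by_snr: dict[float, float]
    by_condition_snr: dict[str, dict[float, float]]
    mint_average: float
    percentile: float | None
    n_trials: dict[str, int]
    missing_trials: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "by_condition": self.by_condition,
            "by_snr": {str(k): v for k, v in self.by_snr.items()},
            "by_condition_snr": {
                c: {str(k): v for k, v in d.items()}
                for c, d in self.by_condition_snr.items()
            },
            "mint_average": self.mint_average,
            "percentile": self.percentile,
            "n_trials": self.n_trials,
            "missing_trials": self.missing_trials,
        }


@dataclass
class ReliabilityResult:
    per_subtask: dict[str, float]
    overall: float | None
    n_splits: int
    seed: int
    dropped_splits: dict[str, int] = field(default_factory=dict)


@dataclass
class NormsTable:
    """Published percentile norms: ordered (percentile, MINT-average) pairs."""

    table: pd.DataFrame  # columns: percentile, score
    fitted_mean: float = 0.78
    fitted_sd: float = 0.09

    def __post_init__(self) -> None:
        s = self.table["score"].to_numpy()
        if np.any(np.diff(s) < 0):
            raise MintError("norms scores must be non-decreasing with percentile")


def load_norms() -> NormsTable:
    """The norms shipped with the package (healthy young adults, n = 67)."""
    with importlib.resources.files("mint").joinpath("data/norms.csv").open() as fh:
        return NormsTable(pd.read_csv(fh))


def percentile_lookup(mint_average: float, norms: NormsTable | None = None) -> float:
    """Percentile for a MINT average score, interpolated between table rows.

    Scores at or above the top row's score return the top percentile band;
    scores below the bottom row clamp to the bottom band.
    """
    if not 0.0 <= mint_average <= 1.0:
        raise InputError("score must be a proportion in [0, 1]")
    norms = norms or load_norms()
    pct = norms.table["percentile"].to_numpy(dtype=float)
    score = norms.table["score"].to_numpy(dtype=float)
    if mint_average >= score[-1]:
        return float(pct[-1])
    if mint_average <= score[0]:
        return float(pct[0])
    return float(np.interp(mint_average, score, pct))


def read_responses_csv(path) -> list[ResponseRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ResponseRecord(
                trial_id=str(row.trial_id),
                response=str(row.response),
                subject_id=str(getattr(row, "subject_id", "s0")),
                latency=float(row.latency)
                if "latency" in df.columns and pd.notna(row.latency)
                else None,
            )
        )
    return records


def _is_correct(response: str, is_match: bool) -> bool:
    return (response == "match") == is_match


def score_session(
    responses: list[ResponseRecord],
    session: SessionVersion,
    norms: NormsTable | None = None,
    include_familiarization: bool = False,
) -> ScoreReport:
    """Accuracy per condition, per SNR, and pooled, for one subject's run.

    Missing trials are reported and excluded from denominators; duplicate
    responses for one trial and unknown trial ids are errors.  The MINT
    average is the unweighted mean over the five noise conditions.
    """
    trial_map = session.trial_map()
    seen: dict[str, bool] = {}
    for r in responses:
        if r.trial_id not in trial_map:
            raise ManifestError(f"unknown trial_id {r.trial_id!r}")
        if r.trial_id in seen:
            raise InputError(f"duplicate response for trial {r.trial_id!r}")
        seen[r.trial_id] = _is_correct(r.response, trial_map[r.trial_id].is_match)

    rows = []
    for t in session.all_trials():
        if t.familiarization and not include_familiarization:
            continue
        rows.append(
            {
                "trial_id": t.trial_id,
                "condition": t.condition,
                "snr_db": t.snr_db,
                "correct": seen.get(t.trial_id),
            }
        )
    df = pd.DataFrame(rows)
    missing = df.loc[df["correct"].isna(), "trial_id"].tolist()
    scored = df.dropna(subset=["correct"]).astype({"correct": float})

    by_condition = scored.groupby("condition")["correct"].mean().to_dict()
    noise = scored[scored["condition"] != CONTROL]
    by_snr = noise.groupby("snr_db")["correct"].mean().to_dict()
    by_condition_snr = {
        c: g.groupby("snr_db")["correct"].mean().to_dict()
        for c, g in noise.groupby("condition")
    }
    cond_scores = [by_condition[c] for c in NOISE_CONDITIONS if c in by_condition]
    mint_average = float(np.mean(cond_scores)) if cond_scores else float("nan")
    percentile = None
    if np.isfinite(mint_average):
        percentile = percentile_lookup(mint_average, norms)
    return ScoreReport(
        by_condition={k: float(v) for k, v in by_condition.items()},
        by_snr={float(k): float(v) for k, v in by_snr.items()},
        by_condition_snr={
            c: {float(k): float(v) for k, v in d.items()}
            for c, d in by_condition_snr.items()
        },
        mint_average=mint_average,
        percentile=percentile,
        n_trials=scored.groupby("condition")["correct"].size().to_dict(),
        missing_trials=missing,
    )


def item_score_matrix(
    cohort_responses: dict[str, list[ResponseRecord]],
    session: SessionVersion,
    condition: str,
) -> np.ndarray:
    """Subjects x items correctness matrix for one condition's 20 items.

    Columns are ordered by stimulus item index, so the same column means
    the same stimulus across subjects regardless of presentation order.
    """
    block = sorted(session.blocks[condition], key=lambda t: t.item_index)
    ids = [t.trial_id for t in block]
    truth = {t.trial_id: t.is_match for t in block}
    subjects = sorted(cohort_responses)
    mat = np.full((len(subjects), len(ids)), np.nan)
    for si, subj in enumerate(subjects):
        answers = {r.trial_id: r.response for r in cohort_responses[subj]}
        for ii, tid in enumerate(ids):
            if tid in answers:
                mat[si, ii] = float(_is_correct(answers[tid], truth[tid]))
    return mat


def spearman_brown(r: float) -> float:
    """Step-up correction from a half-test correlation: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def _half_split_correlations(
    scores: np.ndarray, n_splits: int, rng: np.random.Generator
) -> tuple[list[float], int]:
    n_items = scores.shape[1]
    half = n_items // 2
    rs, dropped = [], 0
    for _ in range(n_splits):
        perm = rng.permutation(n_items)
        a = scores[:, perm[:half]].mean(axis=1)
        b = scores[:, perm[half:]].mean(axis=1)
        if np.std(a) == 0 or np.std(b) == 0:
            dropped += 1
            continue
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    return rs, dropped


def split_half_reliability(
    item_scores: np.ndarray,
    n_splits: int = 1000,
    seed: int = 0,
    return_detail: bool = False,
):
    """Spearman-Brown split-half reliability of one subtask.

    The items are randomly partitioned into two equal halves ``n_splits``
    times; for each split the per-subject half-mean scores are correlated
    (Pearson, across subjects), the correlations are averaged, and the
    Spearman-Brown step-up correction 2r/(1+r) is applied to the average.
    Splits where a half has zero variance across subjects are dropped and
    counted.
    """
    scores = np.asarray(item_scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 3:
        raise InputError("need a subjects x items matrix with >= 3 subjects")
    if scores.shape[1] < 2 or scores.shape[1] % 2 != 0:
        raise InputError("need an even item count >= 2")
    rng = np.random.default_rng(seed)
    rs, dropped = _half_split_correlations(scores, n_splits, rng)
    if not rs:
        raise InputError("every split had zero-variance half-means")
    coefficient = spearman_brown(float(np.mean(rs)))
    if return_detail:
        return coefficient, {"n_used": len(rs), "n_dropped": dropped}
    return coefficient


def overall_reliability(
    condition_item_scores: dict[str, np.ndarray],
    n_splits: int = 1000,
    seed: int = 0,
    return_detail: bool = False,
):
    """Split-half reliability of the MINT average score.

    Item *positions* are split in half; each subject's half score is the
    mean over conditions of that half's accuracy (i.e., accuracy is first
    averaged across conditions, then the split-half procedure is applied,
    matching how the overall score is formed).
    """
    mats = [np.asarray(m, dtype=float) for m in condition_item_scores.values()]
    if not mats:
        raise InputError("no condition matrices given")
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise InputError("condition matrices must share subjects and item count")
    stacked = np.mean(mats, axis=0)  # per-position accuracy averaged over conditions
    return split_half_reliability(stacked, n_splits, seed, return_detail)


def check_normality(scores: np.ndarray) -> dict:
    """Descriptive distributional summary of per-subject average scores.

    Reports the fitted normal parameters, skew, excess kurtosis, the
    Shapiro-Wilk statistic and p-value, and Q-Q points; takes no decisions.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 3:
        raise InputError("need at least 3 scores")
    if np.std(x) == 0:
        return {
            "mean": float(x.mean()),
            "sd": 0.0,
            "degenerate": True,
        }
    w, p = stats.shapiro(x)
    (osm, osr), _ = stats.probplot(x, dist="norm")
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "skew": float(stats.skew(x)),
        "kurtosis": float(stats.kurtosis(x)),
        "shapiro_w": float(w),
        "shapiro_p": float(p),
        "qq_theoretical": osm.tolist(),
        "qq_sample": osr.tolist(),
        "degenerate": False,
    }


def correlate_measures(
    x: np.ndarray, y: np.ndarray, method: str = "spearman"
) -> tuple[float, float]:
    """Spearman or Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise InputError("need paired samples with n >= 4")
    if method == "spearman":
        if np.unique(x).size == 1 or np.unique(y).size == 1:
            raise InputError("constant input: Spearman correlation undefined")
        res = stats.spearmanr(x, y)
    elif method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        raise InputError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def compare_dependent_correlations(
    r_xy: float, r_xz: float, r_yz: float, n: int
) -> tuple[float, float]:
    """Steiger's z for two dependent correlations sharing variable x.

    Tests r_xy against r_xz given the correlation r_yz between the two
    non-shared variables, using Fisher-transformed correlations and the
    Steiger (1980) covariance term evaluated at the pooled correlation.
    Returns (z, two-sided p).  Antisymmetric under swapping r_xy and r_xz.
    """
    for r in (r_xy, r_xz, r_yz):
        if not -1.0 < r < 1.0:
            raise InputError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise InputError("need n > 3")
    z1, z2 = np.arctanh(r_xy), np.arctanh(r_xz)
    rbar = 0.5 * (r_xy + r_xz)
    num = r_yz * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_yz**2)
    s = num / (1 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2 - 2 * s))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)
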