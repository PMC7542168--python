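"""Scale scoring, risk-label logic and auxiliary-target assembly.

The CSSRS is modular: part 1 covers passive ideation (a wish to be dead,
suicidal thoughts), part 2 — administered only after part-1 endorsement —
covers active ideation with method, intent or plan.  Any part-1 endorsement
defines *general risk*; any part-2 endorsement of method/intent/plan defines
the nested *high risk* group.

Auxiliary targets for the multi-task model are the scale totals arranged in
three layers (personality -> psychosocial -> psychiatric), z-scored with
training-set statistics; satisfaction with life is negated before
standardization so that higher always means more risk.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import MEASURE_NAMES

__all__ = [
    "RiskLabels", "AuxiliaryStats", "AuxiliaryTargets", "AUXILIARY_LAYERS",
    "score_cssrs", "auxiliary_matrix", "fit_auxiliary_stats",
    "assemble_auxiliary_targets", "summarize_measures",
]

#: measure names feeding each auxiliary layer, in model order
AUXILIARY_LAYERS: dict[str, tuple[str, ...]] = {
    "personality": ("openness", "conscientiousness", "extraversion",
                    "agreeableness", "neuroticism"),
    "psychosocial": ("brooding", "worry", "loneliness", "swl"),
    "psychiatric": ("depression", "anxiety"),
}

#: targets that are sign-flipped so higher = more risk
_NEGATED = frozenset({"swl"})


@dataclasses.dataclass(frozen=True)
class RiskLabels:
    general_risk: bool
    high_risk: bool

    def __post_init__(self) -> None:
        if self.high_risk and not self.general_risk:
            raise ValueError("high risk implies general risk")


def score_cssrs(part1_responses: dict[str, bool],
                part2_responses: dict[str, bool] | None = None,
                ) -> tuple[int, RiskLabels]:
    """Score a minimal structured CSSRS administration.

    ``part1_responses`` maps ideation items (e.g. "wish_dead",
    "suicidal_thoughts") to endorsements; ``part2_responses`` maps active
    items ("method", "intent", "plan") and may be given only when part 1
    shows ideation.  The total is the count of endorsed items across both
    parts (a severity-sum surrogate calibrated elsewhere to the published
    mean/SD; the licensed instrument's exact weighting is not reproduced).
    """
    ideation = any(part1_responses.values())
    if part2_responses is not None and not ideation:
        raise ValueError(
            "part 2 administered without part-1 ideation endorsement")
    total = sum(bool(v) for v in part1_responses.values())
    high = False
    if part2_responses is not None:
        total += sum(bool(v) for v in part2_responses.values())
        high = any(part2_responses.get(k, False)
                   for k in ("method", "intent", "plan"))
    return total, RiskLabels(general_risk=ideation, high_risk=high)


# ---------------------------------------------------------------------------
# Auxiliary targets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AuxiliaryStats:
    """Per-target mean/SD estimated on training users only."""
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]


@dataclasses.dataclass
class AuxiliaryTargets:
    personality: np.ndarray   # (n, 5)
    psychosocial: np.ndarray  # (n, 4)
    psychiatric: np.ndarray   # (n, 2)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"personality": self.personality,
                "psychosocial": self.psychosocial,
                "psychiatric": self.psychiatric}


def auxiliary_matrix(scores: np.ndarray, layer: str) -> np.ndarray:
    """Raw (unstandardized) layer matrix from a (n, 12) score array; SWL is
    negated here so the low-satisfaction orientation is uniform."""
    cols = []
    for name in AUXILIARY_LAYERS[layer]:
        col = scores[:, MEASURE_NAMES.index(name)].astype(float)
        cols.append(-col if name in _NEGATED else col)
    return np.column_stack(cols)


def fit_auxiliary_stats(train_scores: np.ndarray) -> AuxiliaryStats:
    mean, sd = {}, {}
    for layer in AUXILIARY_LAYERS:
        X = auxiliary_matrix(train_scores, layer)
        mean[layer] = X.mean(axis=0)
        sd[layer] = X.std(axis=0, ddof=0)
        if np.any(sd[layer] == 0):
            raise ValueError(
                f"degenerate training cohort: zero SD in {layer} layer")
    return AuxiliaryStats(mean=mean, sd=sd)


def assemble_auxiliary_targets(scores: np.ndarray,
                               train_stats: AuxiliaryStats
                               ) -> AuxiliaryTargets:
    """z-scored layer targets (5, 4, 2) using training-set statistics."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    out = {}
    for layer in AUXILIARY_LAYERS:
        X = auxiliary_matrix(scores, layer)
        out[layer] = (X - train_stats.mean[layer]) / train_stats.sd[layer]
    return AuxiliaryTargets(**out)


# ---------------------------------------------------------------------------
# Descriptive summary
# ---------------------------------------------------------------------------

def summarize_measures(scores: np.ndarray
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Means/SDs, pairwise Pearson correlations and significance stars.

    Returns (descriptives, correlation matrix, star matrix); stars are
    "*" for p < 0.05 and "**" for p < 0.01 under the t-distributed
    correlation test.
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if n < 3:
        raise ValueError("need at least 3 users")
    if np.any(scores.std(axis=0) == 0):
        raise ValueError("constant column: correlation undefined")
    desc = pd.DataFrame({
        "mean": scores.mean(axis=0),
        "sd": scores.std(axis=0, ddof=1),
    }, index=list(MEASURE_NAMES[:k]))
    R = np.corrcoef(scores, rowvar=False)
    with np.errstate(divide="ignore"):
        t = R * np.sqrt((n - 2) / np.clip(1 - R ** 2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    stars = np.where(p < 0.01, "**", np.where(p < 0.05, "*", ""))
    np.fill_diagonal(stars, "")
    names = list(MEASURE_NAMES[:k])
    return (desc, pd.DataFrame(R, index=names, columns=names),
            pd.DataFrame(stars, index=names, columns=names))
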