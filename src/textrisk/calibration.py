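"""Calibration targets for the synthetic cohort generator.

The generator is calibrated to the descriptive statistics of a published
MTurk Facebook cohort (N = 1650 scored users, 1002 after activity filtering):
twelve psychodiagnostic scale totals with their means, SDs and pairwise
Pearson correlations, nested binary suicide-risk prevalences derived from the
Columbia Suicide Severity Rating Scale (CSSRS), and the per-user posting
activity distribution.

Measure order is fixed and shared across the package:
suicide (CSSRS total), depression (PHQ-9), anxiety (GAD-7), brooding
(5-item RRS), worry (PSWQ), SWL (SWLS), loneliness (UCLA-10), then the five
BFI-10 traits (openness, conscientiousness, extraversion, agreeableness,
neuroticism).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

MEASURE_NAMES: tuple[str, ...] = (
    "suicide",
    "depression",
    "anxiety",
    "brooding",
    "worry",
    "swl",
    "loneliness",
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
)

N_MEASURES = len(MEASURE_NAMES)

#: integer support (lo, hi) of each scale total; the CSSRS sum has no hard
#: published ceiling here — 25 comfortably covers the observed range.
MEASURE_SUPPORTS: dict[str, tuple[int, int]] = {
    "suicide": (0, 25),
    "depression": (0, 27),   # PHQ-9
    "anxiety": (0, 21),      # GAD-7
    "brooding": (5, 20),     # 5 items, 1-4
    "worry": (16, 80),       # PSWQ, 16 items 1-5
    "swl": (5, 35),          # SWLS, 5 items 1-7
    "loneliness": (10, 40),  # UCLA-10, 10 items 1-4
    "openness": (2, 10),     # BFI-10: 2 items 1-5 per trait
    "conscientiousness": (2, 10),
    "extraversion": (2, 10),
    "agreeableness": (2, 10),
    "neuroticism": (2, 10),
}

_MEANS = [0.87, 7.44, 14.25, 10.81, 50.76, 20.66, 23.89,
          7.69, 7.52, 5.52, 6.92, 6.64]
_SDS = [1.41, 5.94, 5.70, 3.53, 15.59, 8.14, 6.73,
        2.03, 1.88, 2.40, 2.01, 2.40]

# Lower triangle of the published correlation matrix, row by row
# (row i lists correlations with measures 0..i-1).
_CORR_LOWER = [
    [],
    [0.436],
    [0.377, 0.754],
    [0.382, 0.610, 0.656],
    [0.346, 0.552, 0.711, 0.656],
    [-0.360, -0.534, -0.449, -0.458, -0.423],
    [0.350, 0.572, 0.479, 0.539, 0.485, -0.607],
    [0.070, -0.019, 0.033, 0.047, 0.033, -0.012, -0.044],
    [-0.184, -0.303, -0.187, -0.254, -0.192, 0.269, -0.271, 0.100],
    [-0.191, -0.242, -0.210, -0.187, -0.249, 0.273, -0.385, 0.143, 0.120],
    [-0.179, -0.262, -0.282, -0.207, -0.278, 0.262, -0.344, 0.053, 0.113,
     0.196],
    [0.300, 0.486, 0.617, 0.564, 0.762, -0.393, 0.461, -0.025, -0.272,
     -0.295, -0.281],
]


def _corr_matrix_from_lower(lower: list[list[float]]) -> np.ndarray:
    R = np.eye(len(lower))
    for i, row in enumerate(lower):
        for j, r in enumerate(row):
            R[i, j] = R[j, i] = r
    return R


@dataclasses.dataclass
class GeneratorCalibration:
    """Targets that drive cohort simulation.

    ``mu``/``sigma``/``R`` describe the *observed-scale* marginal moments and
    Pearson correlations the generated scale totals should reproduce; the
    copula machinery translates them to latent-scale parameters.
    ``signal_strength`` scales how strongly the latent profile projects into
    posts (text mode) or embedding vectors (oracle mode); 0 means no signal.
    """

    measure_names: tuple[str, ...] = MEASURE_NAMES
    mu: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array(_MEANS))
    sigma: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array(_SDS))
    R: np.ndarray = dataclasses.field(
        default_factory=lambda: _corr_matrix_from_lower(_CORR_LOWER))
    pi_general: float = 0.3603
    pi_high: float = 0.1317
    post_count_mean: float = 82.35
    post_count_sd: float = 106.79
    words_per_post_mean: float = 31.14
    words_per_post_sd: float = 66.56
    zero_post_fraction: float = 335.0 / 1985.0
    signal_strength: float = 1.0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        k = len(self.measure_names)
        if self.mu.shape != (k,) or self.sigma.shape != (k,):
            raise ValueError("mu/sigma must have one entry per measure")
        if self.R.shape != (k, k):
            raise ValueError("R must be square over the measures")
        if not np.allclose(self.R, self.R.T):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0):
            raise ValueError("R must have a unit diagonal")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be positive")
        if not 0.0 <= self.pi_high <= self.pi_general <= 1.0:
            raise ValueError("need 0 <= pi_high <= pi_general <= 1")
        if not 0.0 <= self.zero_post_fraction <= 1.0:
            raise ValueError("zero_post_fraction must lie in [0, 1]")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be non-negative")

    def index(self, measure: str) -> int:
        return self.measure_names.index(measure)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["measure_names"] = list(self.measure_names)
        d["mu"] = self.mu.tolist()
        d["sigma"] = self.sigma.tolist()
        d["R"] = self.R.tolist()
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorCalibration":
        d = dict(d)
        d["measure_names"] = tuple(d["measure_names"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_calibration(signal_strength: float = 1.0) -> GeneratorCalibration:
    """Calibration transcribed from the published cohort descriptives."""
    return GeneratorCalibration(signal_strength=signal_strength)
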