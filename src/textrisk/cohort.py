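"""Synthetic cohort generation.

Builds user-level records with the statistical structure the downstream
analysis assumes: correlated psychodiagnostic scale totals (Gaussian copula
over the published correlation structure), nested binary risk labels at the
published prevalences, demographics with small group differences in the
published directions, right-skewed posting activity, and either synthetic
posts (text mode) or latent-derived embedding vectors (oracle mode).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import _lexicons
from .calibration import GeneratorCalibration, MEASURE_NAMES
from .copula import (discretize_to_scales, latent_correlation_matrix,
                     sample_latent_profiles)

__all__ = [
    "UserRecord", "SyntheticCohort", "VocabModel", "default_vocab_model",
    "derive_risk_labels", "sample_post_counts", "generate_user_posts",
    "generate_cohort", "posts_to_jsonl", "load_posts_jsonl",
    "cohort_table", "cohort_to_csv", "load_cohort_csv",
    "embeddings_to_csv", "load_embeddings_csv",
]

COHORT_SCHEMA = "textrisk-cohort-v1"

# Log-scale shift applied to positive post counts of at-risk users, centred
# so the overall mean is unchanged; 0.24 yields a standardized group
# difference of roughly d = 0.2 in count space, matching the published
# direction and magnitude.
_POST_COUNT_RISK_LOGSHIFT = 0.24

# Demographic group parameters (mean, SD) conditional on general risk.
_AGE_PARAMS = {False: (38.3, 11.0), True: (34.6, 10.6)}
_INCOME_PARAMS = {False: (58563.0, 36627.0), True: (48389.0, 35526.0)}
_MALE_FRACTION = 0.2325
_INCOME_MISSING_RATE = 2.0 / 1002.0


@dataclasses.dataclass
class UserRecord:
    """One participant: scores, demographics, labels and activity."""

    user_id: str
    scores: np.ndarray                      # (12,) in MEASURE_NAMES order
    general_risk: bool
    high_risk: bool
    age: float
    income: float | None
    gender: str
    post_count: int
    posts: list[str] | None = None
    embedding: np.ndarray | None = None

    def score(self, measure: str) -> float:
        return float(self.scores[MEASURE_NAMES.index(measure)])


@dataclasses.dataclass
class SyntheticCohort:
    users: list[UserRecord]
    seed: int
    calibration: GeneratorCalibration
    mode: str
    latents: np.ndarray | None = None       # generator provenance

    def __post_init__(self) -> None:
        ids = [u.user_id for u in self.users]
        if len(set(ids)) != len(ids):
            raise ValueError("user identifiers must be unique")
        if any(u.high_risk and not u.general_risk for u in self.users):
            raise ValueError("high risk must imply general risk")

    def __len__(self) -> int:
        return len(self.users)

    @property
    def scores(self) -> np.ndarray:
        return np.array([u.scores for u in self.users])

    @property
    def general_risk(self) -> np.ndarray:
        return np.array([u.general_risk for u in self.users])

    @property
    def high_risk(self) -> np.ndarray:
        return np.array([u.high_risk for u in self.users])

    @property
    def embeddings(self) -> np.ndarray:
        if any(u.embedding is None for u in self.users):
            raise ValueError("cohort has no embeddings")
        return np.array([u.embedding for u in self.users])

    def labels(self, task: str) -> np.ndarray:
        if task == "general":
            return self.general_risk.astype(int)
        if task == "high":
            return self.high_risk.astype(int)
        raise ValueError(f"unknown task {task!r}")

    def subset(self, indices: np.ndarray | list[int]) -> "SyntheticCohort":
        users = [self.users[i] for i in indices]
        lat = self.latents[list(indices)] if self.latents is not None else None
        return SyntheticCohort(users=users, seed=self.seed,
                               calibration=self.calibration, mode=self.mode,
                               latents=lat)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def derive_risk_labels(suicidality: np.ndarray, pi_general: float,
                       pi_high: float) -> tuple[np.ndarray, np.ndarray]:
    """Rank users by (latent) suicidality; the top round(n*pi_general) are
    general-risk and, nested within them, the top round(n*pi_high) are
    high-risk."""
    if pi_high > pi_general:
        raise ValueError("pi_high must not exceed pi_general")
    suicidality = np.asarray(suicidality, dtype=float)
    n = len(suicidality)
    n_gen = int(np.rint(n * pi_general))
    n_high = int(np.rint(n * pi_high))
    order = np.argsort(-suicidality, kind="stable")
    general = np.zeros(n, dtype=bool)
    high = np.zeros(n, dtype=bool)
    general[order[:n_gen]] = True
    high[order[:n_high]] = True
    return general, high


# ---------------------------------------------------------------------------
# Posting activity
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)

def sample_post_counts(calibration: GeneratorCalibration,
                       general_risk: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Right-skewed per-user post counts: a point mass at zero plus a
    lognormal moment-matched to the published mean/SD of posting users, with
    a mean-preserving log-scale tilt toward more posts in the risk group."""
    n = len(general_risk)
    mu, sig = _lognormal_params(calibration.post_count_mean,
                                calibration.post_count_sd)
    shift = _POST_COUNT_RISK_LOGSHIFT * (
        general_risk.astype(float) - calibration.pi_general)
    counts = np.maximum(
        np.rint(rng.lognormal(mu + shift, sig, size=n)), 1).astype(int)
    counts[rng.random(n) < calibration.zero_post_fraction] = 0
    return counts


def _sample_post_lengths(calibration: GeneratorCalibration, n_posts: int,
                         rng: np.random.Generator,
                         cap: int = 400) -> np.ndarray:
    mu, sig = _lognormal_params(calibration.words_per_post_mean,
                                calibration.words_per_post_sd)
    return np.clip(np.rint(rng.lognormal(mu, sig, size=n_posts)),
                   1, cap).astype(int)


# ---------------------------------------------------------------------------
# Vocabulary model and post text
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class VocabModel:
    """Shared vocabulary plus class-tilted sublexicons.

    Per-user token mixture: ``w_neg = neg_base * exp(s*z) * gate`` and
    ``w_pos = pos_base * exp(-pos_tilt*s*z)`` where ``z`` is latent
    suicidality and ``s`` the calibration's ``signal_strength``; the
    remainder goes to the Zipf-weighted neutral pool.  ``gate`` is a per-user
    Bernoulli "discloses distress" indicator with probability
    ``sigmoid(gate_sharpness * s * (z - gate_center))`` — most users never
    use the distress vocabulary at all, which mirrors how rarely explicit
    distress is shared and keeps the sublexicon's document frequency
    informative.  At s = 0 every user draws from the same distribution.
    """

    neutral: tuple[str, ...]
    negative: tuple[str, ...]
    positive: tuple[str, ...]
    neg_base: float = 0.06
    pos_base: float = 0.05
    pos_tilt: float = 0.5
    gate_center: float = 0.8
    gate_sharpness: float = 3.0
    zipf_exponent: float = 1.05
    idiom_rate: float = 0.01

    def __post_init__(self) -> None:
        if not (self.neutral and self.negative and self.positive):
            raise ValueError("vocabulary pools must be non-empty")
        r = np.arange(1, len(self.neutral) + 1, dtype=float)
        self._neutral_p = r ** -self.zipf_exponent
        self._neutral_p /= self._neutral_p.sum()
        self._neg_p = np.full(len(self.negative), 1.0 / len(self.negative))
        self._pos_p = np.full(len(self.positive), 1.0 / len(self.positive))

    def user_token_distribution(self, z: float, s: float,
                                rng: np.random.Generator
                                ) -> tuple[np.ndarray, np.ndarray]:
        gate_p = 1.0 / (1.0 + np.exp(-self.gate_sharpness * s *
                                     (z - self.gate_center)))
        gate = rng.random() < gate_p
        w_neg = min(self.neg_base * np.exp(s * z), 0.5) if gate else 0.0
        w_pos = min(self.pos_base * np.exp(-self.pos_tilt * s * z), 0.5)
        w_neu = 1.0 - w_neg - w_pos
        tokens = np.concatenate([
            np.asarray(self.neutral), np.asarray(self.negative),
            np.asarray(self.positive)])
        probs = np.concatenate([
            w_neu * self._neutral_p, w_neg * self._neg_p,
            w_pos * self._pos_p])
        return tokens, probs


def default_vocab_model() -> VocabModel:
    return VocabModel(neutral=_lexicons.neutral_words(),
                      negative=_lexicons.negative_words(),
                      positive=_lexicons.POSITIVE_WORDS)


def generate_user_posts(general_risk: np.ndarray, latents: np.ndarray,
                        vocab_model: VocabModel,
                        calibration: GeneratorCalibration, seed: int,
                        post_counts: np.ndarray | None = None
                        ) -> list[list[str]]:
    """Synthetic posts per user.  Token frequencies depend on the user's
    latent suicidality through the vocabulary model; post counts and lengths
    follow the calibrated right-skewed distributions.  Occasional idiomatic
    posts use explicit lemmas (kill/die) in non-suicidal contexts,
    independently of class."""
    rng = np.random.default_rng(seed)
    general_risk = np.asarray(general_risk, dtype=bool)
    z = np.asarray(latents)[:, 0]
    s = calibration.signal_strength
    if post_counts is None:
        post_counts = sample_post_counts(calibration, general_risk, rng)
    all_posts: list[list[str]] = []
    for i in range(len(general_risk)):
        tokens, probs = vocab_model.user_token_distribution(z[i], s, rng)
        k = int(post_counts[i])
        posts: list[str] = []
        if k > 0:
            lengths = _sample_post_lengths(calibration, k, rng)
            flat = rng.choice(tokens, size=int(lengths.sum()), p=probs)
            pos = 0
            for ln in lengths:
                if rng.random() < vocab_model.idiom_rate:
                    posts.append(str(rng.choice(_lexicons.IDIOM_TEMPLATES)))
                    pos += ln
                else:
                    posts.append(" ".join(flat[pos:pos + ln]))
                    pos += ln
        all_posts.append(posts)
    return all_posts


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

def _sample_demographics(general_risk: np.ndarray, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(general_risk)
    age = np.empty(n)
    income = np.empty(n)
    for risk in (False, True):
        m = general_risk == risk
        am, asd = _AGE_PARAMS[risk]
        im, isd = _INCOME_PARAMS[risk]
        age[m] = rng.normal(am, asd, size=m.sum())
        income[m] = rng.normal(im, isd, size=m.sum())
    age = np.clip(np.rint(age), 18, 90)
    income = np.clip(np.rint(income / 100.0) * 100.0, 0, None)
    income[rng.random(n) < _INCOME_MISSING_RATE] = np.nan
    gender = np.where(rng.random(n) < _MALE_FRACTION, "male", "female")
    return age, income, gender


def generate_cohort(calibration: GeneratorCalibration, n: int, seed: int,
                    mode: str = "oracle", embed_dim: int = 128,
                    mediated_only: bool = False,
                    vocab_model: VocabModel | None = None
                    ) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    mode="text" attaches synthetic posts; mode="oracle" attaches embedding
    vectors that are a fixed random linear map of the latent profile plus
    unit Gaussian noise, scaled by ``signal_strength``.  With
    ``mediated_only=True`` the oracle map excludes the suicide latent, so
    the label is informative only through the auxiliary (personality,
    psychosocial, psychiatric) latents — the regime in which hierarchical
    auxiliary supervision should pay off.
    """
    if n < 20:
        raise ValueError("need n >= 20")
    if mode not in ("text", "oracle"):
        raise ValueError(f"unknown mode {mode!r}")
    latent_R = latent_correlation_matrix(calibration)
    rng = np.random.default_rng(seed)
    latents = sample_latent_profiles(
        calibration, n, seed=int(rng.integers(2 ** 31)), R=latent_R)
    scores = discretize_to_scales(latents, calibration)
    general, high = derive_risk_labels(
        latents[:, 0], calibration.pi_general, calibration.pi_high)
    age, income, gender = _sample_demographics(general, rng)
    counts = sample_post_counts(calibration, general, rng)

    posts_per_user: list[list[str]] | None = None
    emb: np.ndarray | None = None
    if mode == "text":
        posts_per_user = generate_user_posts(
            general, latents, vocab_model or default_vocab_model(),
            calibration, seed=int(rng.integers(2 ** 31)), post_counts=counts)
    else:
        cols = slice(1, None) if mediated_only else slice(None)
        z_sel = latents[:, cols]
        A = rng.standard_normal((embed_dim, z_sel.shape[1]))
        signal = calibration.signal_strength * (z_sel @ A.T) \
            / np.sqrt(z_sel.shape[1])
        emb = signal + rng.standard_normal((n, embed_dim))

    width = len(str(n))
    users = []
    for i in range(n):
        users.append(UserRecord(
            user_id=f"u{i:0{width}d}",
            scores=scores[i],
            general_risk=bool(general[i]),
            high_risk=bool(high[i]),
            age=float(age[i]),
            income=None if np.isnan(income[i]) else float(income[i]),
            gender=str(gender[i]),
            post_count=int(counts[i]),
            posts=posts_per_user[i] if posts_per_user is not None else None,
            embedding=emb[i] if emb is not None else None,
        ))
    return SyntheticCohort(users=users, seed=seed, calibration=calibration,
                           mode=mode, latents=latents)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def posts_to_jsonl(cohort: SyntheticCohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u in cohort.users:
            for j, text in enumerate(u.posts or []):
                fh.write(json.dumps({"user_id": u.user_id,
                                     "post_id": f"{u.user_id}-p{j}",
                                     "text": text}) + "\n")


def load_posts_jsonl(path: str | Path) -> dict[str, list[str]]:
    posts: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            posts.setdefault(rec["user_id"], []).append(rec["text"])
    return posts


def cohort_table(cohort: SyntheticCohort) -> pd.DataFrame:
    rows = []
    for u in cohort.users:
        row = {"user_id": u.user_id}
        row.update({m: u.scores[k] for k, m in enumerate(MEASURE_NAMES)})
        row.update(age=u.age, income=u.income, gender=u.gender,
                   post_count=u.post_count, general_risk=int(u.general_risk),
                   high_risk=int(u.high_risk))
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_to_csv(cohort: SyntheticCohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {COHORT_SCHEMA}\n")
        cohort_table(cohort).to_csv(fh, index=False)


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def embeddings_to_csv(user_ids: list[str], vectors: np.ndarray,
                      path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(vectors))
    df.columns = [f"e{j}" for j in range(df.shape[1])]
    df.insert(0, "user_id", user_ids)
    df.to_csv(path, index=False)


def load_embeddings_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return df["user_id"].tolist(), df.drop(columns="user_id").to_numpy()
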