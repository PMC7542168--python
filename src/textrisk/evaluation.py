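"""Evaluation protocol: stratified splits, ROC/AUC, effect sizes, repeated
cross-validation summaries and group comparisons.

AUC doubles as a probability (random positive outscores a random negative,
ties half) and, under the equal-variance binormal model, converts to
Cohen's d via d = sqrt(2) * Phi^-1(AUC).  Two-sample t statistics convert
via d = 2t / sqrt(df).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from . import models as _models
from .calibration import MEASURE_NAMES
from .psychometrics import fit_auxiliary_stats, assemble_auxiliary_targets

__all__ = [
    "SplitPlan", "stratified_split", "RocCurve", "roc_and_auc",
    "auc_to_cohens_d", "cohens_d_from_t", "EvaluationReport", "repeated_cv",
    "GroupComparison", "group_comparisons", "summarize_aucs",
]


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplitPlan:
    train: np.ndarray
    dev: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def __iter__(self):
        return iter((self.train, self.dev, self.test))


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    raw = total * fractions
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:short]] += 1
    return base


def stratified_split(labels: np.ndarray,
                     fractions: tuple[float, float, float] = (0.70, 0.15,
                                                              0.15),
                     seed: int = 0) -> SplitPlan:
    """Train/dev/test partition with the positive-class fraction equal
    across portions to within one user.

    Portion sizes floor the earlier fractions and give the remainder to the
    final (test) portion — at n = 1002 that is the familiar 701/150/151.
    Positives are apportioned by largest-remainder rounding and negatives
    fill the portions up; both classes are shuffled with the given seed.
    """
    fractions_arr = np.asarray(fractions, dtype=float)
    if not np.isclose(fractions_arr.sum(), 1.0):
        raise ValueError("fractions must sum to 1")
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    sizes = np.floor(n * fractions_arr).astype(int)
    sizes[-1] = n - sizes[:-1].sum()
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    rng = np.random.default_rng(seed)
    rng.shuffle(pos)
    rng.shuffle(neg)
    pos_counts = np.minimum(_largest_remainder(len(pos), fractions_arr),
                            sizes)
    neg_counts = sizes - pos_counts
    if neg_counts.min() < 0 or neg_counts.sum() != len(neg):
        raise ValueError("fractions incompatible with class sizes")
    parts = []
    p_stop = np.concatenate([[0], np.cumsum(pos_counts)])
    n_stop = np.concatenate([[0], np.cumsum(neg_counts)])
    for i in range(3):
        parts.append(np.sort(np.concatenate(
            [pos[p_stop[i]:p_stop[i + 1]], neg[n_stop[i]:n_stop[i + 1]]])))
    return SplitPlan(train=parts[0], dev=parts[1], test=parts[2],
                     fractions=tuple(fractions), seed=seed)


# ---------------------------------------------------------------------------
# ROC / AUC and effect sizes
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "tpr": self.tpr, "fpr": self.fpr})


def roc_and_auc(scores: np.ndarray, labels: np.ndarray
                ) -> tuple[RocCurve, float]:
    """ROC points and trapezoidal AUC; equal to the Mann-Whitney
    probability with ties counted one half."""
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr), auc


def auc_to_cohens_d(auc: float) -> float:
    """Equal-variance binormal conversion d = sqrt(2) * Phi^-1(AUC)."""
    if not 0.0 < auc < 1.0:
        raise ValueError("auc must lie strictly in (0, 1)")
    return float(np.sqrt(2.0) * stats.norm.ppf(auc))


def cohens_d_from_t(t: float, df: float, ci: bool = False,
                    noncentral: bool = False
                    ) -> float | tuple[float, tuple[float, float]]:
    """d = 2t/sqrt(df) for a pooled two-sample t.  With ``ci=True`` also
    returns the 95% interval d +/- 1.96*2/sqrt(df) (or, with
    ``noncentral=True``, the interval from the usual variance
    approximation of d)."""
    if df <= 0:
        raise ValueError("df must be positive")
    d = 2.0 * t / np.sqrt(df)
    if not ci:
        return float(d)
    if noncentral:
        n_half = (df + 2) / 2.0
        se = np.sqrt((2 * n_half) / (n_half * n_half)
                     + d * d / (2 * (df + 2)))
    else:
        se = 2.0 / np.sqrt(df)
    return float(d), (float(d - 1.96 * se), float(d + 1.96 * se))


def summarize_aucs(aucs: np.ndarray, method: str = "percentile"
                   ) -> dict:
    """Mean, 95% CI over repeats and the binormal effect size of the mean.

    method="percentile" takes the empirical 2.5/97.5 percentiles of the
    repeat AUCs; method="normal" uses mean +/- 1.96 * SD/sqrt(k).
    """
    aucs = np.asarray(aucs, dtype=float)
    mean = float(aucs.mean())
    if method == "percentile":
        lo, hi = np.percentile(aucs, [2.5, 97.5])
    elif method == "normal":
        half = 1.96 * aucs.std(ddof=1) / np.sqrt(len(aucs)) \
            if len(aucs) > 1 else 0.0
        lo, hi = mean - half, mean + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return {"mean_auc": mean, "ci_low": float(lo), "ci_high": float(hi),
            "cohens_d": auc_to_cohens_d(mean) if 0 < mean < 1 else np.nan,
            "aucs": aucs.tolist()}


# ---------------------------------------------------------------------------
# Repeated cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EvaluationReport:
    per_repeat: pd.DataFrame        # columns: repeat, variant, task, auc
    summary: dict                   # (variant, task) -> summarize_aucs dict
    paired: dict                    # (a_minus_b, task) -> difference summary
    ci_method: str
    #: (repeat, variant, task) -> (test indices, test scores); populated
    #: only when repeated_cv(..., keep_scores=True)
    fold_scores: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_repeat": self.per_repeat.to_dict(orient="records"),
                "summary": {f"{v}/{t}": s
                            for (v, t), s in self.summary.items()},
                "paired": {f"{a}/{t}": s
                           for (a, t), s in self.paired.items()},
                "ci_method": self.ci_method}


def _paired_summary(diffs: np.ndarray) -> dict:
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return {"mean_difference": float(diffs.mean()), "ci_low": float(lo),
            "ci_high": float(hi), "differences": diffs.tolist()}


def repeated_cv(cohort, configs: list, repeats: int = 5, seed: int = 0,
                tasks: tuple[str, ...] = ("general",),
                ci_method: str = "percentile",
                keep_scores: bool = False) -> EvaluationReport:
    """Repeated stratified 70/15/15 protocol.

    For each repeat a fresh stratified split is drawn; every model config is
    trained on the train portion (auxiliary targets standardized with
    train-portion statistics), early-stopped on the dev portion and scored
    on the test portion.  AUCs are summarized per (variant, task) with mean
    and 95% CI over repeats; when both "mtm" and "stm" are present their
    repeat-wise paired difference is summarized on matched splits.
    """
    if repeats < 2:
        raise ValueError("need at least 2 repeats")
    X = cohort.embeddings
    rows = []
    fold_scores: dict = {}
    for rep in range(repeats):
        for task in tasks:
            y = cohort.labels(task)
            task_offset = {"general": 0, "high": 1}[task]
            split = stratified_split(y, seed=seed + 1000 * rep + task_offset)
            tr, dv, te = split.train, split.dev, split.test
            aux_stats = fit_auxiliary_stats(cohort.scores[tr])
            aux_all = assemble_auxiliary_targets(cohort.scores, aux_stats)
            aux_tr = {k: v[tr] for k, v in aux_all.as_dict().items()}
            for config in configs:
                cfg = dataclasses.replace(
                    config, task=task, input_dim=X.shape[1],
                    seed=config.seed + rep)
                model = _models.build_model(cfg)
                try:
                    trained = _models.train(model, X[tr], y[tr], X[dv],
                                            y[dv], aux_train=aux_tr)
                except Exception as exc:
                    raise RuntimeError(
                        f"training failed in repeat {rep} "
                        f"({cfg.variant}/{task}): {exc}") from exc
                scores = trained.predict(X[te])["suicide"].ravel()
                _, auc = roc_and_auc(scores, y[te])
                rows.append({"repeat": rep, "variant": cfg.variant,
                             "task": task, "auc": auc})
                if keep_scores:
                    fold_scores[(rep, cfg.variant, task)] = (te, scores)
    per_repeat = pd.DataFrame(rows)
    summary = {}
    for (variant, task), grp in per_repeat.groupby(["variant", "task"]):
        summary[(variant, task)] = summarize_aucs(
            grp.sort_values("repeat")["auc"].to_numpy(), method=ci_method)
    paired = {}
    variants = set(per_repeat["variant"])
    if {"mtm", "stm"} <= variants:
        for task in tasks:
            sub = per_repeat[per_repeat["task"] == task]
            piv = sub.pivot(index="repeat", columns="variant", values="auc")
            paired[("mtm_minus_stm", task)] = _paired_summary(
                (piv["mtm"] - piv["stm"]).to_numpy())
    return EvaluationReport(per_repeat=per_repeat, summary=summary,
                            paired=paired, ci_method=ci_method,
                            fold_scores=fold_scores)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GroupComparison:
    variable: str
    mean_no_risk: float
    sd_no_risk: float
    mean_risk: float
    sd_risk: float
    statistic: float        # t (continuous) or chi-square (categorical)
    kind: str               # "t" or "chi2"
    df: float
    p_value: float
    cohens_d: float | None
    d_ci: tuple[float, float] | None


def _pooled_t(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float, float]:
    n0, n1 = len(x0), len(x1)
    df = n0 + n1 - 2
    sp2 = (((n0 - 1) * x0.var(ddof=1) + (n1 - 1) * x1.var(ddof=1)) / df)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (x1.mean() - x0.mean()) / np.sqrt(sp2 * (1 / n0 + 1 / n1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def group_comparisons(cohort) -> list[GroupComparison]:
    """Socio-demographic comparisons of general-risk vs no-risk users:
    pooled-variance t tests (pairwise-complete for missing income) with
    d = 2t/sqrt(df), and a 2x2 chi-square for gender."""
    table_rows = []
    risk = cohort.general_risk
    if risk.all() or not risk.any():
        raise ValueError("both label groups must be non-empty")
    continuous = {
        "post_count": np.array([u.post_count for u in cohort.users],
                               dtype=float),
        "age": np.array([u.age for u in cohort.users], dtype=float),
        "income": np.array([np.nan if u.income is None else u.income
                            for u in cohort.users], dtype=float),
    }
    for name, values in continuous.items():
        ok = ~np.isnan(values)
        x0, x1 = values[ok & ~risk], values[ok & risk]
        t, df, p = _pooled_t(x0, x1)
        d, ci = cohens_d_from_t(t, df, ci=True)
        table_rows.append(GroupComparison(
            variable=name, mean_no_risk=float(x0.mean()),
            sd_no_risk=float(x0.std(ddof=1)), mean_risk=float(x1.mean()),
            sd_risk=float(x1.std(ddof=1)), statistic=t, kind="t", df=df,
            p_value=p, cohens_d=d, d_ci=ci))
    male = np.array([u.gender == "male" for u in cohort.users])
    contingency = np.array([
        [(male & ~risk).sum(), (~male & ~risk).sum()],
        [(male & risk).sum(), (~male & risk).sum()]])
    chi2, p, df, _ = stats.chi2_contingency(contingency, correction=False)
    table_rows.append(GroupComparison(
        variable="gender_male", mean_no_risk=float(male[~risk].mean()),
        sd_no_risk=np.nan, mean_risk=float(male[risk].mean()), sd_risk=np.nan,
        statistic=float(chi2), kind="chi2", df=float(df), p_value=float(p),
        cohens_d=None, d_ci=None))
    return table_rows
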