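"""End-to-end orchestration: generate -> filter -> embed -> train ->
evaluate -> interpret, as one seeded, logged, reproducible run.

Every stage seed is derived by hashing (global seed, stage name), so any
stage can be re-run in isolation and the whole run is a pure function of
its configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import models as _models
from .calibration import GeneratorCalibration, default_calibration
from .cohort import (SyntheticCohort, cohort_table, cohort_to_csv,
                     embeddings_to_csv, generate_cohort, posts_to_jsonl)
from .embedding import apply_inclusion_filters, embed_users, mock_embedder
from .evaluation import (EvaluationReport, group_comparisons, repeated_cv,
                         roc_and_auc)
from .interpretation import (keyword_search, partition_confusion,
                             select_threshold, tfidf_class_words)
from .models import ModelConfig
from .psychometrics import assemble_auxiliary_targets, fit_auxiliary_stats

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "derive_seed", "run_experiment",
           "structure_recovery_experiment", "compare_models"]


@dataclasses.dataclass
class AnalysisDataset:
    """File-backed stand-in for a cohort in the training/evaluation APIs:
    embeddings joined with scores and labels on user_id."""

    user_ids: list[str]
    X: np.ndarray
    score_matrix: np.ndarray
    general: np.ndarray
    high: np.ndarray

    @classmethod
    def from_tables(cls, user_ids: list[str], X: np.ndarray,
                    table: pd.DataFrame) -> "AnalysisDataset":
        from .calibration import MEASURE_NAMES
        table = table.set_index("user_id").loc[user_ids]
        return cls(user_ids=list(user_ids), X=np.asarray(X, dtype=float),
                   score_matrix=table[list(MEASURE_NAMES)].to_numpy(float),
                   general=table["general_risk"].to_numpy(int),
                   high=table["high_risk"].to_numpy(int))

    @property
    def embeddings(self) -> np.ndarray:
        return self.X

    @property
    def scores(self) -> np.ndarray:
        return self.score_matrix

    def labels(self, task: str) -> np.ndarray:
        if task == "general":
            return self.general
        if task == "high":
            return self.high
        raise ValueError(f"unknown task {task!r}")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic stage seed: BLAKE2 hash of (global seed, stage),
    reduced below 2^31."""
    digest = hashlib.blake2b(f"{global_seed}\x00{stage}".encode(),
                             digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2 ** 31)


@dataclasses.dataclass
class RunConfig:
    n: int = 1650
    seed: int = 0
    mode: str = "text"
    signal_strength: float = 1.0
    mediated_only: bool = False
    embed_dim: int = 128
    variants: tuple[str, ...] = ("stm", "mtm")
    tasks: tuple[str, ...] = ("general",)
    repeats: int = 5
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    top_k_words: int = 100
    max_epochs: int = 60
    patience: int = 8
    out_dir: str = "runs/run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("variants", "tasks", "fractions"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("variants", "tasks", "fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _model_configs(cfg: RunConfig, input_dim: int) -> list[ModelConfig]:
    return [ModelConfig(variant=v, input_dim=input_dim,
                        max_epochs=cfg.max_epochs, patience=cfg.patience,
                        seed=derive_seed(cfg.seed, f"model-{v}"))
            for v in cfg.variants]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default))


def run_experiment(config: RunConfig) -> Path:
    """Execute all stages; artifacts land in ``config.out_dir``.

    Writes the cohort table, posts (text mode), embeddings, filter report,
    evaluation report (JSON + per-repeat TSV), group comparisons and — when
    posts exist — the interpretation bundle for the best general-risk MTM
    fold.  Returns the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    try:
        return _run_experiment(config, out)
    finally:
        log.removeHandler(handler)


def _run_experiment(config: RunConfig, out: Path) -> Path:
    _write_json(out / "config.json",
                config.to_dict() | {"config_hash": config.config_hash})
    cal = default_calibration(signal_strength=config.signal_strength)
    cal.to_json(out / "calibration.json")

    log.info("generate: n=%d mode=%s hash=%s", config.n, config.mode,
             config.config_hash)
    cohort = generate_cohort(cal, config.n, seed=derive_seed(config.seed,
                                                             "cohort"),
                             mode=config.mode, embed_dim=config.embed_dim,
                             mediated_only=config.mediated_only)
    cohort_to_csv(cohort, out / "cohort.csv")
    if config.mode == "text":
        posts_to_jsonl(cohort, out / "posts.jsonl")

    filtered, report = apply_inclusion_filters(cohort)
    _write_json(out / "filter_report.json", report.to_dict())
    log.info("filter: %d -> %d users (median %.1f)", report.n_initial,
             report.n_retained, report.median_posts)

    if config.mode == "text":
        embedder = mock_embedder(config.embed_dim,
                                 seed=derive_seed(config.seed, "embedder"))
        ids, X = embed_users(
            {u.user_id: u.posts for u in filtered.users}, embedder)
        for u, vec in zip(filtered.users, X):
            u.embedding = vec
    embeddings_to_csv([u.user_id for u in filtered.users],
                      filtered.embeddings, out / "embeddings.csv")

    log.info("evaluate: variants=%s repeats=%d", config.variants,
             config.repeats)
    report_eval = repeated_cv(
        filtered, _model_configs(config, config.embed_dim),
        repeats=config.repeats, seed=derive_seed(config.seed, "splits"),
        tasks=config.tasks, keep_scores=True)
    _write_json(out / "evaluation.json", report_eval.to_dict())
    report_eval.per_repeat.to_csv(out / "per_repeat_auc.tsv", sep="\t",
                                  index=False)

    comps = group_comparisons(filtered)
    _write_json(out / "group_comparisons.json", comps)

    if "mtm" in config.variants and "general" in config.tasks:
        interp = interpret_best_fold(filtered, report_eval,
                                     top_k=config.top_k_words)
        _write_json(out / "interpretation.json", interp)
    log.info("run complete: %s", out)
    return out


def interpret_best_fold(cohort, report: EvaluationReport,
                        variant: str = "mtm", task: str = "general",
                        top_k: int = 100) -> dict:
    """Interpretation bundle for the fold where the chosen model reached
    its best test AUC: TP/FP-ratio threshold, confusion partition and — if
    the cohort carries posts — keyword matches and class TF-IDF words."""
    sub = report.per_repeat.query("variant == @variant and task == @task")
    if sub.empty:
        raise ValueError(f"no folds for {variant}/{task}")
    best = int(sub.loc[sub["auc"].idxmax(), "repeat"])
    test_idx, scores = report.fold_scores[(best, variant, task)]
    y = cohort.labels(task)[test_idx]
    ids = [cohort.users[i].user_id for i in test_idx]
    roc, auc = roc_and_auc(scores, y)
    threshold, thr_report = select_threshold(roc)
    part = partition_confusion(ids, scores, y, threshold)
    result = {
        "best_repeat": best, "test_auc": float(auc),
        "threshold": threshold, "threshold_report": thr_report,
        "confusion": {k: v for k, v in part.classes().items()},
        "confusion_counts": {k: len(v) for k, v in part.classes().items()},
        "tp_share_of_test": len(part.tp) / len(ids),
        "test_scores": [{"user_id": uid, "score": float(s), "label": int(l)}
                        for uid, s, l in zip(ids, scores, y)],
    }
    posts_by_user = {u.user_id: u.posts for u in cohort.users
                     if u.posts is not None}
    if posts_by_user:
        tp_posts = {uid: posts_by_user[uid] for uid in part.tp}
        matches = keyword_search(tp_posts)
        result["keyword_matches"] = [dataclasses.asdict(m) for m in matches]
        posts_by_class = {
            cls: [p for uid in uids for p in posts_by_user[uid]]
            for cls, uids in part.classes().items()}
        tfidf = tfidf_class_words(
            {c: p for c, p in posts_by_class.items() if p}, k=top_k)
        result["tfidf_top_words"] = tfidf.top_words
    return result


# ---------------------------------------------------------------------------
# Structure recovery
# ---------------------------------------------------------------------------

def structure_recovery_experiment(n_seeds: int = 5, repeats: int = 5,
                                  n: int = 1002, embed_dim: int = 128,
                                  signal_strength: float = 0.15,
                                  base_seed: int = 0,
                                  max_epochs: int = 60, patience: int = 8
                                  ) -> dict:
    """Does hierarchical auxiliary supervision help when the label is
    mediated by the auxiliary constructs?

    Oracle-mode cohorts whose embeddings carry only the eleven auxiliary
    latents (the suicide latent enters the label but never the embedding),
    at a noise level chosen so the single-task model operates near the
    published real-data AUC.  STM and MTM are trained on matched splits for
    ``n_seeds`` cohorts x ``repeats`` splits; the paired AUC differences
    are summarized with a one-sided Wilcoxon signed-rank test.
    """
    cal = default_calibration(signal_strength=signal_strength)
    rows = []
    for cs in range(n_seeds):
        cohort = generate_cohort(
            cal, n, seed=derive_seed(base_seed, f"sr-cohort-{cs}"),
            mode="oracle", embed_dim=embed_dim, mediated_only=True)
        configs = [ModelConfig(variant=v, input_dim=embed_dim,
                               max_epochs=max_epochs, patience=patience,
                               seed=derive_seed(base_seed, f"sr-model-{cs}"))
                   for v in ("stm", "mtm")]
        rep = repeated_cv(cohort, configs, repeats=repeats,
                          seed=derive_seed(base_seed, f"sr-split-{cs}"))
        for _, row in rep.per_repeat.iterrows():
            rows.append({"cohort_seed": cs, **row.to_dict()})
    df = pd.DataFrame(rows)
    piv = df.pivot_table(index=["cohort_seed", "repeat"], columns="variant",
                         values="auc")
    diffs = (piv["mtm"] - piv["stm"]).to_numpy()
    wilcoxon = stats.wilcoxon(diffs, alternative="greater")
    return {
        "mean_auc_stm": float(piv["stm"].mean()),
        "mean_auc_mtm": float(piv["mtm"].mean()),
        "mean_difference": float(diffs.mean()),
        "n_pairs": len(diffs),
        "n_wins": int((diffs > 0).sum()),
        "wilcoxon_p": float(wilcoxon.pvalue),
        "signal_strength": signal_strength,
        "per_pair": df.to_dict(orient="records"),
    }


# ---------------------------------------------------------------------------
# Cross-run comparison
# ---------------------------------------------------------------------------

def compare_models(run_dirs: list[str | Path]) -> pd.DataFrame:
    """Combine evaluation reports from runs that share a cohort seed into
    one table: rows = (task, model), columns mean AUC, CI, Cohen's d."""
    rows = []
    hashes = set()
    for run in map(Path, run_dirs):
        cfg = json.loads((run / "config.json").read_text())
        hashes.add(cfg["seed"])
        rep = json.loads((run / "evaluation.json").read_text())
        for key, s in rep["summary"].items():
            variant, task = key.split("/")
            rows.append({"run": run.name, "task": task, "model": variant,
                         "mean_auc": s["mean_auc"], "ci_low": s["ci_low"],
                         "ci_high": s["ci_high"],
                         "cohens_d": s["cohens_d"]})
    if len(hashes) > 1:
        raise ValueError("runs do not share a cohort seed")
    return pd.DataFrame(rows).sort_values(["task", "model"])
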