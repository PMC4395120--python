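"""End-to-end study runner: simulate → process/featurize → classify →
compare, as one configured, logged, seeded run.

Every run directory records the root seed and a hash of the effective
configuration; re-running with an identical configuration is a no-op
(stage outputs are reused).  All randomness fans out from the single
root seed, so two runs with the same configuration produce identical
output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .exceptions import ConfigError
from .features import extract_cohort_features, sam_matrix
from .modeling import (
    KNN_K,
    N_COMPONENTS,
    loocv_classify,
    reduce_dimensions,
    sam_classify,
    task_rows,
)
from .resampling import GROUP_KNN_K, run_comparisons
from .synthetic import CohortConfig, generate_cohort
from .types import ARCHETYPE_CLASSES, EMOTION_CLASSES

logger = logging.getLogger(__name__)

_TASKS = {"archetypes": ARCHETYPE_CLASSES, "emotions": EMOTION_CLASSES}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one full study run."""

    seed: int = 0
    n_subjects: int = 25
    stimulus_duration: float = 300.0
    baseline_duration: float = 40.0
    effect_size: float = 1.0
    n_components: int = N_COMPONENTS
    classifiers: tuple[str, ...] = ("knn", "naive_bayes", "lda")
    knn_k: dict = field(default_factory=lambda: dict(KNN_K))
    group_knn_k: int = GROUP_KNN_K
    leakage_mode: str = "strict"
    pca_scope: str = "pooled"
    persist_signals: bool = True

    _SCHEMA = {
        "seed": (int, lambda v: 0 <= v < 2**31),
        "n_subjects": (int, lambda v: v >= 3),
        "stimulus_duration": ((int, float), lambda v: v > 0),
        "baseline_duration": ((int, float), lambda v: v > 0),
        "effect_size": ((int, float), lambda v: 0 <= v <= 1),
        "n_components": (int, lambda v: v >= 1),
        "classifiers": ((tuple, list), lambda v: len(v) >= 1),
        "knn_k": (dict, lambda v: all(isinstance(x, int) and x >= 1 for x in v.values())),
        "group_knn_k": (int, lambda v: v >= 1),
        "leakage_mode": (str, lambda v: v in ("strict", "pooled")),
        "pca_scope": (str, lambda v: v in ("pooled", "per_task")),
        "persist_signals": (bool, lambda v: True),
    }

    def __post_init__(self) -> None:
        for name, (types, check) in self._SCHEMA.items():
            v = getattr(self, name)
            if not isinstance(v, types) or isinstance(v, bool) and types is int:
                raise ConfigError(f"field {name!r}: wrong type {type(v).__name__}")
            if not check(v):
                raise ConfigError(f"field {name!r}: invalid value {v!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "classifiers" in d:
            d = {**d, "classifiers": tuple(d["classifiers"])}
        return cls(**d)

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_subjects=self.n_subjects,
            stimulus_duration=self.stimulus_duration,
            baseline_duration=self.baseline_duration,
            effect_size=self.effect_size,
            seed=self.seed,
        )

    def digest(self) -> str:
        payload = asdict(self)
        payload["classifiers"] = list(payload["classifiers"])
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run configuration."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return RunConfig.from_dict(data)


def _reduce_for_scope(feats: pd.DataFrame, config: RunConfig):
    """PCA scores under the configured fitting scope: one transform on
    the pooled eight-class matrix (default) or one per four-class task."""
    if config.pca_scope == "pooled":
        return reduce_dimensions(feats, config.n_components)
    parts, summary = [], None
    for classes in _TASKS.values():
        scores, summary = reduce_dimensions(
            task_rows(feats, classes), config.n_components
        )
        parts.append(scores)
    return pd.concat(parts), summary


def _stage(out: Path, name: str, digest: str, outputs: list[str]) -> bool:
    """True if this stage's outputs already exist for this config."""
    stamp = out / f".{name}.stamp"
    if stamp.exists() and stamp.read_text() == digest:
        if all((out / f).exists() for f in outputs):
            logger.info("stage %s: up to date, skipping", name)
            return True
    return False


def _stamp(out: Path, name: str, digest: str) -> None:
    (out / f".{name}.stamp").write_text(digest)


def run_study(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages into ``out_dir``; returns the directory.

    Outputs: ``manifest.json`` + ``sam.csv`` (+ per-channel signal
    tables when ``persist_signals``), ``features.csv``, per-task
    ``cv_results.csv`` and confusion matrices, ``group_accuracies.csv``
    and ``comparisons.csv``, plus ``run_meta.json`` and ``run.log``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root_logger = logging.getLogger("archepsy")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        logger.info("run config: %s (hash %s)", asdict(config), digest)
        logger.info(
            "defaults in effect: eq1 scope=within-subject per signal; "
            "leakage_mode=%s; pca_scope=%s; knn_k=%s; group_knn_k=%d",
            config.leakage_mode, config.pca_scope, config.knn_k,
            config.group_knn_k,
        )

        sessions = None

        def need_sessions():
            nonlocal sessions
            if sessions is None:
                t0 = time.perf_counter()
                sessions = generate_cohort(config.cohort_config())
                logger.info("simulate: %.1f s", time.perf_counter() - t0)
            return sessions

        # --- simulate ------------------------------------------------
        if not _stage(out, "simulate", digest, ["manifest.json", "sam.csv"]):
            aio.write_cohort(
                need_sessions(), out, seed=config.seed, config_hash=digest,
                persist_signals=config.persist_signals,
            )
            _stamp(out, "simulate", digest)

        # --- process + featurize --------------------------------------
        if not _stage(out, "featurize", digest, ["features.csv"]):
            t0 = time.perf_counter()
            feats = extract_cohort_features(need_sessions())
            aio.write_feature_matrix(feats, out / "features.csv")
            logger.info("featurize: %.1f s", time.perf_counter() - t0)
            _stamp(out, "featurize", digest)
        feats = aio.read_feature_matrix(out / "features.csv")
        sam = pd.read_csv(out / "sam.csv").set_index(["subject", "class"])

        # --- classify --------------------------------------------------
        cv_outputs = ["cv_results.csv"]
        if not _stage(out, "classify", digest, cv_outputs):
            t0 = time.perf_counter()
            rows = []
            for task, classes in _TASKS.items():
                Xt = task_rows(feats, classes)
                labels = Xt.index.get_level_values("class").to_numpy()
                for clf in config.classifiers:
                    res = loocv_classify(
                        Xt, labels, classifier=clf,
                        k=config.knn_k.get(task, 20),
                        n_components=config.n_components,
                        leakage_mode=config.leakage_mode,
                    )
                    rows.append((task, "physiological", clf, res.accuracy))
                    cm = pd.DataFrame(
                        res.confusion, index=res.classes, columns=res.classes
                    )
                    cm.to_csv(out / f"confusion_{task}_{clf}.csv")
                # SAM LDA
                St = task_rows(sam, classes)
                sres = sam_classify(
                    St, St.index.get_level_values("class").to_numpy(),
                    leakage_mode=config.leakage_mode,
                )
                rows.append((task, "sam", "lda", sres.accuracy))
                pd.DataFrame(
                    sres.confusion, index=sres.classes, columns=sres.classes
                ).to_csv(out / f"confusion_{task}_sam_lda.csv")
            pd.DataFrame(
                rows, columns=["task", "modality", "classifier", "accuracy"]
            ).to_csv(out / "cv_results.csv", index=False, float_format="%.10g")
            logger.info("classify: %.1f s", time.perf_counter() - t0)
            _stamp(out, "classify", digest)

        # --- compare ---------------------------------------------------
        if not _stage(out, "compare", digest,
                      ["group_accuracies.csv", "comparisons.csv"]):
            t0 = time.perf_counter()
            reduced, summary = _reduce_for_scope(feats, config)
            logger.info(
                "PCA: %d components explain %.1f%% of variance",
                config.n_components, 100 * summary.total_explained,
            )
            groups, comparisons = run_comparisons(
                reduced, sam, k=config.group_knn_k
            )
            groups.to_csv(
                out / "group_accuracies.csv", index=False, float_format="%.10g"
            )
            comparisons.to_csv(
                out / "comparisons.csv", index=False, float_format="%.10g"
            )
            logger.info("compare: %.1f s", time.perf_counter() - t0)
            _stamp(out, "compare", digest)

        meta = {"seed": config.seed, "config_hash": digest,
                "config": asdict(config)}
        meta["config"]["classifiers"] = list(meta["config"]["classifiers"])
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return out


def study_in_memory(config: RunConfig) -> dict:
    """Run the identical staged computation without touching disk.

    Returns a dict with the cohort sessions, feature matrix, SAM matrix,
    reduced matrix, CV results and comparison tables — convenient for
    tests and scripted analyses.
    """
    sessions = generate_cohort(config.cohort_config())
    feats = extract_cohort_features(sessions)
    sam = sam_matrix(sessions)
    cv = {}
    for task, classes in _TASKS.items():
        Xt = task_rows(feats, classes)
        labels = Xt.index.get_level_values("class").to_numpy()
        for clf in config.classifiers:
            cv[(task, "physiological", clf)] = loocv_classify(
                Xt, labels, classifier=clf, k=config.knn_k.get(task, 20),
                n_components=config.n_components,
                leakage_mode=config.leakage_mode,
            )
        St = task_rows(sam, classes)
        cv[(task, "sam", "lda")] = sam_classify(
            St, St.index.get_level_values("class").to_numpy(),
            leakage_mode=config.leakage_mode,
        )
    reduced, summary = _reduce_for_scope(feats, config)
    groups, comparisons = run_comparisons(reduced, sam, k=config.group_knn_k)
    return {
        "sessions": sessions,
        "features": feats,
        "sam": sam,
        "reduced": reduced,
        "reduction": summary,
        "cv": cv,
        "groups": groups,
        "comparisons": comparisons,
    }
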