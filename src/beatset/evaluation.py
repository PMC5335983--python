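"""Experimental protocol: repeated halving, set construction, Rank-k rates.

Each trial randomly halves every class into training and testing halves
(stratified; the odd sample goes to training), caps oversized classes at
``cap`` training samples, optionally learns or applies a Mahalanobis
metric, builds one corpus set per class from the capped training samples,
partitions each class's test samples into query sets of the configured
size, ranks the classes for every query set by ascending set
dissimilarity, and scores Rank-1 (accuracy) and Rank-5 rates.  Splits are
deterministic per (seed, trial), so different measures compared under the
same seed consume identical splits.

The reference protocol defaults are built in: 10 trials, 50/50 halving,
per-class training cap 500, query-set size 50 with small-class overrides
(J, Q, e -> 5; the two-sample class S -> singleton sets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .beats_io import map_to_aami
from .features import FeatureTable
from .metric import MetricModel, train
from .setdist import MBDConfig, SampleSet, set_distance_matrix

__all__ = [
    "ExperimentConfig",
    "ResultTable",
    "split_trials",
    "cap_training",
    "build_query_sets",
    "rank_classes",
    "evaluate",
    "baseline_single_sample",
    "contaminated_cluster_study",
]


def _default_small_class_sizes() -> dict[str, int]:
    return {"J": 5, "Q": 5, "e": 5, "S": 1}


@dataclass
class ExperimentConfig:
    n_trials: int = 10
    train_fraction: float = 0.5
    cap: int = 500
    set_size: int = 50
    small_class_set_size: dict[str, int] = field(default_factory=_default_small_class_sizes)
    measure: str = "mbd"
    mbd: MBDConfig = field(default_factory=MBDConfig)
    metric: MetricModel | str | None = None  # None | 'mlr' | a fitted model
    mlr_params: dict = field(default_factory=dict)
    label_scheme: str = "sixteen"  # 'sixteen' (labels as-is) or 'aami'
    keep_leftover: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.set_size < 1 or self.n_trials < 1 or self.cap < 1:
            raise ValueError("set_size, n_trials and cap must be >= 1")
        if self.label_scheme not in ("sixteen", "aami"):
            raise ValueError("label_scheme must be 'sixteen' or 'aami'")


@dataclass
class ResultTable:
    """Rank-1/Rank-5 rates (percent) overall and per class, across trials."""

    rank1: float
    rank5: float
    per_class: dict[str, tuple[float, float]]
    per_trial_rank1: np.ndarray
    per_trial_rank5: np.ndarray

    def to_dict(self) -> dict:
        return {
            "rank1": self.rank1,
            "rank5": self.rank5,
            "per_class": {c: list(v) for c, v in self.per_class.items()},
            "per_trial_rank1": self.per_trial_rank1.tolist(),
            "per_trial_rank5": self.per_trial_rank5.tolist(),
        }


def _trial_rng(seed: int, trial: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, trial, stream]))


def split_trials(
    labels: np.ndarray, config: ExperimentConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random halving per trial; deterministic per (seed, trial).

    With odd class counts the extra sample lands in training.  Returned
    index arrays partition ``arange(len(labels))``.
    """
    labels = np.asarray(labels)
    splits = []
    for trial in range(config.n_trials):
        rng = _trial_rng(config.seed, trial, 0)
        train_idx, test_idx = [], []
        for cls in sorted(set(labels.tolist())):
            idx = np.nonzero(labels == cls)[0]
            perm = rng.permutation(idx)
            n_train = math.ceil(len(idx) * config.train_fraction)
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        splits.append(
            (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))
        )
    return splits


def cap_training(
    train_indices: np.ndarray,
    labels: np.ndarray,
    cap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Randomly subsample classes exceeding ``cap`` to exactly ``cap``."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    labels = np.asarray(labels)
    kept = []
    for cls in sorted(set(labels[train_indices].tolist())):
        idx = train_indices[labels[train_indices] == cls]
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        kept.append(np.sort(idx))
    return np.concatenate(kept)


def build_query_sets(
    test_indices: np.ndarray,
    labels: np.ndarray,
    config: ExperimentConfig,
    rng: np.random.Generator,
    matrix: np.ndarray,
) -> list[SampleSet]:
    """Partition each class's test samples into disjoint query sets.

    Samples are shuffled (seeded) then chunked at the class's set size;
    a final partial chunk is kept as a smaller set when ``keep_leftover``
    (default), else discarded.  Every set carries its true class.
    """
    labels = np.asarray(labels)
    sets: list[SampleSet] = []
    for cls in sorted(set(labels[test_indices].tolist())):
        size = config.small_class_set_size.get(cls, config.set_size)
        idx = rng.permutation(test_indices[labels[test_indices] == cls])
        for start in range(0, len(idx), size):
            chunk = idx[start : start + size]
            if len(chunk) < size and not config.keep_leftover:
                continue
            sets.append(
                SampleSet(
                    vectors=matrix[chunk],
                    set_id=f"{cls}-{start // size}",
                    class_label=str(cls),
                )
            )
    return sets


def rank_classes(
    query: SampleSet,
    corpus_sets: list[SampleSet],
    measure: str = "mbd",
    config: MBDConfig = MBDConfig(),
    projection: np.ndarray | None = None,
) -> list[str]:
    """Classes sorted by ascending dissimilarity to the query set.

    Ties break by ascending class symbol, deterministically.
    """
    for s in corpus_sets:
        if len(s) == 0:
            raise ValueError("empty corpus set")
    dists = set_distance_matrix([query], corpus_sets, measure, config, projection)[0]
    order = sorted(range(len(corpus_sets)), key=lambda j: (dists[j], str(corpus_sets[j].class_label)))
    return [str(corpus_sets[j].class_label) for j in order]


def _resolve_labels(features: FeatureTable, scheme: str) -> np.ndarray:
    labels = np.asarray(features.labels, dtype=object)
    if scheme == "aami":
        return np.array([map_to_aami(str(s)) for s in labels], dtype=object)
    return np.array([str(s) for s in labels], dtype=object)


def evaluate(features: FeatureTable, config: ExperimentConfig) -> ResultTable:
    """Run the full protocol and report Rank-1/Rank-5 rates in percent.

    Rank-1 counts a query set as correct when its true class tops the
    dissimilarity ranking; Rank-5 when it appears in the top five.  Each
    query set is one decision; per-class rates average over that class's
    sets, skipping trials where a class has no test sample.
    """
    X = np.asarray(features.matrix, dtype=float)
    labels = _resolve_labels(features, config.label_scheme)
    splits = split_trials(labels, config)

    classes = sorted(set(labels.tolist()))
    trial_r1, trial_r5 = [], []
    per_class_r1: dict[str, list[float]] = {c: [] for c in classes}
    per_class_r5: dict[str, list[float]] = {c: [] for c in classes}

    for trial, (train_idx, test_idx) in enumerate(splits):
        cap_rng = _trial_rng(config.seed, trial, 1)
        capped = cap_training(train_idx, labels, config.cap, cap_rng)

        projection = None
        if config.metric is not None:
            if isinstance(config.metric, MetricModel):
                model = config.metric
            elif config.metric == "mlr":
                model = train(
                    FeatureTable(matrix=X[capped], labels=labels[capped]),
                    **config.mlr_params,
                )
            else:
                raise ValueError(f"metric must be None, 'mlr' or a MetricModel")
            projection = model.l
        Xp = X @ projection.T if projection is not None else X

        corpus_sets = [
            SampleSet(
                vectors=Xp[capped[labels[capped] == cls]],
                set_id=f"corpus-{cls}",
                class_label=str(cls),
            )
            for cls in sorted(set(labels[capped].tolist()))
        ]
        set_rng = _trial_rng(config.seed, trial, 2)
        query_sets = build_query_sets(test_idx, labels, config, set_rng, Xp)

        hits1: dict[str, list[bool]] = {c: [] for c in classes}
        hits5: dict[str, list[bool]] = {c: [] for c in classes}
        for qs in query_sets:
            ranked = rank_classes(qs, corpus_sets, config.measure, config.mbd)
            truth = str(qs.class_label)
            hits1[truth].append(ranked[0] == truth)
            hits5[truth].append(truth in ranked[:5])
        all1 = [h for hs in hits1.values() for h in hs]
        all5 = [h for hs in hits5.values() for h in hs]
        trial_r1.append(100.0 * np.mean(all1) if all1 else np.nan)
        trial_r5.append(100.0 * np.mean(all5) if all5 else np.nan)
        for c in classes:
            if hits1[c]:
                per_class_r1[c].append(100.0 * np.mean(hits1[c]))
                per_class_r5[c].append(100.0 * np.mean(hits5[c]))

    per_class = {
        c: (float(np.mean(per_class_r1[c])), float(np.mean(per_class_r5[c])))
        for c in classes
        if per_class_r1[c]
    }
    return ResultTable(
        rank1=float(np.nanmean(trial_r1)),
        rank5=float(np.nanmean(trial_r5)),
        per_class=per_class,
        per_trial_rank1=np.asarray(trial_r1),
        per_trial_rank5=np.asarray(trial_r5),
    )


def baseline_single_sample(features: FeatureTable, config: ExperimentConfig) -> ResultTable:
    """Single-sample classification: each test sample is a singleton query.

    Classes are ranked by the distance from the sample to each class's
    nearest training sample, i.e. singleton-query MPD — the Euclidean
    baseline when ``config.metric`` is None, or the metric-space
    single-sample classifier when a metric is supplied.
    """
    cfg = replace(config, set_size=1, small_class_set_size={}, measure="mpd")
    return evaluate(features, cfg)


def contaminated_cluster_study(
    seed: int = 0,
    n_per_class: int = 120,
    n_trials: int = 10,
    set_size: int = 20,
    contamination_rate: float = 0.1,
    contamination_magnitude: float = 30.0,
    C: float = 1.0,
    regularizer: str = "frobenius",
) -> dict[str, np.ndarray]:
    """Distorted-cluster robustness study: per-trial Rank-1 rates per method.

    Generates anisotropically distorted Gaussian clusters (the package's
    default study conditions), then per trial: halves the data, learns the
    ranking metric on the (curated) training half, corrupts a fraction of
    both the corpus samples and the test samples by a large random
    displacement (gross outliers accumulating at the measurement stage),
    and classifies query sets with each set dissimilarity — MBD in the
    learned space ('mlr_mbd') and in raw space ('mbd'), MPD, MAD and APD
    in raw space — plus the two single-sample classifiers ('mlr_single'
    in the learned space, 'baseline' in raw space).  All methods share
    each trial's split and corruption.

    Returns a dict mapping method name to a length-``n_trials`` array of
    Rank-1 percentages.
    """
    from .metric import train as train_metric
    from .synthetic import contaminate, default_cluster_spec, simulate_feature_clusters

    spec = default_cluster_spec()
    features = simulate_feature_clusters(spec, [n_per_class] * spec.n_classes, seed=seed)
    X = features.matrix
    labels = np.array([str(s) for s in features.labels], dtype=object)

    cfg = ExperimentConfig(
        n_trials=n_trials, set_size=set_size, small_class_set_size={}, seed=seed
    )
    splits = split_trials(labels, cfg)
    classes = sorted(set(labels.tolist()))
    methods = ["mlr_mbd", "mbd", "mpd", "mad", "apd", "mlr_single", "baseline"]
    rates: dict[str, list[float]] = {m: [] for m in methods}

    for trial, (train_idx, test_idx) in enumerate(splits):
        capped = cap_training(train_idx, labels, cfg.cap, _trial_rng(seed, trial, 1))
        model = train_metric(
            FeatureTable(matrix=X[capped], labels=labels[capped]),
            C=C,
            regularizer=regularizer,
        )
        X_test = X[test_idx]
        X_corpus = X[capped]
        if contamination_rate > 0:
            corrupt_rng = _trial_rng(seed, trial, 3)
            X_test = contaminate(
                SampleSet(vectors=X_test),
                contamination_rate,
                contamination_magnitude,
                seed=int(corrupt_rng.integers(2**31)),
            ).vectors
            X_corpus = contaminate(
                SampleSet(vectors=X_corpus),
                contamination_rate,
                contamination_magnitude,
                seed=int(corrupt_rng.integers(2**31)),
            ).vectors

        set_rng_state = _trial_rng(seed, trial, 2)
        chunks: list[tuple[str, np.ndarray]] = []  # (class, test-row positions)
        pos_of = {int(g): p for p, g in enumerate(test_idx)}
        for cls in classes:
            idx = set_rng_state.permutation(test_idx[labels[test_idx] == cls])
            for start in range(0, len(idx), set_size):
                chunk = idx[start : start + set_size]
                chunks.append((cls, np.array([pos_of[int(g)] for g in chunk])))

        for method in methods:
            projected = method in ("mlr_mbd", "mlr_single")
            Xc = X_corpus @ model.l.T if projected else X_corpus
            Xt = X_test @ model.l.T if projected else X_test
            corpus = [
                SampleSet(vectors=Xc[labels[capped] == cls], class_label=cls)
                for cls in classes
            ]
            measure = {"mlr_mbd": "mbd", "mlr_single": "mpd", "baseline": "mpd"}.get(
                method, method
            )
            if method in ("mlr_single", "baseline"):
                queries = [
                    SampleSet(vectors=Xt[p : p + 1], class_label=labels[test_idx[p]])
                    for p in range(len(test_idx))
                ]
            else:
                queries = [
                    SampleSet(vectors=Xt[pos], class_label=cls) for cls, pos in chunks
                ]
            hits = [
                rank_classes(q, corpus, measure, cfg.mbd)[0] == q.class_label
                for q in queries
            ]
            rates[method].append(100.0 * float(np.mean(hits)))

    return {m: np.asarray(v) for m, v in rates.items()}
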