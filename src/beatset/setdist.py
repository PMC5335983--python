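"""Set-to-set dissimilarity measures.

A query set of same-class samples is matched against per-class corpus
sets by a dissimilarity between point sets.  Besides the classic measures
— minimum point-wise distance (MPD), mean approach distance (MAD) and
average point-wise distance (APD) — this module implements the
minority-based dissimilarity (MBD): for each set, average the point-to-set
distances of only its alpha members closest to the other set (the
"minority"), then combine the two directional terms with a sum (default),
max or min.  The minority focuses the measure on the informative outer
samples facing the other set while ignoring gross outliers, which makes
MBD markedly more robust to contaminated samples than MAD/APD.

MBD generalizes the classics: alpha = 1 with the min combination is
exactly MPD, and beta = 1 (full sets) with the sum combination is exactly
MAD.

The base point distance is Euclidean; a learned Mahalanobis metric enters
exclusively by projecting all vectors with the metric factor l beforehand
(w = l'l), which is equivalent to measuring with w directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "SampleSet",
    "MBDConfig",
    "point_to_set",
    "minority_subset",
    "mbd",
    "classic",
    "set_distance_matrix",
]


@dataclass
class SampleSet:
    """An ordered collection of feature vectors treated as one unit."""

    vectors: np.ndarray
    set_id: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.shape[0] < 1:
            raise ValueError("a SampleSet needs at least one vector")

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class MBDConfig:
    """Minority ratio beta in (0, 1] and the directional combination op."""

    beta: float = 0.1
    op: str = "sum"

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.op not in ("sum", "max", "min"):
            raise ValueError(f"op must be 'sum', 'max' or 'min', got {self.op!r}")


_OPS = {"sum": lambda u, v: u + v, "max": max, "min": min}


def point_to_set(a: np.ndarray, B: SampleSet) -> float:
    """d(a, B) = min over b in B of the Euclidean distance from a to b."""
    a = np.asarray(a, dtype=float)
    if a.shape[-1] != B.vectors.shape[1]:
        raise ValueError(
            f"dimension mismatch: point has {a.shape[-1]}, set has {B.vectors.shape[1]}"
        )
    return float(np.linalg.norm(B.vectors - a, axis=1).min())


def minority_subset(A: SampleSet, B: SampleSet, alpha: int) -> SampleSet:
    """The alpha members of A nearest to B (smallest point-to-set distance).

    Ties break stably by (distance, original index), so alpha = 1 yields
    the MPD witness sample.
    """
    if not 1 <= alpha <= len(A):
        raise ValueError(f"alpha must be in [1, {len(A)}], got {alpha}")
    d = cdist(A.vectors, B.vectors).min(axis=1)
    order = np.argsort(d, kind="stable")[:alpha]
    return SampleSet(vectors=A.vectors[order], set_id=A.set_id, class_label=A.class_label)


def _directional_minority_means(A: SampleSet, B: SampleSet, alpha: int):
    d = cdist(A.vectors, B.vectors)
    da = np.sort(d.min(axis=1), kind="stable")[:alpha]
    db = np.sort(d.min(axis=0), kind="stable")[:alpha]
    return float(da.mean()), float(db.mean())


def mbd(A: SampleSet, B: SampleSet, config: MBDConfig = MBDConfig()) -> float:
    """Minority-based dissimilarity between two sets.

    Both directional minorities share one size
    ``alpha = max(1, floor(beta * min(|A|, |B|)))``; each directional term
    is the mean point-to-set distance over that minority, and the two
    terms are combined with the configured op.  Symmetric in A and B.
    """
    alpha = max(1, math.floor(config.beta * min(len(A), len(B))))
    term_a, term_b = _directional_minority_means(A, B, alpha)
    return float(_OPS[config.op](term_a, term_b))


def classic(A: SampleSet, B: SampleSet, kind: str) -> float:
    """Classic set dissimilarities: 'mpd', 'mad' or 'apd'.

    MPD is the global minimum pairwise distance; MAD sums the two mean
    point-to-set distances; APD is the mean over all |A|*|B| pairwise
    distances.
    """
    d = cdist(A.vectors, B.vectors)
    kind = kind.lower()
    if kind == "mpd":
        return float(d.min())
    if kind == "mad":
        # summed in ascending order so the MBD full-minority limit is bitwise equal
        return float(
            np.sort(d.min(axis=1), kind="stable").mean()
            + np.sort(d.min(axis=0), kind="stable").mean()
        )
    if kind == "apd":
        return float(d.mean())
    raise ValueError(f"unknown dissimilarity kind {kind!r} (use 'mpd', 'mad' or 'apd')")


def _measure_fn(measure: str, config: MBDConfig):
    measure = measure.lower()
    if measure == "mbd":
        return lambda A, B: mbd(A, B, config)
    if measure in ("mpd", "mad", "apd"):
        return lambda A, B: classic(A, B, measure)
    raise ValueError(f"unknown measure {measure!r} (use 'mbd', 'mpd', 'mad' or 'apd')")


def set_distance_matrix(
    queries: list[SampleSet],
    corpus: list[SampleSet],
    measure: str = "mbd",
    config: MBDConfig = MBDConfig(),
    projection: np.ndarray | None = None,
) -> np.ndarray:
    """Entry (i, j) = measure(query_i, corpus_j), optionally in l-projected space.

    ``projection`` is the metric factor l (rows = projected dimensions);
    applying it first makes the Euclidean base distance equal to the
    Mahalanobis distance under w = l'l.
    """
    fn = _measure_fn(measure, config)
    if projection is not None:
        projection = np.asarray(projection, dtype=float)
        dim = queries[0].vectors.shape[1] if queries else corpus[0].vectors.shape[1]
        if projection.shape[1] != dim:
            raise ValueError(
                f"projection maps dimension {projection.shape[1]}, data has {dim}"
            )
        project = lambda s: SampleSet(
            vectors=s.vectors @ projection.T, set_id=s.set_id, class_label=s.class_label
        )
        queries = [project(s) for s in queries]
        corpus = [project(s) for s in corpus]
    out = np.empty((len(queries), len(corpus)))
    for i, q in enumerate(queries):
        for j, c in enumerate(corpus):
            out[i, j] = fn(q, c)
    return out
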