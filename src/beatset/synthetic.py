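"""Synthetic beat waveforms and feature-space clusters.

Every downstream stage of the pipeline (feature encoding, metric learning,
set dissimilarity, evaluation) is exercisable on data produced here, with
the statistical structure the method assumes: several beat classes with
distinct morphology, within-class amplitude/timing jitter, additive noise,
baseline wander, severe class imbalance, and a controllable fraction of
grossly displaced outlier samples.

The waveform model is a sum of Gaussian humps (P/QRS/T-like) plus a
baseline sinusoid and white noise.  It is not a physiological simulator;
the pipeline only ever sees feature vectors, so class-distinct morphology
is all that is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .beats_io import BeatRecord
from .features import FeatureTable
from .setdist import SampleSet

__all__ = [
    "BeatClassSpec",
    "ClusterSpec",
    "simulate_beats",
    "simulate_feature_clusters",
    "contaminate",
    "default_beat_specs",
    "default_cluster_spec",
]


@dataclass(frozen=True)
class BeatClassSpec:
    """Generative description of one synthetic beat class.

    ``wave_components`` is a list of ``(amplitude, center, width)`` triples;
    each contributes ``amplitude * exp(-(t - center)^2 / (2 width^2))`` to
    the beat template.  Amplitude jitter is relative (a value of 0.05 means
    5% multiplicative jitter), timing jitter and widths are in samples.
    """

    class_id: int
    wave_components: tuple[tuple[float, float, float], ...]
    amp_jitter_sd: float = 0.0
    time_jitter_sd: float = 0.0
    noise_sd: float = 0.0
    baseline_amp: float = 0.0
    baseline_period: float = 350.0

    def __post_init__(self) -> None:
        for amp, center, width in self.wave_components:
            if width <= 0:
                raise ValueError(
                    f"BeatClassSpec(class_id={self.class_id}): width must be > 0, "
                    f"got {width} for component center {center}"
                )
        if self.noise_sd < 0 or self.amp_jitter_sd < 0 or self.time_jitter_sd < 0:
            raise ValueError(
                f"BeatClassSpec(class_id={self.class_id}): jitter/noise SDs must be >= 0"
            )

    def template(self, length: int) -> np.ndarray:
        """Noise-free waveform: the sum of the Gaussian components."""
        t = np.arange(length, dtype=float)
        out = np.zeros(length)
        for amp, center, width in self.wave_components:
            out += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
        return out


@dataclass(frozen=True)
class ClusterSpec:
    """Gaussian class clusters in feature space, optionally distorted.

    Class means sit at scaled simplex vertices so every pair of means is
    ``class_separation`` apart (one interpretable knob).  ``distortion`` is
    a square matrix applied to all samples after drawing; a fraction
    ``contamination_rate`` of samples is then displaced by
    ``contamination_magnitude`` in a uniformly random direction.
    """

    n_classes: int
    dim: int
    class_separation: float = 6.0
    within_sd: float = 1.0
    distortion: np.ndarray | None = None
    contamination_rate: float = 0.0
    contamination_magnitude: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError(
                f"contamination_rate must be in [0, 1], got {self.contamination_rate}"
            )
        if self.within_sd < 0:
            raise ValueError(f"within_sd must be >= 0, got {self.within_sd}")
        if self.dim < self.n_classes:
            raise ValueError(
                f"dim ({self.dim}) must be >= n_classes ({self.n_classes}) to place "
                "simplex-vertex class means"
            )
        if self.distortion is not None:
            d = np.asarray(self.distortion, dtype=float)
            if d.shape != (self.dim, self.dim):
                raise ValueError(
                    f"distortion must be square with side {self.dim}, got {d.shape}"
                )
            object.__setattr__(self, "distortion", d)

    def class_means(self) -> np.ndarray:
        """(n_classes, dim) means before distortion, pairwise ``class_separation`` apart."""
        means = np.zeros((self.n_classes, self.dim))
        scale = self.class_separation / math.sqrt(2.0)
        for i in range(self.n_classes):
            means[i, i] = scale
        return means


def simulate_beats(
    specs: list[BeatClassSpec],
    n_per_class: list[int],
    length: int = 235,
    seed: int = 0,
) -> list[BeatRecord]:
    """Draw labeled beat waveforms from the generative specs.

    Each beat is the spec's jittered Gaussian sum plus a random-phase
    baseline sinusoid and additive white noise.  With all jitter, noise and
    baseline amplitudes zero, every beat equals the class template exactly.
    Deterministic given ``seed``.
    """
    if len(specs) != len(n_per_class):
        raise ValueError("specs and n_per_class must have equal length")
    for spec in specs:
        for _, center, _ in spec.wave_components:
            if not 0 <= center < length:
                raise ValueError(
                    f"BeatClassSpec(class_id={spec.class_id}): component center "
                    f"{center} outside [0, {length})"
                )
    for n in n_per_class:
        if n < 0:
            raise ValueError("counts must be >= 0")

    rng = np.random.default_rng(seed)
    t = np.arange(length, dtype=float)
    records: list[BeatRecord] = []
    for spec, n in zip(specs, n_per_class):
        stochastic = (
            spec.amp_jitter_sd > 0
            or spec.time_jitter_sd > 0
            or spec.noise_sd > 0
            or spec.baseline_amp > 0
        )
        for i in range(n):
            if stochastic:
                wave = np.zeros(length)
                for amp, center, width in spec.wave_components:
                    a = amp * (1.0 + rng.normal(0.0, spec.amp_jitter_sd))
                    c = center + rng.normal(0.0, spec.time_jitter_sd)
                    wave += a * np.exp(-0.5 * ((t - c) / width) ** 2)
                if spec.baseline_amp > 0:
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    wave += spec.baseline_amp * np.sin(
                        2.0 * np.pi * t / spec.baseline_period + phase
                    )
                if spec.noise_sd > 0:
                    wave += rng.normal(0.0, spec.noise_sd, size=length)
            else:
                wave = spec.template(length)
            records.append(
                BeatRecord(
                    samples=wave,
                    label=str(spec.class_id),
                    record_id=f"synthetic-{spec.class_id}",
                    r_index=None,
                )
            )
    return records


def simulate_feature_clusters(
    spec: ClusterSpec, n_per_class: list[int], seed: int = 0
) -> FeatureTable:
    """Draw a labeled feature table of (distorted, contaminated) class clusters.

    Samples are spherical Gaussians around simplex-vertex means; the
    distortion matrix is applied to every sample (means included); finally
    ``ceil(rate * n_total)`` samples, chosen uniformly without replacement,
    are displaced by ``contamination_magnitude`` along uniformly random
    directions.  Deterministic given ``seed``.
    """
    if len(n_per_class) != spec.n_classes:
        raise ValueError(
            f"n_per_class has length {len(n_per_class)}, expected {spec.n_classes}"
        )
    rng = np.random.default_rng(seed)
    means = spec.class_means()
    rows, labels = [], []
    for cls, n in enumerate(n_per_class):
        x = means[cls] + rng.normal(0.0, spec.within_sd, size=(n, spec.dim))
        rows.append(x)
        labels.extend([str(cls)] * n)
    x = np.vstack(rows) if rows else np.zeros((0, spec.dim))
    if spec.distortion is not None:
        x = x @ spec.distortion.T
    if spec.contamination_rate > 0 and len(x):
        n_out = math.ceil(spec.contamination_rate * len(x))
        idx = rng.choice(len(x), size=n_out, replace=False)
        direc = rng.normal(size=(n_out, spec.dim))
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        x[idx] += spec.contamination_magnitude * direc
    names = [f"f{j}" for j in range(spec.dim)]
    return FeatureTable(matrix=x, labels=np.array(labels, dtype=object), feature_names=names)


def contaminate(
    sample_set: SampleSet, fraction: float, magnitude: float, seed: int = 0
) -> SampleSet:
    """Displace ``ceil(fraction * n)`` members of a set by ``magnitude``.

    Selection is uniform without replacement; displacement directions are
    uniform on the sphere.  The output has the same cardinality as the
    input and untouched members are bit-identical.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    n = len(sample_set.vectors)
    if n == 0:
        raise ValueError("cannot contaminate an empty set")
    rng = np.random.default_rng(seed)
    vectors = np.array(sample_set.vectors, dtype=float, copy=True)
    n_out = math.ceil(fraction * n)
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        direc = rng.normal(size=(n_out, vectors.shape[1]))
        direc /= np.linalg.norm(direc, axis=1, keepdims=True)
        vectors[idx] += magnitude * direc
    return replace(sample_set, vectors=vectors)


def default_beat_specs() -> list[BeatClassSpec]:
    """Four separable beat classes with distinct morphology.

    Loosely styled on a narrow-QRS beat, a wide bundle-branch-block beat, a
    premature-ventricular-contraction-like beat, and a paced beat, on the
    235-sample window with the R-like peak near sample 90.  Jitter, noise
    and baseline-wander levels are moderate so classes stay separable in
    wavelet feature space while individual beats visibly vary.
    """
    common = dict(
        amp_jitter_sd=0.08,
        time_jitter_sd=2.0,
        noise_sd=0.04,
        baseline_amp=0.15,
        baseline_period=350.0,
    )
    return [
        BeatClassSpec(  # narrow QRS with P and upright T
            class_id=0,
            wave_components=(
                (0.15, 55.0, 6.0),
                (-0.12, 84.0, 3.0),
                (1.0, 90.0, 4.0),
                (-0.25, 97.0, 3.0),
                (0.30, 150.0, 12.0),
            ),
            **common,
        ),
        BeatClassSpec(  # wide notched complex, tall late T
            class_id=1,
            wave_components=(
                (0.10, 50.0, 7.0),
                (0.90, 88.0, 10.0),
                (0.35, 104.0, 6.0),
                (0.45, 165.0, 15.0),
            ),
            **common,
        ),
        BeatClassSpec(  # broad ectopic-like complex, deep S, inverted T
            class_id=2,
            wave_components=(
                (1.30, 88.0, 14.0),
                (-0.50, 108.0, 8.0),
                (-0.35, 155.0, 14.0),
            ),
            **common,
        ),
        BeatClassSpec(  # pacing-spike-like narrow deflection plus broad wave
            class_id=3,
            wave_components=(
                (1.10, 90.0, 2.5),
                (0.50, 120.0, 18.0),
            ),
            **common,
        ),
    ]


def default_cluster_spec(
    n_classes: int = 4,
    dim: int = 6,
    contamination_rate: float = 0.0,
    contamination_magnitude: float = 0.0,
) -> ClusterSpec:
    """Base conditions for the distorted-cluster experiments.

    The distortion compresses the subspace holding the class means by 0.3
    and inflates the remaining nuisance axes by 3, so raw Euclidean
    distances are dominated by uninformative directions; a learned
    Mahalanobis metric can undo this.  Contamination defaults to zero
    here: the robustness experiments corrupt the incoming query samples
    at measure time with :func:`contaminate` (ranking-based metric
    learning presumes coherent same-class training data, whereas gross
    outliers typically arrive with the queries).
    """
    strengths = np.concatenate(
        [np.full(n_classes, 0.3), np.full(dim - n_classes, 3.0)]
    )
    return ClusterSpec(
        n_classes=n_classes,
        dim=dim,
        class_separation=6.0,
        within_sd=1.0,
        distortion=np.diag(strengths),
        contamination_rate=contamination_rate,
        contamination_magnitude=contamination_magnitude,
    )
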