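"""Wavelet sub-band features for beat waveforms.

A beat is decomposed by a discrete wavelet transform successively up to
``levels`` levels (default 8), giving one approximation sub-band and
``levels`` detail sub-bands.  Two encodings are offered:

``stats``
    per sub-band the (max, min, mean, variance) of the coefficients,
    concatenated in sub-band order — 4*(levels+1) features, i.e. 36 for an
    8-level decomposition;
``all``
    the raw coefficients of every sub-band concatenated.

Conventions (frozen so feature files are reproducible): population
variance (divide by n); symmetric half-point boundary extension by
default; sub-band order is approximation first, then details from
coarsest to finest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .beats_io import BeatRecord

__all__ = [
    "SUPPORTED_FAMILIES",
    "WaveletConfig",
    "FeatureTable",
    "decompose",
    "encode",
    "featurize_table",
    "subband_lengths",
]

# Family aliases (case-insensitive) -> PyWavelets names.  The
# Fejer-Korovkin family is absent from the installed PyWavelets build, so
# fk22 is recognised but reported as unavailable.
_FAMILY_ALIASES = {
    "bior6.8": "bior6.8",
    "db14": "db14",
    "sym8": "sym8",
    "coif5": "coif5",
    "rbio6.8": "rbio6.8",
    "rbior6.8": "rbio6.8",
}
_UNAVAILABLE = {"fk22": "Fejer-Korovkin 22"}

#: Wavelet families supported by this installation.
SUPPORTED_FAMILIES = ("bior6.8", "db14", "sym8", "coif5", "rbio6.8")


def _resolve_family(name: str) -> str:
    key = name.lower()
    if key in _UNAVAILABLE:
        raise ValueError(
            f"wavelet family {name!r} ({_UNAVAILABLE[key]}) is not available in the "
            f"installed PyWavelets build; supported families: {list(SUPPORTED_FAMILIES)}"
        )
    if key not in _FAMILY_ALIASES:
        raise ValueError(
            f"unknown wavelet family {name!r}; supported families: {list(SUPPORTED_FAMILIES)}"
        )
    return _FAMILY_ALIASES[key]


@dataclass(frozen=True)
class WaveletConfig:
    family: str = "bior6.8"
    levels: int = 8
    encoding: str = "stats"
    extension_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.encoding not in ("stats", "all"):
            raise ValueError(f"encoding must be 'stats' or 'all', got {self.encoding!r}")
        _resolve_family(self.family)


@dataclass
class FeatureTable:
    """Per-beat feature vectors with aligned class labels."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("labels must align with feature-matrix rows")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def save_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            names = self.feature_names or [f"x{j}" for j in range(self.matrix.shape[1])]
            fh.write("label," + ",".join(names) + "\n")
            for label, row in zip(self.labels, self.matrix):
                fh.write(str(label) + "," + ",".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def load_csv(cls, path: str) -> "FeatureTable":
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            names = header[1:]
            labels, rows = [], []
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                fields = line.split(",")
                labels.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        matrix = np.array(rows) if rows else np.zeros((0, len(names)))
        return cls(matrix=matrix, labels=np.array(labels, dtype=object), feature_names=names)


def subband_lengths(signal_length: int, config: WaveletConfig) -> list[int]:
    """Coefficient counts per sub-band (approximation first, then coarse->fine).

    Follows the cascade recurrence ``len_k = floor((len_{k-1} + F - 1)/2)``
    for filter length F under full boundary extension.
    """
    family = _resolve_family(config.family)
    flen = pywt.Wavelet(family).dec_len
    lengths = []
    n = signal_length
    for _ in range(config.levels):
        n = pywt.dwt_coeff_len(n, flen, config.extension_mode)
        lengths.append(n)
    return [lengths[-1]] + lengths[::-1]


def _max_feasible_depth(signal_length: int, family: str, mode: str) -> int:
    flen = pywt.Wavelet(family).dec_len
    depth, n = 0, signal_length
    while n >= 2:
        n_next = pywt.dwt_coeff_len(n, flen, mode)
        if n_next >= n:  # cascade stalled; deeper levels add nothing
            break
        depth += 1
        n = n_next
    return depth


def decompose(signal: np.ndarray, config: WaveletConfig = WaveletConfig()) -> list[np.ndarray]:
    """Multi-level DWT of one beat: ``levels + 1`` coefficient vectors.

    Returned in the declared order: approximation first, then detail
    sub-bands from coarsest to finest.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    family = _resolve_family(config.family)
    feasible = _max_feasible_depth(len(signal), family, config.extension_mode)
    if config.levels > feasible:
        raise ValueError(
            f"signal of length {len(signal)} is too short for a {config.levels}-level "
            f"{config.family} decomposition; max feasible depth is {feasible}"
        )
    with warnings.catch_warnings():
        # Decomposing past pywt's "useful" depth is an intentional,
        # documented convention here; silence its boundary-effect warning.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(signal, family, mode=config.extension_mode, level=config.levels)
    return [np.asarray(c, dtype=float) for c in coeffs]


def encode(sub_bands: list[np.ndarray], encoding: str = "stats") -> np.ndarray:
    """Concatenate sub-bands into one feature vector.

    ``stats`` emits (max, min, mean, population variance) per sub-band;
    ``all`` concatenates the raw coefficients.  Sub-band order is preserved.
    """
    if not sub_bands:
        raise ValueError("need at least one sub-band")
    for i, band in enumerate(sub_bands):
        if len(band) == 0:
            raise ValueError(f"sub-band {i} is empty")
    if encoding == "stats":
        blocks = [
            np.array([band.max(), band.min(), band.mean(), band.var()])
            for band in sub_bands
        ]
        return np.concatenate(blocks)
    if encoding == "all":
        return np.concatenate(sub_bands)
    raise ValueError(f"encoding must be 'stats' or 'all', got {encoding!r}")


def _feature_names(sub_band_count: int, lengths: list[int], encoding: str) -> list[str]:
    bands = ["a"] + [f"d{sub_band_count - 1 - i}" for i in range(sub_band_count - 1)]
    if encoding == "stats":
        return [f"{b}_{s}" for b in bands for s in ("max", "min", "mean", "var")]
    return [f"{b}_c{i}" for b, n in zip(bands, lengths) for i in range(n)]


def featurize_table(
    beats: list[BeatRecord], config: WaveletConfig = WaveletConfig()
) -> FeatureTable:
    """Encode every beat; row i of the table is ``encode(decompose(beat_i))``."""
    if not beats:
        raise ValueError("no beats to featurize")
    lengths = {len(b.samples) for b in beats}
    if len(lengths) != 1:
        raise ValueError(f"all beats must share one length, got lengths {sorted(lengths)}")
    rows, labels = [], []
    for i, beat in enumerate(beats):
        try:
            bands = decompose(beat.samples, config)
            rows.append(encode(bands, config.encoding))
        except ValueError as exc:
            raise ValueError(f"beat {i}: {exc}") from exc
        labels.append(beat.label)
    matrix = np.vstack(rows)
    names = _feature_names(config.levels + 1, [len(b) for b in bands], config.encoding)
    return FeatureTable(matrix=matrix, labels=np.array(labels, dtype=object), feature_names=names)
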