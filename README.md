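# beatset

Set-based discriminative measure for ECG beat classification.

Automatic beat classification is hard because ECG beats show large
intra-class variation (the same beat type drifts across patients and
conditions) and small inter-class differences (different types can look
alike). Instead of the usual *feature + classifier* pipeline, `beatset`
implements a *feature + metric + measure* pipeline for researchers working
on arrhythmia classification and set-based recognition:

1. **Wavelet features** — each 235-sample beat window (90 samples before
   the annotated R peak, the peak, 144 after) is decomposed to 8 levels
   (Bior 6.8 by default) and encoded either as per-sub-band statistics
   (max, min, mean, variance → 36 dimensions) or as all coefficients.
2. **Metric learning to rank (MLR)** — a Mahalanobis metric w ⪰ 0 is
   learned by structural-SVM cutting planes so that sorting corpus beats
   by the score g_w(q,x) = −(q−x)ᵀw(q−x) ranks same-class beats above
   different-class ones, under the truncated reciprocal-rank loss
   Δ = 1 − 1/r (r ≤ k, else 1). The factor l with w = lᵀl projects
   features so Euclidean distance in the projected space equals the
   learned Mahalanobis distance.
3. **Minority-based dissimilarity (MBD)** — a query *set* of beats is
   matched against one corpus set per class with

   D(A,B) = (1/|A_u|) Σ_{a∈A_u} d(a,B) ⊙ (1/|B_v|) Σ_{b∈B_v} d(A,b),

   where A_u, B_v are the α = max(1, ⌊β·min(|A|,|B|)⌋) members of each
   set nearest to the other, d(a,B) = min_b ‖a−b‖, and ⊙ is sum by
   default. MBD generalises the minimum point-wise distance (α = 1, min)
   and mean approach distance (full sets, sum), and is robust to outlier
   samples inside the sets. Classes are ranked by ascending dissimilarity;
   Rank-1 equals accuracy.

Everything runs on synthetic data shipped with the package (Gaussian-hump
beat waveforms and distorted feature clusters); real MIT-BIH-style
recordings are an optional input path via the built-in WFDB reader
(formats 212/16 plus MIT beat annotations).

## Worked example

```python
import numpy as np
import beatset as bs
from beatset.evaluation import ExperimentConfig, evaluate
from dataclasses import replace

# four synthetic beat classes -> 36-dim wavelet statistics features
beats = bs.simulate_beats(bs.default_beat_specs(), [200] * 4, 235, seed=7)
table = bs.featurize_table(beats, bs.WaveletConfig())   # 800 x 36

cfg = ExperimentConfig(n_trials=3, set_size=20, small_class_set_size={}, seed=7)
print(evaluate(table, cfg).rank1)                       # MBD, Euclidean space
print(evaluate(table, replace(cfg, metric="mlr")).rank1)  # MBD, learned metric
```

prints

```
100.0
100.0
```

— on cleanly separable synthetic beats, set-based classification is
perfect with and without the learned metric (Rank-1 is the percentage of
query sets whose true class tops the ranking). The interesting regime is
distorted, contaminated data:

```python
from beatset.evaluation import contaminated_cluster_study
study = contaminated_cluster_study(seed=1, n_trials=3)
for name, rates in study.items():
    print(f"{name:10s} {rates.mean():6.2f}")
```

```
mlr_mbd    100.00
mbd        100.00
mpd        100.00
mad         77.78
apd         36.11
mlr_single  92.22
baseline    79.31
```

Here clusters are anisotropically distorted and 10% of measured samples
are gross outliers: the averaging measures (MAD, APD) collapse, the
minority/minimum measures (MBD, MPD) stay perfect, and the learned metric
lifts single-sample classification from 79% to 92%.

A command-line interface mirrors the library
(`beatset simulate | featurize | train | measure | evaluate`), e.g.

```bash
beatset simulate --n-per-class 200 --seed 7 --out beats.csv
beatset featurize --input beats.csv --wavelet bior6.8 --encoding stats --out features.csv
beatset train --features features.csv --C 1 --out metric.json
beatset evaluate --features features.csv --out results.json
```

To use real recordings, fetch a WFDB record (e.g. from the PhysioNet
MIT-BIH Arrhythmia Database) and point the pipeline at it:
`beatset featurize --input path/to/100 --format wfdb --channel 0 --out features.csv`.

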