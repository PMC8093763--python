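"""Class-imbalance treatments: inverse-frequency weights and GaussNoise.

City sample counts are heavily skewed (tens vs. a hundred samples per
class), which biases fitted classifiers toward the majority cities.  Two
remedies are provided, both applied strictly inside training partitions
(after any bootstrap or train/test split): per-class weights w_c = 1/n_c,
and minority oversampling by Gaussian perturbation of existing samples.
"""

from __future__ import annotations

import numpy as np


def compute_class_weights(labels, normalize: bool = False) -> dict:
    """Inverse-frequency class weights w_c = 1 / n_c.

    Left unnormalised by default (only relative magnitudes matter to
    weight-aware fitters); ``normalize`` rescales to mean 1 for
    scale-sensitive fitters.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("empty label set")
    classes, counts = np.unique(labels, return_counts=True)
    weights = {c: 1.0 / n for c, n in zip(classes, counts)}
    if normalize:
        mean = np.mean(list(weights.values()))
        weights = {c: w / mean for c, w in weights.items()}
    return weights


def sample_weights(labels, class_weights: dict | None = None) -> np.ndarray:
    """Per-sample weight vector w_{y_i} from class weights."""
    labels = np.asarray(labels, dtype=object)
    if class_weights is None:
        class_weights = compute_class_weights(labels)
    return np.array([class_weights[y] for y in labels], dtype=float)


def gauss_noise_oversample(X, y, sigma_scale: float = 0.05, seed: int = 0):
    """Bring every minority class up to the majority count with noisy copies.

    Synthetic rows are drawn by picking existing class members uniformly at
    random and adding independent Gaussian noise per feature with standard
    deviation ``sigma_scale`` times the within-class per-feature sd.
    Negative synthetic values are clipped to 0 (abundances are nonnegative).
    Original rows are preserved unchanged and come first in the output.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for c, n_c in zip(classes, counts):
        deficit = int(target - n_c)
        if deficit == 0:
            continue
        if n_c < 2:
            raise ValueError(
                f"class {c!r} has {n_c} sample(s); need >= 2 to oversample"
            )
        members = X[y == c]
        sd = members.std(axis=0, ddof=1)
        picks = rng.integers(0, n_c, size=deficit)
        noise = rng.standard_normal((deficit, X.shape[1])) * (sigma_scale * sd)
        synth = np.clip(members[picks] + noise, 0.0, None)
        new_X.append(synth)
        new_y.append(np.full(deficit, c, dtype=object))
    return np.vstack(new_X), np.concatenate(new_y)
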