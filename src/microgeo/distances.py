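"""Distance-based city prediction.

Two simple alternatives to the ensemble: (a) a Kullback-Leibler projection
predictor that assigns a query sample to the city of the training sample
minimising KL divergence from the query's relative-abundance composition;
and (b) a naive average-distance predictor that, given any sample x sample
distance matrix (e.g. a k-mer ecological distance produced externally),
assigns each query to the city with the smallest mean distance, with
leave-one-out exclusion for labelled queries.  The qualitative Kulczynski
and Bray-Curtis ecological distances are provided for building such
matrices from abundance tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import LabeledAbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample x sample distances, zero diagonal."""

    ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match ids")
        if len(set(self.ids)) != n:
            raise ValueError("sample ids must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], df.values)


def kl_divergence(p, q, pseudocount: float = 1e-6) -> float:
    """KL divergence (nats) between two compositions after smoothing.

    Both vectors are smoothed by adding ``pseudocount`` to every component
    and renormalising, which keeps the divergence finite when q has zeros
    where p does not.  Always >= 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    p = p + pseudocount
    q = q + pseudocount
    p = p / p.sum()
    q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kl_predict(
    query,
    training: LabeledAbundanceTable,
    top_m: int = 3,
    pseudocount: float = 1e-6,
    aggregate: str = "nearest",
) -> list:
    """Rank cities by KL proximity of a query composition to the training set.

    KL divergence is computed from the query to every training sample;
    cities are ranked by the minimum divergence any of their samples attains
    (``aggregate="nearest"``) or by the mean over their samples
    (``aggregate="mean"``).  Returns the ``top_m`` distinct cities, best
    first.
    """
    if training.n_samples == 0:
        raise ValueError("empty training table")
    if training.labels is None:
        raise ValueError("training table must carry city labels")
    if training.mode != "relative":
        raise ValueError("KL prediction expects a relative-mode training table")
    query = np.asarray(query, dtype=float)
    divs = np.array(
        [kl_divergence(query, row, pseudocount) for row in training.values]
    )
    labels = training.label_array()
    cities = sorted(set(labels))
    if aggregate == "nearest":
        score = {c: divs[labels == c].min() for c in cities}
    elif aggregate == "mean":
        score = {c: divs[labels == c].mean() for c in cities}
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    ranked = sorted(cities, key=lambda c: (score[c], c))
    return ranked[:top_m]


def ecological_distance(x, y, method: str = "kulczynski_qualitative",
                        presence_epsilon: float = 0.0) -> float:
    """Pairwise ecological dissimilarity in [0, 1].

    ``kulczynski_qualitative`` works on presence/absence: with a shared
    present taxa, b present only in x and c only in y, the distance is
    1 - (a/(a+b) + a/(a+c)) / 2.  ``bray_curtis`` is the abundance-based
    sum|x-y| / sum(x+y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("vectors must be nonnegative")
    if method == "kulczynski_qualitative":
        px = x > presence_epsilon
        py = y > presence_epsilon
        a = int(np.sum(px & py))
        b = int(np.sum(px & ~py))
        c = int(np.sum(~px & py))
        if a + b == 0 or a + c == 0:
            raise ValueError("qualitative Kulczynski undefined for an empty sample")
        return 1.0 - 0.5 * (a / (a + b) + a / (a + c))
    if method == "bray_curtis":
        denom = np.sum(x + y)
        if denom == 0:
            raise ValueError("Bray-Curtis undefined for two empty samples")
        return float(np.sum(np.abs(x - y)) / denom)
    raise ValueError(f"unknown distance method {method!r}")


def pairwise_distances(table: LabeledAbundanceTable, method: str = "kulczynski_qualitative",
                       presence_epsilon: float = 0.0) -> DistanceMatrix:
    """All-pairs ecological distances over a table's samples."""
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = ecological_distance(
                table.values[i], table.values[j], method, presence_epsilon
            )
    return DistanceMatrix(list(table.sample_ids), d)


def average_distance_predict(dm: DistanceMatrix, labels: dict, query_ids,
                             loocv: bool = False) -> dict:
    """Predict each query's city as the one with smallest mean distance.

    ``labels`` maps reference sample ids to cities.  Under ``loocv`` a
    labelled query is excluded from its own city's reference set, so its
    zero self-distance never contributes.  Ties are broken lexicographically
    with a warning; a city left with no reference samples is skipped.
    """
    index = {s: i for i, s in enumerate(dm.ids)}
    for q in query_ids:
        if q not in index:
            raise ValueError(f"query {q!r} absent from the distance matrix")
    cities = sorted(set(labels.values()))
    predictions = {}
    for q in query_ids:
        qi = index[q]
        means = {}
        for c in cities:
            ref = [index[s] for s, lab in labels.items()
                   if lab == c and not (loocv and s == q)]
            if not ref:
                logger.warning("city %s has no reference samples for query %s", c, q)
                continue
            means[c] = float(np.mean(dm.values[qi, ref]))
        if not means:
            raise ValueError(f"no reference city available for query {q!r}")
        best = min(means.values())
        tied = sorted(c for c, v in means.items() if v <= best + 1e-12)
        if len(tied) > 1:
            logger.warning("query %s: tie among %s, keeping %s", q, tied, tied[0])
        predictions[q] = tied[0]
    return predictions


def loocv_accuracy(dm: DistanceMatrix, labels: dict) -> float:
    """Leave-one-out accuracy of the average-distance predictor."""
    preds = average_distance_predict(dm, labels, list(labels), loocv=True)
    hits = sum(preds[s] == labels[s] for s in labels)
    return hits / len(labels)
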