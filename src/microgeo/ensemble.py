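"""Adaptive ensemble classifier built by stratified bagging and rank
aggregation.

The construction: draw N bootstrap replicates of the training set (each
covering every class), fit all M candidate classifiers on each replicate,
score them on the replicate's out-of-bag (OOB) samples with K performance
measures (kappa, G-mean, MAUC), rank-aggregate the K orderings to crown a
per-bootstrap winner, and keep the N fitted winners.  Prediction is majority
voting over the N winners.  The ensemble thereby adapts to the data: it
tracks the best candidate without knowing it in advance.

The candidate roster mirrors the classifiers commonly used for microbiome
source classification: random forest, RBF-kernel SVM, a single decision
tree (recursive partitioning), gradient-boosted trees, a multilayer
perceptron, and composites that project onto principal components or
supervised partial-least-squares components before a tree learner.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .abundance import LabeledAbundanceTable
from .errors import ConfigurationError, UndefinedMetricError
from .imbalance import compute_class_weights, gauss_noise_oversample, sample_weights
from .metrics import (ConfusionMatrix, MetricReport, ScoreMatrix, accuracy,
                      cohens_kappa, evaluate, gmean, mauc,
                      precision_recall_by_class)
from .rank_aggregation import RankedList, aggregate

logger = logging.getLogger(__name__)

MEASURES = ("kappa", "gmean", "mauc")
IMBALANCE_MODES = ("standard", "weighted", "oversample")


# ---------------------------------------------------------------------------
# candidates


@dataclass
class CandidateSpec:
    """One candidate: an estimator factory plus an optional projection step.

    ``reducer`` is ``None``, ``"pca"`` or ``"pls"``; a PLS projection is
    supervised (fitted against one-hot labels) and both are fitted strictly
    on the training partition before the base learner sees the data.
    """

    id: str
    make_estimator: callable
    reducer: str | None = None
    n_components: int = 10
    supports_sample_weight: bool = True


class _Projection:
    """PCA or one-hot-target PLS projection with component capping."""

    def __init__(self, kind: str, n_components: int, seed: int):
        self.kind = kind
        self.n_components = n_components
        self.seed = seed
        self._model = None

    def fit(self, X, y):
        cap = min(self.n_components, X.shape[0] - 1, X.shape[1])
        cap = max(cap, 1)
        if self.kind == "pca":
            self._model = PCA(n_components=cap, random_state=self.seed).fit(X)
        elif self.kind == "pls":
            classes = np.unique(y)
            onehot = (y[:, None] == classes[None, :]).astype(float)
            self._model = PLSRegression(n_components=cap, scale=False).fit(X, onehot)
        else:
            raise ConfigurationError(f"unknown reducer {self.kind!r}")
        return self

    def transform(self, X):
        if self.kind == "pls":
            return self._model.transform(X)
        return self._model.transform(X)


class FittedCandidate:
    """A trained candidate: label encoding, optional projection, estimator."""

    def __init__(self, spec: CandidateSpec, seed: int):
        self.spec = spec
        self.seed = seed
        self.encoder = LabelEncoder()
        self.projection = None
        self.estimator = None

    @property
    def id(self) -> str:
        return self.spec.id

    @property
    def classes(self) -> np.ndarray:
        return self.encoder.classes_

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        y_enc = self.encoder.fit_transform(y)
        if len(self.encoder.classes_) < 2:
            raise ValueError("cannot fit a classifier on a single class")
        if self.spec.reducer is not None:
            self.projection = _Projection(
                self.spec.reducer, self.spec.n_components, self.seed
            ).fit(X, y)
            X = self.projection.transform(X)
        self.estimator = self.spec.make_estimator(self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            if sample_weight is not None and self.spec.supports_sample_weight:
                self.estimator.fit(X, y_enc, sample_weight=sample_weight)
            else:
                if sample_weight is not None:
                    logger.debug("%s ignores sample weights (unsupported)", self.id)
                self.estimator.fit(X, y_enc)
        return self

    def _features(self, X):
        X = np.asarray(X, dtype=float)
        if self.projection is not None:
            X = self.projection.transform(X)
        return X

    def predict(self, X) -> np.ndarray:
        enc = self.estimator.predict(self._features(X))
        return self.encoder.inverse_transform(enc.astype(int))

    def scores(self, X) -> np.ndarray:
        """Per-class membership scores aligned to ``self.classes``.

        Probabilities where available; otherwise decision-function margins
        (valid for MAUC, which only uses the within-column ordering).
        """
        Xf = self._features(X)
        if hasattr(self.estimator, "predict_proba"):
            return np.asarray(self.estimator.predict_proba(Xf), dtype=float)
        d = np.asarray(self.estimator.decision_function(Xf), dtype=float)
        if d.ndim == 1:  # binary margin -> two columns
            d = np.column_stack([-d, d])
        return d


def _rf(seed):
    return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)


def _svm(seed):
    return SVC(kernel="rbf", random_state=seed)


def _rpart(seed):
    return DecisionTreeClassifier(random_state=seed)


def _xgb(seed):
    return XGBClassifier(
        n_estimators=100, max_depth=6, learning_rate=0.3, verbosity=0,
        random_state=seed, n_jobs=1, tree_method="hist",
    )


def _mlp(seed):
    return MLPClassifier(hidden_layer_sizes=(64,), max_iter=300, random_state=seed)


def standard_roster() -> list:
    """The five base candidates (no projection composites)."""
    return [
        CandidateSpec("rf", _rf),
        CandidateSpec("svm", _svm),
        CandidateSpec("rpart", _rpart),
        CandidateSpec("xgb", _xgb),
        CandidateSpec("mlp", _mlp, supports_sample_weight=False),
    ]


def full_roster(n_components: int = 10) -> list:
    """All nine candidates including the PCA/PLS composites."""
    return standard_roster() + [
        CandidateSpec("pca+rf", _rf, reducer="pca", n_components=n_components),
        CandidateSpec("pls+rf", _rf, reducer="pls", n_components=n_components),
        CandidateSpec("pls+rpart", _rpart, reducer="pls", n_components=n_components),
        CandidateSpec("pls+xgb", _xgb, reducer="pls", n_components=n_components),
    ]


# ---------------------------------------------------------------------------
# ensemble


@dataclass
class EnsembleConfig:
    roster: list = field(default_factory=standard_roster)
    n_bootstraps: int = 50
    measures: tuple = MEASURES
    imbalance_mode: str = "standard"
    oversample_sigma: float = 0.05
    seed: int = 0
    max_bootstrap_retries: int = 100

    def __post_init__(self):
        if self.n_bootstraps < 1 or not self.roster:
            raise ConfigurationError("need N >= 1 bootstraps and M >= 1 candidates")
        if not self.measures:
            raise ConfigurationError("need at least one measure")
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ConfigurationError(f"unknown measures {sorted(unknown)}")
        if self.imbalance_mode not in IMBALANCE_MODES:
            raise ConfigurationError(f"unknown imbalance mode {self.imbalance_mode!r}")
        ids = [c.id for c in self.roster]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("candidate ids must be unique")


@dataclass
class EnsembleModel:
    """N fitted per-bootstrap winners plus the bookkeeping around them."""

    winners: list                 # list of FittedCandidate
    winner_ids: list              # candidate id per bootstrap
    winner_counts: dict           # candidate id -> times chosen
    oob_reports: list             # per bootstrap: {candidate id: MetricReport}
    classes: list                 # training class labels, sorted
    class_counts: dict            # training class -> sample count
    feature_names: list | None
    lineages: list | None = None
    config: EnsembleConfig | None = None

    @property
    def n_bootstraps(self) -> int:
        return len(self.winners)


def stratified_bootstrap(labels, seed: int, max_retries: int = 100):
    """One bootstrap draw of size n in which every class is represented.

    Simple random sampling with replacement, redrawn (with an advanced
    seed) until the in-bag set covers all classes and the out-of-bag
    complement contains at least two classes.  Returns
    ``(in_bag_indices, oob_indices)``.
    """
    labels = np.asarray(labels, dtype=object)
    n = labels.shape[0]
    classes = set(labels)
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        in_bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        if set(labels[in_bag]) == classes and len(set(labels[oob])) >= 2:
            return in_bag, oob
    raise ValueError(
        f"no valid bootstrap found in {max_retries} attempts (data too small?)"
    )


def _resolve_features(table, feature_columns=None):
    if isinstance(table, LabeledAbundanceTable):
        if table.labels is None or any(l is None for l in table.labels):
            raise ValueError("ensemble fitting needs a fully labelled table")
        return (np.asarray(table.values, dtype=float), table.label_array(),
                list(table.taxon_ids), list(table.lineages))
    raise TypeError("expected a LabeledAbundanceTable")


def _score_candidate(fc: FittedCandidate, X_oob, y_oob, measures) -> MetricReport:
    y_pred = fc.predict(X_oob)
    cm = ConfusionMatrix.from_labels(y_oob, y_pred, classes=list(fc.classes))
    prec, rec = precision_recall_by_class(cm)
    sm = ScoreMatrix(list(fc.classes), fc.scores(X_oob), y_oob)
    return MetricReport(
        kappa=cohens_kappa(cm),
        gmean=gmean(cm),
        mauc=mauc(sm),
        accuracy=accuracy(cm),
        per_class_precision=prec,
        per_class_recall=rec,
    )


def _apply_imbalance(X, y, mode: str, sigma: float, seed: int):
    """Training-partition-only imbalance treatment; returns (X, y, weights)."""
    if mode == "standard":
        return X, y, None
    if mode == "weighted":
        return X, y, sample_weights(y)
    X2, y2 = gauss_noise_oversample(X, y, sigma_scale=sigma, seed=seed)
    return X2, y2, None


def fit_ensemble(table, config: EnsembleConfig) -> EnsembleModel:
    """Build the adaptive ensemble from a labelled abundance table.

    For each of the N bootstraps: apply the imbalance treatment to the
    in-bag set only, fit all M candidates, score them on the OOB samples
    with the K measures, rank-aggregate, and keep the winning fitted model
    (no refit).  A candidate whose fit fails on one bootstrap is excluded
    from that bootstrap's lists only.
    """
    X, y, feature_names, lineages = _resolve_features(table)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least two classes to fit the ensemble")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    rng = np.random.default_rng(config.seed)
    boot_seeds = rng.integers(0, 2**31 - 1, size=config.n_bootstraps)
    cand_seeds = rng.integers(0, 2**31 - 1, size=(config.n_bootstraps, len(config.roster)))

    winners, winner_ids, oob_reports = [], [], []
    for j in range(config.n_bootstraps):
        in_bag, oob = stratified_bootstrap(
            y, int(boot_seeds[j]), config.max_bootstrap_retries
        )
        X_in, y_in, sw = _apply_imbalance(
            X[in_bag], y[in_bag], config.imbalance_mode,
            config.oversample_sigma, int(boot_seeds[j]),
        )
        X_oob, y_oob = X[oob], y[oob]

        fitted, reports = {}, {}
        for m, spec in enumerate(config.roster):
            try:
                fc = FittedCandidate(spec, int(cand_seeds[j, m])).fit(X_in, y_in, sw)
                reports[spec.id] = _score_candidate(fc, X_oob, y_oob, config.measures)
                fitted[spec.id] = fc
            except (UndefinedMetricError, ValueError, np.linalg.LinAlgError) as exc:
                logger.error("bootstrap %d: candidate %s dropped: %s", j, spec.id, exc)
        if not fitted:
            raise RuntimeError(f"all candidates failed on bootstrap {j}")

        lists = [
            RankedList.from_scores(
                meas, {cid: getattr(reports[cid], meas) for cid in fitted}
            )
            for meas in config.measures
        ]
        consensus = aggregate(lists)
        winner = consensus[0]
        logger.info("bootstrap %d: winner %s (consensus %s)", j, winner, consensus)
        winners.append(fitted[winner])
        winner_ids.append(winner)
        oob_reports.append(reports)

    return EnsembleModel(
        winners=winners,
        winner_ids=winner_ids,
        winner_counts=dict(Counter(winner_ids)),
        oob_reports=oob_reports,
        classes=classes,
        class_counts={c: int(np.sum(y == c)) for c in classes},
        feature_names=feature_names,
        lineages=lineages,
        config=config,
    )


def _check_features(model: EnsembleModel, features):
    if isinstance(features, LabeledAbundanceTable):
        if model.feature_names is not None and list(features.taxon_ids) != list(model.feature_names):
            raise ValueError("feature columns do not match the training table")
        return np.asarray(features.values, dtype=float)
    X = np.asarray(features, dtype=float)
    if model.feature_names is not None and X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}"
        )
    return X


def vote_fractions(model: EnsembleModel, features) -> pd.DataFrame:
    """Fraction of the N winners voting for each class, per sample."""
    X = _check_features(model, features)
    votes = np.stack([w.predict(X) for w in model.winners])  # (N, n)
    frac = np.zeros((X.shape[0], len(model.classes)))
    for k, c in enumerate(model.classes):
        frac[:, k] = (votes == c).mean(axis=0)
    return pd.DataFrame(frac, columns=model.classes)


def predict_majority(model: EnsembleModel, features) -> np.ndarray:
    """Majority vote over the N winners.

    Ties are broken by the higher total training frequency of the tied
    classes, then lexicographically.
    """
    frac = vote_fractions(model, features).values
    out = []
    for row in frac:
        best = row.max()
        tied = [c for k, c in enumerate(model.classes) if row[k] >= best - 1e-12]
        tied.sort(key=lambda c: (-model.class_counts.get(c, 0), str(c)))
        out.append(tied[0])
    return np.asarray(out, dtype=object)


def evaluate_ensemble(model: EnsembleModel, features, y_true) -> MetricReport:
    """Score the ensemble on a labelled evaluation set.

    Vote fractions serve as the class scores for MAUC (their ordering is
    all the Hand-Till statistic uses).
    """
    X = _check_features(model, features)
    y_true = np.asarray(y_true, dtype=object)
    y_pred = predict_majority(model, X)
    sm = ScoreMatrix(list(model.classes), vote_fractions(model, X).values, y_true)
    return evaluate(y_true, y_pred, scores=sm,
                    classes=sorted(set(model.classes) | set(y_true)))


def rf_feature_importance(model: EnsembleModel, top_k: int = 20) -> pd.DataFrame:
    """Impurity importances averaged over plain random-forest winners.

    Composite winners (PCA/PLS projections) are excluded — their
    importances live in projected space and do not map back to taxa.
    Returns the ``top_k`` taxa, importance-descending; empty (with a
    warning) when no forest won any bootstrap.
    """
    vectors = []
    for fc in model.winners:
        if fc.projection is None and isinstance(fc.estimator, RandomForestClassifier):
            vectors.append(fc.estimator.feature_importances_)
    if not vectors:
        logger.warning("no plain random-forest winners in the ensemble")
        return pd.DataFrame(columns=["taxon_id", "lineage", "importance"])
    mean_imp = np.mean(vectors, axis=0)
    order = np.argsort(mean_imp)[::-1][:top_k]
    names = model.feature_names or [f"f{i}" for i in range(len(mean_imp))]
    lineages = model.lineages or names
    return pd.DataFrame(
        {
            "taxon_id": [names[i] for i in order],
            "lineage": [lineages[i] for i in order],
            "importance": mean_imp[order],
        }
    )


# ---------------------------------------------------------------------------
# repeated train/test study


def stratified_holdout(labels, train_frac: float, min_per_class: int, seed: int):
    """Stratified train/test split with a per-class floor on both sides."""
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in sorted(set(labels)):
        idx = np.flatnonzero(labels == c)
        n_c = len(idx)
        if n_c < 2 * min_per_class:
            raise ValueError(
                f"class {c!r} has {n_c} samples; needs >= {2 * min_per_class} "
                f"for {min_per_class} per side"
            )
        n_test = int(round((1.0 - train_frac) * n_c))
        n_test = min(max(n_test, min_per_class), n_c - min_per_class)
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class StudyReport:
    """Mean held-out measures per classifier and mode, plus vote bookkeeping."""

    summary: pd.DataFrame          # (mode, classifier) x mean measures
    winner_counts: dict            # mode -> {candidate id: count over all repeats}
    per_city_precision: pd.DataFrame  # rows: (mode, repeat), cols: cities
    records: list                  # raw per-repeat MetricReports


def run_repeated_study(
    table,
    config: EnsembleConfig,
    n_repeats: int = 10,
    train_frac: float = 0.8,
    min_per_city: int = 3,
    seed: int = 0,
    modes=None,
) -> StudyReport:
    """Repeated stratified train/test evaluation of ensemble and candidates.

    For each repeat: split 80/20 (stratified, with at least ``min_per_city``
    samples of every city on each side), fit the ensemble and every
    stand-alone candidate on the training side, and score everything on the
    test side.  Stand-alone candidates receive the same imbalance treatment
    on the full training partition.  Reports mean kappa/G-mean/MAUC/accuracy
    per classifier per mode, the ensemble's per-city precision, and winner
    counts out of ``n_repeats * N``.
    """
    X, y, feature_names, lineages = _resolve_features(table)
    if modes is None:
        modes = (config.imbalance_mode,)
    rng = np.random.default_rng(seed)
    split_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    fit_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)

    rows, counts, prec_rows, records = [], {m: Counter() for m in modes}, [], []
    for mode in modes:
        for rep in range(n_repeats):
            tr, te = stratified_holdout(y, train_frac, min_per_city, int(split_seeds[rep]))
            sub = LabeledAbundanceTable(
                sample_ids=[f"s{i}" for i in tr],
                taxon_ids=feature_names,
                lineages=lineages,
                values=X[tr],
                mode=table.mode,
                labels=list(y[tr]),
            )
            cfg = EnsembleConfig(
                roster=config.roster,
                n_bootstraps=config.n_bootstraps,
                measures=config.measures,
                imbalance_mode=mode,
                oversample_sigma=config.oversample_sigma,
                seed=int(fit_seeds[rep]),
                max_bootstrap_retries=config.max_bootstrap_retries,
            )
            model = fit_ensemble(sub, cfg)
            counts[mode].update(model.winner_counts)

            rep_reports = {"ensemble": evaluate_ensemble(model, X[te], y[te])}
            prec_rows.append(
                {"mode": mode, "repeat": rep,
                 **{c: v for c, v in rep_reports["ensemble"].per_class_precision.items()}}
            )
            X_tr, y_tr, sw = _apply_imbalance(
                X[tr], y[tr], mode, config.oversample_sigma, int(fit_seeds[rep])
            )
            for m, spec in enumerate(config.roster):
                try:
                    fc = FittedCandidate(spec, int(fit_seeds[rep]) + m).fit(X_tr, y_tr, sw)
                    rep_reports[spec.id] = _score_candidate(fc, X[te], y[te], config.measures)
                except (UndefinedMetricError, ValueError) as exc:
                    logger.error("repeat %d: stand-alone %s failed: %s", rep, spec.id, exc)
            for cid, report in rep_reports.items():
                rows.append(
                    {"mode": mode, "classifier": cid, "repeat": rep,
                     "kappa": report.kappa, "gmean": report.gmean,
                     "mauc": report.mauc, "accuracy": report.accuracy}
                )
            records.append({"mode": mode, "repeat": rep, "reports": rep_reports})

    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["mode", "classifier"])[["kappa", "gmean", "mauc", "accuracy"]]
        .mean()
        .reset_index()
    )
    return StudyReport(
        summary=summary,
        winner_counts={m: dict(c) for m, c in counts.items()},
        per_city_precision=pd.DataFrame(prec_rows),
        records=records,
    )
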