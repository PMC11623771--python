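"""Two-layer stacked ensemble decoder of memory categories from spikes.

The model is ``y = g(f_r^(m)(x))``: a bank of L1-regularized logistic
base learners, one per (temporal resolution m, bagging replica r),
each fit on B-spline features of the spike pattern, fused by an
L1-regularized logistic meta-learner over the base learners' predicted
probabilities.  The L1 penalty sparsifies both layers — the base layer
selects (neuron, time) support, the meta layer selects temporal
resolutions — which is what makes decoding feasible from ~150 trials of
high-dimensional spike patterns and makes the fitted model directly
interpretable.

Everything is trained under nested cross-validation: outer folds hold
out test trials, inner folds of each outer-training set choose the L1
penalties and supply the out-of-fold base predictions on which the
meta-learner is trained, so no trial ever influences a model that
scores it.  Five independent one-vs-rest binary models share the same
fold scheme and feature ladder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .exceptions import DegenerateFoldError, DimensionError
from .features import BSplineBasis, FeatureMatrix, featurize, resolution_ladder
from .metrics import ConfusionMatrix, cross_entropy, mcc

__all__ = [
    "DecoderConfig",
    "BaseLearner",
    "MetaLearner",
    "TrainedStack",
    "CVScheme",
    "EnsembleDecoder",
    "EvaluationResult",
    "fit_base_learner",
    "fit_bagged_bank",
    "base_predict",
    "fit_meta_learner",
    "fit_ensemble",
    "evaluate_nested",
    "predict_stack",
]

_MAX_BAG_RETRIES = 20


@dataclass(frozen=True)
class DecoderConfig:
    """Hyperparameters of the ensemble and its nested-CV scheme.

    ``knot_ladder`` lists the interior-knot counts m of the B-spline
    bases; each contributes ``n_replicas`` bagged base learners at
    temporal resolution M/(m+1).  ``lambda_*`` define the log-spaced L1
    penalty grid (penalty per trial on standardized features) searched
    on inner folds; ties in validation loss resolve toward the larger
    penalty (sparser model).
    """

    knot_ladder: tuple[int, ...] = (1, 3, 7, 15, 31, 63)
    order: int = 4
    n_replicas: int = 10
    n_lambda: int = 30
    lambda_min: float = 1e-4
    lambda_max: float = 1.0
    outer_folds: int = 5
    inner_folds: int = 4
    bag_mode: str = "bootstrap"  # or "partition"
    lambda_rule: str = "1se"  # or "min"
    tol: float = 1e-8
    max_iter: int = 5000
    threshold: float = 0.5
    fit_full_model: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.knot_ladder)) != len(self.knot_ladder):
            raise ValueError("knot_ladder contains duplicates")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.bag_mode not in ("bootstrap", "partition"):
            raise ValueError("bag_mode must be 'bootstrap' or 'partition'")
        if self.lambda_rule not in ("1se", "min"):
            raise ValueError("lambda_rule must be '1se' or 'min'")

    @property
    def lambda_grid(self) -> np.ndarray:
        """Penalty grid in descending order (sparsest model first)."""
        return np.logspace(np.log10(self.lambda_max), np.log10(self.lambda_min), self.n_lambda)

    @property
    def n_base_learners(self) -> int:
        return len(self.knot_ladder) * self.n_replicas


@dataclass
class BaseLearner:
    """One L1-logistic classifier at a single temporal resolution.

    Coefficients are stored on the raw feature scale (training-fold
    standardization folded back in), so prediction is a plain dot
    product and the coefficients compose directly into the
    classification functional matrix.
    """

    m: int
    replica: int
    coef: np.ndarray
    intercept: float
    lam: float
    training_trial_ids: np.ndarray


@dataclass
class MetaLearner:
    """L1-logistic fusion of base-learner probabilities."""

    weights: np.ndarray
    intercept: float
    lam: float
    learner_keys: tuple[tuple[int, int], ...]  # (m, replica) per column

    @property
    def n_base_learners(self) -> int:
        return len(self.weights)


@dataclass
class TrainedStack:
    """A fitted base bank + meta-learner with its training trial set."""

    base_learners: list[BaseLearner]
    meta: MetaLearner
    lam_by_m: dict[int, float]
    train_idx: np.ndarray
    test_idx: np.ndarray  # empty for a model trained on all trials


@dataclass(frozen=True)
class CVScheme:
    """Stratified nested cross-validation fold generator."""

    outer_folds: int = 5
    inner_folds: int = 4
    seed: int = 0

    def outer_splits(self, strat_labels) -> list[tuple[np.ndarray, np.ndarray]]:
        skf = StratifiedKFold(self.outer_folds, shuffle=True, random_state=self.seed)
        return [(tr, te) for tr, te in skf.split(np.zeros(len(strat_labels)), strat_labels)]

    def inner_splits(self, strat_labels, train_idx, fold: int) -> list[tuple[np.ndarray, np.ndarray]]:
        """Splits of one outer-training set, as positions within train_idx."""
        skf = StratifiedKFold(
            self.inner_folds, shuffle=True, random_state=self.seed + 1000 * (fold + 1)
        )
        sub = np.asarray(strat_labels)[train_idx]
        return [(tr, va) for tr, va in skf.split(np.zeros(len(sub)), sub)]


@dataclass
class CategoryModel:
    category_id: int
    folds: list[TrainedStack]
    full_model: TrainedStack | None


@dataclass
class EnsembleDecoder:
    """Per-category stacked models sharing one feature ladder and fold scheme."""

    config: DecoderConfig
    bases: list[BSplineBasis]
    category_models: list[CategoryModel | None]
    outer_splits: list[tuple[np.ndarray, np.ndarray]]
    category_names: tuple[str, ...]
    n_neurons: int

    @property
    def knot_ladder(self) -> tuple[int, ...]:
        return tuple(b.m for b in self.bases)

    def featurize_tensor(self, tensor) -> dict[int, np.ndarray]:
        return {b.m: featurize(tensor, b).X for b in self.bases}


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _profile_intercept(score: np.ndarray, y: np.ndarray, b0: float = 0.0) -> float:
    """Exact 1-D Newton fit of the unpenalized intercept given fixed weights."""
    b = float(b0)
    for _ in range(100):
        p = _sigmoid(score + b)
        g = float(np.sum(p - y))
        h = float(np.sum(p * (1.0 - p)))
        if h < 1e-12:
            break
        step = g / h
        b -= np.clip(step, -10.0, 10.0)
        if abs(step) < 1e-12:
            break
    return float(np.clip(b, -36.0, 36.0))


def _fit_l1_weights(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float,
    max_iter: int,
    standardize: bool = True,
) -> tuple[np.ndarray, float]:
    """L1-logistic fit; returns raw-scale (coefficients, intercept).

    The penalty ``lam`` multiplies the mean negative log-likelihood
    (sklearn's C = 1 / (lam * n)).  Features are z-scored with the
    statistics of the rows being fit, and the coefficients mapped back
    to the raw scale afterwards; the intercept is then re-optimized
    exactly (it is not part of the penalty).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / sd
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
        Xs = X
    clf = LogisticRegression(
        solver="liblinear",
        l1_ratio=1.0,
        C=1.0 / (lam * n),
        tol=tol,
        max_iter=max_iter,
        intercept_scaling=50.0,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        clf.fit(Xs, y)
    w = clf.coef_[0] / sd
    b = float(clf.intercept_[0]) - float((mu / sd) @ clf.coef_[0])
    b = _profile_intercept(X @ w, y, b)
    return w, b


def base_predict(learner: BaseLearner, X) -> np.ndarray:
    """Predicted probability per trial: sigmoid of the learner's linear score."""
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.shape[1] != learner.coef.shape[0]:
        raise DimensionError(
            f"feature layout mismatch: {X.shape[1]} columns vs {learner.coef.shape[0]} coefficients"
        )
    return _sigmoid(X @ learner.coef + learner.intercept)


def fit_base_learner(
    X,
    y,
    lam: float,
    bag=None,
    m: int = 0,
    replica: int = 0,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> BaseLearner:
    """Fit one L1-logistic base learner on a bag of trials."""
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    bag = np.arange(len(y)) if bag is None else np.asarray(bag)
    yb = y[bag]
    if len(np.unique(yb)) < 2:
        raise DegenerateFoldError("bag contains a single class")
    w, b = _fit_l1_weights(X[bag], yb, lam, tol, max_iter)
    return BaseLearner(m=m, replica=replica, coef=w, intercept=b, lam=lam,
                       training_trial_ids=bag.copy())


def _draw_bags(n: int, y: np.ndarray, n_replicas: int, mode: str, rng) -> list[np.ndarray]:
    bags = []
    if mode == "partition":
        perm = rng.permutation(n)
        chunks = np.array_split(perm, n_replicas)
        for chunk in chunks:
            if len(np.unique(y[chunk])) < 2:
                raise DegenerateFoldError("partition replica contains a single class")
            bags.append(np.sort(chunk))
        return bags
    for _ in range(n_replicas):
        for _attempt in range(_MAX_BAG_RETRIES):
            bag = rng.integers(0, n, size=n)
            if len(np.unique(y[bag])) == 2:
                bags.append(bag)
                break
        else:
            raise DegenerateFoldError("could not draw a two-class bootstrap bag")
    return bags


def _select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    splits,
    tol: float,
    max_iter: int,
    standardize: bool = True,
    rule: str = "1se",
) -> float:
    """Pick the L1 penalty by inner-fold cross-entropy.

    ``lambdas`` must be descending; ties resolve to the larger penalty.
    Fits warm-start along the path within each fold.  With
    ``rule='1se'`` the largest penalty whose mean validation loss is
    within one standard error of the minimum is returned (the sparsest
    model statistically indistinguishable from the best); ``rule='min'``
    returns the loss minimizer.
    """
    ce = np.zeros((len(splits), len(lambdas)))
    for k, (tr, va) in enumerate(splits):
        Xtr, ytr = X[tr], y[tr]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mu, sd = 0.0, 1.0
        Xs = (Xtr - mu) / sd
        Xv = (X[va] - mu) / sd
        clf = LogisticRegression(
            solver="liblinear",
            l1_ratio=1.0,
            C=1.0 / (lambdas[0] * len(ytr)),
            tol=tol,
            max_iter=max_iter,
            intercept_scaling=50.0,
            warm_start=True,
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=UserWarning)
            for i, lam in enumerate(lambdas):
                clf.C = 1.0 / (lam * len(ytr))
                clf.fit(Xs, ytr)
                b = _profile_intercept(Xs @ clf.coef_[0], ytr, float(clf.intercept_[0]))
                p = _sigmoid(Xv @ clf.coef_[0] + b)
                ce[k, i] = cross_entropy(p, y[va])
    mean_ce = ce.mean(axis=0)
    best = int(np.argmin(mean_ce))  # first occurrence = largest lambda
    if rule == "min":
        return float(lambdas[best])
    se = ce[:, best].std(ddof=1) / np.sqrt(ce.shape[0]) if ce.shape[0] > 1 else 0.0
    within = np.flatnonzero(mean_ce <= mean_ce[best] + se)
    return float(lambdas[int(within[0])])


def fit_bagged_bank(
    features: dict[int, np.ndarray],
    y,
    config: DecoderConfig,
    rng,
    lam_by_m: dict[int, float] | None = None,
    inner_splits=None,
) -> tuple[list[BaseLearner], dict[int, float]]:
    """Fit the full bank: n_replicas bagged learners per temporal resolution.

    When ``lam_by_m`` is not supplied, the per-resolution penalty is
    chosen by inner-fold cross-entropy on ``inner_splits`` first.
    """
    y = np.asarray(y).ravel()
    n = len(y)
    if lam_by_m is None:
        if inner_splits is None:
            raise ValueError("need inner_splits to select lambda")
        lam_by_m = {
            m: _select_lambda(X, y, config.lambda_grid, inner_splits, config.tol,
                              config.max_iter, rule=config.lambda_rule)
            for m, X in features.items()
        }
    learners = []
    for m in sorted(features):
        bags = _draw_bags(n, y, config.n_replicas, config.bag_mode, rng)
        for r, bag in enumerate(bags):
            learners.append(
                fit_base_learner(
                    features[m], y, lam_by_m[m], bag, m=m, replica=r,
                    tol=config.tol, max_iter=config.max_iter,
                )
            )
    return learners, lam_by_m


def fit_meta_learner(
    base_predictions: np.ndarray,
    y,
    lambda_grid: np.ndarray,
    inner_splits,
    learner_keys,
    tol: float = 1e-8,
    max_iter: int = 5000,
    rule: str = "1se",
) -> MetaLearner:
    """L1-logistic stacking of out-of-fold base probabilities.

    ``base_predictions`` must be out-of-fold: no column may contain a
    learner's prediction on its own training bag.  Base learners whose
    meta weight is exactly zero drop out of the ensemble decision
    function.
    """
    y = np.asarray(y).ravel()
    P = np.asarray(base_predictions, dtype=float)
    lam = _select_lambda(P, y, np.asarray(lambda_grid), inner_splits, tol, max_iter,
                         standardize=False, rule=rule)
    w, b = _fit_l1_weights(P, y, lam, tol, max_iter, standardize=False)
    return MetaLearner(weights=w, intercept=b, lam=lam, learner_keys=tuple(learner_keys))


def predict_stack(stack: TrainedStack, features: dict[int, np.ndarray]) -> np.ndarray:
    """Ensemble probability for each trial row of ``features``."""
    P = np.column_stack([base_predict(L, features[L.m]) for L in stack.base_learners])
    return _sigmoid(P @ stack.meta.weights + stack.meta.intercept)


def _fit_stack(
    features: dict[int, np.ndarray],
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    inner_splits,
    config: DecoderConfig,
    rng,
) -> TrainedStack:
    """Fit one stacked model on ``train_idx`` with leakage-safe stacking.

    Meta features are built by refitting the bank within each inner
    fold and predicting its validation trials, so every meta-training
    row is an out-of-fold base prediction.
    """
    Xtr = {m: X[train_idx] for m, X in features.items()}
    ytr = y[train_idx]
    # select penalties once per resolution on the inner folds
    lam_by_m = {
        m: _select_lambda(X, ytr, config.lambda_grid, inner_splits, config.tol,
                          config.max_iter, rule=config.lambda_rule)
        for m, X in Xtr.items()
    }
    Q = config.n_base_learners
    P = np.full((len(train_idx), Q), np.nan)
    keys = None
    for itr, ival in inner_splits:
        learners_k, _ = fit_bagged_bank(
            {m: X[itr] for m, X in Xtr.items()}, ytr[itr], config, rng, lam_by_m=lam_by_m
        )
        if keys is None:
            keys = [(L.m, L.replica) for L in learners_k]
        for q, L in enumerate(learners_k):
            P[ival, q] = base_predict(L, Xtr[L.m][ival])
    base_learners, _ = fit_bagged_bank(Xtr, ytr, config, rng, lam_by_m=lam_by_m)
    meta = fit_meta_learner(
        P, ytr, config.lambda_grid, inner_splits, keys, tol=config.tol,
        max_iter=config.max_iter, rule=config.lambda_rule,
    )
    # bag membership recorded as global trial positions
    for L in base_learners:
        L.training_trial_ids = train_idx[L.training_trial_ids]
    return TrainedStack(
        base_learners=base_learners,
        meta=meta,
        lam_by_m=lam_by_m,
        train_idx=np.asarray(train_idx),
        test_idx=np.asarray(test_idx),
    )


def _stratification(labels) -> np.ndarray:
    try:
        return labels.category_index()
    except ValueError:
        # multi-label rows: stratify on the row bit pattern
        return (labels.labels * (2 ** np.arange(labels.labels.shape[1]))).sum(axis=1)


def fit_ensemble(tensor, labels, config: DecoderConfig | None = None) -> EnsembleDecoder:
    """Train the 5 one-vs-rest stacked models under nested cross-validation.

    A category whose label column is degenerate (all 0 or all 1) is
    skipped with a warning and its model set to None.  With
    ``config.fit_full_model`` a sixth stack per category is trained on
    all trials (with inner-fold stacking) for interpretation; held-out
    performance always comes from the outer-fold models.
    """
    config = config or DecoderConfig()
    bases = resolution_ladder(config.knot_ladder, config.order, tensor.window_s, tensor.bin_s)
    features = {b.m: featurize(tensor, b).X for b in bases}
    strat = _stratification(labels)
    scheme = CVScheme(config.outer_folds, config.inner_folds, seed=config.seed)
    splits = scheme.outer_splits(strat)
    n_categories = labels.labels.shape[1]
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_categories)
    category_models: list[CategoryModel | None] = []
    for c in range(n_categories):
        if not labels.column_decodable(c):
            warnings.warn(f"category {c} has a degenerate label column; skipping")
            category_models.append(None)
            continue
        y = labels.labels[:, c].astype(int)
        cat_streams = [np.random.default_rng(s) for s in children[c].spawn(len(splits) + 1)]
        folds = []
        for k, (tr, te) in enumerate(splits):
            inner = scheme.inner_splits(strat, tr, fold=k)
            folds.append(_fit_stack(features, y, tr, te, inner, config, cat_streams[k]))
        full_model = None
        if config.fit_full_model:
            all_idx = np.arange(len(y))
            inner_full = CVScheme(config.outer_folds, config.inner_folds, config.seed).inner_splits(
                strat, all_idx, fold=config.outer_folds
            )
            full_model = _fit_stack(
                features, y, all_idx, np.array([], dtype=int), inner_full, config,
                cat_streams[len(splits)],
            )
        category_models.append(CategoryModel(category_id=c, folds=folds, full_model=full_model))
    return EnsembleDecoder(
        config=config,
        bases=bases,
        category_models=category_models,
        outer_splits=splits,
        category_names=tuple(labels.category_names),
        n_neurons=tensor.n_neurons,
    )


def _stack_to_dict(stack: TrainedStack) -> dict:
    return {
        "base_learners": [
            {
                "m": L.m,
                "replica": L.replica,
                "coef": L.coef.tolist(),
                "intercept": L.intercept,
                "lam": L.lam,
                "training_trial_ids": np.asarray(L.training_trial_ids).tolist(),
            }
            for L in stack.base_learners
        ],
        "meta": {
            "weights": stack.meta.weights.tolist(),
            "intercept": stack.meta.intercept,
            "lam": stack.meta.lam,
            "learner_keys": [list(k) for k in stack.meta.learner_keys],
        },
        "lam_by_m": {str(m): lam for m, lam in stack.lam_by_m.items()},
        "train_idx": stack.train_idx.tolist(),
        "test_idx": stack.test_idx.tolist(),
    }


def _stack_from_dict(d: dict) -> TrainedStack:
    return TrainedStack(
        base_learners=[
            BaseLearner(
                m=b["m"],
                replica=b["replica"],
                coef=np.asarray(b["coef"]),
                intercept=b["intercept"],
                lam=b["lam"],
                training_trial_ids=np.asarray(b["training_trial_ids"]),
            )
            for b in d["base_learners"]
        ],
        meta=MetaLearner(
            weights=np.asarray(d["meta"]["weights"]),
            intercept=d["meta"]["intercept"],
            lam=d["meta"]["lam"],
            learner_keys=tuple(tuple(k) for k in d["meta"]["learner_keys"]),
        ),
        lam_by_m={int(m): lam for m, lam in d["lam_by_m"].items()},
        train_idx=np.asarray(d["train_idx"], dtype=int),
        test_idx=np.asarray(d["test_idx"], dtype=int),
    )


def save_decoder(decoder: EnsembleDecoder, path) -> None:
    """Serialize a trained decoder (coefficients, penalties, folds, seeds) to JSON."""
    import dataclasses
    import json
    from pathlib import Path

    first = decoder.bases[0]
    obj = {
        "config": dataclasses.asdict(decoder.config),
        "basis": {
            "order": first.order,
            "window_s": list(first.window_s),
            "bin_s": first.bin_s,
            "knot_ladder": list(decoder.knot_ladder),
        },
        "n_neurons": decoder.n_neurons,
        "category_names": list(decoder.category_names),
        "outer_splits": [[tr.tolist(), te.tolist()] for tr, te in decoder.outer_splits],
        "category_models": [
            None
            if cm is None
            else {
                "category_id": cm.category_id,
                "folds": [_stack_to_dict(s) for s in cm.folds],
                "full_model": None if cm.full_model is None else _stack_to_dict(cm.full_model),
            }
            for cm in decoder.category_models
        ],
    }
    Path(path).write_text(json.dumps(obj))


def load_decoder(path) -> EnsembleDecoder:
    import json
    from pathlib import Path

    obj = json.loads(Path(path).read_text())
    cfg_dict = obj["config"]
    cfg_dict["knot_ladder"] = tuple(cfg_dict["knot_ladder"])
    config = DecoderConfig(**cfg_dict)
    basis = obj["basis"]
    bases = resolution_ladder(
        basis["knot_ladder"], basis["order"], tuple(basis["window_s"]), basis["bin_s"]
    )
    category_models = [
        None
        if cm is None
        else CategoryModel(
            category_id=cm["category_id"],
            folds=[_stack_from_dict(s) for s in cm["folds"]],
            full_model=None if cm["full_model"] is None else _stack_from_dict(cm["full_model"]),
        )
        for cm in obj["category_models"]
    ]
    return EnsembleDecoder(
        config=config,
        bases=bases,
        category_models=category_models,
        outer_splits=[(np.asarray(tr), np.asarray(te)) for tr, te in obj["outer_splits"]],
        category_names=tuple(obj["category_names"]),
        n_neurons=obj["n_neurons"],
    )


@dataclass
class EvaluationResult:
    """Held-out decoding performance under the nested-CV scheme."""

    per_fold: "object"  # pandas DataFrame: category, fold, n_test, mcc
    pooled_mcc: dict[int, float]
    oof_probabilities: np.ndarray  # trials x categories, NaN for skipped categories
    threshold: float

    @property
    def mean_mcc(self) -> float:
        vals = [v for v in self.pooled_mcc.values() if v is not None]
        return float(np.mean(vals)) if vals else float("nan")


def oof_predictions(decoder: EnsembleDecoder, features: dict[int, np.ndarray],
                    category_id: int) -> np.ndarray:
    """Out-of-fold ensemble probabilities: each trial scored only by the
    fold model whose training excluded it."""
    model = decoder.category_models[category_id]
    if model is None:
        raise ValueError(f"category {category_id} has no trained model")
    n = next(iter(features.values())).shape[0]
    probs = np.full(n, np.nan)
    for stack in model.folds:
        rows = stack.test_idx
        sub = {m: X[rows] for m, X in features.items()}
        probs[rows] = predict_stack(stack, sub)
    return probs


def evaluate_nested(decoder: EnsembleDecoder, tensor, labels) -> EvaluationResult:
    """Per-category, per-fold and pooled held-out MCC."""
    import pandas as pd

    features = decoder.featurize_tensor(tensor)
    thr = decoder.config.threshold
    rows = []
    pooled = {}
    n = tensor.n_trials
    n_categories = labels.labels.shape[1]
    oof = np.full((n, n_categories), np.nan)
    for c in range(n_categories):
        model = decoder.category_models[c]
        if model is None:
            pooled[c] = None
            continue
        probs = oof_predictions(decoder, features, c)
        oof[:, c] = probs
        y = labels.labels[:, c].astype(int)
        for k, stack in enumerate(model.folds):
            te = stack.test_idx
            cm = ConfusionMatrix.from_predictions(y[te], (probs[te] >= thr).astype(int))
            rows.append({"category": c, "fold": k, "n_test": len(te), "mcc": mcc(cm)})
        cm_all = ConfusionMatrix.from_predictions(y, (probs >= thr).astype(int))
        pooled[c] = mcc(cm_all)
    return EvaluationResult(
        per_fold=pd.DataFrame(rows),
        pooled_mcc=pooled,
        oof_probabilities=oof,
        threshold=thr,
    )
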