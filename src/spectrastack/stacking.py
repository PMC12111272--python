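"""Two-layer stacking ensembles with out-of-fold meta-features.

Meta-features are the base classifiers' predicted class labels, one integer
column per base, generated by stratified k-fold cross-validation inside the
training set so that no base model ever predicts a sample it was trained on.
The meta-classifier is trained on those columns; at prediction time the base
models (refitted on the full training set) feed the meta-classifier.

Gaussian Naive Bayes is excluded from the meta role: whenever two bases agree
on every sample of some class, the meta-feature variance for that class is
exactly zero and a floorless Gaussian fit is undefined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import classifiers as clf
from .classifiers import ClassifierSpec
from .errors import ParameterError, StratificationError

DEFAULT_POOL = ("knn", "tree", "svm", "nb")
DEFAULT_EXCLUDED_META = ("nb",)

# Canonical published enumeration for the default 4-family pool:
# stacking 1..9 use two bases, stacking 10..12 use three.
_CANONICAL_TABLE: list[tuple[tuple[str, ...], str]] = [
    (("knn", "tree"), "svm"),
    (("knn", "svm"), "tree"),
    (("svm", "tree"), "knn"),
    (("knn", "nb"), "svm"),
    (("knn", "nb"), "tree"),
    (("svm", "nb"), "knn"),
    (("svm", "nb"), "tree"),
    (("tree", "nb"), "knn"),
    (("tree", "nb"), "svm"),
    (("knn", "nb", "tree"), "svm"),
    (("knn", "nb", "svm"), "tree"),
    (("svm", "nb", "tree"), "knn"),
]


@dataclass(frozen=True)
class StackingConfig:
    """Base specs + meta spec + inner fold count for meta-feature generation.

    ``k_inner=None`` means "use the surrounding evaluation's outer k"; the
    standalone :func:`stack_fit` falls back to 5.
    """

    base_specs: tuple[ClassifierSpec, ...]
    meta_spec: ClassifierSpec
    k_inner: int | None = None
    seed: int = 0
    name: str | None = None

    def __post_init__(self) -> None:
        if not (2 <= len(self.base_specs) <= 3):
            raise ParameterError("stacking needs 2 or 3 base classifiers")
        fams = [s.family for s in self.base_specs]
        if len(set(fams)) != len(fams):
            raise ParameterError("base classifier families must be distinct")
        if self.meta_spec.family in fams:
            raise ParameterError("meta family must differ from all base families")
        if self.meta_spec.family == "nb":
            raise ParameterError(
                "Naive Bayes cannot serve as meta-classifier: label-encoded "
                "meta-features can have zero within-class variance"
            )
        if self.k_inner is not None and self.k_inner < 2:
            raise ParameterError("k_inner must be >= 2")

    @property
    def base_families(self) -> tuple[str, ...]:
        return tuple(s.family for s in self.base_specs)


def default_spec(family: str) -> ClassifierSpec:
    """The module-default hyperparameters for one family."""
    return ClassifierSpec.make(family)


def enumerate_combinations(
    pool: tuple[str, ...] = DEFAULT_POOL,
    n_base: int | None = None,
    excluded_meta: tuple[str, ...] = DEFAULT_EXCLUDED_META,
    k_inner: int | None = None,
) -> list[StackingConfig]:
    """All valid stacking configs: distinct bases, meta outside bases and the
    excluded set.

    For the default pool/exclusion the canonical published ordering
    (stacking1..stacking12) is returned; other pools use a deterministic
    lexicographic ordering.  ``n_base`` restricts to 2- or 3-base configs
    (both when None).
    """
    pool = tuple(f.strip().lower() for f in pool)
    if len(set(pool)) != len(pool):
        raise ParameterError("pool families must be distinct")
    sizes = (2, 3) if n_base is None else (int(n_base),)
    for nb_ in sizes:
        if nb_ not in (2, 3):
            raise ParameterError("n_base must be 2 or 3")
        if len(pool) < nb_ + 1:
            raise ParameterError(
                f"pool of {len(pool)} families cannot form {nb_}-base stacks"
            )
    if set(pool) == set(DEFAULT_POOL) and set(excluded_meta) == set(
        DEFAULT_EXCLUDED_META
    ):
        rows = [
            (i + 1, bases, meta)
            for i, (bases, meta) in enumerate(_CANONICAL_TABLE)
            if len(bases) in sizes
        ]
    else:
        rows = []
        num = 0
        for nb_ in sizes:
            for bases in itertools.combinations(pool, nb_):
                for meta in pool:
                    if meta in bases or meta in excluded_meta:
                        continue
                    num += 1
                    rows.append((num, bases, meta))
    return [
        StackingConfig(
            base_specs=tuple(default_spec(f) for f in bases),
            meta_spec=default_spec(meta),
            k_inner=k_inner,
            name=f"stacking{num}",
        )
        for num, bases, meta in rows
    ]


def resolve_combination(name: str, k_inner: int | None = None) -> StackingConfig:
    """Resolve an id like ``"stacking12"`` to its canonical config."""
    name = name.strip().lower()
    for cfg in enumerate_combinations(k_inner=k_inner):
        if cfg.name == name:
            return cfg
    raise ParameterError(f"unknown stacking id {name!r} (expected stacking1..12)")


# ------------------------------------------------------------------ folds
def stratified_folds(y, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified k-fold partition as (train_idx, test_idx) pairs."""
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ParameterError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} samples, cannot build {k} "
            "stratified folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros_like(y), y)]


def oof_column(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    folds: list[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold predictions for one base spec over an explicit partition."""
    out = np.empty(len(y), dtype=int)
    for tr, te in folds:
        model = clf.fit(spec, X[tr], y[tr], seed=seed)
        out[te] = model.predict(X[te])
    return out


def generate_meta_features(
    X, y, base_specs, k_inner: int, seed: int = 0
) -> np.ndarray:
    """n_samples x n_base matrix of out-of-fold predicted class indices."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, k_inner, seed)
    cols = [oof_column(X, y, spec, folds, seed=seed) for spec in base_specs]
    return np.column_stack(cols)


@dataclass
class FittedStack:
    """Deployable two-layer model: refitted bases feeding a fitted meta."""

    config: StackingConfig
    base_models: list
    meta_model: object
    class_names: list[str] | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        meta_in = np.column_stack([m.predict(X) for m in self.base_models])
        return self.meta_model.predict(meta_in)


def stack_fit(
    config: StackingConfig, X, y, class_names: list[str] | None = None
) -> FittedStack:
    """Fit a stack: meta on out-of-fold meta-features, bases refit on all rows."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    k = config.k_inner if config.k_inner is not None else 5
    meta_X = generate_meta_features(X, y, config.base_specs, k, seed=config.seed)
    meta_model = clf.fit(config.meta_spec, meta_X, y, seed=config.seed)
    base_models = [clf.fit(s, X, y, seed=config.seed) for s in config.base_specs]
    return FittedStack(config, base_models, meta_model, class_names)


def stack_predict(stack: FittedStack, X) -> np.ndarray:
    return stack.predict(X)
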