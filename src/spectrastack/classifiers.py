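"""Uniform fit/predict wrappers around the four weak learners.

Families: ``knn``, ``tree``, ``svm``, ``nb`` (plus a trivial ``majority``
baseline used for chance-level checks).  KNN and Gaussian NB are implemented
here so their tie-break and degenerate-variance behaviour is exactly
specified; the tree and SVM delegate to scikit-learn with deterministic
settings.

Determinism contract: identical training data + seed -> identical
predictions.  KNN ties are broken by smaller mean neighbor distance, then
lower class index; NB ties resolve to the lower class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateDataError, ParameterError

FAMILIES = ("knn", "tree", "svm", "nb")


@dataclass(frozen=True)
class ClassifierSpec:
    """Family name plus family-specific hyperparameters.

    ``hyperparams`` is a sorted tuple of (key, value) pairs so that specs are
    hashable and comparable.  Use :meth:`make` or :func:`parse_spec`.
    """

    family: str
    hyperparams: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES + ("majority",):
            raise ParameterError(f"unknown classifier family {self.family!r}")
        object.__setattr__(self, "hyperparams", tuple(sorted(self.hyperparams)))

    @classmethod
    def make(cls, family: str, **params) -> "ClassifierSpec":
        return cls(family.strip().lower(), tuple(sorted(params.items())))

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)

    def __str__(self) -> str:
        if not self.hyperparams:
            return self.family
        kv = ";".join(f"{k}={v}" for k, v in self.hyperparams)
        return f"{self.family}:{kv}"


def parse_spec(text: str) -> ClassifierSpec:
    """Parse a spec string like ``"knn"`` or ``"knn:K=5"``."""
    text = text.strip()
    if ":" not in text:
        return ClassifierSpec.make(text.lower())
    family, _, rest = text.partition(":")
    family = family.lower()
    params = {}
    for item in rest.split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        try:
            parsed: object = int(value)
        except ValueError:
            try:
                parsed = float(value)
            except ValueError:
                parsed = value
        params[key.strip()] = parsed
    return ClassifierSpec.make(family, **params)


class FittedClassifier:
    """Opaque fitted state behind a uniform predict(X) -> labels contract."""

    supports_proba = False

    def __init__(self, spec: ClassifierSpec, classes: np.ndarray, n_features: int):
        self.spec = spec
        self.classes_ = classes
        self.n_features_ = n_features

    def _check(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_:
            raise ParameterError(
                f"X has {X.shape[1]} features, model was trained on {self.n_features_}"
            )
        return X

    def predict(self, X) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class _KNN(FittedClassifier):
    """Euclidean K-nearest-neighbors on per-feature standardized coordinates.

    Features are standardized with training statistics (constant features are
    left unscaled); distance-based voting is meaningless across features of
    arbitrary scale, and extracted spectral features carry no common unit.
    """

    def __init__(self, spec, X, y):
        super().__init__(spec, np.unique(y), X.shape[1])
        self.K = int(spec.params.get("K", 3))
        if self.K < 1:
            raise ParameterError("KNN K must be >= 1")
        if self.K > X.shape[0]:
            raise ParameterError(f"KNN K={self.K} exceeds n_train={X.shape[0]}")
        self.mu_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd == 0, 1.0, sd)
        self.X_, self.y_ = (X - self.mu_) / self.sd_, y

    def predict(self, X) -> np.ndarray:
        X = (self._check(X) - self.mu_) / self.sd_
        D = cdist(X, self.X_)
        n, K = X.shape[0], self.K
        n_classes = int(self.y_.max()) + 1
        order = np.argsort(D, axis=1, kind="stable")
        sortedD = np.take_along_axis(D, order, axis=1)
        # include every training point tied with the K-th distance, so the
        # neighborhood is a deterministic function of the geometry rather
        # than of training row order
        kth = sortedD[:, K - 1]
        counts_kth = (sortedD == kth[:, None]).sum(axis=1)
        widths = (sortedD < kth[:, None]).sum(axis=1) + counts_kth
        out = np.empty(n, dtype=int)
        fast = widths == K
        if fast.any():
            idx = np.flatnonzero(fast)
            votes = self.y_[order[idx, :K]]
            counts = np.zeros((idx.size, n_classes), dtype=np.int32)
            rows = np.repeat(np.arange(idx.size), K)
            np.add.at(counts, (rows, votes.ravel()), 1)
            top = counts.max(axis=1, keepdims=True)
            tied = counts == top
            unique_win = tied.sum(axis=1) == 1
            out[idx[unique_win]] = np.argmax(counts[unique_win], axis=1)
            slow_rows = idx[~unique_win]
        else:
            slow_rows = np.array([], dtype=int)
        slow = np.concatenate([np.flatnonzero(~fast), slow_rows])
        for i in slow:
            nb = order[i, : widths[i]]
            votes = self.y_[nb]
            dists = D[i, nb]
            counts = np.bincount(votes, minlength=n_classes)
            top = counts.max()
            tied_c = np.flatnonzero(counts == top)
            if tied_c.size == 1:
                out[i] = tied_c[0]
                continue
            mean_d = np.array([dists[votes == c].mean() for c in tied_c])
            best = tied_c[np.flatnonzero(mean_d == mean_d.min())]
            out[i] = best.min()  # lower class index on a residual tie
        return out


class _GaussianNB(FittedClassifier):
    """Per-class, per-feature Gaussian likelihoods with a variance floor.

    With ``variance_floor=0`` a zero within-class feature variance raises,
    reproducing the failure mode that rules NB out as a stacking
    meta-classifier on label-encoded meta-features.
    """

    def __init__(self, spec, X, y):
        super().__init__(spec, np.unique(y), X.shape[1])
        # Gaussian NB is exactly equivariant under per-feature affine maps,
        # so standardizing costs nothing statistically while keeping the
        # variance floor meaningful for features of wildly different scale.
        self.in_mu_ = X.mean(axis=0)
        in_sd = X.std(axis=0)
        self.in_sd_ = np.where(in_sd == 0, 1.0, in_sd)
        X = (X - self.in_mu_) / self.in_sd_
        floor = spec.params.get("variance_floor")
        overall_var = X.var(axis=0)
        if floor is None:
            floor = 1e-9 * (overall_var.max() if overall_var.size else 0.0)
        floor = float(floor)
        if floor < 0:
            raise ParameterError("variance_floor must be >= 0")
        means, variances, priors = [], [], []
        for c in self.classes_:
            Xc = X[y == c]
            var = Xc.var(axis=0)
            if floor == 0.0 and np.any(var == 0):
                j = int(np.flatnonzero(var == 0)[0])
                raise DegenerateDataError(
                    f"zero variance for class {int(c)}, feature {j}: Gaussian NB "
                    "cannot estimate the distribution (variance_floor=0)"
                )
            means.append(Xc.mean(axis=0))
            variances.append(var + floor)
            priors.append(Xc.shape[0] / X.shape[0])
        self.means_ = np.stack(means)
        self.vars_ = np.stack(variances)
        self.log_priors_ = np.log(np.asarray(priors))

    def predict(self, X) -> np.ndarray:
        X = (self._check(X) - self.in_mu_) / self.in_sd_
        # log joint per class; argmax breaks exact ties at the lower index
        diff = X[:, None, :] - self.means_[None, :, :]
        log_lik = -0.5 * np.sum(
            np.log(2 * np.pi * self.vars_)[None] + diff**2 / self.vars_[None], axis=2
        )
        scores = log_lik + self.log_priors_[None]
        return self.classes_[np.argmax(scores, axis=1)]


class _Majority(FittedClassifier):
    def __init__(self, spec, X, y):
        super().__init__(spec, np.unique(y), X.shape[1])
        counts = np.bincount(y)
        self.label_ = int(np.argmax(counts))

    def predict(self, X) -> np.ndarray:
        X = self._check(X)
        return np.full(X.shape[0], self.label_, dtype=int)


class _Sklearn(FittedClassifier):
    def __init__(self, spec, estimator, X, y):
        super().__init__(spec, np.unique(y), X.shape[1])
        self.est_ = estimator.fit(X, y)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.est_.predict(self._check(X)), dtype=int)


def fit(spec: ClassifierSpec, X, y, seed: int = 0) -> FittedClassifier:
    """Train one weak learner; see module docstring for the defaults."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ParameterError("X and y length mismatch")
    if X.shape[0] < 2:
        raise ParameterError("need at least 2 training samples")
    if not np.all(np.isfinite(X)):
        raise ParameterError("features must be finite")
    if spec.family != "majority" and np.unique(y).size < 2:
        raise ParameterError("need at least 2 classes in y")
    p = spec.params
    if spec.family == "knn":
        return _KNN(spec, X, y)
    if spec.family == "nb":
        return _GaussianNB(spec, X, y)
    if spec.family == "majority":
        return _Majority(spec, X, y)
    if spec.family == "tree":
        # trees are scale-free in exact arithmetic; standardizing restores
        # that invariance, which absolute split-threshold constants in the
        # backend otherwise break for features at extreme scales
        est = make_pipeline(
            StandardScaler(),
            DecisionTreeClassifier(
                criterion=p.get("criterion", "gini"),
                max_depth=p.get("max_depth"),
                min_samples_leaf=p.get("min_samples_leaf", 1),
                random_state=seed,
            ),
        )
        return _Sklearn(spec, est, X, y)
    if spec.family == "svm":
        C = float(p.get("C", 1.0))
        if C <= 0:
            raise ParameterError("SVM C must be > 0")
        # feature standardization inside the model: margin penalties are not
        # scale-invariant and extracted features can have arbitrary scale
        est = make_pipeline(
            StandardScaler(),
            SVC(
                kernel=p.get("kernel", "linear"),
                C=C,
                gamma=p.get("gamma", "scale"),
                decision_function_shape="ovo",
            ),
        )
        return _Sklearn(spec, est, X, y)
    raise ParameterError(f"unknown family {spec.family!r}")  # pragma: no cover


def accuracy(y_true, y_pred) -> float:
    """Fraction of exact matches in [0, 1]."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ParameterError("y_true and y_pred length mismatch")
    return float(np.mean(y_true == y_pred))
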