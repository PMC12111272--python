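"""Linear feature extraction: PCA, two-stage PCA+LDA, and OLDA.

All three extractors produce a :class:`ProjectionModel` — a centering vector
plus a ``d x q`` projection matrix — so downstream classifiers never need to
know which extractor produced their features.

OLDA computes an orthonormal discriminant basis that remains well defined
when the within-class scatter matrix is singular (the usual situation for
spectra, where the channel count exceeds the per-fold sample count).  The
construction: factor the total scatter S_t = H_t H_t' and between-class
scatter S_b = H_b H_b'; a reduced SVD of H_t whitens the total scatter, a
second SVD of the whitened H_b picks the discriminant directions (the ULDA
solution), and a QR factorization orthonormalizes them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .core_io import SpectraSet
from .errors import DegenerateDataError, ParameterError

logger = logging.getLogger(__name__)

#: Relative singular-value cutoff used for rank decisions in OLDA.
RANK_RTOL = 1e-10

#: Default cumulative explained-variance target for PCA in classification
#: pipelines (fraction of total variance retained).
DEFAULT_VARIANCE_TARGET = 0.993


@dataclass
class ProjectionModel:
    """Fitted linear map: scores = (X - mean) @ components."""

    kind: str  # "pca" | "pca_lda" | "olda"
    mean: np.ndarray  # length d
    components: np.ndarray  # d x q
    explained_variance_ratio: np.ndarray | None = None  # PCA only
    n_classes_seen: int | None = None  # discriminant kinds

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 2 or self.components.shape[1] < 1:
            raise ParameterError("components must be d x q with q >= 1")
        if not np.all(np.isfinite(self.components)):
            raise ParameterError("components must be finite")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def to_dict(self) -> dict:
        """JSON-serializable form (mean, components, metadata)."""
        return {
            "kind": self.kind,
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": (
                None
                if self.explained_variance_ratio is None
                else self.explained_variance_ratio.tolist()
            ),
            "n_classes_seen": self.n_classes_seen,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionModel":
        return cls(
            kind=d["kind"],
            mean=np.asarray(d["mean"]),
            components=np.asarray(d["components"]),
            explained_variance_ratio=(
                None
                if d.get("explained_variance_ratio") is None
                else np.asarray(d["explained_variance_ratio"])
            ),
            n_classes_seen=d.get("n_classes_seen"),
        )


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectraSet):
        X = X.absorbance
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ParameterError("X must be 2-D")
    return X


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude entry of each column is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def pca_fit(
    X,
    n_components: int | None = None,
    variance_target: float | None = None,
) -> ProjectionModel:
    """PCA via SVD of the centered matrix.

    Exactly one of ``n_components`` / ``variance_target`` may be given; with
    neither, the default variance target (0.993) applies.  With a variance
    target the smallest q whose cumulative explained-variance ratio reaches
    the target is retained.
    """
    X = _as_matrix(X)
    n, d = X.shape
    if n < 2:
        raise ParameterError("PCA needs at least 2 samples")
    if n_components is not None and variance_target is not None:
        raise ParameterError("give n_components or variance_target, not both")
    if n_components is None and variance_target is None:
        variance_target = DEFAULT_VARIANCE_TARGET
    max_q = min(n - 1, d)
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise DegenerateDataError("PCA input has zero total variance")
    ratio = var / total
    if n_components is not None:
        if not (1 <= n_components <= max_q):
            raise ParameterError(
                f"n_components must be in [1, {max_q}], got {n_components}"
            )
        q = int(n_components)
    else:
        if not (0 < variance_target <= 1):
            raise ParameterError("variance_target must be in (0, 1]")
        q = int(np.searchsorted(np.cumsum(ratio), variance_target) + 1)
        q = min(q, max_q)
    components = _fix_signs(Vt[:q].T)
    return ProjectionModel(
        kind="pca",
        mean=mean,
        components=components,
        explained_variance_ratio=ratio[:q],
    )


def project(model: ProjectionModel, X) -> np.ndarray:
    """Score matrix (X - mean) @ components; a pure linear map."""
    X = _as_matrix(X)
    if X.shape[1] != model.mean.size:
        raise ParameterError(
            f"X has {X.shape[1]} features, model expects {model.mean.size}"
        )
    return (X - model.mean) @ model.components


def _check_labels(X: np.ndarray, y: np.ndarray, min_per_class: int = 1) -> int:
    y = np.asarray(y, dtype=int)
    if y.shape != (X.shape[0],):
        raise ParameterError("labels length must match row count")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ParameterError("need at least 2 classes")
    if counts.min() < min_per_class:
        raise ParameterError(f"every class needs >= {min_per_class} samples")
    return classes.size


def pca_lda_fit(X, labels, pca_components: int | None = None) -> ProjectionModel:
    """Two-stage reduction: PCA to ``pca_components`` dims, then Fisher LDA.

    The stored model composes both stages into a single ``d x q`` map with
    ``q <= C - 1``.  The PCA stage defaults to ``min(n - C, 15)`` components
    to keep the within-class scatter in PCA space well conditioned.
    """
    X = _as_matrix(X)
    y = np.asarray(labels, dtype=int)
    C = _check_labels(X, y, min_per_class=2)
    n = X.shape[0]
    if pca_components is None:
        pca_components = min(n - C, 15)
    if pca_components < C - 1:
        raise ParameterError(
            f"pca_components={pca_components} < C-1={C - 1}: too few for LDA"
        )
    pca = pca_fit(X, n_components=min(pca_components, n - 1, X.shape[1]))
    Z = project(pca, X)
    Sw, Sb = _scatter_matrices(Z, y)
    try:
        evals, evecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError as exc:
        raise DegenerateDataError(
            "singular within-class scatter in PCA space: reduce pca_components "
            "or use OLDA"
        ) from exc
    order = np.argsort(evals)[::-1][: C - 1]
    W = evecs[:, order]
    components = _fix_signs(pca.components @ W)
    return ProjectionModel(
        kind="pca_lda", mean=pca.mean, components=components, n_classes_seen=C
    )


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within- and between-class scatter (unnormalized sums of squares)."""
    mu = X.mean(axis=0)
    Sw = np.zeros((X.shape[1], X.shape[1]))
    Sb = np.zeros_like(Sw)
    for c in np.unique(y):
        Xc = X[y == c]
        diff = Xc - Xc.mean(axis=0)
        Sw += diff.T @ diff
        dm = (Xc.mean(axis=0) - mu)[:, None]
        Sb += Xc.shape[0] * (dm @ dm.T)
    return Sw, Sb


def olda_fit(X, labels) -> ProjectionModel:
    """Orthogonal LDA; valid even when within-class scatter is singular.

    Steps: reduced SVD of the total-scatter factor H_t = U S V'; whiten the
    between-class factor, B = S^-1 U' H_b; SVD of B = P W Q'; the ULDA map is
    X_q = U S^-1 P_q, and the OLDA map G is the orthonormal Q-factor of X_q.
    Returns at most C - 1 orthonormal columns.
    """
    X = _as_matrix(X)
    y = np.asarray(labels, dtype=int)
    C = _check_labels(X, y)
    n = X.shape[0]
    if n < C + 1:
        raise ParameterError(f"OLDA needs n >= C + 1 samples (n={n}, C={C})")
    mu = X.mean(axis=0)
    Ht = (X - mu).T / np.sqrt(n)  # d x n,  S_t = Ht Ht'
    cols = []
    for c in np.unique(y):
        nc = np.sum(y == c)
        cols.append(np.sqrt(nc / n) * (X[y == c].mean(axis=0) - mu))
    Hb = np.stack(cols, axis=1)  # d x C,  S_b = Hb Hb'
    U, s, _ = np.linalg.svd(Ht, full_matrices=False)
    t = int(np.sum(s > RANK_RTOL * s[0]))
    if t == 0:
        raise DegenerateDataError("total scatter is zero")
    U, s = U[:, :t], s[:t]
    B = (U.T @ Hb) / s[:, None]
    P, omega, _ = np.linalg.svd(B, full_matrices=False)
    # omega entries are cosines of principal angles, bounded by 1, so an
    # absolute floor doubles as the degenerate (equal class means) check
    if omega.size == 0 or omega[0] <= 1e-8:
        raise DegenerateDataError("zero between-class scatter: all class means equal")
    q = int(np.sum(omega > RANK_RTOL * omega[0]))
    q = min(q, C - 1)
    Xq = U @ (P[:, :q] / s[:, None])
    G, _ = np.linalg.qr(Xq)
    G = _fix_signs(G)
    return ProjectionModel(kind="olda", mean=mu, components=G, n_classes_seen=C)


EXTRACTOR_NAMES = ("pca", "pca+lda", "olda")


def extractor_fit(name: str, X, labels=None, config: dict | None = None) -> ProjectionModel:
    """Dispatch to an extractor by name with module defaults.

    Irrelevant config keys are rejected with a logged warning rather than
    silently ignored.
    """
    name = name.strip().lower()
    config = dict(config or {})
    relevant = {
        "pca": {"n_components", "variance_target"},
        "pca+lda": {"pca_components"},
        "olda": set(),
    }
    if name not in relevant:
        raise ParameterError(
            f"unknown extractor {name!r}; expected one of {EXTRACTOR_NAMES}"
        )
    stray = set(config) - relevant[name]
    for key in sorted(stray):
        logger.warning("extractor %r ignores irrelevant config key %r", name, key)
        config.pop(key)
    if name == "pca":
        return pca_fit(X, **config)
    if labels is None:
        raise ParameterError(f"extractor {name!r} requires labels")
    if name == "pca+lda":
        return pca_lda_fit(X, labels, **config)
    return olda_fit(X, labels)
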