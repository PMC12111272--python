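"""Repeated stratified cross-validation protocols.

The harness runs the full experiment structure: a preprocessing comparison
(PCA+KNN at k=5 over the eight named chain variants), the complete
extractor x model x k grid (4 single classifiers + 12 stacking combinations,
k in {2, 5, 8}, 10 repeats), base/meta role summaries, and the meta-KNN
neighbor sweep.

Leakage discipline: within every fold the preprocessing chain (MSC
reference), the feature extractor, and all classifiers are fitted on the
training rows only.  Fold assignments are derived deterministically from
(seed, k, repeat), so every model evaluated at the same (k, repeat) sees
identical partitions and comparisons are paired.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from . import classifiers as clf
from .classifiers import ClassifierSpec
from .core_io import SpectraSet
from .errors import ParameterError
from .features import EXTRACTOR_NAMES, extractor_fit, project
from .preprocess import CHAIN_VARIANTS, PreprocessChain, chain_fit_apply
from .stacking import (
    StackingConfig,
    enumerate_combinations,
    oof_column,
    resolve_combination,
    stratified_folds,
)

SINGLE_FAMILIES = ("knn", "tree", "svm", "nb")


def derive_seed(*parts: int) -> int:
    """Deterministic child seed below 2**31 from integer parts."""
    ss = np.random.SeedSequence([int(p) & 0x7FFFFFFF for p in parts])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified k-fold settings."""

    k: int = 5
    repeats: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ParameterError("k must be >= 2")
        if self.repeats < 1:
            raise ParameterError("repeats must be >= 1")
        if not self.stratified:
            raise ParameterError("only stratified CV is implemented")


@dataclass
class CVResult:
    """Per-repeat accuracies plus a pooled confusion matrix.

    Accuracies are stored as fractions at full precision; the percentage
    properties round only at the reporting layer.
    """

    repeat_accuracies: np.ndarray  # fractions, length = repeats
    confusion: np.ndarray  # C x C counts pooled over repeats and folds
    fold_signatures: tuple[str, ...]  # one digest per repeat, for pairing checks

    @property
    def grand_mean_pct(self) -> float:
        return float(np.mean(self.repeat_accuracies) * 100.0)

    @property
    def std_pct(self) -> float:
        return float(np.std(self.repeat_accuracies, ddof=1) * 100.0) if len(
            self.repeat_accuracies
        ) > 1 else 0.0

    def report(self) -> str:
        return f"{self.grand_mean_pct:.2f} +/- {self.std_pct:.2f} %"


def _fold_signature(folds) -> str:
    h = hashlib.sha256()
    for _, te in folds:
        h.update(np.asarray(te, dtype=np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()[:16]


def resolve_model(name):
    """Map a model name to a ClassifierSpec or canonical StackingConfig."""
    name = name.strip().lower()
    if name.startswith("stacking"):
        return resolve_combination(name)
    return clf.parse_spec(name)


def default_models() -> list[tuple[str, object]]:
    """The 16 grid models: 4 singles then stacking1..12."""
    models: list[tuple[str, object]] = [
        (fam, ClassifierSpec.make(fam)) for fam in SINGLE_FAMILIES
    ]
    models += [(cfg.name, cfg) for cfg in enumerate_combinations()]
    return models


def _evaluate_block(
    data: SpectraSet,
    chain: PreprocessChain | str,
    extractors: tuple[str, ...],
    models: list[tuple[str, object]],
    k: int,
    repeats: int,
    seed: int,
) -> dict[tuple[str, str], CVResult]:
    """Evaluate every (extractor, model) pair under shared fold assignments.

    Base-classifier out-of-fold columns and refitted base models are computed
    once per (fold, extractor) and shared by all stacking configs, which is
    bit-identical to fitting each stack independently because inner fold
    assignments depend only on (labels, k_inner, derived seed).
    """
    if data.labels is None:
        raise ParameterError("evaluation requires labelled data")
    y_all = data.labels
    C = data.n_classes
    singles = [(n, m) for n, m in models if isinstance(m, ClassifierSpec)]
    stacks = [(n, m) for n, m in models if isinstance(m, StackingConfig)]
    if len(singles) + len(stacks) != len(models):
        raise ParameterError("models must be ClassifierSpec or StackingConfig")

    acc = {key: np.zeros((repeats, k)) for key in (
        (ext, name) for ext in extractors for name, _ in models)}
    conf = {key: np.zeros((C, C), dtype=int) for key in acc}
    signatures: list[str] = []

    for r in range(repeats):
        folds = stratified_folds(y_all, k, derive_seed(seed, k, r))
        signatures.append(_fold_signature(folds))
        for fi, (tr, te) in enumerate(folds):
            train, test = data.subset(tr), data.subset(te)
            ptr, pte, _ = chain_fit_apply(train, test, chain)
            y_tr, y_te = train.labels, test.labels
            inner_seed = derive_seed(seed, k, r, fi)
            for ext in extractors:
                fmodel = extractor_fit(ext, ptr.absorbance, y_tr)
                Ftr = project(fmodel, ptr.absorbance)
                Fte = project(fmodel, pte.absorbance)
                preds: dict[str, np.ndarray] = {}
                for name, spec in singles:
                    m = clf.fit(spec, Ftr, y_tr, seed=0)
                    preds[name] = m.predict(Fte)
                if stacks:
                    oof_cache: dict[tuple, np.ndarray] = {}
                    test_pred_cache: dict[ClassifierSpec, np.ndarray] = {}
                    inner_folds_cache: dict[int, list] = {}
                    for name, cfg in stacks:
                        k_inner = cfg.k_inner if cfg.k_inner is not None else k
                        if k_inner not in inner_folds_cache:
                            inner_folds_cache[k_inner] = stratified_folds(
                                y_tr, k_inner, inner_seed
                            )
                        ifolds = inner_folds_cache[k_inner]
                        meta_cols = []
                        meta_cols_te = []
                        for spec in cfg.base_specs:
                            key = (spec, k_inner)
                            if key not in oof_cache:
                                oof_cache[key] = oof_column(
                                    Ftr, y_tr, spec, ifolds, seed=0
                                )
                            if spec not in test_pred_cache:
                                full = clf.fit(spec, Ftr, y_tr, seed=0)
                                test_pred_cache[spec] = full.predict(Fte)
                            meta_cols.append(oof_cache[key])
                            meta_cols_te.append(test_pred_cache[spec])
                        meta = clf.fit(
                            cfg.meta_spec, np.column_stack(meta_cols), y_tr, seed=0
                        )
                        preds[name] = meta.predict(np.column_stack(meta_cols_te))
                for name, _ in models:
                    y_hat = preds[name]
                    acc[(ext, name)][r, fi] = clf.accuracy(y_te, y_hat)
                    conf[(ext, name)] += confusion_matrix(
                        y_te, y_hat, labels=np.arange(C)
                    )

    sigs = tuple(signatures)
    return {
        key: CVResult(acc[key].mean(axis=1), conf[key], sigs) for key in acc
    }


def repeated_cv(
    data: SpectraSet,
    preprocess_chain: PreprocessChain | str,
    extractor_name: str,
    model,
    cv: CVConfig = CVConfig(),
) -> CVResult:
    """Evaluate one pipeline cell: chain -> extractor -> model, repeated k-fold."""
    if isinstance(model, str):
        model = resolve_model(model)
    name = getattr(model, "name", None) or str(model)
    block = _evaluate_block(
        data, preprocess_chain, (extractor_name,), [(name, model)],
        cv.k, cv.repeats, cv.seed,
    )
    return block[(extractor_name, name)]


def preprocessing_comparison(
    data: SpectraSet,
    chains: tuple[str, ...] = CHAIN_VARIANTS,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """PCA+KNN accuracy per preprocessing chain (paired folds across chains).

    Returns a DataFrame sorted by accuracy, best chain flagged.
    """
    if len(set(chains)) != len(chains):
        raise ParameterError("duplicate preprocessing chains")
    model = ClassifierSpec.make("knn")
    rows = []
    for chain in chains:
        block = _evaluate_block(
            data, chain, ("pca",), [("knn", model)], k, repeats, seed
        )
        res = block[("pca", "knn")]
        rows.append(
            {"chain": chain, "accuracy_pct": res.grand_mean_pct, "std_pct": res.std_pct}
        )
    df = pd.DataFrame(rows).sort_values("accuracy_pct", ascending=False)
    df["best"] = False
    df.iloc[0, df.columns.get_loc("best")] = True
    return df.reset_index(drop=True)


@dataclass
class GridResult:
    """Complete extractor x model x k grid of CVResults."""

    results: dict[tuple[str, str, int], CVResult]
    extractors: tuple[str, ...]
    model_names: tuple[str, ...]
    models: dict[str, object]
    ks: tuple[int, ...]

    def to_dataframe(self) -> pd.DataFrame:
        """Grand-mean accuracies (%) with one row per model, columns (extractor, k)."""
        cols = pd.MultiIndex.from_product(
            [self.extractors, self.ks], names=["extractor", "k"]
        )
        table = pd.DataFrame(index=list(self.model_names), columns=cols, dtype=float)
        for (ext, name, k), res in self.results.items():
            table.loc[name, (ext, k)] = res.grand_mean_pct
        return table

    def extractor_mean_pct(self, extractor: str) -> float:
        """Unweighted mean accuracy over all model x k cells of one extractor."""
        vals = [
            res.grand_mean_pct
            for (ext, _, _), res in self.results.items()
            if ext == extractor
        ]
        if not vals:
            raise ParameterError(f"extractor {extractor!r} not in grid")
        return float(np.mean(vals))


def run_grid(
    data: SpectraSet,
    chain: PreprocessChain | str = "sg+msc",
    extractors: tuple[str, ...] = EXTRACTOR_NAMES,
    models: list[tuple[str, object]] | None = None,
    ks: tuple[int, ...] = (2, 5, 8),
    repeats: int = 10,
    seed: int = 0,
) -> GridResult:
    """Run the full grid; fold assignments are shared across models per (k, repeat)."""
    if models is None:
        models = default_models()
    results: dict[tuple[str, str, int], CVResult] = {}
    for k in ks:
        block = _evaluate_block(data, chain, tuple(extractors), models, k, repeats, seed)
        for (ext, name), res in block.items():
            results[(ext, name, k)] = res
    return GridResult(
        results=results,
        extractors=tuple(extractors),
        model_names=tuple(name for name, _ in models),
        models=dict(models),
        ks=tuple(ks),
    )


ROLE_NAMES = ("base", "meta")


def role_analysis(grid: GridResult, role: str, family: str) -> pd.DataFrame:
    """Mean stacking accuracy for configs using ``family`` in ``role``.

    One row per (extractor, k): the unweighted mean over the matching stacking
    configs, the number of configs averaged, and the best single-classifier
    accuracy at the same (extractor, k) for reference.
    """
    if role not in ROLE_NAMES:
        raise ParameterError(f"role must be one of {ROLE_NAMES}")
    family = family.strip().lower()
    matching = []
    for name, model in grid.models.items():
        if not isinstance(model, StackingConfig):
            continue
        fams = model.base_families if role == "base" else (model.meta_spec.family,)
        if family in fams:
            matching.append(name)
    if not matching:
        raise ParameterError(
            f"family {family!r} never appears in role {role!r} in this grid"
        )
    singles = [
        n for n, m in grid.models.items() if isinstance(m, ClassifierSpec)
    ]
    rows = []
    for ext in grid.extractors:
        for k in grid.ks:
            cells = [grid.results[(ext, n, k)].grand_mean_pct for n in matching]
            best_single = (
                max(grid.results[(ext, n, k)].grand_mean_pct for n in singles)
                if singles
                else np.nan
            )
            rows.append(
                {
                    "extractor": ext,
                    "k": k,
                    "role": role,
                    "family": family,
                    "stacking_mean_pct": float(np.mean(cells)),
                    "n_configs": len(matching),
                    "best_single_pct": best_single,
                }
            )
    return pd.DataFrame(rows)


def knn_meta_sweep(
    data: SpectraSet,
    K_values: tuple[int, ...] = (1, 3, 5, 7, 9),
    ks: tuple[int, ...] = (2, 5, 8),
    repeats: int = 10,
    seed: int = 0,
    chain: PreprocessChain | str = "sg+msc",
    extractor: str = "olda",
) -> pd.DataFrame:
    """Neighbor-count sweep for the KNN meta-classifier of stacking12 + OLDA.

    Returns a K x k table of grand-mean accuracies (%); the best K per k is
    the per-column argmax.
    """
    if any(K < 1 for K in K_values):
        raise ParameterError("K values must be >= 1")
    base12 = resolve_combination("stacking12")
    table = pd.DataFrame(index=list(K_values), columns=list(ks), dtype=float)
    table.index.name = "K"
    table.columns.name = "k"
    for k in ks:
        models = []
        for K in K_values:
            cfg = StackingConfig(
                base_specs=base12.base_specs,
                meta_spec=ClassifierSpec.make("knn", K=K),
                name=f"stacking12_k{K}",
            )
            models.append((cfg.name, cfg))
        block = _evaluate_block(data, chain, (extractor,), models, k, repeats, seed)
        for K in K_values:
            table.loc[K, k] = block[(extractor, f"stacking12_k{K}")].grand_mean_pct
    return table
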