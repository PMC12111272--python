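"""Spectral preprocessing operators: SG smoothing, SNV, MSC, first derivative.

All operators preserve matrix shape and wavelength grid.  MSC is the only
stateful step (its reference spectrum is fitted on training data); chains
therefore expose an explicit fit-on-train / apply-to-both protocol.

Conventions
-----------
* SG derivatives are taken with respect to channel *index*, not nm; grid
  spacing is never consulted.
* SG edges are handled by evaluating the window polynomial at off-centre
  positions for the first/last ``(window-1)/2`` channels, so the channel
  count never changes.
* SNV uses the sample standard deviation (divisor ``n_channels - 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .core_io import SpectraSet, WavelengthGrid
from .errors import DegenerateDataError, ParameterError

_MSC_SLOPE_TOL = 1e-12


@dataclass(frozen=True)
class SGParams:
    """Savitzky-Golay window/polynomial/derivative parameters (channel units)."""

    window: int = 9
    polyorder: int = 1
    deriv: int = 0

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ParameterError("SG window must be an odd integer >= 3")
        if not (0 <= self.polyorder < self.window):
            raise ParameterError("SG polyorder must satisfy 0 <= polyorder < window")
        if self.deriv not in (0, 1):
            raise ParameterError("SG deriv must be 0 or 1")


def sg_coefficients(params: SGParams) -> np.ndarray:
    """Convolution weights of the SG filter, ordered for a dot product.

    ``weights @ window_values`` equals the ``deriv``-th derivative of the
    least-squares degree-``polyorder`` polynomial fit, evaluated at the window
    centre (derivative w.r.t. channel index).
    """
    return savgol_coeffs(
        params.window, params.polyorder, deriv=params.deriv, delta=1.0, use="dot"
    )


def _sg_run(spectra: SpectraSet, params: SGParams) -> SpectraSet:
    if spectra.n_channels < params.window:
        raise ParameterError(
            f"need >= {params.window} channels, got {spectra.n_channels}"
        )
    out = savgol_filter(
        spectra.absorbance,
        params.window,
        params.polyorder,
        deriv=params.deriv,
        delta=1.0,
        axis=1,
        mode="interp",
    )
    return spectra.with_absorbance(out)


def sg_smooth(spectra: SpectraSet, params: SGParams = SGParams()) -> SpectraSet:
    """SG smoothing (deriv=0); defaults to the window-9 / order-1 filter."""
    if params.deriv != 0:
        raise ParameterError("sg_smooth requires deriv=0")
    return _sg_run(spectra, params)


def first_derivative(
    spectra: SpectraSet, params: SGParams = SGParams(deriv=1)
) -> SpectraSet:
    """SG first derivative; additive baselines map to zero."""
    if params.deriv != 1:
        raise ParameterError("first_derivative requires deriv=1")
    return _sg_run(spectra, params)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: centre/scale each spectrum individually."""
    A = spectra.absorbance
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise DegenerateDataError(
            f"constant spectrum (zero sd): sample {spectra.sample_ids[flat[0]]!r}"
        )
    return spectra.with_absorbance((A - mu) / sd)


@dataclass(frozen=True)
class MSCReference:
    """Reference spectrum for multiplicative scatter correction."""

    reference: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference, dtype=float)
        object.__setattr__(self, "reference", ref)
        if ref.shape != (len(self.grid),):
            raise ParameterError("MSC reference length must match grid")
        if not np.all(np.isfinite(ref)):
            raise ParameterError("MSC reference must be finite")
        if ref.std() == 0:
            raise DegenerateDataError("MSC reference has zero variance")


def msc_fit(training_spectra: SpectraSet) -> MSCReference:
    """Fit the MSC reference = column-wise mean of the training spectra."""
    if training_spectra.n_samples < 2:
        raise ParameterError("MSC needs >= 2 training samples")
    return MSCReference(training_spectra.absorbance.mean(axis=0), training_spectra.grid)


def msc_apply(spectra: SpectraSet, ref: MSCReference) -> SpectraSet:
    """Regress each spectrum on the reference (x ~ a + b*ref), return (x-a)/b."""
    if spectra.grid != ref.grid:
        raise ParameterError("spectra grid does not match MSC reference grid")
    r = ref.reference
    rc = r - r.mean()
    denom = rc @ rc
    A = spectra.absorbance
    b = (A - A.mean(axis=1, keepdims=True)) @ rc / denom
    bad = np.flatnonzero(np.abs(b) < _MSC_SLOPE_TOL)
    if bad.size:
        raise DegenerateDataError(
            f"near-zero MSC slope for sample {spectra.sample_ids[bad[0]]!r}"
        )
    a = A.mean(axis=1) - b * r.mean()
    return spectra.with_absorbance((A - a[:, None]) / b[:, None])


# ------------------------------------------------------------------ chains
@dataclass(frozen=True)
class _Step:
    """One chain step: kind in {sg, snv, msc, fd}; msc may carry fitted state."""

    kind: str
    sg_params: SGParams | None = None
    msc_reference: MSCReference | None = None

    def fitted(self, train: SpectraSet) -> "_Step":
        if self.kind == "msc" and self.msc_reference is None:
            return replace(self, msc_reference=msc_fit(train))
        return self

    def apply(self, spectra: SpectraSet) -> SpectraSet:
        if self.kind == "sg":
            return sg_smooth(spectra, self.sg_params or SGParams())
        if self.kind == "snv":
            return snv(spectra)
        if self.kind == "fd":
            return first_derivative(spectra, self.sg_params or SGParams(deriv=1))
        if self.kind == "msc":
            if self.msc_reference is None:
                raise ParameterError("MSC step applied before fitting")
            return msc_apply(spectra, self.msc_reference)
        raise ParameterError(f"unknown step kind {self.kind!r}")


@dataclass(frozen=True)
class PreprocessChain:
    """Ordered preprocessing steps; at most one (stateful) MSC step."""

    steps: tuple[_Step, ...] = ()

    def __post_init__(self) -> None:
        if sum(1 for s in self.steps if s.kind == "msc") > 1:
            raise ParameterError("a chain may contain at most one MSC step")

    @property
    def is_fitted(self) -> bool:
        return all(s.kind != "msc" or s.msc_reference is not None for s in self.steps)

    def fit(self, train: SpectraSet) -> "PreprocessChain":
        """Return a fitted copy: the MSC reference is frozen from ``train``.

        Stateless prefixes are applied in order before the MSC fit, so the
        reference lives in the same space the MSC step will see.
        """
        fitted_steps = []
        current = train
        for step in self.steps:
            step = step.fitted(current)
            fitted_steps.append(step)
            current = step.apply(current)
        return PreprocessChain(tuple(fitted_steps))

    def apply(self, spectra: SpectraSet) -> SpectraSet:
        if not self.is_fitted:
            raise ParameterError("chain must be fitted before apply")
        for step in self.steps:
            spectra = step.apply(spectra)
        return spectra

    @classmethod
    def from_string(cls, spec: str, sg_params: SGParams = SGParams()) -> "PreprocessChain":
        """Build a chain from a variant name like ``"sg+msc"`` (case-insensitive).

        Recognized atoms: raw, sg, snv, msc, fd; combined variants run the
        atoms in the stated order (SG first in the standard combinations).
        """
        name = spec.strip().lower()
        if name in ("", "raw"):
            return cls(())
        steps = []
        for atom in name.split("+"):
            atom = atom.strip()
            if atom == "sg":
                steps.append(_Step("sg", sg_params=sg_params))
            elif atom == "snv":
                steps.append(_Step("snv"))
            elif atom == "msc":
                steps.append(_Step("msc"))
            elif atom == "fd":
                steps.append(_Step("fd", sg_params=replace(sg_params, deriv=1)))
            else:
                raise ParameterError(f"unknown preprocessing atom {atom!r}")
        return cls(tuple(steps))


#: The eight named variants of the standard preprocessing comparison.
CHAIN_VARIANTS = ("raw", "sg", "snv", "msc", "fd", "sg+msc", "sg+snv", "sg+fd")


def chain_fit_apply(
    train: SpectraSet,
    test: SpectraSet,
    chain: PreprocessChain | str,
    msc_on_all: bool = False,
) -> tuple[SpectraSet, SpectraSet, PreprocessChain]:
    """Fit a chain on ``train`` and apply it to both sets.

    ``msc_on_all=True`` fits the MSC reference on train+test pooled, mimicking
    the common (leaky) preprocess-before-split convention; default is
    train-only fitting.
    """
    if isinstance(chain, str):
        chain = PreprocessChain.from_string(chain)
    if msc_on_all:
        pooled = SpectraSet(
            np.vstack([train.absorbance, test.absorbance]),
            train.grid,
            [f"t{i}" for i in range(train.n_samples + test.n_samples)],
        )
        fitted = chain.fit(pooled)
    else:
        fitted = chain.fit(train)
    return fitted.apply(train), fitted.apply(test), fitted
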