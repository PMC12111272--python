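"""Synthetic NIR wolfberry-style spectra with controllable class structure.

The generator emulates the statistical features the pipeline assumes of
dried-fruit NIR absorbance data over 900.76-1674.98 nm:

* Gaussian absorption bands for six chemical components, with the moisture
  band near 1445 nm dominant so every class-mean spectrum peaks between
  1400 and 1500 nm;
* per-sample additive offset, sloped baseline drift and multiplicative
  scatter (the distortions MSC/SNV exist to remove);
* a smooth structured within-class residual field (sample-to-sample texture
  and matrix chemistry) whose variance dwarfs the subtle class contrasts, so
  variance-ranked projections truncate discriminant information while
  whitening-based projections recover it;
* heteroscedastic instrument noise, inflated above 1440 nm;
* five class profiles that differ mainly in minor components (phenol-rich
  "ZY", flavonoid-rich "BY", carotenoid-rich "DH"), with "BY"/"YM" an
  intentionally near-duplicate pair.

Spectral smoothness: both stochastic fields (noise and residual) live in the
span of the first K = n_channels/3 cosine modes — one mode per ~10 nm
optical-resolution element of the grating instrument the grid emulates.
Heteroscedastic white noise is projected onto that band-limited basis, so a
sample's spectrum is exactly low rank (bands + baseline + K modes) the way
an optically band-limited measurement is.

Sample model::

    A_i = m_i * (baseline + sum_c conc_ic * band_c + r_i) + o_i + s_i * t + eps_i

with ``t`` the normalized wavelength position, ``m_i ~ N(1, scatter_mult_sd)``,
``o_i, s_i ~ N(0, .)``, ``conc_ic`` truncated-normal draws from the class
profile, ``r_i`` the smooth residual field (1/k mode-power decay, pointwise
sd ``residual_sd``) and ``eps_i`` the band-limited heteroscedastic noise.
Each sample has its own child seed spawned from the global seed, so subsets
are reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import (
    DEFAULT_GRID_MAX_NM,
    DEFAULT_GRID_MIN_NM,
    SpectraSet,
    WavelengthGrid,
)
from .errors import ParameterError


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: centre and width (sd) in nm."""

    component: str
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ParameterError("band width must be > 0")


#: Band centres sit inside the published absorption ranges for each
#: component; widths are generator defaults.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("protein", 1010.0, 25.0),
    BandSpec("polysaccharide", 1200.0, 40.0),
    BandSpec("flavonoid", 1200.0, 18.0),
    BandSpec("phenol", 1425.0, 20.0),
    BandSpec("moisture", 1445.0, 35.0),
    BandSpec("carotenoid", 1660.0, 12.0),
)

#: Relative within-class sd of each component concentration.  Moisture and
#: polysaccharide vary a lot between individual fruits (drying state, sugar
#: content); the minor discriminative components are tightly regulated.
DEFAULT_REL_SD: dict[str, float] = {
    "protein": 0.05,
    "polysaccharide": 0.08,
    "flavonoid": 0.02,
    "phenol": 0.02,
    "moisture": 0.10,
    "carotenoid": 0.02,
}


@dataclass(frozen=True)
class ClassProfile:
    """Per-component concentration mean and sd (arbitrary units) for one class.

    ``correlations`` optionally lists pairwise concentration correlations
    ``(component_a, component_b, rho)``; unlisted pairs are independent.
    Opposite-signed correlations are how two classes with identical mean
    composition can still differ (the covariance signature of distinct
    cultivation/harvest practice), which no mean-based projection can see.
    """

    name: str
    means: tuple[tuple[str, float], ...]
    sds: tuple[tuple[str, float], ...]
    correlations: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if any(v < 0 for _, v in self.means) or any(v < 0 for _, v in self.sds):
            raise ParameterError("concentration means/sds must be >= 0")
        for a, b, rho in self.correlations:
            if not (-1.0 <= rho <= 1.0):
                raise ParameterError(f"correlation({a},{b})={rho} outside [-1, 1]")

    @classmethod
    def make(
        cls,
        name: str,
        means: dict,
        rel_sd: dict | float = None,
        sd_override: dict | None = None,
        correlations: tuple[tuple[str, str, float], ...] = (),
    ) -> "ClassProfile":
        if rel_sd is None:
            rel_sd = DEFAULT_REL_SD
        if isinstance(rel_sd, (int, float)):
            rel_sd = {c: float(rel_sd) for c in means}
        sds = {c: rel_sd[c] * v for c, v in means.items()}
        sds.update(sd_override or {})
        return cls(
            name,
            tuple(sorted(means.items())),
            tuple(sorted(sds.items())),
            tuple(correlations),
        )

    @property
    def mean_dict(self) -> dict:
        return dict(self.means)

    @property
    def sd_dict(self) -> dict:
        return dict(self.sds)

    def covariance(self, components: tuple[str, ...]) -> np.ndarray:
        """Concentration covariance over ``components`` (symmetric PSD)."""
        sd = self.sd_dict
        s = np.array([sd.get(c, 0.0) for c in components])
        cov = np.diag(s**2)
        idx = {c: i for i, c in enumerate(components)}
        for a, b, rho in self.correlations:
            if a in idx and b in idx:
                cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = rho * s[idx[a]] * s[idx[b]]
        return cov


def _default_profiles() -> tuple[ClassProfile, ...]:
    # Moisture/polysaccharide (the dominant-variance components) barely
    # differ between classes; discrimination rides on the minor components
    # (phenol-rich ZY, carotenoid-rich DH, depleted WW).  "BY" and "YM" are
    # deliberate near-duplicates: identical in every major component, with
    # only a modest flavonoid/phenol offset separating their means.
    table = {
        "ZY": dict(protein=0.33, polysaccharide=0.50, flavonoid=0.195,
                   phenol=0.475, moisture=0.92, carotenoid=0.13),
        "YM": dict(protein=0.285, polysaccharide=0.47, flavonoid=0.285,
                   phenol=0.295, moisture=0.90, carotenoid=0.105),
        "WW": dict(protein=0.21, polysaccharide=0.49, flavonoid=0.135,
                   phenol=0.235, moisture=0.89, carotenoid=0.06),
        "BY": dict(protein=0.29, polysaccharide=0.48, flavonoid=0.33,
                   phenol=0.34, moisture=0.91, carotenoid=0.12),
        "DH": dict(protein=0.24, polysaccharide=0.46, flavonoid=0.105,
                   phenol=0.205, moisture=0.88, carotenoid=0.235),
    }
    return tuple(ClassProfile.make(name, means) for name, means in table.items())


DEFAULT_PROFILES: tuple[ClassProfile, ...] = _default_profiles()


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults are the standard study conditions."""

    n_per_class: int = 80
    n_classes: int = 5
    n_channels: int = 228
    grid_min: float = DEFAULT_GRID_MIN_NM
    grid_max: float = DEFAULT_GRID_MAX_NM
    scatter_mult_sd: float = 0.08
    offset_sd: float = 0.02
    slope_sd: float = 0.01
    residual_sd: float = 0.012
    noise_sd: float = 0.004
    noise_high_mult: float = 3.0
    noise_split_nm: float = 1440.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2 or self.n_classes < 2:
            raise ParameterError("need n_per_class >= 2 and n_classes >= 2")
        if min(self.scatter_mult_sd, self.offset_sd, self.slope_sd,
               self.residual_sd, self.noise_sd) < 0:
            raise ParameterError("all sds must be >= 0")
        if self.noise_high_mult < 0:
            raise ParameterError("noise_high_mult must be >= 0")


def strong_scatter_config(seed: int = 0, **overrides) -> SynthConfig:
    """The scatter-stress condition: amplified multiplicative/additive scatter.

    Used to demonstrate how much scatter-correcting preprocessing recovers.
    """
    params = dict(scatter_mult_sd=0.25, offset_sd=0.15, slope_sd=0.08, seed=seed)
    params.update(overrides)
    return SynthConfig(**params)


def _baseline(t: np.ndarray) -> np.ndarray:
    # gentle upward-sloping background absorbance, small next to the bands
    return 0.25 + 0.05 * t


def _smooth_basis(n_channels: int) -> np.ndarray:
    """Orthonormal cosine modes up to the instrument-resolution band limit.

    One mode per ~3 channels matches a ~10 nm optical resolution on the
    default 3.4 nm channel spacing.
    """
    K = max(8, round(n_channels / 3))
    j = np.arange(n_channels)
    basis = np.stack(
        [np.cos(np.pi * k * (j + 0.5) / n_channels) for k in range(K)]
    ) * np.sqrt(2.0 / n_channels)
    basis[0] /= np.sqrt(2.0)
    return basis


def _residual_weights(basis: np.ndarray, residual_sd: float) -> np.ndarray:
    """Mode amplitudes with 1/k power decay, normalized to the pointwise sd.

    With orthonormal rows, the average channel variance of ``(eta * w) @ basis``
    is ``sum(w^2) / n_channels``, which pins the scale analytically.
    """
    K, N = basis.shape
    w = 1.0 / np.sqrt(np.arange(1, K + 1))
    return w * residual_sd * np.sqrt(N / np.sum(w**2))


def generate(
    config: SynthConfig = SynthConfig(),
    profiles: tuple[ClassProfile, ...] | None = None,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
) -> SpectraSet:
    """Generate a labelled SpectraSet under ``config``."""
    if profiles is None:
        profiles = DEFAULT_PROFILES[: config.n_classes]
    if len(profiles) != config.n_classes:
        raise ParameterError(
            f"{len(profiles)} profiles given for {config.n_classes} classes"
        )
    band_names = {b.component for b in bands}
    for p in profiles:
        missing = set(p.mean_dict) - band_names
        if missing:
            raise ParameterError(
                f"profile {p.name!r} references unknown components {sorted(missing)}"
            )
    grid = WavelengthGrid.uniform(config.n_channels, config.grid_min, config.grid_max)
    wl = grid.values
    t = (wl - wl[0]) / (wl[-1] - wl[0])
    shapes = {
        b.component: np.exp(-0.5 * ((wl - b.center) / b.width) ** 2) for b in bands
    }
    noise_scale = np.where(
        wl > config.noise_split_nm, config.noise_sd * config.noise_high_mult,
        config.noise_sd,
    )
    base = _baseline(t)
    basis = _smooth_basis(config.n_channels)
    K = basis.shape[0]
    res_w = _residual_weights(basis, config.residual_sd)
    # projecting white noise onto K of N dims shrinks the pointwise sd by
    # sqrt(K/N); compensate so the channel-wise sd stays near noise_scale
    noise_renorm = np.sqrt(config.n_channels / K)

    n_total = config.n_classes * config.n_per_class
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    A = np.empty((n_total, config.n_channels))
    labels = np.empty(n_total, dtype=int)
    ids = []
    for c, profile in enumerate(profiles):
        comps = tuple(sorted(profile.mean_dict))
        mean_vec = np.array([profile.mean_dict[comp] for comp in comps])
        cov = profile.covariance(comps)
        # symmetric PSD square root copes with zero sds and exact +/-1 corr
        evals, evecs = np.linalg.eigh(cov)
        L = evecs * np.sqrt(np.clip(evals, 0.0, None))
        shape_mat = np.stack([shapes[comp] for comp in comps])
        for j in range(config.n_per_class):
            i = c * config.n_per_class + j
            rng = np.random.default_rng(children[i])
            conc = np.maximum(
                0.0, mean_vec + L @ rng.normal(0.0, 1.0, len(comps))
            )
            clean = base + conc @ shape_mat
            clean += (rng.normal(0.0, 1.0, K) * res_w) @ basis
            m = rng.normal(1.0, config.scatter_mult_sd)
            o = rng.normal(0.0, config.offset_sd)
            s = rng.normal(0.0, config.slope_sd)
            white = rng.normal(0.0, 1.0, config.n_channels) * noise_scale
            eps = ((white @ basis.T) @ basis) * noise_renorm
            A[i] = m * clean + o + s * t + eps
            labels[i] = c
            ids.append(f"{profile.name}-{j:03d}")
    return SpectraSet(A, grid, ids, labels, [p.name for p in profiles])


def make_overlapping_pair(
    profiles: tuple[ClassProfile, ...],
    similarity: float,
    pair: tuple[str, str] = ("BY", "YM"),
) -> tuple[ClassProfile, ...]:
    """Blend two profiles' component means toward their midpoint.

    ``similarity=0`` leaves them unchanged; ``similarity=1`` makes the means
    identical.
    """
    if not (0.0 <= similarity <= 1.0):
        raise ParameterError("similarity must be in [0, 1]")
    if len(profiles) < 2:
        raise ParameterError("need at least 2 profiles")
    names = [p.name for p in profiles]
    for target in pair:
        if target not in names:
            raise ParameterError(f"profile {target!r} not found")
    a, b = (profiles[names.index(p)] for p in pair)
    mid = {c: 0.5 * (a.mean_dict[c] + b.mean_dict[c]) for c in a.mean_dict}
    out = []
    for p in profiles:
        if p.name in pair:
            new_means = {
                c: v + similarity * (mid[c] - v) for c, v in p.mean_dict.items()
            }
            out.append(ClassProfile(p.name, tuple(sorted(new_means.items())), p.sds))
        else:
            out.append(p)
    return tuple(out)


FIXTURE_SEED = 170_215


def fixture_small() -> SpectraSet:
    """Deterministic tiny dataset for fast tests: 5 classes x 10 x 40 channels."""
    return generate(SynthConfig(n_per_class=10, n_channels=40, seed=FIXTURE_SEED))
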