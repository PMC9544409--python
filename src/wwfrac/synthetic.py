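"""Synthetic test data with recorded ground truth.

Two generators: gel-lane intensity profiles (sum of Gaussian bands on a
smooth polynomial baseline plus additive noise) and noisy fractionation
yield observations from the partition model at a known λ_eff. Every
output comes with a truth record holding the quantities a downstream
recovery test needs (true band areas, baseline, noiseless yields, the
generating parameter), so calibration and densitometry accuracy can be
asserted without re-reading generator internals.

All randomness flows through one ``numpy.random.Generator`` seeded from
the spec: identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .densitometry import LaneProfile
from .errors import ValidationError
from .geometry import StructureSpec, builtin_catalog, get_structure, surface_area
from .partition import PartitionModel, Protocol, cumulative_yield

__all__ = [
    "GaussianBand",
    "SyntheticLaneSpec",
    "LaneTruth",
    "synth_lane",
    "SyntheticFractionationSpec",
    "FractionationObservation",
    "FractionationTruth",
    "synth_fractionation",
]


@dataclass(frozen=True)
class GaussianBand:
    """One gel band: Gaussian bump with a known integrated area."""

    center: float
    sd: float
    area: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValidationError(f"band sd must be > 0, got {self.sd}")
        if not self.area > 0:
            raise ValidationError(f"band area must be > 0, got {self.area}")


@dataclass(frozen=True)
class SyntheticLaneSpec:
    """Recipe for one synthetic lane profile.

    ``baseline_coeffs`` are polynomial coefficients in increasing degree
    (constant first), degree ≤ 3. ``noise_sd`` is the additive Gaussian
    noise standard deviation expressed as a fraction of the tallest band
    peak (absolute units when there are no bands).
    """

    bands: tuple[GaussianBand, ...] = ()
    baseline_coeffs: tuple[float, ...] = (0.0,)
    noise_sd: float = 0.0
    seed: int = 0
    position_start: float = 0.0
    position_stop: float = 500.0
    n_points: int = 512

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        object.__setattr__(self, "baseline_coeffs", tuple(self.baseline_coeffs))
        if len(self.baseline_coeffs) > 4:
            raise ValidationError("baseline polynomial degree must be <= 3")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_points < 3:
            raise ValidationError("n_points must be >= 3")
        if not self.position_start < self.position_stop:
            raise ValidationError("position_start must be < position_stop")
        for band in self.bands:
            if not self.position_start <= band.center <= self.position_stop:
                raise ValidationError(
                    f"band at {band.center} lies outside the position range "
                    f"[{self.position_start}, {self.position_stop}]"
                )


@dataclass(frozen=True)
class LaneTruth:
    """Ground truth accompanying a synthetic lane."""

    band_areas: tuple[float, ...]
    band_regions: tuple[tuple[float, float], ...]  # center ± 5 sd, clipped
    baseline: np.ndarray
    noise_sd_abs: float
    seed: int


def synth_lane(spec: SyntheticLaneSpec) -> tuple[LaneProfile, LaneTruth]:
    """Generate a lane profile and its truth record.

    Intensities are the sum of Gaussian bands (each normalised so its
    full integral equals the requested area), the baseline polynomial,
    and iid Gaussian noise. Deterministic per seed.
    """
    pos = np.linspace(spec.position_start, spec.position_stop, spec.n_points)
    baseline = np.polynomial.polynomial.polyval(pos, np.asarray(spec.baseline_coeffs))
    baseline = np.broadcast_to(baseline, pos.shape).astype(float).copy()
    signal = np.zeros_like(pos)
    peak_heights = []
    regions = []
    for band in spec.bands:
        amp = band.area / (band.sd * np.sqrt(2.0 * np.pi))
        signal += amp * np.exp(-0.5 * ((pos - band.center) / band.sd) ** 2)
        peak_heights.append(amp)
        regions.append(
            (
                max(band.center - 5.0 * band.sd, spec.position_start),
                min(band.center + 5.0 * band.sd, spec.position_stop),
            )
        )
    noise_sd_abs = spec.noise_sd * (max(peak_heights) if peak_heights else 1.0)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, noise_sd_abs, pos.shape) if noise_sd_abs > 0 else 0.0
    profile = LaneProfile(pos, baseline + signal + noise)
    truth = LaneTruth(
        band_areas=tuple(b.area for b in spec.bands),
        band_regions=tuple(regions),
        baseline=baseline,
        noise_sd_abs=noise_sd_abs,
        seed=spec.seed,
    )
    return profile, truth


def _default_structures() -> tuple[StructureSpec, ...]:
    cat = builtin_catalog()
    names = ("staple", "mini_triangle", "triangular_origami", "hexagonal_origami", "24hb")
    return tuple(get_structure(n, cat) for n in names)


@dataclass(frozen=True)
class SyntheticFractionationSpec:
    """Recipe for noisy fractionation-yield observations.

    Defaults emulate the study conditions: the five fixed-size catalog
    structures taken through the typical three-round protocol at the
    default λ_eff, with additive Gaussian yield noise (absolute on the
    [0, 1] yield scale) clipped back into [0, 1].
    """

    lambda_true: float = 5e-4
    structures: tuple[StructureSpec, ...] = field(default_factory=_default_structures)
    protocol: Protocol = field(default_factory=Protocol)
    yield_noise_sd: float = 0.0
    seed: int = 0
    K_cap: float = 1e6

    def __post_init__(self) -> None:
        object.__setattr__(self, "structures", tuple(self.structures))
        if self.lambda_true < 0:
            raise ValidationError("lambda_true must be >= 0")
        if self.yield_noise_sd < 0:
            raise ValidationError("yield_noise_sd must be >= 0")
        for s in self.structures:
            if s.has_area_range:
                raise ValidationError(
                    f"structure {s.name!r} has an area range; observations need "
                    "fixed-size structures"
                )


@dataclass(frozen=True)
class FractionationObservation:
    """One observed (noisy) cumulative yield."""

    structure: str
    area: float
    observed_yield: float


@dataclass(frozen=True)
class FractionationTruth:
    """Ground truth accompanying synthetic fractionation observations."""

    lambda_true: float
    noiseless_yields: tuple[float, ...]
    yield_noise_sd: float
    seed: int


def synth_fractionation(
    spec: SyntheticFractionationSpec,
) -> tuple[list[FractionationObservation], FractionationTruth]:
    """Observed yields = clip(model yield + noise, 0, 1), seeded.

    With zero noise the observations equal the model yields exactly.
    Zero observed yields are nudged to the smallest positive float so
    the calibration precondition (yields in (0, 1]) always holds.
    """
    model = PartitionModel(lambda_eff=spec.lambda_true, K_cap=spec.K_cap)
    rng = np.random.default_rng(spec.seed)
    observations = []
    clean = []
    for s in spec.structures:
        area = surface_area(s)
        assert not isinstance(area, tuple)
        y = cumulative_yield(model, spec.protocol, area)
        clean.append(y)
        y_obs = y
        if spec.yield_noise_sd > 0:
            y_obs = float(np.clip(y + rng.normal(0.0, spec.yield_noise_sd), 0.0, 1.0))
        y_obs = max(y_obs, np.finfo(float).tiny)
        observations.append(FractionationObservation(s.name, float(area), y_obs))
    truth = FractionationTruth(
        lambda_true=spec.lambda_true,
        noiseless_yields=tuple(clean),
        yield_noise_sd=spec.yield_noise_sd,
        seed=spec.seed,
    )
    return observations, truth
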