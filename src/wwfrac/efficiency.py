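"""Purification-efficiency statistic and the two-axis efficiency landscape.

The separation of a target structure from a contaminant after n rounds of
W/W-droplet fractionation is scored by

    E = (Y_t − Y_c) / (Y_t + Y_c),

where Y_t and Y_c are the cumulative yields of target and contaminant.
E = 1 means perfect separation (all target kept, all contaminant gone),
E = 0 no separation, and E < 0 the contaminant is retained preferentially.

The landscape evaluates E over a log-spaced grid of contaminant surface
area A_c and area ratio A_t/A_c, reproducing the three regimes of the
size-dependence: high E for small contaminants with much larger targets;
E ≈ 0 along the ratio-1 diagonal (identical species cannot be separated);
and E ≈ 0 for large contaminants, which are retained by the droplets just
like the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedEfficiencyError, ValidationError
from .geometry import StructureSpec, builtin_catalog, surface_area
from .partition import (
    PartitionModel,
    Protocol,
    cumulative_yield,
    simulate_yield,
    typical_protocol,
)

__all__ = [
    "efficiency",
    "EfficiencyMap",
    "LandscapeAnnotation",
    "landscape",
    "annotate_catalog_pairs",
    "MinRoundsResult",
    "min_rounds_to_purity",
]


def efficiency(Y_target: float, Y_contaminant: float) -> float:
    """Purification efficiency E = (Y_t − Y_c)/(Y_t + Y_c), in [−1, 1].

    Yields are fractions in [0, 1]; both zero is undefined (0/0) and
    raises :class:`UndefinedEfficiencyError`. Antisymmetric under swapping
    target and contaminant.
    """
    for label, y in (("Y_target", Y_target), ("Y_contaminant", Y_contaminant)):
        if not 0.0 <= y <= 1.0:
            raise ValidationError(f"{label} must lie in [0, 1], got {y}")
    total = Y_target + Y_contaminant
    if total == 0.0:
        raise UndefinedEfficiencyError(
            "both yields are zero: purification efficiency is undefined"
        )
    return (Y_target - Y_contaminant) / total


@dataclass(frozen=True)
class LandscapeAnnotation:
    """A structure pair marked on the landscape.

    Fixed-size pairs are points; pairs whose target spans an area range
    (hydrogels, microtubes) are lines along the ratio axis, with ratio
    and efficiency given at the range endpoints.
    """

    label: str
    target: str
    contaminant: str
    kind: str  # "point" | "line"
    A_contaminant: float
    ratio: float | tuple[float, float]
    E: float | tuple[float, float]


@dataclass(frozen=True)
class EfficiencyMap:
    """E over a (ratio × contaminant-area) grid after ``n_rounds`` rounds."""

    contaminant_areas: np.ndarray  # (n_c,) nm², log-spaced
    area_ratios: np.ndarray        # (n_r,) A_target/A_contaminant, log-spaced
    E_values: np.ndarray           # (n_r, n_c)
    n_rounds: int
    annotations: tuple[LandscapeAnnotation, ...] = ()

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns A_contaminant, ratio, E."""
        ratio_grid, area_grid = np.meshgrid(
            self.area_ratios, self.contaminant_areas, indexing="ij"
        )
        return pd.DataFrame(
            {
                "A_contaminant": area_grid.ravel(),
                "ratio": ratio_grid.ravel(),
                "E": self.E_values.ravel(),
            }
        )


def annotate_catalog_pairs(
    model: PartitionModel,
    protocol: Protocol,
    catalog: list[StructureSpec] | None = None,
) -> tuple[LandscapeAnnotation, ...]:
    """Annotations for the canonical target/contaminant pairs.

    Origami vs staples plot as points; hydrogel vs free Y-motifs and the
    tile microtubes vs staples plot as lines because those targets span a
    size range.
    """
    catalog = builtin_catalog() if catalog is None else catalog
    by_name = {s.name: s for s in catalog}
    pairs = [
        ("a", "hexagonal_origami", "staple"),
        ("a'", "triangular_origami", "staple"),
        ("b", "mini_triangle", "staple"),
        ("c", "dna_hydrogel", "y_motif"),
        ("d", "microtube_4ht", "staple"),
        ("d'", "microtube_13ht", "staple"),
    ]
    out = []
    for label, t_name, c_name in pairs:
        if t_name not in by_name or c_name not in by_name:
            continue
        A_c = surface_area(by_name[c_name])
        assert not isinstance(A_c, tuple)
        Y_c = cumulative_yield(model, protocol, A_c)
        A_t = surface_area(by_name[t_name])
        if isinstance(A_t, tuple):
            E_pair = tuple(
                efficiency(cumulative_yield(model, protocol, a), Y_c) for a in A_t
            )
            out.append(
                LandscapeAnnotation(
                    label, t_name, c_name, "line", A_c,
                    (A_t[0] / A_c, A_t[1] / A_c), E_pair,
                )
            )
        else:
            E_pt = efficiency(cumulative_yield(model, protocol, A_t), Y_c)
            out.append(
                LandscapeAnnotation(label, t_name, c_name, "point", A_c, A_t / A_c, E_pt)
            )
    return tuple(out)


def landscape(
    model: PartitionModel | None = None,
    protocol: Protocol | None = None,
    contaminant_area_range: tuple[float, float] = (10.0, 1e9),
    ratio_range: tuple[float, float] = (1.0, 1e6),
    n_rounds: int = 3,
    n_contaminant: int = 200,
    n_ratio: int = 200,
    annotate: bool = True,
) -> EfficiencyMap:
    """Efficiency E over a log-spaced (A_contaminant × ratio) grid.

    The grid cell at (ratio, A_c) holds E computed from the cumulative
    yields of two species with areas A_c and ratio·A_c under the same
    model and protocol. When ``protocol`` is omitted the typical protocol
    extended to ``n_rounds`` is used; a supplied protocol overrides
    ``n_rounds``.
    """
    model = PartitionModel() if model is None else model
    if protocol is None:
        protocol = typical_protocol(n_rounds)
    n_rounds = protocol.n_rounds
    if n_rounds < 1:
        raise ValidationError("landscape needs at least one round")
    lo_a, hi_a = contaminant_area_range
    lo_r, hi_r = ratio_range
    if not (0 < lo_a < hi_a and 0 < lo_r < hi_r):
        raise ValidationError("area and ratio ranges must be positive and increasing")

    A_c = np.logspace(np.log10(lo_a), np.log10(hi_a), n_contaminant)
    ratios = np.logspace(np.log10(lo_r), np.log10(hi_r), n_ratio)
    Y_c = cumulative_yield(model, protocol, A_c)              # (n_c,)
    Y_t = cumulative_yield(model, protocol, ratios[:, None] * A_c[None, :])
    E = (Y_t - Y_c[None, :]) / (Y_t + Y_c[None, :])
    annotations = (
        annotate_catalog_pairs(model, protocol) if annotate else ()
    )
    return EfficiencyMap(A_c, ratios, E, n_rounds, annotations)


@dataclass(frozen=True)
class MinRoundsResult:
    """Result of :func:`min_rounds_to_purity`.

    ``n`` is the smallest round count whose cumulative yield drops below
    the threshold, or ``None`` when the threshold is unreachable within
    ``max_rounds`` (e.g. the partition coefficient is large enough that
    the yield plateaus near 1). ``yield_at_stop`` is Yⁿ at ``n`` or at
    the round cap; ``limiting_retention`` is the per-round retention of
    the repeated step, which governs the asymptotic decay rate.
    """

    n: int | None
    yield_at_stop: float
    limiting_retention: float

    @property
    def reached(self) -> bool:
        return self.n is not None


def min_rounds_to_purity(
    model: PartitionModel,
    area: float,
    threshold: float,
    max_rounds: int = 20,
    V_total: float = 40.0,
    V_droplet: float = 2.0,
) -> MinRoundsResult:
    """Smallest round count n with cumulative yield Yⁿ below ``threshold``.

    Rounds follow the typical protocol template (15 µL retained per
    round, 5 µL in the final round once n ≥ 3). Termination is
    guaranteed by ``max_rounds``: a species whose yield has not dropped
    below the threshold by then is reported as unreachable (``n=None``)
    together with the plateau yield.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    if max_rounds < 1:
        raise ValidationError("max_rounds must be >= 1")
    last_yield = 1.0
    for n in range(1, max_rounds + 1):
        protocol = typical_protocol(n, V_total=V_total, V_droplet=V_droplet)
        traj = simulate_yield(model, protocol, area)
        last_yield = traj.final_yield
        if last_yield < threshold:
            return MinRoundsResult(n, last_yield, traj.per_round_retention[0])
    protocol = typical_protocol(max_rounds, V_total=V_total, V_droplet=V_droplet)
    traj = simulate_yield(model, protocol, area)
    return MinRoundsResult(None, last_yield, traj.per_round_retention[0])
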