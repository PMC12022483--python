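"""Large-unilamellar-vesicle geometry and surface-occupancy arithmetic.

Supports the back-of-envelope occupancy argument for interfacial enzymes:
how many lipids a vesicle of given diameter contains, the molar vesicle
concentration at a given bulk lipid concentration, how many proteins each
vesicle carries on average, and what fraction of the outer surface those
proteins occlude.  A small occupied fraction justifies treating the
vesicle as an unperturbed membrane reservoir in the binding analysis.

Note the two routes to lipids-per-vesicle: the geometric route
(sphere area × leaflets / head-group area) and an explicit override for
when a vesicle aggregation number is quoted directly.  Quoted aggregation
numbers and geometric estimates frequently disagree; both are supported
and neither is silently preferred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DataError

__all__ = [
    "VesicleSpec",
    "SurfaceOccupancy",
    "lipids_per_vesicle",
    "vesicle_concentration",
    "proteins_per_vesicle",
    "protein_footprint",
    "surface_fraction_occupied",
]


@dataclass(frozen=True)
class VesicleSpec:
    """Geometry of a (monodisperse, spherical) lipid vesicle.

    diameter in nm, head-group area in nm² per lipid, leaflets counted
    when converting surface area to lipid number (2 for a bilayer).
    ``lipids_per_vesicle_override`` short-circuits the geometric estimate
    when an aggregation number is quoted directly.
    """

    diameter: float = 150.0
    head_area: float = 0.6
    leaflets: int = 2
    lipids_per_vesicle_override: int | None = None

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise DataError(f"diameter must be > 0, got {self.diameter!r}")
        if not self.head_area > 0:
            raise DataError(f"head_area must be > 0, got {self.head_area!r}")
        if self.leaflets not in (1, 2):
            raise DataError(f"leaflets must be 1 or 2, got {self.leaflets!r}")
        if self.lipids_per_vesicle_override is not None and not self.lipids_per_vesicle_override > 0:
            raise DataError("lipids_per_vesicle_override must be > 0 when set")

    @property
    def surface_area(self) -> float:
        """Outer spherical surface area, 4πr² (nm²)."""
        return 4 * math.pi * (self.diameter / 2) ** 2


def lipids_per_vesicle(spec: VesicleSpec) -> int:
    """Number of lipids per vesicle (override, or leaflets × 4πr² / head area)."""
    if spec.lipids_per_vesicle_override is not None:
        return spec.lipids_per_vesicle_override
    return round(spec.leaflets * spec.surface_area / spec.head_area)


def vesicle_concentration(lipid_total: float, spec: VesicleSpec) -> float:
    """Molar vesicle concentration (same unit as lipid_total) = lipid / aggregation number."""
    if lipid_total < 0:
        raise DataError("lipid_total must be >= 0")
    return lipid_total / lipids_per_vesicle(spec)


def proteins_per_vesicle(protein_conc: float, vesicle_conc: float) -> float:
    """Mean number of proteins per vesicle = [protein] / [vesicle]."""
    if protein_conc < 0 or vesicle_conc < 0:
        raise DataError("concentrations must be >= 0")
    if vesicle_conc == 0:
        raise ZeroDivisionError("vesicle concentration is zero")
    return protein_conc / vesicle_conc


def protein_footprint(lipids_per_protein: float, spec: VesicleSpec) -> float:
    """Membrane area occluded by one bound protein (nm²) = lipids engaged × head area."""
    if lipids_per_protein < 0:
        raise DataError("lipids_per_protein must be >= 0")
    return lipids_per_protein * spec.head_area


@dataclass(frozen=True)
class SurfaceOccupancy:
    """Occupied fraction of the outer vesicle surface.

    ``fraction`` is clipped to [0, 1] for reporting; ``raw_fraction``
    keeps the unclipped value and ``exceeds_surface`` flags a physically
    impossible (> 1) load.
    """

    fraction: float
    raw_fraction: float
    exceeds_surface: bool


def surface_fraction_occupied(
    n_proteins: float, footprint: float, spec: VesicleSpec
) -> SurfaceOccupancy:
    """Fraction of the outer-leaflet surface covered by bound protein.

    Uses the single (outer) spherical surface since an interfacially bound
    protein sits on the outside of the vesicle.
    """
    if n_proteins < 0 or footprint < 0:
        raise DataError("inputs must be >= 0")
    raw = n_proteins * footprint / spec.surface_area
    return SurfaceOccupancy(
        fraction=min(raw, 1.0), raw_fraction=raw, exceeds_surface=raw > 1.0
    )
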