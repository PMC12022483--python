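"""Closed-form relaxation kinetics of reversible protein–membrane binding.

The binding scheme is a single reversible bimolecular step

    E + S  <-- k_off / k_on -->  ES

where E is free protein and S is a membrane binding *site*.  A site is not
a single lipid: an interfacially bound protein contacts a patch of lipids,
so the site concentration is a fixed fraction ``c1`` of the accessible
(outer-leaflet) lipid concentration, and ``1/c1`` is the number of lipids
per bound protein.

After rapid mixing the approach to equilibrium is, near equilibrium, a
single exponential with observed rate constant

    k_obs = sqrt( k_on^2 (E - S)^2 + k_off^2 + 2 k_on k_off (E + S) )

which reduces to the familiar pseudo-first-order ``k_obs = k_on [S] + k_off``
when either species is in large excess, but remains exact (as the
linearised relaxation rate) when protein and site concentrations are
comparable — the regime of the stopped-flow experiments this package
models.

Units are fixed package-wide: concentrations in μM, time in s, rates in
s⁻¹ and ``k_on`` in μM⁻¹ s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticParams",
    "BindingConditions",
    "accessible_lipid",
    "site_concentration",
    "kobs_closed_form",
    "kd_from_rates",
    "equilibrium_bound",
    "relaxation_rate_identity",
]


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and stoichiometry factor of the binding scheme.

    Parameters
    ----------
    k_on:
        Association rate constant (μM⁻¹ s⁻¹); must be positive.
    k_off:
        Dissociation rate constant (s⁻¹); non-negative (zero means
        irreversible binding).
    c1:
        Stoichiometry factor converting lipid concentration to binding-site
        concentration (sites per lipid, dimensionless, in (0, 1]).  Its
        reciprocal is the number of lipids engaged per bound protein.
    """

    k_on: float
    k_off: float
    c1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k_on) and self.k_on > 0):
            raise ValueError(f"k_on must be finite and > 0, got {self.k_on!r}")
        if not (math.isfinite(self.k_off) and self.k_off >= 0):
            raise ValueError(f"k_off must be finite and >= 0, got {self.k_off!r}")
        if not (math.isfinite(self.c1) and 0 < self.c1 <= 1):
            raise ValueError(f"c1 must lie in (0, 1], got {self.c1!r}")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant k_off / k_on (μM)."""
        return self.k_off / self.k_on


@dataclass(frozen=True)
class BindingConditions:
    """Mixing-cell composition for one binding experiment.

    ``leaflet_factor`` is the fraction of total lipid accessible to an
    externally added protein; 0.5 counts only the outer leaflet of a
    unilamellar vesicle, assuming near-equal partition of lipid between
    the two leaflets.
    """

    protein_conc: float
    lipid_total: float = 0.0
    leaflet_factor: float = 0.5

    def __post_init__(self) -> None:
        if not (math.isfinite(self.protein_conc) and self.protein_conc > 0):
            raise ValueError(f"protein_conc must be > 0, got {self.protein_conc!r}")
        if not (math.isfinite(self.lipid_total) and self.lipid_total >= 0):
            raise ValueError(f"lipid_total must be >= 0, got {self.lipid_total!r}")
        if not (math.isfinite(self.leaflet_factor) and 0 < self.leaflet_factor <= 1):
            raise ValueError(
                f"leaflet_factor must lie in (0, 1], got {self.leaflet_factor!r}"
            )


def accessible_lipid(conditions: BindingConditions) -> float:
    """Lipid concentration accessible to the protein (μM).

    Total lipid times the leaflet accessibility factor: for LUVs only the
    outer-leaflet lipids can be contacted, so the default factor is 0.5.
    """
    return conditions.lipid_total * conditions.leaflet_factor


def site_concentration(params: KineticParams, accessible_lipid_conc: float) -> float:
    """Binding-site concentration c1 × [L]_accessible (μM)."""
    if accessible_lipid_conc < 0:
        raise ValueError("accessible lipid concentration must be >= 0")
    return params.c1 * accessible_lipid_conc


def kobs_closed_form(params: KineticParams, protein, sites):
    """Observed relaxation rate of the reversible bimolecular step (s⁻¹).

    Evaluates ``sqrt(k_on²(E−S)² + k_off² + 2 k_on k_off (E+S))`` which is
    algebraically ``sqrt((k_on(E+S)+k_off)² − 4 k_on² E S)``, the
    linearised relaxation rate around the binding equilibrium.  Symmetric
    in E and S; collapses to ``k_on·E + k_off`` at S=0 (and vice versa).

    ``protein`` and ``sites`` may be scalars or numpy arrays (broadcast).
    """
    e = np.asarray(protein, dtype=float)
    s = np.asarray(sites, dtype=float)
    if np.any(e < 0) or np.any(s < 0):
        raise ValueError("protein and site concentrations must be >= 0")
    kon, koff = params.k_on, params.k_off
    out = np.sqrt(kon**2 * (e - s) ** 2 + koff**2 + 2 * kon * koff * (e + s))
    if out.ndim == 0:
        return float(out)
    return out


def kd_from_rates(params: KineticParams) -> float:
    """Equilibrium dissociation constant K_D = k_off / k_on (μM)."""
    if params.k_on == 0:
        raise ZeroDivisionError("K_D undefined for k_on = 0")
    return params.k_off / params.k_on


def equilibrium_bound(params: KineticParams, protein: float, sites: float) -> float:
    """Equilibrium complex concentration x_eq (μM).

    The physically admissible root of ``k_on (E−x)(S−x) = k_off x`` with
    0 ≤ x ≤ min(E, S), written in the numerically stable form
    ``x = 2 k_on E S / (b + sqrt(b² − 4 k_on² E S))`` with
    ``b = k_on (E+S) + k_off`` to avoid cancellation when the discriminant
    is close to b.
    """
    e, s = float(protein), float(sites)
    if e < 0 or s < 0:
        raise ValueError("protein and site concentrations must be >= 0")
    if e == 0 or s == 0:
        return 0.0
    kon, koff = params.k_on, params.k_off
    b = kon * (e + s) + koff
    # b² − 4k_on²ES expanded to its cancellation-free form (the k_obs
    # expression), exact even at the degenerate point k_off=0, E=S
    disc = kon**2 * (e - s) ** 2 + koff**2 + 2 * kon * koff * (e + s)
    return 2 * kon * e * s / (b + math.sqrt(disc))


def relaxation_rate_identity(params: KineticParams, protein: float, sites: float) -> float:
    """Relaxation rate via the equilibrium route: λ = k_on(E−x) + k_on(S−x) + k_off.

    Algebraically identical to :func:`kobs_closed_form`; exposed separately
    so the two routes can be cross-checked.
    """
    x = equilibrium_bound(params, protein, sites)
    return params.k_on * (float(protein) - x) + params.k_on * (float(sites) - x) + params.k_off
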